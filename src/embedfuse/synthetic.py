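"""Synthetic multi-model embedding datasets with planted class signal.

The generator emulates the situation the fusion framework is built for: the
same K-class samples observed through several "virtual models" of differing
informativeness.  Each virtual model ``m`` produces, for sample ``i`` with
class ``y_i``::

    x_mi = s_m * mu[m, y_i]  +  w * z_i @ P_m  +  eps,   eps ~ N(0, noise_sd^2)

where ``mu[m, c]`` is a per-(model, class) mean direction drawn once from a
standard normal and normalised to unit length (so ``s_m`` is a
dimensionality-independent signal-to-noise ratio against unit noise),
``s_m`` is the model's signal strength (0 = pure noise model),
``z_i`` is a shared latent factor realisation (identical across models,
projected independently through ``P_m``), and ``w`` is the shared-factor
weight.  The shared factors give positive cross-model correlation, so fused
subsets gain less than the sum of their parts — models carry partly
complementary, partly redundant features, which is the premise the subset
search exploits.

A corruption mechanism perturbs the *test* split only (additive shift plus
variance inflation, magnitude monotone in severity), standing in for
image-space corruption benchmarks at the embedding level.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .embeddings import EmbeddingSet
from .errors import ConfigError
from .registry import ModelSpec, Registry

SPLITS = ("train", "valid", "test")
N_CORRUPTIONS = 11
N_SEVERITIES = 5

_LATENT_DIM = 4  # dimensionality of the shared cross-model factors


@dataclass
class SyntheticConfig:
    """Configuration of one synthetic multi-model dataset.

    Defaults describe a five-model pool in which exactly two models carry
    class signal (strength 2.0) and three are pure noise, observed on a
    binary task with 500/200/200 train/valid/test samples — the planted
    ground truth used throughout the test-bench.
    """

    n_models: int = 5
    dims: Sequence[int] = (16, 16, 16, 16, 16)
    n_classes: int = 2
    n_per_split: Sequence[int] = (500, 200, 200)
    signal_strengths: Sequence[float] = (2.0, 2.0, 0.0, 0.0, 0.0)
    shared_factor_weight: float = 0.3
    noise_sd: float = 1.0
    task_type: str = "binary"
    seed: int = 0

    def validate(self) -> None:
        if self.n_models < 1:
            raise ConfigError("n_models must be >= 1")
        if len(self.dims) != self.n_models:
            raise ConfigError("dims must have length n_models")
        if len(self.signal_strengths) != self.n_models:
            raise ConfigError("signal_strengths must have length n_models")
        if any(d < 1 for d in self.dims):
            raise ConfigError("dims entries must be >= 1")
        if any(s < 0 for s in self.signal_strengths):
            raise ConfigError("signal_strengths entries must be >= 0")
        if self.n_classes < 2:
            raise ConfigError("n_classes must be >= 2")
        if self.task_type not in ("binary", "multiclass", "multilabel"):
            raise ConfigError(f"unknown task_type '{self.task_type}'")
        if self.task_type == "binary" and self.n_classes != 2:
            raise ConfigError("task_type 'binary' requires n_classes == 2")
        if len(self.n_per_split) != 3:
            raise ConfigError("n_per_split must give (train, valid, test) counts")
        if any(n < 1 for n in self.n_per_split):
            raise ConfigError("n_per_split entries must be >= 1")
        if not 0.0 <= self.shared_factor_weight <= 1.0:
            raise ConfigError("shared_factor_weight must be in [0, 1]")
        if self.noise_sd <= 0:
            raise ConfigError("noise_sd must be > 0")

    @property
    def model_names(self) -> list[str]:
        return [f"synth{m}" for m in range(self.n_models)]


@dataclass
class SyntheticDataset:
    """A generated dataset: splits, per-(model, split) embeddings, and truth.

    ``truth`` is the generating config; models with ``signal_strengths > 0``
    are the planted informative models the search should recover.
    """

    splits: Mapping[str, tuple[np.ndarray, np.ndarray]]  # split -> (ids, labels)
    embeddings: Mapping[tuple[str, str], EmbeddingSet]  # (model, split) -> block
    truth: SyntheticConfig
    corruption: tuple[int, int] | None = field(default=None)

    @property
    def model_names(self) -> list[str]:
        return self.truth.model_names

    @property
    def informative_models(self) -> list[str]:
        return [
            name
            for name, s in zip(self.truth.model_names, self.truth.signal_strengths)
            if s > 0
        ]

    def provider(self, model_name: str):
        """A provider callable for ``model_name``, closing over this dataset."""

        def _provider(split: str) -> EmbeddingSet:
            return self.embeddings[(model_name, split)]

        return _provider

    def register_all(self, registry: Registry) -> Registry:
        """Register every virtual model (in generation order) on ``registry``."""
        for name, dim in zip(self.truth.model_names, self.truth.dims):
            registry.register(
                ModelSpec(name=name, dim=int(dim), modality="synthetic"),
                self.provider(name),
            )
        return registry


def _draw_labels(rng: np.random.Generator, n: int, cfg: SyntheticConfig) -> np.ndarray:
    if cfg.task_type == "multilabel":
        # independent labels, each present with probability 0.5
        return rng.integers(0, 2, size=(n, cfg.n_classes)).astype(np.int64)
    return rng.integers(0, cfg.n_classes, size=n).astype(np.int64)


def generate(config: SyntheticConfig) -> SyntheticDataset:
    """Generate a dataset; fully reproducible from ``config.seed``.

    Class means and factor projections are drawn once per model from the
    seeded generator, then each split's samples are drawn in a fixed order,
    so two calls with the same config are element-wise identical.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    # per-(model, class) unit mean directions, drawn once; unit norm makes
    # signal_strengths an SNR that does not grow with dimensionality
    means = []
    for d in config.dims:
        mu = rng.normal(size=(config.n_classes, d))
        means.append(mu / np.linalg.norm(mu, axis=1, keepdims=True))
    # per-model projection of the shared latent factors
    projections = [
        rng.normal(size=(_LATENT_DIM, d)) / np.sqrt(_LATENT_DIM) for d in config.dims
    ]

    splits: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    embeddings: dict[tuple[str, str], EmbeddingSet] = {}
    for split, n in zip(SPLITS, config.n_per_split):
        labels = _draw_labels(rng, n, config)
        ids = np.array([f"{split}-{i:06d}" for i in range(n)])
        z = rng.normal(size=(n, _LATENT_DIM))  # shared across models
        splits[split] = (ids, labels)
        for m, name in enumerate(config.model_names):
            s = config.signal_strengths[m]
            if config.task_type == "multilabel":
                signal = s * (labels @ means[m])
            else:
                signal = s * means[m][labels]
            shared = config.shared_factor_weight * (z @ projections[m])
            noise = rng.normal(scale=config.noise_sd, size=(n, config.dims[m]))
            embeddings[(name, split)] = EmbeddingSet(
                model_name=name,
                split=split,
                X=signal + shared + noise,
                sample_ids=ids,
                labels=labels,
            )
    return SyntheticDataset(splits=splits, embeddings=embeddings, truth=config)


def corrupt(
    dataset: SyntheticDataset,
    severity: int,
    corruption_id: int = 1,
    seed: int = 0,
) -> SyntheticDataset:
    """Perturb the test split; train and valid are returned untouched.

    Each corruption id fixes a random direction of additive shift and a
    variance-inflation profile; both scale linearly with ``severity`` (1-5),
    so the probe's balanced error is (stochastically) non-decreasing in
    severity.
    """
    if not 1 <= severity <= N_SEVERITIES:
        raise ConfigError(f"severity must be in 1..{N_SEVERITIES}, got {severity}")
    if not 1 <= corruption_id <= N_CORRUPTIONS:
        raise ConfigError(
            f"corruption_id must be in 1..{N_CORRUPTIONS}, got {corruption_id}"
        )

    out_embeddings = dict(dataset.embeddings)
    # per-severity magnitudes: shift grows linearly, noise sd with it
    shift_scale = 0.5 * severity
    noise_scale = 0.4 * severity
    for m, name in enumerate(dataset.truth.model_names):
        block = dataset.embeddings[(name, "test")]
        # direction is a function of (corruption_id, model), not of severity,
        # so severities form a chain along a fixed perturbation axis
        dir_rng = np.random.default_rng((corruption_id, m, dataset.truth.seed))
        direction = dir_rng.normal(size=block.dim)
        direction /= np.linalg.norm(direction)
        noise_rng = np.random.default_rng((seed, corruption_id, m))
        noise = noise_rng.normal(size=block.X.shape)
        X = block.X + shift_scale * direction + noise_scale * noise
        out_embeddings[(name, "test")] = EmbeddingSet(
            model_name=name,
            split="test",
            X=X,
            sample_ids=block.sample_ids.copy(),
            labels=None if block.labels is None else block.labels.copy(),
        )
    return SyntheticDataset(
        splits=copy.deepcopy(dict(dataset.splits)),
        embeddings=out_embeddings,
        truth=dataset.truth,
        corruption=(corruption_id, severity),
    )
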