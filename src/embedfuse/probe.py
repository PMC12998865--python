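"""The probing classifier: gradient-boosted trees on frozen embeddings.

Embedding quality is measured by training a lightweight XGBoost probe on the
fused embeddings — no backbone fine-tuning anywhere.  Two regimes:

* **Search phase**: one fixed configuration (250 trees, learning rate 0.1,
  depth 6) applied to every candidate subset, so validation-accuracy
  differences reflect the embeddings, not the classifier.
* **Final evaluation**: a budgeted hyperparameter tuner (default 100 trials
  over nine parameters) selects the configuration with the highest
  validation accuracy; the default configuration is always trial 0, so the
  tuner can never do worse than the fixed probe on validation.

Objectives follow the task: multi-class softprob, binary logistic, or
one-vs-rest binary probes for multi-label tasks.  All fits are single-thread
and seeded, so results are reproducible bit-for-bit.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde
from xgboost import XGBClassifier

from .errors import ConfigError, UndefinedMetricError
from .fusion import FusedEmbeddings
from .metrics import MetricReport, accuracy as _accuracy, auc_roc


@dataclass
class ProbeConfig:
    """XGBoost probe configuration.

    The defaults (250 trees, learning rate 0.1, depth 6) are the fixed
    search-phase configuration; ``extra`` carries any further tuned
    hyperparameters passed straight to XGBoost.
    """

    n_estimators: int = 250
    learning_rate: float = 0.1
    max_depth: int = 6
    seed: int = 0
    extra: dict = field(default_factory=dict)

    def xgb_params(self) -> dict:
        return {
            "n_estimators": self.n_estimators,
            "learning_rate": self.learning_rate,
            "max_depth": self.max_depth,
            "random_state": self.seed,
            "n_jobs": 1,
            "tree_method": "hist",
            **self.extra,
        }

    def flat_params(self) -> dict:
        return {
            "n_estimators": self.n_estimators,
            "learning_rate": self.learning_rate,
            "max_depth": self.max_depth,
            **self.extra,
        }


def _as_matrix(data) -> np.ndarray:
    if isinstance(data, FusedEmbeddings):
        return data.matrix
    return np.asarray(data)


def infer_task_type(labels: np.ndarray) -> str:
    labels = np.asarray(labels)
    if labels.ndim == 2:
        return "multilabel"
    return "binary" if np.unique(labels).size == 2 else "multiclass"


@dataclass
class FittedProbe:
    """A fitted probe: one booster, or one per label for multi-label tasks."""

    task_type: str
    config: ProbeConfig
    models: list  # length 1, or n_labels for multilabel
    classes_: np.ndarray | None = None

    def predict_proba(self, data) -> np.ndarray:
        """Per-class probabilities: ``(n, K)``, or ``(n, L)`` positive-class
        probabilities for multi-label."""
        X = _as_matrix(data)
        if self.task_type == "multilabel":
            return np.column_stack([m.predict_proba(X)[:, 1] for m in self.models])
        return self.models[0].predict_proba(X)

    def predict(self, data) -> np.ndarray:
        X = _as_matrix(data)
        if self.task_type == "multilabel":
            return (self.predict_proba(X) >= 0.5).astype(int)
        idx = self.predict_proba(X).argmax(axis=1)
        return self.classes_[idx]


def fit_probe(
    train,
    train_labels: np.ndarray,
    config: ProbeConfig | None = None,
    task_type: str | None = None,
    split_name: str = "train",
) -> FittedProbe:
    """Fit the probe on fused embeddings.

    ``task_type`` is inferred from the label shape when not given.  A single
    class in the training labels (or in one multi-label column) is a
    degenerate fit and raises an error naming the split.
    """
    config = config or ProbeConfig()
    X = _as_matrix(train)
    y = np.asarray(train_labels)
    task_type = task_type or infer_task_type(y)

    if task_type == "multilabel":
        models = []
        for j in range(y.shape[1]):
            if np.unique(y[:, j]).size < 2:
                raise UndefinedMetricError(
                    f"label {j} has a single class in split '{split_name}'"
                )
            clf = XGBClassifier(objective="binary:logistic", **config.xgb_params())
            clf.fit(X, y[:, j])
            models.append(clf)
        return FittedProbe(task_type=task_type, config=config, models=models)

    if np.unique(y).size < 2:
        raise UndefinedMetricError(f"single class in split '{split_name}'")
    objective = "binary:logistic" if task_type == "binary" else "multi:softprob"
    clf = XGBClassifier(objective=objective, **config.xgb_params())
    clf.fit(X, y)
    return FittedProbe(
        task_type=task_type, config=config, models=[clf], classes_=clf.classes_
    )


def probe_accuracy(probe: FittedProbe, data, labels: np.ndarray) -> float:
    return _accuracy(probe.predict(data), np.asarray(labels))


def score_probe(probe: FittedProbe, data, labels: np.ndarray) -> MetricReport:
    """Accuracy and AUC of a fitted probe on one split."""
    labels = np.asarray(labels)
    scores = probe.predict_proba(data)
    return MetricReport(
        accuracy=probe_accuracy(probe, data, labels),
        auc=auc_roc(scores, labels, probe.task_type),
    )


def score_multi_seed(
    train,
    train_labels: np.ndarray,
    test,
    test_labels: np.ndarray,
    config: ProbeConfig | None = None,
    n_runs: int = 3,
    task_type: str | None = None,
) -> MetricReport:
    """Refit the probe under ``n_runs`` seeds and report per-seed and mean
    accuracy/AUC.  Seeds are ``config.seed + i``."""
    config = config or ProbeConfig()
    per_seed: list[tuple[int, float, float]] = []
    for i in range(n_runs):
        cfg = replace(config, seed=config.seed + i)
        probe = fit_probe(train, train_labels, cfg, task_type=task_type)
        rep = score_probe(probe, test, test_labels)
        per_seed.append((cfg.seed, rep.accuracy, rep.auc))
    return MetricReport.from_runs(per_seed)


# --- hyperparameter tuning ------------------------------------------------

# nine tunable hyperparameters; (kind, low, high)
DEFAULT_SEARCH_SPACE: dict[str, tuple[str, float, float]] = {
    "n_estimators": ("int", 50, 1000),
    "learning_rate": ("logfloat", 0.01, 0.3),
    "max_depth": ("int", 3, 10),
    "min_child_weight": ("int", 1, 10),
    "subsample": ("float", 0.5, 1.0),
    "colsample_bytree": ("float", 0.5, 1.0),
    "gamma": ("float", 0.0, 5.0),
    "reg_alpha": ("float", 0.0, 5.0),
    "reg_lambda": ("float", 0.0, 5.0),
}

# booster defaults used to complete the default config on axes it leaves
# untouched, so trial 0 is a full point of the search space
_BOOSTER_DEFAULTS = {
    "min_child_weight": 1,
    "subsample": 1.0,
    "colsample_bytree": 1.0,
    "gamma": 0.0,
    "reg_alpha": 0.0,
    "reg_lambda": 1.0,
}

Sampler = Callable[[np.random.Generator, Mapping, Sequence[tuple[dict, float]]], dict]


def random_sampler(rng, space, history) -> dict:
    """Uniform (log-uniform for logfloat) sample from the search space."""
    params = {}
    for name, (kind, lo, hi) in space.items():
        if kind == "int":
            params[name] = int(rng.integers(int(lo), int(hi) + 1))
        elif kind == "float":
            params[name] = float(rng.uniform(lo, hi))
        elif kind == "logfloat":
            params[name] = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
        else:
            raise ConfigError(f"unknown parameter kind '{kind}' for '{name}'")
    return params


def tpe_sampler(rng, space, history, gamma: float = 0.25, n_candidates: int = 24,
                n_startup: int = 10) -> dict:
    """Tree-structured-estimator sampler.

    After a random warm-up, trials are split into the top ``gamma`` fraction
    ("good") and the rest; per parameter, one-dimensional kernel density
    estimates l(x) (good) and g(x) (bad) are formed, and the candidate
    maximising the product of l(x)/g(x) ratios is proposed.
    """
    if len(history) < n_startup:
        return random_sampler(rng, space, history)
    scores = np.array([s for _, s in history])
    n_good = max(2, int(np.ceil(gamma * len(history))))
    good_idx = set(np.argsort(-scores)[:n_good].tolist())

    def to_internal(name, value):
        kind, lo, hi = space[name]
        return np.log(value) if kind == "logfloat" else float(value)

    candidates = [random_sampler(rng, space, history) for _ in range(n_candidates)]
    log_ratios = np.zeros(n_candidates)
    for name, (kind, lo, hi) in space.items():
        good = np.array([to_internal(name, h[0][name])
                         for i, h in enumerate(history) if i in good_idx])
        bad = np.array([to_internal(name, h[0][name])
                        for i, h in enumerate(history) if i not in good_idx])
        cand = np.array([to_internal(name, c[name]) for c in candidates])
        if np.unique(good).size < 2 or np.unique(bad).size < 2:
            continue  # degenerate KDE; parameter contributes no preference
        l_kde = gaussian_kde(good)
        g_kde = gaussian_kde(bad)
        log_ratios += np.log(l_kde(cand) + 1e-12) - np.log(g_kde(cand) + 1e-12)
    return candidates[int(np.argmax(log_ratios))]


SAMPLERS: dict[str, Sampler] = {"tpe": tpe_sampler, "random": random_sampler}


@dataclass
class TunerConfig:
    """Budgeted hyperparameter search over the probe.

    The default space has exactly nine tunable hyperparameters; the objective
    is validation accuracy.  ``sampler`` is "tpe" (default) or "random"; any
    callable with the sampler signature also works.
    """

    n_trials: int = 100
    search_space: dict = field(default_factory=lambda: dict(DEFAULT_SEARCH_SPACE))
    objective_metric: str = "accuracy"
    sampler: str | Sampler = "tpe"
    seed: int = 0


def tune_probe(
    train,
    train_labels: np.ndarray,
    valid,
    valid_labels: np.ndarray,
    tuner: TunerConfig | None = None,
    task_type: str | None = None,
) -> tuple[ProbeConfig, pd.DataFrame]:
    """Budgeted search for the probe configuration maximising validation
    accuracy.

    Trial 0 always evaluates the default configuration, so the returned
    config never scores below the default on the validation split.  Returns
    the best config and the full trial log (``trial, params_json,
    valid_accuracy``), reproducible given the tuner seed.
    """
    tuner = tuner or TunerConfig()
    if tuner.n_trials < 1:
        raise ConfigError("n_trials must be >= 1")
    if not tuner.search_space:
        raise ConfigError("search_space is empty")
    sampler = SAMPLERS[tuner.sampler] if isinstance(tuner.sampler, str) else tuner.sampler
    rng = np.random.default_rng(tuner.seed)

    default = ProbeConfig(seed=tuner.seed)
    history: list[tuple[dict, float]] = []
    rows = []
    best_cfg, best_score = None, -np.inf
    for trial in range(tuner.n_trials):
        if trial == 0:
            params = default.flat_params()
            for name, (kind, lo, hi) in tuner.search_space.items():
                if name not in params:
                    fallback = _BOOSTER_DEFAULTS.get(name, (lo + hi) / 2)
                    params[name] = min(max(fallback, lo), hi)
        else:
            params = sampler(rng, tuner.search_space, history)
        cfg = ProbeConfig(
            n_estimators=int(params["n_estimators"]),
            learning_rate=float(params["learning_rate"]),
            max_depth=int(params["max_depth"]),
            seed=tuner.seed,
            extra={k: v for k, v in params.items()
                   if k not in ("n_estimators", "learning_rate", "max_depth")},
        )
        probe = fit_probe(train, train_labels, cfg, task_type=task_type)
        score = probe_accuracy(probe, valid, np.asarray(valid_labels))
        history.append((params, score))
        rows.append({"trial": trial, "params_json": json.dumps(params),
                     "valid_accuracy": score})
        if score > best_score:
            best_cfg, best_score = cfg, score
    assert best_cfg is not None
    return best_cfg, pd.DataFrame(rows)
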