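"""Provider registry: the ordered pool of embedding models.

A *provider* is any callable ``provider(split: str) -> EmbeddingSet`` that
returns the embeddings of one registered model for one dataset split.
Providers own their preprocessing entirely; the framework never touches the
raw inputs.  The shipped providers are synthetic (see
:mod:`embedfuse.synthetic`) and a trivial flatten-pixels provider for NPZ
image bundles (:func:`embedfuse.io.flatten_pixels_provider`), so the package
runs end to end without downloading any pre-trained weights.  Adapters that
wrap real pre-trained encoders plug in through the same callable.

Registration order is load-bearing: it fixes the canonical concatenation
order used by every fusion, and it is never re-sorted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterator, Mapping

from .embeddings import EmbeddingSet
from .errors import (
    DimensionMismatchError,
    DuplicateModelError,
    ProviderError,
    UnknownModelError,
)

Provider = Callable[[str], EmbeddingSet]


@dataclass(frozen=True)
class ModelSpec:
    """Registry metadata for one embedding provider.

    ``dim`` is the embedding dimensionality the provider promises; it is
    checked lazily, at extraction time.  ``modality`` is a free-text tag
    ("histopathology", "radiology", "synthetic", ...), and ``metadata`` holds
    optional descriptive strings such as the pre-training corpus or the
    encoder family.
    """

    name: str
    dim: int
    modality: str = "unspecified"
    metadata: Mapping[str, str] | None = None

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("model name must be non-empty")
        if self.dim < 1:
            raise ValueError(f"dim must be >= 1, got {self.dim}")


class Registry:
    """Ordered pool of registered models.

    Iteration yields :class:`ModelSpec` objects in insertion order — this
    order IS the concatenation order and is deliberately never re-sorted.
    """

    def __init__(self) -> None:
        self._specs: dict[str, ModelSpec] = {}
        self._providers: dict[str, Provider] = {}

    def register(self, spec: ModelSpec, provider: Provider) -> "Registry":
        """Append ``spec`` to the pool and bind its provider.

        Raises :class:`DuplicateModelError` if the name is already taken.
        Returns ``self`` so calls can be chained.
        """
        if spec.name in self._specs:
            raise DuplicateModelError(f"model '{spec.name}' is already registered")
        self._specs[spec.name] = spec
        self._providers[spec.name] = provider
        return self

    def spec(self, name: str) -> ModelSpec:
        try:
            return self._specs[name]
        except KeyError:
            raise UnknownModelError(f"model '{name}' is not registered") from None

    def provider(self, name: str) -> Provider:
        self.spec(name)
        return self._providers[name]

    @property
    def names(self) -> list[str]:
        return list(self._specs)

    def __len__(self) -> int:
        return len(self._specs)

    def __contains__(self, name: object) -> bool:
        return name in self._specs

    def __iter__(self) -> Iterator[ModelSpec]:
        return iter(self._specs.values())

    def subset_order(self, names: set[str] | list[str]) -> list[str]:
        """Return ``names`` sorted into registry (concatenation) order."""
        wanted = set(names)
        unknown = wanted - set(self._specs)
        if unknown:
            raise UnknownModelError(f"models not registered: {sorted(unknown)}")
        return [n for n in self._specs if n in wanted]

    def extract_embeddings(self, model_name: str, split: str) -> EmbeddingSet:
        """Invoke a model's provider on a split and validate the contract.

        The returned block must have width equal to the registered ``dim``;
        a mismatch raises :class:`DimensionMismatchError` naming the model
        and both dimensions.  Provider exceptions are re-raised as
        :class:`ProviderError` with the model name attached.
        """
        spec = self.spec(model_name)
        provider = self._providers[model_name]
        try:
            emb = provider(split)
        except Exception as exc:  # noqa: BLE001 - provider is third-party code
            raise ProviderError(f"provider '{model_name}' failed on split "
                                f"'{split}': {exc}") from exc
        if emb.dim != spec.dim:
            raise DimensionMismatchError(
                f"model '{model_name}': provider returned dim {emb.dim}, "
                f"spec declares dim {spec.dim}"
            )
        return emb


def register(registry: Registry, spec: ModelSpec, provider: Provider) -> Registry:
    """Functional alias for :meth:`Registry.register`."""
    return registry.register(spec, provider)


def extract_embeddings(registry: Registry, model_name: str, split: str) -> EmbeddingSet:
    """Functional alias for :meth:`Registry.extract_embeddings`."""
    return registry.extract_embeddings(model_name, split)
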