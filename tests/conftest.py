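import numpy as np
import pytest

from embedfuse import ProbeConfig, Registry, SyntheticConfig, generate


@pytest.fixture(scope="session")
def tiny_dataset():
    """Three virtual models, two informative and one pure noise, desk scale."""
    return generate(
        SyntheticConfig(
            n_models=3,
            dims=(8, 8, 8),
            n_classes=2,
            n_per_split=(150, 80, 80),
            signal_strengths=(2.0, 2.0, 0.0),
            task_type="binary",
            seed=7,
        )
    )


@pytest.fixture()
def tiny_registry(tiny_dataset):
    registry = Registry()
    tiny_dataset.register_all(registry)
    return registry


@pytest.fixture(scope="session")
def fast_probe():
    """A cheap probe configuration for contract tests (not the search default)."""
    return ProbeConfig(n_estimators=30, max_depth=3)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
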