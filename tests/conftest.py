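import numpy as np
import pytest

from multinoise import (
    BinnedDataset,
    MultistageModel,
    NoiseParams,
    SoftplusParams,
    simulate_responses,
)


@pytest.fixture(scope="session")
def mixed_model():
    """A model in which every noise source contributes."""
    return MultistageModel(
        SoftplusParams(1.0, 2.0, 0.0, 0.0),
        NoiseParams(0.5, 1.0, 0.3, 1.0, "gaussian"),
    )


@pytest.fixture(scope="session")
def mixture_model():
    return MultistageModel(
        SoftplusParams(1.0, 2.0, 0.0, 0.0),
        NoiseParams(0.5, 1.0, 0.3, 0.6, "mixture"),
    )


@pytest.fixture(scope="session")
def small_dataset(mixed_model):
    rng = np.random.default_rng(42)
    x = rng.standard_normal(800)
    counts = simulate_responses(mixed_model, x, rng=rng)
    return BinnedDataset(x, counts)


def random_model(rng, variant="gaussian"):
    """A random but numerically benign model for oracle sweeps."""
    nl = SoftplusParams(
        rng.uniform(0.5, 3.0),
        rng.uniform(0.5, 3.0),
        rng.uniform(-1.5, 1.5),
        rng.uniform(0.0, 0.5),
    )
    p_down = rng.uniform(0.2, 1.0) if variant == "mixture" else 1.0
    ns = NoiseParams(
        rng.uniform(0.05, 0.8),
        rng.uniform(0.05, 1.2),
        rng.uniform(0.05, 1.0),
        p_down,
        variant,
    )
    return MultistageModel(nl, ns)
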