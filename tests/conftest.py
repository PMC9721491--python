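import numpy as np
import pytest

from fatecommit import SimConfig, canonical_trace, simulate_population


@pytest.fixture(scope="session")
def canonical():
    """Noise-free canonical differentiating trace (PPARG + FABP4, 0-96 h)."""
    return canonical_trace()


@pytest.fixture(scope="session")
def canonical_undiff():
    return canonical_trace(fate="undifferentiated")


@pytest.fixture(scope="session")
def default_pop():
    """One default population, reused by read-only tests."""
    return simulate_population(SimConfig(n_cells=400, seed=11))


@pytest.fixture(scope="session")
def clean_pop():
    """Same structural draws as an artifact-free, noise-free population."""
    return simulate_population(
        SimConfig(n_cells=400, seed=11, sigma_m=0.0, p_dropout=0.0,
                  p_late_start=0.0, p_spike=0.0)
    )


def normalized_pparg(trace, P_basal=100.0, fold_P=8.0):
    return (trace.values("PPARG") / P_basal - 1.0) / (fold_P - 1.0)


@pytest.fixture(scope="session")
def norm():
    return normalized_pparg
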