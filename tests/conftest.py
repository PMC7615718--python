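import numpy as np
import pytest

from rpodflow import (
    SyntheticFlowSpec,
    build_snapshot_matrix,
    generate_synthetic_flow,
    pod,
)


@pytest.fixture(scope="session")
def small_spec():
    """A fast, fully featured synthetic spec (2 cycles, small grid)."""
    return SyntheticFlowSpec(
        grid_nx=10,
        grid_ny=10,
        n_cycles=2,
        snapshots_per_cycle=18,
        singular_values_true=(10.0, 5.0, 2.0),
        rng_seed=7,
    )


@pytest.fixture(scope="session")
def clean_flow():
    """Noise- and outlier-free series with planted sigma = (10, 5, 2)."""
    spec = SyntheticFlowSpec(
        singular_values_true=(10.0, 5.0, 2.0),
        gaussian_noise_sd=0.0,
        outlier_fraction=0.0,
        rng_seed=3,
    )
    return generate_synthetic_flow(spec)


@pytest.fixture(scope="session")
def clean_basis(clean_flow):
    series, _ = clean_flow
    return pod(build_snapshot_matrix(series))


@pytest.fixture
def rng():
    return np.random.default_rng(42)
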