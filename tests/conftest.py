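import numpy as np
import pytest

from gradflex import AnalysisConfig, SyntheticSpec, make_synthetic_atlas, simulate_dataset


@pytest.fixture(scope="session")
def tiny_atlas():
    return make_synthetic_atlas(n_parcels=6, voxels_per_parcel=8, seed=0)


@pytest.fixture(scope="session")
def small_spec():
    return SyntheticSpec(
        n_participants=14, n_trials=36, n_runs=3, n_parcels=20,
        voxels_per_parcel=27, seed=42,
    )


@pytest.fixture(scope="session")
def small_dataset(small_spec):
    return simulate_dataset(small_spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
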