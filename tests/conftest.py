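import numpy as np
import pytest

import connstab as cs


@pytest.fixture(scope="session")
def parcellation():
    """Small mirror-symmetric parcellation: 6 pairs + 2 medial nodes."""
    return cs.make_parcellation(n_pairs=6, n_medial=2, extent=100.0, seed=7)


@pytest.fixture(scope="session")
def flat_dataset(parcellation):
    """Synthetic study with a flat-profile condition effect (8 subjects,
    2 conditions, 120 time points)."""
    truth = cs.default_truth(parcellation, effect_profile="flat", seed=11)
    return cs.sample_dataset(parcellation, truth, 8, 120, seed=13)


@pytest.fixture(scope="session")
def flat_connectivity(flat_dataset):
    return cs.connectivity_from_timeseries(flat_dataset)


@pytest.fixture(scope="session")
def two_group_connectivity():
    """Two groups x two conditions, for permutation/bootstrap paths that
    exercise group relabeling."""
    parc = cs.make_parcellation(n_pairs=5, extent=90.0, seed=3)
    truth = cs.default_truth(parc, effect_profile="flat", seed=5)
    ds = cs.sample_dataset(parc, truth, 6, 100, seed=9, groups=("g1", "g2"))
    return cs.connectivity_from_timeseries(ds)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
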