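import numpy as np
import pytest

from mcdratchet import default_params
from mcdratchet.params import SimParams


@pytest.fixture
def defaults() -> SimParams:
    return default_params()


@pytest.fixture
def tiny() -> SimParams:
    """Small, cheap parameter set for unit tests: 1x0.5 µm domain,
    40 McdA, short runs.  Physics rates kept at defaults."""
    p = default_params()
    p.geometry.nucleoid_length = 1.0
    p.geometry.nucleoid_width = 0.5
    p.kinetics.n_mcdA = 40
    p.kinetics.n_mcdB_per_carb = 20
    p.run.duration = 1.0
    p.run.record_interval = 0.1
    return p


@pytest.fixture
def quiet(tiny) -> SimParams:
    """tiny with all stochastic channels and forces off: nothing moves."""
    p = tiny.copy()
    p.kinetics.k_off_intrinsic = 0.0
    p.kinetics.k_rebind = 0.0
    p.kinetics.k_bond_on = 0.0
    p.kinetics.k_bond_off = 0.0
    p.kinetics.D_mcdA_nucleoid = 0.0
    p.kinetics.D_carb = 0.0
    p.springs.k_AB = 0.0
    p.springs.k_self = 0.0
    return p


def assert_states_equal(a, b):
    assert a.time == b.time
    np.testing.assert_array_equal(a.centers, b.centers)
    np.testing.assert_array_equal(a.offsets, b.offsets)
    np.testing.assert_array_equal(a.site_bond, b.site_bond)
    np.testing.assert_array_equal(a.a_site, b.a_site)
    np.testing.assert_array_equal(a.a_bond_carb, b.a_bond_carb)
    np.testing.assert_array_equal(a.a_bond_site, b.a_bond_site)
    np.testing.assert_array_equal(a.occ, b.occ)
    np.testing.assert_array_equal(a.rng, b.rng)
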