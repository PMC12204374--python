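"""Stochastic transition channels checked against closed-form oracles.

Each channel (hopping, rebinding, intrinsic release, bond formation,
bond breaking) is driven in isolation and compared with the analytic law
it discretizes: lattice random-walk MSD, two-state equilibrium, binomial
survival, exponential lifetimes, and the deterministic matching rule.
"""

import math

import numpy as np
import pytest

from mcdratchet import engine, kinetics
from mcdratchet.engine import init_state


def _isolated(params, **rates):
    """Copy of params with every stochastic channel off except overrides."""
    p = params.copy()
    p.kinetics.k_off_intrinsic = 0.0
    p.kinetics.k_rebind = 0.0
    p.kinetics.k_bond_on = 0.0
    p.kinetics.k_bond_off = 0.0
    p.kinetics.D_mcdA_nucleoid = 0.0
    p.kinetics.D_carb = 0.0
    p.springs.k_AB = 0.0
    p.springs.k_self = 0.0
    for key, val in rates.items():
        setattr(p.kinetics, key, val)
    return p


class TestHop:
    def test_zero_rate_is_static(self, tiny):
        p = _isolated(tiny)
        st = init_state(p, 0)
        st2 = kinetics.hop_mcdA(st, p)
        np.testing.assert_array_equal(st.a_site, st2.a_site)

    def test_single_particle_msd_matches_lattice_walk(self, tiny):
        """For one walker, per-step MSD = (4 D_A/a^2) dt * a^2 = 4 D_A dt."""
        p = _isolated(tiny, D_mcdA_nucleoid=0.05)
        p.kinetics.n_mcdA = 1
        a = p.geometry.lattice_spacing
        st0 = init_state(p, 0)
        nx, ny = engine.lattice_shape(p)
        engine.place_mcdA(st0, 0, nx // 2, ny // 2)
        nsteps, nrep = 40, 300
        sq = []
        st = st0.copy()
        for rep in range(nrep):
            st.rng[0] = np.uint64(1000 + rep)
            s = st.copy()
            for _ in range(nsteps):
                s = kinetics.hop_mcdA(s, p)
            d = (s.a_site[0] - st.a_site[0]).astype(float) * a
            sq.append(d @ d)
        sq = np.asarray(sq)
        expected = 4.0 * p.kinetics.D_mcdA_nucleoid * 1e6 * p.run.dt * nsteps
        se = sq.std(ddof=1) / math.sqrt(nrep)
        assert abs(sq.mean() - expected) < 3 * se

    def test_full_lattice_blocks_all_hops(self, tiny):
        p = _isolated(tiny, D_mcdA_nucleoid=10.0)
        nx, ny = engine.lattice_shape(p)
        p.kinetics.n_mcdA = nx * ny
        p.kinetics.k_rebind = 1e9   # fill the lattice completely at init
        p.kinetics.k_off_intrinsic = 0.0
        st = init_state(p, 0)
        assert st.n_nucleoid == nx * ny
        p.kinetics.k_rebind = 0.0
        st2 = kinetics.hop_mcdA(st, p)
        np.testing.assert_array_equal(st.a_site, st2.a_site)


class TestRebindUnbind:
    def test_zero_rates_static(self, tiny):
        p = _isolated(tiny)
        st = init_state(p, 3)
        assert kinetics.rebind_mcdA(st, p).n_cytoplasm == st.n_cytoplasm
        assert kinetics.unbind_mcdA_intrinsic(st, p).n_nucleoid == st.n_nucleoid

    def test_two_state_equilibrium_fraction(self, tiny):
        """Long-run bound fraction -> k_rebind/(k_rebind+k_off)."""
        p = _isolated(tiny, k_rebind=20.0, k_off_intrinsic=10.0)
        st = init_state(p, 0)
        nsteps, burn = 4000, 1000
        fracs = []
        for i in range(nsteps):
            st = kinetics.rebind_mcdA(st, p)
            st = kinetics.unbind_mcdA_intrinsic(st, p)
            if i >= burn and i % 100 == 0:  # > 1 relaxation time apart
                fracs.append(st.n_nucleoid / st.n_mcdA)
        fracs = np.asarray(fracs)
        expected = 20.0 / 30.0
        se = fracs.std(ddof=1) / math.sqrt(len(fracs))
        assert abs(fracs.mean() - expected) < 3 * max(se, 1e-6)

    def test_no_empty_site_leaves_particle_cytoplasmic(self, tiny):
        p = _isolated(tiny, k_rebind=1e9)
        nx, ny = engine.lattice_shape(p)
        p.kinetics.n_mcdA = nx * ny + 5
        st = init_state(p, 1)
        for _ in range(3):
            st = kinetics.rebind_mcdA(st, p)
        assert st.n_nucleoid == nx * ny
        assert st.n_cytoplasm == 5
        st.check_consistency()

    def test_unbind_survival_is_binomial(self, tiny):
        """Survivors on the nucleoid after time t follow
        Binomial(N, exp(-k_off t))."""
        p = _isolated(tiny, k_off_intrinsic=5.0)
        p.kinetics.n_mcdA = 500
        p.kinetics.k_rebind = 1e9
        st = init_state(p, 0)
        nx, ny = engine.lattice_shape(p)
        assert st.n_nucleoid == min(500, nx * ny)
        n0 = st.n_nucleoid
        p.kinetics.k_rebind = 0.0
        nsteps = 200
        for _ in range(nsteps):
            st = kinetics.unbind_mcdA_intrinsic(st, p)
        t = nsteps * p.run.dt
        surv = math.exp(-p.kinetics.k_off_intrinsic * t)
        se = math.sqrt(n0 * surv * (1 - surv))
        assert abs(st.n_nucleoid - n0 * surv) < 3 * se

    def test_bonded_particles_never_unbind_intrinsically(self, tiny):
        p = _isolated(tiny, k_off_intrinsic=1e9)
        st = init_state(p, 2)
        nuc = [i for i in range(st.n_mcdA) if st.a_site[i, 0] >= 0]
        for idx, i in enumerate(nuc[:3]):
            engine.attach_bond(st, 0, idx, i)
        st2 = kinetics.unbind_mcdA_intrinsic(st, p)
        for i in nuc[:3]:
            assert st2.a_site[i, 0] >= 0


class TestFormBonds:
    def _bond_setup(self, tiny, offsets, mcdA_sites, k_bond_on=1e9):
        p = _isolated(tiny, k_bond_on=k_bond_on)
        p.run.n_carboxysomes = 1
        p.kinetics.n_mcdB_per_carb = offsets.shape[1]
        p.kinetics.n_mcdA = max(len(mcdA_sites), 1)
        st = init_state(p, 0, mcdB_offsets=offsets)
        for i, (ix, iy) in enumerate(mcdA_sites):
            engine.place_mcdA(st, i, ix, iy)
        return p, st

    def test_out_of_range_forms_nothing(self, tiny):
        offs = np.zeros((1, 1, 2))
        p, st = self._bond_setup(tiny, offs, [(0, 0)])  # far corner
        st2 = kinetics.form_bonds(st, p)
        assert not st2.bonds(p)

    def test_in_range_saturating_rate_binds(self, tiny):
        offs = np.zeros((1, 1, 2))
        p, st = self._bond_setup(tiny, offs, [])
        nx, ny = engine.lattice_shape(p)
        engine.place_mcdA(st, 0, nx // 2, ny // 2)  # within 25 nm of center
        st2 = kinetics.form_bonds(st, p)
        bonds = st2.bonds(p)
        assert len(bonds) == 1
        assert bonds[0].mcdA_id == 0 and bonds[0].site_index == 0

    def test_two_sites_compete_nearer_wins(self, tiny):
        """Two free McdB sites in range of a single McdA: exactly one bond
        forms, to the nearer site (matching rule, enumerated by hand)."""
        p0 = _isolated(tiny, k_bond_on=1e9)
        p0.run.n_carboxysomes = 1
        p0.kinetics.n_mcdB_per_carb = 2
        p0.kinetics.n_mcdA = 1
        nx, ny = engine.lattice_shape(p0)
        a = p0.geometry.lattice_spacing
        anchor = np.array([(nx // 2 + 0.5) * a, (ny // 2 + 0.5) * a])
        st = init_state(p0, 0, mcdB_offsets=np.zeros((1, 2, 2)))
        st.centers[0] = anchor + np.array([0.0, 1.0])
        # site 1 nearer to the anchor than site 0
        st.offsets[0, 0] = [20.0, 0.0]
        st.offsets[0, 1] = [5.0, 0.0]
        engine.place_mcdA(st, 0, nx // 2, ny // 2)
        st2 = kinetics.form_bonds(st, p0)
        bonds = st2.bonds(p0)
        assert len(bonds) == 1
        assert bonds[0].site_index == 1


class TestBreakBonds:
    def _single_bond_state(self, tiny, **rates):
        p = _isolated(tiny, **rates)
        p.run.n_carboxysomes = 1
        p.kinetics.n_mcdB_per_carb = 1
        p.kinetics.n_mcdA = 1
        st = init_state(p, 1, mcdB_offsets=np.zeros((1, 1, 2)))
        nx, ny = engine.lattice_shape(p)
        engine.place_mcdA(st, 0, nx // 2, ny // 2)
        engine.attach_bond(st, 0, 0, 0)
        a = p.geometry.lattice_spacing
        st.centers[0] = [(nx // 2 + 0.5) * a, (ny // 2 + 0.5) * a]
        return p, st

    def test_zero_rate_small_extension_no_breaks(self, tiny):
        p, st = self._single_bond_state(tiny)
        st2 = kinetics.break_bonds(st, p)
        assert len(st2.bonds(p)) == 1

    def test_overextension_guard_breaks_and_ejects(self, tiny):
        p, st = self._single_bond_state(tiny)
        st.centers[0, 0] += 250.0  # extension > max_extension_AB = 200 nm
        st2 = kinetics.break_bonds(st, p)
        assert not st2.bonds(p)
        assert st2.a_site[0, 0] < 0  # ejected to cytoplasm, site vacated
        st2.check_consistency()

    def test_bond_lifetimes_are_exponential(self, tiny):
        """Mean lifetime over many bonds ~ 1/k_bond_off (extension ~ 0)."""
        koff = 20.0
        dt = tiny.run.dt
        p, st0 = self._single_bond_state(tiny, k_bond_off=koff)
        lifetimes = []
        for rep in range(600):
            st = st0.copy()
            st.rng[0] = np.uint64(rep + 1)
            steps = 0
            while st.a_bond_carb[0] >= 0 and steps < 20000:
                st = kinetics.break_bonds(st, p)
                steps += 1
            lifetimes.append(steps * dt)
        lifetimes = np.asarray(lifetimes)
        se = lifetimes.std(ddof=1) / math.sqrt(len(lifetimes))
        assert abs(lifetimes.mean() - 1.0 / koff) < 3 * se + dt
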