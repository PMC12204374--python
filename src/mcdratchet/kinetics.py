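"""Stochastic McdA state transitions, exposed one channel at a time.

These wrappers run the same compiled kernels the full step loop uses, on a
copy of the input state, so each channel can be exercised and validated in
isolation: lattice hopping, cytoplasmic rebinding, intrinsic dissociation,
bond formation, and bond breaking with stimulated release.

All transition probabilities have the tau-leap form 1 - exp(-rate*dt)
(hopping uses the lattice attempt probability (4*D_A/a^2)*dt directly),
so halving dt while doubling the number of steps leaves ensemble
statistics unchanged within sampling error.
"""

from __future__ import annotations

from . import _core
from .engine import SystemState, pack_params
from .params import SimParams


def _apply(kernel_name: str, state: SystemState, params: SimParams) -> SystemState:
    P = pack_params(params)
    out = state.copy()
    if kernel_name == "hop":
        _core.hop(P, out.occ, out.a_site, out.a_bond_carb, out.rng)
    elif kernel_name == "rebind":
        _core.rebind(P, out.occ, out.a_site, out.rng)
    elif kernel_name == "unbind":
        _core.unbind_intrinsic(P, out.occ, out.a_site, out.a_bond_carb, out.rng)
    elif kernel_name == "form":
        _core.form_bonds(P, out.occ, out.a_site, out.a_bond_carb,
                         out.a_bond_site, out.centers, out.offsets,
                         out.site_bond, out.rng)
    elif kernel_name == "break":
        _core.break_bonds(P, out.occ, out.a_site, out.a_bond_carb,
                          out.a_bond_site, out.centers, out.offsets,
                          out.site_bond, out.rng)
    else:  # pragma: no cover
        raise ValueError(kernel_name)
    return out


def hop_mcdA(state: SystemState, params: SimParams) -> SystemState:
    """One sweep of nearest-neighbor lattice hops for unbonded nucleoid
    McdA.  Each particle attempts a hop with probability (4*D_A/a^2)*dt,
    direction uniform over the 4 neighbors; hops into occupied or
    out-of-lattice sites are rejected."""
    return _apply("hop", state, params)


def rebind_mcdA(state: SystemState, params: SimParams) -> SystemState:
    """Cytoplasm -> nucleoid rebinding: each cytoplasmic McdA binds with
    probability 1 - exp(-k_rebind*dt) to a uniformly random empty lattice
    site.  If no empty site exists the particle stays cytoplasmic."""
    return _apply("rebind", state, params)


def unbind_mcdA_intrinsic(state: SystemState, params: SimParams) -> SystemState:
    """Intrinsic dissociation: each *unbonded* nucleoid McdA is ejected to
    the cytoplasm with probability 1 - exp(-k_off_intrinsic*dt).  Bonded
    McdA never leaves through this channel."""
    return _apply("unbind", state, params)


def form_bonds(state: SystemState, params: SimParams) -> SystemState:
    """Bond formation between free McdB sites and in-range free McdA.

    Each free site attempts its nearest free nucleoid McdA within
    capture_radius with probability 1 - exp(-k_bond_on*dt); competition for
    a shared McdA is resolved by smallest distance, then lowest site index,
    and the losing site falls back to its next-nearest candidate.  The bond
    anchor is the McdA lattice position.
    """
    return _apply("form", state, params)


def break_bonds(state: SystemState, params: SimParams) -> SystemState:
    """Bond breaking: each live bond breaks with probability
    1 - exp(-k_bond_off*dt), and unconditionally when stretched past
    max_extension_AB.  A break ejects the McdA to the cytoplasm at once —
    McdB-stimulated release idealized as instantaneous — vacating its
    lattice site."""
    return _apply("break", state, params)
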