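"""Deterministic force evaluation and overdamped motion.

Two Hookean interactions act on a carboxysome: McdA-McdB bond springs
(zero rest length; force -k_AB * x toward the lattice anchor) and the
pairwise self-association spring between carboxysome centers (restoring
toward contact, engaged only within self_range).  Centers follow explicit
Euler-Maruyama overdamped dynamics,

    x <- x + (F_net / gamma) dt + sqrt(2 D_carb dt) eta,

with gamma = kBT / D_carb and eta standard normal per axis, followed by
hard-core overlap resolution (symmetric projection to contact) and
specular reflection into the nucleoid rectangle.
"""

from __future__ import annotations

import numpy as np

from . import _core
from .engine import SystemState, pack_params
from .params import SimParams


def bond_forces(state: SystemState, params: SimParams) -> np.ndarray:
    """Summed McdA-McdB spring force per carboxysome, pN, shape (n_carb, 2)."""
    P = pack_params(params)
    f = np.zeros((state.centers.shape[0], 2), np.float64)
    _core.bond_forces(P, state.centers, state.offsets, state.site_bond,
                      state.a_site, f)
    return f


def self_association_forces(state: SystemState, params: SimParams) -> np.ndarray:
    """Summed self-association force per carboxysome, pN, shape (n_carb, 2)."""
    P = pack_params(params)
    f = np.zeros((state.centers.shape[0], 2), np.float64)
    _core.self_forces(P, state.centers, f)
    return f


def net_forces(state: SystemState, params: SimParams) -> np.ndarray:
    return bond_forces(state, params) + self_association_forces(state, params)


def self_force_pair_table(state: SystemState, params: SimParams) -> np.ndarray:
    """Per-pair self-association forces, shape (n_pairs, 2, 2):
    [pair, member, xy] for pairs (c, d) with c < d in row-major order."""
    P = pack_params(params)
    ncarb = state.centers.shape[0]
    npairs = ncarb * (ncarb - 1) // 2
    table = np.zeros((max(npairs, 1), 2, 2), np.float64)
    if npairs:
        _core.self_force_pairs(P, state.centers, table)
    return table[:npairs]


def newton_third_law_check(state: SystemState, params: SimParams,
                           table: np.ndarray | None = None,
                           tol: float = 1e-9) -> bool:
    """True iff every self-association force pair sums to zero within tol pN.

    A pre-computed (possibly corrupted) pair table may be supplied; by
    default the table is evaluated from the state.
    """
    if table is None:
        table = self_force_pair_table(state, params)
    if table.size == 0:
        return True
    resid = table[:, 0, :] + table[:, 1, :]
    return bool(np.all(np.abs(resid) <= tol))


def displace_carboxysomes(state: SystemState, forces: np.ndarray,
                          params: SimParams) -> SystemState:
    """One overdamped displacement with the given net forces (pN), then
    overlap resolution and boundary reflection.  Input state not mutated."""
    forces = np.asarray(forces, np.float64)
    if not np.all(np.isfinite(forces)):
        raise FloatingPointError("non-finite force input")
    P = pack_params(params)
    out = state.copy()
    ok = _core.displace(P, out.centers, forces, out.rng)
    if not ok:
        raise FloatingPointError("non-finite carboxysome displacement")
    return out
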