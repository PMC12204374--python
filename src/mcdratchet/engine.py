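"""System state, initialization, and time propagation.

The model world: a rectangular nucleoid surface carrying a square lattice
of McdA binding sites (at most one McdA per site — volumetric exclusion),
a well-mixed cytoplasmic McdA pool, and hard-disk carboxysomes decorated
with fixed McdB sites.  McdA-McdB bonds are zero-rest-length springs from
a McdB site to the lattice position of its McdA; carboxysomes also attract
each other through a finite-range self-association spring.  Carboxysome
centers follow overdamped Langevin dynamics driven by the summed spring
forces plus thermal noise.

``run_trajectory`` is the fast path: the whole step loop runs inside the
compiled core.  ``step`` advances a ``SystemState`` one dt at a time for
inspection and testing; both paths execute the same kernels.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import _core
from .params import SimParams, validate

TRAJ_SCHEMA = "mcdratchet-trajectory-v1"


@dataclass
class Bond:
    """A live McdA-McdB bond (view derived from the state arrays)."""

    id: int
    mcdA_id: int
    carb_id: int
    site_index: int
    anchor: tuple[float, float]  # McdA lattice position, nm


@dataclass
class SystemState:
    """Instantaneous simulation state (internal units: nm, s).

    Arrays:
      centers      (n_carb, 2) float64 — carboxysome centers.
      offsets      (n_carb, n_sites, 2) float64 — McdB site offsets, rigid
                   in the body frame (no rotation).
      site_bond    (n_carb, n_sites) int32 — bonded McdA id or -1.
      a_site       (n_mcdA, 2) int32 — lattice (ix, iy), or (-1, -1) when
                   the particle is in the cytoplasmic pool.
      a_bond_carb / a_bond_site (n_mcdA,) int32 — bond partner or -1.
      occ          (nx, ny) int32 — lattice occupancy (McdA id or -1).
      rng          (1,) uint64 — counter-based RNG stream state.
    """

    time: float
    centers: np.ndarray
    offsets: np.ndarray
    site_bond: np.ndarray
    a_site: np.ndarray
    a_bond_carb: np.ndarray
    a_bond_site: np.ndarray
    occ: np.ndarray
    rng: np.ndarray

    def copy(self) -> "SystemState":
        return SystemState(
            time=self.time,
            centers=self.centers.copy(),
            offsets=self.offsets.copy(),
            site_bond=self.site_bond.copy(),
            a_site=self.a_site.copy(),
            a_bond_carb=self.a_bond_carb.copy(),
            a_bond_site=self.a_bond_site.copy(),
            occ=self.occ.copy(),
            rng=self.rng.copy(),
        )

    @property
    def n_mcdA(self) -> int:
        return self.a_site.shape[0]

    @property
    def n_nucleoid(self) -> int:
        return int(np.count_nonzero(self.a_site[:, 0] >= 0))

    @property
    def n_cytoplasm(self) -> int:
        return int(np.count_nonzero(self.a_site[:, 0] < 0))

    def bonds(self, params: SimParams) -> list[Bond]:
        a = params.geometry.lattice_spacing
        out = []
        bid = 0
        ncarb, nsites = self.site_bond.shape
        for c in range(ncarb):
            for s in range(nsites):
                ai = int(self.site_bond[c, s])
                if ai < 0:
                    continue
                ax = (self.a_site[ai, 0] + 0.5) * a
                ay = (self.a_site[ai, 1] + 0.5) * a
                out.append(Bond(bid, ai, c, s, (ax, ay)))
                bid += 1
        return out

    def check_consistency(self) -> None:
        """Assert occupancy/bond bookkeeping invariants; used by tests."""
        occ_ids = self.occ[self.occ >= 0]
        assert len(occ_ids) == len(set(occ_ids.tolist())), "duplicate lattice occupancy"
        on = set(occ_ids.tolist())
        for i in range(self.n_mcdA):
            if self.a_site[i, 0] >= 0:
                assert self.occ[self.a_site[i, 0], self.a_site[i, 1]] == i
                assert i in on
            else:
                assert self.a_bond_carb[i] < 0, "cytoplasmic McdA cannot hold a bond"
        for c in range(self.site_bond.shape[0]):
            for s in range(self.site_bond.shape[1]):
                ai = self.site_bond[c, s]
                if ai >= 0:
                    assert self.a_bond_carb[ai] == c and self.a_bond_site[ai] == s


def pack_params(params: SimParams) -> np.ndarray:
    """Flatten SimParams into the kernel parameter vector (nm / s / pN)."""
    g, k, s, r = params.geometry, params.kinetics, params.springs, params.run
    P = np.zeros(_core.NPAR, np.float64)
    a = g.lattice_spacing
    dt = r.dt
    P[_core.I_LX] = g.nucleoid_length * 1e3
    P[_core.I_LY] = g.nucleoid_width * 1e3
    P[_core.I_A] = a
    P[_core.I_DIAM] = g.carboxysome_diameter
    d_a = k.D_mcdA_nucleoid * 1e6  # um^2/s -> nm^2/s
    P[_core.I_P_HOP] = (4.0 * d_a / (a * a)) * dt
    P[_core.I_P_REBIND] = -math.expm1(-k.k_rebind * dt)
    P[_core.I_P_OFF] = -math.expm1(-k.k_off_intrinsic * dt)
    P[_core.I_P_BON] = -math.expm1(-k.k_bond_on * dt)
    P[_core.I_P_BOFF] = -math.expm1(-k.k_bond_off * dt)
    P[_core.I_KAB] = s.k_AB
    P[_core.I_KSELF] = s.k_self
    P[_core.I_REST_SELF] = s.rest_length_self
    P[_core.I_SELF_RANGE] = s.self_range
    P[_core.I_MAXEXT] = s.max_extension_AB
    P[_core.I_CAPR] = k.capture_radius
    P[_core.I_DT] = dt
    d_c = k.D_carb * 1e6
    P[_core.I_SQ2DDT] = math.sqrt(2.0 * d_c * dt)
    P[_core.I_MOBDT] = d_c * dt / k.kBT  # dt/gamma with gamma = kBT/D
    P[_core.I_REST_AB] = s.rest_length_AB
    if P[_core.I_P_HOP] > 1.0:
        P[_core.I_P_HOP] = 1.0
    return P


def lattice_shape(params: SimParams) -> tuple[int, int]:
    g = params.geometry
    nx = round(g.nucleoid_length * 1e3 / g.lattice_spacing)
    ny = round(g.nucleoid_width * 1e3 / g.lattice_spacing)
    return nx, ny


def init_state(params: SimParams, seed: int,
               mcdB_offsets: Optional[np.ndarray] = None) -> SystemState:
    """Build the t=0 state.

    Carboxysomes start as a row of touching disks centered in the domain
    (center-center spacing = the self-association rest length), so a pair
    begins in contact and inside the self-association range.  McdA is
    placed on distinct uniformly random lattice sites at the two-state
    steady-state bound fraction k_rebind / (k_rebind + k_off_intrinsic),
    the remainder in the cytoplasm.  No bonds exist at t=0.

    mcdB_offsets overrides the default uniform-in-disk McdB placement
    (shape (n_carb, n_sites, 2), nm, body frame); used by controlled
    single-bond setups and tests.
    """
    validate(params)
    g, k, r, s = params.geometry, params.kinetics, params.run, params.springs
    nx, ny = lattice_shape(params)
    ncarb = r.n_carboxysomes
    nsites = k.n_mcdB_per_carb
    lx = g.nucleoid_length * 1e3
    ly = g.nucleoid_width * 1e3
    radius = g.carboxysome_diameter / 2.0

    rng = np.zeros(1, np.uint64)
    rng[0] = np.uint64(seed)

    spacing = s.rest_length_self
    row_len = (ncarb - 1) * spacing
    x0 = lx / 2.0 - row_len / 2.0
    if x0 - radius < 0 or x0 + row_len + radius > lx or radius > ly / 2.0:
        raise ValueError(
            "domain too small to place carboxysomes without overlap: "
            f"{ncarb} disks of diameter {g.carboxysome_diameter} nm in "
            f"{lx} x {ly} nm")
    centers = np.zeros((ncarb, 2), np.float64)
    for c in range(ncarb):
        centers[c, 0] = x0 + c * spacing
        centers[c, 1] = ly / 2.0

    if mcdB_offsets is not None:
        offsets = np.asarray(mcdB_offsets, np.float64).copy()
        if offsets.shape != (ncarb, nsites, 2):
            raise ValueError(
                f"mcdB_offsets must have shape {(ncarb, nsites, 2)}")
        if np.any(np.hypot(offsets[..., 0], offsets[..., 1]) > radius + 1e-9):
            raise ValueError("mcdB offsets must lie within the disk radius")
    else:
        # uniform over the disk footprint: r = R*sqrt(u), angle uniform
        offsets = np.zeros((ncarb, nsites, 2), np.float64)
        for c in range(ncarb):
            for sidx in range(nsites):
                rr = radius * math.sqrt(_core.rand_u(rng))
                th = 2.0 * math.pi * _core.rand_u(rng)
                offsets[c, sidx, 0] = rr * math.cos(th)
                offsets[c, sidx, 1] = rr * math.sin(th)

    denom = k.k_rebind + k.k_off_intrinsic
    bound_frac = k.k_rebind / denom if denom > 0 else 1.0
    n_bound = int(round(k.n_mcdA * bound_frac))
    n_bound = min(n_bound, nx * ny)

    occ = np.full((nx, ny), -1, np.int32)
    a_site = np.full((k.n_mcdA, 2), -1, np.int32)
    for i in range(n_bound):
        while True:
            ix = int(_core.rand_u(rng) * nx)
            iy = int(_core.rand_u(rng) * ny)
            if occ[ix, iy] < 0:
                occ[ix, iy] = i
                a_site[i, 0] = ix
                a_site[i, 1] = iy
                break

    return SystemState(
        time=0.0,
        centers=centers,
        offsets=offsets,
        site_bond=np.full((ncarb, nsites), -1, np.int32),
        a_site=a_site,
        a_bond_carb=np.full(k.n_mcdA, -1, np.int32),
        a_bond_site=np.full(k.n_mcdA, -1, np.int32),
        occ=occ,
        rng=rng,
    )


def attach_bond(state: SystemState, carb: int, site_index: int,
                mcdA_id: int) -> None:
    """Manually create a bond (in place); for controlled setups and tests.

    The McdA must be on the nucleoid and unbonded, the McdB site free.
    """
    if state.a_site[mcdA_id, 0] < 0:
        raise ValueError("McdA is cytoplasmic; cannot bond")
    if state.a_bond_carb[mcdA_id] >= 0:
        raise ValueError("McdA already bonded")
    if state.site_bond[carb, site_index] >= 0:
        raise ValueError("McdB site already bonded")
    state.site_bond[carb, site_index] = mcdA_id
    state.a_bond_carb[mcdA_id] = carb
    state.a_bond_site[mcdA_id] = site_index


def place_mcdA(state: SystemState, mcdA_id: int, ix: int, iy: int) -> None:
    """Move one McdA to lattice site (ix, iy) (in place); test/setup helper."""
    if state.occ[ix, iy] >= 0:
        raise ValueError("target site occupied")
    if state.a_site[mcdA_id, 0] >= 0:
        state.occ[state.a_site[mcdA_id, 0], state.a_site[mcdA_id, 1]] = -1
    state.occ[ix, iy] = mcdA_id
    state.a_site[mcdA_id, 0] = ix
    state.a_site[mcdA_id, 1] = iy


def step(state: SystemState, params: SimParams) -> SystemState:
    """Advance one dt and return the new state (the input is not mutated).

    Sub-steps in fixed order: McdA hops, rebinding, intrinsic unbinding,
    bond formation, force evaluation, overdamped displacement with
    exclusion and reflection, bond breaking with ejection.
    """
    P = pack_params(params)
    out = state.copy()
    f = np.zeros((out.centers.shape[0], 2), np.float64)
    ok = _core.step_once(P, out.occ, out.a_site, out.a_bond_carb,
                         out.a_bond_site, out.centers, out.offsets,
                         out.site_bond, f, out.rng)
    if not ok:
        raise FloatingPointError(
            f"non-finite carboxysome position at t={state.time + params.run.dt:.6g} s; "
            "dt is likely too large for the stiffness/drag combination")
    out.time = state.time + params.run.dt
    return out


@dataclass
class Trajectory:
    """Recorded output of one run (positions in nm internally).

    times      (n_samples,) s
    positions  (n_samples, n_carb, 2) nm
    n_bonds    (n_samples, n_carb) live McdA-McdB bonds at the sample time
    """

    times: np.ndarray
    positions: np.ndarray
    n_bonds: np.ndarray
    seed: int = 0
    params: Optional[SimParams] = field(default=None, repr=False)

    @property
    def n_samples(self) -> int:
        return self.times.shape[0]

    @property
    def n_carboxysomes(self) -> int:
        return self.positions.shape[1]

    def to_frame(self) -> pd.DataFrame:
        """Long-format table in file units (µm, s)."""
        ns, nc = self.n_samples, self.n_carboxysomes
        return pd.DataFrame({
            "time_s": np.repeat(self.times, nc),
            "carb_id": np.tile(np.arange(nc), ns),
            "x_um": (self.positions[:, :, 0] / 1e3).ravel(),
            "y_um": (self.positions[:, :, 1] / 1e3).ravel(),
            "n_bonds": self.n_bonds.ravel(),
        })

    def to_csv(self, path: str | Path) -> None:
        """Write the trajectory CSV (schema header comment, 6 significant
        digits in µm — sub-nm, below physical meaning)."""
        df = self.to_frame()
        buf = io.StringIO()
        buf.write(f"# {TRAJ_SCHEMA}\n")
        df.to_csv(buf, index=False, float_format="%.6g")
        Path(path).write_text(buf.getvalue())

    @classmethod
    def from_csv(cls, path: str | Path) -> "Trajectory":
        df = pd.read_csv(path, comment="#")
        required = {"time_s", "carb_id", "x_um", "y_um"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(
                f"trajectory CSV schema mismatch: missing columns {sorted(missing)}")
        times = np.sort(df["time_s"].unique())
        carbs = np.sort(df["carb_id"].unique())
        ns, nc = len(times), len(carbs)
        if len(df) != ns * nc:
            raise ValueError("trajectory CSV schema mismatch: ragged samples")
        df = df.sort_values(["time_s", "carb_id"], kind="mergesort")
        pos = np.empty((ns, nc, 2), np.float64)
        pos[:, :, 0] = df["x_um"].to_numpy().reshape(ns, nc) * 1e3
        pos[:, :, 1] = df["y_um"].to_numpy().reshape(ns, nc) * 1e3
        if "n_bonds" in df.columns:
            nb = df["n_bonds"].to_numpy().reshape(ns, nc)
        else:
            nb = np.zeros((ns, nc), int)
        return cls(times=times, positions=pos, n_bonds=nb)


def run_trajectory(params: SimParams, seed: int,
                   state: Optional[SystemState] = None) -> Trajectory:
    """Run one full trajectory; identical (params, seed) pairs give
    bit-identical output.

    A pre-built ``state`` (e.g. with manual bonds) may be supplied; it is
    not mutated.
    """
    validate(params)
    r = params.run
    nsteps = round(r.duration / r.dt)
    rec_every = round(r.record_interval / r.dt)
    n_rec = nsteps // rec_every + 1

    st = state.copy() if state is not None else init_state(params, seed)
    ncarb = st.centers.shape[0]
    P = pack_params(params)
    rec_xy = np.zeros((n_rec, ncarb, 2), np.float64)
    rec_nb = np.zeros((n_rec, ncarb), np.int32)
    rec_xy[0] = st.centers
    rec_nb[0] = (st.site_bond >= 0).sum(axis=1)
    code = _core.run_steps(P, nsteps, rec_every, st.occ, st.a_site,
                           st.a_bond_carb, st.a_bond_site, st.centers,
                           st.offsets, st.site_bond, st.rng, rec_xy, rec_nb)
    if code != 0:
        raise FloatingPointError(
            f"non-finite carboxysome position at step {code} "
            f"(t={code * r.dt:.6g} s); dt is likely too large for the "
            "stiffness/drag combination")
    times = np.arange(n_rec) * r.record_interval
    return Trajectory(times=times, positions=rec_xy, n_bonds=rec_nb,
                      seed=seed, params=params.copy())
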