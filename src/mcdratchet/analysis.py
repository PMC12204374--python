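"""Trajectory metrics, regime classification, ensembles, phase sweeps,
and the model-validation oracle suite.

A pair trajectory is summarized by two numbers:

* the **clustered fraction** — the fraction of recorded samples at which
  the two carboxysome centers are within the self-association range; and
* the **movement range** — per carboxysome, the maximum distance between
  any two points of its recorded path, maximized over carboxysomes.

The classification rules are the printed thresholds: "clustered" means
clustered fraction strictly above 0.90; "positioned" means movement range
strictly below 0.25 times the nucleoid length.  The three named regimes
are clustered-and-diffuse, clustered-and-positioned, and
partitioned-and-positioned.  The fourth logical cell (neither clustered
nor positioned) is labeled ``partitioned_diffuse`` in full output and
folded into ``partitioned_positioned`` on the 3-regime map.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import ConvexHull, QhullError
from scipy.spatial.distance import pdist

from . import engine
from .engine import Trajectory
from .params import SimParams, validate

REGIMES3 = ("clustered_diffuse", "clustered_positioned", "partitioned_positioned")
REGIMES4 = REGIMES3 + ("partitioned_diffuse",)

# tie-break priority for majority votes: more-clustered regimes first
_VOTE_PRIORITY = ("clustered_diffuse", "clustered_positioned",
                  "partitioned_positioned", "partitioned_diffuse")


def pair_distances(traj: Trajectory) -> np.ndarray:
    """Center-center distance (nm) of carboxysomes 0 and 1 per sample."""
    if traj.n_carboxysomes != 2:
        raise ValueError(
            f"clustering metrics require exactly 2 carboxysomes, "
            f"got {traj.n_carboxysomes}")
    d = traj.positions[:, 1, :] - traj.positions[:, 0, :]
    return np.hypot(d[:, 0], d[:, 1])


def clustered_fraction(traj: Trajectory, params: SimParams) -> float:
    """Fraction of recorded samples with the two centers within self_range."""
    if traj.n_samples < 2:
        raise ValueError("trajectory must have at least 2 samples")
    dist = pair_distances(traj)
    return float(np.mean(dist <= params.springs.self_range))


def movement_range_brute(traj: Trajectory) -> float:
    """O(n^2) reference path diameter: max pairwise distance of recorded
    points, per carboxysome, maximum over carboxysomes.  Returns µm."""
    if traj.n_samples < 2:
        raise ValueError("trajectory must have at least 2 samples")
    best = 0.0
    for c in range(traj.n_carboxysomes):
        best = max(best, float(pdist(traj.positions[:, c, :]).max()))
    return best / 1e3


def _diameter_hull(points: np.ndarray) -> float:
    """Exact diameter of a 2D point set via its convex hull (the farthest
    pair lies on the hull); degenerate sets fall back to brute force."""
    if len(points) < 3:
        return float(pdist(points).max()) if len(points) == 2 else 0.0
    try:
        hull = ConvexHull(points)
    except QhullError:
        return float(pdist(points).max())
    hp = points[hull.vertices]
    return float(pdist(hp).max())


def movement_range(traj: Trajectory) -> float:
    """Path diameter in µm (convex-hull fast path; equals the brute-force
    O(n^2) reference to floating-point accuracy)."""
    if traj.n_samples < 2:
        raise ValueError("trajectory must have at least 2 samples")
    best = 0.0
    for c in range(traj.n_carboxysomes):
        best = max(best, _diameter_hull(traj.positions[:, c, :]))
    return best / 1e3


@dataclass
class ClassificationResult:
    clustered_fraction: float
    movement_range: float          # µm
    regime: str                    # 3-regime label (phase-map color)
    regime_full: str               # 4-way label incl. partitioned_diffuse
    clustered: bool
    positioned: bool

    def to_dict(self) -> dict:
        return {
            "clustered_fraction": self.clustered_fraction,
            "movement_range_um": self.movement_range,
            "regime": self.regime,
            "regime_full": self.regime_full,
            "clustered": self.clustered,
            "positioned": self.positioned,
        }


def _label(clustered: bool, positioned: bool) -> tuple[str, str]:
    if clustered:
        full = "clustered_positioned" if positioned else "clustered_diffuse"
        return full, full
    full = "partitioned_positioned" if positioned else "partitioned_diffuse"
    return "partitioned_positioned", full


def classify_trajectory(traj: Trajectory, params: SimParams) -> ClassificationResult:
    """Apply the clustered (>90% of time in range) and positioned
    (< 0.25 L movement range) rules to one trajectory."""
    frac = clustered_fraction(traj, params)
    rng_um = movement_range(traj)
    clustered = frac > params.classify.clustered_time_fraction
    positioned = rng_um < (params.classify.positioned_range_fraction
                           * params.geometry.nucleoid_length)
    regime, full = _label(clustered, positioned)
    return ClassificationResult(
        clustered_fraction=frac, movement_range=rng_um, regime=regime,
        regime_full=full, clustered=clustered, positioned=positioned)


@dataclass
class EnsembleResult:
    n: int
    seeds: list[int]
    mean_clustered_fraction: float
    mean_movement_range: float     # µm
    regime_votes: dict[str, int]   # over the 4-way labels
    majority_regime: str           # 3-regime label by plurality
    results: list[ClassificationResult] = field(repr=False, default_factory=list)

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "seeds": self.seeds,
            "mean_clustered_fraction": self.mean_clustered_fraction,
            "mean_movement_range_um": self.mean_movement_range,
            "regime_votes": self.regime_votes,
            "majority_regime": self.majority_regime,
        }


def _majority(votes4: dict[str, int]) -> str:
    # collapse to 3-regime labels, plurality; ties -> more-clustered regime
    votes3 = {r: 0 for r in REGIMES3}
    for r4, v in votes4.items():
        r3 = "partitioned_positioned" if r4 == "partitioned_diffuse" else r4
        votes3[r3] += v
    best = max(votes3.values())
    for r in _VOTE_PRIORITY:
        if r in votes3 and votes3[r] == best:
            return r
    return REGIMES3[0]  # pragma: no cover


def run_ensemble(params: SimParams, base_seed: int, n: int) -> EnsembleResult:
    """Run n trajectories with seeds base_seed .. base_seed+n-1 and
    aggregate their classifications."""
    if n < 1:
        raise ValueError("n must be >= 1")
    seeds = [base_seed + i for i in range(n)]
    results = []
    for sd in seeds:
        traj = engine.run_trajectory(params, sd)
        results.append(classify_trajectory(traj, params))
    votes = {r: 0 for r in REGIMES4}
    for res in results:
        votes[res.regime_full] += 1
    return EnsembleResult(
        n=n,
        seeds=seeds,
        mean_clustered_fraction=float(np.mean([r.clustered_fraction for r in results])),
        mean_movement_range=float(np.mean([r.movement_range for r in results])),
        regime_votes=votes,
        majority_regime=_majority(votes),
        results=results,
    )


@dataclass
class PhaseDiagram:
    k_self_grid: list[float]
    k_AB_grid: list[float]
    cells: list[list[EnsembleResult]]  # [i_kself][j_kAB]

    def majority_map(self) -> list[list[str]]:
        return [[cell.majority_regime for cell in row] for row in self.cells]

    def to_records(self) -> list[dict]:
        out = []
        for i, ks in enumerate(self.k_self_grid):
            for j, kab in enumerate(self.k_AB_grid):
                cell = self.cells[i][j]
                rec = {
                    "k_self": ks,
                    "k_AB": kab,
                    "mean_clustered_fraction": cell.mean_clustered_fraction,
                    "mean_movement_range_um": cell.mean_movement_range,
                    "majority_regime": cell.majority_regime,
                }
                for r in REGIMES4:
                    rec[f"votes_{r}"] = cell.regime_votes[r]
                out.append(rec)
        return out


def sweep_phase_diagram(params: SimParams, k_self_values, k_AB_values,
                        n: int, base_seed: int | None = None) -> PhaseDiagram:
    """Ensemble per (k_self, k_AB) grid cell.  The seed schedule is
    deterministic: cell (i, j) uses seeds base + (i*|k_AB|+j)*n + [0, n)."""
    k_self_values = list(k_self_values)
    k_AB_values = list(k_AB_values)
    if not k_self_values or not k_AB_values:
        raise ValueError("stiffness grids must be nonempty")
    base = params.run.seed if base_seed is None else base_seed
    cells = []
    for i, ks in enumerate(k_self_values):
        row = []
        for j, kab in enumerate(k_AB_values):
            p = params.copy()
            p.springs.k_self = ks
            p.springs.k_AB = kab
            cell_base = base + (i * len(k_AB_values) + j) * n
            row.append(run_ensemble(p, cell_base, n))
        cells.append(row)
    return PhaseDiagram(k_self_grid=k_self_values, k_AB_grid=k_AB_values,
                        cells=cells)


def clustered_fraction_curve(params: SimParams, k_AB_values, n: int,
                             base_seed: int | None = None) -> list[tuple[float, float]]:
    """Mean clustered fraction vs k_AB at the fixed k_self in params;
    the cross-section of the phase diagram."""
    k_AB_values = list(k_AB_values)
    if sorted(k_AB_values) != k_AB_values:
        raise ValueError("k_AB_values must be sorted ascending")
    pd_ = sweep_phase_diagram(params, [params.springs.k_self], k_AB_values,
                              n, base_seed=base_seed)
    return [(kab, cell.mean_clustered_fraction)
            for kab, cell in zip(k_AB_values, pd_.cells[0])]


# ---------------------------------------------------------------------------
# validation oracle suite
# ---------------------------------------------------------------------------

@dataclass
class OracleResult:
    name: str
    status: str       # PASS / FAIL / SKIP
    statistic: float
    bound: float
    detail: str

    @property
    def passed(self) -> bool:
        return self.status != "FAIL"


@dataclass
class ValidationReport:
    entries: list[OracleResult]

    @property
    def all_passed(self) -> bool:
        return all(e.passed for e in self.entries)

    def to_dict(self) -> dict:
        return {"all_passed": self.all_passed,
                "oracles": [vars(e) for e in self.entries]}

    def __str__(self) -> str:
        lines = []
        for e in self.entries:
            lines.append(f"[{e.status:4s}] {e.name}: stat={e.statistic:.4g} "
                         f"bound={e.bound:.4g} — {e.detail}")
        verdict = "ALL PASS" if self.all_passed else "FAILURES PRESENT"
        lines.append(verdict)
        return "\n".join(lines)


def _free_params(params: SimParams) -> SimParams:
    """Interaction-free variant on a large domain for diffusion oracles."""
    p = params.copy()
    p.geometry.nucleoid_length = 4.0
    p.geometry.nucleoid_width = 2.0
    p.springs.k_AB = 0.0
    p.springs.k_self = 0.0
    p.kinetics.k_bond_on = 0.0
    p.kinetics.n_mcdA = 1
    p.kinetics.n_mcdB_per_carb = 1
    p.run.n_carboxysomes = 1
    return p


def msd_free_diffusion(params: SimParams, seed: int = 0, n_runs: int = 64,
                       duration: float = 5.0) -> OracleResult:
    """Ensemble MSD of a force-free carboxysome vs the 2D law 4*D*t."""
    if params.kinetics.D_carb == 0:
        return OracleResult("free_diffusion_msd", "SKIP", 0.0, 0.0,
                            "D_carb = 0: no thermal motion to test")
    p = _free_params(params)
    p.run.duration = duration
    p.run.record_interval = duration
    disp2 = []
    for i in range(n_runs):
        traj = engine.run_trajectory(p, seed + i)
        d = traj.positions[-1, 0, :] - traj.positions[0, 0, :]
        disp2.append(d[0] ** 2 + d[1] ** 2)
    disp2 = np.asarray(disp2)
    expected = 4.0 * p.kinetics.D_carb * 1e6 * duration  # nm^2
    se = disp2.std(ddof=1) / math.sqrt(n_runs)
    z = abs(disp2.mean() - expected) / se
    return OracleResult("free_diffusion_msd", "PASS" if z < 3 else "FAIL",
                        z, 3.0,
                        f"MSD({duration} s) = {disp2.mean():.1f} nm^2, "
                        f"4Dt = {expected:.1f} nm^2, n={n_runs}")


def tethered_extension_oracle(params: SimParams, seed: int = 0,
                              n_samples: int = 1500,
                              sample_interval: float = 0.05) -> OracleResult:
    """Equipartition of a single permanent bond: mean squared 2D extension
    should equal 2*kBT/k_AB."""
    if params.kinetics.D_carb == 0:
        return OracleResult("tethered_equipartition", "SKIP", 0.0, 0.0,
                            "D_carb = 0: no thermal motion to test")
    kab = params.springs.k_AB if params.springs.k_AB > 0 else 0.8
    p = _free_params(params)
    p.springs.k_AB = kab
    p.kinetics.k_bond_off = 0.0
    p.kinetics.k_off_intrinsic = 0.0
    p.kinetics.k_rebind = 0.0
    p.kinetics.D_mcdA_nucleoid = 0.0
    p.springs.max_extension_AB = 1e6
    # McdB site at the disk center; one McdA anchored at the nearest lattice
    # site to the domain center; permanent bond between them.
    offs = np.zeros((1, 1, 2))
    st = engine.init_state(p, seed, mcdB_offsets=offs)
    nx, ny = engine.lattice_shape(p)
    engine.place_mcdA(st, 0, nx // 2, ny // 2)
    engine.attach_bond(st, 0, 0, 0)
    a = p.geometry.lattice_spacing
    anchor = np.array([(nx // 2 + 0.5) * a, (ny // 2 + 0.5) * a])
    st.centers[0] = anchor  # start relaxed

    steps_per_sample = max(1, round(sample_interval / p.run.dt))
    p.run.duration = p.run.dt * steps_per_sample
    p.run.record_interval = p.run.duration
    ext2 = np.empty(n_samples)
    for i in range(n_samples):
        st = _advance_inplace(st, p)
        d = st.centers[0] - anchor
        ext2[i] = d[0] ** 2 + d[1] ** 2
    expected = 2.0 * p.kinetics.kBT / kab
    se = ext2.std(ddof=1) / math.sqrt(n_samples)
    z = abs(ext2.mean() - expected) / se
    return OracleResult("tethered_equipartition", "PASS" if z < 3 else "FAIL",
                        z, 3.0,
                        f"<ext^2> = {ext2.mean():.2f} nm^2, 2kBT/k = "
                        f"{expected:.2f} nm^2 at k_AB={kab} pN/nm")


def two_state_occupancy_oracle(params: SimParams, seed: int = 0,
                               n_runs: int = 12,
                               duration: float = 40.0) -> OracleResult:
    """Without bonds, the nucleoid-bound McdA fraction should sit at the
    two-state equilibrium k_rebind / (k_rebind + k_off_intrinsic)."""
    k = params.kinetics
    if k.k_rebind + k.k_off_intrinsic == 0:
        return OracleResult("two_state_occupancy", "SKIP", 0.0, 0.0,
                            "no exchange rates set")
    p = params.copy()
    p.kinetics.k_bond_on = 0.0
    p.run.n_carboxysomes = 1
    p.run.duration = duration
    p.run.record_interval = duration
    fracs = []
    for i in range(n_runs):
        st = engine.init_state(p, seed + i)
        P = engine.pack_params(p)
        nsteps = round(duration / p.run.dt)
        rec_xy = np.zeros((2, 1, 2))
        rec_nb = np.zeros((2, 1), np.int32)
        code = engine._core.run_steps(P, nsteps, nsteps, st.occ, st.a_site,
                                      st.a_bond_carb, st.a_bond_site,
                                      st.centers, st.offsets, st.site_bond,
                                      st.rng, rec_xy, rec_nb)
        assert code == 0
        fracs.append(st.n_nucleoid / st.n_mcdA)
    fracs = np.asarray(fracs)
    expected = k.k_rebind / (k.k_rebind + k.k_off_intrinsic)
    se = fracs.std(ddof=1) / math.sqrt(n_runs)
    se = max(se, 1e-12)
    z = abs(fracs.mean() - expected) / se
    return OracleResult("two_state_occupancy", "PASS" if z < 3 else "FAIL",
                        z, 3.0,
                        f"bound fraction {fracs.mean():.4f} vs "
                        f"{expected:.4f}, {n_runs} runs of {duration} s")


def depletion_asymmetry_oracle(params: SimParams, seed: int = 0,
                               duration: float = 60.0) -> OracleResult:
    """The ratchet's engine: time-averaged McdA occupancy in the trailing
    half-annulus behind a bond-driven cargo is lower than in the leading
    half-annulus ahead of it."""
    p = params.copy()
    p.run.n_carboxysomes = 1
    if p.springs.k_AB == 0 or p.kinetics.k_bond_on == 0:
        return OracleResult("depletion_asymmetry", "SKIP", 0.0, 0.0,
                            "no bonds: no ratchet to test")
    st = engine.init_state(p, seed)
    a = p.geometry.lattice_spacing
    nx, ny = st.occ.shape
    dt_block = 1.0
    nblocks = round(duration / dt_block)
    p_block = p.copy()
    p_block.run.duration = dt_block
    p_block.run.record_interval = dt_block
    lead_sum, trail_sum, nsamp = 0.0, 0.0, 0
    prev = st.centers[0].copy()
    r_in, r_out = p.geometry.carboxysome_diameter / 2.0, 2.5 * p.geometry.carboxysome_diameter
    for b in range(nblocks):
        st = _advance_inplace(st, p_block)
        cur = st.centers[0].copy()
        v = cur - prev
        prev = cur
        speed = math.hypot(v[0], v[1])
        if speed < 1e-6:
            continue
        u = v / speed
        lead_occ, lead_n, trail_occ, trail_n = 0, 0, 0, 0
        ix0 = max(0, int((cur[0] - r_out) / a))
        ix1 = min(nx - 1, int((cur[0] + r_out) / a))
        iy0 = max(0, int((cur[1] - r_out) / a))
        iy1 = min(ny - 1, int((cur[1] + r_out) / a))
        for ix in range(ix0, ix1 + 1):
            for iy in range(iy0, iy1 + 1):
                dx = (ix + 0.5) * a - cur[0]
                dy = (iy + 0.5) * a - cur[1]
                r = math.hypot(dx, dy)
                if r < r_in or r > r_out:
                    continue
                ahead = dx * u[0] + dy * u[1] > 0
                occupied = 1 if st.occ[ix, iy] >= 0 else 0
                if ahead:
                    lead_occ += occupied
                    lead_n += 1
                else:
                    trail_occ += occupied
                    trail_n += 1
        if lead_n and trail_n:
            lead_sum += lead_occ / lead_n
            trail_sum += trail_occ / trail_n
            nsamp += 1
    if nsamp == 0:
        return OracleResult("depletion_asymmetry", "SKIP", 0.0, 0.0,
                            "cargo never moved; no heading defined")
    lead, trail = lead_sum / nsamp, trail_sum / nsamp
    ok = trail < lead
    return OracleResult("depletion_asymmetry", "PASS" if ok else "FAIL",
                        lead - trail, 0.0,
                        f"leading occupancy {lead:.3f} vs trailing "
                        f"{trail:.3f} over {nsamp} samples")


def _advance_inplace(st, p):
    """Advance a state by p.run.duration using the compiled loop, mutating
    and returning it (internal helper for block-wise oracles)."""
    P = engine.pack_params(p)
    nsteps = round(p.run.duration / p.run.dt)
    ncarb = st.centers.shape[0]
    rec_xy = np.zeros((2, ncarb, 2))
    rec_nb = np.zeros((2, ncarb), np.int32)
    code = engine._core.run_steps(P, nsteps, nsteps, st.occ, st.a_site,
                                  st.a_bond_carb, st.a_bond_site, st.centers,
                                  st.offsets, st.site_bond, st.rng,
                                  rec_xy, rec_nb)
    if code != 0:
        raise FloatingPointError("non-finite position during block advance")
    st.time += p.run.duration
    return st


def movement_range_equivalence_oracle(seed: int = 0,
                                      n_walks: int = 20) -> OracleResult:
    """Convex-hull movement range must match the O(n^2) brute force."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_walks):
        steps = rng.normal(size=(200, 1, 2)) * 30.0
        pos = np.cumsum(steps, axis=0)
        traj = Trajectory(times=np.arange(200) * 0.1, positions=pos,
                          n_bonds=np.zeros((200, 1), int))
        worst = max(worst, abs(movement_range(traj) - movement_range_brute(traj)))
    ok = worst < 1e-12
    return OracleResult("movement_range_equivalence",
                        "PASS" if ok else "FAIL", worst, 1e-12,
                        f"max |fast - brute| = {worst:.2e} µm over "
                        f"{n_walks} random walks")


def conservation_oracle(params: SimParams, seed: int = 0,
                        duration: float = 50.0) -> OracleResult:
    """Total McdA count must be conserved over a long default-dynamics run."""
    p = params.copy()
    p.run.duration = duration
    p.run.record_interval = duration
    st = engine.init_state(p, seed)
    n0 = st.n_mcdA
    st = _advance_inplace(st, p)
    n_now = st.n_nucleoid + st.n_cytoplasm
    ok = n_now == n0
    nsteps = round(duration / p.run.dt)
    return OracleResult("mcdA_conservation", "PASS" if ok else "FAIL",
                        float(n_now - n0), 0.0,
                        f"count {n_now} vs {n0} after {nsteps} steps")


def force_pair_oracle(params: SimParams, seed: int = 0,
                      n_states: int = 200) -> OracleResult:
    """Self-association force pairs must cancel to 1e-9 pN on random states."""
    rng = np.random.default_rng(seed)
    p = params.copy()
    worst = 0.0
    st = engine.init_state(p, 0)
    for _ in range(n_states):
        lx = p.geometry.nucleoid_length * 1e3
        ly = p.geometry.nucleoid_width * 1e3
        st.centers[:, 0] = rng.uniform(0, lx, size=st.centers.shape[0])
        st.centers[:, 1] = rng.uniform(0, ly, size=st.centers.shape[0])
        from .mechanics import self_force_pair_table
        table = self_force_pair_table(st, p)
        if table.size:
            worst = max(worst, float(np.abs(table[:, 0] + table[:, 1]).max()))
    ok = worst <= 1e-9
    return OracleResult("self_force_pairs", "PASS" if ok else "FAIL",
                        worst, 1e-9,
                        f"max |F_c + F_d| = {worst:.2e} pN over "
                        f"{n_states} random configurations")


def tau_leap_consistency_oracle(params: SimParams, seed: int = 0,
                                n_runs: int = 8,
                                duration: float = 15.0) -> OracleResult:
    """Halving dt must leave ensemble statistics unchanged within 3 SE.

    Statistic: final nucleoid-bound McdA fraction under full dynamics.
    Oversized dt (the negative control) distorts the per-step transition
    probabilities and the mechanics, shifting the statistic.
    """
    def stat(dt: float) -> np.ndarray:
        p = params.copy()
        p.run.dt = dt
        p.run.duration = duration
        p.run.record_interval = duration
        vals = []
        for i in range(n_runs):
            st = engine.init_state(p, seed + i)
            st = _advance_inplace(st, p)
            vals.append(st.n_nucleoid / st.n_mcdA)
        return np.asarray(vals)

    dt = params.run.dt
    a = stat(dt)
    b = stat(dt / 2.0)
    se = math.sqrt(a.var(ddof=1) / n_runs + b.var(ddof=1) / n_runs)
    se = max(se, 1e-9)
    z = abs(a.mean() - b.mean()) / se
    return OracleResult("tau_leap_consistency", "PASS" if z < 3 else "FAIL",
                        z, 3.0,
                        f"bound fraction {a.mean():.4f} (dt) vs "
                        f"{b.mean():.4f} (dt/2), n={n_runs}")


def validate_model(params: SimParams, seed: int = 0,
                   include_tau_leap: bool = True) -> ValidationReport:
    """Run the oracle suite against closed-form physics and invariants.

    Oracles use scaled-down problem sizes chosen so the whole suite runs
    in well under two minutes while keeping each test's power at the 3-SE
    level it asserts.
    """
    validate(params)
    entries = [
        msd_free_diffusion(params, seed),
        tethered_extension_oracle(params, seed),
        two_state_occupancy_oracle(params, seed),
        depletion_asymmetry_oracle(params, seed),
        movement_range_equivalence_oracle(seed),
        conservation_oracle(params, seed),
        force_pair_oracle(params, seed),
    ]
    if include_tau_leap:
        entries.append(tau_leap_consistency_oracle(params, seed))
    return ValidationReport(entries=entries)
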