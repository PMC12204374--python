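#!/usr/bin/env python
"""Calibration driver for the reference parameter set.

The published model fixes only the observable scale of the system: disk
diameter, the self-association stiffness of the phase-diagram
cross-section (0.6 pN/nm), the representative McdA-McdB stiffnesses
(0.1 / 0.3 / 0.8 pN/nm), run length, ensemble size, and the two
classification thresholds.  The microscopic constants (rates,
diffusivities, copy numbers, capture geometry, self-association range)
are free, and the reference set is chosen so that the three regimes
appear at the printed stiffnesses:

  k_AB = 0.1 -> clustered and diffuse
  k_AB = 0.3 -> clustered and positioned
  k_AB = 0.8 -> partitioned and positioned

This script scans a small neighborhood of the calibration-sensitive
constants (McdA surface diffusivity, bond turnover rate, cytoplasmic
rebinding rate, carboxysome diffusivity, McdA copy number) and scores
each candidate by how many of the six regime conditions hold in a small
ensemble.  Run time grows quickly with the grid; the default scan is a
sanity check around the shipped defaults rather than a full search.

Usage:  python scripts/calibrate.py [--n 4] [--duration 300]
"""

from __future__ import annotations

import argparse
import itertools

import numpy as np

from mcdratchet import analysis, default_params, engine


def score_config(params, n: int, base_seed: int = 0) -> tuple[int, str]:
    """Six binary conditions: (clustered, diffuse) at 0.1, (clustered,
    positioned) at 0.3, (partitioned, positioned) at 0.8."""
    lines = []
    hits = 0
    thr_f = params.classify.clustered_time_fraction
    thr_r = (params.classify.positioned_range_fraction
             * params.geometry.nucleoid_length)
    for k_AB, want_clustered, want_positioned in (
            (0.1, True, False), (0.3, True, True), (0.8, False, True)):
        p = params.copy()
        p.springs.k_AB = k_AB
        fracs, ranges = [], []
        for i in range(n):
            traj = engine.run_trajectory(p, base_seed + i)
            res = analysis.classify_trajectory(traj, p)
            fracs.append(res.clustered_fraction)
            ranges.append(res.movement_range)
        f, r = float(np.mean(fracs)), float(np.mean(ranges))
        ok_c = (f > thr_f) == want_clustered
        ok_p = (r < thr_r) == want_positioned
        hits += ok_c + ok_p
        lines.append(f"  k_AB={k_AB}: frac={f:.2f} range={r:.2f} um "
                     f"[clustered {'ok' if ok_c else 'MISS'}, "
                     f"positioned {'ok' if ok_p else 'MISS'}]")
    return hits, "\n".join(lines)


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--n", type=int, default=4,
                    help="trajectories per stiffness per candidate")
    ap.add_argument("--duration", type=float, default=300.0)
    ap.add_argument("--full", action="store_true",
                    help="scan the 3^2 x 2^2 neighborhood instead of only "
                         "the shipped defaults")
    args = ap.parse_args()

    base = default_params()
    base.run.duration = args.duration

    if not args.full:
        hits, detail = score_config(base, args.n)
        print(f"shipped defaults: {hits}/6 regime conditions\n{detail}")
        return

    d_a0 = base.kinetics.D_mcdA_nucleoid
    krb0 = base.kinetics.k_rebind
    grid = itertools.product(
        [0.5 * d_a0, d_a0, 2.0 * d_a0],       # McdA surface diffusivity
        [0.5 * krb0, krb0, 2.0 * krb0],       # cytoplasmic rebinding
        [base.kinetics.k_bond_off, 2.0 * base.kinetics.k_bond_off],
        [base.kinetics.D_carb, 1.5 * base.kinetics.D_carb],
    )
    best = (-1, None)
    for d_a, krb, koff, d_c in grid:
        p = base.copy()
        p.kinetics.D_mcdA_nucleoid = d_a
        p.kinetics.k_rebind = krb
        p.kinetics.k_bond_off = koff
        p.kinetics.D_carb = d_c
        hits, detail = score_config(p, args.n)
        print(f"D_A={d_a:g} k_rebind={krb:g} k_bond_off={koff:g} "
              f"D_carb={d_c:g}: {hits}/6\n{detail}", flush=True)
        if hits > best[0]:
            best = (hits, (d_a, krb, koff, d_c))
    print(f"\nbest: {best[0]}/6 at D_A={best[1][0]:g} k_rebind={best[1][1]:g} "
          f"k_bond_off={best[1][2]:g} D_carb={best[1][3]:g}")


if __name__ == "__main__":
    main()
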