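"""Cross-section of the phase diagram at fixed self-association stiffness.

Holds k_self at 0.6 pN/nm and runs small ensembles at the three
representative McdA-McdB stiffnesses.  Expected majority regimes:
0.1 pN/nm -> clustered and diffuse (weak ratchet, mobile cluster),
0.3 pN/nm -> clustered and positioned (ratchet confines, cannot split),
0.8 pN/nm -> partitioned and positioned (ratchet splits the pair).

n = 8 trajectories per stiffness keeps this example at a few minutes;
the classification statistics sharpen with the full n = 64.
"""

from mcdratchet import default_params, run_ensemble

params = default_params()
params.springs.k_self = 0.6

for i, k_AB in enumerate((0.1, 0.3, 0.8)):
    p = params.copy()
    p.springs.k_AB = k_AB
    ens = run_ensemble(p, base_seed=100 * i, n=8)
    print(f"k_AB = {k_AB:.1f} pN/nm: majority {ens.majority_regime:24s} "
          f"mean clustered fraction {ens.mean_clustered_fraction:.2f}, "
          f"mean range {ens.mean_movement_range:.2f} um, "
          f"votes {ens.regime_votes}")
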