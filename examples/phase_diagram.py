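"""Compute a coarse (k_self, k_AB) phase diagram and print the regime map.

Each cell runs a small ensemble and is colored by the majority regime.
The full-resolution map uses finer grids and n = 64 per cell; this scaled
version (2 x 3 grid, n = 4) finishes in a few minutes and already shows
the partitioned phase emerging at strong McdA-McdB bonds.
"""

from mcdratchet import default_params, sweep_phase_diagram

params = default_params()
pd_ = sweep_phase_diagram(params,
                          k_self_values=[0.3, 0.6],
                          k_AB_values=[0.1, 0.3, 0.8],
                          n=4, base_seed=0)

short = {"clustered_diffuse": "CD", "clustered_positioned": "CP",
         "partitioned_positioned": "PP"}
print("majority regime per cell (rows: k_self; cols: k_AB)")
print("          " + "  ".join(f"{k:>4.1f}" for k in pd_.k_AB_grid))
for ks, row in zip(pd_.k_self_grid, pd_.majority_map()):
    print(f"k_self {ks:.1f}:  " + "  ".join(f"{short[r]:>4s}" for r in row))
print("\nCD = clustered+diffuse, CP = clustered+positioned, "
      "PP = partitioned+positioned")
for rec in pd_.to_records():
    print(f"  k_self={rec['k_self']:.1f} k_AB={rec['k_AB']:.1f}: "
          f"clustered fraction {rec['mean_clustered_fraction']:.2f}, "
          f"range {rec['mean_movement_range_um']:.2f} um")
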