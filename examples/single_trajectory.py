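"""Run one 300 s trajectory of the two-carboxysome system and classify it.

With the default (wild-type-like) bond stiffness k_AB = 0.8 pN/nm the
McdA-McdB ratchet is strong enough to pull the pair apart against the
self-association spring: expect a low clustered fraction (the fraction of
recorded samples with the two centers within the self-association range)
and a partitioned regime call.
"""

from mcdratchet import classify_trajectory, default_params, run_trajectory

params = default_params()
print(f"k_AB = {params.springs.k_AB} pN/nm, "
      f"k_self = {params.springs.k_self} pN/nm, "
      f"{params.run.duration:.0f} s run")

traj = run_trajectory(params, seed=1)
res = classify_trajectory(traj, params)

print(f"samples recorded:    {traj.n_samples}")
print(f"clustered fraction:  {res.clustered_fraction:.3f}  "
      "(fraction of samples with centers <= self_range apart)")
print(f"movement range:      {res.movement_range:.3f} um  "
      f"({res.movement_range / params.geometry.nucleoid_length:.2f} of the "
      "nucleoid length; < 0.25 counts as positioned)")
print(f"regime:              {res.regime_full}")
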