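"""Check the simulator against closed-form physics.

Runs the oracle suite: free-diffusion MSD (4 D t), equipartition of a
thermally fluctuating tether (<ext^2> = 2 kBT / k_AB), the two-state
McdA nucleoid/cytoplasm equilibrium, the depletion asymmetry behind a
moving cargo (the ratchet's engine), exact movement-range agreement
between the convex-hull and brute-force paths, force-pair cancellation,
McdA conservation, and tau-leap dt-consistency.  Every line should read
PASS (statistical oracles assert within 3 standard errors).
"""

from mcdratchet import default_params, validate_model

report = validate_model(default_params(), seed=0)
print(report)
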