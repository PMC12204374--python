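# Methods

## The model

`mcdratchet` is an agent-based stochastic model of carboxysome transport
on the bacterial nucleoid by the McdAB system, extended with cargo
self-association.  It asks a single question: as the stiffness of the
McdA-McdB bond is varied against the stiffness of carboxysome-carboxysome
self-association, when does the system merely *position* a carboxysome
cluster and when can it also *partition* the cluster into separated,
individually positioned carboxysomes?

The world is a 2D rectangle representing the nucleoid surface
(default 2.0 µm × 0.5 µm; the long axis is the cell axis).  It contains:

* **McdA** — N identical particles, each either bound to the nucleoid or
  in a well-mixed cytoplasmic pool.  The nucleoid is discretized as a
  square lattice of binding sites (25 nm spacing) holding at most one
  McdA each, which implements volumetric exclusion exactly.  Nucleoid
  McdA hops between adjacent empty sites (surface diffusion D_A);
  unbonded McdA also detaches at a slow intrinsic rate, and cytoplasmic
  McdA rebinds to a uniformly random empty site at rate k_rebind.
  Rebinding is slow compared with bond turnover — this is what lets a
  moving carboxysome leave a depletion wake behind it.
* **Carboxysomes** — hard disks of diameter 150 nm carrying a fixed set
  of McdB sites (default 100), placed uniformly over the disk footprint
  and translating rigidly with it (no rotation).
* **McdA-McdB bonds** — a free McdB site binds its nearest free nucleoid
  McdA within a 25 nm capture radius at rate k_bond_on.  A bond is a
  zero-rest-length Hookean spring of stiffness k_AB between the McdB site
  and the (immobile) lattice position of its McdA.  Bonds break at rate
  k_bond_off, and unconditionally when stretched past max_extension_AB.
  Every break ejects the McdA into the cytoplasm at once — McdB-stimulated
  release, idealized as instantaneous because it is much faster than the
  intrinsic dissociation rate.
* **Self-association** — each carboxysome pair closer than self_range is
  coupled by a Hookean spring of stiffness k_self with rest length one
  diameter (contact).  The spring disengages beyond self_range with no
  hysteresis.

Carboxysome centers follow overdamped Langevin dynamics,

    x ← x + (F_net/γ) dt + sqrt(2 D_c dt) η,    γ = kBT / D_c,

with η standard normal per axis, explicit Euler-Maruyama, forces
evaluated at the start-of-step positions.  After each displacement,
overlapping disks are projected symmetrically back to contact and centers
are reflected specularly into the rectangle.

One time step applies, in fixed order: (1) McdA lattice hops,
(2) cytoplasm→nucleoid rebinding, (3) intrinsic unbinding of unbonded
McdA, (4) bond formation, (5) force evaluation (bond + self-association
springs), (6) carboxysome displacement with exclusion and reflection,
(7) bond breaking with ejection.  Kinetics precede mechanics so the bond
set is consistent during force evaluation; the ordering is a convention
and its effects vanish as dt → 0.  All transition probabilities have the
tau-leap form 1 − exp(−rate·dt), so halving dt leaves ensemble statistics
unchanged within sampling error (checked by an oracle).

### Why this moves: the Brownian ratchet

Bond breaking consumes nucleoid McdA under the cargo (ejection + slow
rebinding), so a carboxysome sits in a self-made depletion zone.  Any
displacement puts more McdA in front of it than behind; new bonds then
form preferentially at the front, and their spring tension rectifies
thermal motion into directed transport.  The depletion-asymmetry oracle
(`validate_model`) measures exactly this: time-averaged McdA occupancy in
the trailing half-annulus behind a moving cargo is lower than in the
leading half-annulus.

### The three regimes

With two carboxysomes and the self-association stiffness fixed at
0.6 pN/nm, the bond stiffness k_AB selects the regime:

* **Clustered and diffuse** (weak bonds, k_AB ≈ 0.1 pN/nm).  The pair
  stays within the self-association range but wanders.  Mobility of a
  bonded cargo is dominated by bond friction — each bond of lifetime
  1/k_bond_off acts as a dashpot, γ_bond ≈ n_b·k_AB/k_bond_off — so the
  effective diffusivity scales like k_bond_off/(n_b·k_AB): *weaker bonds
  mean a more mobile cluster*.  Weak bonds are also frequently dragged
  past the over-extension guard during low-bond-count excursions, which
  further thins the tether set.
* **Clustered and positioned** (intermediate, k_AB ≈ 0.3 pN/nm).  Bond
  friction now pins the cluster, but the summed outward bond tension on
  each member, capped by the guard extension (n_b · k_AB · e_max), stays
  below the maximum self-spring restoring force
  k_self·(self_range − rest), so the pair cannot split: it holds near
  its initial mid-nucleoid position.
* **Partitioned and positioned** (strong, k_AB ≈ 0.8 pN/nm).  The
  outward tension exceeds the self-spring barrier; the pair separates and
  each carboxysome crawls away hand-over-hand until the McdA flux from
  its pole side balances the partner's consumption shadow, where it
  parks with small residual motion.

## Classification

For each 300 s trajectory, recorded every 0.1 s (3001 samples):

* **clustered fraction** — fraction of samples with the two centers
  within self_range.  "Clustered" requires strictly more than 0.90.
* **movement range** — per carboxysome, the maximum distance between any
  two recorded points of its path (the path diameter), maximized over
  the two carboxysomes.  "Positioned" requires strictly less than
  0.25 × nucleoid length.  The diameter is computed from the convex hull
  (the farthest pair lies on the hull) and is checked to 10⁻¹² µm
  against the O(n²) brute force.

The three named regimes cover clustered∧¬positioned, clustered∧positioned
and ¬clustered∧positioned.  The fourth logical cell — partitioned but
wandering — is labeled `partitioned_diffuse` in full (JSON) output and
folded into `partitioned_positioned` on the 3-color phase map, which
preserves information without inventing a fourth phase color.  Ensembles
(default 64 trajectories, seeds base..base+n−1) report mean fractions and
ranges plus a majority-vote regime; vote ties resolve toward the
more-clustered regime (a documented convention; ties are rare).
"Fraction of time" is computed over recorded samples, not integration
over dt sub-steps.

## Parameters

Printed model constants (fixed): disk diameter 150 nm; k_self = 0.6 pN/nm
for the cross-section; representative k_AB = 0.1, 0.3, 0.8 pN/nm;
duration 300 s; 64 trajectories; 2 carboxysomes; thresholds 0.90 and
0.25·L.

Everything else is a calibration of this implementation, chosen once so
that the three regimes appear at the printed stiffnesses, and all
overridable through the config file:

| parameter | default | units | role |
|---|---|---|---|
| nucleoid | 2.0 × 0.5 | µm | elongated nucleoid surface |
| lattice spacing | 25 | nm | McdA site grid (= capture radius) |
| n_mcdA | 800 | – | 50% lattice occupancy when fully bound |
| n_mcdB_per_carb | 100 | – | dense McdB coverage of the disk |
| D_mcdA_nucleoid | 0.008 | µm²/s | slow surface diffusion; sets depletion-zone healing |
| k_rebind | 0.25 | 1/s | slow cytoplasm→nucleoid return (wake memory ~4 s) |
| k_off_intrinsic | 0.03 | 1/s | rare unstimulated release |
| k_bond_on | 50 | 1/s | near-diffusion-limited bond formation in range |
| k_bond_off | 2.0 | 1/s | bond turnover; sets bond friction and consumption |
| D_carb | 0.002 | µm²/s | free-cargo diffusivity (drag γ = kBT/D) |
| capture_radius | 25 | nm | one lattice spacing |
| max_extension_AB | 30 | nm | over-extension guard; see below |
| rest_length_self / self_range | 150 / 200 | nm | contact rest length; finite engagement range |
| kBT | 4.1 | pN·nm | room-temperature thermal energy |
| dt | 5×10⁻⁴ | s | explicit-Euler step (stability: n_b·k_AB·dt/γ ≪ 1) |

Two of these deserve comment.  The **self-association range** (200 nm,
i.e. 50 nm beyond contact) sets the energy barrier a separating pair must
overcome, k_self·(self_range − rest) = 30 pN at 0.6 pN/nm; the
intermediate-stiffness tug stalls below it and the strong-bond tug
exceeds it, which is what places the partition boundary between 0.3 and
0.8 pN/nm.  The **over-extension guard** (30 nm, just above the capture
radius) acts as the hard displacement limit of a bond: bonds whose
anchor is left behind by a moving cargo release quickly instead of
accumulating unbounded tension.  This keeps strong-bond transport
hand-over-hand, and for weak bonds it converts low-bond-count lurches
into slip events that keep the cluster mobile.  Bond breaking remains
extension-independent below the guard.

## Synthetic-data scope

The model generates all of its own data; there is no external input.
What it emulates: an elongated nucleoid with excluded-volume McdA,
depletion-zone transport, cargo aggregation via an effective spring, and
the published classification protocol.  What it does not: 3D geometry,
explicit cytoplasmic diffusion (the cytoplasm is a well-mixed delay
pool — only slow rebinding matters to the ratchet), nucleoid structure
or growth, ATP biochemistry (hydrolysis is abstracted into
break-plus-ejection), cargo rotation, hydrodynamics, and force-dependent
bond kinetics beyond the hard guard.  Passing regime tests therefore
demonstrates the mechanism's internal consistency at the stated
parameters, not a quantitative fit to any measured cell.

## Numerics and conventions

* Internal units nm / s / pN; file outputs µm / s.  CSV positions carry
  6 significant digits (sub-nm).
* One splitmix64 counter-based RNG stream per trajectory, seeded with the
  trajectory seed; draws occur in fixed iteration order (particles by id,
  McdB sites by (carboxysome, site) index), so identical (params, seed)
  give bit-identical trajectories on any platform.
* Bond-formation matching: candidate (site, McdA) pairs are swept in
  order of distance (ties: lower site index, then lower McdA id); each
  free site attempts only its nearest still-free candidate per step.
* Overlap resolution and boundary reflection are alternated up to four
  times after each displacement so neither correction reintroduces the
  other's violation.
* Coincident carboxysome centers (a measure-zero event) separate along
  +x deterministically.
* If a coordinate becomes non-finite the run aborts with a diagnostic
  naming the step — the symptom of a dt too large for n_b·k_AB/γ.
* Initial state: disks in a touching row at the domain center (so all
  three regimes are distinguishable from one start); McdA placed at the
  two-state equilibrium bound fraction k_rebind/(k_rebind+k_off); no
  bonds at t = 0.

## Validation oracles

`validate_model` checks the implementation against closed forms, each at
3 standard errors unless exact: free-diffusion MSD = 4·D·t; tethered-bond
equipartition ⟨ext²⟩ = 2 kBT/k_AB; two-state bound fraction
k_rebind/(k_rebind+k_off); depletion asymmetry (trailing < leading
occupancy); hull/brute-force movement-range agreement (10⁻¹² µm);
self-association force-pair cancellation (10⁻⁹ pN); McdA conservation;
and tau-leap dt-consistency.  Oracle problem sizes are scaled (tens of
seconds of simulated time, small ensembles) so the whole suite runs in
about a minute while keeping each test's stated power.

## Known limitations

* The regime boundaries in (k_self, k_AB) are calibration-dependent;
  only their ordering and the three-regime topology are robust across
  the scanned neighborhood.
* With two cargos starting at mid-nucleoid, a partitioned pair must
  travel a finite distance before parking, so the movement range in the
  partitioned regime sits closer to the 0.25·L threshold than in the
  clustered-positioned regime.
* The fixed-step tau-leap scheme is approximate; event-driven exactness
  was traded for a uniform, vectorizable update (the dt-halving oracle
  bounds the error).
* Whether bonded McdA should retain surface mobility is undetermined;
  here bonded anchors are immobile.
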