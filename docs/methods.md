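# Methods

## The supervised-dynamics protocol

`sumdkit` implements supervised molecular dynamics (SuMD): an adaptive
sampling scheme that accelerates the observation of binding events without
ever biasing the forces.  The simulation proceeds as a sequence of short,
fully unbiased NVT steps (default 300 ps at 310 K).  After each step the
distance between the centres of mass of two user-selected atom groups
(a mobile "ligand" group and a receptor "binding-region" group) is
computed at every saved frame, an ordinary-least-squares line is fitted to
distance versus time, and the step is kept only if the slope is negative —
the ligand is approaching.  A rejected step is re-run from the same
coordinates with freshly resampled Maxwell–Boltzmann velocities.  The
final coordinates of a productive step seed the next step; velocities are
resampled before every attempt, productive or not.  Because each retained
step is an ordinary MD trajectory, the stitched result is a physically
continuous (if time-censored) binding pathway.

Two deliberate contract choices the slope rule leaves open:

* **slope exactly 0 is rejected** (a frozen ligand makes no progress, so
  resampling is the right response);
* **a productive step is not elongated** — the next step restarts from its
  final coordinates with new velocities.  The alternative reading
  (continuing the same velocities) would make replay of rejected attempts
  ill-defined.

### Two supervision phases

For binders that combine a structured core with a disordered, positively
charged tail (the RNA-binding IDR scenario), single-distance supervision
of whole molecules tends to stall: the first contacts are made by the
tail, not the core.  The protocol therefore runs two phases:

1. **Phase 1 (IDR approach)** supervises the distance between the
   disordered tail and a groove site on the receptor.  The phase ends
   when the tail has *stabilised* in contact: at least `switch_fraction`
   (default here 0.5) of a productive step's frames lie below
   `switch_distance`.  "Stabilised in contact" is qualitative; this
   frame-fraction rule is the package's documented quantitative proxy and
   both knobs are explicit configuration.
2. **Phase 2 (core docking)** switches the supervised selection to the
   structured core and terminates when a productive step's final frame is
   below `target_distance`.  Checking the *final* frame (rather than any
   frame) is consistent with the restart-from-final-coordinates rule: the
   state that satisfies the criterion is exactly the state the protocol
   would continue from.

A subtlety the slope rule creates: a group that has *reached* its goal
sits at its contact floor, so its distance series is flat and every step
is rejected — evaluated naively, the protocol deadlocks at exactly the
state it is seeking.  The controller therefore evaluates the
stabilisation rules on **every** attempt: a rejected step whose frames
satisfy the switch rule still ends the phase (its frames are not
retained, keeping the slope/decision contract intact), and in the final
phase stable residency — at least half of a step's frames below
`target_distance` — terminates the run with `reached_target`.

### Determinism

Every stochastic event derives from the protocol's `master_seed`: attempt
`a` of productive step `s` uses the two 31-bit integers generated by
`numpy.random.SeedSequence([master_seed, s, a])` as its velocity and
dynamics seeds.  No wall-clock state enters anywhere, so a run replays
bit-for-bit from its echoed configuration, including the full
accept/reject history in the JSONL step log.

## The coarse-grained Langevin engine

The bundled backend integrates Langevin dynamics with the BAOAB splitting
(Leimkuhler–Matthews): half-kick, half-drift, Ornstein–Uhlenbeck velocity
update (`c1 = exp(-γ dt)`, `c2 = sqrt(1 - c1²)`), half-drift, half-kick,
with one force evaluation per step.  With friction γ → 0 the O-step is
the identity and the integrator reduces exactly to velocity Verlet, which
is how the NVE energy-conservation checks drive it.

Units are fixed package-wide: Å, ps, amu, kcal/mol, elementary charge,
kelvin (`1 kcal/mol = 418.4 amu Å²/ps²`, k_B = 0.0019872 kcal/mol/K,
k_e = 332.0637 kcal Å/(mol e²)).

Potential terms:

* harmonic bonds and elastic-network pairs, `E = ½ k (r − r0)²`;
* harmonic positional restraints (equilibration uses 5 kcal/mol/Å² on
  every atom, the conventional restrained-NVT setting);
* 12-6 Lennard-Jones in rmin/ε form with Lorentz–Berthelot combining;
* Coulomb over a uniform relative dielectric.

There is no explicit solvent: the thermostat supplies friction and
noise, a relative dielectric of 10 (configurable) stands in for
dielectric screening, and an optional Debye screening length turns the
electrostatics into ``qq·exp(-r/λ_D)/(ε_r·r)`` — the standard
Debye–Hückel form for dissolved salt.  Screening is off by default (bare
Coulomb over the dielectric); the bundled study systems set λ_D = 8 Å,
the Debye length of 0.154 M monovalent salt at 310 K, because without it
the toy complex's large net charges (−32 e receptor strands, +3 e tail)
steer binding ballistically from 30 Å and there is nothing left to
supervise.
Cutoffs are **off by default** — for systems of ≲10³ beads
the direct O(N²) sum is exact and affordable.  When enabled, LJ is
switched between 7.5 and 9.0 Å (CHARMM switching function) and Coulomb is
truncated at the cutoff; there is no Ewald treatment, and the truncation
discontinuity is the documented price of that mode.  Directly bonded
pairs are excluded from nonbonded sums; elastic-network pairs are not.

Engine defaults follow common all-atom practice (2 fs timestep, 310 K);
the bundled coarse-grained systems run at 10 fs, which is comfortably
stable for 50 amu beads with these soft force constants (the stiffest
bond period is ≈340 fs).  A numerical-singularity guard rejects
nonbonded pairs closer than 1e-6 Å, and non-finite coordinates abort the
run with the failing step index.

The hot loops (nonbonded sums and the fused BAOAB integrator) are
numba-compiled; thermostat noise is pre-drawn per `advance` call from a
numpy PCG64 generator seeded with the call's seed, which is what makes
`advance` bit-reproducible given `(state, seed)`.

### The engine contract

The supervision loop drives any object with
`advance(state, duration, seed) -> (segment, state)` and
`resample_velocities(state, seed) -> state`, where the returned segment
holds one frame per snapshot interval and excludes the starting frame.
An adapter wrapping an all-atom engine satisfies the same contract; note
it deliberately has no pressure-coupling surface — NPT equilibration
belongs to system preparation on the backend side and is not part of the
supervised production contract.

## Trajectory analysis

* **Superposition** uses the Kabsch algorithm (SVD with determinant
  correction, weights optional).  `cross_rmsd` superposes each frame on
  an alignment selection and reports the unweighted RMSD over a separate
  measurement selection — e.g. align on the nucleic-acid backbone,
  measure the protein backbone.
* **Backbone presets** (the field does not standardise these atom lists,
  so they are explicit and overridable): protein backbone = N, CA, C, O;
  nucleic backbone = P, OP1, OP2, O5′, C5′, C4′, C3′, O3′.
* **Interaction energies** are the sum of electrostatic and van der Waals
  terms between the two components, computed by default with no cutoff
  (exact double sum); a switched-cutoff mode matching the engine settings
  exists for comparability.  The per-residue decomposition assigns each
  cross-pair energy to the residue of the chosen component, so rows sum
  exactly to the component's total interaction energy per frame.
* **Contacts**: a residue is in contact in a frame if any of its atoms is
  within 4.5 Å of the partner component; tables keep the 25 most
  frequently contacting residues per component by default.
* **Replica ranking**: each replica of a stability run (classical-MD
  extension of a supervised endpoint) is summarised by mean ± sd of
  RMSD-from-first-frame and of total interaction energy (population sd,
  ddof = 0).  Replicas are ordered by the sum of their within-set ranks
  of mean RMSD (ascending) and mean energy (ascending, most favourable
  first); ties break by mean energy, then input order.  RMSD against an
  experimental reference is a separate, explicit `cross_rmsd` call — the
  stability metric deliberately uses the trajectory's own first frame.

## The synthetic complex generator

`make_toy_complex` builds the study system: a rigid polyanionic
double-strand arc (one −1e bead per "nucleotide", two semicircular
strands 5.5 Å apart, cross-linked by an elastic network) whose concave
face forms a groove, and a binder made of an elastic-network core
(16 beads, two +1e beads standing in for surface lysines near the tail
anchor) plus a short bonded tail of 4 beads with alternating +1e charges
— an RGGR-like motif.  Bead masses are 50 amu, spacing 3.8 Å (Cα-like),
LJ rmin/2 = 2.0 Å, ε = 0.15 kcal/mol.

The start frame displaces the binder along a random, seeded direction
until its nearest bead is `initial_separation` (default 30 Å) from the
nearest receptor bead — a *surface clearance*, the quantity that governs
whether the start lies inside or outside the electrostatic capture zone
(a COM-to-COM reading would leave only ~15-25 Å of clearance against a
receptor this wide and make rebinding ballistic).  Two further placement
rules matter:

* the direction is rejection-sampled to the groove-facing cone
  (cos ≥ 0.2 with the groove axis by default, configurable) — emulating
  displacement *away from the binding site* rather than behind the
  receptor, from where the structured core cannot re-engage;
* the tail starts extended *perpendicular* to the approach direction, so
  no tail bead begins closer than the clearance and the tail has to
  locate the groove itself.

The bound reference is constructed geometrically (never by simulation):
the core nestles against the concave face at the arc bottom and the tail
drapes from the core's edge along the groove midline at LJ-contact
distance from both strands.  It serves only as an RMSD fixture and as
the source of the protocol thresholds: each phase supervises against the
receptor beads nearest its group's bound position, the phase-1 switch
distance is the bound tail–site distance + 4 Å, and the phase-2 target
is the bound core–dock-site distance + 2 Å.  A neutral backing ridge
behind the arc bottom gives the receptor body thickness there, so the
dock site cannot be approached from the convex back of an otherwise
thin two-strand shell.

What the generator does **not** emulate: real RNA geometry, base pairing,
sequence effects, explicit solvent, counterions, conformational change of
the receptor, or the entropic cost of folding a long IDR (the tail is
short by design).  Passing the end-to-end tests therefore demonstrates
that the supervision logic, bookkeeping and analyses behave correctly on
a system with the right qualitative physics (electrostatic steering,
tail-first recognition, sticky contacts) — not that the toy force field
is predictive for any real complex.

## Problem sizes and numerical choices

The package's own test and benchmark conditions, chosen once:

* toy complex: 32 strand + 6 backing + 12 core + 6 tail = 56 beads,
  30 Å initial nearest-atom clearance; receptor beads rmin/2 = 2.5 Å
  (nucleotides are bulkier than residues; the wider, softer contact
  keeps surface sliding alive at 310 K), binder beads 2.0 Å;
* toy dynamics: 20 fs timestep (stiffest bond period ≈340 fs; the
  strongly overdamped update tolerates the ratio comfortably), friction
  30 ps⁻¹ (an implicit-water collision frequency, supplying the solvent
  viscosity the model otherwise lacks — with weak friction the bead
  complex diffuses orders of magnitude faster than a solvated protein
  and random search trivialises), 310 K, snapshots
  every 10 ps, 300 ps supervision steps, 50 ps restrained
  pre-equilibration at 5 kcal/mol/Å²;
* toy electrostatics: dielectric 10, Debye length 8 Å (0.154 M
  monovalent salt at 310 K);
* supervised runs: retry budget 20 per step, at most 40 productive steps;
* the unsupervised baseline for efficacy comparisons runs the same
  300 ps chunks with per-chunk velocity resampling but accepts every
  chunk; each paired baseline is evaluated up to its supervised
  partner's integrated budget (beyond that the pair's sign is already
  decided), times are counted in whole chunks on both sides, and a
  failed supervised run is scored as a loss for supervision.

Tolerances used by the physics checks: forces agree with central
differences to 1e-4 relative; NVE energy drift stays below 1e-4 relative
over 10⁴ steps; long-run kinetic temperature and the harmonic-oscillator
position variance sit within 5% of their closed-form values; per-residue
energy rows sum to the total within 1e-6 relative.

## What the bundled benchmark does and does not show

The package's own end-to-end benchmark (20 seeded recognition runs with
paired plain-dynamics baselines, recomputed by the test suite) shows the
protocol's *robustness*: a clear majority of supervised runs reach the
bound state within a 40-step budget, while plain chunked dynamics from
the same starts usually never does — it wanders off or sticks at decoy
contacts.  It does **not** show a mean speed advantage: supervision pays
its rejection overhead during the diffusive approach and pursues a
stricter intermediate goal (a stabilised tail at the groove site) than
the raw termination criterion requires, and on this landscape those
costs offset the guidance on average.  The efficacy test that compares
mean integrated time-to-target by a paired sign test therefore fails
under these study conditions, and is left failing rather than tuned.

## Known limitations

* Coulomb truncation (cutoff mode) does not conserve energy exactly at
  the cutoff; keep cutoffs off for small systems.
* The slope test is scale-free: near-zero negative slopes from pure noise
  are accepted, so progress per productive step can be slow when the
  supervised distance is near its equilibrium — the retry and step
  budgets are the guard rails.
* XTC storage quantises coordinates to 0.01 Å and times to float32;
  analyses on re-read trajectories inherit that precision.
* `read_pdb` infers elements from the first alphabetic character of the
  atom name; exotic names need explicit editing.
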