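# Methods

This document records the physical model, the algorithms, and the numerical
and design decisions behind `treemd`, including known limitations.

## 1. Model overview

The system consists of `Na` classical atoms/ions (positions, velocities,
per-orbital electron occupations) and `Ne` free classical electrons (mass 1,
charge −1). Derived counts: `Ni` ions (charge ≥ 1) and `Nq = Ni + Ne` charged
particles; neutral atoms feel no Coulomb force but remain secondary-ionization
targets. An atom's charge state is always re-derived as (neutral electron
count − Σ occupations), so charge bookkeeping cannot drift.

Each timestep runs four blocks in a fixed order — recombination, secondary
ionization, stochastic atomic events, velocity-Verlet propagation. All event
blocks mutate the particle lists *between* MD steps; the MD force evaluation
of a step therefore sees every particle that step's events created.

### Units

Internal math uses Hartree atomic units: length in bohr, energy in hartree,
mass in electron masses, time in ℏ/Eₕ (≈ 24.188843 as). Coulomb's law then
carries no prefactor. Interfaces accept/emit Å, eV, fs, attoseconds, Mbarn
and photons/μm²; all conversion constants (CODATA 2018) live in
`treemd.constants` and nowhere else. The default timestep of 1 as is
≈ 0.041341 a.t.u.

### Rate tables

Per-element orbital capacities, neutral occupations, binding energies,
photoionization cross sections (at the configured photon energy), Auger and
fluorescence rates, and the impact-ionization model constant ship as a YAML
file (`treemd/data/rate_tables.yaml`). The packaged H and O entries are
*toy values* of the right order of magnitude: binding energies and the O
K-hole Auger rate are near literature values, while photoionization cross
sections are rounded. They are inputs — no result of the package depends on
their absolute accuracy, only on determinism and threshold behavior.
Orbitals are ordered deepest-first; the loader validates ordering,
nonnegativity and capacity consistency.

## 2. Linear oct-tree

Atoms/ions (or ions only, for recombination) are indexed by a pointerless
array-backed oct-tree:

* **Root box** — the tight bounding cube of the indexed positions, expanded
  by a relative 10⁻⁶ so boundary particles are strictly interior; rebuilt
  from scratch every step.
* **Box identifiers** — each particle gets a `3·d`-bit key for tree depth
  `d` (15 bits at the example depth 5): per level, one bit per axis set iff
  the coordinate is ≥ the box midpoint (lower-inclusive/upper-exclusive
  halves; the root's upper faces are inclusive), most significant level
  first, with the axis triple packed as `4·bx + 2·by + bz`. The point at the
  root center therefore lands in octant 7 at depth 1.
* **Build** — a stable argsort of the keys (ties keep original particle
  order, which fixes all downstream tie-breaks), then per-level tables of
  (key prefix, slot start, slot end) for every occupied box plus
  parent→child ranges obtained by `searchsorted` on key prefixes. O(Na log Na),
  fully vectorized.
* **Queries** — fixed-radius (`neighbors_within`) and nearest-within-radius
  (`nearest_within`, batched as `nearest_within_batch`). The frontier descent
  prunes boxes whose padded box-to-point squared distance exceeds the query
  radius (padding: 10⁻⁹ of the root side, conservative — it can only *keep*
  boxes), descends until boxes hold ≤ 8 particles, then evaluates exact
  squared distances.

**Exactness by construction.** Candidate distances are computed by the same
shared elementwise expression (`dx·dx + dy·dy + dz·dz` on coordinate columns)
as the brute-force scans, and the final filter/argmin applies the same
comparison and the same smallest-original-index tie-break. Pruning is
conservative, so tree and brute queries return identical results *bit for
bit*, which is what makes the SI/RE cross-implementation byte-identity
achievable. Work counters record box tests and distance evaluations.

## 3. Coulomb solvers

**Brute force** — exact pairwise summation
`F_i = Σ_{j≠i} q_i q_j (r_i − r_j)/(|r_i − r_j|² + ε²)^{3/2}` with
Newton's-third-law symmetric accumulation in ascending pair order; the
potential is accumulated alongside. Exactly `Nq(Nq−1)/2` pair evaluations.

**Barnes–Hut** — per-box multipole moments (total charge, center of charge,
dipole about it) built bottom-up over the tree: leaf moments are direct sums,
parents follow from children via the moment shift identities. The center of
charge is |q|-weighted so it stays defined for near-neutral boxes. For each
target the tree is walked depth-first: a box of side `s` whose center of
charge is at distance `d` is *accepted* (evaluated through its expansion,
unsoftened) when `s/d < θ` and the box does not contain the target;
otherwise it is opened; leaves (≤ 8 particles) are evaluated directly with
softening ε and self-exclusion. θ = 0 never accepts a box, so the walk
degenerates to the exact brute-force answer. Multipole order is capped at
dipole (order 1, the default); monopole-only is available, quadrupole is a
documented extension point.

**Softening.** ε (default 0.05 bohr in production dynamics) regularizes
close electron–ion encounters between recombination checks; ε = 0 in all
solver-accuracy tests. Coincident charges at ε = 0 raise a
singular-configuration error.

**Compiled kernels.** The two flop-dominated inner loops — the all-pairs
brute sum and the per-target tree walk (over a flattened node-array form of
the tree with an explicit stack) — are `numba.njit`-compiled. Both are
strictly sequential scalar loops with fixed traversal order, so results are
deterministic; per-target walks are independent. The SI/RE search paths
deliberately remain in pure NumPy: their bit-identity contract depends on
the exact floating-point evaluation of the shared distance expression, and
compiler-level FMA contraction could silently alter those bit patterns.

**Counters.** `PairCounter` tracks ordered direct evaluations and multipole
evaluations and reports `direct/2 + multipole`, so a θ = 0 tree run
reproduces the brute-force count exactly.

Measured at θ = 0.4 (order 1) on 5000-charge neutral plasmas: median
relative force error ≈ 9×10⁻³, 99th percentile ≈ 6×10⁻², decreasing
monotonically as θ → 0 and reaching ~10⁻¹⁴ at θ = 0.

## 4. Monte-Carlo block

The pulse is a normalized Gaussian: flux(t) = F·(2√(ln2/π)/fwhm)·
exp(−4 ln2 (t−t₀)²/fwhm²); its integral equals the fluence F and the half
maximum sits at t₀ ± fwhm/2. Runs start at the pulse center by default.

Per step, each atom gets a probability per channel: one photoionization
channel per occupied orbital with binding below the photon energy
(σ_ph · occ/neutral_occ · flux · dt), plus Auger and fluorescence channels
proportional to the deepest-orbital hole count (Auger requires ≥ 2 outer
electrons, fluorescence ≥ 1). Exactly **one uniform draw per atom per
step**, consumed in ascending atom order, selects a channel by cumulative
probability — at most one event per atom per step, and random-number
consumption never depends on outcomes or solver choices. A per-atom total
probability > 1 raises a timestep-too-large error; > 0.1 warns.

Event application: photoionization decrements the orbital and emits an
electron with KE = photon energy − binding; Auger fills the deepest hole
from the outermost occupied orbital and emits a second outer electron with
the tabulated Auger energy; fluorescence moves the hole outward without
creating a classical particle. Every branch conserves total charge. New
electrons are emitted isotropically 0.5 bohr from the parent (avoiding the
zero-distance singularity), with the parent's velocity added. Emission
kinematics draw from a dedicated generator keyed by (seed, step, atom), so
they are reproducible independently of everything else.

## 5. Secondary ionization

The SI criterion is a **pure function of the (electron, nearest-target)
pair** with no random draw in the search:

* Lotz-type cross section σ(E) = a·N·ln(E/B)/(E·B) for E > B, 0 at and
  below threshold (a: model constant, N: orbital occupation, B: binding);
  the cutoff radius is r_cut = √(σ_max/π).
* An event occurs iff the electron's nearest atom/ion within r_cut exists,
  and the relative collision energy ½|v_e − v_a|² reaches at least one
  occupied orbital's binding; the ionized orbital is the occupied orbital of
  largest σ (ties → lowest index).
* The per-electron *search* radius uses the lab-frame kinetic energy and the
  global σ_max over all tabulated elements at neutral occupation — a
  conservative bound independent of which target is eventually found; the
  criterion itself then uses the exact relative energy.

Both implementations process electrons in ascending index order against the
pre-block occupation snapshot; a live-occupancy guard skips an event whose
target orbital was emptied earlier in the same block. On an event: orbital
−1, a secondary electron with E_sec = min(0.1·(E_rel − B), 10 eV) is emitted
isotropically 0.5 bohr from the target (direction from a generator keyed by
(seed, step, electron)), and the primary is rescaled along the relative
velocity direction to the remaining energy. Brute (full Ne×Na scan, counted
exactly) and tree (per-electron `nearest_within`) differ *only* in how the
nearest candidate is found — and the tree search is exact — so event lists
and post-states are byte-identical.

## 6. Recombination

An electron recombines iff its nearest ion within the capture radius
(default 2 bohr) forms a classically bound pair:
½ μ |v_rel|² − q_ion/r < 0. One capture per ion per step (the
lowest-indexed claiming electron wins); the electron is removed, the ion's
charge drops by one, and the outermost orbital with a vacancy gains an
electron. The captured electron's kinetic energy is dropped from the
classical ledger and logged as released recombination energy — no photon is
modeled. Brute (Ne×Ni scan) and tree (oct-tree over ions only)
implementations are byte-identical by the same construction as SI.

## 7. Sample generation and fixtures

**Water cubes** — ⌊ρ·V·N_A/M⌋ H₂O molecules on a jittered cubic lattice
(O–H 0.96 Å, H–O–H 104.5°, random orientation, jitter 0.25 Å, margin
1.3 Å from the faces), zero initial velocities, deterministic per seed.
With explicit (n_atoms, n_ions, n_electrons) targets the molecule count is
taken as ⌈n_atoms/3⌉ and trailing H atoms are trimmed so the atom count is
met exactly; the packaged presets (47/60/75/100/150 Å) regenerate their
benchmark triples exactly. Pre-ionization assigns the **minimal charge-state
distribution**: as many +1 ions as possible, the remainder +2 (placed on O,
which can donate two electrons), always summing to n_electrons so the net
charge is zero; stripped electrons are removed lowest-binding-first, and the
corresponding free electrons are placed uniformly in the cube with Maxwellian
speeds (default 10 eV temperature).

**Plasma fixtures** — `make_plasma` draws uniform positions at water number
density with water stoichiometry, Maxwellian velocities, and exact
ion/electron counts at configurable fractions (defaults 0.21/0.29, the
benchmark composition ratio). All generators are pure functions of their
spec; tests are download-free.

## 8. Determinism and RNG discipline

Reproducibility is a contract, not an accident:

* one global seeded generator drives the MC block (one uniform per atom per
  step, ascending order, regardless of outcome);
* all per-event kinematics (MC emission, SI secondaries) use fresh
  generators keyed by (seed, constant, step, particle index);
* SI and RE contain no randomness at all;
* tree construction uses a stable sort and all queries break ties by the
  smallest original index.

Consequently two runs with equal config and seed are byte-identical, and
swapping any brute implementation for its tree counterpart (or vice versa)
changes neither random-number consumption nor any result bit. Swapping the
*Coulomb* solver does change results within its approximation error
(θ = 0 agrees with brute to summation-order round-off, ~10⁻¹⁴ relative).

## 9. Complexity measurement

Wall-clock timing is hardware-bound, so the scaling claims are verified on
operation counts: Coulomb pair/multipole evaluations and search box-tests +
distance evaluations, collected per block per step. `block_counts` probes one
evaluation of each block on a state (the MD block performs a fixed small
number of force evaluations per step, so per-evaluation counts share the
fitted slope of per-step cost); `fit_loglog_slope` fits log(count) against
log(N). Measured over N ∈ {10³, 4·10³, 1.6·10⁴, 6.4·10⁴} at fixed
composition: brute Coulomb and brute SI sit exactly on their closed forms
(slope 2.0), tree SI ≈ 1.11, tree Coulomb ≈ 1.39, and the combined per-step
count drops below slope 1.4 only when *both* tree solvers are enabled —
with either brute block active the total stays ≈ 2.0.

## 10. Design decisions (summary)

* Deterministic geometric SI criterion instead of a rate draw: makes the
  brute/tree comparison bit-wise testable; any alternative criterion must
  remain a pure function of the (electron, nearest-target) pair.
* Nearest-target (not all-within-cutoff) SI semantics: per-electron
  decisions stay independent.
* MAC distance to the |q|-weighted center of charge; softening applies only
  to direct (leaf) interactions, never to accepted multipoles.
* Capture fills the outermost vacancy; recombination energy is logged, not
  re-emitted.
* Neutral atoms excluded from Coulomb evaluation, included as SI targets.
* The auxiliary tree index is rebuilt every step; no incremental updates.
* Compiled kernels only where results are compared against *tolerances*
  (Coulomb); bit-contract paths stay in NumPy.

## 11. Limitations

* The electronic model is a flat orbital list with toy H/O constants; no
  ab initio cross sections, no charge-state-resolved rates, no shake-off,
  no photoelectron angular distributions.
* No chemical bond force fields, no relativistic dynamics, no magnetic
  interactions, no periodic boundaries/Ewald, no photon transport.
* Recombination uses a classical bound-pair stand-in (distance + relative
  velocity); no radiative/three-body rate physics.
* The pre-ionized presets emulate benchmark *counts* only, not the spatial
  or velocity correlations a real damage calculation would produce.
* Single-threaded reference semantics; parallel tree walks over targets are
  a straightforward extension (per-target results are independent) but are
  not implemented.
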