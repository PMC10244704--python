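# Methods

`pocketdyn` implements the computational workflow used to explain how an
enlarged methyltransferase active-site pocket enables productive cofactor
binding: steered association simulation, geometric detection of
S_N_2 transition-state-like docking, grid-based pocket volumetrics, residue
contact occupancy, and the accompanying statistics. All components run at desk
scale on synthetic structures with analytic ground truth; nothing here
requires an MD engine or experimental data.

Units are Å for length, ps for time, Da for mass and kJ/mol for energy
throughout.

## S_N_2 transition-state detection

A frame of a cofactor-association trajectory counts as a productive docking
event when the four catalytic atoms — the substrate lysine Nε and Cδ, and the
cofactor (AdoMet) methyl carbon and sulfur — satisfy the geometry of an S_N_2
methyl transfer:

1. d(Nε, C_methyl) < 4 Å — strict inequality, as the criterion is printed;
2. attack angle ∠(Cδ, Nε, C_methyl) ∈ 109° ± 30° — inclusive window;
3. donor-axis linearity ∠(Nε, C_methyl, S) ∈ 180° ± 30° — inclusive window.

Interior angles are folded to [0, 180°], so the linearity window is
effectively "angle ≥ 150°". Whether the angle edges are open or closed is not
observable in floating point after a rigid transform; the implementation uses
closed windows and the test suite probes the edges at a 10⁻³ degree offset.
Angles are computed as `atan2(‖u×v‖, u·v)` rather than the arccos of the
normalized dot product: the two are identical on [0, 180°] but the atan2 form
stays well-conditioned near 0° and 180°, which the 10⁻⁹-degree
internal-coordinate round-trip guarantee requires for near-linear geometries.

A replicate is *successful* when at least one recorded frame passes; success
is evaluated only on recorded frames, never on interpolated states. Docked
poses are compared to a bound reference by Kabsch superposition (SVD with
determinant correction; degenerate fit groups are an error) over a
receptor fit group, then an RMSD over the ligand heavy atoms. The fit group
defaults to receptor Cα-like atoms and the ligand group to cofactor heavy
atoms; both are caller-configurable because no canonical subset exists for
the toy systems.

## Steered-association toy simulator

The simulator exists to exercise the detection and statistics pipeline
end-to-end, not to model kinetics. A rigid coarse receptor (a spherical atom
shell around the substrate lysine with a conical mouth; ~200 spheres) and a
mobile 8-bead bonded ligand standing in for the cofactor evolve under
overdamped Langevin dynamics (Euler–Maruyama):

    x ← x + F·dt/(m·γ) + √(2·kB·T·dt/(m·γ))·ξ,   ξ ~ N(0, 1) per coordinate

with per-bead diffusion D = kB·T/(m·γ). Receptor atoms never move; at T = 0
the noise term is exactly zero. Internally 1 kJ/mol = 100 Da·Å²/ps², so the
deterministic update is exactly F·dt/(m·γ) in internal units. The integrator
refuses any step whose displacement reaches the smallest receptor exclusion
radius (tunnelling guard) and advises a smaller dt.

Forces:

- **Steering** — three zero-rest-length harmonic centroid–centroid pulls,
  U = ½·k·d², F = k·d, with the protocol's constants k = 0.2 (methyl group →
  lysine Nε), 0.1 and 0.05 kJ·mol⁻¹·Å⁻² (two guiding pulls orienting the
  ligand's adenine-like and amino-acid-like triads toward anchor triads above
  the pocket mouth). "0.2 × distance" is read as a force linear in distance,
  i.e. a harmonic potential — the printed unit kJ/(mol·Å²) rules out a
  constant force. Reaction forces on the rigid receptor are discarded.
- **Bonds** — harmonic springs (k = 50 kJ·mol⁻¹·Å⁻², rest lengths from the
  ligand template) closing each triad into a triangle. The bead connectivity
  is capped so that the stiffest bond mode stays inside the overdamped
  stability limit k_eff·dt/(m·γ) < 1 at the default time step.
- **Excluded volume** — a purely repulsive pair force
  F = k_rep·(σ − r)·û for r < σ, σ = receptor exclusion radius + bead radius,
  k_rep = 100 kJ·mol⁻¹·Å⁻², soft enough to relax overlaps monotonically.

Defaults: dt = 0.001 ps, friction γ = 1 ps⁻¹, T = 300 K, 20 000 steps per
replicate with one recorded frame per 200 steps (101 frames), bead mass
30 Da, bead radius 1.0 Å, wall exclusion radius 1.2 Å. Temperature and
friction are the production protocol's values; the step count and recording
stride are chosen so that one hundred replicates of each condition run in a
few minutes on one core while leaving the ligand several relaxation times to
find the pocket. Replicate i of an ensemble uses seed `base_seed + i` with
NumPy's default PCG64 generator; identical inputs give bit-identical
trajectories.

The `open` receptor has a 55° conical mouth — wide enough that a thermally
wandering bead (lateral spread ≈ √(kB·T/k₁) ≈ 3.5 Å) finds the entrance in a
minority of replicates, which puts per-ensemble success counts in the
low-tens-per-100 regime where the binomial comparison is informative. The
`occluded` variant caps the mouth with gate spheres whose gaps are smaller
than the bead contact distance, so the catalytic geometry is sterically
unreachable and its success count is structurally zero. Ensemble success
counts are then binomially distributed under replicate exchangeability.

What the toy emulates: seeded stochastic association under guiding forces, a
steric open/closed dichotomy, and TS-geometry detection on recorded frames.
What it does not: force-field energetics, solvent, electrostatics, real
NSD2/AdoMet geometry beyond the four catalytic internal coordinates, or
association kinetics on any physical timescale. Passing tests therefore
validate the *analysis machinery*, not biomolecular predictions.

## Pocket volumetrics

The pocket volume measurement re-implements the POVME-style grid algorithm
with every stage's semantics pinned down:

1. **Grid** — an axis-aligned lattice (default spacing 0.4 Å) anchored at the
   first inclusion sphere's center; a point is kept iff it lies in a closed
   inclusion ball. Anchoring makes results deterministic and independent of
   point order.
2. **Proximity pruning** (distance cut 0.4 Å) — `center` mode drops points
   within the cut of any heavy-atom center; `vdw` mode inflates by per-element
   van der Waals radii (C 1.70, N 1.55, O 1.52, S 1.80, P 1.80 Å; hydrogens
   excluded). Whether the printed cut is measured to centers or surfaces is
   ambiguous, so both modes exist: `vdw` is the realistic default, `center`
   makes the analytic-sphere oracle exact.
3. **Convex-hull exclusion** (optional) — keep points inside or on the hull
   of the receptor heavy atoms (facet half-space test; a degenerate hull is
   an error).
4. **Contiguity** (criterion 3) — iteratively delete points with fewer than
   three occupied 26-neighbours until a fixed point, then keep only
   26-connected components seeded at each inclusion-sphere center (the
   center's nearest lattice cell, falling back to the nearest surviving point
   when that cell was pruned — the fallback matters when a catalytic atom
   sits exactly at the sphere center). This is an explicit, oracle-testable
   interpretation of a "contiguous points criterion of three", not a claim
   about any particular third-party implementation.

Volume = n_points · spacing³; it can never exceed the inclusion-region
volume, and every stage only removes points. Distributions are reported in
right-open bands 0–25 / 25–70 / ≥70 Å³, the large-volume enrichment between
two conditions is the ratio of the fractions of frames ≥ 70 Å³, and
triplicate 10% random frame subsamples (seeded, without replacement) provide
the replicate vector for the t-test. A zero reference fraction yields an
infinite fold with a warning rather than an exception.

The hollow-shell fixture (atoms on a cubic lattice filling a radial band
around an empty cavity) provides the analytic oracle: after inflation the
accessible region is a ball of radius `cavity_radius − inflation`. The
default shell atom spacing of 0.25 Å keeps the lattice gaps well under the
0.4 Å distance cut, so the measured volume tracks the continuum value to
within ~8%; the documented tolerance is 10%.

## Contact occupancy

Two residues (or named atom subsets, e.g. a hydroxyl oxygen vs. a backbone
nitrogen) are in contact in a frame when any heavy-atom pair across the two
groups is strictly below 4.5 Å. No angular hydrogen-bond criterion is
applied — the readout is distance-only by design. Occupancy is the fraction
of recorded frames in contact; per-replicate occupancies, not pooled frames,
are the statistical unit, so a 30-replicate condition contributes a
30-component vector to the t-test.

## Statistics

- **t-test**: classical equal-variance two-sample test, two-tailed, pooled
  df = n₁+n₂−2; the p-value is the regularized incomplete beta
  I_{df/(df+t²)}(df/2, ½). When the pooled variance is zero the test is
  degenerate: p = 1 if the means coincide, else p = 0 (documented
  convention). Verified against an independent implementation and a
  hand-computed example.
- **Binomial tails**: P(X ≥ k) summed in log space (gammaln + logsumexp);
  exact complement identity with the lower tail. For success-count
  comparisons the default construction is the upper tail of the alternative
  condition's count under the reference condition's empirical rate — the
  minimal construction that tests "more successes than the reference
  predicts". A zero reference rate is floored at 1/(2·n_ref) with a warning.
  Two alternative constructions (pooled rate; lower tail of the reference at
  the alternative rate) are selectable, and the construction tag always
  travels with the number, because tail direction and null rate are genuine
  degrees of freedom in this kind of comparison.

## Synthetic data

Every fixture is generated programmatically and is seed-deterministic:

- `make_sn2_geometry` places the four catalytic atoms with prescribed
  internal coordinates (canonical bond lengths Cδ–Nε 1.5 Å, C–S 1.8 Å carry
  no influence on classification) and applies a seeded random rigid
  transform; measuring the internals recovers the prescription to 10⁻⁹.
- `make_pocket_shell` gives the analytic-volume oracle above.
- `make_contact_trajectory` produces exactly round(F·fraction) contact frames
  at a chosen separation, shuffled by seed.
- `make_volume_trajectory` interleaves large-cavity shell frames with the
  same shell radially shrunk so its cavity lands in the 0–25 Å³ band
  (open cavity 3.2 Å, collapsed 1.8 Å), sharing one topology.
- `make_toy_association_system` wires the open/occluded receptor, the 8-bead
  ligand (center of mass placed 27 Å from the lysine Nε along the pocket
  axis), the three steering forces and the TS atom map.

## Pipeline and reproducibility

`run_pipeline` executes conditions from a single config with shared defaults
and per-condition overrides; unknown config keys are hard errors. Per
condition it runs the ensemble, scans for TS-like frames, measures volumes on
triplicate subsamples (ligand beads count as blockers, so docking visibly
collapses the accessible volume) and computes contact occupancies; across the
first two conditions it reports the binomial success-count comparison and
t-tests on subsample large-volume fractions and contact occupancies. Every
output file is listed in a manifest with its SHA-256 checksum together with
the config hash and all seeds; reruns with identical config are
byte-identical.

## Known limitations

- The toy simulator's success rates depend on its fixed geometry; they are
  qualitative (open ≫ occluded), not calibrated to any measured system.
- The contiguity stage is one explicit interpretation of the printed
  parameters; other grid codes may differ near the criterion boundary.
- Inclusion-sphere coordinates are plain config inputs in the frame of the
  structure being analysed; no automatic transfer between structures is
  attempted.
- The binomial construction for comparing success counts is reported, not
  unique; consumers should quote the construction tag alongside the p-value.
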