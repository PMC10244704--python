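# pocketdyn

Steered cofactor-association simulation and trajectory analysis for studying
how active-site pocket geometry controls productive cofactor binding in
SET-domain protein lysine methyltransferases (PKMTs).

## The problem

PKMTs such as NSD2 transfer methyl groups from the cofactor AdoMet to a
substrate lysine (histone H3K36) by an S_N_2 mechanism. How many methyl
groups an enzyme can install — its *product specificity* — is controlled by
the size of the active-site pocket: in a processive mechanism each further
methylation requires a fresh AdoMet to dock onto the enzyme–peptide complex
in a reaction-competent pose, and a collapsed pocket blocks that docking.
Comparing a wild-type-like (occluded) and a mutant-like (enlarged) pocket
therefore comes down to four measurements on simulation trajectories:

1. **TS-like docking detection** — a frame is a productive docking event when
   d(Nε, C_methyl) < 4 Å, the attack angle ∠(Cδ, Nε, C_methyl) is within
   109° ± 30°, and the donor axis ∠(Nε, C_methyl, S) is within 180° ± 30°
   (the S_N_2 transition-state geometry). A replicate *succeeds* if any
   recorded frame passes; success counts over replicate ensembles are
   compared with binomial tail probabilities.
2. **Pocket volumetrics** — POVME-style grid volumes inside user-placed
   inclusion spheres: 0.4 Å grid, 0.4 Å distance cut, contiguity criterion 3,
   optional convex-hull exclusion; distributions in volume bands and
   fold-enrichment of large volumes, on triplicate 10% frame subsamples.
3. **Contact occupancy** — two residues are in contact when any heavy-atom
   pair is below 4.5 Å; the per-replicate fraction of frames in contact is
   the statistical unit.
4. **Statistics** — equal-variance two-tailed t-tests (p via the regularized
   incomplete beta) and numerically stable binomial tails.

A desk-scale overdamped-Langevin toy simulator (rigid coarse receptor,
8-bead cofactor ligand, the protocol's three distance-dependent steering
forces k = 0.2 / 0.1 / 0.05 kJ·mol⁻¹·Å⁻², 300 K, friction 1 ps⁻¹, start
distance 27 Å) generates the trajectories, and a synthetic-data module
provides fixtures with analytic ground truth for every stage. See
`docs/methods.md` for the full model description and design choices.

## Worked example

Run the numbered analyses (thin drivers over the library; tables land in
`results/`):

```bash
python analysis/01_simulate_association.py
python analysis/02_pocket_volumes.py
python analysis/03_contact_occupancy.py
python analysis/04_statistics.py
```

Output (30 replicates per condition, base seed 1):

```
open: 6/30 replicates reached a TS-like frame
occluded: 0/30 replicates reached a TS-like frame
open: mean volume 119.3 Å³ over 303 subsampled frames
occluded: mean volume 95.9 Å³ over 303 subsampled frames
open: mean occupancy 0.0363
occluded: mean occupancy 0.0000
docking: binomial p = 9.02e-06 (upper_tail_alt_at_ref_rate)
large volumes: t = inf, p = 0
contacts: t = 3.222, p = 0.00209
```

Reading: the open (enlarged) pocket reaches the S_N_2 transition-state-like
pose in 6 of 30 steered replicates, the gated pocket in none — far more often
than the occluded condition's empirical rate predicts (binomial upper tail,
zero-count floor at 1/(2n)). The gate atoms also shrink the measured
accessible volume (96 vs 119 Å³, the pocket-collapse analogue); with a rigid
toy receptor the occluded subsample fractions are exactly constant, so the
volume t-test lands on its documented zero-variance convention (t = ±inf,
p = 0). Methyl–lysine contact occupancy is nonzero only where docking
happened (t-test on per-replicate fractions, p ≈ 0.002).

The same experiment is available as a config-driven pipeline with manifested,
byte-reproducible outputs:

```bash
pocketdyn pipeline --config configs/quickstart.yml --out results/pipeline
```

Other CLI entry points: `pocketdyn fixtures` (materialize the synthetic
fixtures with a ground-truth manifest), `simulate`, `ts-scan`, `volume`,
`contacts`, and `stats ttest|binomial|compare`. Formats: multi-MODEL PDB and
multi-frame XYZ in, TSV/JSON out.

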