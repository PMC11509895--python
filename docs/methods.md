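# Methods

## Scope and model

`pbflex` quantifies and compares the local conformational dynamics of
protein systems — typically a wild type and a set of point/truncation
mutants — from conformational ensembles (multi-model PDB files, one MODEL
per frame). The analysis has two complementary tracks:

1. **Coordinate space.** After least-squares rigid superposition on
   C-alpha atoms (Kabsch, proper rotations only, no mass weighting), the
   per-frame RMSD against the first frame monitors global stability, and
   the per-residue RMSF about the mean structure measures positional
   flexibility. ΔRMSF (variant − wild type, signed) localises
   flexibility changes.
2. **Dihedral space.** Each residue of each frame is assigned one of the
   16 Protein Blocks (PBs), a structural alphabet of local backbone
   prototypes labelled `a`–`p`. A residue's window collects the eight
   dihedrals (ψ(i−2), φ(i−1), ψ(i−1), φ(i), ψ(i), φ(i+1), ψ(i+1),
   φ(i+2)); the assigned block minimises the RMSDA dissimilarity — the
   sum over the window of squared angular differences, each wrapped to
   (−180°, 180°]. Ties (measure zero in practice) break alphabetically.
   Per position, the PB frequency vector f over the ensemble yields

   * **Neq** = exp(−Σ_x f_x ln f_x), the equivalent number of blocks:
     1 = one conformer ever observed, 16 = uniform over the alphabet.
     Qualitative bands: < 4 rigid, 4–6 flexible, 6–8 highly flexible,
     ≥ 8 disordered.
   * **ΔPB** = Σ_x |f_x¹ − f_x²|, the L1 distance between two systems'
     frequency vectors at that position: 0 identical usage, 2 disjoint.
   * **ΔNeq** = |Neq¹ − Neq²|.

   These are descriptive statistics; no significance testing is attached,
   deliberately — the comparisons are profiles, not hypothesis tests.

RMSDA uses the *sum* (not the mean) of squared wrapped differences; the
argmin is identical either way, so the cheaper form is used and the
constant factor (8×) is simply part of the reported dissimilarity scale.

## Conventions and degenerate inputs

* Residues are identified by PDB author numbering everywhere; internal
  indices are 0-based. Region annotation (FR1–FR4, CDR1–CDR3) is a config
  mapping of inclusive author ranges; the shipped default uses the common
  approximate nanobody bounds CDR1 23–37, CDR2 50–63, CDR3 99–105 with
  framework regions filling the complement. Other numbering schemes (e.g.
  IMGT) are handled by supplying a different region config, not by
  renumbering.
* φ(first) and ψ(last) are undefined by construction; the first/last two
  positions of a chain are always unassignable (`Z`). A CA–CA distance
  above 4.5 Å (well beyond trans peptide geometry) marks a chain break
  and undefines the spanning dihedrals. Undefined window angles propagate
  to `Z`; `Z` frames are excluded from every frequency denominator, and a
  position with no assignable frame is reported as missing (never 0).
* Torsion angles follow the IUPAC sign convention, range (−180°, 180°];
  numerically collinear triples give an undefined angle rather than an
  error.
* On reading, hydrogens are skipped and the highest-occupancy altloc is
  kept. Heavy atoms missing from some models are dropped with a warning;
  a backbone atom (N, CA, C, O) missing anywhere is an error, as is an
  inconsistent residue composition across models.
* Superposition requires ≥ 3 points of rank ≥ 2; reflections are excluded
  by construction. The RMSF mean structure is refined by two passes of
  superpose-to-mean/recompute-mean (standard practice; one pass already
  converges to numerical noise on the test ensembles, the second is
  insurance for strongly moving systems).
* Replicate handling: PB counts are pooled across replicates before
  normalisation (profiles can also be emitted per replicate for
  dispersion checks); RMSF is computed over whichever ensemble is given,
  concatenated or per replicate.

## Mutant construction

Disulfide-disrupting mutants are built by side-chain truncation:
CYS→ALA keeps exactly {N, CA, C, O, CB}, CYS→GLY keeps {N, CA, C, O},
coordinates untouched, applied to every frame. No rotamer rebuilding or
minimisation is attempted: the pipeline consumes backbone dihedrals and
C-alpha positions only, and the truncation operator provably leaves both
bit-identical (this is tested). The mutants are inputs for *new*
simulations in a real study; here they exercise the construction and
locality contracts.

## Synthetic ensembles: what they emulate, what they do not

The generators replace molecular-dynamics trajectories with ensembles of
known statistics; every downstream number is therefore checkable against
ground truth.

* **Dihedral-space generator.** Residues are grouped into segments, each
  with a conformer distribution over PB labels. Per frame, each segment
  draws a state; every position in the segment takes the drawn
  prototype's central (φ, ψ), plus independent wrapped-Gaussian noise
  (default σ = 10°, small enough that well-separated basins such as m/d
  stay non-overlapping — the m→d misassignment margin is ≈ 7.7 standard
  deviations — yet large enough to exercise angle wrapping). The default
  *collective* switching (one draw per segment) models what comparative
  PB studies actually observe: whole conformer words exchanging
  occupancy between systems. Per-position independent drawing
  (`coupled=False`) is available for marginal-statistics tests, but note
  that with independent neighbours the five-residue window is chimeric
  and the assignment is dominated by the six flanking angles, so the
  centre's sampled label is *not* recoverable position-by-position —
  this is a property of windowed alphabets, not a defect.
* **Collapse of replicated windows.** A segment dwelling in one state
  replicates that prototype's central (φ, ψ) across its window, which
  the alphabet reads as the nearest ideal repetitive structure; the
  induced state→assigned-label map is many-to-one (e.g. e, f, h → d;
  k, l, n, o → m). Recovery experiments therefore use repertoires on
  which the map is injective ({m, d, i, j} → {m, d, n, e}); since Neq
  and ΔPB are invariant under relabelling, the recovered values equal
  the generating-distribution values. At segment boundaries windows mix
  neighbouring states, broadening local frequency vectors; per-region
  maxima of Neq/ΔNeq can exceed the segment-interior analytic value
  there. This mimics real conformational junctions and is left visible.
* **Coordinate-space generator.** Frames are a single reference
  conformation plus an isotropic Gaussian displacement per residue
  (standard deviation σ_i per Cartesian component) and a random global
  rigid motion per frame. Expected RMSF is σ_i√3. Superposition fitting
  absorbs a small part of localised noise (≈ −4% for one noisy residue
  on a 40-residue scaffold, ≈ −0.7% at 120 residues); recovery tests use
  a 120-residue scaffold, a typical single-domain antibody length.
* **Ideal conformations.** Backbones are built from standard internal
  coordinates (N–CA 1.458 Å, CA–C 1.525 Å, C–N 1.329 Å, trans ω) with
  uniform (φ, ψ) = (−57°, −47°) for the helix and (−120°, +135°) for the
  strand; extraction reproduces the targets to numerical precision, and
  the interiors assign to PB m and d respectively — the two anchors of
  the alphabet.

What the generators deliberately do **not** model: force-field physics,
solvent, correlated backbone/side-chain motion, anisotropic or
time-correlated fluctuations, and real transition kinetics between
conformers (draws are i.i.d. across frames). Passing recovery tests
therefore demonstrates the correctness of the measurement pipeline, not
the realism of any particular trajectory.

## Problem sizes and seeds

Statistical-recovery tests use 10⁴ frames (binomial standard error
≈ 0.005 on a frequency, so the ±0.02 recovery bands are ≈ 4σ) on 15–120
residue chains; the five-system analysis study uses 2000 frames × 120
residues per system. All generators take explicit seeds and are
bit-reproducible; analysis scripts fix their seeds in the source.

## The packaged PB reference table

The canonical 16×8 prototype-angle table ships as
`data/pb_reference_angles.csv`, guarded by a checksum test. The
prototypes are used as published; no re-training is attempted. Two
consequences worth knowing: prototype angles are means of training
clusters, so even ideal secondary structure sits at a small nonzero
RMSDA from its prototype; and the assignment is purely geometric — no
sequence information enters.

## Known limitations

* Multi-model PDB is the only trajectory carrier (convert XTC/DCD/TRR
  upstream); mmCIF is not read.
* ΔPB is reported raw (0–2); no attempt is made to re-express it as a
  "percent different" figure.
* Unassignable (`Z`) positions make the first/last two residues of every
  chain invisible to PB statistics; flexibility there is covered only by
  the RMSF track.
* The interpretation bands for Neq are labels to aid reading, not
  calibrated thresholds.
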