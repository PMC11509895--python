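# pbflex

Protein Blocks based conformational-flexibility analysis of structural
ensembles.

## The problem

Many structural questions — does breaking a disulfide bridge loosen an
antibody loop? does a mutation open new conformations or merely shift the
balance between existing ones? — are questions about *local* backbone
dynamics that a global RMSD cannot answer. `pbflex` is for structural
bioinformaticians comparing conformational ensembles of two or more
related systems (wild type vs mutants, free vs bound, ...), e.g. frames
saved from molecular-dynamics trajectories of a nanobody (VHH) and its
disulfide-disrupting cysteine mutants. It reads multi-model PDB files,
builds side-chain-truncation mutants, and computes per-position
flexibility statistics and between-system comparisons.

## The statistics

Each residue of each frame is assigned one of the 16 **Protein Blocks**
(`a`–`p`), local backbone prototypes defined by eight dihedrals over a
five-residue window (ψ(i−2), φ(i−1), ψ(i−1), φ(i), ψ(i), φ(i+1), ψ(i+1),
φ(i+2)); the assigned block minimises the sum of squared wrapped angular
differences (RMSDA) to the prototype. PB `m` is the α-helix prototype,
`d` the central β-strand. From the per-position PB frequency vector f:

* **Neq** = exp(−Σ_x f_x ln f_x) — equivalent number of blocks; 1 means a
  single conformation ever observed, 16 a uniform spread over the
  alphabet (≈ 4 flexible, ≈ 6 highly flexible, ≥ 8 disordered).
* **ΔPB** = Σ_x |f_x¹ − f_x²| — L1 distance between two systems'
  frequency vectors at a position; 0 identical, 2 disjoint PB usage.
* **ΔNeq** = |Neq¹ − Neq²|.

In coordinate space, **RMSD** (per frame, vs the first frame) and
**RMSF** (per residue, about the mean structure) are computed on
C-alpha atoms after Kabsch superposition, with **ΔRMSF** (variant −
wild type) localising flexibility changes. Seeded synthetic-ensemble
generators with known statistics (conformer mixtures in dihedral space,
harmonic fluctuation in coordinate space) make every stage verifiable
without trajectories. See `docs/methods.md` for the full model.

## Worked example

```python
import pbflex as pf

table = pf.load_reference_table()

# Two systems sharing the same two local conformers (PBs m and d) but
# with shifted occupancies -- the signature of a mutation that changes
# the equilibrium without creating new conformations.
systems = {
    "wild-type": ({"m": 0.8, "d": 0.2}, 1),
    "mutant":    ({"m": 0.4, "d": 0.6}, 2),
}

profiles = {}
for name, (dist, seed) in systems.items():
    cfg = pf.SyntheticEnsembleConfig(
        n_residues=15, n_frames=5000, seed=seed,
        segments=[pf.Segment(0, 14, dist)],
    )
    series = pf.sample_dihedral_ensemble(cfg, table)
    prof = pf.pb_frequency_profile(pf.assign_ensemble(series, table))
    f = prof.frequencies[7]          # position 8, mid-chain
    profiles[name] = f
    print(f"{name:9s}  f(m)={f[pf.PB_LABELS.index('m')]:.3f}  "
          f"Neq={pf.neq(f):.3f}  (analytic {pf.analytic_neq(dist):.3f})")

dpb = pf.delta_pb(profiles["wild-type"], profiles["mutant"])
print(f"deltaPB(wild-type, mutant) = {dpb:.3f}  (analytic 0.800)")
```

prints

```
wild-type  f(m)=0.798  Neq=1.655  (analytic 1.649)
mutant     f(m)=0.406  Neq=1.964  (analytic 1.960)
deltaPB(wild-type, mutant) = 0.784  (analytic 0.800)
```

The assignment recovers each system's conformer frequencies to binomial
sampling error, the Neq entropies match the generating distributions,
and the ΔPB between the systems matches the analytic L1 distance 0.8 —
a moderate equilibrium shift, with no new conformer appearing in either
system.

## Command line

```sh
pbflex simulate --kind helix --n-residues 30 --n-frames 100 \
    --sequence AAACAAAAAAAAAAAAAAAAAAAACAAAAA --seed 3 --output wt.pdb
pbflex mutate wt.pdb mut.pdb --spec C4A,C25G
pbflex profile wt.pdb --out-dir wt_profile
pbflex compare mut.pdb wt.pdb --labels mutant,wild-type --out-dir cmp
```

`profile` writes RMSD/RMSF/flexibility/PB-frequency TSVs; `compare`
writes the per-position ΔPB/ΔNeq/ΔRMSF table plus a JSON summary of
per-region maxima (regions default to nanobody FR/CDR bounds,
overridable with `--regions regions.yaml`).

## The analysis study

The numbered scripts under `analysis/` run a five-system synthetic study
emulating a nanobody with an extra CDR1–CDR3 disulfide bridge and its
four bridge-disrupting mutants (32A-C99, C32-99A, 32A-99A, 32G-99G):

```sh
python analysis/01_simulate_ensembles.py   # ensembles -> per-system profiles
python analysis/02_flexibility_profiles.py # Neq/RMSF tables, region summary
python analysis/03_compare_to_wildtype.py  # deltaPB/deltaNeq/deltaRMSF vs WT
```

Outputs land under `results/`; all seeds are fixed in the scripts, so
the tables regenerate identically. Measured per-region ΔPB maxima sit
within sampling error of the analytic L1 distances implied by the
generating conformer distributions.

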