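# twinmeth

Twin and population analysis of CpG-unit DNA methylation at an imprinted
locus, packaged as a tested, reusable pipeline with a synthetic-data
generator, so the whole workflow runs end-to-end with no external data.

## The scientific problem

How much of the person-to-person variability in DNA methylation is due to
*space* (geography/ancestry) and how much to *time* (ageing)?  The
IGF2/H19 locus is the canonical testbed: it is imprinted (expected ~50%
methylation at its differentially methylated regions), measured by
EpiTYPER mass spectrometry as **CpG units** (one or more adjacent CpG
sites quantified jointly) grouped into four PCR **amplicons** (IGF2AS,
IGF2_shore, IGF2_island, H19).  Two study designs answer the two
questions:

* a **population cohort** of unrelated, age-homogeneous males from
  distinct geographic groups — if ancestry shaped methylation, a one-way
  ANOVA on the first principal component of each amplicon would detect it;
* a **twin cohort** of monozygotic (MZ) and dizygotic (DZ) pairs spanning
  ages 22–97 — within an MZ pair any methylation divergence is
  non-genetic, so the pair's **intra-couple Pearson correlation** and
  **Euclidean distance** over an amplicon's units track epigenetic drift,
  and comparing pairs below vs above age 60 (Student t-test) asks whether
  drift accelerates late in life.

Zygosity comparison adds the genetics: with MZ pairs sharing all and DZ
pairs half of segregating variants, Falconer's formula

    h² = 2 (r_MZ − r_DZ)

estimates the additive-genetic fraction of methylation variance per
amplicon.  Finally the **S statistic**, S = (years lived in a different
house / age) × 100, separates shared environment from age itself: pairs
with low S but high distance ("discordant cohabiters") diverged while
living together, arguing that drift is intrinsic to ageing.

## What the package provides

| module | contents |
|---|---|
| `twinmeth.simulate` | ACE-model generator: additive-genetic (A), common- (C) and unique-environment (E) variance per amplicon, MZ/DZ sharing structure, step or linear variance drift after a threshold age, missingness and SNP-bimodality corruption operators |
| `twinmeth.qc` | the cleaning rules: drop samples measured for <60% of units, drop units >30% missing, drop units with a SNP-style bimodal distribution (Gaussian-mixture BIC test), with an auditable report |
| `twinmeth.population` | per-group summaries, CpG correlation matrix, per-amplicon PCA (covariance, fixed sign convention) and ANOVA on PC1 |
| `twinmeth.twins` | per-pair correlation/distance, Spearman age trends, threshold t-tests, age-class summaries |
| `twinmeth.heritability` | intra-couple correlations by zygosity, Falconer h², S statistic, distance-vs-S analysis |
| `twinmeth.calibration` | Monte-Carlo size/power/recovery analyses of the above tests |
| `twinmeth.io` / `pipeline` / `cli` | TSV/JSON formats, end-to-end orchestration with a checksum manifest, `twinmeth` command |

## Worked example

`examples/` holds one short script per capability.  Running
`python examples/04_twin_age_drift.py` (120 simulated MZ pairs, default
generator in which only IGF2_shore and IGF2AS drift after 60) prints:

```
amplicon      rho(r,age)  rho(d,age)  p(r) @60  p(d) @60
IGF2AS            -0.169      +0.280    0.0088   0.00028
IGF2_shore        -0.338      +0.592   2.1e-06   8.5e-11
IGF2_island       -0.136      +0.090      0.06      0.79
H19               +0.006      +0.074      0.85     0.047
```

Read it column-wise: the two drifting amplicons show intra-couple
correlation falling with age (negative Spearman rho), distance rising
(positive rho) and clearly significant young-vs-old t-tests, while the
drift-free amplicons stay near the null.  `examples/03_population_structure.py`
shows the complementary spatial null — all four ANOVAs on PC1
non-significant under a no-group-effect population — and what a true
stratification signal would look like.  `examples/05_heritability_environment.py`
prints per-amplicon r_MZ/r_DZ/h² and flags lifelong-cohabiting old pairs
whose methylation drifted apart anyway.

The same pipeline runs from the shell:

```bash
twinmeth run --seed 7 --out results/demo     # simulate → qc → analyses
twinmeth simulate --seed 7 --out data/       # or stage by stage
twinmeth qc data/twin_matrix.tsv --out qc/
```

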