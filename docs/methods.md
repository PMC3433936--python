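# Methods

## The generative model

Each amplicon's methylation is generated from an ACE variance
decomposition on the methylated-fraction scale.  For individual *i* of a
twin pair, CpG unit *u* of an amplicon with mean level μ:

    x_iu = μ + m_u + A_iu + C_u + E_iu + ε_iu,   clamped to [0, 1]

* **m_u** — deterministic per-unit offsets spanning ±`unit_mean_spread`
  (default 0.15), the per-CpG mean profile real EpiTYPER amplicons show.
* **A** (additive genetic) — shared exactly by MZ co-twins, correlated
  0.5 between DZ co-twins (implemented as √0.5·shared + √0.5·own).
* **C** (common environment) — shared by both co-twins of a pair
  regardless of zygosity.
* **E** (unique environment) — independent per individual.
* **ε** — technical noise, SD `unit_noise_sd`, independent per
  measurement.

Each of A, C, E is split between two levels by `amplicon_share` (*w*,
default 0.5): a scalar shared by all of the amplicon's units (variance
*w*·σ²) and independent per-unit effects (variance (1−*w*)·σ²).  The two
levels serve different observables.  The scalar level creates the strong
within-amplicon / weak between-amplicon correlation seen across samples.
The per-unit level is what makes the *intra-couple* correlation — Pearson
across a pair's unit vectors — sensitive to the ACE parameters at all: a
scalar effect shifts a whole vector by a constant, and Pearson correlation
is invariant to constant shifts.  A generator with only a scalar latent
per individual would therefore produce pair correlations that do not
depend on var_A/var_C/var_E, and Falconer's formula could not recover
anything from it.  With per-unit components and small noise the expected
intra-couple correlations are

    r_MZ ≈ (V_m + (1−w)(a + c)) / D,   r_DZ ≈ (V_m + (1−w)(a/2 + c)) / D,
    D = V_m + (1−w)(a + c + e) + σ²_noise,

so 2(r_MZ − r_DZ) = (1−w)·a / D, which equals a/(a+c+e) whenever the unit
profile variance V_m and the noise are negligible — the configuration the
recovery analyses use.  With a realistic profile (V_m > 0) both
correlations are pushed toward 1 and h² is attenuated; this mirrors how
high-ICC, low-h² readings arise in real data and is why the calibration
module zeroes the profile.

**Ageing drift** inflates var_E by `drift_multiplier` for pairs older than
`drift_threshold_age` (default 60 years) — a step, reflecting an abrupt
late-life loss of maintenance fidelity.  A `drift_mode="linear"` ramp
(reaching the multiplier at the oldest age) is available for sensitivity
analyses.  Drift raises the expected within-pair Euclidean distance and
lowers the expected intra-couple correlation, producing the
negative-correlation / positive-distance age trends the twins module
tests for.

**Life histories.** Pair ages are uniform over `age_range` (default
22–97, shared by co-twins).  Years lived apart are
max(0, age − leaving-home age) with leaving-home age ~ Uniform[18, 35],
so the S statistic rises with age — which also means low-S pairs are
young under the default model; demonstrating the "old lifelong
cohabiter" signature requires setting years_apart to 0 for selected old
pairs (see `examples/05`).

**Defaults.**  The four bundled amplicon specs use the measured mean
levels (IGF2AS 0.49, IGF2_shore 0.61, IGF2_island 0.45, H19 0.36), unit
counts 5/6/14/14, and total latent SD ~0.06–0.09 per unit — the scale of
per-CpG SDs seen in blood EpiTYPER data.  Drift is confined to
IGF2_shore (×3) and IGF2AS (×2); the shore also carries the smallest
additive variance, so it shows the weakest h² and the closest MZ/DZ
correlations.  Values are clamped (not resampled) at [0, 1]; with these
variances clamping is a <0.1% tail event and its bias is negligible.
All randomness flows from a single `numpy.random.default_rng(seed)`, so a
fixed seed reproduces every byte of output.

### What the generator does *not* emulate

No raw mass spectra, fragment masses or bisulfite-conversion efficiency;
no LD structure behind the SNP-bimodality operator (it replaces a unit's
values with an equal-weight two-mode mixture, modes ≥0.4 apart); no
batch effects or cell-composition variation; missingness is
missing-completely-at-random, whereas real EpiTYPER dropout correlates
with fragment mass and methylation level.  Passing tests therefore
demonstrate that the statistical machinery behaves correctly under its
own assumptions, not that those assumptions exhaust real blood
methylation data.

## Cleaning rules

Applied in fixed order, thresholds configurable:

1. samples measured for <60% of units removed (strict `<`: a sample at
   exactly 60% is kept, following the wording "fewer than");
2. units with >30% missing among the retained samples removed (strict
   `>`);
3. units with a bimodal value distribution removed.  No canonical test
   exists for step 3, so the detector fits 1- and 2-component Gaussian
   mixtures and flags a unit only when BIC prefers two components *and*
   the fitted modes are ≥0.2 apart *and* the minor component holds ≥20%
   weight.  The guards keep the false-positive rate below ~1% on
   unimodal units at n = 100–400 while catching a genuine SNP split
   (modes ≥0.4 apart) essentially always; units with <20 observed values
   or zero variance are skipped and logged rather than tested.

The report carries every removal with its triggering value, and the run
is idempotent: re-cleaning a cleaned matrix removes nothing.

## Statistical choices

* **PCA** is computed on the covariance matrix (units share the
  methylated-fraction scale; correlation PCA available via
  `standardize=True`) after per-unit mean imputation of missing values
  (preserves the sample count; complete-case via `missing="complete"`).
  PC1's sign is fixed by making its largest-|loading| positive, so
  results are stable across seeds and LAPACK implementations.
* **ANOVA** on PC1 is classical one-way fixed-effects; a Welch variant
  (statsmodels `anova_oneway`, unequal variances) is a flag.
* **Threshold grouping** at age 60 is ≤60 vs >60 (60 is printed as the
  upper bound of the 46–60 class).  The t-test is the classical
  equal-variance Student test; Welch via `equal_var=False`.  The
  threshold is a parameter, not an estimate — no change-point fitting.
* **Trend and threshold analyses run on MZ pairs only** (within-MZ
  divergence is non-genetic); DZ pairs enter the zygosity comparison.
* **Falconer h²** is fed by the *mean* of per-pair correlations by
  default, with the median available (`summary="median"`); published
  analyses rarely state which summary they use and the two differ at
  small n.  h² is reported unclamped — truncating to [0, 1] would hide
  estimation noise — with a logged flag when outside.
* **Intra-couple correlation** requires ≥3 shared (both-observed) units
  and non-constant vectors; Euclidean distance requires ≥1 shared unit
  and is reported on the raw fraction scale (a /√n_units-normalised
  variant exists because amplicons differ in unit count).  Undefined
  statistics carry an explicit reason string instead of a silent NaN.
* **Age classes** (20–45, 46–60, 61–75, 76–97) are assigned by upper
  edges so continuous ages between the printed integer labels (e.g.
  45.5) fall in the later class.
* **Discordant cohabiters** are operationalised as pairs with S below
  the threshold (default 35, the value that corresponds to age 60 under
  the default life-history model) whose distance exceeds the 75th
  percentile of the below-threshold group; the quantile is configurable.

## Coordinates and formats

Genomic coordinates are 1-based inclusive (length = end − start + 1),
with exact converters to and from 0-based half-open BED.  Three of the
four bundled amplicon regions satisfy this convention against their
published lengths (276, 338 and 413 bp); the IGF2_island record is
published end-first with a length inconsistent under any single
convention, so it is stored normalised (start ≤ end) and construction
emits a warning rather than guessing the intended span.  Matrices,
metadata, pairs and amplicon tables are plain TSV with `NA` for missing
and `.` as the decimal separator; methylation lives in [0, 1] internally
and values outside that range are rejected at read time with their file
location.

## Calibration and problem sizes

`twinmeth.calibration` measures the pipeline's operating characteristics
by full simulation: type-I error of the ANOVA-on-PC1 test (4 groups × 50
samples, 1000 null cohorts), type-I error of the threshold t-test (40 MZ
pairs, ages uniform 22–97, 1000 null cohorts), power against a ×3
unique-environment drift (100 cohorts, paired with a drift-free amplicon
for specificity), and Falconer recovery at 300 pairs per zygosity (100
replicates; sampling SE of h² there is ~0.03, so ±0.1 is a comfortable
bound).  These sizes make each analysis take seconds while leaving
Monte-Carlo error well below the margins being asserted.

## Known limitations

* The Gaussian ACE model ignores the boundedness of fractions except by
  clamping; amplicons with extreme mean levels would need a logit-scale
  generator.
* Falconer's formula assumes no dominance, no epistasis and equal
  environments across zygosities; the package deliberately offers no
  structural-equation twin modelling.
* The bimodality detector tests marginal distributions only; a SNP in
  partial linkage with methylation (allele-specific methylation proper)
  can produce subtler patterns it will miss.
* `h² = 2(r_MZ − r_DZ)` applied to *within-amplicon* pair correlations
  recovers the per-unit additive fraction only when the per-unit mean
  profile is flat (see the model section); on profiled data it is a
  relative, not absolute, measure.
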