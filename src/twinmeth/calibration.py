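"""Monte-Carlo calibration and power analyses of the pipeline's tests.

These routines answer design questions about the analysis itself: does the
PCA/ANOVA stratification test hold its nominal size on a null population?
Does the age-threshold t-test detect a given drift effect with the cohort
sizes at hand, while staying calibrated on drift-free amplicons?  How
accurately does Falconer's formula recover a known additive-genetic
fraction?  Each replicate simulates a fresh cohort, runs the full
statistic path and tallies the outcome.

The single-amplicon specs used here have no per-unit mean profile and
little technical noise, so the ACE variance arithmetic is the only thing
being measured.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .heritability import heritability_estimates
from .population import anova_pc1, pca_pc1
from .simulate import AmpliconSimSpec, SimConfig, simulate_population_cohort, simulate_twin_cohort
from .twins import compute_pair_statistics, threshold_test

__all__ = [
    "anova_null_rejection_rate",
    "threshold_null_rejection_rate",
    "drift_power",
    "falconer_recovery",
    "DriftPowerResult",
    "RecoveryResult",
]


def _flat_spec(name: str = "A", n_units: int = 8, drift_multiplier: float = 1.0,
               **kw) -> AmpliconSimSpec:
    defaults = dict(mean_level=0.5, var_A=0.002, var_C=0.0015, var_E=0.002,
                    unit_noise_sd=0.01, unit_mean_spread=0.0)
    defaults.update(kw)
    return AmpliconSimSpec(name, n_units=n_units,
                           drift_multiplier=drift_multiplier, **defaults)


def anova_null_rejection_rate(
    n_seeds: int = 1000,
    base_seed: int = 0,
    n_per_group: int = 50,
    n_groups: int = 4,
    alpha: float = 0.05,
) -> float:
    """Type-I error of the ANOVA-on-PC1 stratification test.

    Simulates ``n_seeds`` null population cohorts (identical generating
    distribution in every group) and returns the fraction in which the
    per-amplicon ANOVA rejects at ``alpha``.  A calibrated test returns
    approximately ``alpha``.
    """
    labels = tuple(f"g{i}" for i in range(n_groups))
    rejections = 0
    for i in range(n_seeds):
        cfg = SimConfig(seed=base_seed + i, amplicons=(_flat_spec(),),
                        group_labels=labels, n_pop_samples_per_group=n_per_group,
                        group_effect=0.0)
        matrix, meta = simulate_population_cohort(cfg)
        groups = meta.set_index("sample_id")["group"]
        res = anova_pc1(pca_pc1(matrix, "A").scores, groups)
        rejections += res.p_value < alpha
    return rejections / n_seeds


def threshold_null_rejection_rate(
    n_seeds: int = 1000,
    base_seed: int = 0,
    n_pairs: int = 40,
    statistic: str = "distance",
    alpha: float = 0.05,
) -> float:
    """Type-I error of the age-60 threshold t-test on a drift-free amplicon.

    MZ pairs are drawn with ages uniform over 22–97, so both sides of the
    threshold are populated; with no drift the young and old groups share
    one distribution and rejections are pure type-I error.
    """
    rejections = 0
    for i in range(n_seeds):
        cfg = SimConfig(seed=base_seed + i, n_mz_pairs=n_pairs, n_dz_pairs=0,
                        amplicons=(_flat_spec(),))
        matrix, _, pairs = simulate_twin_cohort(cfg)
        stats = compute_pair_statistics(matrix, pairs)
        res = threshold_test(stats, "A", statistic)
        rejections += res.p_value < alpha
    return rejections / n_seeds


@dataclass(frozen=True)
class DriftPowerResult:
    power_drift: float  # rejection rate on the drifting amplicon
    rate_drift_free: float  # rejection rate on the matched drift-free amplicon
    n_seeds: int


def drift_power(
    n_seeds: int = 100,
    base_seed: int = 0,
    n_pairs: int = 40,
    drift_multiplier: float = 3.0,
    statistic: str = "distance",
    alpha: float = 0.05,
) -> DriftPowerResult:
    """Power of the threshold t-test against a step drift after age 60.

    Each replicate carries two otherwise identical amplicons — one with
    ``drift_multiplier`` applied to its unique-environment variance past
    the threshold, one without — so power and false-positive rate come
    from the same cohorts.
    """
    specs = (_flat_spec("drift", drift_multiplier=drift_multiplier),
             _flat_spec("calm"))
    hits_drift = hits_calm = 0
    for i in range(n_seeds):
        cfg = SimConfig(seed=base_seed + i, n_mz_pairs=n_pairs, n_dz_pairs=0,
                        amplicons=specs)
        matrix, _, pairs = simulate_twin_cohort(cfg)
        stats = compute_pair_statistics(matrix, pairs)
        hits_drift += threshold_test(stats, "drift", statistic).p_value < alpha
        hits_calm += threshold_test(stats, "calm", statistic).p_value < alpha
    return DriftPowerResult(hits_drift / n_seeds, hits_calm / n_seeds, n_seeds)


@dataclass(frozen=True)
class RecoveryResult:
    a2_true: float
    mean_h2: float
    frac_within_tol: float  # fraction of replicates with |h2 - a2| <= tol
    tol: float
    n_seeds: int


def falconer_recovery(
    a2_true: float,
    n_seeds: int = 100,
    base_seed: int = 0,
    n_pairs_per_zygosity: int = 300,
    total_variance: float = 0.005,
    tol: float = 0.1,
) -> RecoveryResult:
    """Parameter recovery of Falconer's h² under the ACE generator.

    The amplicon's additive fraction of the latent variance is set to
    ``a2_true`` (common environment and unique environment split the
    remainder evenly); each replicate simulates ``n_pairs_per_zygosity``
    MZ and DZ pairs and re-estimates h² = 2(r_MZ − r_DZ) from the
    intra-couple correlations.
    """
    if not 0.0 < a2_true < 1.0:
        raise ValueError(f"a2_true must be in (0, 1), got {a2_true}")
    var_A = a2_true * total_variance
    rest = (1.0 - a2_true) * total_variance / 2.0
    spec = _flat_spec(var_A=var_A, var_C=rest, var_E=rest,
                      unit_noise_sd=0.005, n_units=12)
    h2s = []
    for i in range(n_seeds):
        cfg = SimConfig(seed=base_seed + i, n_mz_pairs=n_pairs_per_zygosity,
                        n_dz_pairs=n_pairs_per_zygosity, amplicons=(spec,))
        matrix, _, pairs = simulate_twin_cohort(cfg)
        stats = compute_pair_statistics(matrix, pairs)
        h2s.append(heritability_estimates(stats)[0].h2)
    h2s = np.asarray(h2s)
    within = float(np.mean(np.abs(h2s - a2_true) <= tol))
    return RecoveryResult(a2_true, float(h2s.mean()), within, tol, n_seeds)
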