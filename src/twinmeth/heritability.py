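"""MZ/DZ comparison: intra-couple correlations by zygosity, Falconer
heritability, and the shared-environment statistic S.

Falconer's formula estimates narrow-sense heritability from twin
correlations: MZ co-twins share all segregating variants and DZ co-twins
half on average, so under an additive model

    h² = 2 (r_MZ − r_DZ).

The shared-environment statistic quantifies how much of a twin pair's
lifetime was spent in different households,

    S = (years lived in a different house / age) × 100,

and relating S to the within-pair Euclidean distance separates the effect
of shared environment from the age-related drift itself: pairs that always
cohabited (low S) yet show large distances argue that drift is intrinsic
to ageing rather than environmental divergence.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "HeritabilityEstimate",
    "DistanceVsS",
    "icc_by_zygosity",
    "falconer_h2",
    "heritability_estimates",
    "s_statistic",
    "shared_environment_table",
    "distance_vs_s",
]


def icc_by_zygosity(pair_stats: pd.DataFrame) -> pd.DataFrame:
    """Distribution of per-pair intra-couple correlations by zygosity.

    Expects the table from
    :func:`twinmeth.twins.compute_pair_statistics`.  Returns one row per
    (amplicon, zygosity) with ``n, mean, median, q1, q3`` and the full
    vector of defined correlations in the ``values`` column; empty cells
    are reported with ``n = 0`` and NaN summaries.
    """
    rows = []
    for amp in pair_stats["amplicon"].unique():
        for zyg in ("MZ", "DZ"):
            sub = pair_stats[
                (pair_stats["amplicon"] == amp) & (pair_stats["zygosity"] == zyg)
            ]
            vals = sub["pearson_r"].to_numpy(dtype=float)
            vals = vals[np.isfinite(vals)]
            if vals.size:
                rows.append({
                    "amplicon": amp, "zygosity": zyg, "n": int(vals.size),
                    "mean": float(vals.mean()),
                    "median": float(np.median(vals)),
                    "q1": float(np.quantile(vals, 0.25)),
                    "q3": float(np.quantile(vals, 0.75)),
                    "values": vals,
                })
            else:
                rows.append({
                    "amplicon": amp, "zygosity": zyg, "n": 0,
                    "mean": np.nan, "median": np.nan,
                    "q1": np.nan, "q3": np.nan,
                    "values": vals,
                })
    return pd.DataFrame(rows)


def falconer_h2(r_mz: float, r_dz: float) -> float:
    """Falconer heritability ``h² = 2 (r_MZ − r_DZ)``.

    The raw value is returned without clamping; estimates outside [0, 1]
    reflect sampling noise (or model misfit) and are logged, not hidden.
    """
    for name, r in (("r_mz", r_mz), ("r_dz", r_dz)):
        if not -1.0 <= r <= 1.0:
            raise ValueError(f"{name} must be in [-1, 1], got {r}")
    h2 = 2.0 * (r_mz - r_dz)
    if not 0.0 <= h2 <= 1.0:
        logger.warning("Falconer h2 = %.3f outside [0, 1]; reported unclamped", h2)
    return h2


@dataclass(frozen=True)
class HeritabilityEstimate:
    """Per-amplicon twin-correlation summaries and Falconer h²."""

    amplicon: str
    r_mz_mean: float
    r_mz_median: float
    r_dz_mean: float
    r_dz_median: float
    h2: float
    n_mz_pairs: int
    n_dz_pairs: int
    summary: str  # which summary fed h2: "mean" or "median"

    @property
    def h2_out_of_range(self) -> bool:
        return not 0.0 <= self.h2 <= 1.0


def heritability_estimates(
    pair_stats: pd.DataFrame, summary: str = "mean"
) -> list[HeritabilityEstimate]:
    """Falconer h² per amplicon from the per-pair correlation table.

    ``summary`` selects which location summary of the per-pair correlations
    feeds Falconer's formula (``"mean"`` default, ``"median"`` available);
    both summaries are always reported.
    """
    if summary not in ("mean", "median"):
        raise ValueError(f"summary must be 'mean' or 'median', got {summary!r}")
    icc = icc_by_zygosity(pair_stats)
    out = []
    for amp in icc["amplicon"].unique():
        cell = {
            z: icc[(icc["amplicon"] == amp) & (icc["zygosity"] == z)].iloc[0]
            for z in ("MZ", "DZ")
        }
        if cell["MZ"]["n"] == 0 or cell["DZ"]["n"] == 0:
            logger.warning("amplicon %s: missing a zygosity cell, h2 skipped", amp)
            continue
        h2 = falconer_h2(cell["MZ"][summary], cell["DZ"][summary])
        out.append(HeritabilityEstimate(
            amplicon=amp,
            r_mz_mean=cell["MZ"]["mean"], r_mz_median=cell["MZ"]["median"],
            r_dz_mean=cell["DZ"]["mean"], r_dz_median=cell["DZ"]["median"],
            h2=h2, n_mz_pairs=int(cell["MZ"]["n"]), n_dz_pairs=int(cell["DZ"]["n"]),
            summary=summary,
        ))
    return out


def s_statistic(years_apart: float, age: float) -> float:
    """Percentage of lifetime a twin pair lived in different houses.

    ``S = (years lived in a different house / age) * 100``; requires
    ``age > 0`` and ``0 <= years_apart <= age``, so S lies in [0, 100].
    """
    if age <= 0:
        raise ValueError(f"age must be > 0, got {age}")
    if not 0 <= years_apart <= age:
        raise ValueError(
            f"years_apart must be in [0, age={age}], got {years_apart}"
        )
    return years_apart / age * 100.0


def shared_environment_table(
    pair_stats: pd.DataFrame, amplicon: str, zygosity: str | None = "MZ"
) -> pd.DataFrame:
    """Per-pair table of (S, Euclidean distance, age) for one amplicon."""
    sub = pair_stats[pair_stats["amplicon"] == amplicon]
    if zygosity is not None:
        sub = sub[sub["zygosity"] == zygosity]
    sub = sub[np.isfinite(sub["euclidean_d"])]
    records = pd.DataFrame({
        "pair_id": sub["pair_id"].to_numpy(),
        "S": [s_statistic(y, a) for y, a in zip(sub["years_apart"], sub["age"])],
        "euclidean_d": sub["euclidean_d"].to_numpy(),
        "age": sub["age"].to_numpy(),
    })
    return records


@dataclass
class DistanceVsS:
    """Relationship between within-pair distance and shared-environment S."""

    amplicon: str
    s_threshold: float
    spearman_rho: float
    p_value: float
    n_pairs: int
    n_below: int
    n_above: int
    #: pairs with S below threshold but distance above the 75th percentile of
    #: the below-threshold group: lifelong cohabiters that diverged anyway
    discordant_cohabiters: pd.DataFrame = field(repr=False, default=None)
    records: pd.DataFrame = field(repr=False, default=None)


def distance_vs_s(
    records: pd.DataFrame,
    amplicon: str,
    s_threshold: float = 35.0,
    high_quantile: float = 0.75,
) -> DistanceVsS:
    """Relate within-pair Euclidean distance to the S statistic.

    Emits the (S, d) scatter, their Spearman correlation, and the list of
    "discordant cohabiters": pairs below the S threshold whose distance
    exceeds the ``high_quantile`` of the below-threshold group — the pairs
    arguing that drift is age-intrinsic rather than environment-driven.
    """
    if not {"pair_id", "S", "euclidean_d"} <= set(records.columns):
        raise ValueError("records needs columns pair_id, S, euclidean_d")
    below = records[records["S"] < s_threshold]
    above = records[records["S"] >= s_threshold]
    if len(records) >= 4 and np.ptp(records["euclidean_d"].to_numpy()) > 0:
        rho, p = stats.spearmanr(records["S"], records["euclidean_d"])
    else:
        rho, p = np.nan, np.nan
    if len(below) > 0:
        cut = float(np.quantile(below["euclidean_d"], high_quantile))
        spread = np.ptp(below["euclidean_d"].to_numpy()) if len(below) > 1 else 0.0
        if spread > 0:
            discordant = below[below["euclidean_d"] > cut].copy()
        else:
            # all cohabiters equally concordant: nothing stands out
            discordant = below.iloc[0:0].copy()
    else:
        discordant = below.copy()
    return DistanceVsS(
        amplicon=amplicon,
        s_threshold=s_threshold,
        spearman_rho=float(rho),
        p_value=float(p),
        n_pairs=len(records),
        n_below=len(below),
        n_above=len(above),
        discordant_cohabiters=discordant,
        records=records,
    )
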