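"""Within-twin-pair discordance analysis across age.

For each pair and amplicon two discordance statistics are computed over
the pair's shared (both-observed) CpG units:

* the intra-couple Pearson correlation between the two co-twins' unit
  vectors (high when the twins' methylation profiles agree), and
* the Euclidean distance between the vectors on the methylated-fraction
  scale (low when they agree).

Age trends are summarised with Spearman rank correlation, and the
epigenetic-drift hypothesis — a step increase in divergence late in life —
is tested by splitting pairs at a threshold age (60 years) and comparing
the statistic between the young and old groups with a two-sample t-test.
The trend/threshold analyses are run on MZ pairs, for whom any divergence
is non-genetic; DZ pairs still receive per-pair statistics for the
zygosity comparison in the heritability module.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import MethylationMatrix, validate_pairs

logger = logging.getLogger(__name__)

__all__ = [
    "PairStatistic",
    "TrendResult",
    "ThresholdTestResult",
    "pair_correlation",
    "pair_euclidean",
    "compute_pair_statistics",
    "age_trend",
    "threshold_test",
    "age_class_summary",
    "DEFAULT_AGE_CLASSES",
]

#: Age classes used for cohort summaries (inclusive bounds, per class labels).
DEFAULT_AGE_CLASSES: tuple[tuple[float, float], ...] = (
    (20, 45), (46, 60), (61, 75), (76, 97),
)


@dataclass(frozen=True)
class PairStatistic:
    """Discordance of one twin pair within one amplicon."""

    pair_id: str
    amplicon: str
    pearson_r: float  # NaN when undefined
    euclidean_d: float  # NaN when undefined
    n_shared_units: int
    reason: str | None = None  # why a statistic is undefined, if any


def _shared_vectors(
    matrix: MethylationMatrix, member_1: str, member_2: str, amplicon: str
) -> tuple[np.ndarray, np.ndarray]:
    sub = matrix.amplicon_view(amplicon)
    for m in (member_1, member_2):
        if m not in sub.index:
            raise KeyError(f"sample {m!r} not in matrix")
    x = sub.loc[member_1].to_numpy(dtype=float)
    y = sub.loc[member_2].to_numpy(dtype=float)
    ok = ~(np.isnan(x) | np.isnan(y))
    return x[ok], y[ok]


def pair_correlation(
    matrix: MethylationMatrix, member_1: str, member_2: str, amplicon: str
) -> tuple[float, int, str | None]:
    """Intra-couple Pearson correlation over the pair's shared units.

    Returns ``(r, n_shared_units, reason)``; ``r`` is NaN (with a reason)
    when fewer than 3 shared units exist or either vector is constant.
    The statistic is symmetric in member order.
    """
    x, y = _shared_vectors(matrix, member_1, member_2, amplicon)
    n = x.size
    if n < 3:
        return math.nan, n, f"only {n} shared units (< 3)"
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return math.nan, n, "constant member vector"
    r = stats.pearsonr(x, y).statistic
    return float(r), n, None


def pair_euclidean(
    matrix: MethylationMatrix, member_1: str, member_2: str, amplicon: str
) -> tuple[float, int, str | None]:
    """Euclidean distance between the co-twins' shared-unit vectors.

    Computed on the methylated-fraction scale; zero iff the vectors are
    identical over the shared units.
    """
    x, y = _shared_vectors(matrix, member_1, member_2, amplicon)
    n = x.size
    if n == 0:
        return math.nan, 0, "no shared units"
    return float(np.linalg.norm(x - y)), n, None


def compute_pair_statistics(
    matrix: MethylationMatrix,
    pairs: pd.DataFrame,
    amplicons: Sequence[str] | None = None,
    normalize_distance: bool = False,
) -> pd.DataFrame:
    """Per (pair, amplicon) discordance table.

    Returns a DataFrame with columns ``pair_id, amplicon, zygosity, age,
    years_apart, pearson_r, euclidean_d, n_shared_units, reason``.  Pairs
    with a member missing from the matrix (e.g. removed by QC) are dropped
    with a log message.  ``normalize_distance`` divides each distance by
    sqrt(n_shared_units), comparable across amplicons of different sizes.
    """
    validate_pairs(pairs)
    amplicons = list(amplicons) if amplicons is not None else matrix.amplicons
    present = set(matrix.sample_ids)
    keep = pairs[
        pairs["member_1"].isin(present) & pairs["member_2"].isin(present)
    ].reset_index(drop=True)
    for pid in pairs.loc[~pairs["pair_id"].isin(keep["pair_id"]), "pair_id"]:
        logger.info("pair %s skipped: member(s) not in matrix", pid)
    if keep.empty:
        return pd.DataFrame(columns=[
            "pair_id", "amplicon", "zygosity", "age", "years_apart",
            "pearson_r", "euclidean_d", "n_shared_units", "reason",
        ])
    row_of = {s: i for i, s in enumerate(matrix.sample_ids)}
    i1 = keep["member_1"].map(row_of).to_numpy()
    i2 = keep["member_2"].map(row_of).to_numpy()

    frames = []
    for amp in amplicons:
        block = matrix.amplicon_view(amp).to_numpy(dtype=float)
        x, y = block[i1], block[i2]
        mask = np.isfinite(x) & np.isfinite(y)
        n = mask.sum(axis=1)
        safe_n = np.maximum(n, 1)
        xm = np.where(mask, x, 0.0)
        ym = np.where(mask, y, 0.0)
        mx = xm.sum(axis=1) / safe_n
        my = ym.sum(axis=1) / safe_n
        xc = np.where(mask, x - mx[:, None], 0.0)
        yc = np.where(mask, y - my[:, None], 0.0)
        vx = (xc * xc).sum(axis=1)
        vy = (yc * yc).sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            r = (xc * yc).sum(axis=1) / np.sqrt(vx * vy)
        d = np.sqrt(np.where(mask, (x - y) ** 2, 0.0).sum(axis=1))
        d = np.where(n > 0, d, np.nan)
        reasons = np.full(len(keep), None, dtype=object)
        constant = (vx == 0) | (vy == 0)
        reasons[constant & (n >= 3)] = "constant member vector"
        few = n < 3
        reasons[few] = [f"only {k} shared units (< 3)" for k in n[few]]
        reasons[n == 0] = "no shared units"
        r = np.where(few | constant, np.nan, r)
        if normalize_distance:
            d = d / np.sqrt(np.maximum(n, 1))
        frames.append(pd.DataFrame({
            "pair_id": keep["pair_id"],
            "amplicon": amp,
            "zygosity": keep["zygosity"],
            "age": keep["age"],
            "years_apart": keep["years_apart"],
            "pearson_r": r,
            "euclidean_d": d,
            "n_shared_units": n,
            "reason": reasons,
        }))
    out = pd.concat(frames, ignore_index=True)
    # interleave amplicons per pair, matching the natural reading order
    out = out.sort_values(
        ["pair_id", "amplicon"],
        key=lambda s: s.map({p: i for i, p in enumerate(keep["pair_id"])})
        if s.name == "pair_id" else s.map({a: i for i, a in enumerate(amplicons)}),
        kind="stable",
    ).reset_index(drop=True)
    return out


@dataclass(frozen=True)
class TrendResult:
    """Spearman rank correlation of a per-pair statistic with pair age."""

    amplicon: str
    statistic: str  # "correlation" or "distance"
    spearman_rho: float
    p_value: float
    n_pairs: int


@dataclass(frozen=True)
class ThresholdTestResult:
    """Two-sample t-test of a per-pair statistic across a threshold age."""

    amplicon: str
    statistic: str
    threshold: float
    t_statistic: float
    p_value: float
    n_young: int  # age <= threshold
    n_old: int  # age > threshold


_STAT_COLUMNS = {"correlation": "pearson_r", "distance": "euclidean_d"}


def _extract(pair_stats: pd.DataFrame, amplicon: str, statistic: str) -> pd.DataFrame:
    if statistic not in _STAT_COLUMNS:
        raise ValueError(f"statistic must be one of {sorted(_STAT_COLUMNS)}")
    col = _STAT_COLUMNS[statistic]
    sub = pair_stats[pair_stats["amplicon"] == amplicon]
    sub = sub[np.isfinite(sub[col])]
    return sub.rename(columns={col: "value"})[["pair_id", "age", "value"]]


def age_trend(
    pair_stats: pd.DataFrame, amplicon: str, statistic: str = "correlation"
) -> TrendResult:
    """Spearman correlation of the chosen statistic with pair age.

    Ties receive average ranks.  Requires >= 4 pairs with a defined
    statistic; an all-tied statistic is rejected as undefined.
    """
    sub = _extract(pair_stats, amplicon, statistic)
    if len(sub) < 4:
        raise ValueError(
            f"{amplicon}/{statistic}: need >= 4 defined pairs, got {len(sub)}"
        )
    if np.ptp(sub["value"].to_numpy()) == 0:
        raise ValueError(f"{amplicon}/{statistic}: statistic constant across pairs")
    rho, p = stats.spearmanr(sub["value"], sub["age"])
    return TrendResult(amplicon, statistic, float(rho), float(p), len(sub))


def threshold_test(
    pair_stats: pd.DataFrame,
    amplicon: str,
    statistic: str = "correlation",
    threshold: float = 60.0,
    equal_var: bool = True,
) -> ThresholdTestResult:
    """t-test of the statistic between pairs aged <= threshold and > threshold.

    Classical equal-variance Student t-test by default; ``equal_var=False``
    switches to Welch.
    """
    sub = _extract(pair_stats, amplicon, statistic)
    young = sub[sub["age"] <= threshold]["value"].to_numpy()
    old = sub[sub["age"] > threshold]["value"].to_numpy()
    if young.size < 2 or old.size < 2:
        side = "age <= threshold" if young.size < 2 else "age > threshold"
        raise ValueError(
            f"{amplicon}/{statistic}: group '{side}' has "
            f"{min(young.size, old.size)} defined pairs (< 2)"
        )
    t, p = stats.ttest_ind(young, old, equal_var=equal_var)
    return ThresholdTestResult(
        amplicon, statistic, threshold, float(t), float(p), young.size, old.size
    )


def age_class_summary(
    matrix: MethylationMatrix,
    ages: pd.Series,
    classes: Sequence[tuple[float, float]] = DEFAULT_AGE_CLASSES,
) -> pd.DataFrame:
    """Per (age class, amplicon) mean methylation and mean per-unit SD.

    ``ages`` maps sample id -> age.  Classes are defined by their printed
    integer labels; assignment uses the upper edges, a class covering
    ``(previous upper, its upper]`` so continuous ages between labels (e.g.
    45.5 for classes 20-45 / 46-60) land in the later class.  Ages outside
    the overall range are rejected.  Empty classes are reported with
    ``n_samples = 0`` and NaN summaries.
    """
    ages = pd.Series(ages)
    missing = [s for s in matrix.sample_ids if s not in ages.index]
    if missing:
        raise ValueError(f"samples without an age: {missing[:5]}")
    uppers = [hi for _, hi in classes]
    if uppers != sorted(uppers):
        raise ValueError("age classes must be ordered by upper edge")
    rows = []
    assigned: dict[str, int] = {}
    for s in matrix.sample_ids:
        age = ages[s]
        if age < classes[0][0] or age > uppers[-1]:
            raise ValueError(
                f"sample {s} (age {age}) outside the age-class range "
                f"[{classes[0][0]}, {uppers[-1]}]"
            )
        assigned[s] = int(np.searchsorted(uppers, age, side="left"))
    for i, (lo, hi) in enumerate(classes):
        members = [s for s in matrix.sample_ids if assigned[s] == i]
        for amp in matrix.amplicons:
            if members:
                block = matrix.amplicon_view(amp).loc[members]
                mean = float(np.nanmean(block.to_numpy()))
                mean_sd = float(block.std(axis=0, ddof=1).mean(skipna=True))
            else:
                mean, mean_sd = math.nan, math.nan
            rows.append({
                "age_class": f"{lo:g}-{hi:g}",
                "amplicon": amp,
                "n_samples": len(members),
                "mean_methylation": mean,
                "mean_unit_sd": mean_sd,
            })
    return pd.DataFrame(rows)
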