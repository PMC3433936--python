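"""Population-stratification analysis of a methylation matrix.

The cohort-1 workflow: per-group descriptive statistics for each CpG unit,
the unit-by-unit Pearson correlation structure, and a per-amplicon PCA
whose first principal component is tested for group differences with a
one-way ANOVA.  A significant ANOVA would indicate that geography or
ancestry structures the methylation of that amplicon.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import MethylationMatrix, amplicon_of_unit

logger = logging.getLogger(__name__)

__all__ = [
    "PCAResult",
    "AnovaResult",
    "group_summary",
    "cpg_correlation_matrix",
    "pca_pc1",
    "anova_pc1",
]


def group_summary(matrix: MethylationMatrix, groups: pd.Series) -> pd.DataFrame:
    """Per (group, unit) mean and SD of methylation over non-missing values.

    Parameters
    ----------
    matrix
        Methylation matrix.
    groups
        Group label per sample, indexed by sample id (every sample in the
        matrix must be labelled).

    Returns
    -------
    DataFrame with columns ``group, unit, amplicon, mean, sd, n``; the SD
    uses the n-1 denominator, and cells with no observed values carry NaN.
    """
    groups = pd.Series(groups)
    unlabelled = [s for s in matrix.sample_ids if s not in groups.index or pd.isna(groups[s])]
    if unlabelled:
        raise ValueError(f"samples without a group label: {unlabelled[:5]}")
    rows = []
    labels = groups.loc[matrix.sample_ids]
    for g, df in matrix.data.groupby(labels, observed=True, sort=True):
        n = df.notna().sum(axis=0)
        mean = df.mean(axis=0)
        sd = df.std(axis=0, ddof=1)
        for u in matrix.unit_ids:
            rows.append({
                "group": g,
                "unit": u,
                "amplicon": amplicon_of_unit(u),
                "mean": mean[u] if n[u] > 0 else np.nan,
                "sd": sd[u],
                "n": int(n[u]),
            })
    return pd.DataFrame(rows)


def cpg_correlation_matrix(
    matrix: MethylationMatrix, min_periods: int = 3
) -> pd.DataFrame:
    """Units x units Pearson correlation matrix, pairwise-complete.

    Cells backed by fewer than ``min_periods`` complete pairs are NaN, as
    are the row/column of any zero-variance unit (with a warning).  The
    diagonal is exactly 1 for every unit with variance.
    """
    corr = matrix.data.corr(method="pearson", min_periods=min_periods)
    variances = matrix.data.var(axis=0, skipna=True)
    degenerate = [u for u in matrix.unit_ids if not variances[u] > 0]
    for u in degenerate:
        corr.loc[u, :] = np.nan
        corr.loc[:, u] = np.nan
        logger.warning("correlation matrix: unit %s has zero variance, marked missing", u)
    ok = [u for u in matrix.unit_ids if u not in degenerate]
    for u in ok:
        if matrix.data[u].notna().sum() >= min_periods:
            corr.loc[u, u] = 1.0
    return corr


@dataclass
class PCAResult:
    """PCA of one amplicon's units: PC1 scores and the full spectrum."""

    amplicon: str
    scores: pd.Series  # PC1 score per sample
    loadings: pd.Series  # PC1 loading per unit
    eigenvalues: np.ndarray  # all covariance eigenvalues, descending
    n_imputed_cells: int

    @property
    def variance_explained_pc1(self) -> float:
        return float(self.eigenvalues[0] / self.eigenvalues.sum())

    @property
    def variance_explained(self) -> np.ndarray:
        """Variance fractions for all components (sums to 1)."""
        return self.eigenvalues / self.eigenvalues.sum()


def pca_pc1(
    matrix: MethylationMatrix,
    amplicon: str,
    missing: str = "impute",
    standardize: bool = False,
) -> PCAResult:
    """PC1 of one amplicon's units across samples.

    Missing values are mean-imputed per unit by default (``missing="impute"``,
    preserving the sample count) or rows with any gap are dropped
    (``missing="complete"``).  PCA is on the covariance matrix — the units
    share the methylated-fraction scale — unless ``standardize`` is set.
    The sign of PC1 is fixed so that the loading with the largest absolute
    value is positive, making results stable across seeds and libraries.
    """
    df = matrix.amplicon_view(amplicon)
    if df.shape[1] < 2:
        raise ValueError(f"{amplicon}: PCA needs >= 2 units, got {df.shape[1]}")
    n_imputed = 0
    if missing == "impute":
        n_imputed = int(df.isna().to_numpy().sum())
        if n_imputed:
            df = df.fillna(df.mean(axis=0))
        if df.isna().any().any():
            bad = df.columns[df.isna().any()].tolist()
            raise ValueError(f"{amplicon}: units with no observed values: {bad}")
    elif missing == "complete":
        df = df.dropna(axis=0)
    else:
        raise ValueError(f"missing must be 'impute' or 'complete', got {missing!r}")
    if df.shape[0] < 3:
        raise ValueError(f"{amplicon}: PCA needs >= 3 samples, got {df.shape[0]}")

    X = df.to_numpy(dtype=float)
    X = X - X.mean(axis=0)
    if standardize:
        sd = X.std(axis=0, ddof=1)
        if np.any(sd == 0):
            bad = df.columns[sd == 0].tolist()
            raise ValueError(f"{amplicon}: zero-variance units under standardization: {bad}")
        X = X / sd
    cov = (X.T @ X) / (X.shape[0] - 1)
    eigvals, eigvecs = np.linalg.eigh(cov)
    order = np.argsort(eigvals)[::-1]
    eigvals = np.clip(eigvals[order], 0.0, None)
    if eigvals.sum() <= 0:
        raise ValueError(f"{amplicon}: degenerate covariance (all samples identical)")
    pc1 = eigvecs[:, order[0]]
    if pc1[np.argmax(np.abs(pc1))] < 0:
        pc1 = -pc1
    scores = pd.Series(X @ pc1, index=df.index, name="PC1")
    loadings = pd.Series(pc1, index=df.columns, name="PC1_loading")
    return PCAResult(
        amplicon=amplicon,
        scores=scores,
        loadings=loadings,
        eigenvalues=eigvals,
        n_imputed_cells=n_imputed,
    )


@dataclass(frozen=True)
class AnovaResult:
    f_statistic: float
    p_value: float
    df_between: int
    df_within: float
    group_sizes: tuple[int, ...]


def anova_pc1(
    scores: pd.Series, groups: pd.Series, welch: bool = False
) -> AnovaResult:
    """One-way ANOVA of PC1 scores across groups.

    Classical fixed-effects ANOVA by default; ``welch=True`` uses the
    heteroscedasticity-robust Welch variant.
    """
    groups = pd.Series(groups).loc[scores.index]
    if groups.isna().any():
        raise ValueError("every sample with a PC1 score needs a group label")
    arrays = [scores[groups == g].to_numpy() for g in pd.unique(groups)]
    sizes = tuple(a.size for a in arrays)
    if len(arrays) < 2:
        raise ValueError("ANOVA needs >= 2 groups")
    small = [g for g, a in zip(pd.unique(groups), arrays) if a.size < 2]
    if small:
        raise ValueError(f"ANOVA needs >= 2 samples per group; too small: {small}")
    if welch:
        from statsmodels.stats.oneway import anova_oneway

        res = anova_oneway(arrays, use_var="unequal", welch_correction=True)
        return AnovaResult(float(res.statistic), float(res.pvalue),
                           len(arrays) - 1, float(res.df_denom), sizes)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", stats.ConstantInputWarning)
        f, p = stats.f_oneway(*arrays)
    if np.isnan(f) and all(np.ptp(a) == 0 for a in arrays):
        # all values identical in every group: no between- or within-group
        # variation; report the no-effect limit explicitly
        f, p = 0.0, 1.0
    n_total = sum(sizes)
    return AnovaResult(float(f), float(p), len(arrays) - 1,
                       float(n_total - len(arrays)), sizes)
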