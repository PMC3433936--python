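"""Data-cleaning pipeline for CpG-unit methylation matrices.

Three stages, applied in a fixed order:

1. :func:`filter_samples` — drop samples whose methylation level could be
   established for fewer than 60% of the CpG units (strictly below the
   threshold; a sample exactly at the threshold is kept);
2. :func:`filter_units` — drop CpG units with more than 30% missing data
   points among the retained samples (strictly above; exactly 30% is kept);
3. :func:`detect_bimodal_units` — drop units whose value distribution is
   bimodal, the signature of a SNP segregating under the probe.  The test
   fits 1- and 2-component Gaussian mixtures and flags a unit when the
   2-component fit wins on BIC *and* the fitted modes are well separated
   *and* the minor component carries non-trivial weight; the guards keep
   the flag robust on the 100–400-sample cohorts this pipeline targets.

:func:`run_qc` composes the stages and emits an auditable
:class:`QCReport` in which every removal carries its triggering value.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from typing import Any

import numpy as np

from .datatypes import MethylationMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "QCConfig",
    "QCReport",
    "BimodalFlag",
    "filter_samples",
    "filter_units",
    "detect_bimodal_units",
    "run_qc",
]


@dataclass(frozen=True)
class QCConfig:
    """Thresholds for the cleaning stages.

    ``min_sample_coverage`` and ``max_unit_missing`` reproduce the printed
    cleaning rules (<60% measured removes a sample; >30% missing removes a
    unit).  The bimodality guards are methodological choices exposed for
    tuning; ``control_units`` is a hook for a user-supplied list of
    bisulfite-conversion control units to exclude up front.
    """

    min_sample_coverage: float = 0.60
    max_unit_missing: float = 0.30
    bimodal_min_n: int = 20
    bimodal_min_separation: float = 0.2
    bimodal_min_weight: float = 0.2
    bimodal_random_state: int = 0
    control_units: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not 0.0 <= self.min_sample_coverage <= 1.0:
            raise ValueError(f"min_sample_coverage must be in [0, 1] (got {self.min_sample_coverage})")
        if not 0.0 <= self.max_unit_missing <= 1.0:
            raise ValueError(f"max_unit_missing must be in [0, 1] (got {self.max_unit_missing})")
        if self.bimodal_min_n < 3:
            raise ValueError("bimodal_min_n must be >= 3")


@dataclass(frozen=True)
class BimodalFlag:
    """One unit flagged (or examined) by the bimodality detector."""

    unit: str
    delta_bic: float  # BIC(1) - BIC(2); positive favours two components
    separation: float  # |mu_2 - mu_1| of the fitted mixture
    minor_weight: float


@dataclass
class QCReport:
    """Audit trail of one cleaning run; every removal carries its trigger."""

    removed_samples: list[tuple[str, float]] = field(default_factory=list)
    removed_units_missingness: list[tuple[str, float]] = field(default_factory=list)
    removed_units_bimodal: list[BimodalFlag] = field(default_factory=list)
    skipped_units: list[tuple[str, str]] = field(default_factory=list)
    n_samples_before: int = 0
    n_samples_after: int = 0
    n_units_before: int = 0
    n_units_after: int = 0

    def validate(self) -> None:
        n_removed = len(self.removed_units_missingness) + len(self.removed_units_bimodal)
        if self.n_units_after != self.n_units_before - n_removed:
            raise AssertionError(
                "QC bookkeeping violated: "
                f"{self.n_units_before} - {n_removed} != {self.n_units_after}"
            )
        if self.n_samples_after != self.n_samples_before - len(self.removed_samples):
            raise AssertionError("QC sample bookkeeping violated")

    def to_dict(self) -> dict[str, Any]:
        return {
            "removed_samples": [
                {"sample": s, "measured_fraction": f} for s, f in self.removed_samples
            ],
            "removed_units_missingness": [
                {"unit": u, "missing_fraction": f} for u, f in self.removed_units_missingness
            ],
            "removed_units_bimodal": [asdict(f) for f in self.removed_units_bimodal],
            "skipped_units": [{"unit": u, "reason": r} for u, r in self.skipped_units],
            "n_samples_before": self.n_samples_before,
            "n_samples_after": self.n_samples_after,
            "n_units_before": self.n_units_before,
            "n_units_after": self.n_units_after,
        }

    def to_json(self, indent: int = 2) -> str:
        return json.dumps(self.to_dict(), indent=indent)

    def to_text(self) -> str:
        lines = [
            f"QC report: {self.n_samples_before} -> {self.n_samples_after} samples, "
            f"{self.n_units_before} -> {self.n_units_after} units",
        ]
        for s, f in self.removed_samples:
            lines.append(f"  removed sample {s}: measured fraction {f:.3f}")
        for u, f in self.removed_units_missingness:
            lines.append(f"  removed unit {u}: missing fraction {f:.3f}")
        for flag in self.removed_units_bimodal:
            lines.append(
                f"  removed unit {flag.unit}: bimodal "
                f"(dBIC={flag.delta_bic:.1f}, sep={flag.separation:.2f}, "
                f"minor weight={flag.minor_weight:.2f})"
            )
        for u, r in self.skipped_units:
            lines.append(f"  skipped unit {u}: {r}")
        return "\n".join(lines)


def filter_samples(
    matrix: MethylationMatrix, min_measured_fraction: float = 0.60
) -> tuple[MethylationMatrix, list[tuple[str, float]]]:
    """Remove samples with a measured-unit fraction strictly below threshold."""
    if matrix.n_samples == 0 or matrix.n_units == 0:
        raise ValueError("cannot QC an empty matrix")
    measured = matrix.measured_fraction_per_sample()
    removed = [
        (str(s), float(f)) for s, f in measured.items() if f < min_measured_fraction
    ]
    keep = [s for s in matrix.sample_ids if measured[s] >= min_measured_fraction]
    for s, f in removed:
        logger.info("QC: removed sample %s (measured fraction %.3f)", s, f)
    return matrix.subset(samples=keep), removed


def filter_units(
    matrix: MethylationMatrix, max_missing_fraction: float = 0.30
) -> tuple[MethylationMatrix, list[tuple[str, float]]]:
    """Remove units with a missing fraction strictly above threshold.

    Intended to run after :func:`filter_samples`, so the fraction is
    computed over the retained samples.
    """
    missing = matrix.missing_fraction_per_unit()
    removed = [
        (str(u), float(f)) for u, f in missing.items() if f > max_missing_fraction
    ]
    keep = [u for u in matrix.unit_ids if missing[u] <= max_missing_fraction]
    for u, f in removed:
        logger.info("QC: removed unit %s (missing fraction %.3f)", u, f)
    return matrix.subset(units=keep), removed


def detect_bimodal_units(
    matrix: MethylationMatrix,
    min_n: int = 20,
    min_separation: float = 0.2,
    min_weight: float = 0.2,
    random_state: int = 0,
) -> tuple[list[BimodalFlag], list[tuple[str, str]]]:
    """Flag units whose observed values form two well-separated modes.

    Returns ``(flagged, skipped)``; a unit is skipped (with a reason) when
    it has fewer than ``min_n`` observed values or zero variance.
    """
    from sklearn.mixture import GaussianMixture

    flagged: list[BimodalFlag] = []
    skipped: list[tuple[str, str]] = []
    for u in matrix.unit_ids:
        col = matrix.data[u].to_numpy()
        x = col[~np.isnan(col)]
        if x.size == 0:
            skipped.append((str(u), "all values missing"))
            logger.warning("bimodality check: unit %s all-missing, skipped", u)
            continue
        if x.size < min_n:
            skipped.append((str(u), f"only {x.size} observed values (< {min_n})"))
            continue
        if np.ptp(x) == 0.0:
            skipped.append((str(u), "zero variance (degenerate)"))
            logger.info("bimodality check: unit %s constant, skipped", u)
            continue
        X = x.reshape(-1, 1)
        gm1 = GaussianMixture(1, random_state=random_state).fit(X)
        gm2 = GaussianMixture(2, n_init=3, random_state=random_state).fit(X)
        delta_bic = float(gm1.bic(X) - gm2.bic(X))
        means = gm2.means_.ravel()
        weights = gm2.weights_.ravel()
        separation = float(abs(means[1] - means[0]))
        minor_weight = float(weights.min())
        if delta_bic > 0 and separation >= min_separation and minor_weight >= min_weight:
            flagged.append(BimodalFlag(str(u), delta_bic, separation, minor_weight))
            logger.info(
                "bimodality check: unit %s flagged (dBIC=%.1f, sep=%.2f, w=%.2f)",
                u, delta_bic, separation, minor_weight,
            )
    return flagged, skipped


def run_qc(
    matrix: MethylationMatrix, config: QCConfig | None = None
) -> tuple[MethylationMatrix, QCReport]:
    """Run the full cleaning pipeline in its fixed order and report removals."""
    config = config or QCConfig()
    report = QCReport(
        n_samples_before=matrix.n_samples,
        n_units_before=matrix.n_units,
    )
    if config.control_units:
        keep = [u for u in matrix.unit_ids if u not in set(config.control_units)]
        matrix = matrix.subset(units=keep)
        report.n_units_before = matrix.n_units

    matrix, report.removed_samples = filter_samples(matrix, config.min_sample_coverage)
    matrix, report.removed_units_missingness = filter_units(matrix, config.max_unit_missing)
    flagged, report.skipped_units = detect_bimodal_units(
        matrix,
        min_n=config.bimodal_min_n,
        min_separation=config.bimodal_min_separation,
        min_weight=config.bimodal_min_weight,
        random_state=config.bimodal_random_state,
    )
    report.removed_units_bimodal = flagged
    if flagged:
        keep = [u for u in matrix.unit_ids if u not in {f.unit for f in flagged}]
        matrix = matrix.subset(units=keep)
    report.n_samples_after = matrix.n_samples
    report.n_units_after = matrix.n_units
    report.validate()
    return matrix, report
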