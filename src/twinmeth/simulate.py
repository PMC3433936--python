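"""Synthetic twin-cohort and population-cohort methylation generator.

The generator embodies an ACE variance decomposition per amplicon: each
individual's deviation from the amplicon mean is the sum of an Additive
genetic component (shared fully by monozygotic co-twins, correlated 0.5 in
dizygotic co-twins), a Common-environment component (shared by both
co-twins) and a unique-Environment component (independent per individual).

Each component is split between two levels controlled by
``amplicon_share`` (:math:`w`):

* an **amplicon-level scalar** (variance :math:`w \\cdot \\sigma^2`) shared
  by all CpG units of the amplicon — this produces the strong
  within-amplicon / weak between-amplicon correlation structure seen in
  real EpiTYPER data across samples;
* **independent per-unit effects** (variance :math:`(1-w)\\cdot\\sigma^2`)
  — these are what make the intra-couple correlation (Pearson across a
  pair's unit vectors) sensitive to the ACE parameters, since a scalar
  shift of a whole vector leaves Pearson correlation unchanged.

Age-related epigenetic drift is modelled as an inflation of the
unique-environment variance: by default a step multiplier for pairs older
than ``drift_threshold_age`` (60 years), optionally a linear ramp.

Measured CpG-unit values add independent technical noise and are clamped
to the [0, 1] methylated-fraction scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Any, Sequence

import numpy as np
import pandas as pd

from .datatypes import MethylationMatrix, unit_id

__all__ = [
    "AmpliconSimSpec",
    "SimConfig",
    "default_amplicon_specs",
    "simulate_twin_cohort",
    "simulate_population_cohort",
    "inject_missingness",
    "inject_snp_bimodality",
]


def _check(condition: bool, fieldname: str, message: str) -> None:
    if not condition:
        raise ValueError(f"{fieldname}: {message}")


@dataclass(frozen=True)
class AmpliconSimSpec:
    """Generating parameters for one amplicon.

    Parameters
    ----------
    name
        Amplicon name (becomes the column prefix in the matrix).
    n_units
        Number of CpG units.
    mean_level
        Mean methylated fraction, in (0, 1).
    var_A, var_C, var_E
        Additive-genetic, common-environment and unique-environment
        variances on the methylated-fraction scale (squared fractions).
    unit_noise_sd
        SD of independent per-measurement technical noise.
    drift_multiplier
        Factor (>= 1) applied to ``var_E`` for individuals past the drift
        threshold age; 1 disables drift for this amplicon.
    amplicon_share
        Fraction ``w`` of each ACE variance placed at the amplicon-scalar
        level (shared across units); the remainder is independent per unit.
    unit_mean_spread
        Half-range of deterministic per-unit offsets around ``mean_level``,
        emulating the per-CpG mean profile of a real amplicon.
    """

    name: str
    n_units: int
    mean_level: float
    var_A: float
    var_C: float
    var_E: float
    unit_noise_sd: float = 0.02
    drift_multiplier: float = 1.0
    amplicon_share: float = 0.5
    unit_mean_spread: float = 0.0

    def __post_init__(self) -> None:
        _check(self.n_units >= 1, "n_units", f"must be >= 1 (got {self.n_units})")
        _check(0.0 < self.mean_level < 1.0, "mean_level",
               f"must be in (0, 1) (got {self.mean_level})")
        for fname in ("var_A", "var_C", "var_E"):
            _check(getattr(self, fname) >= 0.0, fname, "must be >= 0")
        _check(self.var_A + self.var_C + self.var_E > 0.0, "var_A+var_C+var_E",
               "total latent variance must be > 0")
        _check(self.unit_noise_sd >= 0.0, "unit_noise_sd", "must be >= 0")
        _check(self.drift_multiplier >= 1.0, "drift_multiplier",
               f"must be >= 1 (got {self.drift_multiplier})")
        _check(0.0 <= self.amplicon_share <= 1.0, "amplicon_share", "must be in [0, 1]")
        _check(self.unit_mean_spread >= 0.0, "unit_mean_spread", "must be >= 0")

    def unit_offsets(self) -> np.ndarray:
        """Deterministic per-unit offsets spanning ±unit_mean_spread."""
        if self.n_units == 1 or self.unit_mean_spread == 0.0:
            return np.zeros(self.n_units)
        return np.linspace(-1.0, 1.0, self.n_units) * self.unit_mean_spread


def default_amplicon_specs() -> tuple[AmpliconSimSpec, ...]:
    """Default generating parameters for the four IGF2/H19 target regions.

    Mean levels follow the measured cohort means (IGF2AS 0.49, IGF2_shore
    0.61, IGF2_island 0.45, H19 0.36).  Drift is confined to IGF2_shore
    (strongest, x3) and IGF2AS (x2), the two regions where within-pair
    divergence accelerates after age 60; the shore carries the smallest
    additive-genetic share, matching its weak heritability.
    """
    return (
        AmpliconSimSpec("IGF2AS", n_units=5, mean_level=0.49,
                        var_A=0.0020, var_C=0.0005, var_E=0.0015,
                        unit_noise_sd=0.015, drift_multiplier=2.0,
                        unit_mean_spread=0.15),
        AmpliconSimSpec("IGF2_shore", n_units=6, mean_level=0.61,
                        var_A=0.0002, var_C=0.0018, var_E=0.0020,
                        unit_noise_sd=0.015, drift_multiplier=3.0,
                        unit_mean_spread=0.15),
        AmpliconSimSpec("IGF2_island", n_units=14, mean_level=0.45,
                        var_A=0.0015, var_C=0.0010, var_E=0.0050,
                        unit_noise_sd=0.02, drift_multiplier=1.0,
                        unit_mean_spread=0.15),
        AmpliconSimSpec("H19", n_units=14, mean_level=0.36,
                        var_A=0.0020, var_C=0.0010, var_E=0.0015,
                        unit_noise_sd=0.015, drift_multiplier=1.0,
                        unit_mean_spread=0.15),
    )


@dataclass(frozen=True)
class SimConfig:
    """Study-design parameters for the synthetic cohorts.

    Defaults mirror the modelled study: 31 MZ + 16 DZ pairs aged 22–97 for
    the twin cohort; four geographic groups of middle-aged (30–51) males
    for the population cohort; drift threshold at 60 years.
    """

    n_mz_pairs: int = 31
    n_dz_pairs: int = 16
    age_range: tuple[float, float] = (22.0, 97.0)
    amplicons: tuple[AmpliconSimSpec, ...] = field(default_factory=default_amplicon_specs)
    missing_rate: float = 0.0
    n_bimodal_sites: int = 0
    seed: int = 0
    drift_threshold_age: float = 60.0
    drift_mode: str = "step"  # or "linear"
    n_pop_samples_per_group: int | tuple[int, ...] = 94
    group_labels: tuple[str, ...] = ("North", "Center", "South", "Sardinia")
    group_effect: float = 0.0
    effect_group: str | None = None
    pop_age_range: tuple[float, float] = (30.0, 51.0)
    leaving_home_age_range: tuple[float, float] = (18.0, 35.0)

    def __post_init__(self) -> None:
        _check(self.n_mz_pairs >= 0, "n_mz_pairs", f"must be >= 0 (got {self.n_mz_pairs})")
        _check(self.n_dz_pairs >= 0, "n_dz_pairs", f"must be >= 0 (got {self.n_dz_pairs})")
        _check(self.age_range[0] <= self.age_range[1], "age_range",
               f"must be ordered (got {self.age_range})")
        _check(self.pop_age_range[0] <= self.pop_age_range[1], "pop_age_range",
               f"must be ordered (got {self.pop_age_range})")
        _check(len(self.amplicons) >= 1, "amplicons", "need at least one amplicon spec")
        names = [a.name for a in self.amplicons]
        _check(len(set(names)) == len(names), "amplicons", f"duplicate names in {names}")
        _check(0.0 <= self.missing_rate < 1.0, "missing_rate",
               f"must be in [0, 1) (got {self.missing_rate})")
        _check(self.n_bimodal_sites >= 0, "n_bimodal_sites", "must be >= 0")
        _check(self.drift_mode in ("step", "linear"), "drift_mode",
               f"must be 'step' or 'linear' (got {self.drift_mode!r})")
        _check(len(self.group_labels) == len(set(self.group_labels)), "group_labels",
               "labels must be unique")
        sizes = self._group_sizes()
        _check(all(s >= 0 for s in sizes), "n_pop_samples_per_group", "sizes must be >= 0")
        if self.effect_group is not None:
            _check(self.effect_group in self.group_labels, "effect_group",
                   f"{self.effect_group!r} not among group_labels")
        object.__setattr__(self, "amplicons", tuple(self.amplicons))
        object.__setattr__(self, "group_labels", tuple(self.group_labels))

    def _group_sizes(self) -> tuple[int, ...]:
        if isinstance(self.n_pop_samples_per_group, int):
            return tuple([self.n_pop_samples_per_group] * len(self.group_labels))
        sizes = tuple(self.n_pop_samples_per_group)
        _check(len(sizes) == len(self.group_labels), "n_pop_samples_per_group",
               "length must match group_labels")
        return sizes

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "SimConfig":
        """Build a config from a plain mapping (YAML/JSON); unknown keys rejected."""
        d = dict(d)
        known = set(cls.__dataclass_fields__)
        unknown = sorted(set(d) - known)
        if unknown:
            raise ValueError(f"unknown SimConfig keys: {unknown}")
        if "amplicons" in d:
            specs = []
            for spec in d["amplicons"]:
                if isinstance(spec, AmpliconSimSpec):
                    specs.append(spec)
                else:
                    spec = dict(spec)
                    bad = sorted(set(spec) - set(AmpliconSimSpec.__dataclass_fields__))
                    if bad:
                        raise ValueError(f"unknown AmpliconSimSpec keys: {bad}")
                    specs.append(AmpliconSimSpec(**spec))
            d["amplicons"] = tuple(specs)
        for key in ("age_range", "pop_age_range", "leaving_home_age_range",
                    "group_labels", "n_pop_samples_per_group"):
            if key in d and isinstance(d[key], list):
                d[key] = tuple(d[key])
        return cls(**d)


# ---------------------------------------------------------------------------
# twin cohort
# ---------------------------------------------------------------------------

def _drift_factor(spec: AmpliconSimSpec, ages: np.ndarray, config: SimConfig) -> np.ndarray:
    """Per-pair variance inflation of var_E for this amplicon."""
    if spec.drift_multiplier == 1.0:
        return np.ones_like(ages)
    t = config.drift_threshold_age
    if config.drift_mode == "step":
        return np.where(ages > t, spec.drift_multiplier, 1.0)
    # linear ramp from 1 at the threshold to drift_multiplier at the oldest age
    top = max(config.age_range[1], t + 1.0)
    frac = np.clip((ages - t) / (top - t), 0.0, 1.0)
    return 1.0 + (spec.drift_multiplier - 1.0) * frac


def _ace_values(
    spec: AmpliconSimSpec,
    is_mz: np.ndarray,
    drift: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Latent + measured values for one amplicon, shape (n_pairs, 2, n_units)."""
    n = is_mz.size
    k = spec.n_units
    w = spec.amplicon_share

    def twin_component(var: float, dz_corr: float, per_unit: bool) -> np.ndarray:
        """Draws with MZ co-twins identical and DZ co-twins correlated dz_corr."""
        shape_shared = (n, 1, k) if per_unit else (n, 1, 1)
        shape_own = (n, 2, k) if per_unit else (n, 2, 1)
        shared = rng.standard_normal(shape_shared)
        own = rng.standard_normal(shape_own)
        mz_part = np.broadcast_to(shared, (n, 2, k if per_unit else 1))
        dz_part = np.sqrt(dz_corr) * shared + np.sqrt(1.0 - dz_corr) * own
        z = np.where(is_mz[:, None, None], mz_part, dz_part)
        return np.sqrt(var) * z

    # additive genetic: MZ share fully, DZ correlate 0.5
    a = twin_component(w * spec.var_A, 0.5, per_unit=False) \
        + twin_component((1 - w) * spec.var_A, 0.5, per_unit=True)
    # common environment: shared by both co-twins regardless of zygosity
    c = twin_component(w * spec.var_C, 1.0, per_unit=False) \
        + twin_component((1 - w) * spec.var_C, 1.0, per_unit=True)
    # unique environment: independent per individual, drift-inflated variance
    sd_scale = np.sqrt(drift)[:, None, None]
    e = sd_scale * (
        np.sqrt(w * spec.var_E) * rng.standard_normal((n, 2, 1))
        + np.sqrt((1 - w) * spec.var_E) * rng.standard_normal((n, 2, k))
    )
    latent = spec.mean_level + spec.unit_offsets()[None, None, :] + a + c + e
    noise = spec.unit_noise_sd * rng.standard_normal((n, 2, k)) \
        if spec.unit_noise_sd > 0 else 0.0
    return np.clip(latent + noise, 0.0, 1.0)


def simulate_twin_cohort(
    config: SimConfig,
) -> tuple[MethylationMatrix, pd.DataFrame, pd.DataFrame]:
    """Simulate an MZ/DZ twin cohort.

    Returns
    -------
    matrix, metadata, pairs
        The methylation matrix (2 rows per pair), the per-sample metadata
        table and the twin-pairs table.  Co-twins share their age; the
        years the pair lived apart grow with age through a random
        leaving-home age.  Fully deterministic for a fixed ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    n_pairs = config.n_mz_pairs + config.n_dz_pairs
    is_mz = np.arange(n_pairs) < config.n_mz_pairs

    lo, hi = config.age_range
    ages = rng.uniform(lo, hi, n_pairs)
    leave_lo, leave_hi = config.leaving_home_age_range
    leaving_age = rng.uniform(leave_lo, leave_hi, n_pairs)
    years_apart = np.maximum(0.0, ages - leaving_age)

    # MZ co-twins are necessarily same-sex; DZ co-twins drawn independently
    sex_codes = np.asarray(["M", "F"])
    mz_sex = sex_codes[rng.integers(0, 2, n_pairs)]
    dz_sex_2 = sex_codes[rng.integers(0, 2, n_pairs)]
    sex_1 = mz_sex
    sex_2 = np.where(is_mz, mz_sex, dz_sex_2)

    pair_ids = np.array([
        f"{'MZ' if mz else 'DZ'}{i + 1:03d}"
        for i, mz in enumerate(is_mz)
    ])
    blocks = []
    columns: list[str] = []
    for spec in config.amplicons:
        drift = _drift_factor(spec, ages, config)
        vals = _ace_values(spec, is_mz, drift, rng)
        blocks.append(vals.reshape(2 * n_pairs, spec.n_units))
        columns.extend(unit_id(spec.name, f"u{j + 1}") for j in range(spec.n_units))

    sample_ids = [f"{pid}_{m}" for pid in pair_ids for m in (1, 2)]
    data = pd.DataFrame(
        np.hstack(blocks) if blocks else np.empty((2 * n_pairs, 0)),
        index=pd.Index(sample_ids, name="sample_id"),
        columns=columns,
    )
    matrix = MethylationMatrix(data)

    meta = pd.DataFrame({
        "sample_id": sample_ids,
        "pair_id": np.repeat(pair_ids, 2),
        "zygosity": np.repeat(np.where(is_mz, "MZ", "DZ"), 2),
        "age": np.repeat(ages, 2),
        "sex": np.stack([sex_1, sex_2], axis=1).ravel(),
        "group": pd.array([pd.NA] * (2 * n_pairs)),
        "years_apart": np.repeat(years_apart, 2),
    })
    pairs = pd.DataFrame({
        "pair_id": pair_ids,
        "member_1": [f"{pid}_1" for pid in pair_ids],
        "member_2": [f"{pid}_2" for pid in pair_ids],
        "zygosity": np.where(is_mz, "MZ", "DZ"),
        "age": ages,
        "sex_1": sex_1,
        "sex_2": sex_2,
        "years_apart": years_apart,
    })
    matrix = _apply_corruption(matrix, config, rng)
    return matrix, meta, pairs


# ---------------------------------------------------------------------------
# population cohort
# ---------------------------------------------------------------------------

def simulate_population_cohort(
    config: SimConfig,
) -> tuple[MethylationMatrix, pd.DataFrame]:
    """Simulate a population cohort of unrelated individuals with group labels.

    Under ``group_effect = 0`` every group is drawn from the same
    distribution (the null for downstream stratification tests); a nonzero
    ``group_effect`` shifts the designated group's mean methylation.
    """
    if len(config.group_labels) < 2:
        raise ValueError("group_labels: need at least 2 groups")
    rng = np.random.default_rng(config.seed)
    sizes = config._group_sizes()
    groups = np.repeat(np.asarray(config.group_labels, dtype=object), sizes)
    n = int(groups.size)
    effect_group = config.effect_group or config.group_labels[0]
    shift = np.where(groups == effect_group, config.group_effect, 0.0)

    lo, hi = config.pop_age_range
    ages = rng.uniform(lo, hi, n)

    blocks = []
    columns: list[str] = []
    for spec in config.amplicons:
        w = spec.amplicon_share
        total = spec.var_A + spec.var_C + spec.var_E
        scalar = np.sqrt(w * total) * rng.standard_normal((n, 1))
        per_unit = np.sqrt((1 - w) * total) * rng.standard_normal((n, spec.n_units))
        noise = (spec.unit_noise_sd * rng.standard_normal((n, spec.n_units))
                 if spec.unit_noise_sd > 0 else 0.0)
        vals = (spec.mean_level + spec.unit_offsets()[None, :]
                + shift[:, None] + scalar + per_unit + noise)
        blocks.append(np.clip(vals, 0.0, 1.0))
        columns.extend(unit_id(spec.name, f"u{j + 1}") for j in range(spec.n_units))

    sample_ids = [f"P{i + 1:04d}" for i in range(n)]
    data = pd.DataFrame(
        np.hstack(blocks) if blocks else np.empty((n, 0)),
        index=pd.Index(sample_ids, name="sample_id"),
        columns=columns,
    )
    matrix = MethylationMatrix(data)
    meta = pd.DataFrame({
        "sample_id": sample_ids,
        "pair_id": pd.array([pd.NA] * n),
        "zygosity": pd.array([pd.NA] * n),
        "age": ages,
        "sex": "M",
        "group": groups,
        "years_apart": pd.array([pd.NA] * n),
    })
    matrix = _apply_corruption(matrix, config, rng)
    return matrix, meta


# ---------------------------------------------------------------------------
# corruption operators
# ---------------------------------------------------------------------------

def _apply_corruption(
    matrix: MethylationMatrix, config: SimConfig, rng: np.random.Generator
) -> MethylationMatrix:
    if config.n_bimodal_sites > 0:
        if config.n_bimodal_sites > matrix.n_units:
            raise ValueError("n_bimodal_sites: exceeds number of units")
        chosen = rng.choice(matrix.unit_ids, size=config.n_bimodal_sites, replace=False)
        matrix = inject_snp_bimodality(
            matrix, list(chosen), seed=int(rng.integers(0, 2**31 - 1))
        )
    if config.missing_rate > 0.0:
        matrix = inject_missingness(
            matrix, config.missing_rate, seed=int(rng.integers(0, 2**31 - 1))
        )
    return matrix


def inject_missingness(
    matrix: MethylationMatrix, rate: float, seed: int
) -> MethylationMatrix:
    """Mask each cell independently with probability ``rate``."""
    if not 0.0 <= rate < 1.0:
        raise ValueError(f"rate: must be in [0, 1) (got {rate})")
    rng = np.random.default_rng(seed)
    data = matrix.data.copy()
    mask = rng.random(data.shape) < rate
    values = data.to_numpy()
    values[mask] = np.nan
    data.iloc[:, :] = values
    return MethylationMatrix(data)


def inject_snp_bimodality(
    matrix: MethylationMatrix,
    unit_ids: Sequence[str],
    seed: int,
    separation: float = 0.44,
    component_sd: float = 0.04,
) -> MethylationMatrix:
    """Replace the listed units' values with draws from a two-mode mixture.

    Emulates a SNP under the probe: roughly half the samples carry the
    variant allele and cluster at a second methylation mode.  Modes are
    equal-weight and separated by ``separation`` (>= 0.4 by default) on the
    methylated-fraction scale, centred near the unit's observed mean.
    Missing cells stay missing.
    """
    if separation < 0.4:
        raise ValueError(f"separation: must be >= 0.4 (got {separation})")
    unknown = [u for u in unit_ids if u not in matrix.data.columns]
    if unknown:
        raise KeyError(f"unknown unit ids: {unknown}")
    rng = np.random.default_rng(seed)
    data = matrix.data.copy()
    half = separation / 2.0
    for u in unit_ids:
        col = data[u].to_numpy()
        observed = ~np.isnan(col)
        center = float(np.nanmean(col)) if observed.any() else 0.5
        center = float(np.clip(center, half + 0.02, 1.0 - half - 0.02))
        comp = rng.integers(0, 2, col.size)
        modes = np.where(comp == 0, center - half, center + half)
        new = np.clip(modes + component_sd * rng.standard_normal(col.size), 0.0, 1.0)
        new[~observed] = np.nan
        data[u] = new
    return MethylationMatrix(data)
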