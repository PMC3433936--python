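"""Core containers for CpG-unit methylation data.

The central object is :class:`MethylationMatrix`, a thin wrapper around a
samples x CpG-units :class:`pandas.DataFrame` of methylated fractions in
[0, 1], with ``NaN`` as the explicit missing mask.  Column names encode the
owning amplicon as ``"<amplicon>.<unit>"`` (amplicon names must not contain
a dot), e.g. ``"IGF2_shore.CpG_9_10_11"``.

Sample metadata and twin pairings are plain DataFrames with a documented
schema (see :data:`METADATA_COLUMNS` and :data:`PAIRS_COLUMNS`); validators
are provided rather than bespoke table classes so the tables stay directly
usable with pandas/statsmodels idioms.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MethylationMatrix",
    "AmpliconDef",
    "unit_id",
    "amplicon_of_unit",
    "validate_metadata",
    "validate_pairs",
    "METADATA_COLUMNS",
    "PAIRS_COLUMNS",
]

#: Separator between amplicon name and unit label in matrix column names.
UNIT_SEP = "."

METADATA_COLUMNS = (
    "sample_id",
    "pair_id",
    "zygosity",
    "age",
    "sex",
    "group",
    "years_apart",
)

PAIRS_COLUMNS = (
    "pair_id",
    "member_1",
    "member_2",
    "zygosity",
    "age",
    "sex_1",
    "sex_2",
    "years_apart",
)

ZYGOSITIES = ("MZ", "DZ")


def unit_id(amplicon: str, label: str) -> str:
    """Build a matrix column name from an amplicon name and a CpG-unit label.

    Labels such as ``"CpG 9,10,11"`` (several CpG sites measured jointly
    because their cleavage fragments share a mass) are sanitised to
    ``"CpG_9_10_11"`` so the full id is filesystem- and header-safe.
    """
    if UNIT_SEP in amplicon:
        raise ValueError(f"amplicon name may not contain '{UNIT_SEP}': {amplicon!r}")
    clean = label.strip().replace(",", "_").replace(" ", "_")
    while "__" in clean:
        clean = clean.replace("__", "_")
    return f"{amplicon}{UNIT_SEP}{clean}"


def amplicon_of_unit(unit: str) -> str:
    """Return the amplicon name encoded in a unit id."""
    if UNIT_SEP not in unit:
        raise ValueError(f"unit id {unit!r} does not encode an amplicon (no '{UNIT_SEP}')")
    return unit.split(UNIT_SEP, 1)[0]


@dataclass
class MethylationMatrix:
    """Samples x CpG-unit methylated fractions with an explicit missing mask.

    Parameters
    ----------
    data
        DataFrame indexed by sample id with one column per CpG unit.  Values
        are methylated fractions in [0, 1]; ``NaN`` marks a missing call.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        if df.index.has_duplicates:
            dupes = df.index[df.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample ids: {dupes}")
        if df.columns.has_duplicates:
            dupes = df.columns[df.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate unit ids: {dupes}")
        for col in df.columns:
            amplicon_of_unit(str(col))  # raises if the amplicon tag is absent
        values = df.to_numpy(dtype=float)
        with np.errstate(invalid="ignore"):
            bad = (values < 0.0) | (values > 1.0)
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValueError(
                "methylation fraction outside [0, 1]: "
                f"sample {df.index[i]!r}, unit {df.columns[j]!r}, value {values[i, j]!r}"
            )
        # normalise dtype once so downstream numpy views are cheap
        self.data = df.astype(float)

    # -- basic geometry -------------------------------------------------
    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def unit_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_units(self) -> int:
        return self.data.shape[1]

    @property
    def amplicons(self) -> list[str]:
        """Amplicon names in first-appearance column order."""
        seen: dict[str, None] = {}
        for unit in self.data.columns:
            seen.setdefault(amplicon_of_unit(unit), None)
        return list(seen)

    def units_of(self, amplicon: str) -> list[str]:
        units = [u for u in self.data.columns if amplicon_of_unit(u) == amplicon]
        if not units:
            raise KeyError(f"no units for amplicon {amplicon!r}")
        return units

    # -- masks ----------------------------------------------------------
    def measured_fraction_per_sample(self) -> pd.Series:
        """Fraction of units with a methylation call, per sample."""
        return self.data.notna().mean(axis=1)

    def missing_fraction_per_unit(self) -> pd.Series:
        """Fraction of samples without a call, per unit."""
        return self.data.isna().mean(axis=0)

    # -- subsetting ------------------------------------------------------
    def subset(
        self,
        samples: Sequence[str] | None = None,
        units: Sequence[str] | None = None,
    ) -> "MethylationMatrix":
        """Return a copy restricted to the given samples/units, order preserved."""
        df = self.data
        if samples is not None:
            missing = [s for s in samples if s not in df.index]
            if missing:
                raise KeyError(f"unknown sample ids: {missing}")
            df = df.loc[list(samples)]
        if units is not None:
            missing = [u for u in units if u not in df.columns]
            if missing:
                raise KeyError(f"unknown unit ids: {missing}")
            df = df[list(units)]
        return MethylationMatrix(df.copy())

    def amplicon_view(self, amplicon: str) -> pd.DataFrame:
        """DataFrame restricted to one amplicon's units (no copy of the wrapper)."""
        return self.data[self.units_of(amplicon)]

    def copy(self) -> "MethylationMatrix":
        return MethylationMatrix(self.data.copy())

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"MethylationMatrix({self.n_samples} samples x {self.n_units} units, "
            f"amplicons={self.amplicons})"
        )


@dataclass(frozen=True)
class AmpliconDef:
    """A PCR amplicon: a named genomic region owning ordered CpG-unit labels.

    Coordinates are 1-based inclusive (``length = end - start + 1``).  If the
    input coordinates arrive end-first they are normalised to ``start <= end``
    with a warning, since published tables occasionally list minus-strand
    regions end-first.
    """

    name: str
    chrom: str
    start: int
    end: int
    units: tuple[str, ...]
    assembly: str = "NCBI36"

    def __post_init__(self) -> None:
        if UNIT_SEP in self.name:
            raise ValueError(f"amplicon name may not contain '{UNIT_SEP}': {self.name!r}")
        if self.start <= 0 or self.end <= 0:
            raise ValueError(f"{self.name}: coordinates must be positive 1-based")
        if self.start > self.end:
            warnings.warn(
                f"amplicon {self.name}: start {self.start} > end {self.end}; "
                "coordinates normalised to start <= end",
                stacklevel=2,
            )
            s, e = self.start, self.end
            object.__setattr__(self, "start", e)  # frozen: swap via object.__setattr__
            object.__setattr__(self, "end", s)
        if len(set(self.units)) != len(self.units):
            raise ValueError(f"{self.name}: duplicate unit labels")
        object.__setattr__(self, "units", tuple(self.units))

    @property
    def length(self) -> int:
        """Region length in base pairs under the 1-based inclusive convention."""
        return self.end - self.start + 1

    @property
    def n_units(self) -> int:
        return len(self.units)

    def unit_ids(self) -> list[str]:
        """Matrix column names for this amplicon's units."""
        return [unit_id(self.name, label) for label in self.units]


def _require_columns(df: pd.DataFrame, required: Iterable[str], what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{what} table is missing columns: {missing}")


def validate_metadata(meta: pd.DataFrame) -> pd.DataFrame:
    """Validate a sample-metadata table; returns it unchanged on success."""
    _require_columns(meta, METADATA_COLUMNS, "metadata")
    if meta["sample_id"].duplicated().any():
        raise ValueError("metadata: duplicate sample_id values")
    ages = pd.to_numeric(meta["age"], errors="raise")
    if (ages < 0).any():
        raise ValueError("metadata: negative age")
    zyg = meta["zygosity"].dropna()
    bad = sorted(set(zyg) - set(ZYGOSITIES))
    if bad:
        raise ValueError(f"metadata: unknown zygosity values {bad}")
    return meta


def validate_pairs(pairs: pd.DataFrame) -> pd.DataFrame:
    """Validate a twin-pairs table; returns it unchanged on success."""
    _require_columns(pairs, PAIRS_COLUMNS, "pairs")
    if pairs["pair_id"].duplicated().any():
        raise ValueError("pairs: duplicate pair_id values")
    if (pairs["member_1"] == pairs["member_2"]).any():
        raise ValueError("pairs: a pair must have two distinct members")
    bad = sorted(set(pairs["zygosity"]) - set(ZYGOSITIES))
    if bad:
        raise ValueError(f"pairs: unknown zygosity values {bad}")
    ya = pd.to_numeric(pairs["years_apart"], errors="raise")
    age = pd.to_numeric(pairs["age"], errors="raise")
    if ((ya < 0) | (ya > age)).any():
        raise ValueError("pairs: years_apart must satisfy 0 <= years_apart <= age")
    return pairs
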