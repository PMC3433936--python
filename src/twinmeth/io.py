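"""Tab-separated I/O for methylation matrices, sample metadata, twin pairs
and amplicon definitions, plus genomic-coordinate helpers.

Conventions
-----------
* Missing methylation calls are written as ``NA``; the decimal separator is
  always ``.`` regardless of locale.
* Genomic coordinates are stored 1-based inclusive; :func:`to_bed_interval`
  and :func:`from_bed_interval` convert exactly to/from the 0-based
  half-open BED convention.
* Methylation is stored as a fraction in [0, 1] everywhere in memory and on
  disk; rendering as a percentage is left to reports.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from .datatypes import (
    METADATA_COLUMNS,
    PAIRS_COLUMNS,
    AmpliconDef,
    MethylationMatrix,
    amplicon_of_unit,
    validate_metadata,
    validate_pairs,
)

__all__ = [
    "MISSING_TOKEN",
    "read_matrix",
    "write_matrix",
    "read_metadata",
    "write_metadata",
    "read_pairs",
    "write_pairs",
    "read_amplicons",
    "write_amplicons",
    "amplicon_length",
    "to_bed_interval",
    "from_bed_interval",
    "read_config",
]

MISSING_TOKEN = "NA"

#: Separator between unit labels in the amplicon table's ``units`` column
#: (labels themselves contain commas, e.g. ``CpG 9,10,11``).
_UNITS_FIELD_SEP = ";"


# ---------------------------------------------------------------------------
# methylation matrix
# ---------------------------------------------------------------------------

def write_matrix(matrix: MethylationMatrix, path: str | Path) -> None:
    """Write a methylation matrix as TSV (rows = samples, columns = units)."""
    matrix.data.to_csv(path, sep="\t", na_rep=MISSING_TOKEN, index_label="sample_id")


def read_matrix(path: str | Path) -> MethylationMatrix:
    """Read a methylation-matrix TSV, validating every value.

    Raises
    ------
    ValueError
        On a malformed row (with its line number) or an out-of-range value
        (naming the sample and unit).
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if df.columns[0] != "sample_id":
        raise ValueError(f"{path}: first column must be 'sample_id', got {df.columns[0]!r}")
    n_fields = df.shape[1]
    values = np.full(df.shape[0:1] + (n_fields - 1,), np.nan)
    for i, row in enumerate(df.itertuples(index=False)):
        for j, raw in enumerate(row[1:]):
            if raw == MISSING_TOKEN or raw == "":
                continue
            try:
                v = float(raw)
            except ValueError:
                raise ValueError(
                    f"{path}, line {i + 2}: cannot parse methylation value {raw!r}"
                ) from None
            if not 0.0 <= v <= 1.0:
                raise ValueError(
                    f"{path}, line {i + 2}: value {raw} outside [0, 1] "
                    f"for sample {row[0]!r}, unit {df.columns[j + 1]!r}"
                )
            values[i, j] = v
    out = pd.DataFrame(values, index=pd.Index(df.iloc[:, 0], name="sample_id"),
                       columns=df.columns[1:])
    return MethylationMatrix(out)


# ---------------------------------------------------------------------------
# metadata / pairs
# ---------------------------------------------------------------------------

def write_metadata(meta: pd.DataFrame, path: str | Path) -> None:
    validate_metadata(meta)
    meta.to_csv(path, sep="\t", na_rep=MISSING_TOKEN, index=False)


def read_metadata(path: str | Path) -> pd.DataFrame:
    meta = pd.read_csv(
        path, sep="\t", na_values=[MISSING_TOKEN], keep_default_na=False,
        dtype={"sample_id": str, "pair_id": str, "zygosity": str, "sex": str, "group": str},
    )
    missing = [c for c in METADATA_COLUMNS if c not in meta.columns]
    if missing:
        raise ValueError(f"{path}: metadata table missing columns {missing}")
    return validate_metadata(meta)


def write_pairs(pairs: pd.DataFrame, path: str | Path) -> None:
    validate_pairs(pairs)
    pairs.to_csv(path, sep="\t", na_rep=MISSING_TOKEN, index=False)


def read_pairs(path: str | Path) -> pd.DataFrame:
    pairs = pd.read_csv(
        path, sep="\t", na_values=[MISSING_TOKEN], keep_default_na=False,
        dtype={"pair_id": str, "member_1": str, "member_2": str,
               "zygosity": str, "sex_1": str, "sex_2": str},
    )
    missing = [c for c in PAIRS_COLUMNS if c not in pairs.columns]
    if missing:
        raise ValueError(f"{path}: pairs table missing columns {missing}")
    return validate_pairs(pairs)


# ---------------------------------------------------------------------------
# amplicon table
# ---------------------------------------------------------------------------

def write_amplicons(amplicons: list[AmpliconDef] | tuple[AmpliconDef, ...],
                    path: str | Path) -> None:
    rows = [
        {
            "name": a.name,
            "chrom": a.chrom,
            "start_1based": a.start,
            "end_1based": a.end,
            "assembly": a.assembly,
            "units": _UNITS_FIELD_SEP.join(a.units),
        }
        for a in amplicons
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_amplicons(path: str | Path) -> list[AmpliconDef]:
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = ["name", "chrom", "start_1based", "end_1based", "units"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: amplicon table missing columns {missing}")
    out: list[AmpliconDef] = []
    for i, row in df.iterrows():
        try:
            start = int(row["start_1based"])
            end = int(row["end_1based"])
        except ValueError:
            raise ValueError(
                f"{path}, line {i + 2}: non-integer coordinates "
                f"({row['start_1based']!r}, {row['end_1based']!r})"
            ) from None
        units = tuple(u for u in row["units"].split(_UNITS_FIELD_SEP) if u)
        out.append(
            AmpliconDef(
                name=row["name"],
                chrom=row["chrom"],
                start=start,
                end=end,
                units=units,
                assembly=row.get("assembly", "") or "NCBI36",
            )
        )
    return out


# ---------------------------------------------------------------------------
# coordinates
# ---------------------------------------------------------------------------

def amplicon_length(amplicon: AmpliconDef) -> int:
    """Region length in bp: ``end - start + 1`` (1-based inclusive)."""
    if amplicon.start > amplicon.end:
        raise ValueError(f"{amplicon.name}: start > end")
    return amplicon.end - amplicon.start + 1


def to_bed_interval(amplicon: AmpliconDef) -> tuple[str, int, int]:
    """1-based inclusive -> 0-based half-open (chrom, chromStart, chromEnd)."""
    return amplicon.chrom, amplicon.start - 1, amplicon.end


def from_bed_interval(chrom: str, chrom_start: int, chrom_end: int) -> tuple[str, int, int]:
    """0-based half-open BED interval -> (chrom, start, end), 1-based inclusive."""
    if chrom_start < 0 or chrom_end <= chrom_start:
        raise ValueError(f"invalid BED interval {chrom}:{chrom_start}-{chrom_end}")
    return chrom, chrom_start + 1, chrom_end


# ---------------------------------------------------------------------------
# config files
# ---------------------------------------------------------------------------

def read_config(path: str | Path) -> dict[str, Any]:
    """Read a YAML or JSON configuration file into a plain dict."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        return json.loads(text)
    loaded = yaml.safe_load(text)
    if not isinstance(loaded, dict):
        raise ValueError(f"{path}: config root must be a mapping")
    return loaded
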