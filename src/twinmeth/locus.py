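"""The four IGF2/H19 target regions assayed by the study design this package models.

Coordinates are NCBI build 36 (hg18), chromosome 11, 1-based inclusive.
Each amplicon carries the CpG units retained after data cleaning; a unit
groups adjacent CpG sites whose cleavage fragments are indistinguishable by
mass (e.g. ``"CpG 9,10,11"``) and is the atomic measurement column.

The IGF2_island region is published end-first (minus-strand orientation);
constructing its :class:`~twinmeth.datatypes.AmpliconDef` normalises the
coordinates and emits a warning, because the printed length is internally
inconsistent with the convention that fits the other three regions.
"""

from __future__ import annotations

import warnings

from .datatypes import AmpliconDef

__all__ = [
    "IGF2_SHORE",
    "IGF2_ISLAND",
    "IGF2AS",
    "H19",
    "TARGET_AMPLICONS",
]

IGF2_SHORE = AmpliconDef(
    name="IGF2_shore",
    chrom="chr11",
    start=2_111_039,
    end=2_111_314,
    units=("CpG 1,2", "CpG 3,4", "CpG 6", "CpG 7", "CpG 8", "CpG 9,10,11"),
)

IGF2AS = AmpliconDef(
    name="IGF2AS",
    chrom="chr11",
    start=2_126_035,
    end=2_126_372,
    units=("CpG 1", "CpG 3", "CpG 4", "CpG 6,7", "CpG 8"),
)

H19 = AmpliconDef(
    name="H19",
    chrom="chr11",
    start=1_975_948,
    end=1_976_360,
    units=(
        "CpG 1",
        "CpG 2",
        "CpG 6",
        "CpG 7",
        "CpG 8",
        "CpG 9,10",
        "CpG 12",
        "CpG 13",
        "CpG 14,15",
        "CpG 17",
        "CpG 18,19",
        "CpG 20",
        "CpG 22",
        "CpG 24",
    ),
)

with warnings.catch_warnings():
    # published end-first; normalisation is intentional here
    warnings.simplefilter("ignore")
    IGF2_ISLAND = AmpliconDef(
        name="IGF2_island",
        chrom="chr11",
        start=2_111_119,
        end=2_110_666,
        units=(
            "CpG 1,2",
            "CpG 4",
            "CpG 11,12",
            "CpG 13",
            "CpG 14",
            "CpG 15",
            "CpG 16",
            "CpG 17",
            "CpG 18,19",
            "CpG 20",
            "CpG 21",
            "CpG 25",
            "CpG 26",
            "CpG 27",
        ),
    )

#: The four assayed regions in reporting order.
TARGET_AMPLICONS: tuple[AmpliconDef, ...] = (IGF2AS, IGF2_SHORE, IGF2_ISLAND, H19)
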