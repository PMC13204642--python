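"""Genomic interval lists used for masking and exclusion.

All internal coordinates are 1-based with both endpoints inclusive, on a
single declared genome build (GRCh37 by convention). BED input (0-based,
half-open) is converted on read.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

# Extended HLA/MHC region on chromosome 6 (GRCh37): extreme LD and immune-gene
# density make its association statistics unrepresentative, so it is excluded
# from conditional-cdf fitting and from positional gene mapping.
HLA_REGION = ("6", 25_000_000, 34_000_000)

# The 8p23.1 cytoband (GRCh37) hosts a common large inversion polymorphism with
# long-range LD; excluded from cdf fitting alongside the HLA region.
CHR8P23_REGION = ("8", 6_300_001, 12_800_000)

DEFAULT_EXCLUSION_REGIONS = (HLA_REGION, CHR8P23_REGION)


@dataclass(frozen=True)
class Region:
    """A 1-based, both-endpoints-inclusive genomic interval."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < self.start:
            raise ValueError(f"invalid region {self.chrom}:{self.start}-{self.end}")

    def contains(self, chrom, pos) -> bool:
        return str(chrom) == self.chrom and self.start <= int(pos) <= self.end


def as_regions(regions: Iterable) -> list[Region]:
    """Normalize (chrom, start, end) tuples / Regions into Region objects."""
    out = []
    for r in regions or []:
        if isinstance(r, Region):
            out.append(r)
        else:
            chrom, start, end = r
            out.append(Region(str(chrom), int(start), int(end)))
    return out


def in_regions(chrom: Sequence, pos: Sequence, regions: Iterable) -> np.ndarray:
    """Boolean mask: does (chrom[i], pos[i]) fall inside any region?"""
    chrom = np.asarray(chrom).astype(str)
    pos = np.asarray(pos, dtype=np.int64)
    mask = np.zeros(len(pos), dtype=bool)
    for r in as_regions(regions):
        mask |= (chrom == r.chrom) & (pos >= r.start) & (pos <= r.end)
    return mask


def read_bed_regions(path) -> list[Region]:
    """Read a BED file (0-based, half-open) into 1-based inclusive Regions."""
    df = pd.read_csv(
        path,
        sep=r"\s+",
        header=None,
        comment="#",
        usecols=[0, 1, 2],
        names=["chrom", "start", "end"],
        dtype={"chrom": str},
    )
    df["chrom"] = df["chrom"].str.removeprefix("chr")
    # BED [start, end) -> 1-based inclusive [start+1, end]
    return [
        Region(c, int(s) + 1, int(e))
        for c, s, e in df.itertuples(index=False)
    ]
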