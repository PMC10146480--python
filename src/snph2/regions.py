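"""Genomic interval sets used for SNP filtering.

Coordinates are 1-based inclusive internally (the PLINK .bim convention);
BED files (0-based half-open) are converted at the parser boundary:
``start_1based = start_bed + 1``, ``end_1based = end_bed``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

__all__ = ["RegionSet", "APOE_REGION", "apoe_region_set"]

#: The APOE-analog window on (simulated) chromosome 19, matching the
#: chr19:44.4-46.5 Mb region excluded in the real-data analyses
#: (1-based inclusive).
APOE_REGION: tuple[int, int, int] = (19, 44_400_000, 46_500_000)


@dataclass
class RegionSet:
    """A labelled union of (chromosome, start_bp, end_bp) intervals, 1-based inclusive."""

    intervals: list[tuple[int, int, int]] = field(default_factory=list)
    label: str = ""

    def __post_init__(self) -> None:
        self.intervals = [(int(c), int(s), int(e)) for c, s, e in self.intervals]
        for c, s, e in self.intervals:
            if s > e:
                raise ValueError(f"interval start {s} > end {e} on chromosome {c}")

    def __len__(self) -> int:
        return len(self.intervals)

    @classmethod
    def from_bed(cls, path: str | Path, label: str | None = None) -> "RegionSet":
        """Read a BED interval file (0-based half-open) into 1-based inclusive intervals."""
        df = pd.read_csv(path, sep=r"\s+", header=None, comment="#", usecols=[0, 1, 2])
        ivals = []
        for chrom, start, end in df.itertuples(index=False):
            c = int(str(chrom).removeprefix("chr"))
            ivals.append((c, int(start) + 1, int(end)))
        return cls(ivals, label=label if label is not None else Path(path).stem)

    def to_bed(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for c, s, e in self.intervals:
                fh.write(f"{c}\t{s - 1}\t{e}\n")

    def contains(self, chrom, pos_bp, flank_bp: int = 0):
        """Boolean mask: does (chrom, pos) fall inside any interval +/- flank?"""
        import numpy as np

        chrom = np.asarray(chrom)
        pos = np.asarray(pos_bp)
        hit = np.zeros(pos.shape, dtype=bool)
        for c, s, e in self.intervals:
            hit |= (chrom == c) & (pos >= s - flank_bp) & (pos <= e + flank_bp)
        return hit


def apoe_region_set() -> RegionSet:
    """The default APOE-analog exclusion window as a :class:`RegionSet`."""
    return RegionSet([APOE_REGION], label="APOE")
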