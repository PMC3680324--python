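"""Genomic intervals and BED round-tripping.

All intervals are 0-based half-open internally; the BED reader/writer keeps
that convention, and one-based inclusive dialects (as emitted by some target
predictors) are converted at parse time.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable


@dataclass(frozen=True)
class GenomicRegion:
    chrom: str
    start: int
    end: int
    name: str = ""

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"region {self.name!r}: start {self.start} < 0")
        if not self.start < self.end:
            raise ValueError(
                f"region {self.name!r}: start {self.start} must be < end {self.end}"
            )

    def __len__(self) -> int:
        return self.end - self.start

    def contains(self, chrom: str, pos: int) -> bool:
        return chrom == self.chrom and self.start <= pos < self.end

    def overlaps(self, other: "GenomicRegion") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


def read_bed(path: str | Path) -> list[GenomicRegion]:
    """Read BED3+name; ignores extra columns, comment and track lines."""
    regions: list[GenomicRegion] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: fewer than 3 BED columns")
            name = parts[3] if len(parts) > 3 else f"region{len(regions) + 1}"
            regions.append(
                GenomicRegion(parts[0], int(parts[1]), int(parts[2]), name)
            )
    return regions


def write_bed(regions: Iterable[GenomicRegion], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in regions:
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.name}\n")
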