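"""Genomic intervals, element annotations, and BED I/O.

All coordinates are 0-based half-open, matching BED natively. Conversion to
or from 1-based dialects happens only at I/O boundaries (the bismark
coverage reader/writer in :mod:`rrmp.enrichment`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

VALID_LABELS = {"cpg_island", "cpg_shore", "cpg_shelf", "promoter", "tss", "peak"}


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A half-open interval [start, end) on a named chromosome.

    ``strand`` is '+', '-' or '.' (unstranded).
    """

    chrom: str
    start: int
    end: int
    strand: str = "."
    name: str = "."

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        """True iff the two intervals share >= 1 base."""
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def contains(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )


@dataclass
class ElementAnnotation:
    """A labelled set of genomic intervals (islands, shores, promoters, ...)."""

    label: str
    intervals: list[GenomicInterval] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.label not in VALID_LABELS:
            raise ValueError(f"unknown element label {self.label!r}")
        self.intervals = sorted(self.intervals)

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self):
        return iter(self.intervals)

    def total_bases(self) -> int:
        return sum(len(iv) for iv in self.intervals)

    def overlaps_point(self, chrom: str, pos: int) -> bool:
        probe = GenomicInterval(chrom, pos, pos + 1)
        return any(iv.overlaps(probe) for iv in self.intervals)

    def overlapping(self, query: GenomicInterval) -> list[GenomicInterval]:
        return [iv for iv in self.intervals if iv.overlaps(query)]


def any_overlap(query: GenomicInterval, intervals: Sequence[GenomicInterval]) -> bool:
    """>= 1 bp overlap between ``query`` and any member of ``intervals``."""
    return any(query.overlaps(iv) for iv in intervals)


# ---------------------------------------------------------------------------
# BED I/O (BED3 / BED6)
# ---------------------------------------------------------------------------

def read_bed(path: str | Path, label: str = "peak",
             require_strand: bool = False) -> ElementAnnotation:
    """Read a BED3/BED6 file into an :class:`ElementAnnotation`.

    ``require_strand`` enforces a strand column (needed for TSS records).
    """
    intervals: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: fewer than 3 BED columns")
            chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            name = fields[3] if len(fields) > 3 else "."
            strand = fields[5] if len(fields) > 5 else "."
            if require_strand and strand not in ("+", "-"):
                raise ValueError(f"{path}:{lineno}: strand column required")
            intervals.append(GenomicInterval(chrom, start, end, strand, name))
    return ElementAnnotation(label=label, intervals=intervals)


def write_bed(annotation: ElementAnnotation | Iterable[GenomicInterval],
              path: str | Path, bed6: bool = True) -> None:
    intervals = (annotation.intervals
                 if isinstance(annotation, ElementAnnotation) else list(annotation))
    label = (annotation.label
             if isinstance(annotation, ElementAnnotation) else ".")
    with open(path, "w") as fh:
        for iv in intervals:
            name = iv.name if iv.name != "." else label
            if bed6:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t0\t{iv.strand}\n")
            else:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")
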