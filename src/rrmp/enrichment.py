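"""Enrichment analytics: CpG coverage, element capture, saturation curves.

An element (CpG island, promoter, ...) counts as captured when its CpGs
accumulate at least 100-fold combined coverage — by default the SUM of
per-CpG depths across the element (a per-CpG mean is available as an
alternative rule). Saturation curves downsample by cumulative base pairs
with nested subsamples, so the curve is exactly monotone.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .intervals import ElementAnnotation, GenomicInterval
from .library import ConvertedMolecule

logger = logging.getLogger(__name__)


class CpGCoverageTrack:
    """Observed methylated/unmethylated counts per CpG unit.

    depth = methylated_count + unmethylated_count by construction;
    beta = methylated_count / depth, defined only at depth > 0.
    """

    def __init__(self) -> None:
        # (chrom) -> pos -> [methylated, unmethylated]
        self._counts: dict[str, dict[int, list[int]]] = {}

    def add(self, chrom: str, pos: int, methylated: bool, n: int = 1) -> None:
        per_chrom = self._counts.setdefault(chrom, {})
        entry = per_chrom.setdefault(pos, [0, 0])
        entry[0 if methylated else 1] += n

    def chroms(self) -> list[str]:
        return list(self._counts)

    def positions(self, chrom: str) -> list[int]:
        return sorted(self._counts.get(chrom, {}))

    def n_cpgs(self) -> int:
        return sum(len(v) for v in self._counts.values())

    def counts(self, chrom: str, pos: int) -> tuple[int, int]:
        m, u = self._counts[chrom][pos]
        return m, u

    def depth(self, chrom: str, pos: int) -> int:
        entry = self._counts.get(chrom, {}).get(pos)
        return 0 if entry is None else entry[0] + entry[1]

    def beta(self, chrom: str, pos: int) -> float:
        m, u = self._counts[chrom][pos]
        if m + u == 0:
            raise ValueError(f"beta undefined at zero depth ({chrom}:{pos})")
        return m / (m + u)

    def to_dataframe(self) -> pd.DataFrame:
        rows = [(chrom, pos, mu[0], mu[1])
                for chrom, per in self._counts.items()
                for pos, mu in sorted(per.items())]
        df = pd.DataFrame(rows, columns=["chrom", "pos", "methylated", "unmethylated"])
        df["depth"] = df["methylated"] + df["unmethylated"]
        df["beta"] = df["methylated"] / df["depth"]
        return df

    # -- bismark coverage dialect: chrom, 1-based start, end(=start), %meth, m, u
    def write_bismark_cov(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for chrom in sorted(self._counts):
                for pos, (m, u) in sorted(self._counts[chrom].items()):
                    pct = 100.0 * m / (m + u) if m + u else 0.0
                    fh.write(f"{chrom}\t{pos + 1}\t{pos + 1}\t{pct:.6g}\t{m}\t{u}\n")

    @classmethod
    def read_bismark_cov(cls, path: str | Path) -> "CpGCoverageTrack":
        track = cls()
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                fields = line.rstrip("\n").split("\t")
                if len(fields) != 6:
                    raise ValueError(f"{path}:{lineno}: expected 6 columns")
                chrom, start = fields[0], int(fields[1])
                m, u = int(fields[4]), int(fields[5])
                if m:
                    track.add(chrom, start - 1, True, m)
                if u:
                    track.add(chrom, start - 1, False, u)
                if m == 0 and u == 0:
                    track._counts.setdefault(chrom, {}).setdefault(start - 1, [0, 0])
        return track


@dataclass
class SaturationCurve:
    element_label: str
    points: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        bases = [b for b, _ in self.points]
        if any(b2 <= b1 for b1, b2 in zip(bases, bases[1:])):
            raise ValueError("sequencing_bases must be strictly increasing")
        if any(c < 0 for _, c in self.points):
            raise ValueError("captured_elements must be non-negative")

    def captured(self) -> list[int]:
        return [c for _, c in self.points]


# ---------------------------------------------------------------------------
# Coverage accumulation and capture
# ---------------------------------------------------------------------------

def accumulate_coverage(molecules: list[ConvertedMolecule]) -> CpGCoverageTrack:
    """Tally each molecule's drawn CpG states onto the Watson CpG coordinates.

    Origin coordinates are known in simulation, so no alignment step exists;
    this plays the role of a methylation extractor.
    """
    track = CpGCoverageTrack()
    for m in molecules:
        chrom = m.fragment.interval.chrom
        for pos, state in m.cpg_states.items():
            track.add(chrom, pos, state == "methylated")
    return track


def element_combined_depth(track: CpGCoverageTrack, element: GenomicInterval,
                           mode: str = "sum") -> float:
    """Combined coverage of an element: sum (default) or mean of per-CpG depths."""
    depths = [track.depth(element.chrom, pos)
              for pos in track.positions(element.chrom)
              if element.start <= pos < element.end]
    if not depths:
        return 0.0
    return float(sum(depths)) if mode == "sum" else float(np.mean(depths))


def element_captured(track: CpGCoverageTrack, element: GenomicInterval,
                     threshold: int = 100, mode: str = "sum") -> bool:
    """True iff combined coverage over the element's CpGs reaches the threshold.

    An element containing no covered CpG is simply not captured.
    """
    if threshold < 1:
        raise ValueError("threshold must be >= 1")
    return element_combined_depth(track, element, mode) >= threshold


def count_captured(track: CpGCoverageTrack, elements: ElementAnnotation,
                   threshold: int = 100, mode: str = "sum") -> int:
    return sum(element_captured(track, iv, threshold, mode) for iv in elements)


def saturation_curve(molecules: list[ConvertedMolecule],
                     elements: ElementAnnotation,
                     depth_grid: list[int], threshold: int = 100,
                     seed: int = 0, mode: str = "sum") -> SaturationCurve:
    """Captured elements vs sequenced bases under nested downsampling.

    Molecules are permuted once; each grid target takes the shortest prefix
    whose cumulative length reaches the target (the crossing molecule is
    included). Prefixes are nested, so captured counts are non-decreasing by
    construction. A target beyond the total base count saturates at the
    full-data capture count (logged).
    """
    grid = list(depth_grid)
    if any(b2 <= b1 for b1, b2 in zip(grid, grid[1:])):
        raise ValueError("depth_grid must be strictly increasing")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(molecules))
    lengths = np.array([len(molecules[i]) for i in order], dtype=np.int64)
    cum = np.cumsum(lengths)
    total = int(cum[-1]) if len(cum) else 0

    track = CpGCoverageTrack()
    consumed = 0
    points: list[tuple[int, int]] = []
    for target in grid:
        if target > total:
            logger.info("saturation target %d exceeds total bases %d; "
                        "curve saturates at full data", target, total)
        n_needed = int(np.searchsorted(cum, target, side="left") + 1) if target > 0 else 0
        n_needed = min(n_needed, len(molecules))
        for idx in order[consumed:n_needed]:
            m = molecules[idx]
            chrom = m.fragment.interval.chrom
            for pos, state in m.cpg_states.items():
                track.add(chrom, pos, state == "methylated")
        consumed = max(consumed, n_needed)
        points.append((target, count_captured(track, elements, threshold, mode)))
    return SaturationCurve(elements.label, points)


# ---------------------------------------------------------------------------
# Read fractions and length statistics
# ---------------------------------------------------------------------------

def _merge(intervals: list[GenomicInterval]) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for iv in intervals:
        by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end))
    merged: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom, spans in by_chrom.items():
        spans.sort()
        out: list[list[int]] = []
        for s, e in spans:
            if out and s <= out[-1][1]:
                out[-1][1] = max(out[-1][1], e)
            else:
                out.append([s, e])
        merged[chrom] = (np.array([s for s, _ in out]), np.array([e for _, e in out]))
    return merged


def read_fraction_by_element(molecules: list[ConvertedMolecule],
                             annotations: dict[str, ElementAnnotation]) -> dict[str, float]:
    """Fraction of molecules overlapping (>= 1 bp) each element label.

    Labels are not mutually exclusive. With zero molecules the fractions are
    undefined (NaN), never zero.
    """
    n = len(molecules)
    fractions: dict[str, float] = {}
    for label, ann in annotations.items():
        if n == 0:
            fractions[label] = float("nan")
            continue
        merged = _merge(list(ann))
        count = 0
        for m in molecules:
            iv = m.fragment.interval
            spans = merged.get(iv.chrom)
            if spans is None:
                continue
            starts, ends = spans
            idx = int(np.searchsorted(starts, iv.end, side="left")) - 1
            if idx >= 0 and ends[idx] > iv.start:
                count += 1
        fractions[label] = count / n
    return fractions


def fragment_length_stats(molecules: list) -> tuple[pd.Series, int | None]:
    """Integer length histogram and modal length (smallest length at the max)."""
    lengths = [len(m) for m in molecules]
    if not lengths:
        return pd.Series(dtype=int), None
    hist = pd.Series(lengths).value_counts().sort_index()
    modal = int(hist.index[np.argmax(hist.to_numpy())])
    return hist, modal
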