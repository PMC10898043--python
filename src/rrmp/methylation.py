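"""Beta-value analytics: windows, concordance, DMRs, peak association.

The DMR caller forms candidate regions from runs of nearby CpGs (inter-CpG
gap <= 100 bp, region span <= 300 bp), requires every sample to reach the
depth floor, and tests pooled methylated/unmethylated counts of the two
groups with a two-sided Fisher exact test. The three standard threshold
configurations are (p < 1e-7, dbeta > 0.5), (p < 0.05, dbeta > 0.2) and
(p < 0.05, dbeta > 0.33); promoter comparisons use Benjamini-Hochberg q
values (q < 0.01, dbeta > 0.5) over TSS +/- 4 kb regions. Threshold
comparisons are inclusive at the boundary by default (``strict=True``
switches to strict inequalities).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .enrichment import CpGCoverageTrack
from .intervals import ElementAnnotation, GenomicInterval

#: the printed DMR threshold configurations: (p_max, delta_min)
DMR_CONFIGS = {
    "strict": (1e-7, 0.5),
    "loose": (0.05, 0.2),
    "pairwise": (0.05, 0.33),
}


@dataclass
class ConcordanceResult:
    pearson_r: float  # NaN when undefined (< 2 shared CpGs)
    n_cpgs: int
    discordant_fraction: float  # share of CpGs with |dbeta| > 0.5


@dataclass
class DMRRecord:
    interval: GenomicInterval
    mean_beta_a: float
    mean_beta_b: float
    delta_beta: float
    p_value: float
    q_value: float | None
    direction: str  # hyper: A above B


def fisher_exact_p(table) -> float:
    """Two-sided Fisher exact p for a 2x2 table of non-negative counts."""
    return float(stats.fisher_exact(np.asarray(table), alternative="two-sided")[1])


# ---------------------------------------------------------------------------
# Windows and concordance
# ---------------------------------------------------------------------------

def window_betas(track: CpGCoverageTrack, window: int = 100_000,
                 min_depth: int = 1) -> pd.DataFrame:
    """Unweighted mean beta per tiling window (from coordinate 0).

    Only CpGs at depth >= min_depth contribute; windows with no qualifying
    CpG are omitted (missing), so genome-wide averages never count them as
    zero.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    rows = []
    for chrom in track.chroms():
        for pos in track.positions(chrom):
            m, u = track.counts(chrom, pos)
            if m + u >= min_depth and m + u > 0:
                rows.append((chrom, (pos // window) * window, m / (m + u)))
    if not rows:
        return pd.DataFrame(columns=["chrom", "window_start", "mean_beta", "n_cpgs"])
    df = pd.DataFrame(rows, columns=["chrom", "window_start", "beta"])
    out = (df.groupby(["chrom", "window_start"])["beta"]
           .agg(mean_beta="mean", n_cpgs="size").reset_index())
    return out


def concordance(track_a: CpGCoverageTrack, track_b: CpGCoverageTrack,
                min_depth: int = 20) -> ConcordanceResult:
    """Per-CpG agreement between two tracks.

    Restricted to CpGs reaching min_depth in BOTH tracks; Pearson r over the
    paired betas, plus the fraction of discordant CpGs (|dbeta| > 0.5).
    """
    if min_depth < 1:
        raise ValueError("min_depth must be >= 1")
    betas_a, betas_b = [], []
    for chrom in track_a.chroms():
        for pos in track_a.positions(chrom):
            if track_a.depth(chrom, pos) >= min_depth and \
                    track_b.depth(chrom, pos) >= min_depth:
                betas_a.append(track_a.beta(chrom, pos))
                betas_b.append(track_b.beta(chrom, pos))
    n = len(betas_a)
    if n < 2:
        return ConcordanceResult(float("nan"), n, float("nan"))
    a, b = np.array(betas_a), np.array(betas_b)
    with np.errstate(invalid="ignore"):
        r = float(np.corrcoef(a, b)[0, 1])
    discordant = float(np.mean(np.abs(a - b) > 0.5))
    return ConcordanceResult(r, n, discordant)


# ---------------------------------------------------------------------------
# DMR calling
# ---------------------------------------------------------------------------

def _candidate_regions(tracks: list[CpGCoverageTrack], max_region: int,
                       gap_max: int) -> list[tuple[str, list[int]]]:
    """Maximal runs of nearby CpGs, chunked to spans <= max_region bp."""
    chroms = sorted({c for t in tracks for c in t.chroms()})
    regions: list[tuple[str, list[int]]] = []
    for chrom in chroms:
        positions = sorted({p for t in tracks for p in t.positions(chrom)})
        run: list[int] = []
        for pos in positions:
            if run and pos - run[-1] > gap_max:
                regions.extend(_chunk(chrom, run, max_region))
                run = []
            run.append(pos)
        if run:
            regions.extend(_chunk(chrom, run, max_region))
    return regions


def _chunk(chrom: str, run: list[int], max_region: int) -> list[tuple[str, list[int]]]:
    chunks, current = [], [run[0]]
    for pos in run[1:]:
        # region span counts the full CpG dinucleotide of the last unit
        if (pos + 2) - current[0] > max_region:
            chunks.append((chrom, current))
            current = [pos]
        else:
            current.append(pos)
    chunks.append((chrom, current))
    return chunks


def _region_counts(track: CpGCoverageTrack, chrom: str,
                   positions: list[int]) -> tuple[int, int]:
    m_tot = u_tot = 0
    for pos in positions:
        entry = track._counts.get(chrom, {}).get(pos)
        if entry is not None:
            m_tot += entry[0]
            u_tot += entry[1]
    return m_tot, u_tot


def _passes(value: float, threshold: float, strict: bool) -> bool:
    return value > threshold if strict else value >= threshold


def call_dmrs(group_a: list[CpGCoverageTrack], group_b: list[CpGCoverageTrack],
              p_max: float = 1e-7, delta_min: float = 0.5,
              max_region: int = 300, min_depth: int = 10,
              gap_max: int = 100, strict: bool = False) -> list[DMRRecord]:
    """Differentially methylated regions between two sample groups.

    A region is testable only if its summed depth reaches ``min_depth`` in
    every sample of both groups. Group betas are means of per-sample region
    betas; the p value is a two-sided Fisher exact test on the pooled
    (methylated, unmethylated) counts of group A vs group B.
    """
    if not group_a or not group_b:
        raise ValueError("both groups must contain at least one track")
    if not (0 < p_max <= 1) or not (0 <= delta_min <= 1):
        raise ValueError("thresholds out of range")
    all_tracks = list(group_a) + list(group_b)
    records: list[DMRRecord] = []
    for chrom, positions in _candidate_regions(all_tracks, max_region, gap_max):
        per_sample = [_region_counts(t, chrom, positions) for t in all_tracks]
        if any(m + u < min_depth for m, u in per_sample):
            continue
        counts_a = per_sample[:len(group_a)]
        counts_b = per_sample[len(group_a):]
        beta_a = float(np.mean([m / (m + u) for m, u in counts_a]))
        beta_b = float(np.mean([m / (m + u) for m, u in counts_b]))
        delta = beta_a - beta_b
        pooled_a = (sum(m for m, _ in counts_a), sum(u for _, u in counts_a))
        pooled_b = (sum(m for m, _ in counts_b), sum(u for _, u in counts_b))
        p = fisher_exact_p([pooled_a, pooled_b])
        if p <= p_max and _passes(abs(delta), delta_min, strict):
            interval = GenomicInterval(chrom, positions[0],
                                       positions[-1] + 2)
            records.append(DMRRecord(interval, beta_a, beta_b, delta, p, None,
                                     "hyper" if delta > 0 else "hypo"))
    return records


def write_dmrs(records: list[DMRRecord], path: str | Path) -> None:
    """BED6+ output: delta_beta, p, q and direction as extra columns."""
    with open(path, "w") as fh:
        for i, r in enumerate(records):
            q = "NA" if r.q_value is None else f"{r.q_value:.6g}"
            fh.write(f"{r.interval.chrom}\t{r.interval.start}\t{r.interval.end}\t"
                     f"dmr_{i}\t0\t.\t{r.delta_beta:.6g}\t{r.p_value:.6g}\t"
                     f"{q}\t{r.direction}\n")


# ---------------------------------------------------------------------------
# Cell-specific promoter methylation
# ---------------------------------------------------------------------------

def differential_promoters(tracks: dict[str, CpGCoverageTrack],
                           tss: ElementAnnotation, flank: int = 4000,
                           q_max: float = 0.01, delta_min: float = 0.5,
                           min_depth: int = 10, strict: bool = False,
                           ) -> tuple[dict[str, dict[str, list[GenomicInterval]]], dict]:
    """One-vs-rest promoter comparisons per cell over TSS +/- flank regions.

    Fisher exact p on pooled counts (cell vs all other cells), BH-adjusted
    across every tested region x cell pair; emits each cell's hyper- and
    hypomethylated region sets at q <= q_max and |dbeta| >= delta_min.
    Regions failing the depth floor on either side are skipped and counted.
    """
    if len(tracks) < 2:
        raise ValueError("need at least two cell tracks")
    cells = list(tracks)
    tests: list[tuple[str, GenomicInterval, float, float]] = []  # cell, region, delta, p
    skipped = 0
    for iv in tss:
        region = GenomicInterval(iv.chrom, max(0, iv.start - flank),
                                 iv.start + flank, iv.strand, iv.name)
        counts = {}
        for cell in cells:
            track = tracks[cell]
            pos_in = [p for p in track.positions(region.chrom)
                      if region.start <= p < region.end]
            counts[cell] = _region_counts(track, region.chrom, pos_in)
        for cell in cells:
            m_c, u_c = counts[cell]
            m_r = sum(counts[c][0] for c in cells if c != cell)
            u_r = sum(counts[c][1] for c in cells if c != cell)
            if m_c + u_c < min_depth or m_r + u_r < min_depth:
                skipped += 1
                continue
            delta = m_c / (m_c + u_c) - m_r / (m_r + u_r)
            p = fisher_exact_p([(m_c, u_c), (m_r, u_r)])
            tests.append((cell, region, delta, p))

    result: dict[str, dict[str, list[GenomicInterval]]] = {
        cell: {"hyper": [], "hypo": []} for cell in cells}
    if tests:
        pvals = [t[3] for t in tests]
        qvals = multipletests(pvals, method="fdr_bh")[1]
        for (cell, region, delta, _p), q in zip(tests, qvals):
            if q <= q_max and _passes(abs(delta), delta_min, strict):
                result[cell]["hyper" if delta > 0 else "hypo"].append(region)
    summary = {"n_tested": len(tests), "n_skipped": skipped}
    return result, summary


# ---------------------------------------------------------------------------
# Methylation - ChIP peak association
# ---------------------------------------------------------------------------

#: regions below this beta count as hypomethylated
HYPOMETHYLATED_BETA = 0.10


@dataclass
class PeakAssociation:
    """Hypomethylation specificity vs ChIP-peak containment for two cells.

    For each peak set k there is one 2x2 table whose rows are the
    cell-1-specific and cell-2-specific hypomethylated regions and whose
    columns split regions by containment (>= 1 bp overlap) of a peak of
    cell k, with the two-sided Fisher exact p. ``own_peak_percentages``
    holds the diagonal summaries: the share of each cell's specific regions
    containing that same cell's peak.
    """

    tables: dict[str, np.ndarray]
    p_values: dict[str, float]
    row_percentages: dict[str, dict[str, float]]   # peak cell -> region cell -> %
    own_peak_percentages: dict[str, float]


def peak_association(hypo_regions: dict[str, list[GenomicInterval]],
                     peaks: dict[str, ElementAnnotation | list[GenomicInterval]],
                     ) -> PeakAssociation:
    """Test whether cell-specific hypomethylation co-locates with peaks.

    A positive association shows as each cell's specific regions containing
    that cell's peaks far more often than the other cell's regions do. The
    p value for a peak set is NaN if either region set is empty.
    """
    if len(hypo_regions) != 2 or len(peaks) != 2:
        raise ValueError("exactly two cells required")
    cells = list(hypo_regions)
    tables: dict[str, np.ndarray] = {}
    p_values: dict[str, float] = {}
    row_pct: dict[str, dict[str, float]] = {}
    for peak_cell in cells:
        peak_list = list(peaks[peak_cell])
        table = np.zeros((2, 2), dtype=int)
        for i, region_cell in enumerate(cells):
            for region in hypo_regions[region_cell]:
                hit = any(region.overlaps(pk) for pk in peak_list)
                table[i, 0 if hit else 1] += 1
        tables[peak_cell] = table
        row_pct[peak_cell] = {
            region_cell: (100.0 * table[i, 0] / table[i].sum()
                          if table[i].sum() else float("nan"))
            for i, region_cell in enumerate(cells)}
        p_values[peak_cell] = (fisher_exact_p(table)
                               if table[0].sum() and table[1].sum()
                               else float("nan"))
    own = {cell: row_pct[cell][cell] for cell in cells}
    return PeakAssociation(tables, p_values, row_pct, own)
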