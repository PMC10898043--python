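"""Restriction-site scanning and depletion of AT-rich molecules after conversion.

The trick behind RRMP: after C->T conversion the genome's AT-rich background
becomes saturated with AT-only recognition sites (MseI TTAA; MluCI AATT;
SspI AATATT; PsiI TTATAA), while GC-rich CpG islands — whose G content is
untouched by conversion — rarely form one. Digesting the converted library
therefore removes background molecules and leaves island molecules intact,
lengths and sequences preserved.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
import pandas as pd

from .genome import MethylationProfile, ReferenceGenome, reverse_complement

from .library import WATSON, CRICK, ConvertedMolecule, Fragment


@dataclass(frozen=True)
class EnzymeSpec:
    name: str
    recognition: str

    def __post_init__(self) -> None:
        if len(self.recognition) < 4:
            raise ValueError("recognition site must be >= 4 bp")
        if set(self.recognition) - set("ACGT"):
            raise ValueError("recognition site must be over {A,C,G,T}")

    @property
    def palindromic(self) -> bool:
        return self.recognition == reverse_complement(self.recognition)


MSEI = EnzymeSpec("MseI", "TTAA")
MLUCI = EnzymeSpec("MluCI", "AATT")
SSPI = EnzymeSpec("SspI", "AATATT")
PSII = EnzymeSpec("PsiI", "TTATAA")


@dataclass
class EnzymePanel:
    enzymes: list[EnzymeSpec]
    name: str = "custom"

    def __post_init__(self) -> None:
        if not self.enzymes:
            raise ValueError("panel must contain at least one enzyme")

    @classmethod
    def one_cut(cls) -> "EnzymePanel":
        return cls([MSEI], "one_cut")

    @classmethod
    def four_cut(cls) -> "EnzymePanel":
        return cls([MSEI, MLUCI, SSPI, PSII], "four_cut")

    @classmethod
    def from_name(cls, name: str) -> "EnzymePanel":
        if name == "one_cut":
            return cls.one_cut()
        if name == "four_cut":
            return cls.four_cut()
        raise ValueError(f"unknown panel {name!r}")


@dataclass
class SiteMap:
    """Per-chromosome, per-strand recognition-site coordinates (Watson frame).

    For a Crick-strand site the reported coordinate is the leftmost Watson
    base under the site.
    """

    sites: dict[str, dict[str, list[tuple[int, str]]]] = field(default_factory=dict)
    chrom_lengths: dict[str, int] = field(default_factory=dict)

    def positions(self, chrom: str, strand: str) -> np.ndarray:
        entries = self.sites.get(chrom, {}).get(strand, [])
        return np.array(sorted(p for p, _ in entries), dtype=int)

    def to_bed(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for chrom in sorted(self.sites):
                rows = []
                for strand, bed_strand in ((WATSON, "+"), (CRICK, "-")):
                    for pos, enzyme in self.sites[chrom].get(strand, []):
                        rows.append((pos, enzyme, bed_strand))
                for pos, enzyme, bed_strand in sorted(rows):
                    fh.write(f"{chrom}\t{pos}\t{pos + 4}\t{enzyme}\t0\t{bed_strand}\n")


# ---------------------------------------------------------------------------
# Scanning
# ---------------------------------------------------------------------------

def scan_sites(sequence: str, panel: EnzymePanel) -> list[tuple[int, str]]:
    """All exact recognition-site occurrences (overlaps included, N never matches).

    Built-in enzymes are palindromic so scanning the given strand suffices;
    for a non-palindromic custom enzyme the reverse-complement motif is also
    scanned, positions always reported on the given sequence.
    """
    hits: list[tuple[int, str]] = []
    for enz in panel.enzymes:
        motifs = [enz.recognition]
        if not enz.palindromic:
            motifs.append(reverse_complement(enz.recognition))
        for motif in motifs:
            start = sequence.find(motif)
            while start != -1:
                hits.append((start, enz.name))
                start = sequence.find(motif, start + 1)
    return sorted(hits)


def has_site(sequence: str, panel: EnzymePanel) -> bool:
    """Fast predicate: does the sequence contain any complete recognition site?"""
    for enz in panel.enzymes:
        if enz.recognition in sequence:
            return True
        if not enz.palindromic and reverse_complement(enz.recognition) in sequence:
            return True
    return False


def _convert_strand(chrom_seq: str, strand: str, profile: MethylationProfile,
                    chrom: str, methylation_rule: str) -> str:
    """Deterministic full-strand conversion under a consensus methylation rule."""
    if methylation_rule not in ("all_unmethylated", "threshold_0.5"):
        raise ValueError(f"unknown methylation rule {methylation_rule!r}")
    n = len(chrom_seq)
    seq = list(chrom_seq if strand == WATSON else reverse_complement(chrom_seq))
    for i, base in enumerate(seq):
        if base != "C":
            continue
        if strand == WATSON:
            p, unit_ok = i, i + 1 < n and chrom_seq[i + 1] == "G"
            unit = i
        else:
            c = n - 1 - i
            unit_ok = c - 1 >= 0 and chrom_seq[c - 1] == "C"
            unit = c - 1
        protected = False
        if unit_ok and methylation_rule == "threshold_0.5":
            beta = profile.get(chrom, unit, 0.0)
            protected = beta is not None and beta >= 0.5
        if not protected:
            seq[i] = "T"
    return "".join(seq)


def converted_site_map(genome: ReferenceGenome, profile: MethylationProfile,
                       panel: EnzymePanel,
                       methylation_rule: str = "threshold_0.5") -> SiteMap:
    """Deterministic per-strand site map of the fully converted genome.

    Each strand is converted independently (C->T except CpG cytosines deemed
    protected under the rule) and scanned; Crick hits are mapped back into
    the Watson coordinate frame.
    """
    site_map = SiteMap()
    for chrom, chrom_seq in genome.sequences.items():
        n = len(chrom_seq)
        site_map.chrom_lengths[chrom] = n
        per_strand: dict[str, list[tuple[int, str]]] = {}
        enzyme_len = {e.name: len(e.recognition) for e in panel.enzymes}
        for strand in (WATSON, CRICK):
            converted = _convert_strand(chrom_seq, strand, profile, chrom,
                                        methylation_rule)
            hits = scan_sites(converted, panel)
            if strand == CRICK:
                hits = sorted((n - pos - enzyme_len[name], name)
                              for pos, name in hits)
            per_strand[strand] = hits
        site_map.sites[chrom] = per_strand
    return site_map


# ---------------------------------------------------------------------------
# Digestion
# ---------------------------------------------------------------------------

def digest_library(molecules: list[ConvertedMolecule],
                   panel: EnzymePanel) -> tuple[list[ConvertedMolecule],
                                                list[ConvertedMolecule]]:
    """Partition molecules into (retained, digested).

    Digestion is modeled as complete: a molecule is cut iff a full
    recognition site lies within its insert. Retained molecules are
    untouched — length and ends preserved.
    """
    retained, digested = [], []
    for m in molecules:
        (digested if has_site(m.sequence, panel) else retained).append(m)
    return retained, digested


def cg_fraction(seq: str) -> float:
    return (seq.count("C") + seq.count("G")) / len(seq) if seq else float("nan")


def deplete_reads(reads: Iterable[tuple[str, str]],
                  panel: EnzymePanel) -> tuple[list[tuple[str, str]], dict]:
    """In silico depletion of already-converted reads (no strand inference).

    Returns the retained (name, sequence) pairs and a summary with input and
    retained counts plus mean CG fraction before/after.
    """
    reads = list(reads)
    retained = [(name, seq) for name, seq in reads if not has_site(seq, panel)]
    summary = {
        "input_count": len(reads),
        "retained_count": len(retained),
        "retained_fraction": len(retained) / len(reads) if reads else float("nan"),
        "mean_cg_input": (float(np.mean([cg_fraction(s) for _, s in reads]))
                          if reads else float("nan")),
        "mean_cg_retained": (float(np.mean([cg_fraction(s) for _, s in retained]))
                             if retained else float("nan")),
    }
    return retained, summary


def _iter_fastq(path: str | Path) -> Iterator[tuple[str, str]]:
    with open(path) as fh:
        record_index = 0
        while True:
            header = fh.readline()
            if not header:
                return
            seq = fh.readline().rstrip("\n")
            plus = fh.readline()
            qual = fh.readline().rstrip("\n")
            if (not header.startswith("@") or not plus.startswith("+")
                    or len(qual) != len(seq) or not seq):
                raise ValueError(f"malformed FASTQ record at index {record_index}")
            yield header[1:].split()[0], seq.upper()
            record_index += 1


def deplete_fastq(in_path: str | Path, out_path: str | Path,
                  panel: EnzymePanel) -> dict:
    """Streaming FASTQ-to-FASTQ depletion; returns the summary dict."""
    retained, summary = deplete_reads(_iter_fastq(in_path), panel)
    with open(out_path, "w") as fh:
        for name, seq in retained:
            fh.write(f"@{name}\n{seq}\n+\n{'I' * len(seq)}\n")
    return summary


# ---------------------------------------------------------------------------
# Coverage vs inter-site distance
# ---------------------------------------------------------------------------

def coverage_array(fragments: Iterable[Fragment], chrom: str, length: int) -> np.ndarray:
    """Per-base depth from fragment inserts, via a difference array."""
    diff = np.zeros(length + 1, dtype=np.int64)
    for f in fragments:
        if f.interval.chrom == chrom:
            diff[f.interval.start] += 1
            diff[f.interval.end] -= 1
    return np.cumsum(diff[:-1])


def intersite_coverage_profile(site_map: SiteMap, retained: list[Fragment],
                               chrom: str, strand: str,
                               max_d: int = 2000, bin_size: int = 50) -> pd.DataFrame:
    """Mean retained depth as a function of inter-site distance d.

    Every position between two consecutive same-strand sites is annotated
    with d (the distance between those sites); positions before the first or
    after the last site are excluded. Depth is computed from retained
    fragments whose origin strand matches. Returns one row per d bin.
    """
    positions = site_map.positions(chrom, strand)
    if len(positions) < 2:
        return pd.DataFrame(columns=["d_bin", "mean_depth", "n_positions"])
    length = site_map.chrom_lengths[chrom]
    frags = [f for f in retained if f.origin_strand == strand]
    depth = coverage_array(frags, chrom, length)

    d_of_pos = np.zeros(length, dtype=int)
    mask = np.zeros(length, dtype=bool)
    for left, right in zip(positions[:-1], positions[1:]):
        d = int(right - left)
        if d > max_d:
            continue
        d_of_pos[left:right] = d
        mask[left:right] = True

    d_vals = d_of_pos[mask]
    depths = depth[mask]
    bins = (d_vals // bin_size) * bin_size
    frame = pd.DataFrame({"d_bin": bins, "depth": depths})
    out = (frame.groupby("d_bin")["depth"]
           .agg(mean_depth="mean", n_positions="size")
           .reset_index())
    return out
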