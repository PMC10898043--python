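"""Reference genomes, ground-truth methylation, and the synthetic-genome generator.

The synthetic genome emulates the architecture that reduced-representation
enrichment exploits: short GC-rich CpG islands embedded in long AT-rich
background spacers. CpG identity is the Watson-strand C coordinate; evidence
from the Crick strand at position p+1 is folded onto the Watson coordinate,
so a CpG "unit" has a single beta value shared by both strands.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .intervals import ElementAnnotation, GenomicInterval

_VALID = re.compile(r"^[ACGTN]+$")

COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]


@dataclass
class ReferenceGenome:
    """Chromosome name -> uppercase sequence over {A, C, G, T, N}."""

    sequences: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, seq in self.sequences.items():
            seq = seq.upper()
            if len(seq) < 1:
                raise ValueError(f"chromosome {name!r} is empty")
            if not _VALID.match(seq):
                bad = sorted(set(seq) - set("ACGTN"))
                raise ValueError(f"chromosome {name!r} contains invalid characters {bad}")
            self.sequences[name] = seq

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.sequences

    def chrom_names(self) -> list[str]:
        return list(self.sequences)

    def length(self, chrom: str) -> int:
        return len(self.sequences[chrom])

    def fetch(self, chrom: str, start: int, end: int) -> str:
        seq = self.sequences[chrom]
        if not (0 <= start < end <= len(seq)):
            raise ValueError(f"interval {chrom}:{start}-{end} out of bounds")
        return seq[start:end]

    def cpg_positions(self, chrom: str) -> np.ndarray:
        """0-based Watson coordinates of the C of every CpG dinucleotide."""
        seq = np.frombuffer(self.sequences[chrom].encode(), dtype="S1")
        is_c = seq[:-1] == b"C"
        is_g = seq[1:] == b"G"
        return np.flatnonzero(is_c & is_g)

    def gc_fraction(self, chrom: str, start: int | None = None,
                    end: int | None = None) -> float:
        seq = self.sequences[chrom][start:end]
        return (seq.count("G") + seq.count("C")) / len(seq)


def read_fasta(path: str | Path) -> ReferenceGenome:
    """Load a (possibly line-wrapped, multi-record) FASTA; sequence upper-cased."""
    sequences: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in sequences:
            raise ValueError(f"duplicate chromosome name {rec.id!r}")
        sequences[rec.id] = str(rec.seq).upper()
    if not sequences:
        raise ValueError(f"no FASTA records in {path}")
    return ReferenceGenome(sequences)


def write_fasta(genome: ReferenceGenome, path: str | Path, width: int = 70) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="")
               for name, seq in genome.sequences.items()]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


@dataclass
class MethylationProfile:
    """Ground-truth beta per CpG unit, keyed by (chrom, Watson C coordinate)."""

    betas: dict[str, dict[int, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for chrom, per_pos in self.betas.items():
            for pos, beta in per_pos.items():
                if not (0.0 <= beta <= 1.0):
                    raise ValueError(f"beta {beta} at {chrom}:{pos} outside [0, 1]")

    def beta(self, chrom: str, pos: int) -> float:
        return self.betas[chrom][pos]

    def get(self, chrom: str, pos: int, default: float | None = None) -> float | None:
        return self.betas.get(chrom, {}).get(pos, default)

    def positions(self, chrom: str) -> list[int]:
        return sorted(self.betas.get(chrom, {}))

    def n_cpgs(self) -> int:
        return sum(len(v) for v in self.betas.values())

    def validate_against(self, genome: ReferenceGenome) -> None:
        """Every keyed position must be the C of a Watson CpG dinucleotide."""
        for chrom, per_pos in self.betas.items():
            seq = genome.sequences[chrom]
            for pos in per_pos:
                if not (pos + 1 < len(seq) and seq[pos] == "C" and seq[pos + 1] == "G"):
                    raise ValueError(f"{chrom}:{pos} is not a CpG cytosine")


def write_beta_tsv(profile: MethylationProfile, path: str | Path) -> None:
    """Ground-truth betas as TSV: chrom, 0-based Watson C position, beta."""
    with open(path, "w") as fh:
        fh.write("chrom\tpos\tbeta\n")
        for chrom in sorted(profile.betas):
            for pos in sorted(profile.betas[chrom]):
                fh.write(f"{chrom}\t{pos}\t{profile.betas[chrom][pos]:.6g}\n")


def read_beta_tsv(path: str | Path) -> MethylationProfile:
    betas: dict[str, dict[int, float]] = {}
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("chrom\tpos\tbeta"):
            raise ValueError(f"{path}: expected header 'chrom\\tpos\\tbeta'")
        for line in fh:
            chrom, pos, beta = line.rstrip("\n").split("\t")
            betas.setdefault(chrom, {})[int(pos)] = float(beta)
    return MethylationProfile(betas)


# ---------------------------------------------------------------------------
# Element geometry from the promoter / shore / shelf definitions
# ---------------------------------------------------------------------------

def promoters_from_tss(tss: ElementAnnotation, chrom_lengths: dict[str, int],
                       upstream: int = 1000, downstream: int = 500) -> ElementAnnotation:
    """Promoter = 1 kb upstream and 500 bp downstream of each TSS, by strand.

    A + strand TSS at p yields [p-upstream, p+downstream); a - strand TSS
    mirrors it. Intervals are clipped to chromosome bounds.
    """
    promoters = []
    for iv in tss:
        if iv.strand not in ("+", "-"):
            raise ValueError(f"TSS at {iv.chrom}:{iv.start} lacks a strand")
        p = iv.start
        if iv.strand == "+":
            start, end = p - upstream, p + downstream
        else:
            start, end = p - downstream, p + upstream
        clen = chrom_lengths[iv.chrom]
        start, end = max(0, start), min(clen, end)
        if start < end:
            promoters.append(GenomicInterval(iv.chrom, start, end, iv.strand, iv.name))
    return ElementAnnotation("promoter", promoters)


def derive_shores_shelves(islands: ElementAnnotation,
                          chrom_lengths: dict[str, int],
                          shore_bp: int = 2000,
                          shelf_bp: int = 2000) -> tuple[ElementAnnotation, ElementAnnotation]:
    """CpG shores (0-2 kb island flanks) and shelves (2-4 kb flanks).

    Flanks of adjacent islands are truncated at the midpoint of the
    inter-island gap so no base is assigned twice.
    """
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for iv in islands:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    shores, shelves = [], []
    for chrom, ivs in by_chrom.items():
        ivs = sorted(ivs)
        clen = chrom_lengths[chrom]
        for i, iv in enumerate(ivs):
            left_limit = 0 if i == 0 else (ivs[i - 1].end + iv.start) // 2
            right_limit = clen if i == len(ivs) - 1 else (iv.end + ivs[i + 1].start) // 2
            # left flank
            sh_start = max(left_limit, iv.start - shore_bp)
            if sh_start < iv.start:
                shores.append(GenomicInterval(chrom, sh_start, iv.start))
            lf_start = max(left_limit, iv.start - shore_bp - shelf_bp)
            if lf_start < sh_start:
                shelves.append(GenomicInterval(chrom, lf_start, sh_start))
            # right flank
            sh_end = min(right_limit, iv.end + shore_bp)
            if iv.end < sh_end:
                shores.append(GenomicInterval(chrom, iv.end, sh_end))
            rf_end = min(right_limit, iv.end + shore_bp + shelf_bp)
            if sh_end < rf_end:
                shelves.append(GenomicInterval(chrom, sh_end, rf_end))
    return (ElementAnnotation("cpg_shore", shores),
            ElementAnnotation("cpg_shelf", shelves))


# ---------------------------------------------------------------------------
# Synthetic genome generator
# ---------------------------------------------------------------------------

def _random_segment(rng: np.random.Generator, length: int, gc: float,
                    cpg_rate: float = 0.0) -> str:
    """Random sequence with the given GC fraction, optionally CpG-seeded.

    ``cpg_rate`` is the per-base probability of forcing a CG dinucleotide,
    giving islands their elevated CpG density without an island-detection
    step.
    """
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    bases = rng.choice(np.array(["A", "C", "G", "T"]), size=length, p=probs)
    if cpg_rate > 0 and length >= 2:
        n_seed = rng.binomial(length, cpg_rate)
        if n_seed:
            starts = rng.choice(length - 1, size=min(n_seed, length - 1), replace=False)
            bases[starts] = "C"
            bases[starts + 1] = "G"
    return "".join(bases)


def simulate_genome(n_islands: int = 30,
                    island_len: tuple[int, int] = (600, 1400),
                    spacer_len: tuple[int, int] = (3000, 6000),
                    island_gc: float = 0.65,
                    background_gc: float = 0.30,
                    island_cpg_rate: float = 0.06,
                    island_beta: tuple[float, float] = (0.02, 0.15),
                    background_beta: tuple[float, float] = (0.75, 0.98),
                    chrom: str = "chrS",
                    seed: int = 0,
                    ) -> tuple[ReferenceGenome, dict[str, ElementAnnotation], MethylationProfile]:
    """Single-chromosome genome of alternating AT-rich spacers and CpG islands.

    Ground-truth betas are low inside islands and high outside, the canonical
    somatic pattern. One TSS is placed at each island start (+ strand), and
    promoters, shores and shelves are derived from the standard definitions.
    Deterministic for a fixed seed.
    """
    if not (0 < background_gc < island_gc <= 1):
        raise ValueError("need 0 < background_gc < island_gc <= 1")
    if n_islands < 1:
        raise ValueError("n_islands must be >= 1")
    for lo, hi in (island_len, spacer_len):
        if not (0 < lo <= hi):
            raise ValueError("length ranges must be positive and non-empty")

    rng = np.random.default_rng(seed)
    parts: list[str] = []
    island_ivs: list[GenomicInterval] = []
    pos = 0
    for i in range(n_islands):
        sp = int(rng.integers(spacer_len[0], spacer_len[1] + 1))
        parts.append(_random_segment(rng, sp, background_gc))
        pos += sp
        il = int(rng.integers(island_len[0], island_len[1] + 1))
        parts.append(_random_segment(rng, il, island_gc, cpg_rate=island_cpg_rate))
        island_ivs.append(GenomicInterval(chrom, pos, pos + il, name=f"island_{i}"))
        pos += il
    sp = int(rng.integers(spacer_len[0], spacer_len[1] + 1))
    parts.append(_random_segment(rng, sp, background_gc))
    genome = ReferenceGenome({chrom: "".join(parts)})
    clen = {chrom: genome.length(chrom)}

    islands = ElementAnnotation("cpg_island", island_ivs)
    tss = ElementAnnotation("tss", [
        GenomicInterval(chrom, iv.start, iv.start + 1, "+", f"tss_{i}")
        for i, iv in enumerate(island_ivs)])
    promoters = promoters_from_tss(tss, clen)
    shores, shelves = derive_shores_shelves(islands, clen)

    cpg_pos = genome.cpg_positions(chrom)
    in_island = np.zeros(len(cpg_pos), dtype=bool)
    for iv in island_ivs:
        in_island |= (cpg_pos >= iv.start) & (cpg_pos < iv.end)
    betas = np.where(
        in_island,
        rng.uniform(island_beta[0], island_beta[1], size=len(cpg_pos)),
        rng.uniform(background_beta[0], background_beta[1], size=len(cpg_pos)),
    )
    profile = MethylationProfile({chrom: dict(zip(cpg_pos.tolist(), betas.tolist()))})

    annotations = {"cpg_island": islands, "tss": tss, "promoter": promoters,
                   "cpg_shore": shores, "cpg_shelf": shelves}
    return genome, annotations, profile
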