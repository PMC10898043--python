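"""Library simulation: fragmentation, per-molecule methylation, C->T conversion.

A library molecule is a single converted strand of one original duplex
fragment. Conversion turns every unmethylated cytosine into thymine while
methylated CpG cytosines are protected; cytosines outside CpG context (CH)
are always unmethylated here, so any CH cytosine surviving in the output is
a recorded conversion failure — the basis of the incomplete-conversion read
filter (reads with more than 3 unconverted CHs are removed).
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .genome import MethylationProfile, ReferenceGenome, reverse_complement
from .intervals import GenomicInterval

WATSON = "watson"
CRICK = "crick"


@dataclass(frozen=True)
class Fragment:
    """A library insert: genomic interval plus the strand the molecule derives from."""

    interval: GenomicInterval
    origin_strand: str
    molecule_id: str

    def __post_init__(self) -> None:
        if self.origin_strand not in (WATSON, CRICK):
            raise ValueError(f"invalid origin strand {self.origin_strand!r}")

    def __len__(self) -> int:
        return len(self.interval)


@dataclass
class ConvertedMolecule:
    """Post-conversion sequence of a fragment, 5'->3' in origin-strand orientation.

    ``cpg_states`` maps the Watson C coordinate of each CpG unit whose
    origin-strand cytosine lies inside the insert to the state drawn for this
    molecule. ``unconverted_ch_count`` counts CH-context cytosines that
    failed to convert.
    """

    fragment: Fragment
    sequence: str
    cpg_states: dict[int, str] = field(default_factory=dict)
    unconverted_ch_count: int = 0

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.fragment):
            raise ValueError("sequence length does not match fragment length")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class ConversionParams:
    """Conversion chemistry efficiencies; both default to ideal (1.0)."""

    conversion_rate: float = 1.0
    protection_rate: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("conversion_rate", "protection_rate"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {v}")


# ---------------------------------------------------------------------------
# Fragmentation
# ---------------------------------------------------------------------------

def fragment_genome(genome: ReferenceGenome, mode: str = "cfdna",
                    mean_len: int | None = None, n_fragments: int = 1000,
                    seed: int = 0, len_sd: float | None = None) -> list[Fragment]:
    """Draw random fragments from the genome.

    cfdna mode uses a tight unimodal length distribution with its mode at
    ``mean_len`` (default 170 bp, the nucleosomal cfDNA peak); gdna mode
    emulates mechanical shearing (default mean 250 bp, sd 80). Start
    positions are uniform; origin strand is Bernoulli(0.5).
    """
    if n_fragments < 1:
        raise ValueError("n_fragments must be >= 1")
    if mode not in ("cfdna", "gdna"):
        raise ValueError(f"unknown fragmentation mode {mode!r}")
    if mean_len is None:
        mean_len = 170 if mode == "cfdna" else 250
    if mean_len < 20:
        raise ValueError("mean_len must be >= 20")
    if len_sd is None:
        len_sd = 15.0 if mode == "cfdna" else 80.0

    rng = np.random.default_rng(seed)
    chroms = genome.chrom_names()
    lengths = np.array([genome.length(c) for c in chroms], dtype=float)
    if lengths.max() < 20:
        raise ValueError("no chromosome long enough to fragment")
    weights = lengths / lengths.sum()

    fragments: list[Fragment] = []
    for i in range(n_fragments):
        for _attempt in range(1000):
            chrom = chroms[rng.choice(len(chroms), p=weights)]
            clen = genome.length(chrom)
            flen = int(np.clip(round(rng.normal(mean_len, len_sd)), 20, None))
            if flen <= clen:
                break
        else:
            raise ValueError("could not draw a fragment fitting any chromosome")
        start = int(rng.integers(0, clen - flen + 1))
        strand = WATSON if rng.random() < 0.5 else CRICK
        fragments.append(Fragment(
            GenomicInterval(chrom, start, start + flen),
            strand, f"mol_{i:07d}"))
    return fragments


# ---------------------------------------------------------------------------
# Conversion
# ---------------------------------------------------------------------------

def _molecule_rng(params: ConversionParams, molecule_id: str) -> np.random.Generator:
    # crc32 keeps per-molecule seeding deterministic across processes
    return np.random.default_rng([params.seed, zlib.crc32(molecule_id.encode())])


def convert_molecule(fragment: Fragment, genome: ReferenceGenome,
                     profile: MethylationProfile, params: ConversionParams,
                     rng: np.random.Generator | None = None) -> ConvertedMolecule:
    """Convert one fragment into a library molecule.

    The origin-strand sequence is taken (for a Crick-origin molecule the
    reverse complement is taken first), then each of its cytosines is
    converted to T unless it is the cytosine of a CpG unit whose
    per-molecule state — one Bernoulli(beta) draw per unit — is methylated
    and protected. CpG context is decided from the reference, so units
    straddling the insert edge keep their genomic context.
    """
    if rng is None:
        rng = _molecule_rng(params, fragment.molecule_id)
    iv = fragment.interval
    chrom_seq = genome.sequences[iv.chrom]
    insert = chrom_seq[iv.start:iv.end]
    if fragment.origin_strand == WATSON:
        seq = list(insert)
    else:
        seq = list(reverse_complement(insert))

    cpg_states: dict[int, str] = {}
    ch_failures = 0
    n = len(seq)
    for i in range(n):
        if seq[i] != "C":
            continue
        if fragment.origin_strand == WATSON:
            p = iv.start + i  # Watson C coordinate
            is_cpg = p + 1 < len(chrom_seq) and chrom_seq[p + 1] == "G"
            unit = p
        else:
            c = iv.end - 1 - i  # Watson coordinate opposite this Crick base
            is_cpg = c - 1 >= 0 and chrom_seq[c - 1] == "C"
            unit = c - 1
        if is_cpg:
            beta = profile.get(iv.chrom, unit, 0.0)
            methylated = rng.random() < beta
            cpg_states[unit] = "methylated" if methylated else "unmethylated"
            protected = methylated and rng.random() < params.protection_rate
            if not protected and rng.random() < params.conversion_rate:
                seq[i] = "T"
        else:
            if rng.random() < params.conversion_rate:
                seq[i] = "T"
            else:
                ch_failures += 1
    return ConvertedMolecule(fragment, "".join(seq), cpg_states, ch_failures)


def convert_library(fragments: list[Fragment], genome: ReferenceGenome,
                    profile: MethylationProfile,
                    params: ConversionParams | None = None) -> list[ConvertedMolecule]:
    """Convert a whole fragment list with one RNG stream seeded from params.seed."""
    if params is None:
        params = ConversionParams()
    rng = np.random.default_rng(params.seed)
    return [convert_molecule(f, genome, profile, params, rng=rng) for f in fragments]


def filter_non_conversion(molecules: list[ConvertedMolecule],
                          max_ch: int = 3) -> tuple[list[ConvertedMolecule],
                                                    list[ConvertedMolecule]]:
    """Remove incompletely converted molecules (more than ``max_ch`` CHs retained)."""
    retained = [m for m in molecules if m.unconverted_ch_count <= max_ch]
    removed = [m for m in molecules if m.unconverted_ch_count > max_ch]
    return retained, removed


# ---------------------------------------------------------------------------
# FASTQ export / import
# ---------------------------------------------------------------------------

def write_fastq(molecules: list[ConvertedMolecule], path) -> None:
    """Export converted molecules as FASTQ (fixed quality 'I')."""
    records = []
    for m in molecules:
        rec = SeqRecord(Seq(m.sequence), id=m.fragment.molecule_id, description="")
        rec.letter_annotations["phred_quality"] = [40] * len(m.sequence)
        records.append(rec)
    SeqIO.write(records, str(path), "fastq")


def read_fastq(path) -> list[tuple[str, str]]:
    """Read a FASTQ file as (read name, sequence) pairs."""
    return [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fastq")]
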