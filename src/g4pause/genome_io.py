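"""Genomic primitives on a single circular contig.

The human mitochondrial genome is a 16.6-kb circle transcribed as two
near-genome-length polycistronic RNAs, one from each strand.  Everything in
this package therefore works in a single, shared coordinate convention:
0-based half-open intervals on one circular contig, with wrap-around
("origin-crossing") intervals encoded as ``start > end``.  "Upstream" and
"downstream" are always meant in the transcription direction of the strand
under consideration, i.e. 5' and 3' on the nascent RNA.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO

__all__ = [
    "CircularGenome",
    "GenomicInterval",
    "GeneAnnotation",
    "VariantSet",
    "FormatError",
    "read_fasta_circular",
    "write_fasta",
    "reverse_complement",
    "base_composition",
    "read_bed",
    "write_bed",
    "read_variants_bed",
    "read_variants_tsv",
    "write_variants_tsv",
]

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_ALPHABET = frozenset("ACGTN")

BIOTYPES = ("mRNA", "tRNA", "rRNA", "other")


class FormatError(ValueError):
    """Malformed input file or sequence."""


def reverse_complement(sequence: str) -> str:
    """Reverse complement over the {A,C,G,T,N} alphabet.

    Involution: ``reverse_complement(reverse_complement(s)) == s``.
    """
    seq = sequence.upper()
    if not set(seq) <= _ALPHABET:
        bad = sorted(set(seq) - _ALPHABET)
        raise FormatError(f"sequence contains non-ACGTN characters: {bad}")
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class GenomicInterval:
    """0-based half-open interval on a circular contig.

    ``start > end`` encodes an interval that crosses the origin; its width is
    computed modulo the genome length.  ``strand`` is '+' or '-'.
    """

    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    @property
    def wraps(self) -> bool:
        return self.start >= self.end

    def width(self, genome_length: int) -> int:
        w = (self.end - self.start) % genome_length
        return genome_length if w == 0 else w

    def contains(self, position: int, genome_length: int) -> bool:
        pos = position % genome_length
        if not self.wraps:
            return self.start <= pos < self.end
        return pos >= self.start or pos < self.end

    def positions(self, genome_length: int) -> np.ndarray:
        """All reference positions covered, in 5'->3' reference order."""
        return (np.arange(self.start, self.start + self.width(genome_length))
                % genome_length)


@dataclass(frozen=True)
class CircularGenome:
    """A single circular DNA sequence with strand-aware windowed access."""

    name: str
    sequence: str
    circular: bool = True

    def __post_init__(self) -> None:
        seq = self.sequence.upper()
        if not seq:
            raise FormatError("empty genome sequence")
        if not set(seq) <= _ALPHABET:
            bad = sorted(set(seq) - _ALPHABET)
            raise FormatError(f"genome contains non-ACGTN characters: {bad}")
        object.__setattr__(self, "sequence", seq)

    @property
    def length(self) -> int:
        return len(self.sequence)

    def fetch(self, start: int, width: int) -> str:
        """``width`` reference bases starting at ``start``, wrapping the origin."""
        L = self.length
        if width < 0 or (not self.circular and width > L):
            raise ValueError("window wider than genome")
        if width > L:
            raise ValueError("window wider than genome")
        s = start % L
        if s + width <= L:
            return self.sequence[s:s + width]
        if not self.circular:
            raise ValueError("window crosses the end of a linear sequence")
        return self.sequence[s:] + self.sequence[:(s + width) % L]

    def window(self, center: int, upstream: int, downstream: int,
               strand: str = "+") -> str:
        """Sequence around ``center`` in transcription orientation.

        The returned string reads 5'->3' on the nascent-RNA sense of
        ``strand``, so its first ``upstream`` characters are upstream of the
        center, the character at index ``upstream`` is the center base, and
        the rest is downstream.  Minus-strand windows are reverse
        complemented.
        """
        if upstream < 0 or downstream < 0:
            raise ValueError("upstream/downstream must be non-negative")
        width = upstream + downstream + 1
        if width > self.length:
            raise ValueError("window wider than genome")
        if strand == "+":
            return self.fetch(center - upstream, width)
        if strand == "-":
            return reverse_complement(self.fetch(center - downstream, width))
        raise ValueError(f"strand must be '+' or '-', got {strand!r}")

    def rotated(self, k: int) -> "CircularGenome":
        """Genome with the origin moved by ``k`` bases (coordinate i -> i-k)."""
        k %= self.length
        return CircularGenome(self.name, self.sequence[k:] + self.sequence[:k],
                              self.circular)


def base_composition(sequence: str) -> dict[str, float]:
    """Fraction of each of A/C/G/T, with N excluded from the denominator."""
    seq = sequence.upper()
    if not set(seq) <= _ALPHABET:
        bad = sorted(set(seq) - _ALPHABET)
        raise FormatError(f"sequence contains non-ACGTN characters: {bad}")
    denom = len(seq) - seq.count("N")
    if denom == 0:
        raise FormatError("composition undefined: sequence is empty or all N")
    return {b: seq.count(b) / denom for b in "ACGT"}


def read_fasta_circular(path: str | Path, circular: bool = True) -> CircularGenome:
    """Read the first record of a FASTA file as a circular genome.

    Multi-record files use the first record only (single-contig pipeline); a
    warning is emitted in that case.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise FormatError(f"no FASTA records in {path}")
    if len(records) > 1:
        warnings.warn(
            f"{path} has {len(records)} records; using the first "
            f"({records[0].id}) — this pipeline is single-contig")
    rec = records[0]
    return CircularGenome(name=rec.id, sequence=str(rec.seq), circular=circular)


def write_fasta(genome: CircularGenome, path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        fh.write(f">{genome.name}\n")
        for i in range(0, genome.length, width):
            fh.write(genome.sequence[i:i + width] + "\n")


# --------------------------------------------------------------------------
# BED / variant I/O
# --------------------------------------------------------------------------

@dataclass
class BedRecord:
    chrom: str
    start: int
    end: int
    name: str = "."
    score: float = 0.0
    strand: str = "+"


def read_bed(path: str | Path) -> list[BedRecord]:
    """Parse BED3+ text (0-based half-open); extra columns ignored."""
    records: list[BedRecord] = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{ln}: fewer than 3 BED columns")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise FormatError(f"{path}:{ln}: non-integer coordinates") from exc
            if end <= start:
                raise FormatError(f"{path}:{ln}: end <= start")
            name = fields[3] if len(fields) > 3 else "."
            score = float(fields[4]) if len(fields) > 4 and fields[4] != "." else 0.0
            strand = fields[5] if len(fields) > 5 else "+"
            if strand not in ("+", "-", "."):
                raise FormatError(f"{path}:{ln}: bad strand {strand!r}")
            records.append(BedRecord(chrom, start, end, name, score,
                                     "+" if strand == "." else strand))
    return records


def write_bed(records: Iterable[BedRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in records:
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.name}\t"
                     f"{r.score:g}\t{r.strand}\n")


@dataclass
class GeneAnnotation:
    """Strand-aware gene intervals with a closed biotype vocabulary."""

    genes: list[tuple[GenomicInterval, str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        for _, name, biotype in self.genes:
            if biotype not in BIOTYPES:
                raise ValueError(f"unknown biotype {biotype!r} for gene {name}")

    @classmethod
    def from_bed(cls, path: str | Path) -> "GeneAnnotation":
        """BED6 with the biotype carried in the score-agnostic name field as
        ``genename|biotype`` (falling back to biotype 'other')."""
        genes = []
        for rec in read_bed(path):
            if "|" in rec.name:
                gname, biotype = rec.name.rsplit("|", 1)
            else:
                gname, biotype = rec.name, "other"
            if biotype not in BIOTYPES:
                biotype = "other"
            genes.append((GenomicInterval(rec.start, rec.end, rec.strand),
                          gname, biotype))
        return cls(genes)

    def to_bed(self, path: str | Path, chrom: str = "chrM") -> None:
        write_bed(
            (BedRecord(chrom, iv.start, iv.end, f"{name}|{bt}", 0, iv.strand)
             for iv, name, bt in self.genes), path)


@dataclass
class VariantSet:
    """Point variants (e.g. disease-associated SNPs) as 0-based positions."""

    positions: list[int]
    ids: list[str]

    def __post_init__(self) -> None:
        if len(self.positions) != len(self.ids):
            raise ValueError("positions and ids differ in length")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("variant ids are not unique")

    def __len__(self) -> int:
        return len(self.positions)


def read_variants_bed(path: str | Path) -> VariantSet:
    recs = read_bed(path)
    ids = [r.name if r.name != "." else f"var_{i}" for i, r in enumerate(recs)]
    return VariantSet([r.start for r in recs], ids)


def read_variants_tsv(path: str | Path) -> VariantSet:
    """Plain TSV with header ``pos<TAB>id``; positions 0-based."""
    positions, ids = [], []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:2] != ["pos", "id"]:
            raise FormatError(f"{path}: expected header 'pos\\tid'")
        for ln, line in enumerate(fh, 2):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            try:
                positions.append(int(fields[0]))
            except ValueError as exc:
                raise FormatError(f"{path}:{ln}: non-integer position") from exc
            ids.append(fields[1])
    return VariantSet(positions, ids)


def write_variants_tsv(variants: VariantSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("pos\tid\n")
        for pos, vid in zip(variants.positions, variants.ids):
            fh.write(f"{pos}\t{vid}\n")
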