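"""Per-base, per-strand 3'-end coverage tracks.

In precision nuclear run-on sequencing (PRO-seq) the 3' end of each read is
the last base the engaged polymerase incorporated, so a per-base histogram
of read 3' ends is a single-nucleotide map of polymerase occupancy.  This
module turns aligned reads (SAM/BAM) or stranded bedGraph files into such
tracks, collapses PCR duplicates by unique molecular identifier (UMI), and
applies reads-per-million (RPM) normalization against either the total or
the nuclear mapped-read count.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
import pysam

from .genome_io import CircularGenome, FormatError

__all__ = [
    "EndCoverageTrack",
    "extract_three_prime_ends",
    "dedup_umi",
    "normalize",
    "read_bedgraph_pair",
    "write_bedgraph_pair",
]

NORMALIZATIONS = ("raw", "rpm_total", "rpm_nuclear")


@dataclass
class EndCoverageTrack:
    """3'-end counts per base on each strand of one circular contig.

    ``plus``/``minus`` hold the nascent-RNA-sense counts: a value at
    ``plus[i]`` means a polymerase whose active site was at reference base
    ``i`` while transcribing the plus strand.  Raw tracks hold non-negative
    integers; normalized tracks hold raw * 1e6 / denominator.
    """

    sample: str
    plus: np.ndarray
    minus: np.ndarray
    normalization: str = "raw"
    denominator: float | None = None

    def __post_init__(self) -> None:
        self.plus = np.asarray(self.plus, dtype=float)
        self.minus = np.asarray(self.minus, dtype=float)
        if self.plus.shape != self.minus.shape or self.plus.ndim != 1:
            raise ValueError("plus/minus arrays must be 1-D and equal length")
        if self.normalization not in NORMALIZATIONS:
            raise ValueError(f"unknown normalization {self.normalization!r}")

    @property
    def length(self) -> int:
        return self.plus.size

    def strand(self, strand: str) -> np.ndarray:
        if strand == "+":
            return self.plus
        if strand == "-":
            return self.minus
        raise ValueError(f"strand must be '+' or '-', got {strand!r}")

    def total_count(self) -> float:
        return float(self.plus.sum() + self.minus.sum())


def _iter_primary(alignments: Iterable[pysam.AlignedSegment]
                  ) -> Iterator[pysam.AlignedSegment]:
    for aln in alignments:
        if aln.is_unmapped or aln.is_secondary or aln.is_supplementary:
            continue
        yield aln


def three_prime_end(aln: pysam.AlignedSegment, genome_length: int
                    ) -> tuple[int, str]:
    """(position, strand) of the read's 3' end on the nascent-RNA sense.

    Soft-clipped bases are excluded (pysam's reference_start/reference_end
    already span only aligned bases).  For a forward alignment the 3' end is
    the last aligned reference base; for a reverse alignment, the first.
    Positions are reduced mod L so circle-aware alignments that run past the
    origin still land on the contig.
    """
    if aln.is_reverse:
        return aln.reference_start % genome_length, "-"
    return (aln.reference_end - 1) % genome_length, "+"


def extract_three_prime_ends(alignments: Iterable[pysam.AlignedSegment] | str | Path,
                             genome: CircularGenome,
                             sample: str = "sample",
                             flip_strand: bool = False) -> EndCoverageTrack:
    """Histogram read 3' ends into a raw per-base, per-strand track.

    ``flip_strand`` accommodates library preparations that sequence the
    reverse complement of the nascent RNA; with it set, a forward alignment
    counts on the minus strand and vice versa.
    """
    if isinstance(alignments, (str, Path)):
        with pysam.AlignmentFile(str(alignments), check_sq=False) as fh:
            return extract_three_prime_ends(list(fh), genome, sample, flip_strand)

    L = genome.length
    plus = np.zeros(L, dtype=np.int64)
    minus = np.zeros(L, dtype=np.int64)
    for aln in _iter_primary(alignments):
        if aln.reference_name is not None and aln.reference_name != genome.name:
            raise FormatError(
                f"alignment contig {aln.reference_name!r} != genome "
                f"{genome.name!r}")
        pos, strand = three_prime_end(aln, L)
        if flip_strand:
            strand = "-" if strand == "+" else "+"
        (plus if strand == "+" else minus)[pos] += 1
    return EndCoverageTrack(sample=sample, plus=plus, minus=minus)


def read_umi(aln: pysam.AlignedSegment, umi_tag: str = "RX",
             name_sep: str = "_") -> str | None:
    """UMI from a SAM tag (default RX), else from the read-name suffix."""
    if aln.has_tag(umi_tag):
        return str(aln.get_tag(umi_tag))
    if name_sep and aln.query_name and name_sep in aln.query_name:
        return aln.query_name.rsplit(name_sep, 1)[1]
    return None


def dedup_umi(alignments: Iterable[pysam.AlignedSegment],
              genome_length: int,
              umi_tag: str = "RX",
              name_sep: str = "_") -> list[pysam.AlignedSegment]:
    """Collapse PCR duplicates: one read per (3'-end position, strand, UMI).

    Reads without a UMI pass through untouched.  Keyed on the 3' end rather
    than full sequence identity: equivalent for fixed-length reads and
    robust to base-call errors elsewhere in the read.  Idempotent.
    """
    seen: set[tuple[int, str, str]] = set()
    kept: list[pysam.AlignedSegment] = []
    for aln in alignments:
        umi = read_umi(aln, umi_tag=umi_tag, name_sep=name_sep)
        if umi is None:
            kept.append(aln)
            continue
        pos, strand = three_prime_end(aln, genome_length)
        key = (pos, strand, umi)
        if key in seen:
            continue
        seen.add(key)
        kept.append(aln)
    return kept


def normalize(track: EndCoverageTrack, mode: str,
              denominator: float) -> EndCoverageTrack:
    """Scale a raw track to reads per million (RPM).

    ``mode`` records what the denominator is: 'rpm_total' for total mapped
    reads, 'rpm_nuclear' for reads mapping to the nuclear genome (useful
    when a treatment changes mitochondrial read yield itself).
    """
    if mode not in ("rpm_total", "rpm_nuclear"):
        raise ValueError(f"mode must be rpm_total or rpm_nuclear, got {mode!r}")
    if denominator <= 0:
        raise ValueError("normalization denominator must be > 0")
    if track.normalization != "raw":
        raise ValueError(f"track already normalized ({track.normalization})")
    scale = 1e6 / denominator
    return replace(track, plus=track.plus * scale, minus=track.minus * scale,
                   normalization=mode, denominator=float(denominator))


# --------------------------------------------------------------------------
# bedGraph I/O (one file per strand)
# --------------------------------------------------------------------------

def _read_bedgraph(path: str | Path, length: int) -> np.ndarray:
    values = np.zeros(length, dtype=float)
    covered = np.zeros(length, dtype=bool)
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split()
            if len(fields) < 4:
                raise FormatError(f"{path}:{ln}: fewer than 4 bedGraph columns")
            try:
                start, end, value = int(fields[1]), int(fields[2]), float(fields[3])
            except ValueError as exc:
                raise FormatError(f"{path}:{ln}: bad coordinates/value") from exc
            if end <= start or end > length:
                raise FormatError(f"{path}:{ln}: bad span [{start},{end})")
            if covered[start:end].any():
                raise FormatError(f"{path}:{ln}: overlapping spans")
            covered[start:end] = True
            values[start:end] = value
    return values


def _write_bedgraph(values: np.ndarray, path: str | Path, chrom: str) -> None:
    # run-length encode; zero runs are omitted
    with open(path, "w") as fh:
        L = values.size
        i = 0
        while i < L:
            j = i + 1
            while j < L and values[j] == values[i]:
                j += 1
            if values[i] != 0:
                fh.write(f"{chrom}\t{i}\t{j}\t{values[i]:g}\n")
            i = j


def write_bedgraph_pair(track: EndCoverageTrack, prefix: str | Path,
                        chrom: str = "chrM") -> tuple[Path, Path]:
    """Write ``<prefix>.plus.bedGraph`` / ``.minus.bedGraph`` plus a JSON
    sidecar with sample id and normalization state."""
    prefix = Path(prefix)
    plus_path = prefix.with_name(prefix.name + ".plus.bedGraph")
    minus_path = prefix.with_name(prefix.name + ".minus.bedGraph")
    _write_bedgraph(track.plus, plus_path, chrom)
    _write_bedgraph(track.minus, minus_path, chrom)
    sidecar = prefix.with_name(prefix.name + ".json")
    with open(sidecar, "w") as fh:
        json.dump({"sample": track.sample,
                   "normalization": track.normalization,
                   "denominator": track.denominator,
                   "length": track.length}, fh, indent=2)
    return plus_path, minus_path


def read_bedgraph_pair(prefix: str | Path, length: int | None = None
                       ) -> EndCoverageTrack:
    prefix = Path(prefix)
    sidecar = prefix.with_name(prefix.name + ".json")
    meta = {}
    if sidecar.exists():
        with open(sidecar) as fh:
            meta = json.load(fh)
    if length is None:
        length = meta.get("length")
    if length is None:
        raise ValueError("genome length required (no JSON sidecar found)")
    plus = _read_bedgraph(prefix.with_name(prefix.name + ".plus.bedGraph"), length)
    minus = _read_bedgraph(prefix.with_name(prefix.name + ".minus.bedGraph"), length)
    return EndCoverageTrack(sample=meta.get("sample", prefix.name),
                            plus=plus, minus=minus,
                            normalization=meta.get("normalization", "raw"),
                            denominator=meta.get("denominator"))
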