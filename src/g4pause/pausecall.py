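"""Pause-site calling from 3'-end coverage on a circular genome.

A pause is a base where polymerase occupancy (3'-end read density) is a
local outlier: the per-base count is converted to a Z-score against the
mean and population standard deviation of a 201-nt window centered on the
base, with circular wrap-around.  Bases with Z >= 3 and at least 1 RPM
coverage are peaks; bases that peak in two or more replicate samples are
consensus pause bases, and runs of consecutive consensus bases on the same
strand merge into pause sites.

The window statistics are computed with a uniform filter but are required
(and tested) to agree with a naive per-base loop to 1e-9 relative
tolerance, so the optimized path is an implementation detail.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.ndimage import uniform_filter1d

from .coverage import EndCoverageTrack
from .genome_io import BedRecord, GenomicInterval, write_bed

__all__ = [
    "PauseCallParams",
    "PausePeak",
    "PauseSite",
    "rolling_window_stats",
    "zscore_track",
    "zscore_pair",
    "call_peaks",
    "consensus_sites",
    "threshold_sweep",
    "write_sites",
]

# relative floor below which a window is considered flat (sd treated as 0)
_SD_FLOOR = 1e-8


@dataclass(frozen=True)
class PauseCallParams:
    """Tunable thresholds of the pause caller.

    window: odd window width in nt for the local mean/sd (default 201).
    zmin: minimum Z-score for a peak (default 3).
    min_cov: minimum normalized coverage in RPM for a peak (default 1).
    min_samples: replicates that must peak at a base for consensus (default 2).
    """

    window: int = 201
    zmin: float = 3.0
    min_cov: float = 1.0
    min_samples: int = 2

    def __post_init__(self) -> None:
        if self.window % 2 == 0 or self.window <= 0:
            raise ValueError("window must be odd and positive")
        if self.zmin <= 0:
            raise ValueError("zmin must be > 0")
        if self.min_samples < 1:
            raise ValueError("min_samples must be >= 1")


@dataclass(frozen=True)
class PausePeak:
    """A single-sample peak base."""

    position: int
    strand: str
    z: float
    coverage: float
    sample: str


@dataclass
class PauseSite:
    """A consensus pause interval with its summit base."""

    interval: GenomicInterval
    summit: int
    strand: str
    n_supporting_samples: int
    max_z_per_sample: dict[str, float] = field(default_factory=dict)

    @property
    def max_z(self) -> float:
        return max(self.max_z_per_sample.values(), default=0.0)


def rolling_window_stats(values: np.ndarray, window: int
                         ) -> tuple[np.ndarray, np.ndarray]:
    """Centered circular rolling mean and population standard deviation.

    The window includes the center base.  The population (divide-by-W)
    standard deviation is used.  Values are centered on their global mean
    before the moment computation to avoid cancellation on near-constant
    tracks.
    """
    x = np.asarray(values, dtype=float)
    L = x.size
    if window % 2 == 0:
        raise ValueError("window must be odd")
    if window > L:
        raise ValueError("window exceeds track length")
    shift = x.mean()
    xc = x - shift
    mean_c = uniform_filter1d(xc, size=window, mode="wrap")
    meansq_c = uniform_filter1d(xc * xc, size=window, mode="wrap")
    var = np.maximum(meansq_c - mean_c * mean_c, 0.0)
    return mean_c + shift, np.sqrt(var)


def zscore_track(values: np.ndarray, window: int = 201) -> np.ndarray:
    """Per-base Z-score against the local circular window.

    Z_i = (c_i - mean_i) / sd_i; windows with sd == 0 (all values equal)
    get Z = 0, consistent because the center then equals the mean.
    """
    x = np.asarray(values, dtype=float)
    mean, sd = rolling_window_stats(x, window)
    floor = _SD_FLOOR * (1.0 + np.abs(mean))
    z = np.zeros_like(x)
    ok = sd > floor
    z[ok] = (x[ok] - mean[ok]) / sd[ok]
    return z


def zscore_pair(track: EndCoverageTrack, window: int = 201
                ) -> dict[str, np.ndarray]:
    """Z-score arrays for both strands of a coverage track."""
    return {"+": zscore_track(track.plus, window),
            "-": zscore_track(track.minus, window)}


def call_peaks(track: EndCoverageTrack, params: PauseCallParams,
               zscores: dict[str, np.ndarray] | None = None
               ) -> list[PausePeak]:
    """Bases with Z >= zmin and coverage >= min_cov, on both strands.

    The track must be normalized so that its units match ``min_cov`` (RPM);
    calling on a raw track with an RPM threshold is a unit mismatch.
    """
    if track.normalization == "raw" and params.min_cov > 0:
        raise ValueError(
            "track is raw but min_cov is in RPM; normalize first or set "
            "min_cov=0")
    if zscores is None:
        zscores = zscore_pair(track, params.window)
    peaks: list[PausePeak] = []
    for strand in ("+", "-"):
        cov = track.strand(strand)
        z = zscores[strand]
        hits = np.nonzero((z >= params.zmin) & (cov >= params.min_cov))[0]
        for pos in hits:
            peaks.append(PausePeak(int(pos), strand, float(z[pos]),
                                   float(cov[pos]), track.sample))
    return peaks


def _circular_runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True in a circular boolean mask as (start, end mod L).

    ``end`` is exclusive; a run crossing the origin is returned with
    start > end.  An all-True mask is one run covering the whole circle.
    """
    L = mask.size
    if not mask.any():
        return []
    if mask.all():
        return [(0, 0)]  # whole circle, width L
    prev = np.roll(mask, 1)
    starts = np.nonzero(mask & ~prev)[0]
    nxt = np.roll(mask, -1)
    ends = np.nonzero(mask & ~nxt)[0] + 1  # exclusive; may equal L
    runs = []
    for s in starts:
        # matching end: first end strictly after s, else wrap to the first end
        later = ends[ends > s]
        if later.size:
            runs.append((int(s), int(later[0])))  # end == L stays L (no wrap)
        else:
            runs.append((int(s), int(ends[0])))  # crosses the origin
    return runs


def consensus_sites(peak_lists: Sequence[Sequence[PausePeak]],
                    genome_length: int,
                    params: PauseCallParams) -> list[PauseSite]:
    """Merge per-sample peaks into replicate-consensus pause sites.

    Per-base voting on each strand: a base is a consensus base when it peaks
    in >= min_samples samples.  Consecutive consensus bases on one strand
    merge (wrap-aware) into a site.  The summit is the base with the largest
    Z summed over the samples that peaked there; ties go to the base reached
    first in the transcription direction.
    """
    if len(peak_lists) < params.min_samples:
        raise ValueError("fewer samples than min_samples")
    sites: list[PauseSite] = []
    L = genome_length
    for strand in ("+", "-"):
        votes = np.zeros(L, dtype=int)
        zsum = np.zeros(L, dtype=float)
        per_sample_z: list[tuple[str, dict[int, float]]] = []
        for k, peaks in enumerate(peak_lists):
            sample_z: dict[int, float] = {}
            sample_name = next((p.sample for p in peaks), f"sample_{k + 1}")
            for p in peaks:
                if p.strand != strand:
                    continue
                if p.position >= L:
                    raise ValueError("peak position beyond genome length")
                votes[p.position] += 1
                zsum[p.position] += p.z
                sample_z[p.position] = p.z
            per_sample_z.append((sample_name, sample_z))
        mask = votes >= params.min_samples
        for start, end in _circular_runs(mask):
            iv = GenomicInterval(start, end, strand)
            positions = iv.positions(L)
            if strand == "-":
                # transcription runs toward decreasing coordinates
                positions = positions[::-1]
            summit = int(positions[int(np.argmax(zsum[positions]))])
            max_z = {}
            for sample_name, sample_z in per_sample_z:
                zs = [sample_z[p] for p in positions if p in sample_z]
                if zs:
                    max_z[sample_name] = max(zs)
            sites.append(PauseSite(iv, summit, strand,
                                   int(votes[positions].max()), max_z))
    sites.sort(key=lambda s: (s.interval.start, s.strand))
    return sites


def threshold_sweep(tracks: Sequence[EndCoverageTrack],
                    zmins: Sequence[float],
                    params: PauseCallParams | None = None
                    ) -> list[tuple[float, int]]:
    """Consensus-site counts across a range of Z thresholds.

    Z-score tracks are computed once per sample; only the peak gate varies.
    Counts are non-increasing in the threshold.
    """
    if params is None:
        params = PauseCallParams()
    if list(zmins) != sorted(zmins):
        raise ValueError("zmins must be sorted ascending")
    zs = [zscore_pair(t, params.window) for t in tracks]
    out = []
    for zmin in zmins:
        p = PauseCallParams(params.window, zmin, params.min_cov,
                            params.min_samples)
        peak_lists = [call_peaks(t, p, zscores=z) for t, z in zip(tracks, zs)]
        sites = consensus_sites(peak_lists, tracks[0].length, p)
        out.append((float(zmin), len(sites)))
    return out


def write_sites(sites: Sequence[PauseSite], genome_length: int,
                path: str | Path, chrom: str = "chrM") -> None:
    """Write sites as BED6; a wrapped site becomes two lines sharing a name.

    Score is 10 x the site's maximum consensus Z, rounded and capped at 1000.
    """
    records = []
    for i, site in enumerate(sites, 1):
        name = f"site_{i}"
        score = min(1000, round(10 * site.max_z))
        iv = site.interval
        if iv.wraps:
            records.append(BedRecord(chrom, iv.start, genome_length, name,
                                     score, site.strand))
            records.append(BedRecord(chrom, 0, iv.end, name, score,
                                     site.strand))
        else:
            records.append(BedRecord(chrom, iv.start, iv.end, name, score,
                                     site.strand))
    if not records:
        with open(path, "w") as fh:
            fh.write("# no pause sites\n")
        return
    write_bed(records, path)
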