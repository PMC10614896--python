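"""Statistics linking pause sites to sequence and structure.

Metaprofiles (anchor-centered signal averages oriented by transcription
direction), upstream-guanine enrichment against random control sites,
strand asymmetry of pause counts, grouping of sites by upstream guanine
content, variant overlap, and gene annotation of sites.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .coverage import EndCoverageTrack
from .genome_io import CircularGenome, GeneAnnotation, GenomicInterval, VariantSet
from .pausecall import PauseSite

__all__ = [
    "Metaprofile",
    "EnrichmentResult",
    "metaprofile",
    "random_control_sites",
    "upstream_g_content",
    "upstream_enrichment_test",
    "strand_asymmetry_test",
    "group_by_upstream_g",
    "variant_overlap",
    "annotate_sites",
]


@dataclass
class Metaprofile:
    """Positionwise mean +/- SEM of a signal around anchor summits.

    Offsets run upstream-negative to downstream-positive in transcription
    orientation; on a circular genome every anchor contributes a value at
    every offset (no edge loss), so each mean is over exactly ``n`` values.
    """

    offsets: np.ndarray
    mean: np.ndarray
    sem: np.ndarray
    n: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"offset": self.offsets, "mean": self.mean,
                             "sem": self.sem, "n": self.n})


@dataclass
class EnrichmentResult:
    """A named test statistic with p-value and group bookkeeping."""

    name: str
    statistic: float
    pvalue: float
    group_sizes: tuple[int, ...]
    direction: str = ""
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0 <= self.pvalue <= 1):
            raise ValueError("p-value outside [0, 1]")


@dataclass(frozen=True)
class Anchor:
    """A (position, strand) anchor; pause-site summits or controls."""

    position: int
    strand: str


def _anchors(sites: Sequence) -> list[Anchor]:
    out = []
    for s in sites:
        if isinstance(s, Anchor):
            out.append(s)
        elif isinstance(s, PauseSite):
            out.append(Anchor(s.summit, s.strand))
        else:
            pos, strand = s
            out.append(Anchor(int(pos), strand))
    return out


def metaprofile(tracks: dict[str, np.ndarray], sites: Sequence,
                up: int = 100, down: int = 100) -> Metaprofile:
    """Average a per-strand signal around site summits.

    Negative offsets are upstream of the summit in the transcription
    direction: plus-strand anchors read the track left-to-right, minus-
    strand anchors right-to-left, so a feature a fixed distance 5' of the
    polymerase appears at the same negative offset on both strands.
    """
    anchors = _anchors(sites)
    if not anchors:
        raise ValueError("empty site list")
    L = tracks["+"].size
    offsets = np.arange(-up, down + 1)
    rows = np.empty((len(anchors), offsets.size))
    for i, a in enumerate(anchors):
        if a.strand == "+":
            idx = (a.position + offsets) % L
        else:
            idx = (a.position - offsets) % L
        rows[i] = tracks[a.strand][idx]
    mean = rows.mean(axis=0)
    if len(anchors) > 1:
        sem = rows.std(axis=0, ddof=1) / np.sqrt(len(anchors))
    else:
        sem = np.zeros_like(mean)
    return Metaprofile(offsets, mean, sem, len(anchors))


def random_control_sites(genome: CircularGenome, n: int,
                         strand_proportions: tuple[float, float] = (0.5, 0.5),
                         exclude: Sequence = (),
                         seed: int | np.random.Generator = 0) -> list[Anchor]:
    """Uniform control positions avoiding the excluded set.

    Positions are drawn without replacement from bases not occupied by any
    excluded anchor (strand-blind exclusion: a paused base is not a control
    on either strand).  Strands are assigned to match the requested
    proportions as closely as integer counts allow.
    """
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    excluded = {a.position for a in _anchors(exclude)}
    allowed = np.array([p for p in range(genome.length) if p not in excluded])
    if n > allowed.size:
        raise ValueError(f"cannot draw {n} controls from {allowed.size} "
                         "available positions")
    chosen = rng.choice(allowed, size=n, replace=False)
    n_plus = int(round(n * strand_proportions[0] /
                       (strand_proportions[0] + strand_proportions[1])))
    strands = np.array(["+"] * n_plus + ["-"] * (n - n_plus))
    rng.shuffle(strands)
    return [Anchor(int(p), s) for p, s in zip(chosen, strands)]


def upstream_g_content(genome: CircularGenome, site,
                       k: int = 50) -> tuple[int, float]:
    """Guanine count and fraction in the k nt 5' of a summit.

    The window is taken on the nascent-RNA sense strand and excludes the
    summit base itself: for a plus-strand summit at p it covers reference
    [p-k, p); for a minus-strand summit, (p, p+k] complemented.
    """
    (a,) = _anchors([site])
    window = genome.window(a.position, upstream=k, downstream=0,
                           strand=a.strand)[:k]
    g = window.count("G")
    return g, g / k


def upstream_enrichment_test(pause_sites: Sequence, control_sites: Sequence,
                             genome: CircularGenome,
                             k: int = 50) -> EnrichmentResult:
    """Rank-sum comparison of upstream-G counts, pause vs control sites.

    Two-sided Wilcoxon rank-sum (Mann-Whitney U); direction reports which
    group has the larger median count.  Because the two strands have very
    different background guanine levels, per-strand sub-tests are computed
    alongside the pooled test and carried in ``extra['per_strand']``; the
    per-strand values are the interpretable ones on asymmetric genomes.
    Fully tied input yields p = 1 with a warning rather than an error.
    """
    if not pause_sites or not control_sites:
        raise ValueError("both site lists must be non-empty")
    ap = _anchors(pause_sites)
    ac = _anchors(control_sites)
    gp = np.array([upstream_g_content(genome, a, k)[0] for a in ap])
    gc = np.array([upstream_g_content(genome, a, k)[0] for a in ac])

    def _ranksum(a, b):
        if a.size == 0 or b.size == 0:
            return None
        if np.ptp(np.concatenate([a, b])) == 0:
            return {"statistic": 0.0, "pvalue": 1.0,
                    "n": (int(a.size), int(b.size))}
        s, p = stats.mannwhitneyu(a, b, alternative="two-sided")
        return {"statistic": float(s), "pvalue": float(p),
                "n": (int(a.size), int(b.size))}

    per_strand = {}
    for strand in ("+", "-"):
        sub = _ranksum(
            gp[np.array([a.strand == strand for a in ap], dtype=bool)],
            gc[np.array([a.strand == strand for a in ac], dtype=bool)])
        if sub is not None:
            per_strand[strand] = sub
    if np.ptp(np.concatenate([gp, gc])) == 0:
        warnings.warn("all upstream-G counts tied; test degenerate")
        return EnrichmentResult("upstream_g_ranksum", 0.0, 1.0,
                                (gp.size, gc.size), "none",
                                extra={"per_strand": per_strand})
    stat, p = stats.mannwhitneyu(gp, gc, alternative="two-sided")
    direction = "pause>control" if np.median(gp) > np.median(gc) else \
        ("pause<control" if np.median(gp) < np.median(gc) else "none")
    return EnrichmentResult("upstream_g_ranksum", float(stat), float(p),
                            (gp.size, gc.size), direction,
                            extra={"median_pause": float(np.median(gp)),
                                   "median_control": float(np.median(gc)),
                                   "per_strand": per_strand})


def strand_asymmetry_test(n_plus: int, n_minus: int,
                          null_prop: float = 0.5) -> EnrichmentResult:
    """Chi-square goodness of fit of the strand split against a null
    proportion (1 degree of freedom)."""
    total = n_plus + n_minus
    if total == 0:
        raise ValueError("no sites on either strand")
    expected = [total * null_prop, total * (1 - null_prop)]
    chi2, p = stats.chisquare([n_plus, n_minus], expected)
    direction = "plus" if n_plus > n_minus else \
        ("minus" if n_minus > n_plus else "none")
    return EnrichmentResult("strand_asymmetry_chi2", float(chi2), float(p),
                            (n_plus, n_minus), direction)


def site_abundance(sites: Sequence[PauseSite],
                   tracks: Sequence[EndCoverageTrack]) -> np.ndarray:
    """Per-site polymerase abundance: summit coverage averaged over samples."""
    vals = np.zeros(len(sites))
    for i, s in enumerate(sites):
        vals[i] = np.mean([t.strand(s.strand)[s.summit] for t in tracks])
    return vals


def group_by_upstream_g(sites: Sequence[PauseSite],
                        tracks: Sequence[EndCoverageTrack],
                        genome: CircularGenome, k: int = 50,
                        bins: Sequence[float] | None = None,
                        alpha: float = 0.05
                        ) -> tuple[pd.DataFrame, pd.DataFrame, EnrichmentResult]:
    """Bin sites by upstream-G count and compare abundance across bins.

    Default binning is by quartile of the upstream-G count; fixed bin edges
    may be supplied instead.  Returns the per-site table, a table of
    pairwise two-sided Mann-Whitney tests with Benjamini-Hochberg adjusted
    p-values (unadjusted values retained), and a global Kruskal-Wallis
    rank test across bins.
    """
    g_counts = np.array([upstream_g_content(genome, s, k)[0] for s in sites])
    abundance = site_abundance(sites, tracks)
    if bins is None:
        try:
            labels = pd.qcut(g_counts, 4, duplicates="drop")
        except ValueError:
            labels = pd.Series(["all"] * len(sites))
    else:
        labels = pd.cut(g_counts, bins=list(bins), include_lowest=True)
    table = pd.DataFrame({"upstream_g": g_counts, "abundance": abundance,
                          "bin": pd.Series(labels).astype(str)})
    groups = {name: grp["abundance"].to_numpy()
              for name, grp in table.groupby("bin", observed=True)}
    names = sorted(groups, key=lambda b: table.loc[table["bin"] == b,
                                                   "upstream_g"].median())
    rows = []
    for a, b in combinations(names, 2):
        ga, gb = groups[a], groups[b]
        if ga.size < 2 or gb.size < 2:
            warnings.warn(f"bin comparison {a} vs {b} skipped (<2 sites)")
            continue
        if np.ptp(np.concatenate([ga, gb])) == 0:
            stat, p = 0.0, 1.0
        else:
            stat, p = stats.mannwhitneyu(ga, gb, alternative="two-sided")
        rows.append({"bin_a": a, "bin_b": b, "n_a": ga.size, "n_b": gb.size,
                     "statistic": float(stat), "pvalue": float(p)})
    pairwise = pd.DataFrame(rows)
    if not pairwise.empty:
        rej, adj, _, _ = multipletests(pairwise["pvalue"], alpha=alpha,
                                       method="fdr_bh")
        pairwise["pvalue_adj"] = adj
        pairwise["significant"] = rej
    arrays = [groups[nm] for nm in names if groups[nm].size >= 2]
    if len(arrays) >= 2 and np.ptp(np.concatenate(arrays)) > 0:
        h, p_global = stats.kruskal(*arrays)
    else:
        h, p_global = 0.0, 1.0
    global_test = EnrichmentResult("abundance_by_g_kruskal", float(h),
                                   float(p_global),
                                   tuple(groups[nm].size for nm in names))
    return table, pairwise, global_test


def variant_overlap(sites: Sequence[PauseSite], variants: VariantSet,
                    genome_length: int) -> dict:
    """Overlap between point variants and pause-site intervals.

    Intervals are half-open and wrap-aware.  Reports both the number of
    variants inside any site and the number of sites containing at least
    one variant; the percentage uses variants-in-sites over the site count
    (with the sites-with-variant ratio also included, since either reading
    of "percent of sites" occurs in practice).
    """
    n_var_in_sites = 0
    var_ids = []
    sites_hit = np.zeros(len(sites), dtype=bool)
    for pos, vid in zip(variants.positions, variants.ids):
        inside = False
        for i, s in enumerate(sites):
            if s.interval.contains(pos, genome_length):
                sites_hit[i] = True
                inside = True
        if inside:
            n_var_in_sites += 1
            var_ids.append(vid)
    n_sites = len(sites)
    return {
        "n_variants_in_sites": n_var_in_sites,
        "n_sites_with_variant": int(sites_hit.sum()),
        "pct_variants_per_site": 100.0 * n_var_in_sites / n_sites
        if n_sites else 0.0,
        "pct_sites_with_variant": 100.0 * sites_hit.sum() / n_sites
        if n_sites else 0.0,
        "variant_ids": var_ids,
    }


def annotate_sites(sites: Sequence[PauseSite], annotation: GeneAnnotation,
                   genome_length: int,
                   end_fraction: float = 0.1) -> pd.DataFrame:
    """Label each site with its overlapping same-strand gene and position class.

    A site belongs to the first same-strand gene whose interval contains
    its summit, else it is intergenic.  In-gene sites are classified by the
    summit's relative position along the gene in transcription direction:
    the first ``end_fraction`` of the gene is the 5' end, the last is the
    3' end, the rest is body.
    """
    rows = []
    for s in sites:
        gene_name, biotype, rel, klass = "intergenic", "none", np.nan, "intergenic"
        for iv, name, bt in annotation.genes:
            if iv.strand == s.strand and iv.contains(s.summit, genome_length):
                gene_name, biotype = name, bt
                w = iv.width(genome_length)
                off = (s.summit - iv.start) % genome_length
                rel = off / w if iv.strand == "+" else (w - 1 - off) / w
                if rel < end_fraction:
                    klass = "5prime"
                elif rel >= 1 - end_fraction:
                    klass = "3prime"
                else:
                    klass = "body"
                break
        rows.append({"summit": s.summit, "strand": s.strand, "gene": gene_name,
                     "biotype": biotype, "relative_position": rel,
                     "class": klass})
    return pd.DataFrame(rows)


def biotype_summary(annotated: pd.DataFrame,
                    annotation: GeneAnnotation) -> pd.DataFrame:
    """Genes with at least one pause per biotype, against the totals."""
    totals = {}
    for _, name, bt in annotation.genes:
        totals[bt] = totals.get(bt, 0) + 1
    hit = annotated[annotated["gene"] != "intergenic"]
    genes_hit = hit.groupby("biotype")["gene"].nunique()
    rows = []
    for bt, total in sorted(totals.items()):
        rows.append({"biotype": bt, "genes_with_pause":
                     int(genes_hit.get(bt, 0)), "genes_total": total})
    return pd.DataFrame(rows)
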