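# Methods

## Coordinate model

The pipeline operates on exactly one circular contig. Coordinates are
0-based half-open everywhere internally; an interval with `start > end`
crosses the origin and has width `(end - start) mod L`. Every sequence
window, rolling statistic and metaprofile wraps the origin, so no position
is an edge case. "Upstream"/"downstream" are defined on the nascent-RNA
sense: on the minus strand, upstream means higher reference coordinates
and extracted windows are reverse complemented. BED output is native
0-based half-open; wrapped sites are split into two BED lines sharing a
name. Multi-record FASTA input uses the first record with a warning; `N`
bases are excluded from composition denominators and score 0 in G4
scoring.

## 3′-end coverage

For a forward-strand alignment the 3′ end is the last aligned reference
base; for a reverse-strand alignment, the first. Soft clips are excluded
(only aligned bases count) and circle-aware alignments that run past the
origin are reduced mod L. Each primary alignment increments exactly one
(position, strand) cell, so raw track totals equal surviving read counts.
PCR duplicates are collapsed on the key (3′-end position, strand, UMI) —
equivalent to full sequence identity for fixed-length reads and robust to
base-call errors elsewhere in the read; reads without a UMI pass through.
Strand semantics assume the library reports the nascent RNA sense
directly; a `flip_strand` switch accommodates reverse-complemented
preparations, since kits differ.

Two RPM normalization modes are provided: against total mapped reads (the
usual choice for comparing replicate samples) and against nuclear-mapped
reads (preferable when a treatment changes mitochondrial transcription
itself, so mitochondrial totals are not a stable yardstick). The
denominator is supplied by the caller and recorded on the track; a track
can be normalized once.

## Pause calling

Per base i, Z_i = (c_i − μ_i)/σ_i with μ, σ the mean and population
(divide-by-W) standard deviation of the W = 201 values centered on i,
center included, circular wrap. Windows with σ = 0 get Z = 0, consistent
because the center then equals the mean. The implementation uses a uniform
filter over globally centered values (to avoid cancellation on
near-constant tracks) and is tested to agree with a naive per-base loop to
1e-9 relative tolerance; an isolated spike of any height h on zero
background has Z = √(W−1) ≈ 14.14 at W = 201, a useful closed form because
it is height-free.

Peaks are bases with Z ≥ 3 and ≥ 1 RPM; both thresholds, the window, and
the replicate requirement are parameters. Consensus is per-base voting
across samples (≥ 2 by default) per strand; runs of consecutive consensus
bases merge (wrap-aware) into one site whose summit is the base with the
largest Z summed over supporting samples, ties resolved to the base
reached first in transcription direction. Site extent is the merged run —
single-base sites are common and expected; the choice is recorded in
output so interval-overlap analyses are reproducible. A threshold sweep
re-gates precomputed Z tracks over Z = 3..6 and reports consensus-site
counts, which are non-increasing by construction.

## G4 propensity

Per-base run scoring: every base in a run of n guanines scores +min(n, 4),
in a cytosine run −min(n, 4), otherwise 0; a centered moving average
(default 25 nt) gives the windowed track. On a duplex the minus-strand
track is the negation of the plus-strand track (G/C antisymmetry), which
the implementation exploits and the tests assert.

Motif enumeration finds all substrings G_x N_ℓ1 G_x N_ℓ2 G_x N_ℓ3 G_x with
x ≥ 2, each ℓ ∈ [1, 7] (zero-length loops excluded by default; the doublet
G2 class with short spacers is the biologically salient one here), total
width ≤ 45. Loops may contain guanines; candidates are every
(start, x, ℓ1, ℓ2, ℓ3) tuple, verified against a character-level
brute-force oracle. The G-score is a local convention,

    gscore = 20·(x − 2) + Σᵢ(8 − ℓᵢ) − (max ℓ − min ℓ),

chosen to satisfy three ordering criteria: more tetrads better, shorter
loops better, uniform loops better. The spread penalty uses coefficient 1
because any larger value breaks monotonicity in individual loop lengths
(lengthening the unique shortest loop would gain more from reduced spread
than it loses in length). Only relative ordering is relied upon
downstream. Overlapping candidates are reduced greedily (score descending,
then leftmost) per strand; the full candidate list remains available
(`reduce=False`). Genome scans extend the sequence past the origin by
max_len − 1 so wrapped motifs are found once.

Per-base "metatracks" for profiling: hunter mode uses the windowed mean;
qgrs mode assigns each covered base the maximum G-score over covering
motifs (an aggregation convention, recorded in output metadata).

## Association statistics

Metaprofiles average a per-strand track at offsets −100..+100 around site
summits, oriented so negative offsets are upstream in transcription
direction; means come with SEM. Controls are uniform positions excluding
paused bases, strand-assigned to match the query set's proportions;
a coverage-matched control mode is deliberately not the default since the
data-generating process here does not couple G content to background
coverage. Upstream-G enrichment uses the two-sided Mann–Whitney U on
guanine counts in the 50 nt 5′ of the summit (summit excluded), pooled and
per strand — the per-strand tests are the interpretable ones on a genome
whose strands differ 13% vs 31% in background G, because pooling mixes the
two baselines and dilutes rank separation. Strand asymmetry is a 1-df
chi-square goodness of fit ((60, 40) vs 0.5 gives χ² = 4.0 exactly).
Abundance-by-upstream-G grouping bins sites by quartile of upstream-G
count (fixed edges optional), compares summit coverage between bins by
pairwise Mann–Whitney with Benjamini–Hochberg adjustment (unadjusted
values retained, since published work often reports them) and a global
Kruskal–Wallis test. Degenerate inputs (all tied, bins with < 2 sites)
warn and return p = 1 or skip rather than fail.

Variant overlap counts both variants-inside-any-site and
sites-containing-a-variant, wrap-aware and half-open, and reports both
percentage conventions since "percent of sites" is ambiguous between
them. Gene annotation assigns each summit its same-strand containing gene;
in-gene sites are classified 5′-end / body / 3′-end by relative position
with a 10% end window (configurable — the field has no fixed convention).

## Synthetic data: what it emulates, and what it does not

The generator is the package's study-conditions definition, not a tuning
dial. Defaults: L = 16,569; base composition A/C/G/T =
0.309/0.313/0.131/0.247 on the reference strand (so the complement is
31.3% G — the real mitochondrial asymmetry); 13 motifs on the G-poor and
27 on the G-rich strand (≈ 2:1, echoing the observed excess of pausing on
the G-rich transcript); tract length 2 with probability 0.7 and 3 with
0.3; loops uniform on 1–7 nt; pause probability 0.8 per motif; pause
offset uniform on 20–40 nt downstream of the motif midpoint (clamped below
by half the motif width + 5 so the pause always falls downstream of the
motif's 3′ end) — this anchoring reproduces the signature of the real
data, a windowed G4-score metaprofile peaking 20–40 nt upstream of
summits, which anchoring at the motif's 3′ edge does not (it pushes the
score mass to 30–50 nt); 5 noise pauses; negative-binomial background
with mean 2 counts/base/strand and size 20; pause fold 30; 3 replicates
with library sizes 4.5/5.0/5.5 million.

Composition is planted exactly: the background is a shuffled multiset of
the target base counts, and after motif blocks overwrite it, free
background bases are rewritten to restore the exact counts. A simulated
genome therefore always rounds to 13% / 31% G, as the real sequence does,
independent of seed. Motifs are placed with ≥ 100 nt clear margins and
8-nt G-free flanks (longer than the maximum loop), which guarantees the
planted motif — and nothing bridging into background — is the candidate a
scan recovers at the truth coordinates.

Deliberate simplifications, hence limits of what green tests show about
real data: no gene order or real annotation structure; loops and flanks
are G-free on the motif strand, which on the G-rich strand makes planted
motif neighborhoods slightly G-depleted relative to the 31% background —
so the upstream-G enrichment test shows clear signal on the G-poor strand
but little on the G-rich strand at desk scale, whereas real data shows
both; no read-level simulation (UMI logic is tested on hand-built SAM
records); pause elevation is multiplicative on the NB mean, keeping the
dispersion structure uniform; background counts are i.i.d. across bases,
with none of the correlated coverage structure of real libraries.

Recovery scoring matches called summits to planted pauses one-to-one,
greedily by circular distance, same strand, within ±1 nt. At the default
conditions the caller achieves recall ≥ 0.9 and precision ≥ 0.8 (typically
1.00 / 0.95).

## Numerical and procedural choices

- Rolling moments via `scipy.ndimage.uniform_filter1d` in wrap mode over
  globally centered values; variance clipped at 0 before the square root;
  σ below 1e-8·(1 + |μ|) treated as zero.
- Mann–Whitney U uses scipy's tie-corrected asymptotic method at these
  sample sizes; null calibration (positions resampled under exchangeable
  assignment, 1,000–2,000 reps) rejects at 5% within the 4–6% band.
- The real reference sequence is not bundled; the composition and
  end-to-end checks run on generated genomes whose composition is planted
  exactly at the real values. Given per-sample stranded 3′-end bedGraphs
  from real libraries, the same `run` command performs the full analysis.
- Problem sizes in the test suite and acceptance script (tracks ≤ 2,000 nt
  for oracle comparisons, 100 random 200-mers for enumeration oracles,
  1,000–2,000 calibration reps) were chosen to estimate each quantity to
  well under its decision tolerance while keeping the default run fast.
- Analyses aligned against hg19 use a mitochondrial contig two bases
  longer than the revised reference (16,571 vs 16,569 nt); the package
  standardizes on the 16,569-nt length and leaves reconciliation of
  coordinates to the user's liftover.
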