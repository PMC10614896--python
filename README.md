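# g4pause

Pause-site calling and G-quadruplex association analysis for nascent
transcription on circular genomes — built around the human mitochondrial
genome, a 16,569-nt circle transcribed as two near-genome-length
polycistronic RNAs by the single-subunit mitochondrial RNA polymerase
(mtRNAP).

## The problem

Precision nuclear run-on sequencing (PRO-seq) maps the 3′ end of each
nascent RNA — the base the engaged polymerase last incorporated — at
single-nucleotide resolution. Where the polymerase dwells, 3′-end read
density accumulates. On the mitochondrial genome, guanine-rich sequences
that can fold into G-quadruplexes (G4s) in the nascent RNA lie just
upstream of many such pause positions. `g4pause` provides the
computational half of that analysis as a tested, reusable pipeline:

- **Pause calling.** Per-base, per-strand 3′-end counts (from SAM/BAM with
  optional UMI deduplication, or from stranded bedGraph) are RPM-normalized
  and converted to a Z-score against the mean μᵢ and population standard
  deviation σᵢ of a 201-nt circular window centered on each base:
  Zᵢ = (cᵢ − μᵢ)/σᵢ. Bases with Z ≥ 3 and ≥ 1 RPM are peaks; bases that
  peak in ≥ 2 replicate samples are consensus pause bases, merged into
  pause sites with a summit.
- **G4 propensity.** Two strand-aware scorers: a per-base run score
  (+min(run, 4) in G-runs, −min(run, 4) in C-runs) averaged in a 25-nt
  window, and explicit enumeration of four-tract motifs
  G_x N_{1–7} G_x N_{1–7} G_x N_{1–7} G_x (x ≥ 2) with a G-score that
  prefers more tetrads, shorter loops, and uniform loops.
- **Association statistics.** Transcription-oriented metaprofiles around
  summits (mean ± SEM), upstream-guanine enrichment against random
  controls (Wilcoxon rank-sum, pooled and per strand), chi-square strand
  asymmetry, abundance-by-upstream-G binning (Mann–Whitney pairs with
  Benjamini–Hochberg, Kruskal–Wallis global), gene annotation with 5′/3′
  classification, and wrap-aware variant overlap.
- **Synthetic data.** A generator that plants G4 motifs and downstream
  pauses in a composition-faithful circular genome (13.1% G reference
  strand, 31.3% G complement) with negative-binomial replicate coverage,
  so every stage is testable against known truth.

All coordinates are 0-based half-open on a single circular contig;
intervals may wrap the origin (`start > end`). "Upstream" always means 5′
on the nascent RNA of the strand in question.

## Worked example

```python
import numpy as np
from g4pause import association, coverage, g4score, pausecall
from g4pause.synthetic import SimulationParams, evaluate_recovery, simulate

params = SimulationParams(seed=1)
genome, truth, raw = simulate(params)
tracks = [coverage.normalize(t, "rpm_total", t.denominator) for t in raw]
call_params = pausecall.PauseCallParams()  # W=201, Z>=3, >=1 RPM, >=2 samples
peaks = [pausecall.call_peaks(t, call_params) for t in tracks]
sites = pausecall.consensus_sites(peaks, genome.length, call_params)
rec = evaluate_recovery(sites, truth, genome.length, tolerance=1)
print(f"called {len(sites)} consensus pause sites "
      f"({len(truth.pauses)} planted)")
print(f"recall {rec['recall']:.2f}, precision {rec['precision']:.2f}")

hunter = g4score.g4_metatrack(genome, "hunter")
prof = association.metaprofile(hunter, sites, up=100, down=100)
print(f"G4 score metaprofile peaks at offset "
      f"{int(prof.offsets[np.argmax(prof.mean)])} nt")
```

prints

```
called 39 consensus pause sites (37 planted)
recall 1.00, precision 0.95
G4 score metaprofile peaks at offset -26 nt
```

Of the 40 planted motifs, 37 nucleated a pause under the default pause
probability; the caller recovers all of them within ±1 nt, with two of the
39 calls being background false positives. The windowed G4 score averaged
around the called summits peaks 20–40 nt *upstream* — the planted (and
biologically observed) geometry in which the polymerase pauses after
transcribing through a quadruplex-forming sequence.

The same analysis runs from the shell:

```sh
g4pause simulate --outdir sim --seed 1
g4pause call sim/genome.fa sim/raw_rep1 sim/raw_rep2 sim/raw_rep3 --out sites.bed
g4pause g4 sim/genome.fa --out motifs.bed
g4pause run config.yaml       # full pipeline + Markdown report
```

To analyze real data, point `run` at a genome FASTA and per-sample
stranded bedGraph pairs (`<prefix>.plus.bedGraph` / `.minus.bedGraph`)
with `simulate: false` in the YAML config.

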