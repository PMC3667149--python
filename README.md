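# chiptile

A tested, reusable pipeline for **histone-modification ChIP-chip analysis**
on tiling microarrays: peak calling with permutation-estimated FDR,
peak-to-feature annotation, Gibbs-sampling motif discovery, transcription-
factor binding-site (TFBS) enrichment against randomized genomic controls,
expression-stratified TSS metaprofiles, differential-expression
intersection, and DNase-hypersensitivity co-occurrence — together with a
synthetic-study generator that plants every signal it later has to recover.

It is written for computational biologists who work with probe-level log2
enrichment ratios (ChIP over input) from tiling arrays — probes of ~50 bp
every ~100 bp — and for anyone who needs a transparent, seedable
re-implementation of the classic cutoff-ladder detection scheme to
benchmark against.

## The core method

Peak detection anchors a descending cutoff ladder on the *hypothetical
maximum* of each chromosome's ratios, `H = mean(r) + k·sd(r)`, with rungs
at 90%, 89%, …, 15% of `H`. At each rung, probes above the cutoff merge
when separated by ≤ 500 bp, and a merged group is enriched when ≥ 4
above-cutoff probes fit in one 500-bp window (or, optionally, when ≥ m
consecutive probes are all above the cutoff). A peak's score is the highest
rung at which any part of it qualifies; lower rungs only extend boundaries.

The false discovery rate is estimated by permutation: ratios are shuffled
over the fixed probe positions, peaks are re-called, and

```
FDR(s) = E_perm[ # permuted peaks with score ≥ s ] / # observed peaks with score ≥ s
```

clipped to [0, 1] and made monotone in s. Peaks with FDR < 0.005 pass.
Downstream, motifs are found with a one-occurrence-per-sequence Gibbs site
sampler (12-bp sites, log-likelihood-ratio score
`F = Σ_i Σ_b c(i,b) ln(q(i,b)/p(b))`), and TFBS enrichment compares total
PWM hits over the peak set against the mean over ten same-chromosome,
same-length random control sets with a χ² statistic at p < 0.0005. See
[docs/methods.md](docs/methods.md) for every formula, convention and
default.

## Worked example

Generate a synthetic study (3 × 2 Mb genome, 60,000 probes, 100 planted
peaks of mean length 692 bp at 2.0 log2 units over N(0, 0.5) noise), call
peaks, and annotate them:

```python
import numpy as np
from chiptile import synthdata as sd, peakcall as pc, annotate as ann, profiles

study = sd.generate_study(sd.SyntheticConfig(seed=2))
all_peaks, peaks = pc.call_and_filter(study.tracks, pc.PeakCallParams(seed=2))
print(f"called {len(all_peaks)} candidate regions, {len(peaks)} at FDR<0.005")
print(f"mean peak length: {np.mean([p.interval.length for p in peaks]):.0f} bp")
for _, row in ann.summarize_categories(peaks, study.genes).iterrows():
    print(f"  {row['category']:<11} {row['percent']:5.1f}%")
frac, _ = profiles.dhs_cooccurrence(peaks, study.dhs)
print(f"DHS co-occurrence: {100*frac:.2f}%")
```

prints

```
called 99 candidate regions, 99 at FDR<0.005
mean peak length: 796 bp
  promoter     17.2%
  tes          11.1%
  coding       11.1%
  exon          2.0%
  intron       40.4%
  intergenic   18.2%
DHS co-occurrence: 12.12%
```

All 99 filtered regions overlap planted peaks: at this signal-to-noise the
caller is essentially exact, and the called mean length (796 bp) tracks the
planted mean (692 bp) plus roughly one probe spacing of boundary slack per
side. Category percentages scatter around the configured planting mix
(intron 45%, intergenic 18%, …) with binomial noise at n = 99, and the
measured DNase co-occurrence (12.1%) estimates the planted 13.44% rate.

The same stages are available from the shell:

```bash
chiptile simulate --outdir sim --seed 2
chiptile callpeaks --probes sim/probes.tsv --fdr 0.005 --out peaks.bed
chiptile annotate --peaks peaks.bed --genes sim/genes.gff --out annotated.tsv
chiptile motif --fasta peaks.fa --width 12 --iterations 5000 --seed 2 --out motif.transfac
chiptile run --outdir results/   # full pipeline with a manifest
```

`chiptile run` executes every stage in order and writes a `manifest.json`
with per-file SHA-256 digests; two runs at the same seed are byte-identical.

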