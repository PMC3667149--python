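# Methods

`chiptile` re-implements a classic histone-modification ChIP-chip analysis
as a reusable, tested pipeline. The substrate is a tiling microarray: probes
of ~50 bp spaced every ~100 bp across the genome, each carrying a log2
enrichment ratio (ChIP over input). The pipeline detects enriched regions
(peaks), annotates them against gene models, discovers a binding motif in
their sequences, tests transcription-factor binding site (TFBS) enrichment
against randomized genomic controls, and relates peaks to expression strata,
differential expression and DNase-I hypersensitive sites (DHS). A synthetic
study generator with a complete truth ledger provides the test bed.

## Peak calling

Detection uses a cutoff-ladder / sliding-window scheme. For each chromosome
a scaling anchor, the *hypothetical maximum*

    H = mean(r) + k * sd(r)

is computed from the probe ratios r (population sd). A descending ladder of
absolute cutoffs is derived as percentages of H: starting at `p_start` = 90%
and stepping down by `p_step` = 1% for `n_steps` = 76 rungs (90% → 15%). At
each rung, probes strictly above the cutoff are grouped (gap ≤ `window` =
500 bp merges) and a group qualifies when either

* at least `min_probes` = 4 of its above-cutoff probes fit inside one
  `window`-bp window (probe-start span < 500 bp), or
* it contains a run of at least `min_probes_all_above` consecutive track
  probes all above the cutoff.

A peak's **score** is the highest rung percentage at which any part of it
qualifies; regions found at lower rungs that overlap a higher-scoring peak
extend its boundaries but keep the higher score. The reported interval runs
from the first above-cutoff probe start to the last plus one probe spacing;
sub-probe boundary resolution is not attempted.

**False discovery rate.** For `n_permutations` = 20 seeded shuffles of the
ratio values over the fixed probe positions (per chromosome), peaks are
re-called and, for every observed score level s,

    FDR(s) = mean permuted count of peaks scoring >= s
             / observed count scoring >= s,

clipped to [0, 1] and made monotone non-increasing in s. Peaks pass the
filter when FDR < 0.005 (strict inequality). Pooling is genome-wide; the
ladder is per-chromosome by default (`global_ladder` pools the ratios).

Two defaults here are deliberate design choices, and the analysis behind
them matters for anyone changing them:

* `min_probes_all_above` defaults to 4, which folds the consecutive-run
  shortcut into the window rule. With the shortcut at its permissive value
  of 2, the permutation null is contaminated: shuffling scatters the
  genuinely enriched ratio values, and adjacent pairs of them (expected
  count ≈ N·π² for N probes with enriched fraction π — about 8 per
  permutation at the default study scale) qualify as peaks at *every* score
  level in proportion to the observed peaks, putting a floor of roughly
  1–2% under every estimated FDR. No score threshold can then satisfy a
  0.005 filter. Setting the parameter to 2 restores the permissive variant.
* `hypmax_k` defaults to 12, placing the ladder's bottom rung (15% of H) at
  ~1.8 noise sd. At k = 6 the bottom rung sits at ~1 sd, where ~16% of
  noise probes exceed the cutoff; boundary extension then chains through
  noise probes (expected extension of several hundred bp per side at 100-bp
  spacing), roughly doubling called peak lengths. The anchor is a free
  scaling constant — scores are percentages of it — so the choice moves the
  operating range of rungs, not the detection logic.

## Annotation

A peak is represented by its midpoint and receives exactly one feature
category with fixed precedence **promoter > tes > coding > exon > intron >
intergenic**: promoter = within 10 kb upstream of a transcription start
site (TSS) in gene orientation, tes = within 10 kb downstream of a
transcription end site, coding = in an exon inside the CDS bounds, exon =
in an exon outside the CDS, intron = in a gene body but no exon. The
promoter category is upstream-only; the *peak-to-gene link* used by the
expression analyses is two-sided (midpoint within ±10 kb of the TSS, closed
window). Chromosome-scale density tracks bin peak midpoints (default 1 Mb)
and report log2(count + 1); the gene-density correlation is a Pearson
coefficient over per-bin gene and peak counts and is reported as undefined
(None) when a vector has zero variance.

## Motif discovery

A one-occurrence-per-sequence (OOPS) Gibbs site sampler over fixed-width
(default 12 bp) sites on both strands. Each sweep holds one sequence out,
re-estimates the position weight matrix (PWM) from the other sites with
Dirichlet pseudocounts (background frequency × 1.0 per column; background =
0-order model of the input sequences), and resamples the held-out site
proportional to the PWM/background likelihood ratio. Every 100 sweeps a
phase-shift move tries common offsets of ±1..3 columns and accepts on score
improvement. The motif score is the log-likelihood ratio

    F = sum_i sum_b c(i,b) * ln( q(i,b) / p(b) )

(c site counts, q pseudocounted frequencies, p background); the best state
over all sweeps is returned, so the result is deterministic at fixed seed
and never worse than the initial state. The default iteration count is
5,000 sweeps; motif-recovery tests use 1,000, which suffices at the planted
signal strengths. Presence calls (`fraction_with_motif`) flag a sequence
when its best log-odds window on either strand reaches `threshold_fraction`
(default 0.8) of the PWM's maximal achievable log-odds.

## TFBS enrichment

PWM scanning uses the information-weighted matrix-similarity score: with
column frequencies f(i,b) and I(i) = Σ_b f(i,b) ln(4 f(i,b)),

    score = (Σ_i I(i) f(i, b_i) − min) / (max − min) ∈ [0, 1],

where min/max substitute each column's least/most frequent base. A single
global threshold (default 0.85) replaces the per-matrix cutoff profiles of
proprietary scanners. Windows containing non-ACGT letters are ineligible.

Controls: for each peak and each of 10 control sets, one uniformly placed
interval of identical length on the same chromosome, rejected if it
overlaps any peak (capped retries, then a warning and the overlap is
allowed). Enrichment per TF: O = total hits over the peak set, E = mean
total hits over the control sets, χ² = (O − E)²/E with df 1, upper-tail p,
significant at p < 0.0005 (no multiple-testing correction by default;
Bonferroni behind a flag; a 2×2 presence/absence variant behind another).
This one-cell statistic is anti-conservative on Poisson-distributed counts
— in null simulations its realized type-I rate runs several-fold above
nominal α while remaining far inside the aggregate bound used by the test
suite — which is why the acceptance checks bound the aggregate false-positive
fraction rather than asserting exact calibration. The degenerate consensus
scanner expands bracket/IUPAC patterns (the 9-mer CTCF motif
`AG[GA][GT]GG[CAT][GAT][CG]` expands to 72 words) and counts every offset
matching the pattern or its reverse complement, overlaps included.

## Profiles, DE intersection, DHS co-occurrence

Genes are ranked by expression (descending, ties broken by gene id) and
split top 30% / middle 40% / bottom 30% with ceiling arithmetic. For each
group, peak midpoints within ±10 kb of member TSSs are histogrammed in
strand-oriented coordinates (200-bp bins; positive = downstream); density
normalizes by the group's gene count (a coverage-weighted mode exists
behind a flag). A peak near two genes contributes an event to each. The
differential-expression intersection takes the peak-gene links and counts
linked genes with signed fold change > +1.5 (up) or < −1.5 (down), each
gene once. DHS co-occurrence flags a peak when any DHS interval overlaps
[start − 1 kb, end + 1 kb) (half-open margin) and reports the flagged
fraction.

## Synthetic data generator

The generator emulates the study conditions end to end and records every
planted object in a truth ledger. Defaults: 3 chromosomes × 2 Mb, GC 0.41
(human-like), 150 genes (2–20 kb, 2–8 exons, CDS inside the outer exons,
bodies separated by ≥ 12 kb so neighbor promoter/TES windows do not blanket
gene interiors), probes every 100 bp (50-mers), 100 planted peaks, flat
additive enrichment of 2.0 log2 units over Normal(0, 0.5) noise, a 12-bp
G-rich motif planted in 55% of peaks, DHS attached to 13.44% of peaks
(background DHS ≥ 5 kb from every peak; attached DHS avoid other peaks'
margin zones so the planted rate is what the co-occurrence measurement
sees), and 26 up- / 47 down-regulated genes beyond the ±1.5 signed
fold-change threshold among otherwise null genes.

Peak categories are drawn from a configurable mix (defaults: promoter 0.10,
intron 0.45, exon 0.03, coding 0.02, TES 0.10, intergenic 0.18, and an
*unlabeled* 0.12 remainder placed uniformly at random — the emulated
category chart leaves 12% of peaks unassigned, and the generator does not
guess a category for them). A candidate position is proposed from features
of the drawn category and accepted only when the annotation classifier
agrees, so truth labels are exact by construction; planted peaks are
mutually disjoint.

Peak lengths follow a shifted geometric law with mean 692 bp and minimum
500 bp. The minimum is a modeling decision: the generator emulates
*called* regions, and a detector requiring ~4 probes at 100-bp spacing
cannot emit 200–300-bp regions, so seeding the benchmark with such peaks
would build in irrecoverable misses (a third of a 200-bp-minimum geometric
law falls below the 4-probe floor, capping attainable sensitivity near
0.67). Any minimum ≥ probe spacing is configurable.

What the generator does **not** emulate — and therefore what passing tests
do not show about real arrays: probe-level GC/affinity bias and saturation,
spatially correlated noise and chromatin-domain structure, replicate
variability (the emulated ratios correspond to already-merged replicates),
non-flat peak shapes, overlapping genes and alternative transcripts, and
realistic motif co-occurrence structure. Recovery rates measured here are
upper bounds for data with correlated noise.

## Numerical and tie-break conventions

* All internal coordinates are 0-based half-open; GFF (1-based inclusive)
  and fixedStep WIG (1-based) are converted only at I/O boundaries.
* "Above cutoff" is strict (>); the FDR filter is strict (<); the window
  qualification uses probe-start span < window; the TSS link window is
  closed at ±10 kb; the DHS margin is half-open at end + margin.
* Overlapping rung regions merge with the higher score; equal-rung overlaps
  merge into one region.
* Ties in expression ranking break lexicographically by gene id; writers
  emit chromosome-lexicographic, then start-coordinate order, making every
  output byte-stable at fixed seed.
* The Gibbs sampler excludes sequences shorter than the motif width (or
  with no ACGT-only window) with a warning; scanning skips windows with
  non-ACGT letters; GC computations ignore non-ACGT letters.
* One pipeline seed expands into fixed per-stage seeds, so stages are
  independently rerunnable and bit-reproducible.

## Problem sizes

Test and acceptance runs use the default 3 × 2 Mb genome (60,000 probes)
for peak calling (10 recovery seeds, 50 null seeds), 3 × 4 Mb with 2,000
peaks for annotation fidelity, 200 sequences × 1,000 sweeps × 5 seeds for
motif recovery, 500 peak sequences × 10 control sets for enrichment power
and 50 × 20 null tests for calibration, 5,000 peaks on 3 × 16 Mb for DHS
co-occurrence, and two full default pipeline runs for determinism. These
sizes give binomial standard errors comfortably inside the asserted
tolerances while keeping a full run in minutes on one core.

## Known limitations

* The permutation FDR assumes exchangeable probe ratios within a
  chromosome; spatially correlated noise would make it optimistic.
* The one-cell χ² enrichment test is anti-conservative (see above); treat
  its p-values as a ranking with a validated aggregate error bound, not as
  calibrated tail probabilities.
* The matrix-similarity threshold is global; matrices of very different
  information content are not equated the way per-matrix profiles would.
* OOPS sampling assumes at most one true site per sequence; multi-site
  peaks bias the PWM toward the strongest site.
* Category assignment by midpoint ignores peaks straddling feature
  boundaries; the percentages are point estimates of a point
  representation.
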