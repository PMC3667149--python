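"""Synthetic ChIP-chip study generator.

Produces a fully self-contained miniature study — genome, gene models, tiling
probe track with planted enriched regions, planted sequence motifs,
expression/fold-change labels and DNase-hypersensitive sites — together with
a truth ledger recording every planted object, so that each downstream stage
(peak calling, annotation, motif discovery, enrichment, profiles) can be
tested against known ground truth.

Defaults emulate the tiling-array study conditions this package targets:
100-bp probe spacing, 50-mer probes, enriched regions of mean length 692 bp,
a 12-bp G-rich motif planted in 55% of peaks, DNase-site co-occurrence of
13.44%, and 26 up- / 47 down-regulated genes at the |1.5|-fold threshold.
"""

from __future__ import annotations

import warnings
from bisect import bisect_left, insort
from collections import OrderedDict
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .annotate import GenomeAnnotator
from .types import BASES, GeneModel, GenomicInterval, ProbeTrack, PWM, revcomp

#: 12-mer G-rich motif used as the default planted signal.
DEFAULT_MOTIF = "GGAGGGGGCGGG"

#: Feature-category mix: six labeled categories plus an "unlabeled" remainder
#: planted at uniformly random positions (the source distribution the
#: generator emulates leaves 12% of peaks unassigned).
DEFAULT_CATEGORY_PROPORTIONS = {
    "promoter": 0.10,
    "intron": 0.45,
    "exon": 0.03,
    "coding": 0.02,
    "tes": 0.10,
    "intergenic": 0.18,
    "unlabeled": 0.12,
}

_CATEGORY_VOCAB = set(DEFAULT_CATEGORY_PROPORTIONS)

# fixed per-stage seed offsets so each generator op is independently
# reproducible from one study seed
_STAGE = {
    "genome": 1,
    "genes": 2,
    "peaks": 3,
    "probes": 4,
    "motifs": 5,
    "expression": 6,
    "dhs": 7,
    "pwmlib": 8,
}


def stage_rng(seed: int, stage: str) -> np.random.Generator:
    """Deterministic per-stage RNG derived from the study seed."""
    return np.random.default_rng([seed % (2**31), _STAGE[stage]])


@dataclass
class SyntheticConfig:
    """Parameters of a synthetic study.

    Units: lengths/spacings in bp, enrichment and noise in log2-ratio units,
    rates as fractions in [0, 1].
    """

    n_chromosomes: int = 3
    chrom_length: int = 2_000_000
    gc_content: float = 0.41
    n_genes: int = 150
    min_gene_gap: int = 12_000
    probe_spacing: int = 100
    probe_length: int = 50
    n_true_peaks: int = 100
    peak_length_mean: int = 692
    # detected regions in a 4-probe / 100-bp-spacing design are never
    # shorter than ~5 probes; the generator emulates called-region lengths
    peak_length_min: int = 500
    enrich_mu: float = 2.0
    noise_sigma: float = 0.5
    motif_plant_rate: float = 0.55
    dhs_overlap_rate: float = 0.1344
    de_up: int = 26
    de_down: int = 47
    seed: int = 0
    category_proportions: dict = field(
        default_factory=lambda: dict(DEFAULT_CATEGORY_PROPORTIONS)
    )
    n_background_dhs: int | None = None
    promoter_window: int = 10_000
    tes_window: int = 10_000

    def __post_init__(self):
        for name in (
            "n_chromosomes", "chrom_length", "n_genes", "probe_length",
            "n_true_peaks", "de_up", "de_down",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("gc_content", "motif_plant_rate", "dhs_overlap_rate"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1]")
        if self.probe_spacing < 1:
            raise ValueError("probe_spacing must be >= 1")
        if self.peak_length_mean < self.probe_spacing:
            raise ValueError("peak_length_mean must be >= probe_spacing")
        if self.peak_length_min < self.probe_spacing:
            raise ValueError("peak_length_min must be >= probe_spacing")
        if self.peak_length_mean < self.peak_length_min:
            raise ValueError("peak_length_mean must be >= peak_length_min")
        bad = set(self.category_proportions) - _CATEGORY_VOCAB
        if bad:
            raise ValueError(f"unknown peak categories: {sorted(bad)}")
        total = sum(self.category_proportions.values())
        if abs(total - 1.0) > 1e-6:
            raise ValueError(f"category proportions must sum to 1 (got {total})")


@dataclass
class SyntheticTruth:
    """Ledger of every planted object; the oracle for downstream tests."""

    planted_peaks: list[GenomicInterval] = field(default_factory=list)
    peak_categories: list[str] = field(default_factory=list)
    motif_flags: list[bool] = field(default_factory=list)
    motif_placements: list[tuple[int, str] | None] = field(default_factory=list)
    dhs_flags: list[bool] = field(default_factory=list)
    de_labels: dict = field(default_factory=dict)  # gene_id -> up/down/null

    def validate(self, genome: dict | None = None) -> None:
        n = len(self.planted_peaks)
        if len(self.peak_categories) != n:
            raise ValueError("peak_categories must align 1:1 with planted peaks")
        for flags in (self.motif_flags, self.dhs_flags):
            if flags and len(flags) != n:
                raise ValueError("flags must align 1:1 with planted peaks")
        if genome is not None:
            for iv in self.planted_peaks:
                if iv.chrom not in genome or iv.end > len(genome[iv.chrom]):
                    raise ValueError(f"planted peak outside chromosome: {iv}")

    def to_frame(self) -> pd.DataFrame:
        n = len(self.planted_peaks)
        return pd.DataFrame(
            {
                "chrom": [iv.chrom for iv in self.planted_peaks],
                "start": [iv.start for iv in self.planted_peaks],
                "end": [iv.end for iv in self.planted_peaks],
                "category": self.peak_categories,
                "motif": self.motif_flags if self.motif_flags else [False] * n,
                "motif_offset": [
                    p[0] if p else -1
                    for p in (self.motif_placements or [None] * n)
                ],
                "motif_strand": [
                    p[1] if p else "."
                    for p in (self.motif_placements or [None] * n)
                ],
                "dhs": self.dhs_flags if self.dhs_flags else [False] * n,
            }
        )


# ---------------------------------------------------------------------------
# genome and genes


def generate_genome(config: SyntheticConfig, rng=None) -> "OrderedDict[str, str]":
    """I.i.d. random genome at the configured GC content."""
    if config.chrom_length <= 0:
        raise ValueError("chrom_length must be positive")
    if config.n_chromosomes <= 0:
        raise ValueError("n_chromosomes must be positive")
    rng = rng or stage_rng(config.seed, "genome")
    gc, at = config.gc_content / 2, (1 - config.gc_content) / 2
    cum = np.cumsum([at, gc, gc, at])  # A, C, G, T
    genome = OrderedDict()
    base_arr = np.frombuffer("ACGT".encode(), dtype=np.uint8)
    for i in range(config.n_chromosomes):
        codes = np.searchsorted(cum, rng.random(config.chrom_length), side="right")
        genome[f"chr{i + 1}"] = base_arr[np.minimum(codes, 3)].tobytes().decode()
    return genome


def generate_gene_models(
    genome: dict, config: SyntheticConfig, rng=None, max_tries: int = 200
) -> list[GeneModel]:
    """Place non-overlapping stranded multi-exon genes on the genome.

    Gene lengths are uniform on 2-20 kb with 2-8 exons; the CDS spans from
    inside the first exon to inside the last, so every gene has non-CDS
    (UTR) exon sequence and introns. Genes keep at least ``min_gene_gap`` bp
    of intergenic space between bodies so that promoter and TES windows of
    neighbors do not blanket gene interiors.
    """
    if not genome:
        raise ValueError("genome is empty")
    rng = rng or stage_rng(config.seed, "genes")
    chroms = list(genome)
    occupied: dict[str, list[tuple[int, int]]] = {c: [] for c in chroms}
    genes = []
    for gi in range(config.n_genes):
        placed = False
        for _ in range(max_tries):
            chrom = chroms[int(rng.integers(len(chroms)))]
            clen = len(genome[chrom])
            glen = int(rng.integers(2_000, 20_001))
            if clen <= glen + 2:
                continue
            start = int(rng.integers(0, clen - glen))
            end = start + glen
            gap = config.min_gene_gap
            if any(s - gap < end and start < e + gap for s, e in occupied[chrom]):
                continue
            occupied[chrom].append((start, end))
            placed = True
            break
        if not placed:
            raise ValueError(
                f"could not place gene {gi + 1} of {config.n_genes}: "
                "genome capacity exhausted"
            )
        strand = "+" if rng.random() < 0.5 else "-"
        n_ex = int(rng.integers(2, 9))
        exons = _random_exons(start, end, n_ex, rng)
        # CDS from inside the first exon to inside the last
        f0, f1 = exons[0]
        l0, l1 = exons[-1]
        cds_start = int(rng.integers(f0 + 1, f1)) if f1 - f0 > 1 else f0
        cds_end = int(rng.integers(l0 + 1, l1)) if l1 - l0 > 1 else l1
        if cds_end <= cds_start:
            cds_start, cds_end = f0, l1
        genes.append(
            GeneModel(
                gene_id=f"gene{gi + 1:04d}",
                chrom=chrom,
                tx_start=start,
                tx_end=end,
                strand=strand,
                exons=exons,
                cds_start=cds_start,
                cds_end=cds_end,
            )
        )
    return genes


def _random_exons(start: int, end: int, n_ex: int, rng) -> list[tuple[int, int]]:
    """Split [start, end) into n_ex exons separated by positive introns."""
    length = end - start
    if n_ex == 1 or length < 4 * n_ex:
        return [(start, end)]
    sizes = rng.integers(100, 401, size=n_ex)
    total_intron = length - int(sizes.sum())
    if total_intron < n_ex - 1:
        sizes = np.maximum(1, sizes * length // (2 * int(sizes.sum())))
        total_intron = length - int(sizes.sum())
    cuts = np.sort(rng.choice(total_intron - 1, size=n_ex - 2, replace=False)) + 1 \
        if n_ex > 2 else np.array([], dtype=int)
    gaps = np.diff(np.concatenate([[0], cuts, [total_intron]]))
    gaps = np.maximum(gaps, 1)
    exons = []
    pos = start
    for i in range(n_ex):
        exons.append((pos, pos + int(sizes[i])))
        if i < n_ex - 1:
            pos += int(sizes[i]) + int(gaps[i])
    # pin the last exon to the transcript end
    ls, _ = exons[-1]
    if ls >= end:
        return [(start, end)]
    exons[-1] = (ls, end)
    return exons


# ---------------------------------------------------------------------------
# planted enrichment


def _draw_peak_length(config: SyntheticConfig, rng) -> int:
    """Shifted geometric: min peak_length_min, mean peak_length_mean."""
    lo = config.peak_length_min
    mean_excess = max(config.peak_length_mean - lo, 0)
    if mean_excess == 0:
        return lo
    p = 1.0 / (mean_excess + 1)
    return lo + int(rng.geometric(p)) - 1


def _overlaps_sorted(starts_ends: list[tuple[int, int]], start: int, end: int) -> bool:
    i = bisect_left(starts_ends, (start, end))
    if i < len(starts_ends) and starts_ends[i][0] < end:
        return True
    return i > 0 and starts_ends[i - 1][1] > start


def plant_enrichment(
    genome: dict,
    genes: list[GeneModel],
    config: SyntheticConfig,
    rng=None,
    max_tries: int = 2000,
) -> tuple[list[GenomicInterval], SyntheticTruth]:
    """Plant disjoint enriched regions by target feature category.

    Each peak's category is drawn from ``config.category_proportions``; a
    candidate midpoint is proposed from features of that category and
    accepted only if the annotation classifier agrees, so the truth label is
    exact by construction. "unlabeled" peaks are placed uniformly at random.
    """
    rng = rng or stage_rng(config.seed, "peaks")
    cats = sorted(config.category_proportions)
    probs = np.array([config.category_proportions[c] for c in cats])
    annotator = GenomeAnnotator(
        genes,
        promoter_window=config.promoter_window,
        tes_window=config.tes_window,
    )
    _check_feasible(config, genes, cats, probs)
    chroms = list(genome)
    chrom_lens = {c: len(genome[c]) for c in chroms}
    placed: dict[str, list[tuple[int, int]]] = {c: [] for c in chroms}
    draw = rng.choice(len(cats), size=config.n_true_peaks, p=probs)
    intervals, labels = [], []
    features = {
        "intron": _collect_introns(genes),
        "exon": _collect_utr_exons(genes),
        "coding": _collect_coding_segments(genes),
    }
    for k in range(config.n_true_peaks):
        cat = cats[int(draw[k])]
        length = _draw_peak_length(config, rng)
        ok = False
        for _ in range(max_tries):
            chrom, mid = _propose_midpoint(
                cat, genes, features, chroms, chrom_lens, config, rng
            )
            start = mid - length // 2
            end = start + length
            if start < 0 or end > chrom_lens[chrom]:
                continue
            if cat != "unlabeled" and annotator.classify(chrom, mid) != cat:
                continue
            if _overlaps_sorted(placed[chrom], start, end):
                continue
            insort(placed[chrom], (start, end))
            intervals.append(GenomicInterval(chrom, start, end))
            labels.append(cat)
            ok = True
            break
        if not ok:
            raise ValueError(
                f"could not place a '{cat}' peak after {max_tries} tries"
            )
    truth = SyntheticTruth(planted_peaks=intervals, peak_categories=labels)
    truth.validate(genome)
    return intervals, truth


def _check_feasible(config, genes, cats, probs):
    need = {c for c, p in zip(cats, probs) if p > 0}
    if need & {"promoter", "tes"} and not genes:
        raise ValueError("no genes available for gene-anchored categories")
    if "intron" in need and not _collect_introns(genes):
        raise ValueError("category 'intron' infeasible: no introns exist")
    if "exon" in need and not _collect_utr_exons(genes):
        raise ValueError("category 'exon' infeasible: no non-CDS exon bases exist")
    if "coding" in need and not _collect_coding_segments(genes):
        raise ValueError("category 'coding' infeasible: no CDS bases exist")


def _collect_introns(genes) -> list[tuple[str, int, int]]:
    introns = []
    for g in genes:
        for (s1, e1), (s2, _) in zip(g.exons, g.exons[1:]):
            if s2 > e1:
                introns.append((g.chrom, e1, s2))
    return introns


def _collect_coding_segments(genes) -> list[tuple[str, int, int]]:
    """Exon segments inside the CDS bounds (candidate 'coding' positions)."""
    out = []
    for g in genes:
        for s, e in g.exons:
            lo, hi = max(s, g.cds_start), min(e, g.cds_end)
            if hi > lo:
                out.append((g.chrom, lo, hi))
    return out


def _collect_utr_exons(genes) -> list[tuple[str, int, int]]:
    """Exon segments outside the CDS (candidate 'exon' category positions)."""
    out = []
    for g in genes:
        for s, e in g.exons:
            if s < g.cds_start:
                out.append((g.chrom, s, min(e, g.cds_start)))
            if e > g.cds_end:
                out.append((g.chrom, max(s, g.cds_end), e))
    return out


def _propose_midpoint(cat, genes, features, chroms, chrom_lens, config, rng):
    if cat in ("intergenic", "unlabeled"):
        chrom = chroms[int(rng.integers(len(chroms)))]
        return chrom, int(rng.integers(0, chrom_lens[chrom]))
    if cat in features:
        segs = features[cat]
        chrom, s, e = segs[int(rng.integers(len(segs)))]
        return chrom, int(rng.integers(s, e))
    g = genes[int(rng.integers(len(genes)))]
    if cat == "promoter":
        off = int(rng.integers(1, config.promoter_window + 1))
        mid = g.tss - off if g.strand == "+" else g.tss + off
    elif cat == "tes":
        off = int(rng.integers(0, config.tes_window + 1))
        mid = g.tes + off if g.strand == "+" else g.tes - off
    else:  # pragma: no cover - vocabulary is validated upstream
        raise ValueError(f"unknown category {cat}")
    return g.chrom, mid


# ---------------------------------------------------------------------------
# probe track


def simulate_probe_track(
    genome: dict,
    true_peaks: list[GenomicInterval],
    config: SyntheticConfig,
    rng=None,
) -> list[ProbeTrack]:
    """Tile each chromosome with probes and add flat enrichment over peaks.

    Log2 ratios are Normal(0, noise_sigma) outside planted peaks and
    Normal(enrich_mu, noise_sigma) for probes whose midpoint lies inside one.
    """
    rng = rng or stage_rng(config.seed, "probes")
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for iv in true_peaks:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    tracks = []
    for chrom, seq in genome.items():
        last = len(seq) - config.probe_length
        if last < 0:
            continue
        positions = np.arange(0, last + 1, config.probe_spacing, dtype=np.int64)
        ratios = rng.normal(0.0, config.noise_sigma, size=positions.size)
        peaks = sorted(by_chrom.get(chrom, []), key=lambda p: p.start)
        if peaks:
            mids = positions + config.probe_length // 2
            starts = np.array([p.start for p in peaks])
            ends = np.array([p.end for p in peaks])
            idx = np.searchsorted(starts, mids, side="right") - 1
            inside = (idx >= 0) & (mids < ends[np.clip(idx, 0, None)])
            ratios[inside] += config.enrich_mu
        tracks.append(ProbeTrack(chrom, positions, ratios, config.probe_spacing))
    return tracks


# ---------------------------------------------------------------------------
# motif planting


def consensus_to_pwm(consensus: str, identity: float = 0.9, pwm_id: str = "planted",
                     scale: float = 100.0) -> PWM:
    """Build a PWM whose per-column consensus frequency is ``identity``."""
    if not (0.25 < identity <= 1.0):
        raise ValueError("identity must be in (0.25, 1]")
    w = len(consensus)
    counts = np.full((4, w), scale * (1 - identity) / 3)
    for i, b in enumerate(consensus.upper()):
        counts[BASES.index(b), i] = scale * identity
    return PWM(id=pwm_id, counts=counts)


def sample_motif_instance(motif, rng) -> str:
    """Sample one concrete word from a consensus string, bracket pattern or PWM."""
    if isinstance(motif, PWM):
        freqs = motif.frequencies()
        return "".join(
            BASES[int(rng.choice(4, p=freqs[:, i]))] for i in range(motif.width)
        )
    from .tfbs import parse_pattern  # local import: tfbs does not import synthdata

    sets = parse_pattern(motif)
    return "".join(s[int(rng.integers(len(s)))] for s in sets)


def _motif_width(motif) -> int:
    if isinstance(motif, PWM):
        return motif.width
    from .tfbs import parse_pattern

    return len(parse_pattern(motif))


def plant_motifs(
    genome: dict,
    true_peaks: list[GenomicInterval],
    motif,
    config: SyntheticConfig,
    truth: SyntheticTruth | None = None,
    rng=None,
    rate: float | None = None,
) -> tuple[dict, SyntheticTruth]:
    """Overwrite a motif instance into each peak with probability ``rate``.

    Returns an updated genome (the input mapping is not modified) and the
    truth ledger with per-peak motif flags and (offset, strand) placements.
    """
    rng = rng or stage_rng(config.seed, "motifs")
    rate = config.motif_plant_rate if rate is None else rate
    width = _motif_width(motif)
    mutable = {c: bytearray(s, "ascii") for c, s in genome.items()}
    if truth is None:
        truth = SyntheticTruth(
            planted_peaks=list(true_peaks),
            peak_categories=["unlabeled"] * len(true_peaks),
        )
    flags: list[bool] = []
    placements: list[tuple[int, str] | None] = []
    for iv in true_peaks:
        if width > iv.length:
            warnings.warn(
                f"motif width {width} exceeds peak length {iv.length}; skipping"
            )
            flags.append(False)
            placements.append(None)
            continue
        if rng.random() >= rate:
            flags.append(False)
            placements.append(None)
            continue
        offset = int(rng.integers(0, iv.length - width + 1))
        strand = "+" if rng.random() < 0.5 else "-"
        word = sample_motif_instance(motif, rng)
        if strand == "-":
            word = revcomp(word)
        pos = iv.start + offset
        mutable[iv.chrom][pos : pos + width] = word.encode()
        flags.append(True)
        placements.append((offset, strand))
    truth.motif_flags = flags
    truth.motif_placements = placements
    new_genome = OrderedDict((c, b.decode()) for c, b in mutable.items())
    return new_genome, truth


def peak_sequences(genome: dict, peaks) -> list[str]:
    """Extract the sequence under each peak interval."""
    return [genome[p.chrom][p.start : p.end] for p in peaks]


# ---------------------------------------------------------------------------
# expression / differential expression


def simulate_expression_and_de(
    genes: list[GeneModel],
    config: SyntheticConfig,
    rng=None,
    fc_threshold: float = 1.5,
) -> pd.DataFrame:
    """Heavy-tailed expression levels plus signed fold changes.

    Exactly ``de_up`` genes get fold change > fc_threshold and ``de_down``
    get fold change < -fc_threshold; all other genes fall strictly inside
    (-fc_threshold, fc_threshold).
    """
    if not genes:
        raise ValueError("no genes to simulate expression for")
    n = len(genes)
    if config.de_up + config.de_down > n:
        raise ValueError("de_up + de_down exceeds the number of genes")
    rng = rng or stage_rng(config.seed, "expression")
    expr = rng.lognormal(mean=1.0, sigma=1.2, size=n)
    fc = rng.uniform(-fc_threshold + 0.05, fc_threshold - 0.05, size=n)
    label = np.array(["null"] * n, dtype=object)
    perm = rng.permutation(n)
    up_idx = perm[: config.de_up]
    down_idx = perm[config.de_up : config.de_up + config.de_down]
    fc[up_idx] = rng.uniform(fc_threshold + 0.1, 4.0, size=config.de_up)
    fc[down_idx] = -rng.uniform(fc_threshold + 0.1, 4.0, size=config.de_down)
    label[up_idx] = "up"
    label[down_idx] = "down"
    return pd.DataFrame(
        {
            "gene_id": [g.gene_id for g in genes],
            "expr": expr,
            "fold_change": fc,
            "de_label": label,
        }
    )


# ---------------------------------------------------------------------------
# DNase hypersensitive sites


def simulate_dhs(
    genome: dict,
    true_peaks: list[GenomicInterval],
    config: SyntheticConfig,
    truth: SyntheticTruth | None = None,
    rng=None,
    margin: int = 1000,
    far_distance: int = 5000,
    rate: float | None = None,
) -> tuple[list[GenomicInterval], SyntheticTruth]:
    """Give a fraction of peaks a nearby DNase site; scatter the rest far away.

    A flagged peak receives one DHS interval overlapping
    [peak.start - margin, peak.end + margin); background DHS are placed at
    least ``far_distance`` bp from every peak.
    """
    if not true_peaks:
        raise ValueError("no peaks to attach DNase sites to")
    rng = rng or stage_rng(config.seed, "dhs")
    rate = config.dhs_overlap_rate if rate is None else rate
    if truth is None:
        truth = SyntheticTruth(
            planted_peaks=list(true_peaks),
            peak_categories=["unlabeled"] * len(true_peaks),
        )
    chrom_lens = {c: len(s) for c, s in genome.items()}
    peaks_by_chrom: dict[str, list[GenomicInterval]] = {}
    for iv in true_peaks:
        peaks_by_chrom.setdefault(iv.chrom, []).append(iv)
    sites: list[GenomicInterval] = []
    flags: list[bool] = []
    for iv in true_peaks:
        if rng.random() < rate:
            length = int(rng.integers(150, 301))
            lo = max(0, iv.start - margin)
            hi = min(chrom_lens[iv.chrom], iv.end + margin) - length
            # avoid the margin zones of *other* peaks so the flag stays a
            # property of this peak alone; fall back after capped retries
            others = peaks_by_chrom[iv.chrom]
            start = None
            for _try in range(100):
                cand = int(rng.integers(lo, max(lo + 1, hi)))
                clash = any(
                    o is not iv
                    and cand < o.end + margin
                    and o.start - margin < cand + length
                    for o in others
                )
                if not clash:
                    start = cand
                    break
            if start is None:
                start = int(rng.integers(lo, max(lo + 1, hi)))
            sites.append(GenomicInterval(iv.chrom, start, start + length))
            flags.append(True)
        else:
            flags.append(False)
    n_bg = (
        config.n_background_dhs
        if config.n_background_dhs is not None
        else len(true_peaks)
    )
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for iv in true_peaks:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    chroms = list(genome)
    for _ in range(n_bg):
        for _try in range(1000):
            chrom = chroms[int(rng.integers(len(chroms)))]
            length = int(rng.integers(150, 301))
            if chrom_lens[chrom] <= length:
                continue
            start = int(rng.integers(0, chrom_lens[chrom] - length))
            end = start + length
            near = any(
                start < p.end + far_distance and p.start - far_distance < end
                for p in by_chrom.get(chrom, [])
            )
            if not near:
                sites.append(GenomicInterval(chrom, start, end))
                break
    truth.dhs_flags = flags
    sites.sort(key=lambda iv: (iv.chrom, iv.start))
    return sites, truth


# ---------------------------------------------------------------------------
# targeted placement helpers for profile / DE analyses


def place_tss_peaks(
    genes: list[GeneModel],
    gene_ids: list[str],
    config: SyntheticConfig,
    rng=None,
    max_offset: int = 2000,
) -> list[GenomicInterval]:
    """One peak per listed gene with midpoint within ±max_offset of its TSS."""
    rng = rng or stage_rng(config.seed, "peaks")
    by_id = {g.gene_id: g for g in genes}
    out = []
    for gid in gene_ids:
        g = by_id[gid]
        length = _draw_peak_length(config, rng)
        mid = g.tss + int(rng.integers(-max_offset, max_offset + 1))
        start = max(0, mid - length // 2)
        out.append(GenomicInterval(g.chrom, start, start + length))
    return out


def place_tss_flank_peaks(
    genes: list[GeneModel],
    gene_ids: list[str],
    config: SyntheticConfig,
    rng=None,
    window: int = 10_000,
    exclusion: int = 1000,
    peaks_per_gene: int = 3,
) -> list[GenomicInterval]:
    """Peaks in the TSS flanks but depleted within ±exclusion of the TSS.

    Produces the V-shaped metaprofile geometry: offsets are drawn uniformly
    from ±[exclusion, window], never inside the exclusion zone.
    """
    rng = rng or stage_rng(config.seed, "peaks")
    by_id = {g.gene_id: g for g in genes}
    out = []
    for gid in gene_ids:
        g = by_id[gid]
        for _ in range(peaks_per_gene):
            length = _draw_peak_length(config, rng)
            off = int(rng.integers(exclusion, window + 1))
            if rng.random() < 0.5:
                off = -off
            # offsets are strand-oriented (positive = downstream of TSS)
            mid = g.tss + off if g.strand == "+" else g.tss - off
            start = max(0, mid - length // 2)
            out.append(GenomicInterval(g.chrom, start, start + length))
    return out


# ---------------------------------------------------------------------------
# synthetic PWM library


def random_pwm_library(
    n: int,
    width: int = 10,
    identity: float = 0.85,
    seed: int = 0,
    prefix: str = "TF",
) -> list[PWM]:
    """Random-consensus PWM library standing in for a curated TF collection."""
    rng = np.random.default_rng([seed % (2**31), _STAGE["pwmlib"]])
    lib = []
    for i in range(n):
        consensus = "".join(BASES[int(b)] for b in rng.integers(0, 4, size=width))
        lib.append(consensus_to_pwm(consensus, identity, pwm_id=f"{prefix}{i + 1:03d}"))
    return lib


# ---------------------------------------------------------------------------
# whole-study convenience bundle


@dataclass
class SyntheticStudy:
    config: SyntheticConfig
    genome: dict
    genes: list[GeneModel]
    peaks: list[GenomicInterval]
    truth: SyntheticTruth
    tracks: list[ProbeTrack]
    expression: pd.DataFrame
    dhs: list[GenomicInterval]


def generate_study(
    config: SyntheticConfig | None = None, motif=DEFAULT_MOTIF
) -> SyntheticStudy:
    """Run every generator stage in order and bundle the results."""
    config = config or SyntheticConfig()
    genome = generate_genome(config)
    genes = generate_gene_models(genome, config)
    peaks, truth = plant_enrichment(genome, genes, config)
    genome, truth = plant_motifs(genome, peaks, motif, config, truth)
    tracks = simulate_probe_track(genome, peaks, config)
    expression = simulate_expression_and_de(genes, config)
    dhs, truth = simulate_dhs(genome, peaks, config, truth)
    truth.de_labels = dict(zip(expression["gene_id"], expression["de_label"]))
    truth.validate(genome)
    return SyntheticStudy(config, genome, genes, peaks, truth, tracks, expression, dhs)
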