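"""Peak-to-feature annotation, peak-gene mapping and density tracks.

A peak is represented by its midpoint and assigned exactly one feature
category with fixed precedence promoter > tes > coding > exon > intron >
intergenic. The promoter window is upstream-only in gene orientation; the
peak-to-gene link window is two-sided around the TSS.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .types import GeneModel, GenomicInterval

CATEGORIES = ("promoter", "tes", "coding", "exon", "intron", "intergenic")


class GenomeAnnotator:
    """Classifies genomic points against a set of gene models.

    promoter: within ``promoter_window`` bp upstream of a TSS (strand-
    oriented, TSS included); tes: within ``tes_window`` bp downstream of a
    TES; coding: inside a CDS; exon: inside a non-CDS exon; intron: inside a
    gene body but not in an exon; intergenic otherwise.
    """

    def __init__(
        self,
        genes: list[GeneModel],
        promoter_window: int = 10_000,
        tes_window: int = 10_000,
        precedence: tuple = CATEGORIES,
    ):
        if set(precedence) != set(CATEGORIES):
            raise ValueError("precedence must be a permutation of the categories")
        self.promoter_window = promoter_window
        self.tes_window = tes_window
        self.precedence = precedence
        self._by_chrom: dict[str, list[GeneModel]] = {}
        for g in genes:
            self._by_chrom.setdefault(g.chrom, []).append(g)

    def _matches(self, g: GeneModel, pos: int, category: str) -> bool:
        if category == "promoter":
            if g.strand == "+":
                return g.tss - self.promoter_window <= pos <= g.tss
            return g.tss <= pos <= g.tss + self.promoter_window
        if category == "tes":
            if g.strand == "+":
                return g.tes <= pos <= g.tes + self.tes_window
            return g.tes - self.tes_window <= pos <= g.tes
        if category == "coding":
            # CDS bases are exonic positions inside the CDS bounds
            in_exon = any(s <= pos < e for s, e in g.exons)
            return in_exon and g.cds_start <= pos < g.cds_end
        if category == "exon":
            in_exon = any(s <= pos < e for s, e in g.exons)
            return in_exon and not (g.cds_start <= pos < g.cds_end)
        if category == "intron":
            in_body = g.tx_start <= pos < g.tx_end
            return in_body and not any(s <= pos < e for s, e in g.exons)
        raise ValueError(category)

    def classify(self, chrom: str, pos: int) -> str:
        genes = self._by_chrom.get(chrom, [])
        for category in self.precedence:
            if category == "intergenic":
                return "intergenic"
            for g in genes:
                if self._matches(g, pos, category):
                    return category
        return "intergenic"


def assign_category(
    peak,
    genes: list[GeneModel],
    promoter_window: int = 10_000,
    tes_window: int = 10_000,
    annotator: GenomeAnnotator | None = None,
) -> str:
    """Feature category of a peak, decided by its midpoint."""
    annotator = annotator or GenomeAnnotator(genes, promoter_window, tes_window)
    iv = peak.interval if hasattr(peak, "interval") else peak
    return annotator.classify(iv.chrom, iv.midpoint)


def summarize_categories(
    peaks,
    genes: list[GeneModel],
    promoter_window: int = 10_000,
    tes_window: int = 10_000,
) -> pd.DataFrame:
    """Percentage of peaks per feature category (always totals 100)."""
    if not peaks:
        raise ValueError("no peaks to summarize")
    annot = GenomeAnnotator(genes, promoter_window, tes_window)
    labels = [assign_category(p, genes, annotator=annot) for p in peaks]
    counts = {c: 0 for c in CATEGORIES}
    for lab in labels:
        counts[lab] += 1
    n = len(labels)
    return pd.DataFrame(
        {
            "category": list(CATEGORIES),
            "count": [counts[c] for c in CATEGORIES],
            "percent": [100.0 * counts[c] / n for c in CATEGORIES],
        }
    )


@dataclass(frozen=True)
class PeakGeneLink:
    """A peak whose midpoint lies within the TSS window of a gene.

    ``offset`` is the strand-oriented signed distance of the peak midpoint
    from the TSS (negative = upstream of the gene).
    """

    peak_index: int
    gene_id: str
    offset: int


def map_peaks_to_genes(
    peaks, genes: list[GeneModel], window: int = 10_000
) -> tuple[list[PeakGeneLink], int, int]:
    """Link peaks to genes whose TSS lies within ±window of the peak midpoint.

    The window is closed: |offset| == window still links. Returns the link
    list plus the number of distinct peaks and distinct genes linked.
    """
    if window <= 0:
        raise ValueError("window must be positive")
    links = []
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    for pi, p in enumerate(peaks):
        iv = p.interval if hasattr(p, "interval") else p
        mid = iv.midpoint
        for g in by_chrom.get(iv.chrom, []):
            delta = mid - g.tss
            offset = delta if g.strand == "+" else -delta
            if -window <= offset <= window:
                links.append(PeakGeneLink(pi, g.gene_id, offset))
    n_peaks = len({l.peak_index for l in links})
    n_genes = len({l.gene_id for l in links})
    return links, n_peaks, n_genes


def density_track(
    peaks, chrom_lengths: dict, bin: int = 1_000_000
) -> pd.DataFrame:
    """Binned peak-midpoint counts per chromosome, reported as log2(count+1)."""
    if bin <= 0:
        raise ValueError("bin must be positive")
    rows = []
    mids: dict[str, list[int]] = {c: [] for c in chrom_lengths}
    for p in peaks:
        iv = p.interval if hasattr(p, "interval") else p
        if iv.chrom in mids:
            mids[iv.chrom].append(iv.midpoint)
    for chrom in sorted(chrom_lengths):
        n_bins = max(1, -(-chrom_lengths[chrom] // bin))
        counts = np.zeros(n_bins, dtype=np.int64)
        if mids[chrom]:
            idx = np.asarray(mids[chrom]) // bin
            np.add.at(counts, np.clip(idx, 0, n_bins - 1), 1)
        for b in range(n_bins):
            rows.append(
                {
                    "chrom": chrom,
                    "bin_start": b * bin,
                    "bin_end": min((b + 1) * bin, chrom_lengths[chrom]),
                    "count": int(counts[b]),
                    "log2_density": float(np.log2(counts[b] + 1)),
                }
            )
    return pd.DataFrame(rows)


def gene_peak_density_correlation(
    peaks, genes: list[GeneModel], chrom_lengths: dict, bin: int = 100_000
):
    """Pearson correlation of per-bin gene and peak midpoint counts.

    Returns None when either binned vector has zero variance (the
    correlation is undefined, not zero).
    """
    if bin <= 0:
        raise ValueError("bin must be positive")
    gene_counts, peak_counts = [], []
    for chrom in sorted(chrom_lengths):
        n_bins = max(1, -(-chrom_lengths[chrom] // bin))
        gc = np.zeros(n_bins)
        pc = np.zeros(n_bins)
        for g in genes:
            if g.chrom == chrom:
                b = min(((g.tx_start + g.tx_end) // 2) // bin, n_bins - 1)
                gc[b] += 1
        for p in peaks:
            iv = p.interval if hasattr(p, "interval") else p
            if iv.chrom == chrom:
                pc[min(iv.midpoint // bin, n_bins - 1)] += 1
        gene_counts.append(gc)
        peak_counts.append(pc)
    x = np.concatenate(gene_counts)
    y = np.concatenate(peak_counts)
    if x.size < 2 or np.std(x) == 0 or np.std(y) == 0:
        return None
    return float(np.corrcoef(x, y)[0, 1])


def annotate_peaks(
    peaks, genes: list[GeneModel], promoter_window: int = 10_000,
    tes_window: int = 10_000,
) -> pd.DataFrame:
    """Per-peak annotation table (coordinates, score, FDR, category)."""
    annot = GenomeAnnotator(genes, promoter_window, tes_window)
    rows = []
    for i, p in enumerate(peaks):
        iv = p.interval if hasattr(p, "interval") else p
        rows.append(
            {
                "peak_id": f"peak{i + 1}",
                "chrom": iv.chrom,
                "start": iv.start,
                "end": iv.end,
                "score": getattr(p, "score", np.nan),
                "fdr": getattr(p, "fdr", np.nan),
                "category": annot.classify(iv.chrom, iv.midpoint),
            }
        )
    return pd.DataFrame(rows)
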