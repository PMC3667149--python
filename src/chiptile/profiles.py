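"""Expression-stratified TSS metaprofiles, DE intersection, DHS co-occurrence.

Genes are split into expression tertile groups (top 30% / middle 40% /
bottom 30%); peak midpoints within ±10 kb of a group's TSSs are histogrammed
in strand-oriented coordinates (positive = downstream of the TSS). The
differential-expression intersection counts linked genes past a signed
fold-change threshold, and DHS co-occurrence measures the fraction of peaks
with an open-chromatin interval within a ±1 kb margin.
"""

from __future__ import annotations

import math
import warnings

import numpy as np
import pandas as pd

from .annotate import PeakGeneLink
from .types import GeneModel, GenomicInterval

GROUPS = ("top30", "middle40", "bottom30")


def tertile_split(
    expression: pd.DataFrame, fractions: tuple = (0.30, 0.40, 0.30)
) -> dict:
    """Partition genes into expression groups by descending expression rank.

    Group sizes are ceil(f1*n) and ceil(f2*n) with the remainder in the
    bottom group; expression ties are broken by gene id so the split is
    deterministic.
    """
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    df = expression.sort_values(
        ["expr", "gene_id"], ascending=[False, True]
    ).reset_index(drop=True)
    n = len(df)
    n_top = math.ceil(fractions[0] * n)
    n_mid = math.ceil(fractions[1] * n)
    ids = df["gene_id"].tolist()
    return {
        "top30": ids[:n_top],
        "middle40": ids[n_top : n_top + n_mid],
        "bottom30": ids[n_top + n_mid :],
    }


def tss_metaprofile(
    peaks,
    genes: list[GeneModel],
    group_gene_ids: list[str],
    window: int = 10_000,
    bin: int = 200,
    label: str = "",
    coverage: bool = False,
) -> pd.DataFrame:
    """Histogram of peak positions around the TSSs of one gene group.

    Offsets are strand-oriented (negative = upstream in gene orientation).
    ``density`` normalizes counts by the number of genes in the group. By
    default each (peak, gene) pair contributes one midpoint event; with
    ``coverage`` every bin the peak body overlaps is incremented instead.
    """
    if (2 * window) % bin != 0:
        raise ValueError("bin must divide 2*window")
    wanted = set(group_gene_ids)
    group = [g for g in genes if g.gene_id in wanted]
    edges = np.arange(-window, window + bin, bin)
    counts = np.zeros(edges.size - 1, dtype=np.int64)
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in group:
        by_chrom.setdefault(g.chrom, []).append(g)
    for p in peaks:
        iv = p.interval if hasattr(p, "interval") else p
        for g in by_chrom.get(iv.chrom, []):
            if coverage:
                lo, hi = iv.start - g.tss, iv.end - g.tss
                if g.strand == "-":
                    lo, hi = -hi, -lo
                first = max(int(np.floor(lo / bin)), -window // bin)
                last = min(int(np.ceil(hi / bin)), window // bin)
                for b in range(first, last):
                    lo_edge, hi_edge = b * bin, (b + 1) * bin
                    if lo < hi_edge and lo_edge < hi:
                        counts[b + window // bin] += 1
            else:
                delta = iv.midpoint - g.tss
                offset = delta if g.strand == "+" else -delta
                if -window <= offset < window:
                    counts[(offset + window) // bin] += 1
    n_genes = max(len(group), 1)
    return pd.DataFrame(
        {
            "group": label or "group",
            "bin_start": edges[:-1],
            "bin_end": edges[1:],
            "count": counts,
            "density": counts / n_genes,
        }
    )


def expression_metaprofiles(
    peaks,
    genes: list[GeneModel],
    expression: pd.DataFrame,
    window: int = 10_000,
    bin: int = 200,
    fractions: tuple = (0.30, 0.40, 0.30),
) -> pd.DataFrame:
    """TSS metaprofiles for the three expression tertile groups, long format."""
    groups = tertile_split(expression, fractions)
    frames = [
        tss_metaprofile(peaks, genes, groups[name], window, bin, label=name)
        for name in GROUPS
    ]
    return pd.concat(frames, ignore_index=True)


def intersect_de_genes(
    links: list[PeakGeneLink],
    expression: pd.DataFrame,
    fc_threshold: float = 1.5,
) -> tuple[list[str], list[str]]:
    """Peak-linked genes past the signed fold-change threshold.

    Returns (up-regulated, down-regulated) gene id lists, each gene counted
    once regardless of how many peaks link to it.
    """
    fc = dict(zip(expression["gene_id"], expression["fold_change"]))
    linked = sorted({l.gene_id for l in links})
    up, down = [], []
    for gid in linked:
        if gid not in fc or pd.isna(fc[gid]):
            warnings.warn(f"no fold change for linked gene {gid}; skipped")
            continue
        if fc[gid] > fc_threshold:
            up.append(gid)
        elif fc[gid] < -fc_threshold:
            down.append(gid)
    return up, down


def dhs_cooccurrence(
    peaks, dhs: list[GenomicInterval], margin: int = 1000
) -> tuple[float, list[bool]]:
    """Fraction of peaks with >= 1 DHS overlapping [start-margin, end+margin).

    The margin window is half-open: a DHS starting exactly at end+margin
    does not count.
    """
    if margin < 0:
        raise ValueError("margin must be >= 0")
    by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    tmp: dict[str, list[tuple[int, int]]] = {}
    for d in dhs:
        tmp.setdefault(d.chrom, []).append((d.start, d.end))
    for chrom, pairs in tmp.items():
        pairs.sort()
        starts = np.array([p[0] for p in pairs])
        ends = np.array([p[1] for p in pairs])
        # max_end_so_far allows a single binary search per peak
        by_chrom[chrom] = (starts, np.maximum.accumulate(ends))
    flags = []
    for p in peaks:
        iv = p.interval if hasattr(p, "interval") else p
        lo = iv.start - margin
        hi = iv.end + margin
        hit = False
        if iv.chrom in by_chrom:
            starts, cummax_ends = by_chrom[iv.chrom]
            i = np.searchsorted(starts, hi, side="left")  # dhs.start < hi
            hit = i > 0 and cummax_ends[i - 1] > lo  # dhs.end > lo
        flags.append(bool(hit))
    frac = float(np.mean(flags)) if flags else 0.0
    return frac, flags
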