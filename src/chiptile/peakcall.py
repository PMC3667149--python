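"""Sliding-window, cutoff-ladder peak calling with permutation FDR.

The caller mirrors the classic tiling-array detection scheme: a scaling
anchor (the "hypothetical maximum", mean + k*sd of a chromosome's log2
ratios) defines a descending ladder of absolute cutoffs (default 90% down to
15% in 1% steps). At each rung, probes above the cutoff are grouped and a
group qualifies as enriched when either

* some ``min_probes`` of its above-cutoff probes fit inside one sliding
  window of ``window`` bp, or
* it contains a run of at least ``min_probes_all_above`` consecutive track
  probes that are all above the cutoff (no below-cutoff probe in between).

Above-cutoff probes separated by at most ``window`` bp merge into one
region. A peak's score is the highest rung percentage at which any part of
it qualifies; lower rungs only extend boundaries. The false discovery rate
per score level is estimated by re-calling peaks on permutations of the
ratio values over the fixed probe positions.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .types import GenomicInterval, Peak, ProbeTrack


@dataclass
class PeakCallParams:
    """Detection parameters; defaults follow the standard tiling-array setup."""

    p_start: float = 90.0  # ladder top, percent of the hypothetical maximum
    p_step: float = 1.0  # ladder decrement, percent
    n_steps: int = 76  # number of rungs (90% down to 15% by default)
    min_probes: int = 4  # above-cutoff probes required in one window
    # length of a consecutive all-above run that qualifies alone; 4 (the
    # default) folds this rule into the window rule, because under the
    # shuffled-ratio permutation null two-probe runs occur often enough to
    # put a ~1-2% floor under every estimated FDR, defeating control at
    # 0.005 (see docs/methods.md); set to 2 for the permissive variant
    min_probes_all_above: int = 4
    window: int = 500  # sliding window width, bp
    fdr_max: float = 0.005  # strict FDR filter threshold
    n_permutations: int = 20
    # sd multiplier in the hypothetical maximum: 12 places the ladder's
    # bottom rung (15%) near 1.8 noise sd, so boundary extension at low
    # rungs does not chain through 1-sd noise probes
    hypmax_k: float = 12.0
    seed: int = 0
    global_ladder: bool = False  # one ladder from pooled ratios instead of per-chromosome

    def __post_init__(self):
        if self.p_start - self.p_step * (self.n_steps - 1) <= 0:
            raise ValueError("ladder must stay strictly positive")
        if self.min_probes_all_above > self.min_probes:
            raise ValueError("min_probes_all_above must be <= min_probes")
        if self.window < 1:
            raise ValueError("window must be >= 1 bp")
        if not (0 < self.fdr_max <= 1):
            raise ValueError("fdr_max must be in (0, 1]")


def hypothetical_maximum(track: ProbeTrack, k: float = 6.0) -> float:
    """Scaling anchor: mean + k * population standard deviation of the ratios."""
    if len(track) < 2:
        raise ValueError("hypothetical maximum needs at least 2 probes")
    r = track.ratios
    return float(r.mean() + k * r.std())


def ladder(params: PeakCallParams, hypmax: float) -> list[tuple[float, float]]:
    """Descending (percentage, absolute cutoff) rungs of the cutoff ladder."""
    rungs = []
    for i in range(params.n_steps):
        pct = params.p_start - i * params.p_step
        if pct <= 0:
            raise ValueError("ladder percentage fell to zero or below")
        rungs.append((pct, pct / 100.0 * hypmax))
    return rungs


def call_peaks_at_cutoff(
    track: ProbeTrack, cutoff: float, params: PeakCallParams
) -> list[GenomicInterval]:
    """Enriched intervals at one absolute cutoff.

    Returns maximal merged groups of above-cutoff probes that satisfy the
    window rule or the consecutive all-above rule; each interval spans from
    the first above-cutoff probe start to the last plus one probe spacing.
    """
    if len(track) == 0:
        return []
    above = track.ratios > cutoff
    idx = np.flatnonzero(above)
    if idx.size == 0:
        return []
    pos = track.positions[idx]
    # merge above-cutoff probes separated by <= window bp
    new_cluster = np.zeros(idx.size, dtype=bool)
    if idx.size > 1:
        new_cluster[1:] = np.diff(pos) > params.window
    cid = np.cumsum(new_cluster)

    qual = np.zeros(int(cid[-1]) + 1, dtype=bool)

    m = params.min_probes
    if idx.size >= m:
        # m above-cutoff probes inside one window: start span < window bp,
        # and all m in the same cluster
        span_ok = (pos[m - 1 :] - pos[: idx.size - m + 1]) < params.window
        same = cid[m - 1 :] == cid[: idx.size - m + 1]
        hit = span_ok & same
        if hit.any():
            np.logical_or.at(qual, cid[: idx.size - m + 1][hit], True)

    n2 = params.min_probes_all_above
    if idx.size >= n2:
        if n2 == 1:
            qual[:] = True
        else:
            consec = np.diff(idx) == 1  # adjacent in the full track
            # run of n2 probes needs n2-1 consecutive True values
            runlen = np.convolve(consec.astype(int), np.ones(n2 - 1, dtype=int), "valid")
            hit = (runlen == n2 - 1) & (cid[: runlen.size] == cid[n2 - 1 :])
            if hit.any():
                np.logical_or.at(qual, cid[: runlen.size][hit], True)

    intervals = []
    starts = np.flatnonzero(new_cluster)
    bounds = np.concatenate([[0], starts, [idx.size]])
    for c in range(qual.size):
        if qual[c]:
            first, last = bounds[c], bounds[c + 1] - 1
            intervals.append(
                GenomicInterval(
                    track.chrom, int(pos[first]), int(pos[last]) + track.spacing
                )
            )
    return intervals


def _merge_rung(
    peaks: list[list], rung_intervals: list[GenomicInterval], pct: float
) -> None:
    """Fold one rung's intervals into the accumulating peak list (in place).

    Each entry is [start, end, score]. Overlapping entries merge; the higher
    rung's score wins (rungs are processed in descending order, so existing
    scores are always >= pct).
    """
    for iv in rung_intervals:
        start, end, score = iv.start, iv.end, pct
        keep = []
        for p in peaks:
            if p[0] < end and start < p[1]:
                start = min(start, p[0])
                end = max(end, p[1])
                score = max(score, p[2])
            else:
                keep.append(p)
        keep.append([start, end, score])
        peaks[:] = keep


def call_peaks(track: ProbeTrack, params: PeakCallParams | None = None) -> list[Peak]:
    """Run the full cutoff ladder on one chromosome track."""
    params = params or PeakCallParams()
    if len(track) < 2:
        return []
    hypmax = hypothetical_maximum(track, params.hypmax_k)
    return call_peaks_with_ladder(track, params, ladder(params, hypmax))


def call_peaks_with_ladder(
    track: ProbeTrack, params: PeakCallParams, rungs: list[tuple[float, float]]
) -> list[Peak]:
    merged: list[list] = []
    for pct, cutoff in rungs:  # descending
        ivs = call_peaks_at_cutoff(track, cutoff, params)
        _merge_rung(merged, ivs, pct)
    merged.sort(key=lambda p: p[0])
    out = []
    cutoff_of = {pct: cut for pct, cut in rungs}
    for start, end, score in merged:
        sel = (track.positions >= start) & (track.positions < end)
        ratios = track.ratios[sel]
        n_above = int((ratios > cutoff_of[score]).sum())
        out.append(
            Peak(
                interval=GenomicInterval(track.chrom, start, end),
                score=score,
                n_probes=n_above,
                mean_ratio=float(ratios.mean()) if ratios.size else float("nan"),
            )
        )
    return out


def call_peaks_genome(
    tracks: list[ProbeTrack], params: PeakCallParams | None = None
) -> list[Peak]:
    """Call peaks on every chromosome track.

    The ladder is computed per chromosome by default; with
    ``params.global_ladder`` one ladder is derived from the pooled ratios.
    """
    params = params or PeakCallParams()
    peaks: list[Peak] = []
    rungs_global = None
    if params.global_ladder:
        pooled = np.concatenate([t.ratios for t in tracks])
        hyp = float(pooled.mean() + params.hypmax_k * pooled.std())
        rungs_global = ladder(params, hyp)
    for track in sorted(tracks, key=lambda t: t.chrom):
        if len(track) < 2:
            continue
        rungs = rungs_global or ladder(
            params, hypothetical_maximum(track, params.hypmax_k)
        )
        peaks.extend(call_peaks_with_ladder(track, params, rungs))
    return peaks


def estimate_fdr(
    tracks: list[ProbeTrack],
    peaks: list[Peak],
    params: PeakCallParams | None = None,
) -> list[Peak]:
    """Permutation FDR per score level, pooled over the genome.

    Ratios are shuffled over the fixed probe positions within each
    chromosome; peaks are re-called on each permutation. FDR(s) = mean
    permuted count of peaks with score >= s divided by the observed count,
    clipped to [0, 1] and made monotone non-increasing in s.
    """
    params = params or PeakCallParams()
    if params.n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    if not peaks:
        return []
    rng = np.random.default_rng(params.seed)
    obs_scores = np.array([p.score for p in peaks])
    levels = np.unique(obs_scores)[::-1]  # descending
    null_counts = np.zeros(levels.size)
    for _ in range(params.n_permutations):
        perm_scores = []
        for track in tracks:
            shuffled = ProbeTrack(
                track.chrom,
                track.positions,
                rng.permutation(track.ratios),
                track.spacing,
            )
            perm_scores.extend(p.score for p in call_peaks(shuffled, params))
        perm_scores = np.asarray(perm_scores)
        for li, s in enumerate(levels):
            null_counts[li] += (perm_scores >= s).sum()
    null_mean = null_counts / params.n_permutations
    fdr_by_level = {}
    running = 0.0  # enforce monotone non-increasing FDR in score
    for li, s in enumerate(levels):
        observed = (obs_scores >= s).sum()
        raw = min(1.0, null_mean[li] / observed) if observed else 1.0
        running = max(running, raw)
        fdr_by_level[s] = running
    return [replace(p, fdr=fdr_by_level[p.score]) for p in peaks]


def filter_peaks(peaks: list[Peak], fdr_max: float = 0.005) -> list[Peak]:
    """Keep peaks with FDR strictly below the threshold; order preserved."""
    return [p for p in peaks if p.fdr < fdr_max]


def call_and_filter(
    tracks: list[ProbeTrack], params: PeakCallParams | None = None
) -> tuple[list[Peak], list[Peak]]:
    """Convenience: call, FDR-annotate, and filter; returns (all, filtered)."""
    params = params or PeakCallParams()
    peaks = call_peaks_genome(tracks, params)
    peaks = estimate_fdr(tracks, peaks, params)
    return peaks, filter_peaks(peaks, params.fdr_max)
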