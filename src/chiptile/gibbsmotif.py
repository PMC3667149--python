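"""Fixed-width Gibbs site-sampler motif discovery over peak sequences.

A classical one-occurrence-per-sequence (OOPS) sampler: each sequence holds
one candidate site (offset + strand). Per sweep, each sequence in turn is
held out, the PWM is re-estimated with Dirichlet pseudocounts from the other
sequences' sites, and the held-out sequence's site is re-sampled over both
strands proportional to the PWM/background likelihood ratio. Every 100
sweeps a global phase-shift move (all sites +/-1..3 columns, accepted on
improvement) guards against phase-locked optima. The best-scoring state
across all sweeps is returned.

The motif score is the log-likelihood ratio
``F = sum_cols sum_bases c(i,b) * log(q(i,b) / p(b))`` with c the site
counts, q the pseudocounted column frequencies, and p the 0-order background
estimated from the input sequences.
"""

from __future__ import annotations

import warnings

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .types import MotifModel, PWM, encode_seq

_PHASE_PERIOD = 100  # sweeps between phase-shift proposals
_PHASE_SHIFTS = (-3, -2, -1, 1, 2, 3)


def _background_from_codes(codes_list) -> np.ndarray:
    counts = np.zeros(4)
    for codes in codes_list:
        valid = codes[codes < 4]
        counts += np.bincount(valid, minlength=4)
    total = counts.sum()
    if total == 0:
        return np.full(4, 0.25)
    return counts / total


class _SeqWindows:
    """Concatenated forward + reverse-complement windows of one sequence.

    Window index i < n_fwd is the forward window at offset i; i >= n_fwd is
    the reverse-complement window at reverse offset i - n_fwd. ``flat``
    holds ravel indices into a (5, width) log-odds matrix (row 4 = non-ACGT,
    always -inf), so one gather scores every window on both strands.
    """

    def __init__(self, codes: np.ndarray, width: int):
        fwd = sliding_window_view(codes, width)
        rc = 3 - codes[::-1].astype(np.int64)
        rc[rc < 0] = 4  # non-ACGT stays ineligible
        rev = sliding_window_view(rc, width)
        self.n_fwd = fwd.shape[0]
        self.wins = np.concatenate([fwd, rev]).astype(np.int64)
        self.valid = ~(self.wins == 4).any(axis=1)
        self.flat = self.wins * width + np.arange(width)
        self.seq_len = codes.size

    def site(self, pick: int, width: int) -> tuple[int, str]:
        """(forward-coordinate offset, strand) of a window index."""
        if pick < self.n_fwd:
            return pick, "+"
        return self.seq_len - width - (pick - self.n_fwd), "-"


def motif_score(counts: np.ndarray, background: np.ndarray,
                pseudo_total: float = 1.0) -> float:
    """Log-likelihood-ratio score F of a count matrix against the background."""
    q = counts + background[:, None] * pseudo_total
    q = q / q.sum(axis=0, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        ll = counts * np.log(q / background[:, None])
    return float(np.nansum(ll))


def _counts_from_picks(seqs: list[_SeqWindows], picks, width) -> np.ndarray:
    counts = np.zeros((4, width))
    cols = np.arange(width)
    for sw, pick in zip(seqs, picks):
        counts[sw.wins[pick], cols] += 1
    return counts


def gibbs_sample(
    sequences: list[str],
    width: int = 12,
    iterations: int = 5000,
    seed: int = 0,
    pseudo_total: float = 1.0,
    background: np.ndarray | None = None,
) -> MotifModel:
    """Discover one fixed-width motif by OOPS Gibbs sampling.

    Sequences shorter than ``width`` (or without any ACGT-only window) are
    excluded with a warning. Returns the best state observed across all
    sweeps; a fixed ``seed`` gives a fully deterministic result.
    """
    rng = np.random.default_rng(seed)
    kept_idx: list[int] = []
    seqs: list[_SeqWindows] = []
    for i, seq in enumerate(sequences):
        codes = encode_seq(seq)
        if codes.size < width:
            warnings.warn(f"sequence {i} shorter than motif width; excluded")
            continue
        sw = _SeqWindows(codes, width)
        if not sw.valid.any():
            warnings.warn(f"sequence {i} has no ACGT-only window; excluded")
            continue
        kept_idx.append(i)
        seqs.append(sw)
    n = len(seqs)
    if n < 2:
        raise ValueError("need at least 2 usable sequences")
    if background is None:
        background = _background_from_codes(
            [encode_seq(sequences[i]) for i in kept_idx]
        )
    background = np.asarray(background, dtype=float)
    log_bg = np.log(background)
    bg_pseudo = background[:, None] * pseudo_total
    cols = np.arange(width)

    picks = []
    for sw in seqs:
        valid_idx = np.flatnonzero(sw.valid)
        picks.append(int(valid_idx[int(rng.integers(valid_idx.size))]))

    counts = _counts_from_picks(seqs, picks, width)
    best_score = motif_score(counts, background, pseudo_total)
    best_picks = list(picks)
    lw5 = np.full((5, width), -np.inf)

    for sweep in range(iterations):
        for si in range(n):
            sw = seqs[si]
            counts[sw.wins[picks[si]], cols] -= 1  # hold out
            q = counts + bg_pseudo
            q /= q.sum(axis=0, keepdims=True)
            lw5[:4] = np.log(q) - log_bg[:, None]
            scores = lw5.ravel()[sw.flat].sum(axis=1)
            scores -= scores.max()
            np.exp(scores, out=scores)
            cdf = np.cumsum(scores)
            pick = int(np.searchsorted(cdf, rng.random() * cdf[-1], side="right"))
            pick = min(pick, scores.size - 1)
            picks[si] = pick
            counts[sw.wins[pick], cols] += 1
        score = motif_score(counts, background, pseudo_total)
        if score > best_score:
            best_score = score
            best_picks = list(picks)
        if (sweep + 1) % _PHASE_PERIOD == 0:
            counts, score = _try_phase_shift(
                seqs, picks, counts, score, background, pseudo_total, width
            )
            if score > best_score:
                best_score = score
                best_picks = list(picks)

    best_counts = _counts_from_picks(seqs, best_picks, width)
    pwm = PWM(id="gibbs_motif", counts=best_counts)
    sites = [
        (kept_idx[si], *seqs[si].site(best_picks[si], width))
        for si in range(n)
    ]
    sites = [(i, int(off), strand) for i, off, strand in sites]
    return MotifModel(pwm=pwm, sites=sites, score=best_score, background=background)


def _try_phase_shift(seqs, picks, counts, score, background, pseudo_total, width):
    """Propose shifting every site by a common offset; keep if score improves."""
    best = (score, None)
    for d in _PHASE_SHIFTS:
        shifted = []
        feasible = True
        for sw, pick in zip(seqs, picks):
            new_pick = pick + d
            # stay on the same strand segment of the concatenated windows
            if pick < sw.n_fwd:
                ok = 0 <= new_pick < sw.n_fwd
            else:
                ok = sw.n_fwd <= new_pick < sw.wins.shape[0]
            if not ok or not sw.valid[new_pick]:
                feasible = False
                break
            shifted.append(new_pick)
        if not feasible:
            continue
        new_counts = _counts_from_picks(seqs, shifted, width)
        new_score = motif_score(new_counts, background, pseudo_total)
        if new_score > best[0]:
            best = (new_score, (shifted, new_counts))
    if best[1] is not None:
        shifted, new_counts = best[1]
        picks[:] = shifted
        return new_counts, best[0]
    return counts, score


def information_content(pwm: PWM, background=None, per_column: bool = False):
    """Information content in bits: sum_cols sum_b q log2(q/p)."""
    q = pwm.frequencies()
    p = np.asarray(
        background if background is not None else np.full(4, 0.25), dtype=float
    )
    if np.any(p == 0) and np.any(q[p == 0, :] > 0):
        raise ValueError("zero background frequency with nonzero motif frequency")
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = q * np.log2(q / p[:, None])
    terms = np.nan_to_num(terms, nan=0.0)
    colsums = terms.sum(axis=0)
    return colsums if per_column else float(colsums.sum())


def _logodds_matrix(pwm: PWM, background) -> np.ndarray:
    q = pwm.frequencies()
    return np.log2(q / np.asarray(background, dtype=float)[:, None])


def best_window_logodds(seq_codes: np.ndarray, lw5: np.ndarray, width: int) -> float:
    """Best log-odds of any window on one strand; -inf if none eligible."""
    if seq_codes.size < width:
        return -np.inf
    wins = sliding_window_view(seq_codes, width)
    scores = lw5[wins, np.arange(width)].sum(axis=1)
    return float(scores.max()) if scores.size else -np.inf


def fraction_with_motif(
    pwm: PWM,
    sequences: list[str],
    threshold_fraction: float = 0.8,
    background=None,
) -> tuple[float, list[bool]]:
    """Fraction of sequences whose best window reaches a log-odds threshold.

    A sequence is flagged when its best log-odds window (either strand)
    scores at least ``threshold_fraction`` times the maximal achievable
    log-odds of the PWM.
    """
    bg = np.asarray(
        background if background is not None else np.full(4, 0.25), dtype=float
    )
    lo = _logodds_matrix(pwm, bg)
    lw5 = np.vstack([lo, np.full(pwm.width, -np.inf)])
    thresh = threshold_fraction * float(lo.max(axis=0).sum())
    rc = pwm.reverse_complement()
    # sites on the minus strand are still read as forward-strand bases, so
    # the forward background applies to the reverse-complement PWM as well
    lo_rc = _logodds_matrix(rc, bg)
    lw5_rc = np.vstack([lo_rc, np.full(pwm.width, -np.inf)])
    flags = []
    for seq in sequences:
        codes = encode_seq(seq)
        best = max(
            best_window_logodds(codes, lw5, pwm.width),
            best_window_logodds(codes, lw5_rc, pwm.width),
        )
        flags.append(bool(best >= thresh))
    frac = sum(flags) / len(flags) if flags else 0.0
    return frac, flags


def logo_matrix(model: MotifModel) -> np.ndarray:
    """Per-column, per-base bit contributions for sequence-logo rendering.

    Column sums equal the per-column information content.
    """
    q = model.pwm.frequencies()
    ic = information_content(model.pwm, model.background, per_column=True)
    return q * ic[None, :]


def write_motif_report(model: MotifModel, path) -> None:
    """TSV report: per-column frequencies and bit contributions."""
    import pandas as pd

    q = model.pwm.frequencies()
    bits = logo_matrix(model)
    rows = []
    for i in range(model.pwm.width):
        row = {"column": i + 1, "consensus": model.pwm.consensus[i]}
        for bi, b in enumerate("ACGT"):
            row[f"freq_{b}"] = q[bi, i]
            row[f"bits_{b}"] = bits[bi, i]
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format="%.5g")
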