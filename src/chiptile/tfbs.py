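"""TFBS scanning and enrichment against randomized genomic controls.

PWM matches use the information-weighted matrix similarity score: with
column frequencies f(i, b) and column information I(i) = sum_b f(i,b) *
ln(4 f(i,b)), a window b_1..b_w scores

    (sum_i I(i) f(i, b_i) - min) / (max - min)

where min/max substitute each column's minimum/maximum frequency; the score
is 1 exactly on the per-column argmax word. Enrichment compares total hit
counts over the peak set against the mean over randomized control interval
sets (same chromosome, same length per peak) with a one-cell chi-square.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy import stats

from .types import GenomicInterval, PWM, encode_seq, revcomp

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


# ---------------------------------------------------------------------------
# matrix similarity scoring


def _match_weights(pwm: PWM) -> tuple[np.ndarray, float, float]:
    """Per-column information-weighted frequencies plus min/max window scores."""
    f = pwm.frequencies()
    # I(i) = sum_b f ln(4f), with the 0*ln(0) term read as 0
    info = np.nansum(f * np.where(f > 0, np.log(4.0 * f), 0.0), axis=0)
    weighted = info[None, :] * f  # 4 x width
    smin = float(weighted.min(axis=0).sum())
    smax = float(weighted.max(axis=0).sum())
    return weighted, smin, smax


def match_score(pwm: PWM, window: str) -> float:
    """Matrix similarity score in [0, 1] for one window; None if ineligible."""
    if len(window) != pwm.width:
        raise ValueError("window length must equal PWM width")
    codes = encode_seq(window)
    if (codes == 4).any():
        return None
    weighted, smin, smax = _match_weights(pwm)
    current = float(weighted[codes, np.arange(pwm.width)].sum())
    if smax == smin:
        return 1.0
    return (current - smin) / (smax - smin)


def _scan_codes(codes: np.ndarray, weighted, smin, smax, threshold) -> np.ndarray:
    """Offsets of windows scoring >= threshold on one strand."""
    width = weighted.shape[1]
    if codes.size < width:
        return np.array([], dtype=int), np.array([])
    w5 = np.vstack([weighted, np.full(width, -np.inf)])
    wins = sliding_window_view(codes, width)
    raw = w5[wins, np.arange(width)].sum(axis=1)
    if smax == smin:
        scores = np.where(np.isfinite(raw), 1.0, -np.inf)
    else:
        scores = (raw - smin) / (smax - smin)
    hit = scores >= threshold
    return np.flatnonzero(hit), scores[hit]


def scan_pwm(
    sequence: str, pwm: PWM, threshold: float = 0.85, both_strands: bool = True
) -> list[tuple[int, str, float]]:
    """All windows with matrix similarity >= threshold as (offset, strand, score).

    Offsets are forward-sequence coordinates of the window start on either
    strand.
    """
    weighted, smin, smax = _match_weights(pwm)
    codes = encode_seq(sequence)
    hits = []
    offs, scores = _scan_codes(codes, weighted, smin, smax, threshold)
    hits.extend((int(o), "+", float(s)) for o, s in zip(offs, scores))
    if both_strands:
        rc_codes = encode_seq(revcomp(sequence))
        offs, scores = _scan_codes(rc_codes, weighted, smin, smax, threshold)
        n = len(sequence)
        hits.extend(
            (int(n - pwm.width - o), "-", float(s)) for o, s in zip(offs, scores)
        )
    return sorted(hits)


def count_hits(
    sequences: list[str], pwm: PWM, threshold: float = 0.85,
    both_strands: bool = True, cap_per_sequence: bool = False,
) -> int:
    """Total PWM hits over a sequence set (optionally capped at 1/sequence)."""
    weighted, smin, smax = _match_weights(pwm)
    total = 0
    for seq in sequences:
        codes = encode_seq(seq)
        n = _scan_codes(codes, weighted, smin, smax, threshold)[0].size
        if both_strands:
            n += _scan_codes(
                encode_seq(revcomp(seq)), weighted, smin, smax, threshold
            )[0].size
        total += min(n, 1) if cap_per_sequence else n
    return total


# ---------------------------------------------------------------------------
# randomized controls


def sample_controls(
    peaks,
    genome: dict,
    n_sets: int = 10,
    seed: int = 0,
    max_tries: int = 200,
) -> list[list[GenomicInterval]]:
    """Randomized control intervals: same chromosome and length per peak.

    Controls avoid overlap with any peak by rejection sampling; if the retry
    cap is exhausted a warning is issued and the overlap allowed.
    """
    rng = np.random.default_rng(seed)
    ivs = [p.interval if hasattr(p, "interval") else p for p in peaks]
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for iv in ivs:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    chrom_lens = {c: len(s) for c, s in genome.items()}
    sets = []
    for _ in range(n_sets):
        controls = []
        for iv in ivs:
            clen = chrom_lens[iv.chrom]
            if clen < iv.length:
                raise ValueError(
                    f"chromosome {iv.chrom} shorter than peak length {iv.length}"
                )
            placed = None
            for _t in range(max_tries):
                start = int(rng.integers(0, clen - iv.length + 1))
                end = start + iv.length
                if any(
                    start < q.end and q.start < end for q in by_chrom[iv.chrom]
                ):
                    continue
                placed = GenomicInterval(iv.chrom, start, end)
                break
            if placed is None:
                warnings.warn(
                    f"control placement retries exhausted on {iv.chrom}; "
                    "allowing peak overlap"
                )
                start = int(rng.integers(0, clen - iv.length + 1))
                placed = GenomicInterval(iv.chrom, start, start + iv.length)
            controls.append(placed)
        sets.append(controls)
    return sets


# ---------------------------------------------------------------------------
# chi-square enrichment


@dataclass
class EnrichmentRecord:
    tf_id: str
    observed_hits: int
    expected_hits: float
    chi2: float
    p: float
    significant: bool


def chi_square_enrichment(
    peak_sequences: list[str],
    control_sequence_sets: list[list[str]],
    pwm_library: list[PWM],
    threshold: float = 0.85,
    alpha: float = 0.0005,
    cap_per_sequence: bool = False,
    two_by_two: bool = False,
    bonferroni: bool = False,
) -> list[EnrichmentRecord]:
    """Observed-vs-expected TFBS enrichment per PWM.

    O = total hits over the peak set, E = mean total hits over the control
    sets; chi2 = (O-E)^2 / E with df 1 (one-cell goodness of fit). With
    ``two_by_two`` a 2x2 hit/non-hit contingency chi-square (per-sequence
    presence) is used instead. Records are sorted by p value.
    """
    if not pwm_library:
        raise ValueError("empty PWM library")
    if not control_sequence_sets:
        raise ValueError("need at least one control set")
    m = len(pwm_library) if bonferroni else 1
    records = []
    for pwm in pwm_library:
        if two_by_two:
            o_pos = count_hits(
                peak_sequences, pwm, threshold, cap_per_sequence=True
            )
            c_pos = [
                count_hits(cs, pwm, threshold, cap_per_sequence=True)
                for cs in control_sequence_sets
            ]
            e_pos = float(np.mean(c_pos))
            n = len(peak_sequences)
            table = np.array(
                [[o_pos, n - o_pos], [e_pos, n - e_pos]]
            )
            if table.min() <= 0:
                chi2, p = 0.0, 1.0
            else:
                chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
            observed, expected = o_pos, e_pos
        else:
            observed = count_hits(
                peak_sequences, pwm, threshold, cap_per_sequence=cap_per_sequence
            )
            totals = [
                count_hits(cs, pwm, threshold, cap_per_sequence=cap_per_sequence)
                for cs in control_sequence_sets
            ]
            expected = float(np.mean(totals))
            if expected > 0:
                chi2 = (observed - expected) ** 2 / expected
                p = float(stats.chi2.sf(chi2, df=1))
            elif observed > 0:
                chi2, p = float("inf"), float(np.nextafter(0, 1))
            else:
                chi2, p = 0.0, 1.0
        records.append(
            EnrichmentRecord(
                tf_id=pwm.id,
                observed_hits=int(observed),
                expected_hits=float(expected),
                chi2=float(chi2),
                p=float(p),
                significant=bool(p < alpha / m),
            )
        )
    records.sort(key=lambda r: (r.p, r.tf_id))
    return records


# ---------------------------------------------------------------------------
# degenerate consensus scanning


def parse_pattern(pattern: str) -> list[str]:
    """Parse a bracket/IUPAC degenerate pattern into per-position base sets."""
    sets = []
    i = 0
    while i < len(pattern):
        ch = pattern[i].upper()
        if ch == "[":
            j = pattern.find("]", i)
            if j < 0:
                raise ValueError(f"unclosed bracket at position {i}")
            inner = pattern[i + 1 : j].upper()
            if not inner or any(b not in "ACGT" for b in inner):
                raise ValueError(f"invalid bracket content at position {i}")
            sets.append("".join(sorted(set(inner))))
            i = j + 1
        elif ch in IUPAC:
            sets.append(IUPAC[ch])
            i += 1
        else:
            raise ValueError(f"invalid pattern symbol {ch!r} at position {i}")
    if not sets:
        raise ValueError("empty pattern")
    return sets


def pattern_revcomp(sets: list[str]) -> list[str]:
    return ["".join(sorted(_COMP[b] for b in s)) for s in reversed(sets)]


def expand_pattern(sets: list[str]) -> list[str]:
    """All concrete words of a degenerate pattern."""
    words = [""]
    for s in sets:
        words = [w + b for w in words for b in s]
    return words


@dataclass
class ConsensusPattern:
    """Degenerate consensus, e.g. the 9-mer CTCF motif AG[GA][GT]GG[CAT][GAT][CG]."""

    pattern: str
    include_revcomp: bool = True

    def __post_init__(self):
        self.sets = parse_pattern(self.pattern)
        self.width = len(self.sets)


CTCF_PATTERN = ConsensusPattern("AG[GA][GT]GG[CAT][GAT][CG]")


def _pattern_table(sets: list[str]) -> np.ndarray:
    """(width, 5) eligibility table; non-ACGT code 4 never matches."""
    tab = np.zeros((len(sets), 5), dtype=bool)
    for i, s in enumerate(sets):
        for b in s:
            tab[i, "ACGT".index(b)] = True
    return tab


def scan_consensus(
    sequences: list[str], pattern: ConsensusPattern
) -> tuple[list[int], float]:
    """Per-sequence degenerate-match counts and the fraction with >= 1 match.

    An offset counts once when the window matches the pattern or (if
    enabled) its reverse complement; overlapping matches all count.
    """
    tabs = [_pattern_table(pattern.sets)]
    if pattern.include_revcomp:
        tabs.append(_pattern_table(pattern_revcomp(pattern.sets)))
    width = pattern.width
    counts = []
    for seq in sequences:
        codes = encode_seq(seq)
        if codes.size < width:
            counts.append(0)
            continue
        wins = sliding_window_view(codes, width)
        ok = np.zeros(wins.shape[0], dtype=bool)
        for tab in tabs:
            ok |= tab[np.arange(width), wins].all(axis=1)
        counts.append(int(ok.sum()))
    frac = float(np.mean([c > 0 for c in counts])) if counts else 0.0
    return counts, frac
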