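import numpy as np
import pytest

from chiptile import peakcall as pc
from chiptile import synthdata as sd


@pytest.fixture(scope="session")
def small_config():
    """Compact study: one 500 kb chromosome, quick to generate."""
    return sd.SyntheticConfig(
        seed=11,
        n_chromosomes=1,
        chrom_length=500_000,
        n_genes=15,
        n_true_peaks=30,
        de_up=3,
        de_down=5,
    )


@pytest.fixture(scope="session")
def small_study(small_config):
    return sd.generate_study(small_config)


@pytest.fixture(scope="session")
def default_study():
    """The default study conditions (3 x 2 Mb, 100 planted peaks)."""
    return sd.generate_study(sd.SyntheticConfig(seed=4))


def make_track(positions, ratios, chrom="chr1", spacing=100):
    return sd.ProbeTrack(
        chrom,
        np.asarray(positions, dtype=np.int64),
        np.asarray(ratios, dtype=np.float64),
        spacing,
    )


@pytest.fixture
def track_factory():
    return make_track


# ---------------------------------------------------------------------------
# independent brute-force peak-calling oracle


def oracle_call_at_cutoff(track, cutoff, params):
    """Direct enumeration of the qualification rules (no vectorization)."""
    pos = list(track.positions)
    above = [i for i in range(len(pos)) if track.ratios[i] > cutoff]
    clusters = []
    for i in above:
        if clusters and pos[i] - pos[clusters[-1][-1]] <= params.window:
            clusters[-1].append(i)
        else:
            clusters.append([i])
    out = []
    for cl in clusters:
        ok = False
        m = params.min_probes
        for j in range(len(cl) - m + 1):
            if pos[cl[j + m - 1]] - pos[cl[j]] < params.window:
                ok = True
        n2 = params.min_probes_all_above
        for j in range(len(cl) - n2 + 1):
            run = cl[j : j + n2]
            consecutive = run == list(range(run[0], run[0] + n2))
            gaps_ok = all(
                pos[b] - pos[a] <= params.window for a, b in zip(run, run[1:])
            )
            if consecutive and gaps_ok:
                ok = True
        if ok:
            out.append((pos[cl[0]], pos[cl[-1]] + track.spacing))
    return out


def oracle_call_peaks(track, params):
    """Union-merge formulation over all ladder rungs (independent of the
    incremental rung-by-rung merge the implementation uses)."""
    hyp = float(track.ratios.mean() + params.hypmax_k * track.ratios.std())
    rung_intervals = []
    for i in range(params.n_steps):
        pct = params.p_start - i * params.p_step
        cutoff = pct / 100.0 * hyp
        for s, e in oracle_call_at_cutoff(track, cutoff, params):
            rung_intervals.append((s, e, pct))
    # connected components of interval overlap
    rung_intervals.sort()
    merged = []
    for s, e, pct in rung_intervals:
        if merged and s < merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
            merged[-1][2] = max(merged[-1][2], pct)
        else:
            merged.append([s, e, pct])
    return [(s, e, pct) for s, e, pct in merged]
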