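import numpy as np
import pytest

from g4pause import coverage, pausecall
from g4pause.synthetic import SimulationParams, simulate


@pytest.fixture(scope="session")
def default_sim():
    """One default-parameter synthetic dataset shared across tests."""
    params = SimulationParams(seed=1)
    genome, truth, raw_tracks = simulate(params)
    return params, genome, truth, raw_tracks


@pytest.fixture(scope="session")
def default_called(default_sim):
    """Consensus pause sites called on the default synthetic dataset."""
    params, genome, truth, raw_tracks = default_sim
    tracks = [coverage.normalize(t, "rpm_total", t.denominator)
              for t in raw_tracks]
    call_params = pausecall.PauseCallParams()
    peak_lists = [pausecall.call_peaks(t, call_params) for t in tracks]
    sites = pausecall.consensus_sites(peak_lists, genome.length, call_params)
    return tracks, call_params, sites


def naive_rolling_stats(values, window):
    """Brute-force circular rolling mean / population sd, one window at a
    time.  Oracle for the optimized implementation."""
    x = np.asarray(values, dtype=float)
    L = x.size
    half = window // 2
    mean = np.empty(L)
    sd = np.empty(L)
    for i in range(L):
        w = x[(np.arange(i - half, i + half + 1)) % L]
        mean[i] = w.mean()
        sd[i] = w.std()  # ddof=0: population sd
    return mean, sd


def sam_text(reads, length=1000, chrom="chrM"):
    """Minimal single-contig SAM document from (name, flag, pos, cigar[, tags])
    tuples; pos is 0-based."""
    lines = ["@HD\tVN:1.6\tSO:unknown", f"@SQ\tSN:{chrom}\tLN:{length}"]
    for read in reads:
        name, flag, pos, cigar, *rest = read
        tags = rest[0] if rest else []
        seqlen = sum(int(n) for n, op in _cigar_ops(cigar) if op in "MIS=X")
        fields = [name, str(flag), chrom, str(pos + 1), "60", cigar, "*",
                  "0", "0", "A" * seqlen, "I" * seqlen] + list(tags)
        lines.append("\t".join(fields))
    return "\n".join(lines) + "\n"


def _cigar_ops(cigar):
    num = ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
        else:
            yield num, ch
            num = ""
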