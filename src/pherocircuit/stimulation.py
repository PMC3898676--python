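"""Glomerular-stimulation analysis: artifact removal, evoked depolarization, latency.

Square voltage pulses (500 ms) delivered into a glomerulus produce transient
edge artifacts plus a sustained artifact of roughly 1 mV per stimulation volt.
The sustained component is fitted per cell from control-glomerulus trials and
subtracted; the ~2 ms edge transients are masked, not modeled.  Latency is
estimated by boxcar-filtering (~2.2 kHz), normalizing each trace to its mean
over the first 0.5 ms after stimulation, binning at 0.5 ms, and finding the
earliest bin from which the test trace stays significantly above the control
trace (one-tailed rank-sum, p < 0.05) through the end of stimulation.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from functools import lru_cache
from math import comb, erfc, sqrt

import numpy as np
from scipy.ndimage import uniform_filter1d
from scipy.optimize import brentq
from scipy.stats import rankdata

from .ephys import VoltageTrial

__all__ = [
    "StimPair",
    "boxcar_kernel_length",
    "boxcar_smooth",
    "fit_artifact_gain",
    "subtract_sustained_artifact",
    "evoked_depolarization",
    "ranksum_greater",
    "stimulation_latency",
]


@dataclass
class StimPair:
    """Test (DA1) and control-glomerulus stimulation trials for one cell."""

    test_trials: list
    control_trials: list
    stim_onset: float  # s
    stim_duration: float = 0.5  # s, 500 ms pulses
    stim_voltage: float = 1.0  # V

    def __post_init__(self) -> None:
        if not self.test_trials or not self.control_trials:
            raise ValueError("both trial lists must be nonempty")
        rates = {t.sampling_rate for t in self.test_trials + self.control_trials}
        if max(rates) / min(rates) > 1.001:
            raise ValueError("test and control trials must share a sampling rate")


def boxcar_kernel_length(sampling_rate: float, cutoff: float) -> int:
    """Odd moving-average length whose -3 dB point is nearest to ``cutoff`` Hz.

    |H(f)| = |sin(pi f L / fs) / (L sin(pi f / fs))|; the continuous L solving
    |H(cutoff)| = 1/sqrt(2) is rounded to the nearest odd sample count (min 1).
    """
    if not 0 < cutoff < sampling_rate / 2:
        raise ValueError("cutoff must be below Nyquist")
    x = np.pi * cutoff / sampling_rate

    def h_minus(lval):
        return abs(np.sin(x * lval) / (lval * np.sin(x))) - 1.0 / np.sqrt(2)

    upper = min(np.pi / x * 0.999, 1e6)
    if h_minus(upper) > 0:
        l_star = upper
    else:
        l_star = brentq(h_minus, 1.0, upper)
    l_odd = int(2 * round((l_star - 1) / 2) + 1)
    return max(1, l_odd)


def boxcar_smooth(x: np.ndarray, sampling_rate: float, cutoff: float = 2200.0) -> np.ndarray:
    n = boxcar_kernel_length(sampling_rate, cutoff)
    if n == 1:
        return np.asarray(x, float).copy()
    return uniform_filter1d(np.asarray(x, float), n, mode="reflect")


def fit_artifact_gain(control_trials, stim_onset: float, stim_duration: float,
                      stim_voltage: float, plateau: float = 0.100,
                      baseline: float = 0.500) -> float:
    """Sustained-artifact gain (mV/V) from control-glomerulus plateaus.

    Per trial: mean over the last ``plateau`` s of the stimulation window minus
    the mean over ``baseline`` s before onset, divided by the stimulation
    voltage; averaged over trials.
    """
    if stim_voltage == 0:
        raise ValueError("cannot fit a gain at zero stimulation voltage")
    gains = []
    for t in control_trials:
        fs = t.sampling_rate
        lo_p = int(round((stim_onset + stim_duration - plateau) * fs))
        hi_p = int(round((stim_onset + stim_duration) * fs))
        lo_b = int(round((stim_onset - baseline) * fs))
        hi_b = int(round(stim_onset * fs))
        if lo_b < 0 or hi_p > len(t.voltage):
            raise ValueError("stimulation window outside the trace")
        gains.append((t.voltage[lo_p:hi_p].mean() - t.voltage[lo_b:hi_b].mean())
                     / stim_voltage)
    return float(np.mean(gains))


def subtract_sustained_artifact(v: VoltageTrial, stim_onset: float,
                                stim_duration: float, stim_voltage: float,
                                gain_mv_per_v: float = 1.0,
                                edge_mask: float = 0.002) -> VoltageTrial:
    """Subtract the fitted constant artifact inside the stimulation window.

    Samples within ``edge_mask`` s of the pulse edges (transient artifacts) are
    replaced by linear interpolation across the masked span.  Zero stimulation
    voltage returns the trace unchanged.
    """
    fs = v.sampling_rate
    lo = int(round(stim_onset * fs))
    hi = int(round((stim_onset + stim_duration) * fs))
    if lo < 0 or hi > len(v.voltage):
        raise ValueError("stimulation window outside the trace")
    offset = gain_mv_per_v * stim_voltage
    if offset == 0:
        return replace(v, voltage=v.voltage.copy())
    out = v.voltage.copy()
    out[lo:hi] -= offset
    m = max(1, int(round(edge_mask * fs)))
    for edge in (lo, hi):
        a = max(0, edge - m)
        b = min(len(out) - 1, edge + m)
        out[a:b + 1] = np.linspace(out[a], out[b], b - a + 1)
    return replace(v, voltage=out)


def evoked_depolarization(v: VoltageTrial, stim_onset: float,
                          stim_duration: float, baseline: float = 0.500) -> float:
    """Mean depolarization (mV) during stimulation relative to the 500 ms before."""
    fs = v.sampling_rate
    lo = int(round(stim_onset * fs))
    hi = int(round((stim_onset + stim_duration) * fs))
    lo_b = int(round((stim_onset - baseline) * fs))
    if lo_b < 0 or hi > len(v.voltage):
        raise ValueError("insufficient pre-window or stimulation window outside trace")
    return float(v.voltage[lo:hi].mean() - v.voltage[lo_b:lo].mean())


# ---------------------------------------------------------------------------
# one-tailed rank-sum with an exact small-sample null


@lru_cache(maxsize=64)
def _u_counts(m: int, n: int) -> tuple:
    """Number of rank configurations with Mann-Whitney U = u, u = 0..m*n."""
    if m == 0 or n == 0:
        return (1,)
    a = _u_counts(m - 1, n)
    b = _u_counts(m, n - 1)
    size = m * n + 1
    out = [0] * size
    for u, c in enumerate(a):  # last x-sample beats all n? shift by n
        out[u + n] += c
    for u, c in enumerate(b):
        out[u] += c
    return tuple(out)


def _u_sf(m: int, n: int) -> np.ndarray:
    """P(U >= u) for u = 0..m*n under the exact null."""
    counts = np.array(_u_counts(m, n), float)
    return counts[::-1].cumsum()[::-1] / comb(m + n, m)


def ranksum_greater(x, y, exact_max: int = 400):
    """One-tailed Mann-Whitney rank-sum p-value for x stochastically greater than y.

    Exact null when m*n <= ``exact_max`` (ties resolved by midranks, survival
    evaluated at ceil(U)); otherwise the normal approximation with tie and
    continuity corrections.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    m, n = x.size, y.size
    ranks = rankdata(np.concatenate([x, y]))
    u = ranks[:m].sum() - m * (m + 1) / 2.0
    if m * n <= exact_max:
        return float(_u_sf(m, n)[min(int(np.ceil(u - 1e-9)), m * n)])
    mu = m * n / 2.0
    _, tie_counts = np.unique(ranks, return_counts=True)
    tie_term = ((tie_counts**3 - tie_counts).sum()) / ((m + n) * (m + n - 1.0))
    var = m * n / 12.0 * ((m + n + 1) - tie_term)
    if var <= 0:
        return 1.0
    z = (u - mu - 0.5) / sqrt(var)
    return float(0.5 * erfc(z / sqrt(2.0)))


def _bin_means(trials, stim_onset: float, stim_duration: float,
               bin_s: float, boxcar_cutoff: float, norm_window: float) -> np.ndarray:
    """(n_trials, n_bins) per-trial bin means of filtered, normalized traces."""
    fs = trials[0].sampling_rate
    n_bins = int(round(stim_duration / bin_s))
    lo = int(round(stim_onset * fs))
    hi = int(round((stim_onset + stim_duration) * fs))
    hi_norm = int(round((stim_onset + norm_window) * fs))
    sample_bins = np.minimum(
        (np.floor((np.arange(lo, hi) - lo) / (fs * bin_s))).astype(int), n_bins - 1)
    denom = np.bincount(sample_bins, minlength=n_bins)
    out = np.empty((len(trials), n_bins))
    for i, t in enumerate(trials):
        sm = boxcar_smooth(t.voltage, fs, boxcar_cutoff)
        sm = sm - sm[lo:max(hi_norm, lo + 1)].mean()
        out[i] = np.bincount(sample_bins, weights=sm[lo:hi], minlength=n_bins) / denom
    return out


def stimulation_latency(pair: StimPair, alpha: float = 0.05,
                        bin_s: float = 0.0005, boxcar_cutoff: float = 2200.0,
                        norm_window: float = 0.0005) -> float | None:
    """Latency (ms after onset) of persistent test/control divergence, or None.

    Each trace is boxcar-filtered (~2.2 kHz), normalized by its own mean over
    [onset, onset+0.5 ms], and binned at 0.5 ms.  Per bin, per-trial bin means
    are compared with a one-tailed rank-sum test (test > control); the latency
    is the start of the earliest bin from which every bin through the end of
    stimulation has p < alpha.  Returns None when no such bin exists.
    """
    if len(pair.test_trials) < 3 or len(pair.control_trials) < 3:
        raise ValueError("need >= 3 trials per condition")
    rates = {t.sampling_rate for t in pair.test_trials + pair.control_trials}
    if max(rates) / min(rates) > 1.001:
        raise ValueError("mismatched sampling rates")
    test = _bin_means(pair.test_trials, pair.stim_onset, pair.stim_duration,
                      bin_s, boxcar_cutoff, norm_window)
    ctrl = _bin_means(pair.control_trials, pair.stim_onset, pair.stim_duration,
                      bin_s, boxcar_cutoff, norm_window)
    m, n = test.shape[0], ctrl.shape[0]
    n_bins = test.shape[1]
    ranks = rankdata(np.vstack([test, ctrl]), axis=0)
    u = ranks[:m].sum(axis=0) - m * (m + 1) / 2.0
    if m * n <= 400:
        sf = _u_sf(m, n)
        p = sf[np.minimum(np.ceil(u - 1e-9).astype(int), m * n)]
    else:
        p = np.array([ranksum_greater(test[:, b], ctrl[:, b]) for b in range(n_bins)])
    sig = p < alpha
    if not sig[-1]:
        return None
    # earliest bin from which significance persists to the end
    run_start = n_bins - 1
    for b in range(n_bins - 2, -1, -1):
        if sig[b]:
            run_start = b
        else:
            break
    return run_start * bin_s * 1000.0
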