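"""Odor-response quantification and significance testing.

Response magnitude is the mean spike count in a 500 ms window starting 150 ms
after valve opening, minus the same count for the mineral-oil control stimulus.
Significance uses the exact one-sided two-sample Poisson test (in its
conditional-binomial form) on the summed counts over the trials, with
Benjamini-Hochberg FDR control at alpha = 0.01.  Tuning sharpness is lifetime
sparseness; subthreshold responses are peak boxcar-smoothed depolarizations
tested against pre-stimulus pseudo responses with a permutation test on the
difference in means.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from math import comb

import numpy as np
import pandas as pd
from scipy.ndimage import uniform_filter1d
from scipy.stats import binom

from .ephys import SpikeTrain, TrialSet, VoltageTrial, detect_spikes

__all__ = [
    "DEPOL_SPIKE_THRESHOLD_MV",
    "SubthresholdResult",
    "window_spike_count",
    "response_magnitude",
    "poisson_response_test",
    "bh_adjust",
    "peak_firing_rate",
    "lifetime_sparseness",
    "subthreshold_response",
    "subthreshold_test",
    "subthreshold_table",
    "group_comparison_test",
    "build_response_table",
]

# Reported empirical threshold (~5.5 mV peak averaged depolarization) above
# which cells tended to spike; an annotation constant, never inferred here.
DEPOL_SPIKE_THRESHOLD_MV = 5.5


def window_spike_count(st: SpikeTrain, onset: float,
                       start_offset: float = 0.150, length: float = 0.500) -> int:
    """Spikes in the half-open window [onset+start_offset, onset+start_offset+length)."""
    if length < 0:
        raise ValueError("window length must be >= 0")
    lo = onset + start_offset
    t = np.asarray(st.times)
    return int(np.count_nonzero((t >= lo) & (t < lo + length)))


def response_magnitude(odor_counts, control_counts, window_length: float = 0.5):
    """mean(odor) - mean(control) in spikes per window, and as Hz."""
    odor = np.asarray(odor_counts, float)
    ctrl = np.asarray(control_counts, float)
    if odor.size == 0 or ctrl.size == 0:
        raise ValueError("count lists must be nonempty")
    diff = float(odor.mean() - ctrl.mean())
    return diff, diff / window_length


def poisson_response_test(odor_counts, control_counts,
                          exposure_ratio: float | None = None) -> float:
    """Exact one-sided two-sample Poisson test (conditional binomial form).

    With K_o = sum(odor), K_c = sum(control) and N = K_o + K_c, conditioning on
    N makes K_o ~ Binomial(N, r/(1+r)) under the null, where r is the exposure
    ratio (1 for equal trial counts).  Returns P(X >= K_o); 1 when N = 0.
    """
    odor = np.asarray(odor_counts)
    ctrl = np.asarray(control_counts)
    if np.any(odor < 0) or np.any(ctrl < 0):
        raise ValueError("spike counts must be nonnegative")
    if exposure_ratio is None:
        exposure_ratio = odor.size / ctrl.size if ctrl.size else 1.0
    k_o = int(np.sum(odor))
    n = k_o + int(np.sum(ctrl))
    if n == 0:
        return 1.0
    p_null = exposure_ratio / (1.0 + exposure_ratio)
    return float(binom.sf(k_o - 1, n, p_null))


def bh_adjust(raw_p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, original order preserved."""
    p = np.asarray(raw_p, float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("raw_p must be a nonempty 1-D sequence")
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    scaled = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(scaled[::-1])[::-1]
    adj = np.clip(adj, 0.0, 1.0)
    out = np.empty(m)
    out[order] = adj
    return out


def peak_firing_rate(st: SpikeTrain, onset: float, start_offset: float = 0.150,
                     window: float = 0.200, n_windows: int = 5) -> float:
    """Peak rate (Hz) over five consecutive 200 ms windows starting +150 ms."""
    if st.trial is not None:
        if onset + start_offset + n_windows * window > st.trial.duration + 1e-9:
            raise ValueError("windows extend past the end of the trace")
    rates = [
        window_spike_count(st, onset, start_offset + i * window, window) / window
        for i in range(n_windows)
    ]
    return float(max(rates))


def lifetime_sparseness(responses, rectify: bool = True) -> float:
    """Tuning sharpness S in [0, 1].

    S = (1 - (mean r)^2 / mean(r^2)) / (1 - 1/n): 0 for a neuron responding
    equally to all n odorants, 1 for one excited by a single odorant.  Negative
    (inhibitory) mean responses are rectified to 0 first, since the statistic
    is undefined for negative rates; an all-zero vector gives 0 by convention.
    """
    r = np.asarray(responses, float)
    if r.size < 2:
        raise ValueError("need responses to at least 2 odorants")
    if rectify:
        r = np.maximum(r, 0.0)
    elif np.any(r < 0):
        raise ValueError("negative responses; enable rectify or pass rates >= 0")
    if not np.any(r > 0):
        return 0.0
    n = r.size
    s = (1.0 - (r.mean() ** 2) / np.mean(r**2)) / (1.0 - 1.0 / n)
    return float(np.clip(s, 0.0, 1.0))


# ---------------------------------------------------------------------------
# subthreshold responses


def subthreshold_response(v: VoltageTrial, boxcar: float = 0.045,
                          onset: float | None = None,
                          peak_window=(0.2, 0.8),
                          baseline_window=(-1.0, 0.0)) -> float:
    """Peak boxcar-smoothed depolarization (mV), baseline-subtracted.

    The membrane potential is smoothed with a 45 ms boxcar; the result is the
    maximum in [onset+0.2, onset+0.8] s minus the mean over [onset-1, onset] s.
    ``onset`` defaults to the trial's stimulus onset; passing an earlier time
    yields a pseudo response from the pre-stimulus period.
    """
    fs = v.sampling_rate
    t0 = v.stimulus_onset if onset is None else onset
    nbox = int(round(boxcar * fs))
    if nbox % 2 == 0:
        nbox += 1
    lo_b = int(round((t0 + baseline_window[0]) * fs))
    hi_b = int(round((t0 + baseline_window[1]) * fs))
    lo_p = int(round((t0 + peak_window[0]) * fs))
    hi_p = int(round((t0 + peak_window[1]) * fs))
    if lo_b < 0 or hi_p > len(v.voltage):
        raise ValueError("trace lacks pre/post context for the response windows")
    sm = uniform_filter1d(v.voltage, nbox, mode="reflect")
    return float(sm[lo_p:hi_p].max() - sm[lo_b:hi_b].mean())


@dataclass
class SubthresholdResult:
    cell_id: str
    stimulus_label: str
    peak_depolarization: float  # mV, mean over trials
    null_pseudo_responses: np.ndarray
    raw_p: float
    adjusted_p: float | None = None
    significant: bool | None = None


def group_comparison_test(values_a, values_b, n_perm: int = 10000,
                          seed=None, alternative: str = "two-sided",
                          max_exact: int = 100_000) -> float:
    """Permutation p-value for the difference in means between two samples.

    Unlike a rank test, the magnitude of the values (not just their order)
    enters the statistic.  All group reassignments are enumerated when
    C(n_a+n_b, n_a) <= ``max_exact``; otherwise ``n_perm`` Monte-Carlo draws
    with the observed assignment counted in numerator and denominator.
    """
    a = np.asarray(values_a, float)
    b = np.asarray(values_b, float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be nonempty")
    na, nb = a.size, b.size
    pooled = np.concatenate([a, b])
    total_sum = pooled.sum()
    obs = a.mean() - b.mean()
    tol = 1e-12 * (1.0 + abs(obs))

    def exceed(d):
        if alternative == "two-sided":
            return np.abs(d) >= abs(obs) - tol
        if alternative == "greater":
            return d >= obs - tol
        if alternative == "less":
            return d <= obs + tol
        raise ValueError("alternative must be two-sided/greater/less")

    n = na + nb
    n_comb = comb(n, na)
    if n_comb <= max_exact:
        idx = np.fromiter(
            itertools.chain.from_iterable(itertools.combinations(range(n), na)),
            dtype=np.intp, count=n_comb * na,
        ).reshape(n_comb, na)
        sums_a = pooled[idx].sum(axis=1)
        diffs = sums_a / na - (total_sum - sums_a) / nb
        return float(np.count_nonzero(exceed(diffs)) / n_comb)
    rng = np.random.default_rng(seed)
    mat = rng.permuted(np.tile(pooled, (n_perm, 1)), axis=1)
    sums_a = mat[:, :na].sum(axis=1)
    diffs = sums_a / na - (total_sum - sums_a) / nb
    return float((1 + np.count_nonzero(exceed(diffs))) / (1 + n_perm))


def subthreshold_test(cell_trials: TrialSet, stimulus_label: str,
                      n_null_windows: int = 3, null_spacing: float = 1.0,
                      n_perm: int = 10000, seed=None,
                      boxcar: float = 0.045) -> SubthresholdResult:
    """Test one cell/stimulus subthreshold response against pseudo responses.

    Real responses come from that stimulus' trials; the null pool applies the
    identical peak/baseline procedure at pseudo onsets shifted into the
    pre-stimulus period (``n_null_windows`` per trace, ``null_spacing`` s
    apart) of *every* trace available for the cell, odors and control alike.
    """
    if n_null_windows < 1:
        raise ValueError("need at least one pseudo window per trace")
    real_trials = [t for t in cell_trials.trials if t.stimulus_label == stimulus_label]
    if len(real_trials) < 2:
        raise ValueError("need >= 2 trials for the tested stimulus")
    real = [subthreshold_response(t, boxcar=boxcar) for t in real_trials]
    pseudo = []
    for t in cell_trials.trials:
        for k in range(1, n_null_windows + 1):
            pseudo.append(subthreshold_response(
                t, boxcar=boxcar, onset=t.stimulus_onset - k * null_spacing))
    raw_p = group_comparison_test(real, pseudo, n_perm=n_perm, seed=seed)
    cell = real_trials[0].cell_id
    return SubthresholdResult(
        cell_id=cell, stimulus_label=stimulus_label,
        peak_depolarization=float(np.mean(real)),
        null_pseudo_responses=np.asarray(pseudo), raw_p=raw_p,
    )


def subthreshold_table(cell_trials: TrialSet, alpha: float = 0.01,
                       include_control: bool = False, **kwargs) -> list[SubthresholdResult]:
    """Subthreshold tests for all of one cell's stimuli, FDR-adjusted across them."""
    stimuli = [s for s in cell_trials.stimuli()
               if include_control or s != cell_trials.control_label]
    if not stimuli:
        raise ValueError("no non-control stimuli to test")
    results = [subthreshold_test(cell_trials, s, **kwargs) for s in stimuli]
    adj = bh_adjust([r.raw_p for r in results])
    for r, ap in zip(results, adj):
        r.adjusted_p = float(ap)
        r.significant = bool(ap < alpha)
    return results


# ---------------------------------------------------------------------------
# spiking response table


def build_response_table(ts: TrialSet, alpha: float = 0.01,
                         start_offset: float = 0.150, window: float = 0.500,
                         smooth_cutoff: float = 400.0,
                         fdr_scope: str = "cell",
                         spike_kwargs: dict | None = None) -> pd.DataFrame:
    """Per cell x stimulus response magnitudes and FDR-adjusted Poisson p-values.

    Spike counts come from the second-derivative detector; the control
    stimulus supplies the subtracted baseline counts.  ``fdr_scope`` is
    ``"cell"`` (BH across each cell's odors, the default) or ``"global"``.
    """
    if not ts.control_label:
        raise ValueError("response testing needs a control_label on the TrialSet")
    spike_kwargs = spike_kwargs or {}
    counts: dict[tuple, list] = {}
    for t in ts.trials:
        st = detect_spikes(t, smooth_cutoff=smooth_cutoff, **spike_kwargs)
        c = window_spike_count(st, t.stimulus_onset, start_offset, window)
        counts.setdefault((t.cell_id, t.stimulus_label), []).append(c)

    rows = []
    for cell in ts.cells():
        ctrl = counts.get((cell, ts.control_label))
        if not ctrl:
            raise ValueError(f"cell {cell!r} has no control trials")
        for stim in ts.stimuli():
            if stim == ts.control_label or (cell, stim) not in counts:
                continue
            odor = counts[(cell, stim)]
            mean_resp, rate = response_magnitude(odor, ctrl, window)
            raw_p = poisson_response_test(odor, ctrl)
            rows.append({"cell_id": cell, "stimulus_label": stim,
                         "mean_response": mean_resp, "rate_hz": rate,
                         "raw_p": raw_p})
    df = pd.DataFrame(rows)
    if df.empty:
        raise ValueError("no odor trials to test")
    if fdr_scope == "cell":
        df["adjusted_p"] = df.groupby("cell_id")["raw_p"].transform(
            lambda s: bh_adjust(s.to_numpy()))
    elif fdr_scope == "global":
        df["adjusted_p"] = bh_adjust(df["raw_p"].to_numpy())
    else:
        raise ValueError("fdr_scope must be 'cell' or 'global'")
    df["significant"] = df["adjusted_p"] < alpha
    return df
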