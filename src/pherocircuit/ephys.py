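"""Trial-structured current-clamp recordings, binomial smoothing, spike extraction.

Recordings are digitized at ~11.1 kHz.  Traces are smoothed with a binomial
(Pascal-row) kernel characterised by its -3 dB cutoff, and action potentials
are extracted by applying a negative threshold to the second derivative of the
smoothed trace.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.ndimage import convolve1d
from scipy.stats import binom

__all__ = [
    "VoltageTrial",
    "TrialSet",
    "SpikeTrain",
    "binomial_kernel",
    "binomial_smooth",
    "detect_spikes",
    "read_trials",
    "write_trials",
]


@dataclass
class VoltageTrial:
    """One voltage trace (mV) with stimulus metadata."""

    sampling_rate: float  # Hz
    voltage: np.ndarray  # mV
    stimulus_onset: float  # s, valve opening / stimulation onset
    stimulus_duration: float = 0.5  # s; odor pulses are 500 ms
    stimulus_label: str = ""
    cell_id: str = ""

    def __post_init__(self) -> None:
        self.voltage = np.asarray(self.voltage, float)
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be > 0")
        if not np.all(np.isfinite(self.voltage)):
            raise ValueError("voltage contains non-finite samples")
        if not 0 <= self.stimulus_onset <= self.duration:
            raise ValueError("stimulus_onset outside the trace")

    @property
    def duration(self) -> float:
        return len(self.voltage) / self.sampling_rate

    @property
    def times(self) -> np.ndarray:
        return np.arange(len(self.voltage)) / self.sampling_rate


@dataclass
class TrialSet:
    """A collection of trials (one or more cells), plus the control stimulus label."""

    trials: list
    control_label: str = ""

    def __post_init__(self) -> None:
        if not self.trials:
            raise ValueError("TrialSet needs at least one trial")
        rates = np.array([t.sampling_rate for t in self.trials])
        if rates.max() / rates.min() > 1.001:
            raise ValueError("trials differ in sampling rate by more than 0.1%")

    @property
    def sampling_rate(self) -> float:
        return self.trials[0].sampling_rate

    def cells(self) -> list:
        seen = dict.fromkeys(t.cell_id for t in self.trials)
        return list(seen)

    def stimuli(self) -> list:
        seen = dict.fromkeys(t.stimulus_label for t in self.trials)
        return list(seen)

    def select(self, cell_id=None, stimulus_label=None) -> "TrialSet":
        sel = [
            t for t in self.trials
            if (cell_id is None or t.cell_id == cell_id)
            and (stimulus_label is None or t.stimulus_label == stimulus_label)
        ]
        if not sel:
            raise KeyError(f"no trials for cell={cell_id!r} stimulus={stimulus_label!r}")
        return TrialSet(trials=sel, control_label=self.control_label)


@dataclass
class SpikeTrain:
    """Sorted spike times (s) from one trial."""

    times: np.ndarray
    trial: VoltageTrial | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, float)
        if len(self.times) and np.any(np.diff(self.times) <= 0):
            raise ValueError("spike times must be strictly increasing")
        if self.trial is not None and len(self.times):
            if self.times[0] < 0 or self.times[-1] > self.trial.duration:
                raise ValueError("spike times outside the trace")

    def __len__(self) -> int:
        return len(self.times)


def binomial_kernel(sampling_rate: float, cutoff: float) -> np.ndarray:
    """Normalized Pascal-row smoothing kernel with -3 dB frequency <= ``cutoff``.

    The frequency response of the (n+1)-tap binomial kernel is cos(pi f / fs)^n,
    so the smallest even n with cos(pi fc / fs)^n <= 1/sqrt(2) gives the
    shortest odd kernel whose -3 dB point does not exceed the cutoff.
    """
    nyquist = sampling_rate / 2.0
    if not 0 < cutoff < nyquist:
        raise ValueError(f"cutoff must be in (0, {nyquist}) Hz")
    x = math.pi * cutoff / sampling_rate
    n_star = math.log(0.5) / (2.0 * math.log(math.cos(x)))
    n = max(2, math.ceil(n_star))
    if n % 2:
        n += 1
    return binom.pmf(np.arange(n + 1), n, 0.5)


def binomial_smooth(v: VoltageTrial, cutoff: float) -> VoltageTrial:
    """Smooth the trace with the binomial kernel; reflection at the edges."""
    kernel = binomial_kernel(v.sampling_rate, cutoff)
    smoothed = convolve1d(v.voltage, kernel, mode="reflect")
    return replace(v, voltage=smoothed)


def _second_difference(x: np.ndarray) -> np.ndarray:
    d2 = np.zeros_like(x)
    d2[1:-1] = x[2:] - 2.0 * x[1:-1] + x[:-2]
    return d2


def detect_spikes(
    v: VoltageTrial,
    smooth_cutoff: float = 400.0,
    threshold_mode: str = "auto",
    threshold_value: float | None = None,
    mad_factor: float = 8.0,
    refractory: float = 0.002,
) -> SpikeTrain:
    """Extract spike times via a negative threshold on the second derivative.

    The trace is binomially smoothed, the second central difference taken, and
    samples below the (negative) threshold are grouped into events; events
    closer than the 2 ms refractory gap merge.  Each event yields one spike,
    timed at the raw-trace voltage maximum within the event.

    In ``auto`` mode the threshold is -(mad_factor x scaled MAD) of the second
    derivative; the scaled MAD (x1.4826) estimates its noise SD robustly, so
    the threshold adapts to the noise floor while ignoring the spikes
    themselves.
    """
    if len(v.voltage) <= 3:
        raise ValueError("trace too short for spike detection")
    sm = binomial_smooth(v, smooth_cutoff).voltage
    d2 = _second_difference(sm)
    if threshold_mode == "auto":
        mad = np.median(np.abs(d2 - np.median(d2)))
        thr = -(mad_factor * 1.4826 * mad)
    elif threshold_mode == "fixed":
        if threshold_value is None:
            raise ValueError("fixed threshold mode requires threshold_value")
        thr = -abs(threshold_value)
    else:
        raise ValueError("threshold_mode must be 'auto' or 'fixed'")

    below = np.flatnonzero(d2 < thr)
    if len(below) == 0 or thr == 0:
        return SpikeTrain(times=np.array([]), trial=v)

    gap = max(1, int(round(refractory * v.sampling_rate)))
    breaks = np.flatnonzero(np.diff(below) > gap)
    starts = np.concatenate([[0], breaks + 1])
    ends = np.concatenate([breaks, [len(below) - 1]])
    idx = []
    for s, e in zip(starts, ends):
        lo, hi = below[s], below[e] + 1
        idx.append(lo + int(np.argmax(v.voltage[lo:hi])))
    idx = np.unique(idx)
    return SpikeTrain(times=idx / v.sampling_rate, trial=v)


# ---------------------------------------------------------------------------
# disk round trip: a directory of per-trial voltage CSVs plus a trials.csv sidecar

SIDECAR_COLUMNS = ["trial_id", "cell_id", "stimulus_label", "onset_s",
                   "duration_s", "rate_hz", "file"]


def write_trials(ts: TrialSet, directory) -> str:
    os.makedirs(directory, exist_ok=True)
    rows = []
    for i, t in enumerate(ts.trials):
        fname = f"trial_{i:04d}.csv"
        pd.DataFrame({"voltage_mv": t.voltage}).to_csv(
            os.path.join(directory, fname), index=False, float_format="%.17g"
        )
        rows.append((i, t.cell_id, t.stimulus_label, t.stimulus_onset,
                     t.stimulus_duration, t.sampling_rate, fname))
    side = pd.DataFrame(rows, columns=SIDECAR_COLUMNS)
    side.attrs["control_label"] = ts.control_label
    side.insert(0, "control_label", ts.control_label)
    side.to_csv(os.path.join(directory, "trials.csv"), index=False, float_format="%.17g")
    return str(directory)


def read_trials(directory) -> TrialSet:
    sidecar = os.path.join(directory, "trials.csv")
    if not os.path.exists(sidecar):
        raise FileNotFoundError(f"missing sidecar {sidecar}")
    side = pd.read_csv(sidecar, float_precision="round_trip")
    missing = [c for c in SIDECAR_COLUMNS if c not in side.columns]
    if missing:
        raise ValueError(f"sidecar missing fields: {missing}")
    trials = []
    for r in side.itertuples():
        v = pd.read_csv(os.path.join(directory, r.file),
                        float_precision="round_trip")["voltage_mv"].to_numpy(float)
        trials.append(VoltageTrial(
            sampling_rate=float(r.rate_hz), voltage=v,
            stimulus_onset=float(r.onset_s), stimulus_duration=float(r.duration_s),
            stimulus_label=str(r.stimulus_label), cell_id=str(r.cell_id),
        ))
    control = str(side["control_label"].iloc[0]) if "control_label" in side.columns else ""
    return TrialSet(trials=trials, control_label=control)
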