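"""Synthetic morphologies and recordings with the statistical structure the analysis assumes.

The morphology generator emulates populations whose dendritic arbours occupy
group-specific territories (as sexually dimorphic lateral horn neurons do)
while sharing an axon tract; the recording generator emulates current-clamp
trials digitized at 11.1 kHz with Gaussian baseline noise, odor-locked
EPSP-like depolarizations arriving 150-200 ms after valve opening, stereotyped
spike waveforms riding on an inhomogeneous Poisson process, and 500 ms
stimulus pulses.  Every generator is a pure function of its spec plus seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ephys import TrialSet, VoltageTrial
from .skeletons import NODE_COLUMNS, NeuronSkeleton
from .stimulation import StimPair

__all__ = [
    "MorphoPopulationSpec",
    "EphysSimSpec",
    "simulate_skeleton_population",
    "simulate_trialset",
    "simulate_stimulation_pair",
    "epsp_kernel",
    "spike_waveform",
]


# ---------------------------------------------------------------------------
# morphology


@dataclass(frozen=True)
class MorphoPopulationSpec:
    """Population of branching skeletons with group-specific dendrite placement.

    Each neuron is a soma, an axon path toward ``axon_target_centroid`` (shared
    across groups) and a stereotyped dendritic subtree whose point cloud is
    centred on the group's ``dendrite_centroid``; isotropic Gaussian jitter of
    SD ``jitter_sd`` μm perturbs every non-soma node.
    """

    n_per_group: int = 10
    groups: tuple = (
        ("A", (0.0, 40.0, 0.0), (150.0, -50.0, 30.0)),
        ("B", (0.0, 70.0, 0.0), (150.0, -50.0, 30.0)),
    )
    branch_count: tuple = (3, 6)
    nodes_per_branch: int = 10
    segment_length: float = 3.0
    jitter_sd: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_group < 1:
            raise ValueError("n_per_group must be >= 1")
        if self.jitter_sd < 0:
            raise ValueError("jitter_sd must be >= 0")
        for _, dend, axon in self.groups:
            if not (np.all(np.isfinite(dend)) and np.all(np.isfinite(axon))):
                raise ValueError("centroids must be finite")


def _branch_directions(n: int) -> np.ndarray:
    """n deterministic, well-spread unit vectors (golden-spiral points)."""
    i = np.arange(n) + 0.5
    phi = np.arccos(1 - 2 * i / n)
    theta = np.pi * (1 + 5**0.5) * i
    return np.stack([np.sin(phi) * np.cos(theta),
                     np.sin(phi) * np.sin(theta),
                     np.cos(phi)], axis=1)


def _one_skeleton(label: str, dend_centroid, axon_target, n_branches: int,
                  nodes_per_branch: int, segment_length: float,
                  jitter_sd: float, rng: np.random.Generator) -> NeuronSkeleton:
    soma = np.zeros(3)
    axon_target = np.asarray(axon_target, float)
    dend_centroid = np.asarray(dend_centroid, float)

    # axon: straight chain soma -> target, one node per segment_length
    ax_len = np.linalg.norm(axon_target - soma)
    n_ax = max(2, int(np.ceil(ax_len / segment_length)))
    fracs = np.arange(1, n_ax + 1) / n_ax
    axon_nodes = soma + fracs[:, None] * (axon_target - soma)

    # dendrite: stereotyped template (deterministic directions), recentred
    dirs = _branch_directions(n_branches)
    branch_nodes = []
    for b in range(n_branches):
        steps = np.arange(1, nodes_per_branch + 1)[:, None] * segment_length * dirs[b]
        branch_nodes.append(steps)
    dend = np.vstack([np.zeros(3)] + branch_nodes)  # local root + branches
    dend = dend - dend.mean(axis=0) + dend_centroid

    coords = np.vstack([soma, axon_nodes, dend])
    if jitter_sd > 0:
        jitter = rng.normal(0.0, jitter_sd, size=(len(coords), 3))
        jitter[0] = 0.0  # soma fixed
        coords = coords + jitter
    else:
        rng.normal(size=(len(coords), 3))  # keep the stream position identical

    rows = []
    nid = 1
    rows.append((nid, -1, *coords[0], 1.0))  # soma root
    prev = 1
    for i in range(len(axon_nodes)):
        nid += 1
        rows.append((nid, prev, *coords[1 + i], 0.5))
        prev = nid
    dend_base = 1 + len(axon_nodes)
    nid += 1
    dend_root_id = nid
    rows.append((nid, 1, *coords[dend_base], 0.5))
    k = dend_base + 1
    for b in range(n_branches):
        prev = dend_root_id
        for _ in range(nodes_per_branch):
            nid += 1
            rows.append((nid, prev, *coords[k], 0.5))
            prev = nid
            k += 1
    nodes = pd.DataFrame(rows, columns=NODE_COLUMNS)
    return NeuronSkeleton(nodes=nodes, label=label, space_tag="synthetic-template")


def simulate_skeleton_population(spec: MorphoPopulationSpec):
    """Generate the population; returns (skeletons, ground-truth group labels)."""
    rng = np.random.default_rng(spec.seed)
    skels, labels = [], []
    lo, hi = spec.branch_count
    for g_label, dend, axon in spec.groups:
        for i in range(spec.n_per_group):
            nb = int(rng.integers(lo, hi + 1))
            skels.append(_one_skeleton(
                f"{g_label}_{i:03d}", dend, axon, nb, spec.nodes_per_branch,
                spec.segment_length, spec.jitter_sd, rng))
            labels.append(g_label)
    return skels, labels


# ---------------------------------------------------------------------------
# electrophysiology


@dataclass(frozen=True)
class EphysSimSpec:
    """Parameters of simulated current-clamp trials.

    Defaults mirror the recording conditions the analysis expects: 11.1 kHz
    digitization, 500 ms odor pulses, response latency uniform in 150-200 ms,
    4 trials per stimulus.  ``pre_s`` leaves room for pseudo-response windows.
    """

    sampling_rate: float = 11100.0
    baseline: float = -55.0  # mV resting potential
    noise_sd: float = 0.5  # mV
    spike_amplitude: float = 40.0  # mV
    spike_width: float = 0.002  # s
    epsp_amplitude: float = 5.0  # mV
    epsp_latency_range: tuple = (0.150, 0.200)  # s after valve opening
    odor_rate_hz: float = 40.0
    control_rate_hz: float = 2.0
    stimulus_duration: float = 0.5  # s
    n_trials: int = 4
    pre_s: float = 4.0  # trace before onset
    post_s: float = 0.5  # trace after stimulus end
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.odor_rate_hz, self.control_rate_hz) < 0:
            raise ValueError("rates must be >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.epsp_latency_range[1] + self.stimulus_duration > self.post_s + self.stimulus_duration:
            raise ValueError("latency pushes the response past the trace end")


def epsp_kernel(t: np.ndarray, tau_rise: float = 0.005,
                tau_decay: float = 0.040) -> np.ndarray:
    """Difference-of-exponentials EPSP, peak-normalized to 1; zero for t < 0."""
    t = np.asarray(t, float)
    k = np.where(t >= 0, np.exp(-np.maximum(t, 0) / tau_decay)
                 - np.exp(-np.maximum(t, 0) / tau_rise), 0.0)
    t_peak = tau_rise * tau_decay / (tau_decay - tau_rise) * np.log(tau_decay / tau_rise)
    peak = np.exp(-t_peak / tau_decay) - np.exp(-t_peak / tau_rise)
    return k / peak


def spike_waveform(sampling_rate: float, amplitude: float, width: float) -> np.ndarray:
    """Triangular action-potential transient of the given width and amplitude."""
    half = max(1, int(round(width * sampling_rate / 2)))
    up = np.linspace(0.0, 1.0, half + 1)
    down = np.linspace(1.0, 0.0, half + 1)[1:]
    return amplitude * np.concatenate([up, down])


def _add_spikes(v: np.ndarray, times: np.ndarray, wf: np.ndarray, fs: float) -> None:
    half = (len(wf) - 1) // 2
    for t in times:
        c = int(round(t * fs))
        lo, hi = c - half, c - half + len(wf)
        wlo = max(0, -lo)
        whi = len(wf) - max(0, hi - len(v))
        if whi > wlo:
            v[max(0, lo):min(len(v), hi)] += wf[wlo:whi]


def simulate_trialset(spec: EphysSimSpec, odors, control_label: str = "oil",
                      responsive=None, cell_id: str = "cell0"):
    """Simulate one cell's trials for each odor plus the control stimulus.

    ``responsive`` lists the odors that drive the cell (default: the first);
    those trials carry the elevated Poisson spike rate and the EPSP-like
    depolarization inside the 500 ms stimulus window, onset-delayed by the
    odor-response latency.  Returns (TrialSet, truth) where truth maps
    (stimulus, trial_index) to the injected spike times, EPSP amplitude and
    latency.
    """
    if responsive is None:
        responsive = [odors[0]] if odors else []
    rng = np.random.default_rng(spec.seed)
    fs = spec.sampling_rate
    onset = spec.pre_s
    duration = spec.pre_s + spec.stimulus_duration + spec.post_s
    n_samples = int(round(duration * fs))
    t_axis = np.arange(n_samples) / fs
    wf = spike_waveform(fs, spec.spike_amplitude, spec.spike_width)

    trials, truth = [], {}
    for stim in list(odors) + [control_label]:
        driven = stim in responsive
        for k in range(spec.n_trials):
            v = spec.baseline + (rng.normal(0.0, spec.noise_sd, n_samples)
                                 if spec.noise_sd > 0 else np.zeros(n_samples))
            latency = float(rng.uniform(*spec.epsp_latency_range))
            amp = 0.0
            win_lo = onset + latency
            win_hi = win_lo + spec.stimulus_duration
            if driven and spec.epsp_amplitude > 0:
                amp = spec.epsp_amplitude
                v += amp * epsp_kernel(t_axis - win_lo)
            # inhomogeneous Poisson: odor rate inside the response window,
            # control rate elsewhere
            rate_in = spec.odor_rate_hz if driven else spec.control_rate_hz
            n_in = rng.poisson(rate_in * (win_hi - win_lo))
            t_in = rng.uniform(win_lo, win_hi, n_in)
            out_span = duration - (win_hi - win_lo)
            n_out = rng.poisson(spec.control_rate_hz * out_span)
            t_out_raw = rng.uniform(0.0, out_span, n_out)
            t_out = np.where(t_out_raw < win_lo, t_out_raw,
                             t_out_raw + (win_hi - win_lo))
            spikes = np.unique(np.concatenate([t_in, t_out]))
            _add_spikes(v, spikes, wf, fs)
            trials.append(VoltageTrial(
                sampling_rate=fs, voltage=v, stimulus_onset=onset,
                stimulus_duration=spec.stimulus_duration,
                stimulus_label=stim, cell_id=cell_id))
            truth[(stim, k)] = {"spike_times": spikes, "epsp_amplitude": amp,
                                "latency": latency,
                                "n_spikes_in_window": int(n_in)}
    return TrialSet(trials=trials, control_label=control_label), truth


# ---------------------------------------------------------------------------
# glomerular stimulation


def simulate_stimulation_pair(onset_latency_ms: float = 2.0,
                              epsp_amplitude: float = 10.0,
                              artifact_gain: float = 1.0,
                              stim_voltage: float = 3.0,
                              n_trials: int = 6,
                              noise_sd: float = 0.5,
                              sampling_rate: float = 11100.0,
                              stim_onset: float = 1.0,
                              stim_duration: float = 0.5,
                              post_s: float = 0.5,
                              baseline: float = -55.0,
                              rise_tau: float = 0.001,
                              edge_transient_mv_per_v: float = 5.0,
                              seed=None):
    """Simulate test (stimulated) and control-glomerulus trials for one cell.

    Both conditions carry the sustained artifact step (``artifact_gain`` mV/V)
    and brief exponential edge transients; test trials additionally contain a
    fast-rising sustained depolarization starting ``onset_latency_ms`` after
    stimulation onset.  Noise streams depend only on the seed and trial index,
    never on the signal parameters, so amplitude sweeps share noise.
    Returns (StimPair, truth).
    """
    if onset_latency_ms <= 0:
        raise ValueError("latency must be > 0")
    fs = sampling_rate
    n_samples = int(round((stim_onset + stim_duration + post_s) * fs))
    t = np.arange(n_samples) / fs

    step = np.zeros(n_samples)
    in_win = (t >= stim_onset) & (t < stim_onset + stim_duration)
    step[in_win] = artifact_gain * stim_voltage
    tr = edge_transient_mv_per_v * stim_voltage
    transient = (tr * np.exp(-np.maximum(t - stim_onset, 0) / 3e-4) * (t >= stim_onset)
                 - tr * np.exp(-np.maximum(t - stim_onset - stim_duration, 0) / 3e-4)
                 * (t >= stim_onset + stim_duration))

    t0 = stim_onset + onset_latency_ms / 1000.0
    resp = np.zeros(n_samples)
    rising = (t >= t0) & (t < stim_onset + stim_duration)
    resp[rising] = 1.0 - np.exp(-(t[rising] - t0) / rise_tau)
    after = t >= stim_onset + stim_duration
    level = 1.0 - np.exp(-(stim_onset + stim_duration - t0) / rise_tau)
    resp[after] = level * np.exp(-(t[after] - stim_onset - stim_duration) / 0.020)
    resp *= epsp_amplitude

    streams = np.random.SeedSequence(seed).spawn(2 * n_trials)
    make = lambda ss: (np.random.default_rng(ss).normal(0.0, noise_sd, n_samples)
                       if noise_sd > 0 else np.zeros(n_samples))
    test, ctrl = [], []
    for i in range(n_trials):
        test.append(VoltageTrial(
            sampling_rate=fs, voltage=baseline + make(streams[i]) + step + transient + resp,
            stimulus_onset=stim_onset, stimulus_duration=stim_duration,
            stimulus_label="DA1", cell_id="stim_cell"))
        ctrl.append(VoltageTrial(
            sampling_rate=fs, voltage=baseline + make(streams[n_trials + i]) + step + transient,
            stimulus_onset=stim_onset, stimulus_duration=stim_duration,
            stimulus_label="control", cell_id="stim_cell"))
    pair = StimPair(test_trials=test, control_trials=ctrl,
                    stim_onset=stim_onset, stim_duration=stim_duration,
                    stim_voltage=stim_voltage)
    truth = {"latency_ms": onset_latency_ms, "epsp_amplitude": epsp_amplitude,
             "artifact_gain": artifact_gain}
    return pair, truth
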