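# Methods

## Morphology representation and similarity

Traced neurons enter as SWC trees (1-based node ids, parent −1 for roots,
coordinates in μm).  Coordinates are assumed to be registered to a common
template brain already; registration itself is out of scope.  The `space_tag`
field records the registration space and is compared only with a warning,
never an error, since mismatched tags are a workflow smell rather than a
computational fault.

Before scoring, skeletons are resampled so no edge exceeds a step of 1 μm
(default).  The original point spacing of a tracing is tool-dependent; 1 μm is
well below σ = 3 μm, so scores are insensitive to node density while branch
and end points are preserved exactly and cable length is conserved (both
property-tested).  Each node then receives a unit tangent: the first principal
axis of its k = 5 nearest nodes (the node itself included), computed by SVD of
the centred neighbourhood.  The estimator is deterministic and
rotation-equivariant; because a principal axis is defined only up to sign, the
tangent is canonicalized so its first nonzero component (x, then y, then z) is
nonnegative.  The score uses only |q·t|, so the sign convention never affects
results — it exists to make outputs reproducible and comparable across runs.

The similarity score is

S(Q,T) = (1/n) Σ_i |q_i · t_j| exp(−d_ij² / 2σ²),  D(Q,T) = 1 − S(Q,T),

with the nearest neighbour j found by a k-d tree (ties resolved to the lowest
target index, for determinism; verified against an exhaustive double loop to
1e-12).  σ defaults to 3 μm, matching registration accuracy / biological
variability in the fly brain; it is the only free parameter and the one most
worth varying when adapting the method to other systems.

S is asymmetric (each direction averages over its own query points).  How the
two directions were combined before clustering is not derivable from the
method's description, so the package symmetrizes with the mean by default
(the least-informative symmetric combination that stays in [0,1]); min, max
and none are selectable.

Clustering is classic Ward on the distances as given — the "ward.D"-style
Lance–Williams update on unsquared dissimilarities, matching the behaviour of
the R clustering environment this analysis style originated in.  It is
computed exactly by running scipy's Ward recurrence on √d and squaring the
merge heights back (the recurrence on squared inputs is identical
algebraically); a unit test cross-checks merge heights against R's
`hclust(method="ward.D")`.  The D2 variant and average/complete/single
linkage are selectable.  `cut_clusters` uses `cut_tree`, guaranteeing exactly
k groups.

## Spike extraction

Traces are smoothed with a binomial (Pascal-row) kernel.  The kernel length
for a requested cutoff is a convention the original description leaves open:
here the (n+1)-tap kernel has frequency response cos(πf/fs)ⁿ, and the
smallest even n with −3 dB point at or below the cutoff is used, giving the
shortest odd kernel that honours the cutoff (the response at the cutoff is
then 0.707 within a few percent, FFT-verified).  The smoothing band in the
source protocol was 180–550 Hz tuned per cell with no stated rule; the
default is 400 Hz with a per-call override.

Spikes are samples where the second central difference of the smoothed trace
falls below a negative threshold.  The threshold value is unstated in the
protocol; auto mode uses −8 × (1.4826·MAD) of the second derivative — the MAD
estimates the derivative's noise SD robustly, so the threshold adapts to the
noise floor while ignoring the spikes themselves.  Sub-threshold samples are
grouped into events; events separated by less than the 2 ms refractory gap
merge (two simulated spikes 1 ms apart yield one event), and each event is
timed at the raw-trace voltage maximum within it.  Detection is invariant to
DC offsets and achieves ≥95% recall and precision on the synthetic benchmark
(40 mV spikes, 0.5 mV noise, 11.1 kHz).

## Response statistics

Spiking responses: mean spike count in [onset+0.15 s, onset+0.65 s), minus the
control-stimulus count; Hz values divide by the 0.5 s window.  Significance is
the exact one-sided two-sample Poisson test in its conditional form: given
total count N = K_odor + K_control over equal trial counts, K_odor is
Binomial(N, ½) under the null, and p = P(X ≥ K_odor).  Unequal trial counts
enter through the exposure ratio r, giving success probability r/(1+r).  The
implementation is checked exhaustively against the binomial tail sum for all
K ≤ 50.  BH adjustment is the standard step-up, cross-checked against
statsmodels; FDR is applied per cell across its odors by default (a global
scope is selectable — the original scope is unstated).  α = 0.01.

Peak firing rate: max over five consecutive 200 ms windows from +150 ms.
Lifetime sparseness S = (1 − (Σr/n)²/(Σr²/n)) / (1 − 1/n); whether the
original used raw or baseline-subtracted rates is unstated, and the formula is
undefined for negative entries, so inhibitory (negative) mean responses are
rectified to 0 first (configurable) and an all-zero vector returns 0.

Subthreshold responses: 45 ms boxcar smoothing, peak in +200…+800 ms minus
the mean over −1000…0 ms.  Pseudo responses repeat the identical computation
at pseudo-onsets stepped back 1.0 s at a time into the pre-stimulus period of
every trace available for the cell (odors and control alike), by default 3
windows per trace.  The count of pseudo windows is a genuine design choice:
with 4 trials and a single pseudo window per trace the exact permutation
p-value can never fall below 2/C(8,4) ≈ 0.029, so the FDR-0.01 significance
rule could never fire; pooling the pre-stimulus periods of all traces (as the
procedure describes) with 3 windows each gives a p-value floor of
1/C(16,4) ≈ 5.5·10⁻⁴ even for a single-odor cell.  Real vs pseudo responses
are compared by a permutation test on the difference of means — magnitude-
sensitive, unlike a Wilcoxon test — exact when C(n, n_real) ≤ 10⁵, otherwise
seeded Monte-Carlo with the observed assignment counted in numerator and
denominator.  Two-sided by default; one-sided selectable.  Under the null the
raw rejection rate at α = 0.05 calibrates to 0.03–0.07 (500 simulations in
the acceptance suite).

Group comparisons (e.g. wild-type vs mutant response magnitudes) use the same
permutation test directly.

The ~5.5 mV peak-depolarization threshold above which cells tended to spike
is exposed as the annotation constant `DEPOL_SPIKE_THRESHOLD_MV`; it is a
reported observation, not something the package infers.

## Glomerular stimulation

The sustained stimulation artifact is modelled as a constant per-cell gain
(mV per stimulation volt, typically ~1), fitted from control-glomerulus
trials as (plateau mean over the last 100 ms of stimulation − 500 ms
pre-onset baseline)/voltage, then subtracted inside the stimulation window
only.  The <2 ms edge transients are masked by linear interpolation across
the edge, not modelled.  Evoked depolarization is the stimulation-window mean
minus the 500 ms pre-onset mean.

Latency: traces are smoothed with a moving-average kernel whose −3 dB point
is nearest to 2.2 kHz (length rounded to the nearest odd sample count — 3
samples at 11.1 kHz), normalized by each trace's mean over the first 0.5 ms
after stimulation, and averaged within 0.5 ms bins.  Per bin, the per-trial
bin means of the test condition are compared with the control condition by a
one-tailed rank-sum test (per-trial bin means are used as the independent
replicates; the pooled-samples alternative is a documented open choice).  The
exact Mann–Whitney null distribution (partition-count recurrence, cached per
group-size pair) is used for m·n ≤ 400, the normal approximation with
continuity and tie corrections beyond.  The latency is the start of the
earliest bin from which every bin through the end of the 500 ms pulse has
p < 0.05; if no such bin exists the estimator returns none.  Note the strict
inequality: with exactly 3 trials per condition the one-sided exact floor is
1/20 = 0.05, so 3-trial experiments can never reach significance — a property
of the printed rule, documented rather than patched.  Estimates are invariant
to common DC shifts and to artifact subtraction, and on synthetic pairs with
SNR ≥ 10 recover a true onset uniform in 1–5 ms to within half a bin in ≥90%
of runs.

## Synthetic data

The morphology generator emulates group-specific dendritic placement: each
neuron is a soma at the origin, an axon chain to a shared target, and a
stereotyped dendritic template (branch directions on a golden spiral, so
geometry is deterministic apart from the drawn branch count) recentred on the
group's dendrite centroid, with isotropic Gaussian positional jitter
(default SD 2 μm) on all non-soma nodes.  Default centroid separation is
30 μm = 10σ.  It does *not* emulate tracing errors, registration distortion,
cut branches or radius information; clustering successes on it show the score
separates displaced but otherwise similar arbours, not that it is robust to
tracing pathology.

The recording generator produces trials at 11.1 kHz: −55 mV baseline,
Gaussian noise (default SD 0.5 mV), an EPSP-like depolarization (difference
of exponentials, τ_rise 5 ms, τ_decay 40 ms, default 5 mV) starting at the
odor-response latency drawn uniformly from 150–200 ms after valve opening,
and triangular 2 ms spike waveforms (default 40 mV) at times from an
inhomogeneous Poisson process — the odor rate inside the 500 ms response
window of driven odors, the control rate elsewhere — so ground-truth window
counts are exactly Poisson (χ²-verified).  Four trials per stimulus, 4 s
pre-stimulus context by default so three pseudo-response windows fit.  White
noise and stereotyped kernels mean the generator underrepresents slow drift,
synaptic bombardment and spike-shape variability; detector and calibration
results should be read as behaviour under those idealized conditions.

The stimulation generator adds, to both conditions, the sustained artifact
step plus fast exponential edge transients, and to the test condition a
sustained depolarization rising with τ = 1 ms from the synaptic latency to
the end of the pulse.  Noise streams derive only from the seed and trial
index, never from signal parameters, so amplitude sweeps share noise — which
is what makes the latency-vs-amplitude monotonicity property testable per
seed.

All generators are pure functions of spec + seed; per-component substreams
derive from one SeedSequence.

## Problem sizes in the shipped suites

The test and acceptance suites use deliberately modest sizes chosen to keep a
full run around half a minute on one core while leaving the statistical
assertions well-powered: 1000-point clouds for oracle equivalence, 20 seeds
for cluster recovery, 50 traces for the detector benchmark, 100 pairs for
latency recovery, 2000 null cells for Poisson+BH calibration and 500
simulations for subthreshold null calibration.
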