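import itertools
from math import comb

import numpy as np
import pytest
from statsmodels.stats.multitest import multipletests

from pherocircuit.ephys import SpikeTrain, TrialSet, VoltageTrial
from pherocircuit.responses import (bh_adjust, build_response_table,
                                    group_comparison_test, lifetime_sparseness,
                                    peak_firing_rate, poisson_response_test,
                                    response_magnitude, subthreshold_response,
                                    subthreshold_table, subthreshold_test,
                                    window_spike_count)
from pherocircuit.simulate import EphysSimSpec, simulate_trialset

FS = 11100.0


def train(times):
    return SpikeTrain(times=np.asarray(times, float))


class TestWindowCount:
    def test_default_window_interval_arithmetic(self):
        st = train([1.2, 1.4, 1.7])
        assert window_spike_count(st, onset=1.0) == 2  # window is [1.15, 1.65)

    def test_empty_train(self):
        assert window_spike_count(train([]), onset=0.0) == 0

    def test_matches_brute_force(self, rng):
        t = np.sort(rng.uniform(0, 5, 100))
        t = t[np.concatenate([[True], np.diff(t) > 0])]
        st = train(t)
        got = window_spike_count(st, onset=1.0, start_offset=0.3, length=0.8)
        assert got == sum(1 for x in t if 1.3 <= x < 2.1)

    def test_negative_length_rejected(self):
        with pytest.raises(ValueError):
            window_spike_count(train([1.0]), onset=0.0, length=-1.0)


class TestMagnitude:
    def test_arithmetic(self):
        assert response_magnitude([4, 5, 4, 5], [1, 1, 1, 1], 0.5) == (3.5, 7.0)

    def test_identical_lists_zero(self):
        assert response_magnitude([2, 3], [2, 3])[0] == 0.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            response_magnitude([], [1])


class TestPoissonTest:
    def test_known_tail_sum(self):
        assert poisson_response_test([10], [2]) == pytest.approx(79 / 4096, abs=1e-15)

    def test_symmetric_counts_at_least_half(self):
        for k in (0, 1, 5, 20):
            assert poisson_response_test([k], [k]) >= 0.5

    def test_degenerate_zero_counts(self):
        assert poisson_response_test([0, 0], [0, 0]) == 1.0

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            poisson_response_test([-1], [2])

    def test_exposure_ratio_from_unequal_trials(self):
        # 2 odor trials vs 4 control trials: null success prob = 1/3
        p = poisson_response_test([3, 3], [1, 1, 1, 1])
        n, k_o, q = 10, 6, 1 / 3
        expected = sum(comb(n, k) * q**k * (1 - q) ** (n - k) for k in range(k_o, n + 1))
        assert p == pytest.approx(expected, rel=1e-12)


class TestBH:
    def test_hand_step_up(self):
        assert np.allclose(bh_adjust([0.01, 0.02, 0.03, 0.04]), 0.04)

    def test_single_and_equal_inputs(self):
        assert bh_adjust([0.3]) == pytest.approx([0.3])
        assert np.allclose(bh_adjust([0.2, 0.2, 0.2]), 0.2)

    def test_against_statsmodels(self, rng):
        for _ in range(20):
            p = rng.uniform(size=rng.integers(1, 40))
            expected = multipletests(p, method="fdr_bh")[1]
            assert np.allclose(bh_adjust(p), expected, atol=1e-12)

    def test_permutation_equivariance_and_monotonicity(self, rng):
        p = rng.uniform(size=15)
        perm = rng.permutation(15)
        assert np.allclose(bh_adjust(p)[perm], bh_adjust(p[perm]))
        adj = bh_adjust(p)
        bumped = p.copy()
        bumped[3] = min(1.0, bumped[3] + 0.1)
        assert np.all(bh_adjust(bumped) >= adj - 1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])


class TestPeakRate:
    def test_spikes_in_one_window(self):
        # windows from onset+0.15 in 200 ms steps: [1.15,1.35) ... [1.75,1.95)
        st = train([1.76, 1.78, 1.80, 1.84])  # 4 spikes, all in the last window
        assert peak_firing_rate(st, onset=1.0) == 20.0

    def test_empty_train_zero(self):
        assert peak_firing_rate(train([]), onset=1.0) == 0.0

    def test_matches_brute_force(self, rng):
        t = np.sort(rng.uniform(1.0, 2.2, 40))
        st = train(t)
        rates = [sum(1 for x in t if 1.15 + 0.2 * i <= x < 1.35 + 0.2 * i) / 0.2
                 for i in range(5)]
        assert peak_firing_rate(st, onset=1.0) == max(rates)


class TestSparseness:
    def test_uniform_tuning_zero(self):
        assert lifetime_sparseness([5.0] * 6) == 0.0

    def test_single_odor_tuning_one(self):
        assert lifetime_sparseness([20.0, 0, 0, 0, 0, 0]) == pytest.approx(1.0)

    def test_direct_formula_value(self):
        assert lifetime_sparseness([2, 1, 0, 0]) == pytest.approx(0.733333, abs=1e-6)

    def test_scale_invariance(self, rng):
        r = rng.uniform(0, 30, 8)
        assert lifetime_sparseness(3.7 * r) == pytest.approx(lifetime_sparseness(r))

    def test_negative_rectified_and_all_zero(self):
        assert lifetime_sparseness([-1.0, -2.0]) == 0.0
        assert lifetime_sparseness([-1.0, 5.0]) == pytest.approx(1.0)

    def test_needs_two_odorants(self):
        with pytest.raises(ValueError):
            lifetime_sparseness([1.0])


def flat_trial(onset=2.0, dur=3.2, level=-55.0, fs=FS, **kw):
    return VoltageTrial(sampling_rate=fs, voltage=np.full(int(dur * fs), level),
                        stimulus_onset=onset, **kw)


class TestSubthresholdResponse:
    def test_flat_trace_zero(self):
        assert subthreshold_response(flat_trial()) == pytest.approx(0.0, abs=1e-12)

    def test_injected_plateau_recovered(self, rng):
        v = flat_trial().voltage + rng.normal(0, 0.2, int(3.2 * FS))
        lo, hi = int(2.3 * FS), int(2.6 * FS)
        v[lo:hi] += 4.0
        t = VoltageTrial(sampling_rate=FS, voltage=v, stimulus_onset=2.0)
        assert subthreshold_response(t) == pytest.approx(4.0, abs=0.2)

    def test_dc_offset_invariant(self, rng):
        base = flat_trial().voltage + rng.normal(0, 0.3, int(3.2 * FS))
        a = VoltageTrial(sampling_rate=FS, voltage=base, stimulus_onset=2.0)
        b = VoltageTrial(sampling_rate=FS, voltage=base + 17.0, stimulus_onset=2.0)
        assert subthreshold_response(a) == pytest.approx(subthreshold_response(b),
                                                         abs=1e-9)

    def test_insufficient_context_rejected(self):
        with pytest.raises(ValueError):
            subthreshold_response(flat_trial(onset=0.5, dur=1.5))


class TestGroupComparison:
    def test_symmetric_groups_p_one(self):
        assert group_comparison_test([1, 2], [1, 2]) == 1.0

    def test_full_enumeration_extreme(self):
        assert group_comparison_test([0, 0, 0], [10, 10, 10]) == pytest.approx(0.1)

    def test_exact_matches_manual_enumeration(self, rng):
        a, b = rng.normal(size=4), rng.normal(size=4)
        pooled = np.concatenate([a, b])
        obs = abs(a.mean() - b.mean())
        count = 0
        for idx in itertools.combinations(range(8), 4):
            sel = pooled[list(idx)]
            rest = np.delete(pooled, list(idx))
            if abs(sel.mean() - rest.mean()) >= obs - 1e-12:
                count += 1
        assert group_comparison_test(a, b) == pytest.approx(count / comb(8, 4))

    def test_zero_variance_identical_groups(self):
        assert group_comparison_test([3.0, 3.0], [3.0, 3.0]) == 1.0

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            group_comparison_test([], [1.0])

    def test_monte_carlo_null_type_i_error(self):
        """Type-I error 0.05 +/- 0.02 for Normal(0,1) groups of 10 (MC path)."""
        rejections = 0
        n_sims = 1000
        for seed in range(n_sims):
            rng = np.random.default_rng(seed)
            p = group_comparison_test(rng.normal(size=10), rng.normal(size=10),
                                      n_perm=999, seed=seed)
            rejections += p < 0.05
        assert 0.03 <= rejections / n_sims <= 0.07


class TestSubthresholdTest:
    def _cell(self, seed, epsp=0.0, odors=("cva",)):
        spec = EphysSimSpec(seed=seed, epsp_amplitude=epsp, odor_rate_hz=0.0,
                            control_rate_hz=0.0, noise_sd=0.5)
        ts, _ = simulate_trialset(spec, list(odors))
        return ts

    def test_responsive_cell_detected_nonresponsive_not(self):
        """Male-like cell (5 mV EPSP) flagged; female-like (no input) not."""
        hits = misses = 0
        for seed in range(20):
            male = subthreshold_table(self._cell(seed, epsp=5.0), seed=seed)[0]
            female = subthreshold_table(self._cell(1000 + seed, epsp=0.0),
                                        seed=seed)[0]
            hits += male.significant
            misses += not female.significant
        assert hits == 20 and misses >= 19

    def test_zero_pseudo_room_rejected(self):
        spec = EphysSimSpec(seed=0, pre_s=1.5)
        ts, _ = simulate_trialset(spec, ["cva"])
        with pytest.raises(ValueError):
            subthreshold_test(ts, "cva", n_null_windows=3)

    def test_adjusted_at_least_raw(self):
        ts = self._cell(3, epsp=2.0, odors=("cva", "pa"))
        for r in subthreshold_table(ts, seed=3):
            assert r.adjusted_p >= r.raw_p - 1e-15


class TestResponseTable:
    def test_driven_cell_significant_table(self):
        spec = EphysSimSpec(seed=9, pre_s=1.0, post_s=0.5)
        ts, _ = simulate_trialset(spec, ["cva", "pa"])
        df = build_response_table(ts)
        row = df.set_index("stimulus_label")
        assert bool(row.loc["cva", "significant"])
        assert not bool(row.loc["pa", "significant"])
        assert (df["adjusted_p"] >= df["raw_p"] - 1e-15).all()

    def test_control_label_required(self):
        spec = EphysSimSpec(seed=9, pre_s=1.0, post_s=0.5)
        ts, _ = simulate_trialset(spec, ["cva"])
        ts.control_label = ""
        with pytest.raises(ValueError):
            build_response_table(ts)
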