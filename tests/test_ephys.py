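"""Unit and property tests for the patch-clamp analysis chain."""
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from optoresp import ephys
from optoresp.types import InputError, ThresholdPair

from conftest import (
    classify_oracle,
    percentile_oracle,
    sliding_median_oracle,
    trapezoid_oracle,
    wilcoxon_exact_oracle,
)

RATE = 1000.0  # Hz; small rate keeps the brute-force oracles cheap


class TestMedianFilter:
    def test_constant_trace_unchanged(self):
        out = ephys.median_filter_trace(np.full(500, 3.5), 0.25, RATE)
        assert np.allclose(out, 3.5)

    def test_single_impulse_removed(self):
        x = np.zeros(2000)
        x[1000] = 50.0
        out = ephys.median_filter_trace(x, 0.25, RATE)
        assert np.allclose(out, 0.0)

    def test_matches_naive_sliding_median(self, rng):
        x = rng.normal(size=1000)
        w = int(round(0.25 * RATE))
        out = ephys.median_filter_trace(x, 0.25, RATE)
        assert np.allclose(out, sliding_median_oracle(x, w), rtol=1e-9, atol=1e-12)

    def test_empty_trace_rejected(self):
        with pytest.raises(InputError):
            ephys.median_filter_trace(np.array([]), 0.25, RATE)


class TestCenterTrace:
    def test_simple_example(self):
        assert np.allclose(ephys.center_trace([1.0, 2.0, 3.0]), [-1, 0, 1])

    def test_idempotent_on_zero_median(self):
        x = np.array([-1.0, 0.0, 1.0])
        assert np.allclose(ephys.center_trace(x), x)

    @settings(deadline=None, derandomize=True, max_examples=30)
    @given(st.lists(st.floats(-100, 100), min_size=1, max_size=200))
    def test_output_median_is_zero(self, values):
        out = ephys.center_trace(np.array(values))
        assert abs(np.median(out)) < 1e-9


class TestTrialMedian:
    def test_identical_trials(self, rng):
        tr = rng.normal(size=100)
        assert np.allclose(ephys.trial_median(np.tile(tr, (5, 1))), tr)

    def test_odd_count_median(self):
        trials = np.array([[0.0], [0.0], [3.0]])
        assert ephys.trial_median(trials)[0] == 0.0

    def test_matches_per_column_sort(self, rng):
        m = rng.normal(size=(5, 100))
        expected = np.array([sorted(m[:, j])[2] for j in range(100)])
        assert np.allclose(ephys.trial_median(m), expected)


class TestBaselineThresholds:
    def test_constant_baseline(self):
        trials = np.full((3, 1200), 7.0)
        thr = ephys.baseline_thresholds(trials, RATE)
        assert thr.lower == thr.upper == 7.0

    def test_matches_percentile_oracle(self):
        trials = np.linspace(1, 100, 100).reshape(1, 100)
        # window covering all samples: start 0, len covering everything
        thr = ephys.baseline_thresholds(trials, sampling_rate=100.0,
                                        window_start=0.0, window_len=1.0)
        assert thr.lower == pytest.approx(percentile_oracle(trials.ravel(), 10))
        assert thr.upper == pytest.approx(percentile_oracle(trials.ravel(), 90))

    def test_gaussian_coverage(self, rng):
        trials = rng.normal(size=(10, 2000))
        thr = ephys.baseline_thresholds(trials, RATE, 0.1, 0.9)
        seg = trials[:, 100:1000].ravel()
        frac = np.mean((seg > thr.lower) & (seg < thr.upper))
        se = np.sqrt(0.8 * 0.2 / seg.size)
        assert abs(frac - 0.8) < 3 * se + 1e-3

    def test_window_outside_trace_rejected(self):
        with pytest.raises(InputError):
            ephys.baseline_thresholds(np.zeros((2, 100)), RATE, 0.1, 0.9)


class TestClassification:
    THR = ThresholdPair(lower=-1.0, upper=1.0)

    def test_flat_trace_unaffected(self):
        trace = np.zeros(3000)
        assert ephys.classify_vm_response(trace, self.THR, 1.0, RATE) == "unaffected"

    def test_step_80ms_excited(self):
        trace = np.zeros(3000)
        trace[1000:1080] = 2.0  # 80 ms ≥ 50 ms criterion
        assert ephys.classify_vm_response(trace, self.THR, 1.0, RATE) == "excited"

    def test_short_dip_unaffected(self):
        trace = np.zeros(3000)
        trace[1100:1130] = -2.0  # 30 ms < 50 ms criterion
        assert ephys.classify_vm_response(trace, self.THR, 1.0, RATE) == "unaffected"

    def test_long_dip_inhibited(self):
        trace = np.zeros(3000)
        trace[1100:1180] = -2.0
        assert ephys.classify_vm_response(trace, self.THR, 1.0, RATE) == "inhibited"

    def test_matches_run_length_oracle_on_random_traces(self, rng):
        min_len = int(round(0.05 * RATE))
        for _ in range(100):
            trace = rng.normal(scale=1.2, size=2200)
            got = ephys.classify_vm_response(trace, self.THR, 1.0, RATE)
            seg = trace[1000:2000]
            assert got == classify_oracle(seg, -1.0, 1.0, min_len)

    def test_earlier_run_precedence(self):
        trace = np.zeros(3000)
        trace[1010:1090] = -2.0   # inhibition run starts first
        trace[1200:1280] = 2.0
        assert ephys.classify_vm_response(trace, self.THR, 1.0, RATE) == "inhibited"


class TestSpikeDetection:
    def test_flat_trace_no_spikes(self):
        assert ephys.detect_spikes(np.zeros(2000), RATE).size == 0

    def test_two_template_spikes_recovered(self, rng):
        from optoresp.synthetic import spike_template

        rate = 20_000.0
        trace = -40.0 + rng.normal(0, 0.1, int(rate))
        tpl = spike_template(rate)
        for ts in (0.20, 0.70):
            i = int(ts * rate)
            trace[i:i + tpl.size] += tpl
        peaks = ephys.detect_spikes(trace, rate)
        assert peaks.size == 2
        # template peaks a fraction of a ms after insertion onset
        assert np.all(np.abs(peaks - np.array([0.20, 0.70])) < 2e-3)

    def test_refractory_deduplication(self):
        from optoresp.synthetic import spike_template

        rate = 20_000.0
        trace = np.zeros(int(rate * 0.5))
        tpl = spike_template(rate)
        for ts in (0.2, 0.2005):  # 0.5 ms apart
            i = int(ts * rate)
            trace[i:i + tpl.size] += tpl
        peaks = ephys.detect_spikes(trace, rate, refractory=0.002)
        assert peaks.size == 1


class TestFiringRate:
    def test_no_spikes_all_zero(self):
        from optoresp.types import SpikeTrain
        rates = ephys.bin_firing_rate(SpikeTrain([[]]), duration=1.0)
        assert np.allclose(rates, 0.0)

    def test_hand_counted_bins(self):
        from optoresp.types import SpikeTrain
        rates = ephys.bin_firing_rate(SpikeTrain([[0.1, 0.3]]), duration=1.0)
        assert np.allclose(rates, [4.0, 4.0, 0.0, 0.0])

    def test_trial_average_of_identical_trials(self):
        from optoresp.types import SpikeTrain
        st10 = SpikeTrain([[0.1]] * 10)
        rates = ephys.bin_firing_rate(st10, duration=1.0)
        assert rates[0] == pytest.approx(4.0)
        assert np.allclose(rates[1:], 0.0)


class TestResponseAuc:
    def test_zero_trace(self):
        post, base, delta = ephys.response_auc(np.zeros(3000), RATE, 1.0)
        assert post == base == delta == 0.0

    def test_constant_trace(self):
        post, base, delta = ephys.response_auc(np.full(3000, 2.0), RATE, 1.0)
        assert post == pytest.approx(2.0)
        assert base == pytest.approx(2.0)
        assert delta == pytest.approx(0.0)

    def test_linear_ramp_triangle_area(self):
        rate = 20_000.0
        n = int(2.5 * rate)
        trace = np.zeros(n)
        i0 = int(1.0 * rate)
        i1 = int(2.0 * rate)
        trace[i0:i1] = np.linspace(0, 1, i1 - i0)
        post, base, delta = ephys.response_auc(trace, rate, 1.0)
        assert base == pytest.approx(0.0, abs=1e-9)
        assert post == pytest.approx(0.5, abs=1e-4)
        assert delta == pytest.approx(0.5, abs=1e-4)

    def test_matches_trapezoid_oracle(self, rng):
        trace = rng.normal(size=2200)
        post, base, delta = ephys.response_auc(trace, RATE, 1.0)
        assert post == pytest.approx(trapezoid_oracle(trace[1000:2001], 1 / RATE), rel=1e-9)
        assert base == pytest.approx(trapezoid_oracle(trace[0:1001], 1 / RATE), rel=1e-9)


class TestLatency:
    def _step_trials(self, rate, delay, amp, noise, rng, n_trials=10,
                     drift_amp=0.0):
        n = int(2.5 * rate)
        step = int((1.0 + delay) * rate)
        trials = rng.normal(0, noise, (n_trials, n)) if noise > 0 else np.zeros((n_trials, n))
        if drift_amp > 0:
            # slow baseline wander so the SG-filtered percentile thresholds
            # stay meaningful (pure white noise is annihilated by the filter)
            t = np.arange(n) / rate
            for k in range(n_trials):
                trials[k] += drift_amp * np.sin(2 * np.pi * 0.7 * t
                                                + rng.uniform(0, 2 * np.pi))
        trials[:, step:] += amp
        return trials

    def test_step_latency_matches_scan_oracle(self, rng):
        rate = 5000.0
        trials = self._step_trials(rate, 0.05, 5.0, 0.3, rng, drift_amp=0.8)
        lat, per = ephys.estimate_latency(trials, rate, 1.0, "excited")
        # crossings can only precede a sharp step, never trail it; the
        # shortest SG window barely smears the edge and stays close to it
        assert lat is not None and 0.0 <= lat <= 0.055
        assert 0.02 <= per[0.05] <= 0.055
        # each per-window latency must match a direct scan on that filtered trace
        from scipy.signal import savgol_filter
        for w, got in per.items():
            wl = int(round(w * rate))
            wl += (wl % 2 == 0)
            filt = savgol_filter(trials, wl, 4, axis=1)
            filt = filt - np.median(filt, axis=1, keepdims=True)
            med = np.median(filt, axis=0)
            thr = ephys.baseline_thresholds(filt, rate, 0.1, 0.9)
            seg = med[int(rate):int(2 * rate)]
            hits = np.flatnonzero(seg > thr.upper)
            expected = hits[0] / rate if hits.size else None
            assert got == pytest.approx(expected)

    def test_no_crossing_is_undefined(self):
        rate = 2000.0
        trials = np.zeros((5, int(2.5 * rate)))
        lat, per = ephys.estimate_latency(trials, rate, 1.0, "excited")
        assert lat is None
        assert all(v is None for v in per.values())

    def test_sign_symmetry(self, rng):
        rate = 5000.0
        up = self._step_trials(rate, 0.05, 5.0, 0.02, rng)
        lat_up, _ = ephys.estimate_latency(up, rate, 1.0, "excited")
        down = -(up - np.median(up))  # mirror around the baseline
        lat_down, _ = ephys.estimate_latency(down, rate, 1.0, "inhibited")
        assert lat_up == pytest.approx(lat_down, abs=1e-9)

    def test_unaffected_label_rejected(self):
        with pytest.raises(InputError):
            ephys.estimate_latency(np.zeros((2, 100)), 100.0, 0.5, "unaffected")


class TestWilcoxon:
    def test_identical_vectors_degenerate(self):
        assert ephys.paired_wilcoxon([1, 2, 3], [1, 2, 3]) == 1.0

    def test_six_positive_differences_exact(self):
        pre = np.zeros(6)
        post = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        assert ephys.paired_wilcoxon(pre, post) == pytest.approx(0.03125)

    def test_matches_exact_enumeration(self, rng):
        for _ in range(20):
            pre = rng.normal(size=8)
            post = pre + rng.normal(size=8)
            p = ephys.paired_wilcoxon(pre, post)
            assert p == pytest.approx(wilcoxon_exact_oracle(pre, post), abs=1e-9)

    def test_length_mismatch_rejected(self):
        with pytest.raises(InputError):
            ephys.paired_wilcoxon([1, 2], [1, 2, 3])


class TestEffectCoefficient:
    def test_single_excited_cell_is_one(self):
        coeff, norm, fb = ephys.population_effect_coefficient([2.5], ["excited"])
        assert coeff == 1.0 and not fb

    def test_hand_arithmetic(self):
        coeff, norm, fb = ephys.population_effect_coefficient(
            [2.0, -1.0], ["excited", "inhibited"])
        assert coeff == pytest.approx(0.25)
        assert norm == 2.0 and not fb

    def test_all_unaffected_fallback(self):
        coeff, norm, fb = ephys.population_effect_coefficient(
            [1e-12, -1e-12], ["unaffected", "unaffected"])
        assert fb
        assert abs(coeff) < 1.0 + 1e-9

    def test_bounded_by_one_when_excited_max_positive(self, rng):
        aucs = rng.normal(size=20)
        labels = ["excited" if a > 0.5 else "inhibited" for a in aucs]
        if "excited" in labels:
            coeff, norm, fb = ephys.population_effect_coefficient(aucs, labels)
            assert coeff <= 1.0 + 1e-12


class TestRecoveryProperties:
    def test_delta_auc_sign_matches_polarity(self):
        from optoresp.synthetic import EphysSimConfig, gen_ephys_session

        labels = ["excited", "inhibited"] * 3
        cfg = EphysSimConfig(n_cells=6, sampling_rate=2000.0, response_labels=labels,
                             noise_sd=0.3, response_amplitude=8.0, seed=21)
        sets, gt = gen_ephys_session(cfg)
        for ts in sets:
            res = ephys.classify_cell(ts, with_latency=False)
            assert res.label == gt.labels[ts.cell_id]
            want = 1.0 if gt.labels[ts.cell_id] == "excited" else -1.0
            assert np.sign(res.delta_auc) == want

    def test_population_summary_counts_and_pvalues(self):
        from optoresp.synthetic import EphysSimConfig, gen_ephys_session

        labels = ["excited"] * 6 + ["unaffected"] * 2
        cfg = EphysSimConfig(n_cells=8, sampling_rate=2000.0, response_labels=labels,
                             noise_sd=0.3, seed=5)
        sets, _ = gen_ephys_session(cfg)
        results = ephys.analyze_session(sets, with_latency=False)
        summ = ephys.summarize_population(results, "testline")
        assert sum(summ.cluster_counts.values()) == 8
        assert "all" in summ.p_values
        assert "excited" in summ.p_values          # n = 6 ≥ 5
        assert "unaffected" not in summ.p_values   # n = 2 < 5
        assert summ.effect_coefficient <= 1.0
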