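"""iEEG preprocessing, median-ratio artifact filters, ERPs, peak latencies."""

import warnings

import numpy as np
import pytest
from scipy import signal

from adaptmtl import ieeg
from adaptmtl.synth import ErpTemplateSpec, simulate_ieeg, simulate_ieeg_raw
from adaptmtl.synth.stimuli import ConfigurationError


def _segments(data, conditions=None, rate=256.0, window=(-1000.0, 2000.0)):
    n = len(data)
    conds = conditions if conditions is not None else np.array(["primed", "control"] * (n // 2 + 1))[:n]
    return ieeg.IeegSegments(data=np.asarray(data, float), rate=rate, window_ms=window, conditions=conds)


class TestPreprocess:
    def test_constant_voltage_becomes_zero(self):
        segs = ieeg.preprocess(
            np.full((4, 4096), 3.5), 1024.0, np.array(["primed"] * 4), epoch_tmin_ms=-1500.0
        )
        assert np.abs(segs.data).max() < 1e-12
        assert segs.data.shape == (4, 768)

    def test_stopband_attenuation_at_100hz(self):
        sos = ieeg.design_bandpass(256.0)
        _, h = signal.sosfreqz(sos, worN=[100.0 / 128.0 * np.pi])
        forward_backward_db = 2 * 20 * np.log10(abs(h[0]))
        assert forward_backward_db <= -20.0

    def test_template_recovered_through_pipeline(self, small_table):
        spec = ErpTemplateSpec(noise_sd=0.0, artifact_rate=0.0)
        raw, conds, _ = simulate_ieeg_raw(small_table, spec, seed=0, native_rate=1024.0)
        segs = ieeg.preprocess(raw, 1024.0, conds, epoch_tmin_ms=-1500.0)
        t = segs.times
        tmpl = spec.template(t)
        mid = (t >= 0) & (t < 1500)
        rel_err = np.abs(segs.data[segs.conditions == "control"][0][mid] - tmpl[mid]).max()
        assert rel_err / np.abs(tmpl).max() < 0.02  # up to filter transients

    def test_baseline_window_mean_is_zero(self, small_table):
        raw, conds, _ = simulate_ieeg_raw(small_table, ErpTemplateSpec(), seed=1, native_rate=512.0)
        segs = ieeg.preprocess(raw, 512.0, conds, epoch_tmin_ms=-1500.0)
        t = segs.times
        bl = (t >= -200) & (t < 0)
        assert np.abs(segs.data[:, bl].mean(axis=1)).max() < 1e-9

    def test_continuous_input_drops_edge_events(self):
        rate = 1024.0
        trace = np.random.default_rng(0).standard_normal(int(10 * rate))
        onsets = np.array([0.5, 5.0, 9.8])  # first and last too close to the edges
        with pytest.warns(UserWarning, match="too close"):
            segs = ieeg.preprocess(trace, rate, np.array(["primed", "control", "primed"]), onsets_s=onsets)
        assert segs.n_trials == 1

    def test_insufficient_native_rate_rejected(self):
        with pytest.raises(ValueError):
            ieeg.preprocess(np.zeros((2, 100)), 256.0, np.array(["a", "b"]), epoch_tmin_ms=-1500.0)


class TestArtifactRejection:
    def test_homogeneous_segments_all_retained(self, rng):
        base = np.sin(np.linspace(0, 20, 768))
        segs = _segments(np.tile(base, (100, 1)))
        mask = ieeg.reject_artifacts(segs)
        assert not mask.any()

    def test_single_scaled_segment_flagged_by_both_rules(self):
        base = np.sin(np.linspace(0, 20, 768))
        data = np.tile(base, (100, 1))
        data[17] *= 10.0
        segs = _segments(data)
        maxima = np.abs(data).max(axis=1)
        medians = np.median(np.abs(data), axis=1)
        assert maxima[17] / np.median(maxima) > 2.5
        assert medians[17] / np.median(medians) > 2.5
        mask = ieeg.reject_artifacts(segs)
        assert mask[17] and mask.sum() == 1

    @pytest.mark.parametrize("factor,expected", [(2.4, False), (2.6, True)])
    def test_strict_boundary_at_ratio_2_5(self, factor, expected):
        base = np.sin(np.linspace(0, 20, 768))
        data = np.tile(base, (101, 1))
        data[50] *= factor  # scales both its maximum and its median by `factor`
        mask = ieeg.reject_artifacts(_segments(data))
        assert mask[50] == expected
        assert mask.sum() == int(expected)

    def test_reordering_segments_reorders_mask(self, rng):
        data = rng.standard_normal((40, 768))
        data[3] *= 12.0
        perm = rng.permutation(40)
        m1 = ieeg.reject_artifacts(_segments(data))
        m2 = ieeg.reject_artifacts(_segments(data[perm]))
        assert np.array_equal(m1[perm], m2)

    def test_all_zero_data_rejected(self):
        with pytest.raises(ValueError):
            ieeg.reject_artifacts(_segments(np.zeros((10, 768))))

    def test_too_few_segments_rejected(self, rng):
        with pytest.raises(ValueError):
            ieeg.reject_artifacts(_segments(rng.standard_normal((2, 768))))

    def test_clean_simulation_rejects_nothing(self, small_table):
        spec = ErpTemplateSpec(artifact_rate=0.0)
        segs = simulate_ieeg(small_table, spec, seed=2)
        mask = ieeg.reject_artifacts(segs)
        assert mask.mean() < 0.02


class TestErp:
    def test_mean_of_single_segment_is_that_segment(self, rng):
        data = rng.standard_normal((2, 768))
        segs = _segments(data, conditions=np.array(["primed", "control"]))
        erp = ieeg.compute_erp(segs)
        assert np.array_equal(erp.means["primed"], data[0])
        assert erp.n == {"primed": 1, "control": 1}

    def test_noise_variance_shrinks_as_one_over_n(self, rng):
        n = 400
        data = rng.standard_normal((n, 768))
        segs = _segments(data, conditions=np.array(["primed"] * n))
        erp = ieeg.compute_erp(segs, conditions=("primed",))
        assert erp.means["primed"].var() == pytest.approx(1.0 / n, rel=0.3)

    def test_empty_condition_raises_with_name(self, rng):
        segs = _segments(rng.standard_normal((4, 768)), conditions=np.array(["primed"] * 4))
        with pytest.raises(ValueError, match="control"):
            ieeg.compute_erp(segs)

    def test_masked_segments_excluded(self, rng):
        data = np.ones((4, 768))
        data[1] = 100.0
        segs = _segments(data, conditions=np.array(["primed"] * 4))
        erp = ieeg.compute_erp(segs, mask=np.array([False, True, False, False]), conditions=("primed",))
        assert np.allclose(erp.means["primed"], 1.0)


class TestPeakLatency:
    def _erp_with_peak(self, lat_ms, shift_primed=0.0, rate=256.0):
        t = -1000.0 + np.arange(768) * 1000.0 / rate
        trace = lambda shift: -np.exp(-0.5 * ((t - lat_ms - shift) / 40.0) ** 2)
        return ieeg.Erp(
            means={"primed": trace(shift_primed), "control": trace(0.0)},
            sems={"primed": np.zeros(768), "control": np.zeros(768)},
            n={"primed": 100, "control": 100},
            rate=rate,
            window_ms=(-1000.0, 2000.0),
        )

    def test_known_negative_peak_found_within_one_sample(self):
        erp = self._erp_with_peak(270.0)
        lat = ieeg.peak_latency(erp.means["control"], erp.times, (200.0, 400.0), "negative")
        assert abs(lat - 270.0) <= 1000.0 / 256.0

    def test_window_clipping_returns_in_window_extremum(self):
        t = -1000.0 + np.arange(768) * 1000.0 / 256.0
        trace = -np.exp(-0.5 * ((t - 450.0) / 30.0) ** 2)  # global peak outside window
        lat = ieeg.peak_latency(trace, t, (200.0, 400.0), "negative")
        assert 200.0 <= lat < 400.0

    def test_flat_trace_warns_and_returns_first_sample(self):
        t = np.arange(0.0, 1000.0, 4.0)
        with pytest.warns(UserWarning, match="flat"):
            lat = ieeg.peak_latency(np.zeros_like(t), t, (200.0, 400.0), "negative")
        assert lat == 200.0

    def test_latency_invariant_to_amplitude_scaling(self):
        erp = self._erp_with_peak(300.0)
        t = erp.times
        l1 = ieeg.peak_latency(erp.means["control"], t, (200.0, 400.0), "negative")
        l2 = ieeg.peak_latency(5.0 * erp.means["control"], t, (200.0, 400.0), "negative")
        assert l1 == l2

    def test_constructed_shift_recovered_across_sessions(self):
        erps = [self._erp_with_peak(270.0 + j, shift_primed=-16.0) for j in range(20)]
        res = ieeg.peak_latency_contrast(erps, (200.0, 400.0), "negative")
        diffs = res.latencies["primed"] - res.latencies["control"]
        assert abs(np.median(diffs) - (-16.0)) <= 1000.0 / 256.0
        assert res.pvalue < 0.001
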