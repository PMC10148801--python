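"""Single-unit analyses: z-scores, response criterion, tuning curves, bursts."""

import warnings

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from adaptmtl import spikes as spk
from adaptmtl.synth import MechanismSpec, UnitRecording, simulate_unit
from adaptmtl.synth.sequence import CONTROL, PRIMED

NO_TUNING = np.array([], dtype=int)


def _unit_from_trains(trains, stimuli, conditions, window=(-1000.0, 2000.0)):
    offsets = np.zeros(len(trains) + 1, dtype=np.int64)
    offsets[1:] = np.cumsum([len(t) for t in trains])
    times = np.concatenate([np.sort(np.asarray(t, float)) for t in trains]) if trains else np.array([])
    return UnitRecording(
        unit_id="u_test",
        region="AM",
        unit_class="SU",
        spike_times=times,
        trial_offsets=offsets,
        stimuli=np.asarray(stimuli),
        conditions=np.asarray(conditions),
        window=window,
    )


class TestBinGrid:
    def test_nineteen_overlapping_bins(self):
        bins = spk.bin_grid()
        assert bins.shape == (19, 2)
        assert np.allclose(bins[:10, 0], np.arange(0, 1000, 100))
        assert np.allclose(bins[10:, 0], np.arange(50, 950, 100))
        assert np.allclose(bins[:, 1] - bins[:, 0], 100.0)


class TestZScore:
    def test_definition_one_sd_above_baseline(self):
        # activation rate = baseline mean + 1 SD on every trial -> z = 1
        trains = []
        for i in range(100):
            n_base = 2 if i % 2 else 4  # baseline rates 4 or 8 Hz; mean 6, sd ~2
            trains.append(
                list(np.linspace(-499, -1, n_base)) + list(np.linspace(101, 998, 8))
            )
        u = _unit_from_trains(trains, np.zeros(100), np.array([PRIMED, CONTROL] * 50))
        params = spk.baseline_params(u)
        z = spk.zscore_rates(u, params=params)
        expected = (8 / 0.9 - params.baseline_mean) / params.baseline_sd
        assert np.allclose(z, expected)

    def test_homogeneous_unit_has_zero_mean_z(self, trial_table):
        u = simulate_unit(
            trial_table,
            MechanismSpec(mechanism="none", baseline_rate=10.0, tuning_gains=()),
            seed=0,
            tuned_stimuli=NO_TUNING,
        )
        z = spk.zscore_rates(u)
        assert abs(z.mean()) < 0.15

    def test_silent_unit_flagged(self):
        u = _unit_from_trains([[] for _ in range(10)], np.zeros(10), [PRIMED] * 10)
        with pytest.raises(ValueError, match="silent"):
            spk.zscore_rates(u)


class TestRankSum:
    @given(seed=st.integers(0, 5_000))
    def test_matches_scipy_mannwhitneyu(self, seed):
        r = np.random.default_rng(seed)
        bs = r.poisson(r.uniform(0.3, 4.0), 300).astype(float)
        obs = r.poisson(r.uniform(0.3, 6.0), (5, 10)).astype(float)
        mine = spk.ranksum_vs_baseline(obs, bs)
        ref = np.array(
            [
                stats.mannwhitneyu(row, bs, alternative="two-sided", method="asymptotic").pvalue
                for row in obs
            ]
        )
        assert np.allclose(mine, ref)


class TestSimes:
    def test_matches_brute_force_on_random_vectors(self, rng):
        p = rng.uniform(0, 1, (20_000, 19)) ** 3  # skew toward small values
        alpha = 0.001
        got = spk.simes_reject(p, alpha)
        sp = np.sort(p, axis=1)
        want = (sp * 19 / np.arange(1, 20) <= alpha).any(axis=1)
        assert np.array_equal(got, want)

    def test_single_vector_interface(self):
        assert spk.simes_reject(np.array([0.00001] + [0.9] * 18), 0.001)
        assert not spk.simes_reject(np.full(19, 0.5), 0.001)


class TestResponseCriterion:
    def test_silent_unit_not_responsive(self, small_table):
        n = (small_table["condition"] != "discarded_first").sum()
        tgt = small_table[small_table["condition"] != "discarded_first"]
        u = _unit_from_trains(
            [[] for _ in range(n)], tgt["stimulus"].to_numpy(), tgt["condition"].to_numpy()
        )
        decs = spk.response_decisions(u, min_presentations=4)
        assert all(not d.responsive for d in decs)
        assert all(not d.spike_presence for d in decs)

    def test_planted_response_detected(self, trial_table, stimulus_set):
        spec = MechanismSpec(
            mechanism="none", baseline_rate=3.0, tuning_gains=(5.0,), onset_latency=200.0
        )
        hits = 0
        for seed in range(10):
            u = simulate_unit(trial_table, spec, seed=seed, sset=stimulus_set)
            d = spk.binwise_response_criterion(u, u.ground_truth["tuned_stimuli"][0])
            hits += d.responsive
        assert hits >= 9

    def test_too_few_presentations_rejected(self, trial_table, stimulus_set):
        u = simulate_unit(trial_table, MechanismSpec(), seed=0, sset=stimulus_set)
        with pytest.raises(ValueError, match="presentations"):
            spk.response_decisions(u, min_presentations=11)

    def test_criterion_invariant_to_common_time_shift(self, small_table):
        tgt = small_table[small_table["condition"] != "discarded_first"]
        r = np.random.default_rng(0)
        trains = [np.sort(r.uniform(-1000, 2000, 12)) for _ in range(len(tgt))]
        u1 = _unit_from_trains(trains, tgt["stimulus"].to_numpy(), tgt["condition"].to_numpy())
        shift = 250.0
        u2 = _unit_from_trains(
            [t + shift for t in trains], tgt["stimulus"].to_numpy(), tgt["condition"].to_numpy(),
            window=(-1000.0 + shift, 2000.0 + shift),
        )
        d1 = spk.response_decisions(u1, min_presentations=4)
        # shifting spikes and windows together must not change any decision
        import adaptmtl.spikes as mod
        orig = (mod.BASELINE_WINDOW, mod.RESPONSE_WINDOW)
        grid = mod.bin_grid
        try:
            # baseline_bin_grid follows BASELINE_WINDOW automatically
            mod.BASELINE_WINDOW = (-500.0 + shift, 0.0 + shift)
            mod.RESPONSE_WINDOW = (0.0 + shift, 1000.0 + shift)
            mod.bin_grid = lambda: grid() + shift
            d2 = mod.response_decisions(u2, min_presentations=4)
        finally:
            mod.BASELINE_WINDOW, mod.RESPONSE_WINDOW = orig
            mod.bin_grid = grid
        assert [d.responsive for d in d1] == [d.responsive for d in d2]
        assert np.allclose(
            np.concatenate([d.p_bins for d in d1]), np.concatenate([d.p_bins for d in d2])
        )


class TestSelection:
    def _decisions(self, counts):
        out = {}
        for uid, k in counts.items():
            out[uid] = [
                spk.ResponseDecision(uid, s, np.ones(19), s < k, True, True) for s in range(10)
            ]
        return out

    def test_threshold_and_nesting(self):
        decs = self._decisions({"a": 5, "b": 4, "c": 3, "d": 2, "e": 0})
        sel4 = set(spk.select_multiresponsive_units(decs, 4))
        sel3 = set(spk.select_multiresponsive_units(decs, 3))
        sel2 = set(spk.select_multiresponsive_units(decs, 2))
        assert sel4 == {"a", "b"}
        assert sel4 <= sel3 <= sel2

    def test_exact_recovery_of_known_counts(self, trial_table, stimulus_set):
        spec = MechanismSpec(mechanism="none")
        u = simulate_unit(trial_table, spec, seed=42, sset=stimulus_set)
        decs = {u.unit_id: spk.response_decisions(u)}
        responsive = {d.stimulus for d in decs[u.unit_id] if d.responsive}
        assert responsive == set(u.ground_truth["tuned_stimuli"])
        assert spk.select_multiresponsive_units(decs, 4) == [u.unit_id]


class TestTuningCurve:
    def test_control_rank_one_normalized_to_one(self, trial_table, stimulus_set):
        u = simulate_unit(trial_table, MechanismSpec(), seed=1, sset=stimulus_set)
        curve = spk.build_tuning_curve(u)
        assert curve.control[0] == 1.0

    def test_untuned_unit_has_flat_curve(self, trial_table):
        spec = MechanismSpec(mechanism="none", baseline_rate=20.0, tuning_gains=())
        u = simulate_unit(trial_table, spec, seed=2, tuned_stimuli=NO_TUNING)
        curve = spk.build_tuning_curve(u)
        # up to sampling noise, both conditions stay near 1 across ranks
        assert np.all(curve.control[:20] > 0.7) and np.all(curve.control[:20] < 1.4)
        assert np.all(curve.primed[:20] > 0.6) and np.all(curve.primed[:20] < 1.4)

    def test_fatiguing_ratio_recovered_on_average(self, trial_table, stimulus_set):
        spec = MechanismSpec(mechanism="fatiguing", attenuation=0.3, baseline_rate=20.0)
        ratios = []
        for seed in range(10):
            u = simulate_unit(trial_table, spec, seed=seed, sset=stimulus_set)
            c = spk.build_tuning_curve(u)
            ratios.append(c.primed[:2] / c.control[:2])
        # response window [0,1000) includes 400 ms of unattenuated baseline,
        # so the measured rate ratio sits slightly above 1 - attenuation
        lo = 1 - 0.3
        hi = 1 - 0.3 * 0.8
        assert lo - 0.05 < np.mean(ratios) < hi + 0.05

    def test_ordering_deterministic_under_ties(self):
        trains = [[10.0]] * 40  # every trial identical -> all pooled rates tie
        stim = np.repeat(np.arange(4), 10)
        cond = np.tile([PRIMED, CONTROL], 20)
        u = _unit_from_trains(trains, stim, cond)
        c1 = spk.build_tuning_curve(u)
        assert list(c1.order) == [0, 1, 2, 3]  # ties broken by stimulus id

    def test_zero_frmax_excluded_with_warning(self):
        # spikes only on primed trials: control rank-1 rate is 0
        stim = np.repeat([0], 10)
        cond = np.array([PRIMED, CONTROL] * 5)
        trains = [[100.0] if c == PRIMED else [] for c in cond]
        u = _unit_from_trains(trains, stim, cond)
        with pytest.warns(UserWarning, match="FRmax"):
            assert spk.build_tuning_curve(u) is None


class TestTuningContrast:
    def _curves(self, n, primed_scale, rng):
        out = []
        base = np.array([1.0, 0.7, 0.5, 0.4])
        for i in range(n):
            ctrl = base + rng.normal(0, 0.05, 4)
            prim = base * primed_scale + rng.normal(0, 0.05, 4)
            out.append(
                spk.TuningCurve(
                    unit_id=f"u{i}", region="AM", order=np.arange(4), pooled=base,
                    primed=prim, control=ctrl, fr_max=30.0,
                )
            )
        return out

    def test_identical_conditions_give_null_p_everywhere(self, rng):
        curves = []
        base = np.array([1.0, 0.7, 0.5, 0.4])
        for i in range(10):
            v = base + rng.normal(0, 0.05, 4)
            curves.append(
                spk.TuningCurve(f"u{i}", "AM", np.arange(4), base, v.copy(), v.copy(), 30.0)
            )
        res = spk.contrast_tuning(curves)
        assert all(r.t_pvalue == 1.0 for r in res.ranks)

    def test_proportional_attenuation_classified_fatiguing(self, rng):
        res = spk.contrast_tuning(self._curves(60, np.full(4, 0.7), rng))
        assert res.rank(1).t_pvalue < 0.05 and res.rank(1).mean_diff < 0
        assert spk.classify_population_profile(res) == "fatiguing"

    def test_rank1_sparing_classified_sharpening(self, rng):
        res = spk.contrast_tuning(self._curves(60, np.array([1.0, 0.7, 0.7, 0.7]), rng))
        assert res.rank(1).t_pvalue > 0.05
        assert res.rank(2).t_pvalue < 0.05
        att = res.attenuation_pair(1, 2)
        assert att.p_rel < 0.05 and att.mean_diff_rel > 0
        assert spk.classify_population_profile(res) == "sharpening"

    def test_no_effect_classified_indeterminate(self, rng):
        res = spk.contrast_tuning(self._curves(60, np.ones(4), rng))
        assert spk.classify_population_profile(res) == "indeterminate"


class TestBurst:
    def test_constructed_burst_extent_recovered(self, rng):
        trains = []
        for _ in range(50):
            base = rng.uniform(-1000, 2000, rng.poisson(15))
            burst = rng.uniform(250, 600, 18)
            trains.append(np.concatenate([base, burst]))
        u = _unit_from_trains(trains, np.zeros(50), [PRIMED, CONTROL] * 25)
        res = spk.detect_burst(u, baseline_rate=5.0)
        assert res.method == "poisson_burst"
        ok = np.isfinite(res.onset)
        assert ok.mean() > 0.9
        assert np.median(res.onset[ok]) == pytest.approx(250, abs=40)
        assert np.median(res.offset[ok]) == pytest.approx(600, abs=40)

    def test_false_positive_rate_controlled_by_threshold(self, trial_table):
        spec = MechanismSpec(mechanism="none", baseline_rate=5.0, tuning_gains=())
        u = simulate_unit(trial_table, spec, seed=5, tuned_stimuli=NO_TUNING)
        rates = []
        for thr in (2.0, 6.0, 10.0):
            r = spk.detect_burst(u, threshold=thr)
            rates.append(np.isfinite(r.onset).mean())
        assert rates[0] > rates[1] > rates[2] or rates[2] == 0.0
        assert rates[1] < 0.05

    def test_low_rate_unit_uses_first_spike_latency(self):
        trains = [[50.0, 150.0, 900.0], [120.0], [-300.0, 1500.0]]
        u = _unit_from_trains(trains, np.zeros(3), [PRIMED, CONTROL, PRIMED])
        res = spk.detect_burst(u, baseline_rate=1.0)
        assert res.method == "first_spike"
        assert res.onset[0] == 150.0  # first spike inside [100, 1000)
        assert res.onset[1] == 120.0
        assert np.isnan(res.onset[2])
        assert np.isnan(res.duration).all()

    def test_facilitation_shortens_primed_durations(self, trial_table, stimulus_set):
        spec = MechanismSpec(mechanism="facilitation", attenuation=0.3)
        results, resp = [], {}
        for seed in range(8):
            u = simulate_unit(
                trial_table, spec, seed=seed, sset=stimulus_set, unit_id=f"u{seed}"
            )
            decs = spk.response_decisions(u)
            resp[u.unit_id] = [d.stimulus for d in decs if d.responsive]
            results.append(spk.detect_burst(u))
        out = spk.burst_duration_contrast(results, resp)
        assert out["median_primed_ms"] < out["median_control_ms"]


class TestPrestimulus:
    def _responsive(self, units):
        return {
            u.unit_id: [
                spk.ResponseDecision(u.unit_id, s, np.ones(19), True, True, True)
                for s in u.ground_truth["tuned_stimuli"]
            ]
            for u in units
        }

    def test_null_generator_gives_no_effect(self, trial_table, stimulus_set):
        units = [
            simulate_unit(trial_table, MechanismSpec(), seed=s, sset=stimulus_set, unit_id=f"u{s}")
            for s in range(10)
        ]
        out = spk.prestimulus_test(units, self._responsive(units), region_groups={"AM": ("AM",)})
        assert abs(out["AM"]["mean_primed"] - out["AM"]["mean_control"]) < 0.3

    def test_planted_prestimulus_elevation_detected(self, trial_table, stimulus_set):
        spec = MechanismSpec(prestim_gain_primed=1.6, baseline_rate=10.0)
        units = [
            simulate_unit(trial_table, spec, seed=s, sset=stimulus_set, unit_id=f"u{s}")
            for s in range(12)
        ]
        out = spk.prestimulus_test(units, self._responsive(units), region_groups={"AM": ("AM",)})
        assert out["AM"]["mean_primed"] > out["AM"]["mean_control"]
        assert out["AM"]["pvalue"] < 0.01

    def test_single_unit_rejected(self, trial_table, stimulus_set):
        units = [simulate_unit(trial_table, MechanismSpec(), seed=0, sset=stimulus_set)]
        with pytest.raises(ValueError):
            spk.prestimulus_test(units, self._responsive(units), region_groups={"AM": ("AM",)})
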