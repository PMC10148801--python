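"""End-to-end orchestration: configuration, simulation, analysis, report.

``run_all`` executes the full chain on synthetic sessions — behavioral
contrasts, iEEG artifact rejection / ERPs / cluster permutation / peak
latencies, and the single-unit analyses — and writes a single JSON report
(plus CSV exports) that echoes the resolved configuration, its hash and all
seeds, so every number in it can be reproduced.

One global seed is expanded deterministically into per-module seeds via
``numpy.random.SeedSequence``, so modules can be rerun in isolation.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, behavior, cluster_stats, ieeg, spikes
from .synth.behavior_sim import RtParams, simulate_behavior
from .synth.ieeg_sim import ErpTemplateSpec, simulate_ieeg, simulate_ieeg_raw
from .synth.sequence import generate_trial_sequence
from .synth.spikes_sim import MechanismSpec, PopulationGroup, simulate_population
from .synth.stimuli import ConfigurationError, generate_stimulus_set

STAGES = ("behavior", "ieeg", "spikes")


@dataclass
class RunConfig:
    """All named constants of a run in one declarative document.

    Analysis constants default to the study's values (cluster-forming alpha
    0.001 with 1000 permutations, binwise criterion alpha 0.001, 4+
    responsive stimuli, early 200-400 ms / late 400-750 ms latency windows,
    2 Hz burst-method cutoff). Simulation sizes default to a desk-scale
    study: 12 sessions and a 24-unit sharpening (AM) plus 32-unit fatiguing
    (HC) cohort.
    """

    n_sessions: int = 12
    n_categories: int = 10
    n_exemplars: int = 10
    n_runs: int = 10
    rt: RtParams = field(default_factory=RtParams)
    erp: ErpTemplateSpec = field(default_factory=ErpTemplateSpec)
    ieeg_native_rate: float | None = None  # simulate raw epochs and preprocess when set
    cluster_alpha: float = 0.001
    n_perm: int = 1000
    bin_alpha: float = 0.001
    rank_alpha: float = 0.05
    min_responsive_stimuli: int = 4
    n_ranks: int = 4
    burst_threshold: float = 2.0
    early_window_ms: tuple[float, float] = (200.0, 400.0)
    late_window_ms: tuple[float, float] = (400.0, 750.0)
    cohort: tuple[PopulationGroup, ...] = (
        PopulationGroup("AM", 24, MechanismSpec(mechanism="sharpening")),
        PopulationGroup("HC", 32, MechanismSpec(mechanism="fatiguing")),
    )
    stages: tuple[str, ...] = STAGES

    def validate(self) -> None:
        if self.n_sessions < 1:
            raise ConfigurationError("n_sessions must be >= 1")
        if not 0 < self.cluster_alpha < 1:
            raise ConfigurationError("cluster_alpha must be in (0, 1)")
        if not 0 < self.bin_alpha < 1:
            raise ConfigurationError("bin_alpha must be in (0, 1)")
        if not 0 < self.rank_alpha < 1:
            raise ConfigurationError("rank_alpha must be in (0, 1)")
        if self.n_perm < 100:
            raise ConfigurationError("n_perm must be >= 100")
        if self.min_responsive_stimuli < 1:
            raise ConfigurationError("min_responsive_stimuli must be >= 1")
        for w in (self.early_window_ms, self.late_window_ms):
            if w[0] >= w[1]:
                raise ConfigurationError("latency windows must be increasing")
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ConfigurationError(f"unknown stages: {sorted(unknown)}")
        self.rt.validate()
        self.erp.validate()
        for grp in self.cohort:
            grp.validate()

    def to_dict(self) -> dict:
        return _jsonable(dataclasses.asdict(self))

    def hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "rt" in d and isinstance(d["rt"], dict):
            d["rt"] = RtParams(**d["rt"])
        if "erp" in d and isinstance(d["erp"], dict):
            e = dict(d["erp"])
            for k in ("peaks", "amplitude_scale", "latency_shift_ms"):
                if k in e:
                    e[k] = tuple(tuple(x) for x in e[k])
            if "window_ms" in e:
                e["window_ms"] = tuple(e["window_ms"])
            d["erp"] = ErpTemplateSpec(**e)
        if "cohort" in d:
            groups = []
            for g in d["cohort"]:
                if isinstance(g, PopulationGroup):
                    groups.append(g)
                else:
                    g = dict(g)
                    spec = g.pop("spec", {})
                    if isinstance(spec, dict):
                        spec = dict(spec)
                        if "tuning_gains" in spec:
                            spec["tuning_gains"] = tuple(spec["tuning_gains"])
                        spec = MechanismSpec(**spec)
                    groups.append(PopulationGroup(spec=spec, **g))
            d["cohort"] = tuple(groups)
        for k in ("early_window_ms", "late_window_ms", "stages"):
            if k in d and not isinstance(d[k], tuple):
                d[k] = tuple(d[k])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as f:
            return cls.from_dict(yaml.safe_load(f) or {})


def _jsonable(x):
    if isinstance(x, dict):
        return {str(k): _jsonable(v) for k, v in x.items()}
    if isinstance(x, (list, tuple)):
        return [_jsonable(v) for v in x]
    if isinstance(x, (np.floating, float)):
        return float(x)
    if isinstance(x, (np.integer, int)):
        return int(x)
    if isinstance(x, (np.bool_, bool)):
        return bool(x)
    if isinstance(x, np.ndarray):
        return [_jsonable(v) for v in x.tolist()]
    return x


def _behavior_stage(config: RunConfig, trials: pd.DataFrame) -> dict:
    out = {}
    mask = behavior.exclude_rt_outliers(trials)
    out["n_rt_outliers_excluded"] = int(mask.sum())
    for flag in (False, True):
        rt = behavior.contrast_rt(trials, exclude_response_priming=flag)
        acc = behavior.contrast_accuracy(trials, exclude_response_priming=flag)
        key = "response_priming_excluded" if flag else "all_trials"
        out[key] = {
            "rt": {
                "median_primed_ms": rt.median["primed"],
                "iqr_primed_ms": rt.iqr["primed"],
                "median_control_ms": rt.median["control"],
                "iqr_control_ms": rt.iqr["control"],
                "statistic": rt.statistic,
                "pvalue": rt.pvalue,
                "n_sessions": rt.n_sessions,
            },
            "accuracy": {
                "median_primed_pct": acc.median["primed"],
                "median_control_pct": acc.median["control"],
                "statistic": acc.statistic,
                "pvalue": acc.pvalue,
                "n_sessions": acc.n_sessions,
            },
        }
    return out


def _ieeg_stage(config: RunConfig, session_trials: list[pd.DataFrame], seeds) -> dict:
    erps = []
    n_rejected = 0
    n_total = 0
    for trials, seed in zip(session_trials, seeds):
        if config.ieeg_native_rate:
            raw, conds, truth = simulate_ieeg_raw(
                trials, config.erp, seed=seed, native_rate=config.ieeg_native_rate
            )
            segs = ieeg.preprocess(
                raw,
                config.ieeg_native_rate,
                conds,
                epoch_tmin_ms=-1500.0,
                artifact_truth=truth,
                session=str(trials["session"].iloc[0]),
            )
        else:
            segs = simulate_ieeg(trials, config.erp, seed=seed)
            segs.data = ieeg.baseline_correct(segs.data, segs.rate, segs.window_ms)
        mask = ieeg.reject_artifacts(segs)
        n_rejected += int(mask.sum())
        n_total += segs.n_trials
        erps.append(ieeg.compute_erp(segs))

    pairs_primed = np.stack([e.means["primed"] for e in erps])
    pairs_control = np.stack([e.means["control"] for e in erps])
    times = erps[0].times
    clusters, _ = cluster_stats.cluster_permutation_test(
        pairs_primed,
        pairs_control,
        cluster_alpha=config.cluster_alpha,
        n_perm=config.n_perm,
        seed=int(seeds[0].generate_state(1)[0] % 2**31),
        times_ms=times,
    )
    early = ieeg.peak_latency_contrast(erps, config.early_window_ms, "negative")
    late = ieeg.peak_latency_contrast(erps, config.late_window_ms, "positive")
    return {
        "n_segments": n_total,
        "n_segments_rejected": n_rejected,
        "n_sessions": len(erps),
        "clusters": [
            {
                "start_ms": c.start_ms,
                "end_ms": c.end_ms,
                "clustersize": c.size,
                "sum_t": c.t_sum,
                "sign": c.sign,
                "significant": c.significant,
                "p_mc": c.p_mc,
            }
            for c in clusters
        ],
        "peak_latency": {
            name: {
                "median_primed_ms": r.median["primed"],
                "median_control_ms": r.median["control"],
                "iqr_primed_ms": r.iqr["primed"],
                "iqr_control_ms": r.iqr["control"],
                "pvalue": r.pvalue,
            }
            for name, r in (("early_negative", early), ("late_positive", late))
        },
    }


def _spikes_stage(config: RunConfig, trials: pd.DataFrame, sset, seed) -> dict:
    units = simulate_population(trials, list(config.cohort), seed=seed, sset=sset)
    decisions = {u.unit_id: spikes.response_decisions(u, config.bin_alpha) for u in units}
    selected = set(
        spikes.select_multiresponsive_units(decisions, config.min_responsive_stimuli)
    )
    by_unit = {u.unit_id: u for u in units}
    out: dict = {
        "n_units": len(units),
        "n_multiresponsive": len(selected),
    }
    groups: dict[str, list] = {g: [] for g in spikes.REGION_GROUPS}
    for uid in sorted(selected):
        u = by_unit[uid]
        curve = spikes.build_tuning_curve(u, spikes.count_responsive(decisions[uid]))
        if curve is None:
            continue
        for g, regions in spikes.REGION_GROUPS.items():
            if u.region in regions:
                groups[g].append(curve)
    out["tuning"] = {}
    for g, curves in groups.items():
        if len(curves) < 3:
            out["tuning"][g] = {"notice": f"only {len(curves)} units; contrast skipped"}
            continue
        res = spikes.contrast_tuning(curves, config.n_ranks, group=g)
        out["tuning"][g] = {
            "n_units": res.n_units,
            "profile": spikes.classify_population_profile(res, config.rank_alpha),
            "ranks": [
                {
                    "rank": r.rank,
                    "mean_diff": r.mean_diff,
                    "t": r.t,
                    "pvalue": r.t_pvalue,
                    "ci": list(r.ci),
                    "signed_rank_pvalue": r.w_pvalue,
                }
                for r in res.ranks
            ],
        }
    burst_results = []
    responsive_by_unit = {}
    for uid in sorted(selected):
        burst_results.append(spikes.detect_burst(by_unit[uid], config.burst_threshold))
        responsive_by_unit[uid] = [d.stimulus for d in decisions[uid] if d.responsive]
    try:
        out["burst_duration"] = spikes.burst_duration_contrast(
            burst_results, responsive_by_unit
        )
    except ValueError as e:
        out["burst_duration"] = {"notice": str(e)}
    try:
        out["prestimulus"] = spikes.prestimulus_test(units, decisions)
    except ValueError as e:
        out["prestimulus"] = {"notice": str(e)}
    return out


def run_all(
    config: RunConfig | None = None,
    seed: int = 0,
    out_dir=None,
) -> dict:
    """Run the configured stages on synthetic sessions and return the report.

    When ``out_dir`` is given, writes ``report.json`` plus CSV exports of
    per-session behavior and the rank x condition table. The report is a
    pure function of (config, seed): identical inputs give byte-identical
    reports.
    """
    config = config or RunConfig()
    config.validate()
    ss = np.random.SeedSequence(seed)
    s_stim, s_seq, s_beh, s_ieeg, s_units = ss.spawn(5)

    sset = generate_stimulus_set(config.n_categories, config.n_exemplars, seed=s_stim)
    session_trials = []
    for i, (seq_seed, beh_seed) in enumerate(
        zip(s_seq.spawn(config.n_sessions), s_beh.spawn(config.n_sessions))
    ):
        t = generate_trial_sequence(
            sset, config.n_runs, seed=seq_seed, session=f"S{i + 1:02d}"
        )
        session_trials.append(simulate_behavior(t, config.rt, seed=beh_seed))
    all_trials = pd.concat(session_trials, ignore_index=True)

    report: dict = {
        "version": __version__,
        "seed": int(seed),
        "config_hash": config.hash(),
        "config": config.to_dict(),
        "stages": {},
    }
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        if "behavior" in config.stages:
            report["stages"]["behavior"] = _behavior_stage(config, all_trials)
        if "ieeg" in config.stages:
            report["stages"]["ieeg"] = _ieeg_stage(
                config, session_trials, s_ieeg.spawn(config.n_sessions)
            )
        if "spikes" in config.stages:
            report["stages"]["spikes"] = _spikes_stage(
                config, session_trials[0], sset, s_units
            )
    report = _jsonable(report)

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
        all_trials.to_csv(out / "trials.csv", index=False)
    return report
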