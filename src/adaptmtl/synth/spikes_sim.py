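"""Inhomogeneous-Poisson single-unit simulator with graded semantic tuning.

Each unit fires at its baseline rate outside a response window and at
``baseline * gain(stimulus)`` within ``[onset_latency, onset_latency +
response_duration)``. A small set of *tuned* stimuli (drawn from one
semantic category by default) carries a non-increasing vector of gains, a
graded tuning curve rather than an all-or-none response. The priming
condition modulates the response according to a ground-truth mechanism:

* ``fatiguing``   - all tuned gains scaled by ``1 - attenuation`` on primed
  trials (proportional reduction, tuning shape preserved),
* ``sharpening``  - the rank-1 gain is untouched; gains at ranks >= 2 are
  scaled by ``1 - attenuation`` on primed trials,
* ``facilitation`` - gains untouched; the response duration is scaled by
  ``1 - attenuation`` on primed trials,
* ``none``        - no condition effect.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .sequence import DISCARDED_FIRST, PRIMED
from .stimuli import ConfigurationError, StimulusSet

MECHANISMS = ("none", "sharpening", "fatiguing", "facilitation")
REGIONS = ("AM", "HC", "EC", "PHC")


@dataclass(frozen=True)
class MechanismSpec:
    """Ground-truth generative parameters of one unit.

    ``tuning_gains`` are multiplicative rate gains for the tuned stimuli in
    rank order; all other stimuli have gain 1. ``prestim_gain_primed``
    optionally elevates the pre-stimulus ([-500, 0) ms) rate on primed
    trials to emulate spreading activation (1.0 = none).
    """

    mechanism: str = "none"
    baseline_rate: float = 5.0
    tuning_gains: tuple[float, ...] = (10.0, 7.0, 5.0, 4.0)
    attenuation: float = 0.3
    onset_latency: float = 300.0
    response_duration: float = 600.0
    prestim_gain_primed: float = 1.0

    def validate(self) -> None:
        if self.mechanism not in MECHANISMS:
            raise ConfigurationError(f"unknown mechanism {self.mechanism!r}")
        if self.baseline_rate < 0:
            raise ConfigurationError("baseline_rate must be >= 0")
        if any(g < 0 for g in self.tuning_gains):
            raise ConfigurationError("tuning gains must be >= 0")
        if any(a < b for a, b in zip(self.tuning_gains, self.tuning_gains[1:])):
            raise ConfigurationError("tuning gains must be non-increasing over ranks")
        if not 0 <= self.attenuation <= 1:
            raise ConfigurationError("attenuation must be in [0, 1]")
        if self.response_duration < 0 or self.onset_latency < 0:
            raise ConfigurationError("response window must be non-negative")
        if self.prestim_gain_primed < 0:
            raise ConfigurationError("prestim_gain_primed must be >= 0")


@dataclass
class UnitRecording:
    """Spike timestamps of one unit across all target trials of a session.

    Spike times are continuous milliseconds relative to stimulus onset,
    stored as one concatenated array with per-trial offsets (trial ``i``
    owns ``spike_times[trial_offsets[i]:trial_offsets[i+1]]``, sorted).
    ``stimuli`` and ``conditions`` are aligned with the target rows of the
    session's trial table.
    """

    unit_id: str
    region: str
    unit_class: str
    spike_times: np.ndarray
    trial_offsets: np.ndarray
    stimuli: np.ndarray
    conditions: np.ndarray
    window: tuple[float, float] = (-1000.0, 2000.0)
    session: str = "S01"
    ground_truth: dict = field(default_factory=dict)

    @property
    def n_trials(self) -> int:
        return len(self.trial_offsets) - 1

    def spikes_for_trial(self, i: int) -> np.ndarray:
        return self.spike_times[self.trial_offsets[i] : self.trial_offsets[i + 1]]

    def counts_in_windows(self, windows: np.ndarray) -> np.ndarray:
        """Spike counts per trial in half-open windows.

        ``windows`` is ``(n_windows, 2)`` in ms; returns an
        ``(n_trials, n_windows)`` integer array. Uses a single global
        searchsorted on trial-encoded keys.
        """
        windows = np.atleast_2d(np.asarray(windows, dtype=float))
        w0, w1 = self.window
        span = w1 - w0
        n = self.n_trials
        trial_idx = np.repeat(np.arange(n), np.diff(self.trial_offsets))
        keys = trial_idx * span + (self.spike_times - w0)
        trial_base = np.arange(n)[:, None] * span
        lo = np.searchsorted(keys, trial_base + (windows[:, 0] - w0)[None, :], side="left")
        hi = np.searchsorted(keys, trial_base + (windows[:, 1] - w0)[None, :], side="left")
        return hi - lo

    def rates_in_window(self, lo: float, hi: float) -> np.ndarray:
        """Per-trial firing rate (Hz) in the half-open window [lo, hi) ms."""
        counts = self.counts_in_windows(np.array([[lo, hi]]))[:, 0]
        return counts / ((hi - lo) / 1000.0)


def _target_rows(trials: pd.DataFrame) -> pd.DataFrame:
    return trials[trials["condition"] != DISCARDED_FIRST]


def default_tuned_stimuli(
    sset: StimulusSet, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Pick ``n`` tuned stimuli from a single random semantic category."""
    cat = int(rng.integers(sset.n_categories))
    ex = sset.exemplars(cat)
    if len(ex) < n:
        raise ConfigurationError("category too small for requested tuning width")
    return rng.choice(ex, size=n, replace=False)


def simulate_unit(
    trials: pd.DataFrame,
    spec: MechanismSpec,
    seed=None,
    tuned_stimuli: np.ndarray | None = None,
    sset: StimulusSet | None = None,
    region: str = "AM",
    unit_class: str = "SU",
    unit_id: str = "u000",
    window: tuple[float, float] = (-1000.0, 2000.0),
) -> UnitRecording:
    """Simulate one unit's spike trains for every target trial.

    ``tuned_stimuli`` (rank order, matching ``spec.tuning_gains``) may be
    given explicitly; otherwise they are drawn from one random category
    (requires ``sset``), or from the most frequent stimuli if no set is
    supplied.
    """
    spec.validate()
    rng = np.random.default_rng(seed)
    tgt = _target_rows(trials)
    stims = tgt["stimulus"].to_numpy()
    conds = tgt["condition"].to_numpy()
    n_trials = len(tgt)
    w0, w1 = window
    if w0 > -500 or w1 < spec.onset_latency + spec.response_duration:
        raise ConfigurationError("recording window does not cover baseline/response")

    if tuned_stimuli is None:
        if sset is not None:
            tuned_stimuli = default_tuned_stimuli(sset, len(spec.tuning_gains), rng)
        else:
            tuned_stimuli = np.unique(stims)[: len(spec.tuning_gains)]
    tuned_stimuli = np.asarray(tuned_stimuli)
    if len(tuned_stimuli) != len(spec.tuning_gains):
        raise ConfigurationError("tuned_stimuli must match tuning_gains length")

    # per-trial response gain and duration under the mechanism rules
    gain = np.ones(n_trials)
    rank_of = {int(s): r for r, s in enumerate(tuned_stimuli)}  # 0-based rank
    tuned_rank = np.array([rank_of.get(int(s), -1) for s in stims])
    is_tuned = tuned_rank >= 0
    gain[is_tuned] = np.asarray(spec.tuning_gains)[tuned_rank[is_tuned]]
    primed = conds == PRIMED
    duration = np.full(n_trials, spec.response_duration)
    if spec.mechanism == "fatiguing":
        gain[primed & is_tuned] *= 1 - spec.attenuation
    elif spec.mechanism == "sharpening":
        gain[primed & is_tuned & (tuned_rank >= 1)] *= 1 - spec.attenuation
    elif spec.mechanism == "facilitation":
        duration[primed] *= 1 - spec.attenuation

    prestim_gain = np.where(primed, spec.prestim_gain_primed, 1.0)

    # piecewise-constant rate: [w0,-500), [-500,0), [0,onset), response, tail
    on = spec.onset_latency
    bounds = np.empty((n_trials, 6))
    bounds[:, 0] = w0
    bounds[:, 1] = -500.0
    bounds[:, 2] = 0.0
    bounds[:, 3] = on
    bounds[:, 4] = on + duration
    bounds[:, 5] = w1
    b = spec.baseline_rate
    rates = np.empty((n_trials, 5))
    rates[:, 0] = b
    rates[:, 1] = b * prestim_gain
    rates[:, 2] = b
    rates[:, 3] = b * gain
    rates[:, 4] = b

    seg_len = np.diff(bounds, axis=1)  # ms
    counts = rng.poisson(rates * seg_len / 1000.0)
    total = counts.sum()
    seg_lo = np.repeat(bounds[:, :-1].ravel(), counts.ravel())
    seg_span = np.repeat(seg_len.ravel(), counts.ravel())
    times = seg_lo + rng.random(total) * seg_span
    trial_idx = np.repeat(np.arange(n_trials), counts.sum(axis=1))
    order = np.lexsort((times, trial_idx))
    spike_times = times[order]
    offsets = np.zeros(n_trials + 1, dtype=np.int64)
    np.cumsum(np.bincount(trial_idx, minlength=n_trials), out=offsets[1:])

    return UnitRecording(
        unit_id=unit_id,
        region=region,
        unit_class=unit_class,
        spike_times=spike_times,
        trial_offsets=offsets,
        stimuli=stims,
        conditions=conds,
        window=window,
        session=str(tgt["session"].iloc[0]) if "session" in tgt else "S01",
        ground_truth={
            "mechanism": spec.mechanism,
            "baseline_rate": spec.baseline_rate,
            "tuning_gains": list(spec.tuning_gains),
            "attenuation": spec.attenuation,
            "onset_latency": spec.onset_latency,
            "response_duration": spec.response_duration,
            "tuned_stimuli": [int(s) for s in tuned_stimuli],
        },
    )


@dataclass(frozen=True)
class PopulationGroup:
    """One cohort entry: ``n_units`` units in ``region`` sharing a mechanism."""

    region: str
    n_units: int
    spec: MechanismSpec
    su_fraction: float = 0.41

    def validate(self) -> None:
        if self.n_units < 1:
            raise ConfigurationError("n_units must be >= 1")
        if self.region not in REGIONS:
            raise ConfigurationError(f"unknown region {self.region!r}")
        self.spec.validate()


def simulate_population(
    trials: pd.DataFrame,
    cohort: list[PopulationGroup],
    seed=None,
    sset: StimulusSet | None = None,
) -> list[UnitRecording]:
    """Independently simulate all units of a cohort, with ground truth attached."""
    for grp in cohort:
        grp.validate()
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    children = iter(ss.spawn(sum(g.n_units for g in cohort)))
    units: list[UnitRecording] = []
    k = 0
    for grp in cohort:
        for i in range(grp.n_units):
            child = next(children)
            rng = np.random.default_rng(child)
            unit_class = "SU" if rng.random() < grp.su_fraction else "MU"
            units.append(
                simulate_unit(
                    trials,
                    grp.spec,
                    seed=rng,
                    sset=sset,
                    region=grp.region,
                    unit_class=unit_class,
                    unit_id=f"u{k:04d}",
                )
            )
            k += 1
    return units
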