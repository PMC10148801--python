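"""Single-unit analyses: response detection, tuning curves, bursts, pre-stimulus test.

Firing-rate conventions: spike times are ms relative to stimulus onset, all
windows half-open ``[start, end)``, rates in Hz = count / window length.
Two distinct response windows are used on purpose: the z-score *activation*
window [100, 1000) ms and the tuning / response-criterion window
[0, 1000) ms. The baseline window is [-500, 0) ms.

Response detection (binwise rank-sum criterion): spikes are counted in 19
overlapping 100 ms bins (aligned at 0,100,...,900 ms and offset at
50,150,...,850 ms). For each bin, a two-sided rank-sum test compares the
10 per-trial rates of a stimulus against the distribution of baseline
firing rates of all trials, computed in 100 ms bins of the baseline window
(the same bin width as the test bins — with mismatched window lengths the
rate distributions differ in shape under a homogeneous Poisson null and
the rank-sum would reject without any response). The Simes procedure over
the 19 p-values at alpha = 0.001 decides criterion (a). Criterion (b)
requires mean response-window firing above mean baseline firing, and
criterion (c) at least one spike in the response window in at least half
of the stimulus' trials.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .synth.sequence import CONTROL, PRIMED
from .synth.spikes_sim import UnitRecording

BASELINE_WINDOW = (-500.0, 0.0)
ACTIVATION_WINDOW = (100.0, 1000.0)
RESPONSE_WINDOW = (0.0, 1000.0)
BIN_ALPHA = 0.001
N_BINS = 19
BURST_SURPRISE_THRESHOLD = 2.0
BURST_RATE_CUTOFF = 2.0  # Hz; below this the first-spike fallback is used
FIRST_SPIKE_WINDOW = (100.0, 1000.0)
BURST_SEARCH_WINDOW = (0.0, 2000.0)

REGION_GROUPS = {"AM": ("AM",), "MTL": ("HC", "EC", "PHC")}


def bin_grid() -> np.ndarray:
    """The 19 overlapping 100 ms bins: [0,100),...,[900,1000) and [50,150),...,[850,950)."""
    aligned = np.array([[s, s + 100.0] for s in np.arange(0.0, 1000.0, 100.0)])
    offset = np.array([[s, s + 100.0] for s in np.arange(50.0, 950.0, 100.0)])
    return np.vstack([aligned, offset])


# ---------------------------------------------------------------------------
# normalization


@dataclass
class ZScoreParams:
    """Per-unit baseline statistics used for z-scoring."""

    baseline_mean: float
    baseline_sd: float
    baseline_window: tuple[float, float] = BASELINE_WINDOW
    activation_window: tuple[float, float] = ACTIVATION_WINDOW


def baseline_params(unit: UnitRecording) -> ZScoreParams:
    """Mean and SD of per-trial baseline rates over all trials, conditions pooled."""
    rates = unit.rates_in_window(*BASELINE_WINDOW)
    return ZScoreParams(float(rates.mean()), float(rates.std(ddof=1)))


def zscore_rates(
    unit: UnitRecording,
    window: tuple[float, float] = ACTIVATION_WINDOW,
    params: ZScoreParams | None = None,
) -> np.ndarray:
    """Per-trial z-scored rates in ``window`` relative to the baseline law.

    Raises ``ValueError`` for silent units (zero baseline SD); such units
    are excluded from z-based analyses.
    """
    if params is None:
        params = baseline_params(unit)
    if params.baseline_sd <= 0:
        raise ValueError(f"unit {unit.unit_id}: zero baseline SD (silent unit)")
    rates = unit.rates_in_window(*window)
    return (rates - params.baseline_mean) / params.baseline_sd


# ---------------------------------------------------------------------------
# rank-sum against a common baseline sample, vectorized over many tests


def ranksum_vs_baseline(obs: np.ndarray, baseline: np.ndarray) -> np.ndarray:
    """Two-sided rank-sum (Mann-Whitney) p-values of each row of ``obs``
    against the common ``baseline`` sample.

    Normal approximation with tie correction and continuity correction,
    matching ``scipy.stats.mannwhitneyu(..., method="asymptotic")``. The
    baseline is shared by every test, so cross-sample rank statistics are
    computed with two searchsorted passes instead of full rankings.
    """
    obs = np.atleast_2d(np.asarray(obs, dtype=float))
    m, k = obs.shape
    bs = np.sort(np.asarray(baseline, dtype=float))
    n = len(bs)
    lt = np.searchsorted(bs, obs, side="left")
    le = np.searchsorted(bs, obs, side="right")
    u = (lt + 0.5 * (le - lt)).sum(axis=1)

    # pooled tie correction: baseline-internal ties once, plus the change
    # introduced by each row's values (vectorized over rows; k is small)
    bvals, bcounts = np.unique(bs, return_counts=True)
    base_tie = float(np.sum(bcounts.astype(float) ** 3 - bcounts))
    srt = np.sort(obs, axis=1)
    is_start = np.ones_like(srt, dtype=bool)
    is_start[:, 1:] = srt[:, 1:] != srt[:, :-1]
    o_count = (srt[:, :, None] == srt[:, None, :]).sum(axis=2).astype(float)
    idx = np.searchsorted(bvals, srt)
    idx_c = np.minimum(idx, len(bvals) - 1)
    b_at = np.where((idx < len(bvals)) & (bvals[idx_c] == srt), bcounts[idx_c], 0).astype(float)
    tot = b_at + o_count
    contrib = (tot**3 - tot) - (b_at**3 - b_at)
    tie = base_tie + (contrib * is_start).sum(axis=1)

    big_n = n + k
    mu = k * n / 2.0
    var = (k * n / 12.0) * ((big_n + 1) - tie / (big_n * (big_n - 1.0)))
    p = np.ones(m)
    ok = var > 0
    num = np.abs(u - mu) - 0.5  # continuity correction toward the mean
    num = np.maximum(num, 0.0)
    z = np.zeros(m)
    z[ok] = num[ok] / np.sqrt(var[ok])
    p[ok] = np.minimum(1.0, 2.0 * stats.norm.sf(z[ok]))
    return p


def simes_reject(pvalues: np.ndarray, alpha: float = BIN_ALPHA) -> np.ndarray:
    """Simes global test: reject iff min_i sorted_p(i) * m / i <= alpha.

    Accepts a vector (returns bool) or a matrix of p-value rows (returns a
    boolean per row).
    """
    p = np.asarray(pvalues, dtype=float)
    single = p.ndim == 1
    p = np.atleast_2d(p)
    m = p.shape[1]
    sp = np.sort(p, axis=1)
    adj = sp * m / np.arange(1, m + 1)
    out = adj.min(axis=1) <= alpha
    return bool(out[0]) if single else out


# ---------------------------------------------------------------------------
# response criterion


@dataclass
class ResponseDecision:
    """Outcome of the binwise rank-sum criterion for one unit x stimulus."""

    unit_id: str
    stimulus: int
    p_bins: np.ndarray
    simes_pass: bool
    rate_above_baseline: bool
    spike_presence: bool

    @property
    def responsive(self) -> bool:
        return self.simes_pass and self.rate_above_baseline and self.spike_presence


def baseline_bin_grid() -> np.ndarray:
    """100 ms bins tiling the baseline window: [-500,-400), ..., [-100,0)."""
    starts = np.arange(BASELINE_WINDOW[0], BASELINE_WINDOW[1], 100.0)
    return np.column_stack([starts, starts + 100.0])


def _criterion_arrays(unit: UnitRecording):
    bins = bin_grid()
    bbins = baseline_bin_grid()
    windows = np.vstack([bins, bbins, [BASELINE_WINDOW], [RESPONSE_WINDOW]])
    counts = unit.counts_in_windows(windows)
    nb = len(bbins)
    bin_rates = counts[:, :N_BINS] / 0.1
    baseline_bin_rates = (counts[:, N_BINS : N_BINS + nb] / 0.1).ravel()
    baseline_rates = counts[:, N_BINS + nb] / 0.5
    resp_counts = counts[:, N_BINS + nb + 1]
    return bin_rates, baseline_bin_rates, baseline_rates, resp_counts


def response_decisions(
    unit: UnitRecording,
    alpha: float = BIN_ALPHA,
    min_presentations: int = 10,
) -> list[ResponseDecision]:
    """Apply the binwise rank-sum criterion to every stimulus of a unit."""
    bin_rates, baseline_bin_rates, baseline_rates, resp_counts = _criterion_arrays(unit)
    baseline_mean = baseline_rates.mean()
    stimuli = np.unique(unit.stimuli)
    obs_rows = []
    meta = []
    for s in stimuli:
        trials = np.flatnonzero(unit.stimuli == s)
        if len(trials) < min_presentations:
            raise ValueError(
                f"stimulus {s}: {len(trials)} presentations < required {min_presentations}"
            )
        obs_rows.append(bin_rates[trials].T)  # (19, n_trials)
        n_resp = resp_counts[trials]
        meta.append(
            (
                s,
                n_resp.mean() / (RESPONSE_WINDOW[1] - RESPONSE_WINDOW[0]) * 1000.0,
                int((n_resp > 0).sum()) * 2 >= len(trials),
            )
        )
    obs = np.vstack(obs_rows)  # (n_stim * 19, n_trials)
    p = ranksum_vs_baseline(obs, baseline_bin_rates).reshape(len(stimuli), N_BINS)
    simes = simes_reject(p, alpha)
    out = []
    for i, (s, resp_rate, presence) in enumerate(meta):
        out.append(
            ResponseDecision(
                unit_id=unit.unit_id,
                stimulus=int(s),
                p_bins=p[i],
                simes_pass=bool(simes[i]),
                rate_above_baseline=bool(resp_rate > baseline_mean),
                spike_presence=bool(presence),
            )
        )
    return out


def binwise_response_criterion(
    unit: UnitRecording, stimulus: int, alpha: float = BIN_ALPHA, min_presentations: int = 10
) -> ResponseDecision:
    """The criterion for a single stimulus (see module docstring)."""
    for d in response_decisions(unit, alpha, min_presentations):
        if d.stimulus == int(stimulus):
            return d
    raise ValueError(f"stimulus {stimulus} not presented to unit {unit.unit_id}")


def count_responsive(decisions: list[ResponseDecision]) -> int:
    return sum(d.responsive for d in decisions)


def select_multiresponsive_units(
    decisions_by_unit: dict[str, list[ResponseDecision]], min_stimuli: int = 4
) -> list[str]:
    """Units with at least ``min_stimuli`` response-eliciting stimuli."""
    if min_stimuli < 1:
        raise ValueError("min_stimuli must be >= 1")
    return [
        uid for uid, decs in decisions_by_unit.items() if count_responsive(decs) >= min_stimuli
    ]


# ---------------------------------------------------------------------------
# tuning curves


@dataclass
class TuningCurve:
    """Per-unit stimulus ranking with normalized condition rates per rank.

    Stimuli are ordered by descending mean rate in the response window
    [0, 1000) ms pooled over both conditions (ties broken by stimulus id);
    per-rank primed and control mean rates are both normalized by FRmax,
    the control-condition rate of the rank-1 stimulus, so the control value
    at rank 1 is 1 by construction.
    """

    unit_id: str
    region: str
    order: np.ndarray  # stimulus ids, rank 1 first
    pooled: np.ndarray  # pooled rate (Hz) per rank
    primed: np.ndarray  # normalized primed rate per rank
    control: np.ndarray  # normalized control rate per rank
    fr_max: float
    n_responsive: int = 0

    @property
    def n_ranks(self) -> int:
        return len(self.order)


def build_tuning_curve(
    unit: UnitRecording, n_responsive: int = 0
) -> TuningCurve | None:
    """Rank stimuli by pooled response rate and normalize both conditions by FRmax.

    Returns None (with a warning) when FRmax is zero, i.e. the unit fired
    no control-condition spikes to its top-ranked stimulus.
    """
    rates = unit.rates_in_window(*RESPONSE_WINDOW)
    stimuli = np.unique(unit.stimuli)
    pooled = np.empty(len(stimuli))
    prim = np.empty(len(stimuli))
    ctrl = np.empty(len(stimuli))
    for i, s in enumerate(stimuli):
        sel = unit.stimuli == s
        pooled[i] = rates[sel].mean()
        prim[i] = rates[sel & (unit.conditions == PRIMED)].mean()
        ctrl[i] = rates[sel & (unit.conditions == CONTROL)].mean()
    order = np.lexsort((stimuli, -pooled))  # stable: ties broken by stimulus id
    fr_max = ctrl[order[0]]
    if fr_max == 0:
        warnings.warn(f"unit {unit.unit_id}: FRmax is zero; unit excluded")
        return None
    return TuningCurve(
        unit_id=unit.unit_id,
        region=unit.region,
        order=stimuli[order],
        pooled=pooled[order],
        primed=prim[order] / fr_max,
        control=ctrl[order] / fr_max,
        fr_max=float(fr_max),
        n_responsive=n_responsive,
    )


@dataclass
class RankContrast:
    """Paired primed-vs-control contrast at one stimulus rank."""

    rank: int
    n_units: int
    mean_diff: float  # primed - control, normalized units
    mean_control: float  # mean normalized control value at this rank
    t: float
    t_pvalue: float
    ci: tuple[float, float]
    w: float
    w_pvalue: float


@dataclass
class AttenuationContrast:
    """Between-rank comparison of attenuation (control - primed)."""

    rank_a: int
    rank_b: int
    mean_diff_abs: float  # attenuation(b) - attenuation(a), absolute units
    t_abs: float
    p_abs: float
    mean_diff_rel: float  # same on attenuation relative to the control value
    t_rel: float
    p_rel: float
    n_units: int


@dataclass
class TuningContrastResult:
    """Per-rank contrasts and between-rank attenuation contrasts for one group."""

    group: str
    ranks: list[RankContrast]
    attenuation: list[AttenuationContrast]
    n_units: int
    test: str = "paired_t"

    def rank(self, r: int) -> RankContrast:
        return self.ranks[r - 1]

    def attenuation_pair(self, a: int, b: int) -> AttenuationContrast:
        for ac in self.attenuation:
            if (ac.rank_a, ac.rank_b) == (a, b):
                return ac
        raise KeyError((a, b))


def _paired(a: np.ndarray, b: np.ndarray) -> tuple[float, float, float, tuple[float, float]]:
    d = a - b
    n = len(d)
    t, p = stats.ttest_rel(a, b)
    sem = d.std(ddof=1) / np.sqrt(n)
    if sem == 0:
        t, p = 0.0, 1.0
        ci = (float(d.mean()), float(d.mean()))
    else:
        half = stats.t.ppf(0.975, n - 1) * sem
        ci = (float(d.mean() - half), float(d.mean() + half))
    return float(t), float(p), float(d.mean()), ci


def contrast_tuning(
    curves: list[TuningCurve], n_ranks: int = 4, group: str = ""
) -> TuningContrastResult:
    """Per-rank paired tests of normalized primed vs control values.

    Reports the paired t-test (with CI) and the Wilcoxon signed-rank test at
    every rank, and between-rank contrasts of the attenuation
    (control - primed), both in absolute normalized units and relative to
    the control value at the rank.
    """
    if len(curves) < 3:
        raise ValueError("need at least 3 units")
    ranks_out: list[RankContrast] = []
    for r in range(n_ranks):
        have = [c for c in curves if c.n_ranks > r]
        if len(have) < len(curves):
            warnings.warn(
                f"rank {r + 1}: {len(curves) - len(have)} unit(s) lack this rank; excluded"
            )
        if len(have) < 3:
            raise ValueError(f"rank {r + 1}: fewer than 3 units available")
        p_vals = np.array([c.primed[r] for c in have])
        c_vals = np.array([c.control[r] for c in have])
        t, tp, mean_diff, ci = _paired(p_vals, c_vals)
        if np.all(p_vals == c_vals):
            w, wp = 0.0, 1.0
        else:
            w, wp = stats.wilcoxon(
                p_vals, c_vals, zero_method="zsplit", method="approx", correction=False
            )
        ranks_out.append(
            RankContrast(
                rank=r + 1,
                n_units=len(have),
                mean_diff=mean_diff,
                mean_control=float(c_vals.mean()),
                t=t,
                t_pvalue=tp,
                ci=ci,
                w=float(w),
                w_pvalue=float(wp),
            )
        )

    att_out: list[AttenuationContrast] = []
    for ra in range(1, n_ranks + 1):
        for rb in range(ra + 1, n_ranks + 1):
            have = [c for c in curves if c.n_ranks >= rb]
            if len(have) < 3:
                continue
            att = lambda c, r: c.control[r - 1] - c.primed[r - 1]
            a_abs = np.array([att(c, ra) for c in have])
            b_abs = np.array([att(c, rb) for c in have])
            t_abs, p_abs, md_abs, _ = _paired(b_abs, a_abs)
            rel = lambda c, r: (
                (c.control[r - 1] - c.primed[r - 1]) / c.control[r - 1]
                if c.control[r - 1] != 0
                else np.nan
            )
            a_rel = np.array([rel(c, ra) for c in have])
            b_rel = np.array([rel(c, rb) for c in have])
            ok = np.isfinite(a_rel) & np.isfinite(b_rel)
            if ok.sum() >= 3:
                t_rel, p_rel, md_rel, _ = _paired(b_rel[ok], a_rel[ok])
            else:
                t_rel, p_rel, md_rel = np.nan, np.nan, np.nan
            att_out.append(
                AttenuationContrast(
                    rank_a=ra,
                    rank_b=rb,
                    mean_diff_abs=md_abs,
                    t_abs=t_abs,
                    p_abs=p_abs,
                    mean_diff_rel=md_rel,
                    t_rel=t_rel,
                    p_rel=p_rel,
                    n_units=len(have),
                )
            )
    return TuningContrastResult(
        group=group, ranks=ranks_out, attenuation=att_out, n_units=len(curves)
    )


def classify_population_profile(
    result: TuningContrastResult, alpha: float = 0.05
) -> str:
    """Label a population's adaptation profile from its rank contrasts.

    The axis separating the two mechanisms is the rank-1 to rank-2
    attenuation gradient: sharpening spares the optimal stimulus and
    *disproportionally* attenuates non-optimal ones, whereas fatiguing
    attenuates the optimal stimulus at least as strongly as non-optimal
    ones. Attenuation is measured relative to the control value at each
    rank, so a shape-preserving proportional reduction counts as uniform.
    Because sampling of the estimated rank order leaves small systematic
    gradients of either sign even under a purely proportional reduction,
    the sharpening signature requires both a significantly positive
    gradient and a material one (rank-2 relative attenuation at least
    twice rank-1's):

    * ``sharpening``: rank-2 contrast significant with primed < control,
      relative attenuation significantly stronger at rank 2 than rank 1,
      and at least twice as strong.
    * ``fatiguing``: rank-1 contrast significant with primed < control and
      no sharpening signature.
    * otherwise ``indeterminate``.
    """
    r1, r2 = result.rank(1), result.rank(2)
    att = result.attenuation_pair(1, 2)
    r1_sig = r1.t_pvalue < alpha and r1.mean_diff < 0
    r2_sig = r2.t_pvalue < alpha and r2.mean_diff < 0
    gradient_positive = att.p_rel < alpha and att.mean_diff_rel > 0
    rel_att = lambda r: -r.mean_diff / r.mean_control if r.mean_control else np.nan
    disproportionate = rel_att(r2) >= 2.0 * max(rel_att(r1), 0.0) and rel_att(r2) > 0
    sharpening_signature = r2_sig and gradient_positive and disproportionate
    if sharpening_signature:
        return "sharpening"
    if r1_sig and not sharpening_signature:
        return "fatiguing"
    return "indeterminate"


def rank_condition_table(
    curves: list[TuningCurve], n_ranks: int = 4
) -> pd.DataFrame:
    """Tidy unit x rank x condition table for external ANOVA."""
    rows = []
    for c in curves:
        for r in range(min(n_ranks, c.n_ranks)):
            rows.append((c.unit_id, c.region, r + 1, PRIMED, c.primed[r]))
            rows.append((c.unit_id, c.region, r + 1, CONTROL, c.control[r]))
    return pd.DataFrame(rows, columns=["unit", "region", "rank", "condition", "value"])


# ---------------------------------------------------------------------------
# burst detection


@dataclass
class BurstResult:
    """Per-trial response onset/offset/duration for one unit.

    ``method`` is ``poisson_burst`` for units with baseline rate above
    2 Hz (Poisson-surprise maximization over contiguous spike runs) and
    ``first_spike`` otherwise (onset only; offset and duration are NaN).
    """

    unit_id: str
    method: str
    onset: np.ndarray
    offset: np.ndarray
    duration: np.ndarray
    conditions: np.ndarray
    stimuli: np.ndarray
    baseline_rate: float


def poisson_surprise(k: int, duration_ms: float, rate_hz: float) -> float:
    """-log10 P(>= k spikes in duration | homogeneous Poisson at rate)."""
    mu = rate_hz * duration_ms / 1000.0
    sf = stats.poisson.sf(k - 1, mu)
    return float(-np.log10(sf)) if sf > 0 else np.inf


def _best_burst(spikes: np.ndarray, rate_hz: float, min_spikes: int = 3):
    """Contiguous run maximizing the Poisson surprise; vectorized over runs."""
    n = len(spikes)
    if n < min_spikes:
        return None
    i, j = np.triu_indices(n, k=min_spikes - 1)
    dur = spikes[j] - spikes[i]
    k = j - i + 1
    mu = rate_hz * dur / 1000.0
    with np.errstate(divide="ignore"):
        s = -np.log10(np.maximum(stats.poisson.sf(k - 1, mu), 1e-300))
    best = int(np.argmax(s))
    return float(spikes[i[best]]), float(spikes[j[best]]), float(s[best])


def detect_burst(
    unit: UnitRecording,
    threshold: float = BURST_SURPRISE_THRESHOLD,
    search: tuple[float, float] = BURST_SEARCH_WINDOW,
    baseline_rate: float | None = None,
) -> BurstResult:
    """Per-trial burst onset/offset via Poisson surprise against the unit's baseline.

    The baseline rate is estimated from the unit's own pre-stimulus window
    unless given. Units at or below 2 Hz baseline use the first-spike
    fallback: onset = first spike in [100, 1000) ms, no offset/duration.
    Trials without an accepted burst (or without spikes) yield NaNs.
    """
    if baseline_rate is None:
        baseline_rate = float(unit.rates_in_window(*BASELINE_WINDOW).mean())
    n = unit.n_trials
    onset = np.full(n, np.nan)
    offset = np.full(n, np.nan)
    if baseline_rate <= BURST_RATE_CUTOFF:
        for i in range(n):
            sp = unit.spikes_for_trial(i)
            sp = sp[(sp >= FIRST_SPIKE_WINDOW[0]) & (sp < FIRST_SPIKE_WINDOW[1])]
            if len(sp):
                onset[i] = sp[0]
        return BurstResult(
            unit_id=unit.unit_id,
            method="first_spike",
            onset=onset,
            offset=offset,
            duration=np.full(n, np.nan),
            conditions=unit.conditions,
            stimuli=unit.stimuli,
            baseline_rate=baseline_rate,
        )
    for i in range(n):
        sp = unit.spikes_for_trial(i)
        sp = sp[(sp >= search[0]) & (sp < search[1])]
        found = _best_burst(sp, baseline_rate)
        if found is not None and found[2] >= threshold:
            onset[i], offset[i] = found[0], found[1]
    return BurstResult(
        unit_id=unit.unit_id,
        method="poisson_burst",
        onset=onset,
        offset=offset,
        duration=offset - onset,
        conditions=unit.conditions,
        stimuli=unit.stimuli,
        baseline_rate=baseline_rate,
    )


def burst_duration_contrast(
    results: list[BurstResult],
    responsive_by_unit: dict[str, list[int]] | None = None,
) -> dict:
    """Across units: paired contrast of median burst duration primed vs control.

    When ``responsive_by_unit`` is given, only trials of each unit's
    response-eliciting stimuli enter the per-unit medians (trials of
    non-eliciting stimuli carry no response whose duration could shorten).
    """
    prim, ctrl = [], []
    for r in results:
        if r.method != "poisson_burst":
            continue
        keep = np.ones(len(r.conditions), dtype=bool)
        if responsive_by_unit is not None:
            keep = np.isin(r.stimuli, responsive_by_unit.get(r.unit_id, []))
        p = r.duration[keep & (r.conditions == PRIMED) & np.isfinite(r.duration)]
        c = r.duration[keep & (r.conditions == CONTROL) & np.isfinite(r.duration)]
        if len(p) and len(c):
            prim.append(np.median(p))
            ctrl.append(np.median(c))
    prim, ctrl = np.array(prim), np.array(ctrl)
    if len(prim) < 3:
        raise ValueError("need at least 3 units with bursts in both conditions")
    if np.all(prim == ctrl):
        w, p = 0.0, 1.0
    else:
        w, p = stats.wilcoxon(prim, ctrl, zero_method="zsplit", method="approx", correction=False)
    return {
        "n_units": int(len(prim)),
        "median_primed_ms": float(np.median(prim)),
        "median_control_ms": float(np.median(ctrl)),
        "statistic": float(w),
        "pvalue": float(p),
    }


# ---------------------------------------------------------------------------
# pre-stimulus (spreading activation) test


def prestimulus_test(
    units: list[UnitRecording],
    decisions_by_unit: dict[str, list[ResponseDecision]],
    region_groups: dict[str, tuple[str, ...]] = REGION_GROUPS,
    use_zscore: bool = True,
) -> dict[str, dict]:
    """Pre-stimulus activity before primed vs control presentations.

    For every unit responding to at least one stimulus: the mean
    (optionally z-scored) firing rate in [-500, 0) ms before primed vs
    before control presentations of its responsive stimuli; a two-tailed
    paired t-test across units, reported per region group.
    """
    per_group: dict[str, list[tuple[float, float]]] = {g: [] for g in region_groups}
    for unit in units:
        decs = decisions_by_unit.get(unit.unit_id, [])
        responsive = [d.stimulus for d in decs if d.responsive]
        if not responsive:
            continue
        try:
            if use_zscore:
                vals = zscore_rates(unit, window=BASELINE_WINDOW)
            else:
                vals = unit.rates_in_window(*BASELINE_WINDOW)
        except ValueError:
            continue  # silent unit
        sel = np.isin(unit.stimuli, responsive)
        p_sel = sel & (unit.conditions == PRIMED)
        c_sel = sel & (unit.conditions == CONTROL)
        if not p_sel.any() or not c_sel.any():
            continue
        pair = (float(vals[p_sel].mean()), float(vals[c_sel].mean()))
        for g, regions in region_groups.items():
            if unit.region in regions:
                per_group[g].append(pair)
    out = {}
    for g, pairs in per_group.items():
        if len(pairs) < 2:
            raise ValueError(f"group {g}: need at least 2 responsive units, got {len(pairs)}")
        a = np.array([x for x, _ in pairs])
        b = np.array([y for _, y in pairs])
        t, p = stats.ttest_rel(a, b)
        out[g] = {
            "n_units": int(len(pairs)),
            "mean_primed": float(a.mean()),
            "sd_primed": float(a.std(ddof=1)),
            "mean_control": float(b.mean()),
            "sd_control": float(b.std(ddof=1)),
            "t": float(t),
            "pvalue": float(p),
        }
    return out
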