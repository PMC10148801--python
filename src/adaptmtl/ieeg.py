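"""iEEG preprocessing, artifact rejection, ERPs and peak-latency contrasts.

The analysis entry point is a set of fixed-length per-trial voltage
segments spanning [-1000, 2000) ms around stimulus onset at 256 Hz,
baseline-corrected to the [-200, 0) ms window. Raw traces (continuous or
per-trial epochs at a higher native rate) are brought into that form by
:func:`preprocess`: anti-aliased resampling to 256 Hz, zero-phase
Butterworth bandpass 0.1-80 Hz, segmentation, baseline subtraction.

Two median-ratio artifact filters operate on the segment set: a segment is
excluded when the ratio of its absolute maximum to the median of all
absolute maxima exceeds 2.5, or when the ratio of its median absolute
sample to the median of those medians exceeds 2.5.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np
from scipy import signal, stats

TARGET_RATE = 256.0
SEGMENT_WINDOW_MS = (-1000.0, 2000.0)
BASELINE_WINDOW_MS = (-200.0, 0.0)
BANDPASS_HZ = (0.1, 80.0)
ARTIFACT_RATIO = 2.5
EARLY_WINDOW_MS = (200.0, 400.0)
LATE_WINDOW_MS = (400.0, 750.0)


@dataclass
class IeegSegments:
    """Per-trial voltage segments with condition labels and artifact mask.

    ``data`` is (n_trials, n_samples) spanning ``window_ms`` (half-open) at
    ``rate`` Hz. ``artifact_mask`` is True for segments flagged as
    artifactual (all False until :func:`reject_artifacts` is applied).
    """

    data: np.ndarray
    rate: float
    window_ms: tuple[float, float]
    conditions: np.ndarray
    region: str = "AM"
    session: str = "S01"
    artifact_mask: np.ndarray | None = None
    artifact_truth: np.ndarray | None = None  # ground truth from the simulator

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        self.conditions = np.asarray(self.conditions)
        if self.artifact_mask is None:
            self.artifact_mask = np.zeros(len(self.data), dtype=bool)

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def times(self) -> np.ndarray:
        """Sample times in ms (left edge of each sample)."""
        n = self.data.shape[1]
        return self.window_ms[0] + np.arange(n) * 1000.0 / self.rate


@dataclass
class Erp:
    """Per-condition mean traces of one session (or a grand average)."""

    means: dict[str, np.ndarray]
    sems: dict[str, np.ndarray]
    n: dict[str, int]
    rate: float
    window_ms: tuple[float, float]
    region: str = "AM"
    session: str = "S01"

    @property
    def times(self) -> np.ndarray:
        k = next(iter(self.means))
        return self.window_ms[0] + np.arange(len(self.means[k])) * 1000.0 / self.rate


@dataclass
class PeakLatencyResult:
    """Paired peak-latency contrast across sessions."""

    latencies: dict[str, np.ndarray]  # condition -> per-session latency (ms)
    window_ms: tuple[float, float]
    polarity: str
    median: dict[str, float]
    iqr: dict[str, float]
    statistic: float
    pvalue: float
    n_sessions: int


def design_bandpass(
    rate: float, band: tuple[float, float] = BANDPASS_HZ, order: int = 2
) -> np.ndarray:
    """Second-order-sections Butterworth bandpass used throughout."""
    return signal.butter(order, band, btype="bandpass", fs=rate, output="sos")


def _resample(x: np.ndarray, native_rate: float, target_rate: float) -> np.ndarray:
    if native_rate == target_rate:
        return np.asarray(x, dtype=float)
    frac = Fraction(target_rate / native_rate).limit_denominator(10000)
    return signal.resample_poly(
        np.asarray(x, dtype=float),
        frac.numerator,
        frac.denominator,
        axis=-1,
        padtype="line",  # avoids zero-padding edge taper
    )


def baseline_correct(
    data: np.ndarray, rate: float, window_ms, baseline_ms=BASELINE_WINDOW_MS
) -> np.ndarray:
    """Subtract the mean of the baseline window from every sample per segment."""
    t = window_ms[0] + np.arange(data.shape[-1]) * 1000.0 / rate
    sel = (t >= baseline_ms[0]) & (t < baseline_ms[1])
    if not sel.any():
        raise ValueError("baseline window contains no samples")
    return data - data[..., sel].mean(axis=-1, keepdims=True)


def preprocess(
    raw: np.ndarray,
    native_rate: float,
    conditions: np.ndarray,
    onsets_s: np.ndarray | None = None,
    epoch_tmin_ms: float | None = None,
    target_rate: float = TARGET_RATE,
    band: tuple[float, float] = BANDPASS_HZ,
    order: int = 2,
    segment_ms: tuple[float, float] = SEGMENT_WINDOW_MS,
    baseline_ms: tuple[float, float] = BASELINE_WINDOW_MS,
    region: str = "AM",
    session: str = "S01",
    artifact_truth: np.ndarray | None = None,
) -> IeegSegments:
    """Resample, bandpass (zero-phase), segment and baseline-correct.

    Two input layouts are supported:

    * continuous: ``raw`` is 1-D and ``onsets_s`` gives stimulus onsets in
      seconds from trace start; events whose segment would cross a recording
      edge are dropped with a warning.
    * epoched: ``raw`` is (n_trials, n_samples) and ``epoch_tmin_ms`` gives
      the time of the first sample relative to onset; epochs must cover the
      segment window.
    """
    if native_rate < 2 * target_rate:
        raise ValueError("native rate must be at least twice the target rate")
    raw = np.asarray(raw, dtype=float)
    conditions = np.asarray(conditions)
    sos = design_bandpass(target_rate, band, order)

    if raw.ndim == 1:
        if onsets_s is None:
            raise ValueError("continuous input requires onsets_s")
        x = _resample(raw, native_rate, target_rate)
        x = signal.sosfiltfilt(sos, x)
        lo = int(np.floor(segment_ms[0] / 1000.0 * target_rate))
        n_samp = int(round((segment_ms[1] - segment_ms[0]) / 1000.0 * target_rate))
        onset_idx = np.round(np.asarray(onsets_s) * target_rate).astype(int)
        keep = (onset_idx + lo >= 0) & (onset_idx + lo + n_samp <= len(x))
        if not keep.all():
            warnings.warn(
                f"dropping {int((~keep).sum())} events too close to recording edges"
            )
        starts = onset_idx[keep] + lo
        data = np.stack([x[s : s + n_samp] for s in starts])
        conditions = conditions[keep]
        if artifact_truth is not None:
            artifact_truth = np.asarray(artifact_truth)[keep]
    else:
        if epoch_tmin_ms is None:
            raise ValueError("epoched input requires epoch_tmin_ms")
        x = _resample(raw, native_rate, target_rate)
        # demean per epoch before zero-phase filtering: the highpass corner
        # (0.1 Hz) is slow relative to an epoch, so the DC step would
        # otherwise leave a long transient inside the segment
        x = x - x.mean(axis=-1, keepdims=True)
        x = signal.sosfiltfilt(sos, x, axis=-1, padlen=x.shape[-1] - 1)
        t = epoch_tmin_ms + np.arange(x.shape[-1]) * 1000.0 / target_rate
        sel = (t >= segment_ms[0]) & (t < segment_ms[1])
        n_expect = int(round((segment_ms[1] - segment_ms[0]) / 1000.0 * target_rate))
        if sel.sum() < n_expect:
            raise ValueError("epochs do not cover the segment window")
        idx = np.flatnonzero(sel)[:n_expect]
        data = x[:, idx]

    data = baseline_correct(data, target_rate, segment_ms, baseline_ms)
    return IeegSegments(
        data=data,
        rate=target_rate,
        window_ms=segment_ms,
        conditions=conditions,
        region=region,
        session=session,
        artifact_truth=artifact_truth,
    )


def reject_artifacts(segments: IeegSegments, ratio: float = ARTIFACT_RATIO) -> np.ndarray:
    """Flag artifactual segments by the two median-ratio rules.

    A segment is flagged iff (max-rule) the ratio of its absolute maximum to
    the median of all segments' absolute maxima exceeds ``ratio``, OR
    (noise-floor rule) the ratio of its median absolute sample to the median
    of all segments' median absolute samples exceeds ``ratio``. Both rules
    are evaluated on the full input set; there is no iterative
    re-computation after removal. Returns the boolean mask and stores it on
    ``segments.artifact_mask``.
    """
    if segments.n_trials < 3:
        raise ValueError("artifact rejection needs at least 3 segments")
    absdata = np.abs(segments.data)
    maxima = absdata.max(axis=1)
    med_of_max = np.median(maxima)
    if med_of_max == 0:
        raise ValueError("median of absolute maxima is zero (all-zero data?)")
    medians = np.median(absdata, axis=1)
    med_of_med = np.median(medians)
    if med_of_med == 0:
        raise ValueError("median of segment medians is zero (all-zero data?)")
    mask = (maxima / med_of_max > ratio) | (medians / med_of_med > ratio)
    segments.artifact_mask = mask
    return mask


def compute_erp(
    segments: IeegSegments,
    mask: np.ndarray | None = None,
    conditions: tuple[str, ...] = ("primed", "control"),
) -> Erp:
    """Average clean segments per experimental condition."""
    if mask is None:
        mask = segments.artifact_mask
    means, sems, n = {}, {}, {}
    for cond in conditions:
        sel = (segments.conditions == cond) & ~mask
        if not sel.any():
            raise ValueError(f"no clean segments in condition {cond!r}")
        d = segments.data[sel]
        means[cond] = d.mean(axis=0)
        sems[cond] = d.std(axis=0, ddof=1) / np.sqrt(len(d)) if len(d) > 1 else np.zeros(d.shape[1])
        n[cond] = int(len(d))
    return Erp(
        means=means,
        sems=sems,
        n=n,
        rate=segments.rate,
        window_ms=segments.window_ms,
        region=segments.region,
        session=segments.session,
    )


def grand_average(erps: list[Erp], region: str | None = None) -> Erp:
    """Average session ERPs (optionally restricted to one region)."""
    use = [e for e in erps if region is None or e.region == region]
    if not use:
        raise ValueError("no ERPs to average")
    conds = list(use[0].means)
    means = {c: np.mean([e.means[c] for e in use], axis=0) for c in conds}
    sems = {
        c: np.std([e.means[c] for e in use], axis=0, ddof=1) / np.sqrt(len(use))
        if len(use) > 1
        else np.zeros_like(means[c])
        for c in conds
    }
    return Erp(
        means=means,
        sems=sems,
        n={c: len(use) for c in conds},
        rate=use[0].rate,
        window_ms=use[0].window_ms,
        region=region or use[0].region,
        session="grand_average",
    )


def peak_latency(
    trace: np.ndarray, times: np.ndarray, window_ms, polarity: str
) -> float:
    """Latency (ms) of the signed extremum inside the half-open window."""
    sel = (times >= window_ms[0]) & (times < window_ms[1])
    if not sel.any():
        raise ValueError("window contains no samples")
    seg = trace[sel]
    if np.all(seg == seg[0]):
        warnings.warn("flat trace in window; returning first sample")
        return float(times[sel][0])
    idx = np.argmin(seg) if polarity == "negative" else np.argmax(seg)
    return float(times[sel][idx])


def peak_latency_contrast(
    erps: list[Erp],
    window_ms: tuple[float, float] = EARLY_WINDOW_MS,
    polarity: str = "negative",
    conditions: tuple[str, str] = ("primed", "control"),
) -> PeakLatencyResult:
    """Per-session peak latencies per condition with a paired signed-rank test."""
    if polarity not in ("negative", "positive"):
        raise ValueError("polarity must be 'negative' or 'positive'")
    lats = {c: [] for c in conditions}
    for erp in erps:
        for c in conditions:
            lats[c].append(peak_latency(erp.means[c], erp.times, window_ms, polarity))
    lat = {c: np.array(v) for c, v in lats.items()}
    a, b = lat[conditions[0]], lat[conditions[1]]
    if np.all(a == b):
        stat, p = 0.0, 1.0
    else:
        stat, p = stats.wilcoxon(
            a, b, zero_method="zsplit", method="approx", correction=False
        )
    return PeakLatencyResult(
        latencies=lat,
        window_ms=window_ms,
        polarity=polarity,
        median={c: float(np.median(lat[c])) for c in conditions},
        iqr={c: float(np.subtract(*np.percentile(lat[c], [75, 25]))) for c in conditions},
        statistic=float(stat),
        pvalue=float(p),
        n_sessions=len(erps),
    )
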