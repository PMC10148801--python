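"""ERP-like iEEG segment simulator with pink noise and injected artifacts.

Per-trial traces are a condition-scaled (and condition-shifted) sum-of-
Gaussians ERP template plus 1/f ("pink") noise. The default template has a
negative deflection near 270 ms and a positive deflection near 500 ms, so
the early (200-400 ms, negative) and late (400-750 ms, positive)
peak-latency windows used by the analysis are meaningful. Artifacts are
multiplicative amplitude bursts injected at a configurable rate with a
ground-truth flag, exercising the median-ratio filters as designed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ..ieeg import IeegSegments
from .sequence import DISCARDED_FIRST
from .stimuli import ConfigurationError


@dataclass(frozen=True)
class ErpTemplateSpec:
    """Template and noise model of one region's simulated ERP.

    ``peaks`` are (amplitude, latency_ms, fwhm_ms) Gaussians; amplitudes in
    arbitrary voltage units (signed). ``amplitude_scale`` and
    ``latency_shift_ms`` map condition -> effect. ``noise_sd`` sets the
    pink-noise standard deviation. Artifacts multiply a random 200-400 ms
    span of a segment by ``artifact_factor``.
    """

    rate: float = 256.0
    window_ms: tuple[float, float] = (-1000.0, 2000.0)
    peaks: tuple[tuple[float, float, float], ...] = (
        (-8.0, 270.0, 120.0),
        (10.0, 500.0, 240.0),
        (-3.0, 900.0, 500.0),
    )
    amplitude_scale: tuple[tuple[str, float], ...] = (("primed", 0.8), ("control", 1.0))
    latency_shift_ms: tuple[tuple[str, float], ...] = (("primed", -16.0), ("control", 0.0))
    noise_sd: float = 4.0
    artifact_rate: float = 0.05
    artifact_factor: float = 10.0

    def validate(self) -> None:
        if self.rate <= 0:
            raise ConfigurationError("sampling rate must be positive")
        if self.window_ms[0] > -1000.0 or self.window_ms[1] < 2000.0:
            raise ConfigurationError("segment window must cover [-1000, 2000] ms")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be >= 0")
        if not 0 <= self.artifact_rate <= 1:
            raise ConfigurationError("artifact_rate must be in [0, 1]")
        t = np.arange(200.0, 750.0, 1.0)
        tmpl = self.template(t)
        early = tmpl[(t >= 200) & (t < 400)]
        late = tmpl[(t >= 400) & (t < 750)]
        if early.min() >= 0 or late.max() <= 0:
            raise ConfigurationError(
                "template must have a negative deflection in 200-400 ms "
                "and a positive deflection in 400-750 ms"
            )

    def template(self, t_ms: np.ndarray) -> np.ndarray:
        out = np.zeros_like(np.asarray(t_ms, dtype=float))
        for amp, lat, fwhm in self.peaks:
            sd = fwhm / 2.3548200450309493  # FWHM -> Gaussian sigma
            out += amp * np.exp(-0.5 * ((t_ms - lat) / sd) ** 2)
        return out

    def scale_of(self, condition: str) -> float:
        return dict(self.amplitude_scale).get(condition, 1.0)

    def shift_of(self, condition: str) -> float:
        return dict(self.latency_shift_ms).get(condition, 0.0)


def pink_noise(
    rng: np.random.Generator, shape: tuple[int, int], exponent: float = 1.0
) -> np.ndarray:
    """Unit-variance 1/f^exponent noise rows via spectral shaping."""
    n_trials, n_samples = shape
    white = rng.standard_normal(shape)
    spec = np.fft.rfft(white, axis=1)
    f = np.fft.rfftfreq(n_samples)
    gain = np.zeros_like(f)
    gain[1:] = f[1:] ** (-exponent / 2.0)
    x = np.fft.irfft(spec * gain, n=n_samples, axis=1)
    sd = x.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return x / sd


def _simulate(
    trials: pd.DataFrame,
    spec: ErpTemplateSpec,
    rng: np.random.Generator,
    rate: float,
    window_ms: tuple[float, float],
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    tgt = trials[trials["condition"] != DISCARDED_FIRST]
    conds = tgt["condition"].to_numpy()
    n_trials = len(conds)
    n_samples = int(round((window_ms[1] - window_ms[0]) / 1000.0 * rate))
    t = window_ms[0] + np.arange(n_samples) * 1000.0 / rate

    data = spec.noise_sd * pink_noise(rng, (n_trials, n_samples))
    for cond in np.unique(conds):
        sel = conds == cond
        tmpl = spec.scale_of(cond) * spec.template(t - spec.shift_of(cond))
        data[sel] += tmpl

    artifact = rng.random(n_trials) < spec.artifact_rate
    for i in np.flatnonzero(artifact):
        span = rng.uniform(200.0, 400.0)
        start = rng.uniform(window_ms[0], window_ms[1] - span)
        sel = (t >= start) & (t < start + span)
        data[i, sel] *= spec.artifact_factor
    return data, conds, artifact


def simulate_ieeg(
    trials: pd.DataFrame,
    spec: ErpTemplateSpec = ErpTemplateSpec(),
    seed=None,
    region: str = "AM",
) -> IeegSegments:
    """Simulate analysis-ready segments (at ``spec.rate``, baseline uncorrected).

    One segment per target trial over ``spec.window_ms``; the ground-truth
    artifact flags are stored in ``artifact_truth``.
    """
    spec.validate()
    rng = np.random.default_rng(seed)
    data, conds, artifact = _simulate(trials, spec, rng, spec.rate, spec.window_ms)
    session = str(trials["session"].iloc[0]) if "session" in trials else "S01"
    return IeegSegments(
        data=data,
        rate=spec.rate,
        window_ms=spec.window_ms,
        conditions=conds,
        region=region,
        session=session,
        artifact_truth=artifact,
    )


def simulate_ieeg_raw(
    trials: pd.DataFrame,
    spec: ErpTemplateSpec = ErpTemplateSpec(),
    seed=None,
    native_rate: float = 1024.0,
    epoch_ms: tuple[float, float] = (-1500.0, 2500.0),
    region: str = "AM",
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Simulate raw per-trial epochs at a native rate for the preprocessing path.

    Returns ``(epochs, conditions, artifact_truth)`` where ``epochs`` is
    (n_trials, n_samples) at ``native_rate`` covering ``epoch_ms`` (wider
    than the analysis segment so filtering and segmentation have margin).
    """
    spec.validate()
    if native_rate < 2 * spec.rate:
        raise ConfigurationError("native_rate must be at least twice the analysis rate")
    if epoch_ms[0] > spec.window_ms[0] or epoch_ms[1] < spec.window_ms[1]:
        raise ConfigurationError("epoch window must cover the analysis segment window")
    rng = np.random.default_rng(seed)
    return _simulate(trials, spec, rng, native_rate, epoch_ms)
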