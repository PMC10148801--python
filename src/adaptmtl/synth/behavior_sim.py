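"""Simulated reaction times and response correctness.

RTs follow a shifted lognormal with a condition effect applied additively to
the median: primed responses are faster by ``effect_ms``. A configurable
fraction of trials is replaced by planted outliers (lapses / anticipations)
far outside the generating law so the session-level mean +/- 2.5 SD exclusion
rule is exercised on both tails; planted outliers are flagged in a
ground-truth column for testing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .sequence import CONTROL, DISCARDED_FIRST, PRIMED
from .stimuli import ConfigurationError


@dataclass(frozen=True)
class RtParams:
    """Parameters of the RT / accuracy model.

    Defaults reproduce session medians of about 713 ms (control) and
    604 ms (primed) and error rates of 2% (control) and 0.6% (primed).
    """

    median_control: float = 713.0
    effect_ms: float = 109.0
    shift_ms: float = 250.0
    sigma: float = 0.35
    outlier_rate: float = 0.02
    error_rate_primed: float = 0.006
    error_rate_control: float = 0.02

    def validate(self) -> None:
        if self.sigma <= 0:
            raise ConfigurationError("sigma must be positive")
        if not 0 <= self.outlier_rate < 1:
            raise ConfigurationError("outlier_rate must be in [0, 1)")
        if self.median_control - self.effect_ms <= self.shift_ms:
            raise ConfigurationError("primed median must exceed the RT shift")
        for r in (self.error_rate_primed, self.error_rate_control):
            if not 0 <= r <= 1:
                raise ConfigurationError("error rates must be in [0, 1]")

    def mu(self, condition: str) -> float:
        median = self.median_control - (self.effect_ms if condition == PRIMED else 0.0)
        return float(np.log(median - self.shift_ms))

    def law_moments(self) -> tuple[float, float]:
        """Mean and SD of the 50/50 primed/control RT mixture (no outliers)."""
        means, variances = [], []
        for cond in (PRIMED, CONTROL):
            m = self.mu(cond)
            s2 = self.sigma**2
            mean = self.shift_ms + np.exp(m + s2 / 2)
            var = (np.exp(s2) - 1) * np.exp(2 * m + s2)
            means.append(mean)
            variances.append(var)
        mean = float(np.mean(means))
        var = float(np.mean(variances) + np.var(means))
        return mean, float(np.sqrt(var))


def simulate_behavior(
    trials: pd.DataFrame, params: RtParams = RtParams(), seed: int | None = None
) -> pd.DataFrame:
    """Fill the ``rt`` and ``correct`` columns of a trial table.

    Returns a copy with two added ground-truth columns: ``rt_outlier``
    (planted outlier flag) and ``rt_clean`` (the pre-contamination RT).
    Leading discarded presentations receive control-law RTs; they are
    excluded from all analyses anyway.
    """
    params.validate()
    rng = np.random.default_rng(seed)
    out = trials.copy()
    n = len(out)
    cond = out["condition"].to_numpy()
    mu = np.where(cond == PRIMED, params.mu(PRIMED), params.mu(CONTROL))
    rt = params.shift_ms + rng.lognormal(mean=mu, sigma=params.sigma, size=n)
    out["rt_clean"] = rt

    is_outlier = rng.random(n) < params.outlier_rate
    mean, sd = params.law_moments()
    n_out = int(is_outlier.sum())
    if n_out:
        slow = rng.random(n_out) < 0.8
        mag = rng.uniform(3.2, 6.0, size=n_out)
        planted = np.where(
            slow, mean + mag * sd, np.maximum(50.0, mean - rng.uniform(3.2, 4.0, n_out) * sd)
        )
        rt = rt.copy()
        rt[is_outlier] = planted
    out["rt"] = rt
    out["rt_outlier"] = is_outlier

    err = np.where(cond == PRIMED, params.error_rate_primed, params.error_rate_control)
    out["correct"] = pd.array(rng.random(n) >= err, dtype="boolean")
    out.loc[out["condition"] == DISCARDED_FIRST, "correct"] = True
    return out
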