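"""Behavioral priming: RT outlier exclusion and primed-vs-control contrasts.

Reaction-time outliers are excluded per session using the session's own
mean and standard deviation over all target trials (both conditions
pooled): a trial is excluded iff its RT lies below ``M - 2.5 SD`` or above
``M + 2.5 SD``. The primed-vs-control contrast is a two-tailed Wilcoxon
signed-rank test over per-session condition means, with an optional
response-priming control that drops control trials whose prime belongs to
the other manmade/natural meta-category (prime and target then afford
different motor responses).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .synth.sequence import CONTROL, DISCARDED_FIRST, PRIMED

RT_SD_CRITERION = 2.5
MIN_SESSIONS = 6


@dataclass
class BehavioralContrastResult:
    """Group-level paired contrast over per-session condition summaries."""

    measure: str  # "rt" or "accuracy"
    per_session: pd.DataFrame  # index session, columns primed/control
    median: dict[str, float]
    iqr: dict[str, float]
    statistic: float
    pvalue: float
    n_sessions: int
    response_priming_excluded: bool


def _targets(trials: pd.DataFrame) -> pd.DataFrame:
    return trials[trials["condition"] != DISCARDED_FIRST]


def exclude_rt_outliers(
    trials: pd.DataFrame, criterion: float = RT_SD_CRITERION
) -> np.ndarray:
    """Boolean exclusion mask (True = exclude), aligned with ``trials`` rows.

    M and SD are computed per session over all target trials, conditions
    pooled; leading discarded presentations are never included and never
    flagged. Sessions need at least 2 target trials for the SD to exist.
    """
    if trials["rt"].isna().all():
        raise ValueError("trial table has no reaction times")
    mask = np.zeros(len(trials), dtype=bool)
    is_target = (trials["condition"] != DISCARDED_FIRST).to_numpy()
    for _, idx in trials.groupby("session").indices.items():
        sel = idx[is_target[idx]]
        rt = trials["rt"].to_numpy()[sel]
        if len(rt) < 2:
            raise ValueError("session has fewer than 2 trials; SD undefined")
        m, sd = rt.mean(), rt.std(ddof=1)
        mask[sel] = (rt < m - criterion * sd) | (rt > m + criterion * sd)
    return mask


def _paired_contrast(
    per_session: pd.DataFrame, measure: str, response_priming_excluded: bool
) -> BehavioralContrastResult:
    a = per_session[PRIMED].to_numpy(dtype=float)
    b = per_session[CONTROL].to_numpy(dtype=float)
    if len(a) < MIN_SESSIONS:
        raise ValueError(
            f"need at least {MIN_SESSIONS} sessions for a signed-rank contrast, got {len(a)}"
        )
    if np.all(a == b):
        stat, p = float(len(a) * (len(a) + 1) / 4), 1.0  # statistic at null center
    else:
        stat, p = stats.wilcoxon(a, b, zero_method="zsplit", method="approx", correction=False)
    return BehavioralContrastResult(
        measure=measure,
        per_session=per_session,
        median={c: float(np.median(per_session[c])) for c in (PRIMED, CONTROL)},
        iqr={
            c: float(np.subtract(*np.percentile(per_session[c], [75, 25])))
            for c in (PRIMED, CONTROL)
        },
        statistic=float(stat),
        pvalue=float(p),
        n_sessions=int(len(a)),
        response_priming_excluded=response_priming_excluded,
    )


def _drop_response_priming(df: pd.DataFrame) -> pd.DataFrame:
    """Drop control trials whose prime has the other meta-category."""
    stim_meta = df.drop_duplicates("stimulus").set_index("stimulus")["meta"]
    prime_meta = df["prime"].map(stim_meta)
    # primes whose meta cannot be established are kept (no evidence of mismatch)
    keep = (df["condition"] != CONTROL) | (prime_meta == df["meta"]) | prime_meta.isna()
    return df[keep.to_numpy()]


def _aggregate(
    trials: pd.DataFrame,
    value: pd.Series,
    exclude_response_priming: bool,
) -> pd.DataFrame:
    df = trials.assign(_value=value.to_numpy())
    if exclude_response_priming:
        df = _drop_response_priming(df)
    per = df.pivot_table(index="session", columns="condition", values="_value", aggfunc="mean")
    for cond in (PRIMED, CONTROL):
        if cond not in per:
            per[cond] = np.nan
    incomplete = per[[PRIMED, CONTROL]].isna().any(axis=1)
    if incomplete.any():
        warnings.warn(
            f"dropping {int(incomplete.sum())} session(s) lacking trials in one condition"
        )
        per = per[~incomplete]
    return per[[PRIMED, CONTROL]]


def contrast_rt(
    trials: pd.DataFrame,
    exclude_response_priming: bool = False,
    drop_incorrect: bool = True,
    criterion: float = RT_SD_CRITERION,
) -> BehavioralContrastResult:
    """Primed-vs-control signed-rank contrast on per-session mean RTs.

    RT outliers (per-session mean +/- 2.5 SD rule) are excluded first;
    incorrect trials are excluded by default.
    """
    mask = exclude_rt_outliers(trials, criterion)
    df = _targets(trials[~mask])
    if drop_incorrect and df["correct"].notna().any():
        df = df[df["correct"].fillna(True).astype(bool)]
    per = _aggregate(df, df["rt"], exclude_response_priming)
    return _paired_contrast(per, "rt", exclude_response_priming)


def contrast_accuracy(
    trials: pd.DataFrame, exclude_response_priming: bool = False
) -> BehavioralContrastResult:
    """Primed-vs-control signed-rank contrast on per-session percent correct.

    No RT outlier exclusion is applied to accuracy.
    """
    df = _targets(trials)
    if df["correct"].isna().all():
        raise ValueError("trial table has no correctness data")
    value = df["correct"].astype(float) * 100.0
    per = _aggregate(df, value, exclude_response_priming)
    return _paired_contrast(per, "accuracy", exclude_response_priming)
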