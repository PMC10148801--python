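"""Cluster-based permutation statistics for paired ERP condition contrasts.

A paired t-test is run at every sample point between the two conditions'
traces. Clusters are maximal runs of consecutive samples with p below a
cluster-forming alpha (default 0.001) and a common t-sign. The permutation
null swaps condition labels independently per pair (a within-session
design, equivalent to sign-flipping the difference traces) and records, per
permutation, the maximum positive and minimum negative cluster t-sum (0
when no cluster forms). An observed positive cluster is significant when
its t-sum exceeds the 99th percentile of the positive-tail null; a negative
cluster when its t-sum falls below the 1st percentile of the negative-tail
null. A Monte-Carlo p-value is reported alongside the percentile decision.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

CLUSTER_ALPHA = 0.001
N_PERMUTATIONS = 1000
PERCENTILE = 99.0


@dataclass
class Cluster:
    """A contiguous supra-threshold run with a common t-sign (half-open)."""

    start: int
    end: int  # exclusive
    t_sum: float
    sign: int

    @property
    def size(self) -> int:
        return self.end - self.start


@dataclass
class ClusterResult(Cluster):
    """A scored cluster."""

    p_mc: float = 1.0
    threshold: float = np.nan
    significant: bool = False
    start_ms: float = np.nan
    end_ms: float = np.nan


@dataclass
class PermutationNull:
    """Per-permutation extreme cluster sums for both tails."""

    pos: np.ndarray  # max positive cluster sum per permutation
    neg: np.ndarray  # min negative cluster sum per permutation
    n_perm: int
    exact: bool
    seed: object = None


def _paired_t(diffs: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized paired t on difference traces (n_pairs, n_samples)."""
    n = diffs.shape[0]
    mean = diffs.mean(axis=0)
    sd = diffs.std(axis=0, ddof=1)
    t = np.zeros_like(mean)
    ok = sd > 0
    t[ok] = mean[ok] / (sd[ok] / np.sqrt(n))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 1)
    p[~ok] = 1.0
    return t, p, ok


def samplewise_t(pairs_a: np.ndarray, pairs_b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Two-tailed paired t statistic and p-value at every sample.

    ``pairs_a`` and ``pairs_b`` are (n_pairs, n_samples) with matching rows.
    Samples with zero variance of the pair differences get t = 0, p = 1
    with a warning.
    """
    a = np.atleast_2d(np.asarray(pairs_a, dtype=float))
    b = np.atleast_2d(np.asarray(pairs_b, dtype=float))
    if a.shape != b.shape:
        raise ValueError("conditions must have equal numbers of paired traces")
    if a.shape[0] < 3:
        raise ValueError("need at least 3 pairs")
    t, p, ok = _paired_t(a - b)
    if not ok.all():
        warnings.warn(f"{int((~ok).sum())} sample(s) with zero difference variance; p set to 1")
    return t, p


def find_clusters(
    t: np.ndarray, p: np.ndarray, cluster_alpha: float = CLUSTER_ALPHA
) -> list[Cluster]:
    """Maximal runs of consecutive samples with p < alpha and common t-sign.

    Runs of mixed sign are split at sign changes. Returned in temporal order.
    """
    t = np.asarray(t, dtype=float)
    p = np.asarray(p, dtype=float)
    clusters: list[Cluster] = []
    for sign in (1, -1):
        mask = (p < cluster_alpha) & (np.sign(t) == sign)
        idx = np.flatnonzero(mask)
        if idx.size == 0:
            continue
        breaks = np.flatnonzero(np.diff(idx) > 1)
        starts = np.r_[idx[0], idx[breaks + 1]]
        ends = np.r_[idx[breaks] + 1, idx[-1] + 1]
        for s, e in zip(starts, ends):
            clusters.append(Cluster(int(s), int(e), float(t[s:e].sum()), sign))
    clusters.sort(key=lambda c: c.start)
    return clusters


def _extreme_cluster_sums(t_rows: np.ndarray, t_crit: float) -> tuple[np.ndarray, np.ndarray]:
    """Per row: max positive and min negative supra-threshold cluster t-sum."""
    n_rows = t_rows.shape[0]
    pos = np.zeros(n_rows)
    neg = np.zeros(n_rows)
    for sign, out in ((1, pos), (-1, neg)):
        mask = sign * t_rows > t_crit
        for r in range(n_rows):
            idx = np.flatnonzero(mask[r])
            if idx.size == 0:
                continue
            breaks = np.flatnonzero(np.diff(idx) > 1)
            starts = np.r_[idx[0], idx[breaks + 1]]
            ends = np.r_[idx[breaks] + 1, idx[-1] + 1]
            ind = np.empty(2 * len(starts), dtype=np.int64)
            ind[0::2] = starts
            ind[1::2] = ends
            if ind[-1] == t_rows.shape[1]:  # reduceat indices must be < length
                ind = ind[:-1]
            sums = np.add.reduceat(t_rows[r], ind)[::2]
            out[r] = sums.max() if sign == 1 else sums.min()
    return pos, neg


def _perm_t(diffs: np.ndarray, signs: np.ndarray) -> np.ndarray:
    """t traces for sign-flipped difference sets; signs is (n_perm, n_pairs)."""
    n = diffs.shape[0]
    mean = signs @ diffs / n
    e2 = (diffs**2).mean(axis=0)  # invariant under sign flips
    var = (e2[None, :] - mean**2) * (n / (n - 1))
    var = np.maximum(var, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / np.sqrt(var / n)
    t[~np.isfinite(t)] = 0.0
    return t


def build_null(
    diffs: np.ndarray,
    cluster_alpha: float,
    n_perm: int,
    seed=None,
) -> PermutationNull:
    """Permutation null of extreme cluster sums via per-pair sign flips.

    When ``n_perm`` is at least the number of distinct sign assignments
    (2^n_pairs), the null is computed by exhaustive enumeration instead,
    with a warning.
    """
    n = diffs.shape[0]
    t_crit = stats.t.ppf(1 - cluster_alpha / 2.0, df=n - 1)
    exact = n <= 62 and n_perm >= 2**n
    if exact:
        warnings.warn(
            f"n_perm={n_perm} >= 2^{n} distinct sign assignments; using exact enumeration"
        )
        bits = np.arange(2**n)[:, None] >> np.arange(n)[None, :]
        signs = np.where(bits & 1, -1.0, 1.0)
    else:
        rng = np.random.default_rng(seed)
        signs = rng.choice([-1.0, 1.0], size=(n_perm, n))
    t_rows = _perm_t(diffs, signs)
    pos, neg = _extreme_cluster_sums(t_rows, t_crit)
    return PermutationNull(pos=pos, neg=neg, n_perm=len(signs), exact=exact, seed=seed)


def cluster_permutation_test(
    pairs_a: np.ndarray,
    pairs_b: np.ndarray,
    cluster_alpha: float = CLUSTER_ALPHA,
    n_perm: int = N_PERMUTATIONS,
    seed=None,
    times_ms: np.ndarray | None = None,
    percentile: float = PERCENTILE,
) -> tuple[list[ClusterResult], PermutationNull]:
    """Score observed clusters against the sign-flip permutation null.

    Returns the scored clusters (temporal order) and the null. If
    ``times_ms`` is given, cluster extents are also reported in ms
    (half-open; ``end_ms`` is the time of the first sample after the
    cluster's last member).
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    a = np.atleast_2d(np.asarray(pairs_a, dtype=float))
    b = np.atleast_2d(np.asarray(pairs_b, dtype=float))
    t, p = samplewise_t(a, b)
    observed = find_clusters(t, p, cluster_alpha)
    null = build_null(a - b, cluster_alpha, n_perm, seed)
    hi = np.percentile(null.pos, percentile)
    lo = np.percentile(null.neg, 100.0 - percentile)
    results: list[ClusterResult] = []
    for c in observed:
        if c.sign > 0:
            thr = hi
            sig = c.t_sum > hi
            p_mc = (1 + int(np.sum(null.pos >= c.t_sum))) / (1 + null.n_perm)
        else:
            thr = lo
            sig = c.t_sum < lo
            p_mc = (1 + int(np.sum(null.neg <= c.t_sum))) / (1 + null.n_perm)
        res = ClusterResult(
            start=c.start,
            end=c.end,
            t_sum=c.t_sum,
            sign=c.sign,
            p_mc=float(p_mc),
            threshold=float(thr),
            significant=bool(sig),
        )
        if times_ms is not None:
            step = times_ms[1] - times_ms[0] if len(times_ms) > 1 else 0.0
            res.start_ms = float(times_ms[c.start])
            res.end_ms = float(times_ms[c.end - 1] + step)
        results.append(res)
    return results, null
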