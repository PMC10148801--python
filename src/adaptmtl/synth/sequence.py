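"""Constrained pseudorandom trial sequences for the priming paradigm.

A session consists of ``n_runs`` runs. Within a run every stimulus appears
exactly once as a target, preceded by the previous target in the sequence
(or, for the first target, by one extra leading image that is itself
discarded from analysis). A target is *primed* when its prime belongs to
the same semantic category and *control* otherwise. Across the session each
stimulus must be primed in exactly half of the runs and in the control
condition in the other half.

The generator is constructive: for each run it groups the stimuli of each
category into consecutive same-category blocks. The first item of a block
follows a different category (control) and every later item follows a
same-category item (primed), so a stimulus assigned ``k`` control
presentations in a run contributes ``k`` block leaders. Blocks are then
arranged with no two same-category blocks adjacent, which is done by
shuffle-and-repair with a bounded number of attempts.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .stimuli import ConfigurationError, StimulusSet

PRIMED = "primed"
CONTROL = "control"
DISCARDED_FIRST = "discarded_first"

TRIAL_COLUMNS = [
    "session",
    "run",
    "position",
    "stimulus",
    "category",
    "meta",
    "condition",
    "prime",
    "rt",
    "correct",
]


class SequenceError(RuntimeError):
    """Constraint satisfaction failed within the allowed number of attempts."""


def _assign_conditions(
    sset: StimulusSet, n_runs: int, rng: np.random.Generator, max_attempts: int
) -> np.ndarray:
    """0/1 matrix (stimulus x run), 1 = primed; each row sums to n_runs/2.

    Feasibility per run requires at least one control presentation per
    category (a same-category block needs a leader), i.e. the number of
    primed-assigned exemplars of a category in one run must stay below the
    category size.
    """
    n_stim = sset.n_stimuli
    n_primed = n_runs // 2
    n_exemplars = sset.n_stimuli // sset.n_categories
    for _ in range(max_attempts):
        mat = np.zeros((n_stim, n_runs), dtype=np.int8)
        for s in range(n_stim):
            mat[s, rng.choice(n_runs, size=n_primed, replace=False)] = 1
        per_cat_run = np.add.reduceat(
            mat, np.arange(0, n_stim, n_exemplars), axis=0
        )
        if per_cat_run.max() < n_exemplars:
            return mat
    raise SequenceError("could not find a feasible primed/control assignment")


def _n_conflicts(cats: np.ndarray) -> int:
    return int(np.sum(cats[:-1] == cats[1:]))


def _arrange_blocks(
    blocks: list[tuple[int, list[int]]], rng: np.random.Generator, max_attempts: int
) -> list[tuple[int, list[int]]]:
    """Order blocks so no two adjacent blocks share a category.

    Shuffle, then local search: repeatedly swap a block at a conflicting
    position with a random other block, keeping swaps that do not increase
    the number of same-category adjacencies. Restart on stagnation.
    """
    n = len(blocks)
    if n == 1:
        return list(blocks)
    for _ in range(max_attempts):
        order = rng.permutation(n)
        cats = np.array([blocks[i][0] for i in order])
        best = _n_conflicts(cats)
        stale = 0
        while best > 0 and stale < 50 * n:
            i = int(np.flatnonzero(cats[:-1] == cats[1:])[0]) + 1
            j = int(rng.integers(n))
            if j == i:
                stale += 1
                continue
            cats[i], cats[j] = cats[j], cats[i]
            new = _n_conflicts(cats)
            if new <= best:
                stale = stale + 1 if new == best else 0
                best = new
                order[i], order[j] = order[j], order[i]
            else:
                cats[i], cats[j] = cats[j], cats[i]
                stale += 1
        if best == 0:
            return [blocks[i] for i in order]
    raise SequenceError("could not arrange category blocks without adjacency")


def _build_run(
    sset: StimulusSet,
    primed_this_run: np.ndarray,
    rng: np.random.Generator,
    max_attempts: int,
) -> tuple[int, list[int]]:
    """Return (leading stimulus, ordered target list) for one run."""
    blocks: list[tuple[int, list[int]]] = []
    for c in range(sset.n_categories):
        items = sset.exemplars(c)
        primed_items = [int(s) for s in items if primed_this_run[s]]
        control_items = [int(s) for s in items if not primed_this_run[s]]
        rng.shuffle(primed_items)
        rng.shuffle(control_items)
        cat_blocks: list[list[int]] = [[leader] for leader in control_items]
        for s in primed_items:
            cat_blocks[int(rng.integers(len(cat_blocks)))].append(s)
        blocks.extend((c, b) for b in cat_blocks)
    arranged = _arrange_blocks(blocks, rng, max_attempts)
    targets = [s for _, block in arranged for s in block]
    first_cat = arranged[0][0]
    other = np.flatnonzero(sset.category_of != first_cat)
    lead = int(rng.choice(other))
    return lead, targets


def generate_trial_sequence(
    sset: StimulusSet,
    n_runs: int = 10,
    seed: int | None = None,
    session: str = "S01",
    max_attempts: int = 200,
) -> pd.DataFrame:
    """Generate one session's trial table.

    Returns a DataFrame with one row per presentation: ``n_runs`` leading
    ``discarded_first`` rows (position 0) plus ``n_runs * n_stimuli`` target
    rows. RT and correctness columns are NaN until behavior is simulated.
    Raises :class:`SequenceError` if the constraints cannot be satisfied
    within ``max_attempts`` (no silent relaxation).
    """
    if n_runs < 2 or n_runs % 2 != 0:
        raise ConfigurationError("n_runs must be even and >= 2")
    sset.validate()
    rng = np.random.default_rng(seed)
    assignment = _assign_conditions(sset, n_runs, rng, max_attempts)

    rows = []
    for r in range(n_runs):
        lead, targets = _build_run(sset, assignment[:, r], rng, max_attempts)
        rows.append((r + 1, 0, lead, DISCARDED_FIRST, -1))
        prev = lead
        for pos, s in enumerate(targets, start=1):
            cond = PRIMED if sset.category_of[prev] == sset.category_of[s] else CONTROL
            rows.append((r + 1, pos, s, cond, prev))
            prev = s

    run, position, stimulus, condition, prime = map(np.asarray, zip(*rows))
    df = pd.DataFrame(
        {
            "session": session,
            "run": run,
            "position": position,
            "stimulus": stimulus,
            "category": sset.category_of[stimulus],
            "meta": [sset.meta_of_stimulus(s) for s in stimulus],
            "condition": condition,
            "prime": prime,
            "rt": np.nan,
            "correct": pd.array([None] * len(run), dtype="boolean"),
        }
    )[TRIAL_COLUMNS]

    ok, problems = check_trial_table(df, sset)
    if not ok:  # pragma: no cover - generator is constructive
        raise SequenceError("generated table violates constraints: " + "; ".join(problems))
    return df


def check_trial_table(trials: pd.DataFrame, sset: StimulusSet) -> tuple[bool, list[str]]:
    """Validate a trial table against the paradigm's invariants.

    Checks, per run: one leading discarded presentation; every stimulus
    exactly once as target; the prime column equals the preceding
    presentation; no self-priming; condition consistent with prime/target
    category match. Per stimulus: exactly ``n_runs/2`` primed and
    ``n_runs/2`` control presentations.
    """
    problems: list[str] = []
    n_runs = trials["run"].nunique()
    for r, g in trials.groupby("run"):
        g = g.sort_values("position")
        lead = g[g["condition"] == DISCARDED_FIRST]
        if len(lead) != 1 or lead["position"].iloc[0] != 0:
            problems.append(f"run {r}: expected exactly one leading discarded presentation")
            continue
        targets = g[g["position"] > 0]
        counts = targets["stimulus"].value_counts()
        if len(counts) != sset.n_stimuli or counts.max() != 1:
            problems.append(f"run {r}: targets are not a permutation of the stimulus set")
        seq = g["stimulus"].to_numpy()
        primes = targets["prime"].to_numpy()
        if not np.array_equal(primes, seq[:-1]):
            problems.append(f"run {r}: prime column does not match preceding presentation")
        tgt = targets["stimulus"].to_numpy()
        if np.any(primes == tgt):
            problems.append(f"run {r}: self-priming (prime == target)")
        same_cat = sset.category_of[primes] == sset.category_of[tgt]
        cond = targets["condition"].to_numpy()
        if not np.array_equal(np.where(same_cat, PRIMED, CONTROL), cond):
            problems.append(f"run {r}: condition label inconsistent with prime category")
    targets = trials[trials["condition"] != DISCARDED_FIRST]
    tab = targets.pivot_table(
        index="stimulus", columns="condition", values="run", aggfunc="count", fill_value=0
    ).reindex(np.arange(sset.n_stimuli), fill_value=0)
    for cond in (PRIMED, CONTROL):
        if cond not in tab:
            tab[cond] = 0
        bad = tab.index[tab[cond] != n_runs // 2]
        if len(bad):
            problems.append(
                f"{len(bad)} stimuli do not have {n_runs // 2} {cond} presentations"
            )
    return (not problems), problems
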