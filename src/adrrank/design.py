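"""Comparison-task construction.

A task is the unit of work shown to one worker: 10 ADR pairs, of which exactly
3 are quality-control (gold) pairs with a known expected answer and 7 are
informative random pairs.  QC pairs are built as the full cross product of a
hand-picked severe set and a mild set, so the expected answer is always the
severe member.  Informative pairs avoid both trivially easy comparisons (huge
severity gap) and near-ties (gap too small to judge), using a crude ranking as
the yardstick.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .errors import ConfigError

logger = logging.getLogger(__name__)

QC_PER_TASK = 3
RANDOM_PER_TASK = 7


@dataclass(frozen=True)
class TaskPair:
    adr_a: str
    adr_b: str
    is_qc: bool
    qc_expected: str | None = None  # "a" or "b" for QC pairs

    def key(self) -> tuple[str, str]:
        return (self.adr_a, self.adr_b) if self.adr_a <= self.adr_b else (self.adr_b, self.adr_a)


@dataclass
class Task:
    task_id: str
    pairs: list[TaskPair]

    def __post_init__(self):
        n_qc = sum(p.is_qc for p in self.pairs)
        if len(self.pairs) != QC_PER_TASK + RANDOM_PER_TASK or n_qc != QC_PER_TASK:
            raise ConfigError(
                f"task {self.task_id}: needs {QC_PER_TASK} QC + {RANDOM_PER_TASK} random pairs"
            )
        keys = [p.key() for p in self.pairs]
        if len(set(keys)) != len(keys):
            raise ConfigError(f"task {self.task_id}: repeated pair within task")


def build_qc_pairs(severe_set: Sequence[str], mild_set: Sequence[str]) -> list[tuple[str, str]]:
    """All (severe, mild) combinations; the severe member is the expected answer."""
    severe, mild = list(dict.fromkeys(severe_set)), list(dict.fromkeys(mild_set))
    if not severe or not mild:
        raise ConfigError("QC severe and mild sets must be non-empty")
    overlap = set(severe) & set(mild)
    if overlap:
        raise ConfigError(f"QC sets overlap: {sorted(overlap)}")
    return [(s, m) for s in severe for m in mild]


def crude_scores(comparisons: pd.DataFrame) -> dict[str, float]:
    """Borda-style crude severity: each ADR's fraction of won comparisons.

    Suitable as the yardstick for informative-pair sampling once a first batch
    of comparisons exists.
    """
    wins: dict[str, int] = {}
    seen: dict[str, int] = {}
    for adr_a, adr_b, chosen in zip(
        comparisons["adr_a"], comparisons["adr_b"], comparisons["chosen"]
    ):
        winner = adr_a if chosen == "a" else adr_b
        seen[adr_a] = seen.get(adr_a, 0) + 1
        seen[adr_b] = seen.get(adr_b, 0) + 1
        wins[winner] = wins.get(winner, 0) + 1
    return {t: wins.get(t, 0) / seen[t] for t in seen}


def sample_informative_pairs(
    adrs: Sequence[str],
    crude_scores: Mapping[str, float],
    n: int,
    min_gap_frac: float = 0.05,
    max_gap_frac: float = 0.60,
    rng: np.random.Generator | int | None = None,
) -> list[tuple[str, str]]:
    """Sample unordered ADR pairs whose crude-rank gap is informative.

    The gap is measured as |rank_i - rank_j| / N under the crude ranking; pairs
    below ``min_gap_frac`` are near-ties (frustrating to judge) and pairs above
    ``max_gap_frac`` are trivially easy, so both are excluded.  If fewer than
    ``n`` pairs are eligible, all of them are returned with a warning.
    """
    adrs = list(adrs)
    missing = [t for t in adrs if t not in crude_scores]
    if missing:
        raise ConfigError(f"crude_scores missing terms: {missing[:5]}")
    if not (0 <= min_gap_frac < max_gap_frac <= 1):
        raise ConfigError("need 0 <= min_gap_frac < max_gap_frac <= 1")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    n_adrs = len(adrs)
    ranks = rankdata([-crude_scores[t] for t in adrs], method="average")
    eligible: list[tuple[str, str]] = []
    for i in range(n_adrs):
        for j in range(i + 1, n_adrs):
            gap = abs(ranks[i] - ranks[j]) / n_adrs
            if min_gap_frac <= gap <= max_gap_frac:
                a, b = sorted((adrs[i], adrs[j]))
                eligible.append((a, b))
    if len(eligible) <= n:
        if len(eligible) < n:
            logger.warning(
                "only %d eligible pairs in gap window [%g, %g], requested %d",
                len(eligible), min_gap_frac, max_gap_frac, n,
            )
        return eligible
    idx = rng.choice(len(eligible), size=n, replace=False)
    return [eligible[i] for i in sorted(idx)]


def _randomize_sides(pair: tuple[str, str], is_qc: bool, rng: np.random.Generator) -> TaskPair:
    first, second = pair
    if rng.random() < 0.5:
        first, second = second, first
        expected = "b" if is_qc else None
    else:
        expected = "a" if is_qc else None
    return TaskPair(adr_a=first, adr_b=second, is_qc=is_qc, qc_expected=expected)


def assemble_tasks(
    qc_pool: Sequence[tuple[str, str]],
    candidate_pairs: Sequence[tuple[str, str]] | None = None,
    n_tasks: int = 1,
    rng: np.random.Generator | int | None = None,
    candidate_terms: Sequence[str] | None = None,
    replace: bool = False,
) -> list[Task]:
    """Assemble ``n_tasks`` tasks of 3 QC + 7 random pairs each.

    Random pairs come either from an explicit ``candidate_pairs`` list (drawn
    without replacement across tasks unless ``replace``, to maximize unique-pair
    coverage) or, if ``candidate_terms`` is given instead, as uniform random
    distinct-term pairs.  QC pairs are drawn without replacement within a task.
    Presentation side and order are randomized.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    qc_pool = list(qc_pool)
    if len(qc_pool) < QC_PER_TASK:
        raise ConfigError(f"QC pool must hold at least {QC_PER_TASK} pairs")
    if candidate_pairs is None and candidate_terms is None:
        raise ConfigError("provide candidate_pairs or candidate_terms")

    remaining: list[tuple[str, str]] | None = None
    if candidate_pairs is not None:
        remaining = list(candidate_pairs)
        if not replace and len(remaining) < RANDOM_PER_TASK * n_tasks:
            raise ConfigError(
                f"{len(remaining)} candidate pairs cannot fill {n_tasks} tasks "
                f"without replacement"
            )
        order = rng.permutation(len(remaining))
        remaining = [remaining[i] for i in order]

    tasks: list[Task] = []
    for t in range(n_tasks):
        qc_idx = rng.choice(len(qc_pool), size=QC_PER_TASK, replace=False)
        pairs = [_randomize_sides(qc_pool[i], True, rng) for i in qc_idx]
        used = {p.key() for p in pairs}
        if remaining is not None:
            if replace:
                attempts = 0
                while len(pairs) < QC_PER_TASK + RANDOM_PER_TASK:
                    attempts += 1
                    if attempts > 100 * RANDOM_PER_TASK:
                        raise ConfigError("candidate pool too collision-prone for task assembly")
                    pair = remaining[int(rng.integers(len(remaining)))]
                    tp = _randomize_sides(pair, False, rng)
                    if tp.key() not in used:
                        used.add(tp.key())
                        pairs.append(tp)
            else:
                put_back: list[tuple[str, str]] = []
                while len(pairs) < QC_PER_TASK + RANDOM_PER_TASK and remaining:
                    pair = remaining.pop(0)
                    tp = _randomize_sides(pair, False, rng)
                    if tp.key() in used:  # collides with a QC pair of this task; save for later tasks
                        put_back.append(pair)
                        continue
                    used.add(tp.key())
                    pairs.append(tp)
                remaining = put_back + remaining
                if len(pairs) < QC_PER_TASK + RANDOM_PER_TASK:
                    raise ConfigError("ran out of candidate pairs while assembling tasks")
        else:
            terms = list(candidate_terms)  # type: ignore[arg-type]
            while len(pairs) < QC_PER_TASK + RANDOM_PER_TASK:
                i, j = rng.choice(len(terms), size=2, replace=False)
                tp = _randomize_sides((terms[i], terms[j]), False, rng)
                if tp.key() not in used:
                    used.add(tp.key())
                    pairs.append(tp)
        order = rng.permutation(len(pairs))
        tasks.append(Task(task_id=f"task{t + 1:05d}", pairs=[pairs[i] for i in order]))
    return tasks


def tasks_to_frame(tasks: Sequence[Task]) -> pd.DataFrame:
    """Flatten tasks to a frame (task_id, position, adr_a, adr_b, is_qc, qc_expected)."""
    rows = []
    for task in tasks:
        for pos, p in enumerate(task.pairs, start=1):
            rows.append(
                {
                    "task_id": task.task_id,
                    "position": pos,
                    "adr_a": p.adr_a,
                    "adr_b": p.adr_b,
                    "is_qc": p.is_qc,
                    "qc_expected": p.qc_expected,
                }
            )
    return pd.DataFrame(rows)
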