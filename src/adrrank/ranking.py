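"""Global severity ranking from pairwise votes via linear programming.

The core model assigns every ADR a real-valued score s_i and, for each pair
with a vote majority (winner w, loser l, weight = majority margin), requires

    s_w - s_l + e >= delta,    e >= 0,

minimizing the weighted slack sum  sum_p weight_p * e_p.  Real-valued scores
make the resulting order transitive by construction (the triangular
inequality cannot be violated by a total order), and the slack objective
retains as much of the workers' pairwise preferences as possible: the optimal
objective is the weighted mass of majorities the final order must overrule.

The LP relaxation alone does not always turn its (often degenerate) score
vertex into a minimum-violation order, so the induced order is polished by a
deterministic single-item insertion descent against the weighted majorities —
a standard feedback-arc-set local search that can only reduce the weighted
disagreement.  Scores are then made monotone along the final order by an
antitonic (pool-adjacent-violators) projection so that score order and rank
order always agree.

Large ADR sets are ranked by sample-and-merge: terms are sorted by crude
(win-fraction) severity, overlapping contiguous blocks of that ordering —
each joined by anchor terms spread across the whole crude range — are solved
as separate LPs, every sample's scores are affinely calibrated onto the crude
consensus scale by least squares over its members, and calibrated scores are
averaged per term.  Contiguous blocks keep each LP focused on hard
(near-rank) comparisons, the overlap and anchors stitch the blocks into one
scale, and the construction is deterministic.
"""

from __future__ import annotations

import logging
import math
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.optimize import linprog
from sklearn.base import BaseEstimator

from .errors import ConfigError, DataError
from .qc import build_vote_table

logger = logging.getLogger(__name__)


def to_percentiles(ranks: Iterable[int], n: int) -> np.ndarray:
    """Severity percentile from rank: 100*(N - rank + 1)/N, rank 1 -> 100."""
    ranks = np.asarray(list(ranks), dtype=float)
    return 100.0 * (n - ranks + 1.0) / n


def win_fractions(vote_table: pd.DataFrame) -> pd.Series:
    """Per-term fraction of won votes (crude Borda-style severity)."""
    wins: dict[str, float] = {}
    totals: dict[str, float] = {}
    for a, b, n_ab, n_ba in zip(
        vote_table["adr_a"], vote_table["adr_b"], vote_table["n_ab"], vote_table["n_ba"]
    ):
        wins[a] = wins.get(a, 0) + n_ab
        wins[b] = wins.get(b, 0) + n_ba
        totals[a] = totals.get(a, 0) + n_ab + n_ba
        totals[b] = totals.get(b, 0) + n_ab + n_ba
    return pd.Series({t: wins[t] / totals[t] if totals[t] else 0.5 for t in totals}).sort_index()


def _constraints(vote_table: pd.DataFrame, weight_scheme: str):
    """Yield (winner, loser, weight) LP constraints from the vote table."""
    if weight_scheme == "majority_margin":
        for a, b, n_ab, n_ba in zip(
            vote_table["adr_a"], vote_table["adr_b"], vote_table["n_ab"], vote_table["n_ba"]
        ):
            if n_ab > n_ba:
                yield a, b, float(n_ab - n_ba)
            elif n_ba > n_ab:
                yield b, a, float(n_ba - n_ab)
    elif weight_scheme == "per_vote":
        for a, b, n_ab, n_ba in zip(
            vote_table["adr_a"], vote_table["adr_b"], vote_table["n_ab"], vote_table["n_ba"]
        ):
            if n_ab > 0:
                yield a, b, float(n_ab)
            if n_ba > 0:
                yield b, a, float(n_ba)
    else:
        raise ConfigError(f"unknown weight_scheme {weight_scheme!r}")


def check_connected(vote_table: pd.DataFrame) -> list[set[str]]:
    """Connected components of the comparison graph, largest first."""
    graph = nx.Graph()
    graph.add_nodes_from(vote_table["adr_a"])
    graph.add_nodes_from(vote_table["adr_b"])
    graph.add_edges_from(zip(vote_table["adr_a"], vote_table["adr_b"]))
    return sorted(nx.connected_components(graph), key=len, reverse=True)


def solve_lp(
    vote_table: pd.DataFrame,
    margin: float = 1.0,
    weight_scheme: str = "majority_margin",
    allow_disconnected: bool = False,
) -> tuple[pd.Series, float]:
    """Solve the margin-slack LP; return (scores normalized to [0, 1], objective).

    The objective is the weighted slack sum only.  A vanishingly small penalty
    on the raw (non-negative) scores is added to pick the canonical minimal
    solution out of the LP's flat optimum deterministically; it is orders of
    magnitude below the smallest constraint weight and cannot trade against
    slack.  Tied pairs contribute no constraint.
    """
    if margin <= 0:
        raise ConfigError("margin must be positive")
    if vote_table.empty:
        raise DataError("vote table is empty")
    components = check_connected(vote_table)
    if len(components) > 1:
        msg = f"comparison graph has {len(components)} components"
        if not allow_disconnected:
            raise DataError(msg + "; pass allow_disconnected=True to rank anyway")
        logger.warning("%s; components are mutually incomparable", msg)

    terms = sorted(set(vote_table["adr_a"]) | set(vote_table["adr_b"]))
    index = {t: i for i, t in enumerate(terms)}
    cons = list(_constraints(vote_table, weight_scheme))
    n, m = len(terms), len(cons)
    if n < 2:
        raise DataError("need at least 2 ADRs")
    if m == 0:  # all pairs tied: no preference signal at all
        return pd.Series(0.5, index=pd.Index(terms)), 0.0

    weights = np.array([w for *_, w in cons])
    eps = 0.25 * weights.min() / max(1, n * n)
    c = np.concatenate([np.full(n, eps), weights])
    rows, cols, vals = [], [], []
    for k, (winner, loser, _) in enumerate(cons):
        rows += [k, k, k]
        cols += [index[winner], index[loser], n + k]
        vals += [-1.0, 1.0, -1.0]
    a_ub = sp.csr_matrix((vals, (rows, cols)), shape=(m, n + m))
    b_ub = np.full(m, -margin)
    res = linprog(c, A_ub=a_ub, b_ub=b_ub, bounds=(0, None), method="highs")
    if res.status != 0:
        raise DataError(f"LP solver failed: {res.message}")
    raw = res.x[:n]
    objective = float(weights @ res.x[n:])
    span = raw.max() - raw.min()
    scores = (raw - raw.min()) / span if span > 0 else np.full(n, 0.5)
    return pd.Series(scores, index=pd.Index(terms)), objective


def net_margins(vote_table: pd.DataFrame) -> dict[tuple[str, str], float]:
    """Signed majority margins m[(u, v)] = votes(u beats v) - votes(v beats u)."""
    net: dict[tuple[str, str], float] = {}
    for a, b, n_ab, n_ba in zip(
        vote_table["adr_a"], vote_table["adr_b"], vote_table["n_ab"], vote_table["n_ba"]
    ):
        net[(a, b)] = float(n_ab - n_ba)
        net[(b, a)] = float(n_ba - n_ab)
    return net


def weighted_disagreement(order: Sequence[str], net: Mapping[tuple[str, str], float]) -> float:
    """Total majority mass the given order (most severe first) overrules."""
    pos = {t: i for i, t in enumerate(order)}
    total = 0.0
    for (u, v), margin in net.items():
        if margin > 0 and pos.get(u, 0) > pos.get(v, 0):
            total += margin
    return total


def refine_order(
    order: Sequence[str],
    net: Mapping[tuple[str, str], float],
    max_sweeps: int = 50,
) -> list[str]:
    """Single-item insertion descent on the weighted-disagreement objective.

    Deterministic: items are scanned in order and each is moved to the position
    that most reduces the disagreement (first such position on ties).  Each
    applied move strictly decreases the objective, so the descent terminates.
    """
    order = list(order)
    n = len(order)
    for _ in range(max_sweeps):
        improved = False
        for i in range(n):
            x = order[i]
            best_delta, best_pos = -1e-12, None
            delta = 0.0  # move left: crossing y changes disagreement by -m(x, y)
            for j in range(i - 1, -1, -1):
                delta -= net.get((x, order[j]), 0.0)
                if delta < best_delta:
                    best_delta, best_pos = delta, j
            delta = 0.0  # move right: crossing y changes disagreement by +m(x, y)
            for j in range(i + 1, n):
                delta += net.get((x, order[j]), 0.0)
                if delta < best_delta:
                    best_delta, best_pos = delta, j
            if best_pos is not None:
                order.pop(i)
                order.insert(best_pos, x)
                improved = True
        if not improved:
            break
    return order


def _antitonic(values: np.ndarray) -> np.ndarray:
    """Pool-adjacent-violators projection onto non-increasing sequences."""
    blocks = [[v, 1] for v in values]  # [mean, count]
    merged: list[list[float]] = []
    for blk in blocks:
        merged.append(blk)
        while len(merged) > 1 and merged[-2][0] < merged[-1][0] - 1e-15:
            m2, m1 = merged.pop(), merged.pop()
            total = m1[0] * m1[1] + m2[0] * m2[1]
            count = m1[1] + m2[1]
            merged.append([total / count, count])
    out = []
    for mean, count in merged:
        out.extend([mean] * int(count))
    return np.asarray(out)


class LPSeverityRanker(BaseEstimator):
    """Severity ranking estimator over pairwise comparisons.

    ``fit`` accepts either a raw comparison frame (columns adr_a, adr_b,
    chosen, ...) or a pre-built vote table (columns n_ab, n_ba, ...), solves
    the margin-slack LP (sample-and-merge above ``sample_size`` ADRs), and
    exposes the result as fitted attributes.

    Parameters
    ----------
    margin : float, default 1.0
        Required score separation delta for each majority constraint.
    weight_scheme : {"majority_margin", "per_vote"}, default "majority_margin"
        One constraint per pair weighted by the majority margin, or one per
        vote direction weighted by its count.
    sample_size : int, default 500
        Largest ADR set solved as a single LP; beyond it, sample-and-merge.
    n_anchors : int or None, default None
        Shared anchor terms per sample; None means min(25, ceil(0.1 * N)).
    refine : bool, default True
        Polish the induced order with the insertion-descent local search.
    allow_disconnected : bool, default False
        Rank a disconnected comparison graph anyway (components are mutually
        incomparable and are flagged in ``components_``).
    random_state : int, default 0
        Reserved for stochastic merge variants; the default fit is
        deterministic end to end.

    Attributes
    ----------
    ranking_ : DataFrame with columns term, score, rank, percentile
        rank 1 = most severe; percentile 100 = most severe.
    scores_ : Series indexed by term, normalized to [0, 1].
    objective_ : float; weighted slack sum (single-LP fits only, else NaN).
    vote_table_ : the aggregated vote table used.
    """

    def __init__(
        self,
        margin: float = 1.0,
        weight_scheme: str = "majority_margin",
        sample_size: int = 500,
        n_anchors: int | None = None,
        refine: bool = True,
        allow_disconnected: bool = False,
        random_state: int = 0,
    ):
        self.margin = margin
        self.weight_scheme = weight_scheme
        self.sample_size = sample_size
        self.n_anchors = n_anchors
        self.refine = refine
        self.allow_disconnected = allow_disconnected
        self.random_state = random_state

    # -- fitting ---------------------------------------------------------

    def fit(self, X: pd.DataFrame, y=None):
        vote_table = X if "n_ab" in getattr(X, "columns", ()) else build_vote_table(X)
        if vote_table.empty:
            raise DataError("no comparisons to rank")
        self.vote_table_ = vote_table
        self.components_ = check_connected(vote_table)
        terms = sorted(set(vote_table["adr_a"]) | set(vote_table["adr_b"]))
        n = len(terms)
        crude = win_fractions(vote_table)

        if n <= self.sample_size:
            scores, objective = solve_lp(
                vote_table,
                margin=self.margin,
                weight_scheme=self.weight_scheme,
                allow_disconnected=self.allow_disconnected,
            )
            self.objective_ = objective
            self.is_merged_ = False
        else:
            scores = self._sample_and_merge(vote_table, terms, crude)
            self.objective_ = float("nan")
            self.is_merged_ = True

        net = net_margins(vote_table)
        order = sorted(terms, key=lambda t: (-scores[t], -crude[t], t))
        if self.refine:
            order = refine_order(order, net)
        ordered_scores = _antitonic(np.array([scores[t] for t in order]))
        span = ordered_scores.max() - ordered_scores.min()
        if span > 0:
            ordered_scores = (ordered_scores - ordered_scores.min()) / span
        else:
            ordered_scores = np.full(n, 0.5)
        ranking = pd.DataFrame(
            {
                "term": order,
                "score": ordered_scores,
                "rank": np.arange(1, n + 1),
                "percentile": to_percentiles(np.arange(1, n + 1), n),
            }
        )
        self.terms_ = terms
        self.scores_ = ranking.set_index("term")["score"]
        self.ranking_ = ranking
        self.n_features_in_ = n
        return self

    def fit_predict(self, X: pd.DataFrame, y=None) -> pd.DataFrame:
        return self.fit(X).ranking_

    def _default_anchor_count(self, n: int) -> int:
        rule = self.n_anchors if self.n_anchors is not None else min(25, math.ceil(0.1 * n))
        return max(2, min(rule, n))

    def _sample_and_merge(self, vote_table, terms, crude) -> pd.Series:
        n = len(terms)
        n_anchors = self._default_anchor_count(n)
        if self.sample_size <= n_anchors:
            raise ConfigError("sample_size must exceed the anchor count")
        by_crude = sorted(terms, key=lambda t: (-crude[t], t))
        anchor_idx = np.unique(np.linspace(0, n - 1, n_anchors).round().astype(int))
        anchors = [by_crude[i] for i in anchor_idx]
        anchor_set = set(anchors)
        others = [t for t in by_crude if t not in anchor_set]
        chunk = self.sample_size - len(anchors)
        stride = max(1, chunk // 2)  # 50% overlap between consecutive blocks

        starts = list(range(0, max(len(others) - chunk, 0) + 1, stride))
        if not starts or starts[-1] + chunk < len(others):
            starts.append(max(0, len(others) - chunk))
        sums = {t: [] for t in terms}
        for start in dict.fromkeys(starts):
            sample = anchors + others[start : start + chunk]
            in_sample = set(sample)
            mask = vote_table["adr_a"].isin(in_sample) & vote_table["adr_b"].isin(in_sample)
            sub = vote_table[mask]
            if sub.empty:
                logger.warning("sample with no internal votes; skipped")
                continue
            sub_scores, _ = solve_lp(
                sub,
                margin=self.margin,
                weight_scheme=self.weight_scheme,
                allow_disconnected=True,
            )
            present = [a for a in anchors if a in sub_scores.index]
            if len(present) < 2:
                logger.warning("sample shares <2 anchors with the consensus; skipped")
                continue
            x = sub_scores[present].to_numpy()
            y = crude[present].to_numpy()
            slope, intercept = _affine_fit(x, y)
            for t in sub_scores.index:
                sums[t].append(slope * sub_scores[t] + intercept)
        merged = pd.Series(
            {t: float(np.mean(v)) if v else float(crude[t]) for t, v in sums.items()}
        )
        span = merged.max() - merged.min()
        return (merged - merged.min()) / span if span > 0 else merged * 0 + 0.5


def _affine_fit(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Least-squares y ~ a*x + b with a positivity guard on the slope."""
    var = np.var(x)
    if var <= 0:
        return 0.0, float(np.mean(y))
    slope = float(np.cov(x, y, bias=True)[0, 1] / var)
    if slope <= 0:
        slope = 1e-9
    intercept = float(np.mean(y) - slope * np.mean(x))
    return slope, intercept


def rank_global(X: pd.DataFrame, **params) -> pd.DataFrame:
    """Functional wrapper: fit an :class:`LPSeverityRanker` and return its ranking."""
    return LPSeverityRanker(**params).fit(X).ranking_
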