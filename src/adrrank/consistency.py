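"""Internal consistency and reproducibility of crowdsourced severity judgments.

Three complementary views:

* triangle violations — a triplet of ADRs whose three pairwise majorities form
  a cycle contradicts transitivity of severity; the violation rate over all
  evaluable triplets measures how self-consistent the crowd is.  Under
  completely random majorities the expected rate is 0.25 (2 cyclic of the 8
  orientations of a 3-tournament).
* reproducibility — rank correlation between rankings computed independently
  from duplicate batches of the same comparisons answered by fresh workers.
* rank-variability classes — ADRs binned by mean rank; a one-way ANOVA of the
  per-ADR rank standard deviation (across batches) over the bins asks whether
  rank stability genuinely differs across the severity scale.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigError, DataError
from .qc import build_vote_table
from .ranking import LPSeverityRanker

logger = logging.getLogger(__name__)


@dataclass
class TriangleStats:
    rate: float
    n_violated: int
    n_evaluated: int
    n_excluded_ties: int


def triangle_violation_rate(
    vote_table: pd.DataFrame,
    max_triplets: int | None = None,
    rng: np.random.Generator | int | None = None,
) -> TriangleStats:
    """Fraction of evaluable ADR triplets whose majorities form a cycle.

    A triplet is evaluable when all three of its pairs appear in the vote
    table with a strict majority; triplets touching a tied pair are excluded
    (and counted).  ``max_triplets`` caps the evaluation by uniform
    subsampling of the enumerated triplets.
    """
    majority: dict[tuple[str, str], str] = {}
    tied: set[tuple[str, str]] = set()
    adj: dict[str, set[str]] = {}
    for a, b, maj in zip(vote_table["adr_a"], vote_table["adr_b"], vote_table["majority"]):
        adj.setdefault(a, set()).add(b)
        adj.setdefault(b, set()).add(a)
        if maj is None or (isinstance(maj, float) and np.isnan(maj)):
            tied.add((a, b))
        else:
            majority[(a, b)] = maj

    terms = sorted(adj)
    triplets: list[tuple[str, str, str]] = []
    n_excluded = 0
    for u in terms:
        for v in sorted(adj[u]):
            if v <= u:
                continue
            for w in sorted(adj[u] & adj[v]):
                if w <= v:
                    continue
                if (u, v) in tied or (u, w) in tied or (v, w) in tied:
                    n_excluded += 1
                    continue
                triplets.append((u, v, w))
    if not triplets:
        raise DataError("no evaluable triplets (all missing or tied)")
    if max_triplets is not None and len(triplets) > max_triplets:
        rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
        idx = rng.choice(len(triplets), size=max_triplets, replace=False)
        triplets = [triplets[i] for i in idx]

    n_violated = 0
    for u, v, w in triplets:
        wins = {u: 0, v: 0, w: 0}
        wins[majority[(u, v)]] += 1
        wins[majority[(u, w)]] += 1
        wins[majority[(v, w)]] += 1
        # a 3-tournament is cyclic iff every vertex wins exactly once
        if max(wins.values()) == 1:
            n_violated += 1
    return TriangleStats(
        rate=n_violated / len(triplets),
        n_violated=n_violated,
        n_evaluated=len(triplets),
        n_excluded_ties=n_excluded,
    )


def full_agreement_rate(
    comparisons: pd.DataFrame, min_distinct_workers: int = 3
) -> tuple[float, int]:
    """Fraction of unique pairs, judged by enough distinct workers, with unanimous votes."""
    table = build_vote_table(comparisons)
    qualifying = table[table["n_workers"] >= min_distinct_workers]
    if qualifying.empty:
        raise DataError(f"no pairs with >= {min_distinct_workers} distinct workers")
    unanimous = (qualifying["n_ab"] == 0) | (qualifying["n_ba"] == 0)
    return float(unanimous.mean()), int(len(qualifying))


def split_batches(comparisons: pd.DataFrame) -> list[pd.DataFrame]:
    """Split a comparison frame into per-batch frames by batch_id."""
    return [grp.reset_index(drop=True) for _, grp in comparisons.groupby("batch_id", sort=True)]


@dataclass
class ReproducibilityResult:
    correlations: list[float]
    mean: float
    sd: float
    rankings: list[pd.DataFrame] = field(repr=False, default_factory=list)

    @property
    def rank_frame(self) -> pd.DataFrame:
        """Per-ADR ranks, one column per batch (common ADRs only)."""
        cols = {
            f"batch{i + 1}": r.set_index("term")["rank"] for i, r in enumerate(self.rankings)
        }
        return pd.DataFrame(cols)


def rank_reproducibility(
    batches: Sequence[pd.DataFrame], **ranker_params
) -> ReproducibilityResult:
    """Rank each duplicate batch independently; report pairwise Spearman correlations.

    Batches are restricted to their common ADR set first (logged when that
    drops terms).
    """
    if len(batches) < 2:
        raise ConfigError("need at least 2 batches")
    term_sets = [set(b["adr_a"]) | set(b["adr_b"]) for b in batches]
    common = set.intersection(*term_sets)
    if len(common) < 2:
        raise DataError("fewer than 2 ADRs shared by all batches")
    dropped = max(len(s) for s in term_sets) - len(common)
    if dropped:
        logger.info("restricting batches to %d common ADRs", len(common))
    rankings = []
    for batch in batches:
        mask = batch["adr_a"].isin(common) & batch["adr_b"].isin(common)
        ranker = LPSeverityRanker(**ranker_params).fit(batch[mask])
        rankings.append(ranker.ranking_)
    corrs = []
    for r1, r2 in combinations(rankings, 2):
        joined = r1.set_index("term")["rank"].align(r2.set_index("term")["rank"], join="inner")
        rho = stats.spearmanr(joined[0], joined[1]).statistic
        corrs.append(float(rho))
    return ReproducibilityResult(
        correlations=corrs,
        mean=float(np.mean(corrs)),
        sd=float(np.std(corrs)),
        rankings=rankings,
    )


@dataclass
class VariabilityResult:
    rank_sd: pd.Series
    chosen_k: int | None
    classes: pd.Series | None
    statistic: float | None
    p_value: float | None
    scan: pd.DataFrame


def variability_classes(
    per_batch_ranks: pd.DataFrame,
    k_range: Sequence[int] = range(2, 11),
    alpha: float = 0.001,
) -> VariabilityResult:
    """Scan for the largest number of rank-stability classes supported by ANOVA.

    ``per_batch_ranks`` holds one rank column per duplicate batch (rows =
    ADRs).  For each k, ADRs are binned into k equal-frequency classes by mean
    rank and a one-way ANOVA asks whether the per-ADR rank standard deviation
    (across batches) differs between classes; the largest k in range with
    p < ``alpha`` is reported.  When no k passes, there are no robust classes.
    """
    if per_batch_ranks.shape[1] < 2:
        raise ConfigError("need ranks from at least 2 batches")
    mean_rank = per_batch_ranks.mean(axis=1)
    rank_sd = per_batch_ranks.std(axis=1, ddof=1)
    n = len(per_batch_ranks)
    rows = []
    best = None
    for k in sorted(k_range):
        if n < 2 * k:
            logger.info("k=%d skipped: fewer than 2k ADRs", k)
            continue
        try:
            bins = pd.qcut(mean_rank.rank(method="first"), q=k, labels=False)
        except ValueError:
            continue
        groups = [rank_sd[bins == g].to_numpy() for g in range(k)]
        if any(len(g) < 2 for g in groups):
            continue
        with np.errstate(invalid="ignore", divide="ignore"):
            stat, p = stats.f_oneway(*groups)
        significant = bool(np.isfinite(p) and p < alpha)
        rows.append({"k": k, "statistic": float(stat), "p_value": float(p), "significant": significant})
        if significant:
            best = (k, bins, float(stat), float(p))
    scan = pd.DataFrame(rows, columns=["k", "statistic", "p_value", "significant"])
    if best is None:
        return VariabilityResult(rank_sd, None, None, None, None, scan)
    k, bins, stat, p = best
    return VariabilityResult(rank_sd, k, bins, stat, p, scan)


@dataclass
class ConsistencyReport:
    triangles: TriangleStats
    reproducibility: ReproducibilityResult
    agreement_rate: float
    n_agreement_pairs: int
    variability: VariabilityResult

    def summary(self) -> dict:
        return {
            "triangle_violation_rate": self.triangles.rate,
            "n_triplets": self.triangles.n_evaluated,
            "rank_correlation_mean": self.reproducibility.mean,
            "rank_correlation_sd": self.reproducibility.sd,
            "full_agreement_rate": self.agreement_rate,
            "n_agreement_pairs": self.n_agreement_pairs,
            "n_variability_classes": self.variability.chosen_k,
        }


def evaluate_consistency(
    comparisons: pd.DataFrame,
    min_distinct_workers: int = 3,
    max_triplets: int | None = None,
    **ranker_params,
) -> ConsistencyReport:
    """Full consistency report over a multi-batch comparison set."""
    batches = split_batches(comparisons)
    if len(batches) < 2:
        raise ConfigError("consistency evaluation needs >= 2 duplicate batches")
    vote_table = build_vote_table(comparisons)
    triangles = triangle_violation_rate(vote_table, max_triplets=max_triplets)
    repro = rank_reproducibility(batches, **ranker_params)
    agreement, n_pairs = full_agreement_rate(comparisons, min_distinct_workers)
    variability = variability_classes(repro.rank_frame)
    return ConsistencyReport(triangles, repro, agreement, n_pairs, variability)
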