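"""Worker quality control and vote aggregation.

Workers are screened on their gold-question (QC) record: under the default
strict policy a worker passes only if every QC pair they answered was answered
correctly.  Comparisons from failed workers are discarded; the survivors are
aggregated per unordered ADR pair into a vote table with directed counts,
majority direction and majority margin, which is what the LP ranker consumes.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .errors import ConfigError, DataError

logger = logging.getLogger(__name__)

VOTE_COLUMNS = ("adr_a", "adr_b", "n_ab", "n_ba", "n_total", "n_workers", "majority", "weight")


def score_workers(comparisons: pd.DataFrame, pass_threshold: float = 1.0) -> pd.DataFrame:
    """Per-worker QC tally: qc_answered, qc_correct, passed.

    ``pass_threshold`` is the required fraction of correct QC answers; the
    default 1.0 is the strict all-correct policy.  Workers who answered no QC
    pair cannot be vetted and are marked not-passed.
    """
    if not 0 < pass_threshold <= 1:
        raise ConfigError("pass_threshold must lie in (0, 1]")
    qc = comparisons[comparisons["is_qc"]]
    if qc["qc_expected"].isna().any():
        raise DataError("QC comparison without qc_expected")
    workers = pd.Index(comparisons["worker_id"].unique(), name="worker_id")
    answered = qc.groupby("worker_id").size().reindex(workers, fill_value=0)
    correct = (
        qc.assign(ok=qc["chosen"] == qc["qc_expected"])
        .groupby("worker_id")["ok"]
        .sum()
        .reindex(workers, fill_value=0)
        .astype(int)
    )
    passed = (answered > 0) & (correct >= np.ceil(pass_threshold * answered) - 1e-9)
    n_unvetted = int((answered == 0).sum())
    if n_unvetted:
        logger.info("%d workers answered no QC pairs and are marked not-passed", n_unvetted)
    return pd.DataFrame(
        {
            "worker_id": workers,
            "qc_answered": answered.to_numpy(),
            "qc_correct": correct.to_numpy(),
            "passed": passed.to_numpy(),
        }
    ).reset_index(drop=True)


def filter_usable(
    comparisons: pd.DataFrame,
    worker_records: pd.DataFrame,
    include_qc_pairs: bool = True,
) -> pd.DataFrame:
    """Drop all comparisons from workers who failed QC.

    QC comparisons from passing workers are kept by default: they are genuine
    severity judgments and the study arithmetic (assigned vs. usable counts)
    indicates they count as usable input.
    """
    records = worker_records.set_index("worker_id")["passed"]
    unknown = set(comparisons["worker_id"]) - set(records.index)
    if unknown:
        raise DataError(f"comparisons from unscored workers: {sorted(unknown)[:5]}")
    keep = comparisons["worker_id"].map(records).astype(bool)
    if not include_qc_pairs:
        keep &= ~comparisons["is_qc"]
    usable = comparisons[keep].reset_index(drop=True)
    logger.info(
        "QC filter: %d of %d comparisons usable (%d removed)",
        len(usable), len(comparisons), len(comparisons) - len(usable),
    )
    return usable


def build_vote_table(comparisons: pd.DataFrame) -> pd.DataFrame:
    """Aggregate comparisons into per-unordered-pair directed vote counts.

    Pairs are canonicalized so adr_a < adr_b lexicographically; ``n_ab`` counts
    votes that adr_a is more severe.  ``majority`` is the winning term (missing
    for ties) and ``weight`` the majority margin |n_ab - n_ba|.
    """
    if (comparisons["adr_a"] == comparisons["adr_b"]).any():
        raise DataError("self-pairs in comparisons")
    if comparisons.empty:
        return pd.DataFrame(columns=list(VOTE_COLUMNS))
    a = comparisons["adr_a"].to_numpy()
    b = comparisons["adr_b"].to_numpy()
    chosen_a = (comparisons["chosen"] == "a").to_numpy()
    lo = np.where(a < b, a, b)
    hi = np.where(a < b, b, a)
    # vote for the canonical lo-term iff the chosen side holds lo
    vote_lo = np.where(a < b, chosen_a, ~chosen_a)
    frame = pd.DataFrame(
        {"adr_a": lo, "adr_b": hi, "vote_lo": vote_lo, "worker_id": comparisons["worker_id"]}
    )
    grouped = frame.groupby(["adr_a", "adr_b"], sort=True)
    table = grouped.agg(
        n_ab=("vote_lo", "sum"),
        n_total=("vote_lo", "size"),
        n_workers=("worker_id", "nunique"),
    ).reset_index()
    table["n_ba"] = table["n_total"] - table["n_ab"]
    table["weight"] = (table["n_ab"] - table["n_ba"]).abs()
    table["majority"] = np.select(
        [table["n_ab"] > table["n_ba"], table["n_ba"] > table["n_ab"]],
        [table["adr_a"], table["adr_b"]],
        default=None,
    )
    n_ties = int((table["weight"] == 0).sum())
    if n_ties:
        logger.info("%d tied pairs (no majority): retained but contribute no LP constraint", n_ties)
    return table[list(VOTE_COLUMNS)]


class WorkerQCFilter(BaseEstimator, TransformerMixin):
    """Gold-question worker filter with a scikit-learn transformer interface.

    ``fit`` scores every worker on the QC pairs they answered; ``transform``
    removes all comparisons contributed by failing workers.

    Parameters
    ----------
    pass_threshold : float, default 1.0
        Required fraction of correct QC answers (1.0 = strict all-correct).
    include_qc_pairs : bool, default True
        Keep QC comparisons from passing workers in the usable set.
    """

    def __init__(self, pass_threshold: float = 1.0, include_qc_pairs: bool = True):
        self.pass_threshold = pass_threshold
        self.include_qc_pairs = include_qc_pairs

    def fit(self, X: pd.DataFrame, y=None):
        self.worker_records_ = score_workers(X, pass_threshold=self.pass_threshold)
        self.n_workers_ = len(self.worker_records_)
        self.n_passed_ = int(self.worker_records_["passed"].sum())
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        if not hasattr(self, "worker_records_"):
            raise DataError("WorkerQCFilter is not fitted")
        return filter_usable(X, self.worker_records_, include_qc_pairs=self.include_qc_pairs)
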