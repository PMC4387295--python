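"""Validation of a severity ranking against outcome data, and severity-based triage.

The external check: if the crowd's severity ranking is meaningful, ADRs ranked
more severe should show higher death rates in spontaneous adverse-event
reports.  Outcome rates are per-ADR report fractions (the denominator includes
reports with an unspecific "other serious" tag and reports with no outcome at
all).  Beyond correlation per outcome, an L1-regularized (lasso) regression of
the severity score on all outcome rates identifies the leading outcome.

Triage applications: the severe set (top percentiles of the ranking) is used
to profile therapeutic classes, score genes by their worst associated ADR, and
flag novel severe predictions for widely prescribed drugs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import Lasso, LassoCV
from sklearn.model_selection import KFold

from .errors import ConfigError, DataError
from .io import OUTCOME_CATEGORIES, normalize_term

logger = logging.getLogger(__name__)

#: Predictors for the lasso: all categories except none_specified, which is
#: determined by the others (rates sum to 1 under exclusive outcomes).
REGRESSION_OUTCOMES = tuple(c for c in OUTCOME_CATEGORIES if c != "none_specified")


def outcome_rates(outcome_table: pd.DataFrame) -> pd.DataFrame:
    """Per-ADR outcome rates: category count / total reports for that ADR.

    ADRs with zero reports have undefined rates and are excluded (logged).
    """
    counts = outcome_table[list(OUTCOME_CATEGORIES)]
    if (counts.to_numpy() < 0).any():
        raise DataError("negative outcome counts")
    total = counts.sum(axis=1)
    zero = total == 0
    if zero.any():
        logger.info("excluding %d ADRs with zero reports", int(zero.sum()))
    kept = outcome_table[~zero]
    rates = kept[list(OUTCOME_CATEGORIES)].div(total[~zero], axis=0)
    out = pd.concat([kept[["adr"]].reset_index(drop=True), rates.reset_index(drop=True)], axis=1)
    out["total_reports"] = total[~zero].to_numpy()
    return out


def _match_ranking(ranking: pd.DataFrame, adrs: pd.Series) -> pd.Series:
    """Map ADR names onto ranking percentiles (case/whitespace-insensitive)."""
    lookup = {normalize_term(t): p for t, p in zip(ranking["term"], ranking["percentile"])}
    return adrs.map(lambda t: lookup.get(normalize_term(t), np.nan))


def correlate_rank_outcomes(
    ranking: pd.DataFrame, rates: pd.DataFrame, min_shared: int = 10
) -> pd.DataFrame:
    """Spearman correlation between severity percentile and each outcome rate.

    Positive rho means the outcome is more frequent for ADRs the crowd ranked
    more severe.
    """
    pct = _match_ranking(ranking, rates["adr"])
    mask = pct.notna()
    if int(mask.sum()) < min_shared:
        raise DataError(f"only {int(mask.sum())} ADRs shared between ranking and outcomes")
    rows = []
    for cat in OUTCOME_CATEGORIES:
        res = stats.spearmanr(pct[mask], rates.loc[mask, cat])
        rows.append(
            {"outcome": cat, "rho": float(res.statistic), "p_value": float(res.pvalue),
             "n": int(mask.sum())}
        )
    return pd.DataFrame(rows)


@dataclass
class LassoResult:
    coefficients: pd.Series  # on standardized predictors
    alpha: float
    leading_factor: str | None
    rule: str
    n: int


def l1_outcome_regression(
    rates: pd.DataFrame,
    ranking: pd.DataFrame,
    folds: int = 10,
    seed: int = 0,
    rule: str = "min",
) -> LassoResult:
    """Lasso regression of the severity score on standardized outcome rates.

    The penalty is chosen by ``folds``-fold cross-validation, either at the
    CV-minimum ("min") or by the one-standard-error rule ("1se").  The leading
    factor is the predictor with the largest absolute coefficient at the
    chosen penalty; constant predictors are dropped with a warning.
    """
    pct = _match_ranking(ranking, rates["adr"])
    mask = pct.notna()
    if int(mask.sum()) < 2 * folds:
        raise DataError("too few matched ADRs for cross-validated lasso")
    y = (pct[mask] / 100.0).to_numpy()
    predictors = []
    for cat in REGRESSION_OUTCOMES:
        col = rates.loc[mask, cat].to_numpy(dtype=float)
        if np.std(col) == 0:
            logger.warning("dropping constant predictor %r", cat)
            continue
        predictors.append((cat, (col - col.mean()) / col.std()))
    if not predictors:
        raise DataError("no variable predictors")
    names = [p[0] for p in predictors]
    design = np.column_stack([p[1] for p in predictors])

    cv = KFold(n_splits=folds, shuffle=True, random_state=seed)
    lasso_cv = LassoCV(cv=cv, random_state=seed, max_iter=50_000).fit(design, y)
    if rule == "min":
        alpha = float(lasso_cv.alpha_)
    elif rule == "1se":
        mean_mse = lasso_cv.mse_path_.mean(axis=1)
        se = lasso_cv.mse_path_.std(axis=1, ddof=1) / np.sqrt(folds)
        best = int(np.argmin(mean_mse))
        threshold = mean_mse[best] + se[best]
        eligible = np.where(mean_mse <= threshold)[0]
        alpha = float(lasso_cv.alphas_[eligible].max())
    else:
        raise ConfigError("rule must be 'min' or '1se'")
    model = Lasso(alpha=alpha, max_iter=50_000).fit(design, y)
    coefs = pd.Series(model.coef_, index=names)
    leading = None
    if (coefs.abs() > 0).any():
        leading = str(coefs.abs().idxmax())
    return LassoResult(coefs, alpha, leading, rule, n=len(y))


def severe_set(ranking: pd.DataFrame, percentile_threshold: float = 95.0) -> set[str]:
    """ADRs at or above the given severity percentile (rank 1 = percentile 100)."""
    return set(ranking.loc[ranking["percentile"] >= percentile_threshold, "term"])


@dataclass
class AtcSummary:
    per_class: pd.DataFrame
    rho: float
    p_value: float
    n_retained: int


def atc_class_summary(
    drug_adr: pd.DataFrame,
    drug_class: pd.DataFrame,
    box_warning: pd.DataFrame,
    severe: set[str],
    min_drugs: int = 3,
    min_severe_adrs: int = 4,
) -> AtcSummary:
    """Severe-ADR burden per therapeutic (ATC level 2) class.

    Per drug: number of distinct severe ADRs among its associations.  Per
    class: drug count, median and SD of the per-drug severe counts, and the
    fraction of its drugs carrying a boxed warning.  Classes with too few
    drugs or too few distinct severe ADRs (defaults mirror "more than 2
    drugs"/"more than 3 severe ADRs" display cuts) are flagged out of the
    correlation between median severe burden and boxed-warning fraction.
    """
    if drug_class.empty:
        raise ConfigError("empty drug-class map")
    severe_norm = {normalize_term(t) for t in severe}
    assoc = drug_adr[["subject", "adr"]].drop_duplicates()
    class_map = drug_class.set_index("subject")["atc2"]
    warn_map = box_warning.set_index("subject")["boxed_warning"] if not box_warning.empty else pd.Series(dtype=bool)

    assoc = assoc.assign(
        atc2=assoc["subject"].map(class_map),
        is_severe=assoc["adr"].map(lambda t: normalize_term(t) in severe_norm),
    )
    unmapped = assoc["atc2"].isna()
    if unmapped.any():
        logger.info("excluding %d associations from drugs without a class", int(unmapped.sum()))
        assoc = assoc[~unmapped]
    per_drug = (
        assoc.groupby(["atc2", "subject"])
        .agg(n_severe=("is_severe", "sum"))
        .reset_index()
    )
    per_drug["boxed_warning"] = (
        per_drug["subject"].map(warn_map).fillna(False).astype(bool)
    )
    class_severe = (
        assoc[assoc["is_severe"]]
        .groupby("atc2")["adr"]
        .nunique()
        .rename("n_distinct_severe_adrs")
    )
    per_class = (
        per_drug.groupby("atc2")
        .agg(
            n_drugs=("subject", "nunique"),
            median_severe=("n_severe", "median"),
            sd_severe=("n_severe", "std"),
            box_warning_fraction=("boxed_warning", "mean"),
        )
        .join(class_severe)
        .fillna({"n_distinct_severe_adrs": 0})
        .reset_index()
    )
    per_class["retained"] = (per_class["n_drugs"] >= min_drugs) & (
        per_class["n_distinct_severe_adrs"] >= min_severe_adrs
    )
    kept = per_class[per_class["retained"]]
    if (
        len(kept) >= 3
        and kept["median_severe"].nunique() > 1
        and kept["box_warning_fraction"].nunique() > 1
    ):
        res = stats.spearmanr(kept["median_severe"], kept["box_warning_fraction"])
        rho, p = float(res.statistic), float(res.pvalue)
    else:
        rho, p = float("nan"), float("nan")
    return AtcSummary(per_class=per_class, rho=rho, p_value=p, n_retained=int(len(kept)))


def gene_risk_score(
    gene_adr: pd.DataFrame, ranking: pd.DataFrame, aggregator: str = "max"
) -> pd.DataFrame:
    """Adverse-reaction risk per gene from its associated ADRs' severity percentiles.

    The default aggregator is the maximum percentile — a gene is as risky as
    the most severe ADR it is associated with — and that ADR is reported
    alongside the score.  Genes with no ADR resolvable against the ranking are
    excluded (logged).
    """
    if gene_adr.empty:
        raise DataError("empty gene-ADR table")
    if aggregator not in ("max", "mean", "sum"):
        raise ConfigError(f"unknown aggregator {aggregator!r}")
    table = gene_adr[["subject", "adr"]].drop_duplicates()
    table = table.assign(percentile=_match_ranking(ranking, table["adr"]))
    unresolved = table["percentile"].isna()
    if unresolved.any():
        logger.info("%d gene-ADR rows with unresolvable ADR terms", int(unresolved.sum()))
        table = table[~unresolved]
    rows = []
    for gene, grp in table.groupby("subject"):
        if grp.empty:
            continue
        top = grp.loc[grp["percentile"].idxmax()]
        score = {
            "max": grp["percentile"].max(),
            "mean": grp["percentile"].mean(),
            "sum": grp["percentile"].sum(),
        }[aggregator]
        rows.append(
            {
                "gene": gene,
                "risk_score": float(score),
                "top_adr": top["adr"],
                "top_adr_percentile": float(top["percentile"]),
                "n_adrs": int(len(grp)),
            }
        )
    columns = ["gene", "risk_score", "top_adr", "top_adr_percentile", "n_adrs"]
    if not rows:
        return pd.DataFrame(columns=columns)
    return (
        pd.DataFrame(rows, columns=columns)
        .sort_values(["risk_score", "gene"], ascending=[False, True])
        .reset_index(drop=True)
    )


@dataclass
class TriageResult:
    per_drug: pd.DataFrame  # drug, novel_severe (tuple), n_novel_severe
    n_drugs_with_novel: int


def triage_novel_severe(
    predicted: pd.DataFrame,
    labeled: pd.DataFrame,
    severe: set[str],
    drug_subset: set[str] | None = None,
) -> TriageResult:
    """Novel severe predictions per drug: (predicted \\ labeled) intersected with the severe set."""
    severe_norm = {normalize_term(t) for t in severe}
    drugs = set(predicted["subject"])
    if drug_subset is not None:
        drugs &= set(drug_subset)
    labeled_by_drug = {
        d: {normalize_term(t) for t in grp["adr"]} for d, grp in labeled.groupby("subject")
    }
    rows = []
    for drug in sorted(drugs):
        pred = predicted.loc[predicted["subject"] == drug, "adr"]
        known = labeled_by_drug.get(drug, set())
        novel = sorted(
            {t for t in pred if normalize_term(t) not in known and normalize_term(t) in severe_norm}
        )
        rows.append({"drug": drug, "novel_severe": tuple(novel), "n_novel_severe": len(novel)})
    per_drug = (
        pd.DataFrame(rows, columns=["drug", "novel_severe", "n_novel_severe"])
        .sort_values(["n_novel_severe", "drug"], ascending=[False, True])
        .reset_index(drop=True)
    )
    n_with = int((per_drug["n_novel_severe"] > 0).sum()) if not per_drug.empty else 0
    return TriageResult(per_drug=per_drug, n_drugs_with_novel=n_with)
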