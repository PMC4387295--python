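"""Benchmark experiments exercising the whole pipeline under known ground truth.

Each function simulates its own inputs, runs the relevant pipeline stages and
returns the measured quantities as a plain dict.  They are used both by the
test suite and by the repository's acceptance script, so the study conditions
(sample sizes, noise levels, spammer rates) live here, in one place:

* LP order quality against an exhaustive permutation oracle on 5-ADR
  weighted tournaments.
* exact recovery of the latent order from noise-free judgments, single-LP
  and sample-and-merge.
* latent-order recovery under realistic noise (logistic workers, spammers,
  QC filtering) at 200 ADRs and ~20 usable comparisons per ADR.
* power of the gold-question worker filter at 15 tasks/worker.
* Monte-Carlo checks of the two combinatorial limits under random voting
  (triangle violations and 3-worker unanimity, both exactly 1/4).
* the outcome-validation stage: death-rate correlation and lasso selection
  when the death rate is generated monotone in latent severity.
"""

from __future__ import annotations

from itertools import combinations, permutations

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import spearmanr

from .qc import WorkerQCFilter, build_vote_table
from .ranking import LPSeverityRanker, net_margins, solve_lp, to_percentiles, weighted_disagreement
from .simulate import (
    LatentWorld,
    OutcomeLink,
    WorkerModel,
    sample_latent_scores,
    simulate_full_coverage,
    simulate_reports,
    simulate_study,
    simulate_two_stage_study,
)
from .validate import correlate_rank_outcomes, l1_outcome_regression, outcome_rates

TERMS_ABCDE = ["A", "B", "C", "D", "E"]


def _subseeds(seed: int, n: int) -> list[int]:
    return [int(s) for s in np.random.SeedSequence(seed).generate_state(n) % (2**31 - 1)]


def _comparisons_from_votes(votes) -> pd.DataFrame:
    rows = []
    for k, (winner, loser, count) in enumerate(votes):
        for i in range(count):
            rows.append(
                {
                    "worker_id": f"w{k}_{i}",
                    "batch_id": "b",
                    "adr_a": winner,
                    "adr_b": loser,
                    "chosen": "a",
                    "is_qc": False,
                    "qc_expected": None,
                }
            )
    return pd.DataFrame(rows)


def perfect_ranking(world: LatentWorld) -> pd.DataFrame:
    """Ranking frame read off the latent truth (for validation-stage experiments)."""
    order = np.argsort(-world.scores, kind="stable")
    n = world.n_adrs
    return pd.DataFrame(
        {
            "term": [world.terms[i] for i in order],
            "score": world.scores[order],
            "rank": np.arange(1, n + 1),
            "percentile": to_percentiles(np.arange(1, n + 1), n),
        }
    )


def _latent_spearman(ranking: pd.DataFrame, world: LatentWorld) -> float:
    merged = ranking.set_index("term").join(world.as_frame().set_index("term"))
    return float(spearmanr(-merged["rank"], merged["true_score"]).statistic)


def lp_oracle(seed: int, n_instances: int = 100) -> dict:
    """LP-induced order vs brute-force minimum weighted disagreement, n=5 tournaments.

    Also solves the canonical unit 3-cycle, whose optimal slack objective is
    exactly 3 * margin.
    """
    rng = np.random.default_rng(seed)
    n_match = 0
    n_below = 0
    for _ in range(n_instances):
        votes = []
        for i, j in combinations(range(5), 2):
            if rng.random() < 0.9:
                w = int(rng.integers(1, 6))
                pair = (TERMS_ABCDE[i], TERMS_ABCDE[j]) if rng.random() < 0.5 else (
                    TERMS_ABCDE[j], TERMS_ABCDE[i])
                votes.append((*pair, w))
        if not votes:
            continue
        table = build_vote_table(_comparisons_from_votes(votes))
        ranker = LPSeverityRanker().fit(table)
        net = net_margins(table)
        achieved = weighted_disagreement(list(ranker.ranking_["term"]), net)
        terms = sorted(set(table["adr_a"]) | set(table["adr_b"]))
        best = min(weighted_disagreement(list(p), net) for p in permutations(terms))
        if achieved < best - 1e-9:
            n_below += 1
        elif achieved <= best + 1e-9:
            n_match += 1
    cycle = build_vote_table(
        _comparisons_from_votes([("A", "B", 1), ("B", "C", 1), ("C", "A", 1)])
    )
    _, cycle_objective = solve_lp(cycle, margin=1.0)
    return {
        "n_instances": n_instances,
        "match_fraction": n_match / n_instances,
        "n_below_optimum": n_below,
        "three_cycle_objective": cycle_objective,
    }


def noise_free_recovery(seed: int) -> dict:
    """Exact latent-order recovery from deterministic workers with full pair coverage."""
    s1, s2, s3, s4 = _subseeds(seed, 4)
    deterministic = WorkerModel(beta=1e9, spammer_fraction=0.0)

    world60 = sample_latent_scores(60, seed=s1)
    comps60 = simulate_full_coverage(world60, deterministic, seed=s2)
    ranker60 = LPSeverityRanker().fit(comps60)

    world200 = sample_latent_scores(200, seed=s3)
    comps200 = simulate_full_coverage(world200, deterministic, seed=s4)
    ranker200 = LPSeverityRanker(sample_size=60).fit(comps200)
    assert ranker200.is_merged_

    return {
        "n60_single_lp_spearman": _latent_spearman(ranker60.ranking_, world60),
        "n200_merged_spearman": _latent_spearman(ranker200.ranking_, world200),
    }


def parameter_recovery(seed: int, n_replicates: int = 5) -> dict:
    """Latent-order recovery under noise: 200 ADRs, logistic beta=6 workers,
    10% spammers, informative two-stage task design sized for ~20 usable
    comparisons per ADR after QC filtering.
    """
    model = WorkerModel(beta=6.0, spammer_fraction=0.1)
    rhos = []
    for s in _subseeds(seed, n_replicates):
        world = sample_latent_scores(200, seed=s)
        study = simulate_two_stage_study(
            world, n_workers=65, tasks_per_worker=5, model=model, seed=s + 1
        )
        usable = WorkerQCFilter().fit_transform(study.comparisons)
        ranker = LPSeverityRanker().fit(usable)
        rhos.append(_latent_spearman(ranker.ranking_, world))
    return {
        "rhos": rhos,
        "mean_rho": float(np.mean(rhos)),
        "min_rho": float(np.min(rhos)),
        "n_replicates": n_replicates,
    }


def qc_filter_power(seed: int, n_workers: int = 200, tasks_per_worker: int = 15) -> dict:
    """Sensitivity/specificity of the strict gold-question filter.

    A spammer answers each QC pair with probability 1/2, so passing one task's
    3 QC pairs has probability 1/8 and passing all of 15 tasks (1/8)^15.  A
    diligent worker's pass probability is the product of logistic(beta * gap)
    over the QC pairs they saw; the observed diligent pass rate is compared to
    that closed form.
    """
    s1, s2 = _subseeds(seed, 2)
    world = sample_latent_scores(200, seed=s1)
    model = WorkerModel(beta=6.0, spammer_fraction=0.2)
    study = simulate_study(
        world, n_workers=n_workers, tasks_per_worker=tasks_per_worker, model=model, seed=s2
    )
    records = WorkerQCFilter().fit(study.comparisons).worker_records_.set_index("worker_id")
    truth = study.workers.set_index("worker_id")["is_spammer"]
    spammers = truth[truth].index
    diligent = truth[~truth].index

    sensitivity = float((~records.loc[spammers, "passed"]).mean()) if len(spammers) else float("nan")
    observed = float(records.loc[diligent, "passed"].mean())
    qc = study.comparisons[study.comparisons["is_qc"]]
    qc = qc[qc["worker_id"].isin(diligent)]
    gaps = np.abs(
        qc["adr_a"].map(world.score_of).to_numpy() - qc["adr_b"].map(world.score_of).to_numpy()
    )
    per_worker = qc.assign(p=expit(model.beta * gaps)).groupby("worker_id")["p"].prod()
    predicted = float(per_worker.mean())
    se = float(np.sqrt((per_worker * (1 - per_worker)).sum()) / len(per_worker))
    return {
        "n_spammers": int(len(spammers)),
        "spammer_sensitivity": sensitivity,
        "diligent_pass_observed": observed,
        "diligent_pass_predicted": predicted,
        "diligent_pass_se": se,
        "diligent_pass_z": abs(observed - predicted) / max(se, 1e-12),
    }


def combinatorial_limits(seed: int, n_monte_carlo: int = 10_000) -> dict:
    """Monte-Carlo checks of the exact 1/4 limits under random voting.

    Triangle violations: in a uniformly random tournament 2 of the 8
    orientations of any triplet are cyclic.  Unanimity: 3 independent fair
    coins agree with probability 2/8.
    """
    s1, s2, s3 = _subseeds(seed, 3)
    rng = np.random.default_rng(s1)
    n_terms = 48  # C(48,3) = 17,296 > n_monte_carlo triplets
    terms = [f"T{i:03d}" for i in range(n_terms)]
    rows = [
        {
            "worker_id": f"w{k}",
            "batch_id": "b",
            "adr_a": terms[i],
            "adr_b": terms[j],
            "chosen": "a" if rng.random() < 0.5 else "b",
            "is_qc": False,
            "qc_expected": None,
        }
        for k, (i, j) in enumerate(combinations(range(n_terms), 2))
    ]
    from .consistency import full_agreement_rate, triangle_violation_rate

    triangles = triangle_violation_rate(
        build_vote_table(pd.DataFrame(rows)), max_triplets=n_monte_carlo, rng=s2
    )

    rng2 = np.random.default_rng(s3)
    rows = []
    for p in range(n_monte_carlo):
        for w in range(3):
            rows.append(
                {
                    "worker_id": f"w{p}_{w}",
                    "batch_id": "b",
                    "adr_a": f"P{p}x",
                    "adr_b": f"P{p}y",
                    "chosen": "a" if rng2.random() < 0.5 else "b",
                    "is_qc": False,
                    "qc_expected": None,
                }
            )
    agreement, n_pairs = full_agreement_rate(pd.DataFrame(rows), min_distinct_workers=3)
    se = float(np.sqrt(0.25 * 0.75 / n_monte_carlo))
    return {
        "triangle_rate": triangles.rate,
        "triangle_n": triangles.n_evaluated,
        "triangle_z": abs(triangles.rate - 0.25) / se,
        "unanimity_rate": agreement,
        "unanimity_n": n_pairs,
        "unanimity_z": abs(agreement - 0.25) / se,
        "expected_rate": 0.25,
    }


def outcome_validation(seed: int, n_replicates: int = 5, n_adrs: int = 500,
                       reports_per_adr: int = 200) -> dict:
    """Validation stage under a severity-linked death rate.

    For each replicate: simulate outcome tables whose death probability is
    logistic in the latent severity, correlate every outcome rate with the
    severity percentile, and run the cross-validated lasso.  Reports how often
    death is the leading lasso factor and how often its correlation beats
    every other outcome's.
    """
    death_leading = 0
    death_top_rho = 0
    death_rhos = []
    for s in _subseeds(seed, n_replicates):
        world = sample_latent_scores(n_adrs, seed=s)
        reports = simulate_reports(world, reports_per_adr, link=OutcomeLink(), seed=s + 1)
        rates = outcome_rates(reports)
        ranking = perfect_ranking(world)
        corr = correlate_rank_outcomes(ranking, rates).set_index("outcome")
        death_rho = float(corr.loc["death", "rho"])
        death_rhos.append(death_rho)
        if death_rho > float(corr.drop("death")["rho"].max()):
            death_top_rho += 1
        lasso = l1_outcome_regression(rates, ranking, folds=10, seed=s)
        if lasso.leading_factor == "death":
            death_leading += 1
    return {
        "death_rho_mean": float(np.mean(death_rhos)),
        "death_leading_fraction": death_leading / n_replicates,
        "death_top_rho_fraction": death_top_rho / n_replicates,
        "n_replicates": n_replicates,
    }
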