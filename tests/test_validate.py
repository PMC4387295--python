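import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

import adrrank as ar
from adrrank.errors import ConfigError, DataError

from conftest import perfect_ranking


def outcome_row(adr, **counts):
    row = {"adr": adr, **dict.fromkeys(ar.OUTCOME_CATEGORIES, 0)}
    row.update(counts)
    return row


class TestOutcomeRates:
    def test_rate_arithmetic(self):
        table = pd.DataFrame([outcome_row("coma", death=2, hospitalization=1, none_specified=7)])
        rates = ar.outcome_rates(table)
        assert rates.loc[0, "death"] == pytest.approx(0.2)
        assert rates.loc[0, "hospitalization"] == pytest.approx(0.1)
        assert rates.loc[0, "total_reports"] == 10

    def test_rates_sum_to_one(self):
        table = pd.DataFrame(
            [outcome_row("x", death=3, disability=2, other_serious=5, none_specified=10)]
        )
        rates = ar.outcome_rates(table)
        assert rates[list(ar.OUTCOME_CATEGORIES)].sum(axis=1).iloc[0] == pytest.approx(1.0)

    def test_zero_report_adr_excluded(self):
        table = pd.DataFrame([outcome_row("empty"), outcome_row("ok", none_specified=5)])
        rates = ar.outcome_rates(table)
        assert list(rates["adr"]) == ["ok"]

    def test_negative_count_rejected(self):
        table = pd.DataFrame([outcome_row("bad", death=-1)])
        with pytest.raises(DataError):
            ar.outcome_rates(table)


class TestCorrelation:
    def make_inputs(self, seed, link=None, n=500):
        world = ar.sample_latent_scores(n, seed=seed)
        reports = ar.simulate_reports(world, 200, link=link, seed=seed + 1)
        return perfect_ranking(world), ar.outcome_rates(reports)

    def test_monotone_death_link_recovered(self):
        ranking, rates = self.make_inputs(seed=30)
        corr = ar.correlate_rank_outcomes(ranking, rates).set_index("outcome")
        assert corr.loc["death", "rho"] > 0.8

    def test_severity_independent_outcome_uncorrelated(self):
        ranking, rates = self.make_inputs(seed=31, link=ar.OutcomeLink(death_slope=0.0))
        corr = ar.correlate_rank_outcomes(ranking, rates).set_index("outcome")
        assert abs(corr.loc["death", "rho"]) < 0.1

    def test_reversed_ranking_negates_correlation(self):
        ranking, rates = self.make_inputs(seed=32, n=100)
        n = len(ranking)
        reversed_ranking = ranking.assign(
            rank=n + 1 - ranking["rank"],
            score=1 - ranking["score"],
            percentile=ar.to_percentiles(n + 1 - ranking["rank"], n),
        ).sort_values("rank")
        c1 = ar.correlate_rank_outcomes(ranking, rates).set_index("outcome")
        c2 = ar.correlate_rank_outcomes(reversed_ranking, rates).set_index("outcome")
        assert c1.loc["death", "rho"] == pytest.approx(-c2.loc["death", "rho"])

    def test_too_few_shared_adrs_rejected(self):
        ranking, rates = self.make_inputs(seed=33, n=100)
        with pytest.raises(DataError):
            ar.correlate_rank_outcomes(ranking, rates.head(5))


class TestLasso:
    def test_death_only_signal_selects_death(self):
        """Score generated from the death rate alone: death must lead, others vanish."""
        rng = np.random.default_rng(40)
        n = 300
        death_rate = rng.uniform(0, 0.5, n)
        terms = [f"ADR_{i}" for i in range(n)]
        rates = pd.DataFrame({"adr": terms})
        for cat in ar.OUTCOME_CATEGORIES:
            rates[cat] = rng.uniform(0, 0.2, n)
        rates["death"] = death_rate
        score = death_rate + rng.normal(0, 0.02, n)
        order = np.argsort(-score)
        ranking = pd.DataFrame(
            {
                "term": [terms[i] for i in order],
                "score": score[order],
                "rank": np.arange(1, n + 1),
                "percentile": ar.to_percentiles(np.arange(1, n + 1), n),
            }
        )
        result = ar.l1_outcome_regression(rates, ranking, seed=1, rule="1se")
        assert result.leading_factor == "death"
        assert (result.coefficients.drop("death").abs() < 0.02).all()

    def test_pure_noise_gives_empty_model_at_1se(self):
        rng = np.random.default_rng(41)
        n = 200
        terms = [f"ADR_{i}" for i in range(n)]
        rates = pd.DataFrame({"adr": terms})
        for cat in ar.OUTCOME_CATEGORIES:
            rates[cat] = rng.uniform(0, 0.3, n)
        score = rng.uniform(0, 1, n)
        order = np.argsort(-score)
        ranking = pd.DataFrame(
            {
                "term": [terms[i] for i in order],
                "score": score[order],
                "rank": np.arange(1, n + 1),
                "percentile": ar.to_percentiles(np.arange(1, n + 1), n),
            }
        )
        result = ar.l1_outcome_regression(rates, ranking, seed=2, rule="1se")
        assert result.leading_factor is None

    def test_duplicated_rows_keep_leading_factor(self):
        world = ar.sample_latent_scores(200, seed=42)
        rates = ar.outcome_rates(ar.simulate_reports(world, 200, seed=43))
        ranking = perfect_ranking(world)
        r1 = ar.l1_outcome_regression(rates, ranking, seed=3)
        doubled = pd.concat([rates, rates], ignore_index=True)
        r2 = ar.l1_outcome_regression(doubled, ranking, seed=3)
        assert r1.leading_factor == r2.leading_factor == "death"


class TestSevereSet:
    def test_threshold_boundaries(self):
        world = ar.sample_latent_scores(100, seed=50)
        ranking = perfect_ranking(world)
        severe = ar.severe_set(ranking, 95)
        # percentile >= 95 keeps ranks 1..6 (rank 6 of 100 sits exactly at 95.0)
        kept_ranks = sorted(ranking.set_index("term").loc[sorted(severe), "rank"])
        assert kept_ranks == [1, 2, 3, 4, 5, 6]
        assert ar.severe_set(ranking, 0) == set(ranking["term"])
        top = ar.severe_set(ranking, 100)
        assert top == {ranking.loc[ranking["rank"] == 1, "term"].iloc[0]}

    def test_monotone_in_threshold(self):
        world = ar.sample_latent_scores(57, seed=51)
        ranking = perfect_ranking(world)
        previous = set(ranking["term"])
        for threshold in (10, 50, 90, 99):
            current = ar.severe_set(ranking, threshold)
            assert current <= previous
            previous = current


class TestAtcSummary:
    def make_fixture(self):
        drug_adr = pd.DataFrame(
            [("dX1", f"sev{i}") for i in range(5)]
            + [("dX2", f"sev{i}") for i in range(9)]
            + [("dY1", "mild1")]
            + [("dY2", "sev0"), ("dY2", "mild2")]
            + [("dY3", "mild3")],
            columns=["subject", "adr"],
        )
        drug_class = pd.DataFrame(
            {"subject": ["dX1", "dX2", "dY1", "dY2", "dY3"], "atc2": ["X", "X", "Y", "Y", "Y"]}
        )
        warnings = pd.DataFrame(
            {"subject": ["dX1", "dX2", "dY1", "dY2", "dY3"],
             "boxed_warning": [True, True, False, False, False]}
        )
        severe = {f"sev{i}" for i in range(9)}
        return drug_adr, drug_class, warnings, severe

    def test_median_and_warning_fraction(self):
        drug_adr, drug_class, warnings, severe = self.make_fixture()
        summary = ar.atc_class_summary(drug_adr, drug_class, warnings, severe)
        per_class = summary.per_class.set_index("atc2")
        assert per_class.loc["X", "median_severe"] == 7.0
        assert per_class.loc["Y", "median_severe"] == 0.0
        assert per_class.loc["X", "box_warning_fraction"] == 1.0
        # X has 2 drugs only -> fails the "more than 2 drugs" display cut
        assert not per_class.loc["X", "retained"]

    def test_duplicate_associations_do_not_inflate_counts(self):
        drug_adr, drug_class, warnings, severe = self.make_fixture()
        doubled = pd.concat([drug_adr, drug_adr], ignore_index=True)
        s1 = ar.atc_class_summary(drug_adr, drug_class, warnings, severe)
        s2 = ar.atc_class_summary(doubled, drug_class, warnings, severe)
        pd.testing.assert_frame_equal(s1.per_class, s2.per_class)

    def test_empty_class_map_rejected(self):
        drug_adr, _, warnings, severe = self.make_fixture()
        with pytest.raises(ConfigError):
            ar.atc_class_summary(drug_adr, pd.DataFrame(), warnings, severe)

    def test_class_burden_correlates_with_warnings_on_synthetic_universe(self):
        world = ar.sample_latent_scores(300, seed=52)
        universe = ar.simulate.simulate_drug_universe(
            world, n_drugs=80, n_classes=8, seed=53
        )
        ranking = perfect_ranking(world)
        severe = ar.severe_set(ranking, 95)
        summary = ar.atc_class_summary(
            universe["drug_adr"], universe["drug_class"], universe["box_warning"], severe,
            min_drugs=2, min_severe_adrs=1,
        )
        assert summary.rho > 0


class TestGeneRisk:
    def make_ranking(self):
        return pd.DataFrame(
            {
                "term": ["glioblastoma multiforme", "epilepsy", "headache", "dry mouth"],
                "score": [1.0, 0.8, 0.3, 0.0],
                "rank": [1, 2, 3, 4],
                "percentile": [100.0, 75.0, 50.0, 25.0],
            }
        )

    def test_max_aggregator_reports_worst_adr(self):
        genes = pd.DataFrame(
            {"subject": ["EGFR", "EGFR"], "adr": ["Glioblastoma Multiforme", "headache"]}
        )
        scores = ar.gene_risk_score(genes, self.make_ranking())
        assert scores.loc[0, "gene"] == "EGFR"
        assert scores.loc[0, "risk_score"] == 100.0
        assert scores.loc[0, "top_adr"] == "Glioblastoma Multiforme"

    def test_mean_aggregator(self):
        genes = pd.DataFrame({"subject": ["g", "g"], "adr": ["epilepsy", "headache"]})
        scores = ar.gene_risk_score(genes, self.make_ranking(), aggregator="mean")
        assert scores.loc[0, "risk_score"] == pytest.approx(62.5)

    def test_unresolvable_gene_excluded(self):
        genes = pd.DataFrame({"subject": ["ghost"], "adr": ["not an adr"]})
        scores = ar.gene_risk_score(genes, self.make_ranking())
        assert scores.empty


class TestTriage:
    def test_set_algebra(self):
        predicted = pd.DataFrame({"subject": ["d"] * 3, "adr": ["A", "B", "C"]})
        labeled = pd.DataFrame({"subject": ["d"], "adr": ["A"]})
        result = ar.triage_novel_severe(predicted, labeled, severe={"B"})
        assert result.per_drug.loc[0, "novel_severe"] == ("B",)
        assert result.n_drugs_with_novel == 1

    def test_fully_labeled_drug_not_counted(self):
        predicted = pd.DataFrame({"subject": ["d"], "adr": ["A"]})
        labeled = pd.DataFrame({"subject": ["d"], "adr": ["A"]})
        result = ar.triage_novel_severe(predicted, labeled, severe={"A"})
        assert result.n_drugs_with_novel == 0

    def test_against_brute_force_sets(self):
        rng = np.random.default_rng(60)
        adrs = [f"adr{i}" for i in range(20)]
        severe = set(rng.choice(adrs, 6, replace=False))
        pred_rows, lab_rows = [], []
        for d in range(5):
            drug = f"drug{d}"
            for t in rng.choice(adrs, 8, replace=False):
                pred_rows.append({"subject": drug, "adr": t})
            for t in rng.choice(adrs, 4, replace=False):
                lab_rows.append({"subject": drug, "adr": t})
        predicted, labeled = pd.DataFrame(pred_rows), pd.DataFrame(lab_rows)
        result = ar.triage_novel_severe(predicted, labeled, severe)
        for _, row in result.per_drug.iterrows():
            pred = set(predicted.loc[predicted["subject"] == row["drug"], "adr"])
            lab = set(labeled.loc[labeled["subject"] == row["drug"], "adr"])
            assert set(row["novel_severe"]) == (pred - lab) & severe

    def test_drug_subset_restriction(self):
        predicted = pd.DataFrame({"subject": ["d1", "d2"], "adr": ["A", "A"]})
        labeled = pd.DataFrame({"subject": [], "adr": []})
        result = ar.triage_novel_severe(predicted, labeled, {"A"}, drug_subset={"d1"})
        assert list(result.per_drug["drug"]) == ["d1"]
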