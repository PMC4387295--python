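from itertools import combinations, permutations

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr
from sklearn.base import clone

import adrrank as ar
from adrrank.errors import ConfigError, DataError
from adrrank.ranking import net_margins, refine_order, weighted_disagreement

from conftest import make_comparisons


def vote_rows(*votes):
    """votes: (winner, loser, count) triples -> comparison frame."""
    rows = []
    for k, (winner, loser, count) in enumerate(votes):
        for i in range(count):
            rows.append((f"w{k}_{i}", "b", winner, loser, "a", False, None))
    return make_comparisons(rows)


def random_tournament_votes(rng, n=5, p_observed=0.9, max_weight=5):
    terms = [chr(ord("A") + i) for i in range(n)]
    votes = []
    for i, j in combinations(range(n), 2):
        if rng.random() < p_observed:
            w = int(rng.integers(1, max_weight + 1))
            if rng.random() < 0.5:
                votes.append((terms[i], terms[j], w))
            else:
                votes.append((terms[j], terms[i], w))
    return terms, votes


class TestSolveLP:
    def test_consistent_chain_zero_objective(self):
        table = ar.build_vote_table(vote_rows(("A", "B", 1), ("B", "C", 1)))
        scores, objective = ar.solve_lp(table)
        assert objective == pytest.approx(0.0, abs=1e-9)
        assert scores["A"] > scores["B"] > scores["C"]

    def test_three_cycle_objective_is_three_delta(self):
        table = ar.build_vote_table(vote_rows(("A", "B", 1), ("B", "C", 1), ("C", "A", 1)))
        scores, objective = ar.solve_lp(table, margin=1.0)
        assert objective == pytest.approx(3.0, abs=1e-7)
        assert scores.nunique() == 1  # all equal at the optimum

    def test_relabeling_invariance(self):
        rng = np.random.default_rng(0)
        terms, votes = random_tournament_votes(rng)
        table = ar.build_vote_table(vote_rows(*votes))
        _, obj1 = ar.solve_lp(table)
        mapping = dict(zip(terms, ["V", "W", "X", "Y", "Z"]))
        renamed = [(mapping[w], mapping[l], c) for w, l, c in votes]
        _, obj2 = ar.solve_lp(ar.build_vote_table(vote_rows(*renamed)))
        assert obj1 == pytest.approx(obj2, rel=1e-7)

    def test_per_vote_objective_doubles_with_vote_counts(self):
        votes = [("A", "B", 3), ("B", "A", 1), ("B", "C", 2), ("C", "A", 2)]
        doubled = [(w, l, 2 * c) for w, l, c in votes]
        t1 = ar.build_vote_table(vote_rows(*votes))
        t2 = ar.build_vote_table(vote_rows(*doubled))
        _, obj1 = ar.solve_lp(t1, weight_scheme="per_vote")
        _, obj2 = ar.solve_lp(t2, weight_scheme="per_vote")
        assert obj2 == pytest.approx(2 * obj1, rel=1e-7)
        order1 = ar.LPSeverityRanker(weight_scheme="per_vote").fit(t1).ranking_["term"]
        order2 = ar.LPSeverityRanker(weight_scheme="per_vote").fit(t2).ranking_["term"]
        assert list(order1) == list(order2)

    def test_zero_objective_iff_acyclic_majorities(self):
        rng = np.random.default_rng(7)
        for _ in range(40):
            n = int(rng.integers(3, 7))
            _, votes = random_tournament_votes(rng, n=n, p_observed=1.0, max_weight=3)
            table = ar.build_vote_table(vote_rows(*votes))
            _, objective = ar.solve_lp(table)
            digraph = nx.DiGraph(
                (row["majority"], row["adr_b"] if row["majority"] == row["adr_a"] else row["adr_a"])
                for _, row in table.iterrows()
                if row["weight"] > 0
            )
            acyclic = nx.is_directed_acyclic_graph(digraph)
            assert (objective < 1e-7) == acyclic

    def test_disconnected_graph_errors_unless_allowed(self):
        table = ar.build_vote_table(vote_rows(("A", "B", 1), ("C", "D", 1)))
        with pytest.raises(DataError):
            ar.solve_lp(table)
        scores, _ = ar.solve_lp(table, allow_disconnected=True)
        assert scores["A"] > scores["B"] and scores["C"] > scores["D"]

    def test_bad_margin_rejected(self):
        table = ar.build_vote_table(vote_rows(("A", "B", 1)))
        with pytest.raises(ConfigError):
            ar.solve_lp(table, margin=0.0)


class TestInducedOrderOracle:
    def test_never_below_brute_force_and_usually_optimal(self):
        """The ranking's weighted disagreement vs exhaustive permutation search."""
        rng = np.random.default_rng(42)
        matches = 0
        n_instances = 30
        for _ in range(n_instances):
            terms, votes = random_tournament_votes(rng)
            if not votes:
                continue
            table = ar.build_vote_table(vote_rows(*votes))
            ranker = ar.LPSeverityRanker().fit(table)
            net = net_margins(table)
            achieved = weighted_disagreement(list(ranker.ranking_["term"]), net)
            best = min(weighted_disagreement(list(p), net) for p in permutations(terms))
            assert achieved >= best - 1e-9
            matches += achieved == pytest.approx(best, abs=1e-9)
        assert matches >= 0.8 * n_instances

    def test_refine_order_never_increases_disagreement(self):
        rng = np.random.default_rng(3)
        terms, votes = random_tournament_votes(rng, n=8, p_observed=0.8)
        net = net_margins(ar.build_vote_table(vote_rows(*votes)))
        start = list(rng.permutation(terms))
        refined = refine_order(start, net)
        assert weighted_disagreement(refined, net) <= weighted_disagreement(start, net)
        assert sorted(refined) == sorted(terms)


class TestPercentiles:
    @pytest.mark.parametrize(
        "rank,n,expected",
        [(1, 100, 100.0), (100, 100, 1.0), (146, 2929, 95.0495), (1, 1, 100.0)],
    )
    def test_convention(self, rank, n, expected):
        assert ar.to_percentiles([rank], n)[0] == pytest.approx(expected, abs=0.001)


class TestRanker:
    def test_small_input_is_single_lp_passthrough(self):
        table = ar.build_vote_table(vote_rows(("A", "B", 2), ("B", "C", 2)))
        ranker = ar.LPSeverityRanker(sample_size=500).fit(table)
        assert not ranker.is_merged_
        assert list(ranker.ranking_["term"]) == ["A", "B", "C"]
        assert list(ranker.ranking_["rank"]) == [1, 2, 3]
        assert ranker.objective_ == pytest.approx(0.0, abs=1e-9)

    def test_ranking_invariants(self, noisy_study):
        usable = ar.WorkerQCFilter().fit_transform(noisy_study.comparisons)
        ranking = ar.LPSeverityRanker().fit(usable).ranking_
        n = len(ranking)
        assert sorted(ranking["rank"]) == list(range(1, n + 1))
        ordered = ranking.sort_values("rank")
        assert ordered["score"].is_monotonic_decreasing
        assert ordered["percentile"].is_monotonic_decreasing
        assert ranking["score"].between(0, 1).all()
        assert ranking["percentile"].between(0, 100, inclusive="right").all()

    def test_noise_free_single_lp_recovers_latent_order(self):
        world = ar.sample_latent_scores(30, seed=13)
        comps = ar.simulate_full_coverage(
            world, ar.WorkerModel(beta=1e9, spammer_fraction=0.0), seed=14
        )
        ranking = ar.LPSeverityRanker().fit(comps).ranking_
        recovered = list(ranking["term"])
        expected = [world.terms[i] for i in np.argsort(-world.scores)]
        assert recovered == expected

    def test_noise_free_sample_and_merge_recovers_latent_order(self):
        world = ar.sample_latent_scores(80, seed=15)
        comps = ar.simulate_full_coverage(
            world, ar.WorkerModel(beta=1e9, spammer_fraction=0.0), seed=16
        )
        ranker = ar.LPSeverityRanker(sample_size=30, random_state=1).fit(comps)
        assert ranker.is_merged_
        expected = [world.terms[i] for i in np.argsort(-world.scores)]
        assert list(ranker.ranking_["term"]) == expected

    def test_merge_is_stable_across_partition_seeds(self):
        world = ar.sample_latent_scores(200, seed=17)
        study = ar.simulate_study(
            world, n_workers=100, tasks_per_worker=4,
            model=ar.WorkerModel(beta=6.0, spammer_fraction=0.0), seed=18,
        )
        r1 = ar.LPSeverityRanker(sample_size=60, random_state=1).fit(study.comparisons)
        r2 = ar.LPSeverityRanker(sample_size=60, random_state=2).fit(study.comparisons)
        joined = r1.ranking_.set_index("term")["rank"].align(
            r2.ranking_.set_index("term")["rank"], join="inner"
        )
        assert spearmanr(joined[0], joined[1]).statistic >= 0.95

    def test_sklearn_protocol(self):
        ranker = ar.LPSeverityRanker(margin=2.0, sample_size=100)
        cloned = clone(ranker)
        assert cloned.get_params()["margin"] == 2.0
        table = ar.build_vote_table(vote_rows(("A", "B", 1)))
        ranking = cloned.fit_predict(table)
        assert list(ranking.columns) == ["term", "score", "rank", "percentile"]

    def test_empty_input_rejected(self):
        with pytest.raises(DataError):
            ar.LPSeverityRanker().fit(make_comparisons([]))

    def test_ranking_writable_and_readable(self, tmp_path, noisy_study):
        usable = ar.WorkerQCFilter().fit_transform(noisy_study.comparisons)
        ranking = ar.LPSeverityRanker().fit(usable).ranking_
        ar.write_ranking(ranking, tmp_path / "r.tsv")
        back = ar.read_ranking(tmp_path / "r.tsv").frame
        assert list(back["term"]) == list(ranking.sort_values("rank")["term"])
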