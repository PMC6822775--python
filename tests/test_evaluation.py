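from itertools import combinations

import networkx as nx
import numpy as np
import pytest

from phydca.baselines import PairScoreList
from phydca.couplings import CouplingModel, empirical_frequencies, \
    mf_couplings
from phydca.evaluation import (SignedNetwork, build_signed_network,
                               compare_prediction_sets,
                               correlation_vs_distance, enrichment_bins,
                               ppv_curve, significance_threshold,
                               triangle_census)
from phydca.profiles import ProfileMatrix
from phydca.relations import RelationSet
from phydca.simulate import chain_model, gibbs_sample


def score_list(pairs):
    """Ranked list in the given order (descending synthetic scores)."""
    triples = [(i, j, float(len(pairs) - k))
               for k, (i, j) in enumerate(pairs)]
    return PairScoreList.from_unsorted(triples, "coupling", "larger")


def relation_set(pairs):
    rs = RelationSet()
    for a, b in pairs:
        rs.add(a, b, "structure")
    return rs


def model_from_edges(n, edges):
    j = np.zeros((n, n))
    ids = tuple(f"d{i:02d}" for i in range(n))
    for a, b, w in edges:
        j[a, b] = j[b, a] = w
    return CouplingModel(j, np.zeros(n), "mf", {}, ids)


class TestPpvCurve:
    def test_direct_count(self):
        preds = score_list([("a", "b"), ("a", "c"), ("a", "d"), ("b", "c")])
        pos = relation_set([("a", "b"), ("a", "d")])  # ranks 1 and 3
        curve = ppv_curve(preds, pos, 4)
        assert curve[:, 1].tolist() == [1.0, 0.5, 2 / 3, 0.5]

    def test_perfect_ranking_is_constant_one(self):
        pairs = [("a", "b"), ("a", "c"), ("b", "c")]
        curve = ppv_curve(score_list(pairs), relation_set(pairs), 3)
        assert (curve[:, 1] == 1.0).all()

    def test_empty_positives_warns_and_zeroes(self, caplog):
        import logging
        with caplog.at_level(logging.WARNING):
            curve = ppv_curve(score_list([("a", "b")]), RelationSet(), 1)
        assert (curve[:, 1] == 0).all()

    def test_random_ranking_matches_hypergeometric_expectation(self):
        # p positives among n pairs, random order: E[PPV(k)] = p/n
        rng = np.random.default_rng(17)
        doms = [f"d{i:02d}" for i in range(30)]
        all_pairs = list(combinations(doms, 2))
        p, n, k = 60, len(all_pairs), 50
        pos = relation_set(all_pairs[:p])
        reps = 400
        vals = np.empty(reps)
        for t in range(reps):
            order = [all_pairs[i] for i in rng.permutation(n)]
            vals[t] = ppv_curve(score_list(order), pos, k)[-1, 1]
        expected = p / n
        sigma = np.sqrt(expected * (1 - expected) / (k * reps))
        assert abs(vals.mean() - expected) < 3 * sigma * np.sqrt(k)

    def test_ppv_times_k_is_integer(self):
        preds = score_list([("a", "b"), ("a", "c"), ("b", "c"), ("a", "d")])
        curve = ppv_curve(preds, relation_set([("a", "c")]), 4)
        prods = curve[:, 0] * curve[:, 1]
        assert np.allclose(prods, np.round(prods))


class TestEnrichmentBins:
    def test_single_bin_count(self):
        pairs = [(f"a{i:03d}", f"b{i:03d}") for i in range(100)]
        cat = relation_set(pairs[:40])
        bins = enrichment_bins(score_list(pairs), {"cat": cat}, 100)
        assert bins["cat"].tolist() == [40]

    def test_overlapping_categories_both_counted(self):
        pairs = [("a", "b"), ("a", "c")]
        cats = {"x": relation_set([("a", "b")]),
                "y": relation_set([("a", "b"), ("a", "c")])}
        bins = enrichment_bins(score_list(pairs), cats, 2)
        assert bins["x"].tolist() == [1]
        assert bins["y"].tolist() == [2]
        assert bins["x"][0] + bins["y"][0] > 2  # sums may exceed bin size

    def test_empty_category_is_zero(self):
        bins = enrichment_bins(score_list([("a", "b")]),
                               {"none": RelationSet()}, 1)
        assert bins["none"].tolist() == [0]


class TestComparePredictionSets:
    def test_hand_enumeration(self):
        sets = {"A": {("a", "b"), ("a", "c")}, "B": {("a", "b"), ("a", "d")}}
        pos = relation_set([("a", "b")])
        rows = {tuple(r["pattern"].values()): r
                for r in compare_prediction_sets(sets, pos)}
        assert rows[("YES", "YES")]["count"] == 1
        assert rows[("YES", "YES")]["ppv"] == 1.0
        assert rows[("YES", "NO")]["count"] == 1
        assert rows[("YES", "NO")]["true_positives"] == 0
        assert rows[("NO", "YES")]["count"] == 1

    def test_identical_sets_empty_off_diagonal(self):
        s = {("a", "b"), ("a", "c")}
        rows = {tuple(r["pattern"].values()): r
                for r in compare_prediction_sets({"A": s, "B": set(s)},
                                                 RelationSet())}
        assert rows[("YES", "NO")]["count"] == 0
        assert rows[("NO", "YES")]["count"] == 0

    def test_partition_and_aggregation_identities(self):
        rng = np.random.default_rng(23)
        universe = [(f"x{i}", f"y{i}") for i in range(60)]
        sets = {nm: {universe[i] for i in rng.choice(60, 25, replace=False)}
                for nm in ("A", "B", "C")}
        pos = relation_set([universe[i] for i in range(0, 60, 3)])
        rows = {tuple(r["pattern"].values()): r
                for r in compare_prediction_sets(sets, pos)}
        union = set().union(*sets.values())
        fully = [rows[p] for p in rows if "-" not in p]
        assert sum(r["count"] for r in fully) == len(union)
        # aggregation: (YES, -, -) = sum over fully specified with A=YES
        agg = rows[("YES", "-", "-")]["count"]
        parts = sum(rows[("YES", b, c)]["count"]
                    for b in ("YES", "NO") for c in ("YES", "NO"))
        assert agg == parts == len(sets["A"])


class TestSignificanceThreshold:
    def test_step_function_positives_on_top(self):
        n = 40
        j = np.zeros((n, n))
        ids = tuple(f"d{i:02d}" for i in range(n))
        pairs = list(combinations(range(n), 2))
        rng = np.random.default_rng(1)
        scores = np.sort(rng.random(len(pairs)))[::-1]
        pos = RelationSet()
        for rank, (a, b) in enumerate(pairs):
            j[a, b] = j[b, a] = scores[rank]
            if rank < 500:
                pos.add(ids[a], ids[b], "structure")
        model = CouplingModel(j, np.zeros(n), "mf", {}, ids)
        result = significance_threshold(model, pos, window=100)
        assert result["rank"] == 500
        assert result["threshold"] == pytest.approx(scores[499])

    def test_scattered_positives_give_no_threshold(self):
        n = 30
        rng = np.random.default_rng(2)
        j = rng.random((n, n)) * 0.1
        j = (j + j.T) / 2
        np.fill_diagonal(j, 0)
        ids = tuple(f"d{i:02d}" for i in range(n))
        pairs = list(combinations(ids, 2))
        pos = RelationSet()
        for a, b in pairs[:: len(pairs) // 20]:  # ~5% scattered everywhere
            pos.add(a, b, "structure")
        model = CouplingModel(j, np.zeros(n), "mf", {}, ids)
        result = significance_threshold(model, pos, window=100)
        assert result["threshold"] is None

    def test_empty_positives_rejected(self):
        model = model_from_edges(3, [(0, 1, 0.5)])
        with pytest.raises(ValueError, match="empty"):
            significance_threshold(model, RelationSet())


class TestSignedNetwork:
    def test_thresholding_keeps_signs(self):
        model = model_from_edges(3, [(0, 1, 0.4), (0, 2, -0.35),
                                     (1, 2, 0.1)])
        net = build_signed_network(model, 0.3)
        assert net.n_positive == 1 and net.n_negative == 1
        assert net.graph["d00"]["d02"]["sign"] == -1

    def test_threshold_above_max_gives_empty_network(self):
        model = model_from_edges(3, [(0, 1, 0.4)])
        assert build_signed_network(model, 1.0).graph.number_of_edges() == 0

    def test_edge_count_monotone_in_threshold(self):
        rng = np.random.default_rng(3)
        j = rng.normal(size=(20, 20))
        j = (j + j.T) / 2
        np.fill_diagonal(j, 0)
        model = CouplingModel(j, np.zeros(20), "mf", {},
                              tuple(f"d{i:02d}" for i in range(20)))
        counts = [build_signed_network(model, t).graph.number_of_edges()
                  for t in (0.2, 0.5, 1.0, 2.0)]
        assert counts == sorted(counts, reverse=True)


class TestTriangleCensus:
    def test_two_negative_one_positive(self):
        model = model_from_edges(3, [(0, 1, -0.5), (0, 2, -0.5),
                                     (1, 2, 0.5)])
        census = triangle_census(build_signed_network(model, 0.3))
        assert census["+--"] == 1
        assert census["negative_edges_in_triangles"] == 2

    def test_complete_positive_k4(self):
        edges = [(a, b, 1.0) for a, b in combinations(range(4), 2)]
        census = triangle_census(build_signed_network(
            model_from_edges(4, edges), 0.3))
        assert census["+++"] == 4

    def test_matches_brute_force_on_random_signed_graphs(self):
        rng = np.random.default_rng(29)
        for trial in range(5):
            n = int(rng.integers(10, 50))
            g = nx.gnp_random_graph(n, 0.2, seed=int(rng.integers(1 << 30)))
            sn = nx.Graph()
            for u, v in g.edges:
                w = float(rng.choice([-1.0, 1.0]) * rng.uniform(0.5, 2.0))
                sn.add_edge(f"d{u:02d}", f"d{v:02d}", weight=w,
                            sign=1 if w > 0 else -1)
            net = SignedNetwork(sn, 0.4)
            census = triangle_census(net)
            brute = {"+++": 0, "++-": 0, "+--": 0, "---": 0}
            for a, b, c in combinations(sorted(sn.nodes), 3):
                if sn.has_edge(a, b) and sn.has_edge(a, c) \
                        and sn.has_edge(b, c):
                    signs = sorted([sn[a][b]["sign"], sn[a][c]["sign"],
                                    sn[b][c]["sign"]], reverse=True)
                    brute["".join("+" if s > 0 else "-"
                                  for s in signs)] += 1
            assert {k: census[k] for k in brute} == brute

    def test_relabeling_invariance(self):
        model = model_from_edges(4, [(0, 1, 1.0), (1, 2, -1.0), (0, 2, 1.0),
                                     (2, 3, 1.0)])
        census1 = triangle_census(build_signed_network(model, 0.5))
        perm = [3, 1, 0, 2]
        j2 = model.J[np.ix_(perm, perm)]
        model2 = CouplingModel(j2, np.zeros(4), "mf", {},
                               tuple(model.domain_ids[k] for k in perm))
        census2 = triangle_census(build_signed_network(model2, 0.5))
        assert census1 == census2


class TestCorrelationVsDistance:
    def test_chain_correlation_decays_with_distance(self):
        planted = chain_model([1.8] * 5, h=-0.5)
        ppm = gibbs_sample(planted, 3000, burn_in=500, thin=5, seed=31)
        model = mf_couplings(empirical_frequencies(ppm), 0.01)
        net = build_signed_network(model, 0.5)
        profile = correlation_vs_distance(net, ppm, d_max=3)
        assert profile[1][0] > profile[2][0]

    def test_empty_network_puts_all_pairs_in_baseline(self, random_ppm):
        net = SignedNetwork(nx.Graph(), 1.0)
        profile = correlation_vs_distance(net, random_ppm)
        assert profile["baseline"][1] == 45  # all C(10, 2) domain pairs

    def test_single_edge_network(self, random_ppm):
        g = nx.Graph()
        g.add_edge("d00", "d01", weight=1.0, sign=1)
        profile = correlation_vs_distance(SignedNetwork(g, 0.5), random_ppm)
        assert profile[1][1] == 1
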