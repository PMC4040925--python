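import itertools
import math
from fractions import Fraction

import networkx as nx
import numpy as np
import pytest

from fccskit.stats_network import (
    DynamicsProfile,
    EdgeRecord,
    NearFarDataset,
    ScoreCohort,
    build_network,
    co_dynamics_distance,
    find_ternary_complexes,
    infer_mutual_exclusivity,
    median_association_test,
    near_far_coupled_test,
    near_far_uncoupled_test,
)
from fccskit.synthetic import make_network_fixture, simulate_score_cohorts

# ---------------------------------------------------------------------------
# independent brute-force oracles


def oracle_median_test_p(pair, neg):
    """Exact hypergeometric tail for the pooled-median 2x2 split."""
    pooled = sorted(list(pair) + list(neg))
    n = len(pooled)
    grand = (
        pooled[n // 2] if n % 2 else (pooled[n // 2 - 1] + pooled[n // 2]) / 2
    )
    a = sum(1 for v in pair if v > grand)
    c = sum(1 for v in neg if v > grand)
    above = a + c
    n1, n2 = len(pair), len(neg)
    total = math.comb(n1 + n2, above)
    acc = Fraction(0)
    for k in range(a, min(n1, above) + 1):
        if above - k <= n2:
            acc += Fraction(math.comb(n1, k) * math.comb(n2, above - k), total)
    return float(acc)


def oracle_signed_rank_p(diff, alternative):
    """Full 2^n sign-flip enumeration of the signed-rank statistic."""
    diff = np.asarray(diff, float)
    ranks = np.argsort(np.argsort(np.abs(diff))) + 1.0
    w_obs = float(np.sum(ranks[diff > 0]))
    n = diff.size
    ws = []
    for signs in itertools.product([0, 1], repeat=n):
        ws.append(float(np.sum(ranks[np.array(signs, bool)])))
    ws = np.array(ws)
    p_greater = np.mean(ws >= w_obs)
    p_less = np.mean(ws <= w_obs)
    if alternative == "greater":
        return p_greater
    if alternative == "less":
        return p_less
    return min(1.0, 2 * min(p_greater, p_less))


def oracle_rank_sum_p(s1, s2, alternative):
    """Full combinatorial enumeration of the rank-sum statistic."""
    pooled = np.concatenate([s1, s2])
    n1 = len(s1)
    ranks = np.argsort(np.argsort(pooled)) + 1.0
    w_obs = float(np.sum(ranks[:n1]))
    ws = [float(np.sum(ranks[list(idx)])) for idx in itertools.combinations(range(len(pooled)), n1)]
    ws = np.array(ws)
    p_greater = np.mean(ws >= w_obs)
    p_less = np.mean(ws <= w_obs)
    if alternative == "greater":
        return p_greater
    if alternative == "less":
        return p_less
    return min(1.0, 2 * min(p_greater, p_less))


def oracle_maximal_cliques(graph, min_size=3):
    """Exhaustive subset search for maximal cliques."""
    nodes = sorted(graph.nodes)
    cliques = []
    for r in range(1, len(nodes) + 1):
        for sub in itertools.combinations(nodes, r):
            if all(graph.has_edge(a, b) for a, b in itertools.combinations(sub, 2)):
                cliques.append(set(sub))
    maximal = [c for c in cliques if not any(c < other for other in cliques)]
    return sorted(tuple(sorted(c)) for c in maximal if len(c) >= min_size)


# ---------------------------------------------------------------------------


class TestMedianAssociationTest:
    def test_complete_separation(self):
        res = median_association_test([2, 3, 4, 5], [0, 0, 0, 1])
        assert res.table == ((4, 0), (0, 4))
        assert res.p_value == pytest.approx(1 / 70, rel=1e-9)

    def test_identical_cohorts(self):
        res = median_association_test([1, 2, 3, 4], [1, 2, 3, 4])
        assert res.table == ((2, 2), (2, 2))
        assert res.p_value == pytest.approx(53 / 70, rel=1e-9)

    def test_extreme_separation_saturates(self):
        rng = np.random.default_rng(0)
        pair = rng.normal(100, 1, 30)
        neg = rng.normal(0, 1, 30)
        assert median_association_test(pair, neg).p_value < 1e-4

    def test_all_identical_degenerate(self):
        res = median_association_test([1.0, 1.0, 1.0], [1.0, 1.0])
        assert res.degenerate
        assert res.p_value == 1.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            median_association_test([], [1.0])

    def test_matches_oracle_randomized(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            n1 = int(rng.integers(2, 7))
            n2 = int(rng.integers(2, 7))
            pair = rng.normal(rng.uniform(-1, 1), 1, n1)
            neg = rng.normal(0, 1, n2)
            res = median_association_test(pair, neg)
            assert res.p_value == pytest.approx(oracle_median_test_p(pair, neg), abs=1e-12)

    def test_type_i_error_calibration(self):
        # shift = 0: p < 0.05 in at most 8% of 200 seeded runs
        hits = 0
        for seed in range(200):
            pair, neg = simulate_score_cohorts(15, 15, shift=0.0, spread=1.0, seed=seed)
            if median_association_test(pair, neg).p_value < 0.05:
                hits += 1
        assert hits / 200 <= 0.08

    def test_power_at_large_shift(self):
        hits = 0
        for seed in range(100):
            pair, neg = simulate_score_cohorts(30, 30, shift=5.0, spread=1.0, seed=1000 + seed)
            if median_association_test(pair, neg).p_value < 1e-4:
                hits += 1
        assert hits >= 95


class TestNearFarCoupledTest:
    def test_identical_degenerate(self):
        s = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        res = near_far_coupled_test(NearFarDataset("p", s, s))
        assert res["degenerate"]
        assert res["two-sided"] == 1.0

    def test_all_positive_differences_exact(self):
        near = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        far = np.zeros(6)
        res = near_far_coupled_test(NearFarDataset("p", near, far))
        assert res["greater"] == pytest.approx(1 / 64, rel=1e-12)

    def test_symmetric_differences(self):
        near = np.array([1.0, 2.0, 3.0, 0.0, 0.0, 0.0])
        far = np.array([0.0, 0.0, 0.0, 1.0, 2.0, 3.0])
        res = near_far_coupled_test(NearFarDataset("p", near, far))
        assert res["two-sided"] == pytest.approx(1.0, abs=1e-9)

    def test_matches_signed_rank_oracle(self):
        rng = np.random.default_rng(2)
        for _ in range(25):
            n = int(rng.integers(4, 9))
            diff = rng.normal(0.3, 1.0, n)
            res = near_far_coupled_test(NearFarDataset("p", diff, np.zeros(n)))
            for alt in ("two-sided", "greater", "less"):
                assert res[alt] == pytest.approx(oracle_signed_rank_p(diff, alt), abs=1e-12)

    def test_unpaired_rejected(self):
        with pytest.raises(ValueError):
            NearFarDataset("p", np.ones(5), np.ones(4))


class TestNearFarUncoupledTest:
    def test_identical_samples(self):
        s = np.array([1.0, 2.0, 3.0, 4.0])
        res = near_far_uncoupled_test(s, s)
        assert res["two-sided"] == pytest.approx(1.0)

    def test_complete_separation_exact(self):
        res = near_far_uncoupled_test([10.0, 11.0, 12.0], [1.0, 2.0, 3.0])
        assert res["greater"] == pytest.approx(0.05, rel=1e-12)

    def test_matches_permutation_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            s1 = rng.normal(0.5, 1.0, 4)
            s2 = rng.normal(0.0, 1.0, 4)
            res = near_far_uncoupled_test(s1, s2)
            for alt in ("two-sided", "greater", "less"):
                assert res[alt] == pytest.approx(oracle_rank_sum_p(s1, s2, alt), abs=1e-12)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            near_far_uncoupled_test([], [1.0])


class TestBuildNetwork:
    def _records(self):
        return [
            EdgeRecord("A", "B", 1e-5, 0.001),
            EdgeRecord("A", "C", 0.0001, 0.001),  # exactly at threshold
            EdgeRecord("B", "C", 1e-6, 0.5),  # fails secondary
            EdgeRecord("C", "D", 0.5, 0.5),
        ]

    def test_strict_thresholds(self):
        net = build_network(self._records(), p_primary=1e-4, p_secondary=0.02)
        assert net.edges == [("A", "B")]
        # all proteins stay as nodes even without passing edges
        assert net.nodes == ["A", "B", "C", "D"]

    def test_primary_only_fallback(self):
        records = [EdgeRecord("A", "B", 1e-5), EdgeRecord("A", "C", 0.01)]
        net = build_network(records, p_primary=1e-4, p_secondary=0.02)
        assert net.edges == [("A", "B")]

    def test_duplicate_pair_rejected(self):
        records = [EdgeRecord("A", "B", 0.1), EdgeRecord("B", "A", 0.2)]
        with pytest.raises(ValueError, match="duplicate"):
            build_network(records, p_primary=1.0)

    def test_self_pair_rejected(self):
        with pytest.raises(ValueError):
            build_network([EdgeRecord("A", "A", 0.1)], p_primary=1.0)


class TestTernaryComplexes:
    def test_fixture_cliques(self):
        fixture = make_network_fixture()
        graph = nx.Graph(fixture.edges)
        graph.add_nodes_from(fixture.nodes)
        cliques = find_ternary_complexes(graph)
        assert cliques == [
            ("CAS", "FAK", "paxillin"),
            ("ILK", "PINCH", "α-parvin"),
        ]

    def test_empty_graph(self):
        assert find_ternary_complexes(nx.Graph()) == []

    def test_complete_graph(self):
        assert find_ternary_complexes(nx.complete_graph(4)) == [(0, 1, 2, 3)]

    def test_matches_exhaustive_search_small_graphs(self):
        # all graphs on 5 labeled nodes
        nodes = list(range(5))
        pairs = list(itertools.combinations(nodes, 2))
        for mask in range(1 << len(pairs)):
            graph = nx.Graph()
            graph.add_nodes_from(nodes)
            graph.add_edges_from(p for i, p in enumerate(pairs) if mask >> i & 1)
            assert find_ternary_complexes(graph) == oracle_maximal_cliques(graph)


class TestMutualExclusivity:
    def test_fixture_records(self):
        fixture = make_network_fixture()
        graph = nx.Graph(fixture.edges)
        graph.add_nodes_from(fixture.nodes)
        records = infer_mutual_exclusivity(graph)
        assert ("paxillin", ("FAK", "vinculin")) in records
        assert ("VASP", ("vinculin", "zyxin", "α-actinin")) in records
        assert ("zyxin", ("CAS", "VASP")) in records

    def test_triangle_has_none(self):
        assert infer_mutual_exclusivity(nx.complete_graph(3)) == []

    def test_star_graph(self):
        star = nx.star_graph(3)  # hub 0 with leaves 1, 2, 3
        records = infer_mutual_exclusivity(star)
        assert records == [(0, (1, 2, 3))]

    def test_partners_are_nonadjacent_neighbors(self):
        fixture = make_network_fixture()
        graph = nx.Graph(fixture.edges)
        for hub, partners in infer_mutual_exclusivity(graph):
            for p in partners:
                assert graph.has_edge(hub, p)
            for a, b in itertools.combinations(partners, 2):
                assert not graph.has_edge(a, b)


class TestCoDynamicsDistance:
    def _profile(self, coords):
        return DynamicsProfile(
            {
                name: {"tau_half": th, "mobile_fraction": mf}
                for name, (th, mf) in coords.items()
            }
        )

    def test_hand_computed_distances(self):
        profile = self._profile({"A": (10, 0.5), "B": (20, 0.7), "C": (30, 0.9)})
        proteins, dist = co_dynamics_distance(profile)
        assert proteins == ["A", "B", "C"]
        assert dist[0, 1] == pytest.approx(math.sqrt(2), rel=1e-9)
        assert dist[0, 2] == pytest.approx(2 * math.sqrt(2), rel=1e-9)
        assert np.allclose(dist, dist.T)
        assert np.allclose(np.diag(dist), 0.0)

    def test_identical_proteins_distance_zero(self):
        profile = self._profile({"A": (10, 0.5), "B": (10, 0.5), "C": (30, 0.9)})
        _, dist = co_dynamics_distance(profile)
        assert dist[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_affine_invariance(self):
        p1 = self._profile({"A": (10, 0.5), "B": (20, 0.7), "C": (30, 0.9)})
        p2 = self._profile({"A": (10 / 60, 0.5), "B": (20 / 60, 0.7), "C": (30 / 60, 0.9)})
        _, d1 = co_dynamics_distance(p1)
        _, d2 = co_dynamics_distance(p2)
        assert np.allclose(d1, d2)

    def test_zero_variance_rejected(self):
        profile = self._profile({"A": (10, 0.5), "B": (10, 0.7), "C": (10, 0.9)})
        with pytest.raises(ValueError, match="variance"):
            co_dynamics_distance(profile)

    def test_too_few_proteins_rejected(self):
        with pytest.raises(ValueError):
            co_dynamics_distance(self._profile({"A": (10, 0.5), "B": (20, 0.7)}))

    def test_zscore_normalization(self):
        profile = self._profile({"A": (10, 0.5), "B": (20, 0.7), "C": (30, 0.9), "D": (40, 0.2)})
        proteins, _ = co_dynamics_distance(profile)
        coords = np.array(
            [[profile.medians[p]["tau_half"], profile.medians[p]["mobile_fraction"]] for p in proteins]
        )
        z = (coords - coords.mean(0)) / coords.std(0, ddof=1)
        assert np.allclose(z.mean(0), 0.0, atol=1e-12)
        assert np.allclose(z.std(0, ddof=1), 1.0)


class TestScoreCohortTypes:
    def test_nonfinite_scores_dropped(self):
        cohort = ScoreCohort("A:B", [1.0, math.nan, 2.0])
        assert cohort.scores.size == 2

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            ScoreCohort("A:B", [math.nan])

    def test_bad_location_rejected(self):
        with pytest.raises(ValueError):
            ScoreCohort("A:B", [1.0], location="nowhere")


class TestNullPipelineProperty:
    def test_no_pair_significant_under_null(self):
        # 28 null pairs vs one control; none passes a 0.05/28 bar (fixed seeds)
        _, neg = simulate_score_cohorts(30, 30, shift=0.0, spread=1.0, seed=999)
        p_values = []
        for i in range(28):
            pair, _ = simulate_score_cohorts(20, 30, shift=0.0, spread=1.0, seed=i)
            p_values.append(median_association_test(pair, neg).p_value)
        assert min(p_values) > 0.05 / 28
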