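"""Network measures against brute-force oracles and closed-form examples."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from supplynet.io_model import BipartiteNetwork, DataError, OneModeNetwork, UsageError
from supplynet.netmetrics import (
    degree_centrality,
    density,
    diversity,
    extract_core,
    project_one_mode,
    shared_stats,
)

from conftest import make_supplier


def bip(edges, stores=None):
    stores = stores if stores is not None else sorted({s for s, _ in edges})
    return BipartiteNetwork.from_edges("HSN", stores, edges)


def random_bipartite(rng, n_stores, n_suppliers, p=0.4):
    stores = [f"s{i}" for i in range(n_stores)]
    edges = [
        (s, f"u{j}")
        for s in stores
        for j in range(n_suppliers)
        if rng.random() < p
    ]
    return bip(edges, stores)


# ---------------------------------------------------------------------------
# degree centrality


class TestDegreeCentrality:
    def test_saturation_zero_and_fraction(self):
        net = bip(
            [("a", "u1"), ("a", "u2"), ("a", "u3"), ("b", "u1"), ("b", "u2")],
            stores=["a", "b", "c"],
        )
        ct = degree_centrality(net)
        norm = ct.normalized()
        assert norm["a"] == 100.0
        assert norm["c"] == 0.0
        assert round(norm["b"], 1) == 66.7

    def test_empty_supplier_set_is_flagged(self):
        net = bip([], stores=["a", "b"])
        ct = degree_centrality(net)
        assert not ct.normalized_defined
        assert list(ct.raw()) == [0, 0]
        with pytest.raises(UsageError):
            ct.normalized()

    @pytest.mark.parametrize("seed", range(5))
    def test_two_mode_handshake(self, seed):
        rng = np.random.default_rng(seed)
        net = random_bipartite(rng, 8, 9)
        assert sum(net.store_degree().values()) == net.n_edges
        assert sum(net.supplier_degree().values()) == net.n_edges
        assert degree_centrality(net).raw().sum() == net.n_edges


# ---------------------------------------------------------------------------
# core extraction


def brute_force_core(net, threshold):
    """Smallest supplier set covering >= threshold of edges; among minimal
    sets, the one the ranked-prefix rule selects (highest degrees, then
    lexicographic)."""
    deg = net.supplier_degree()
    ranked = sorted(deg, key=lambda u: (-deg[u], u))
    for k in range(1, len(ranked) + 1):
        best = None
        for combo in itertools.combinations(ranked, k):
            cov = sum(deg[u] for u in combo)
            if cov >= threshold * net.n_edges:
                if best is None:
                    best = combo
        if best is not None:
            return k
    return len(ranked)


class TestCore:
    def test_forced_example(self):
        edges = (
            [(f"s{i}", "S1") for i in range(5)]
            + [(f"s{i}", "S2") for i in range(3)]
            + [(f"s{i}", "S3") for i in range(2)]
        )
        core = extract_core(bip(edges), threshold=0.8)
        assert core.core_suppliers == {"S1", "S2"}
        assert core.covered_edge_fraction == pytest.approx(0.8)

    def test_single_dominant_supplier(self):
        core = extract_core(bip([(f"s{i}", "U") for i in range(6)]))
        assert core.size == 1
        assert core.covered_edge_fraction == 1.0

    def test_uniform_degrees_need_eight_of_ten(self):
        edges = [(f"s{j}", f"u{j}") for j in range(10)]
        core = extract_core(bip(edges), threshold=0.8)
        assert core.size == 8 == brute_force_core(bip(edges), 0.8)

    @pytest.mark.parametrize("threshold", [0.0, -0.2, 1.5])
    def test_bad_threshold_is_usage_error(self, threshold):
        with pytest.raises(UsageError):
            extract_core(bip([("a", "u1")]), threshold=threshold)

    def test_empty_network_is_a_data_error(self):
        with pytest.raises(DataError):
            extract_core(bip([], stores=["a"]))

    @pytest.mark.parametrize("seed", range(8))
    def test_core_size_matches_brute_force_and_is_minimal(self, seed):
        rng = np.random.default_rng(100 + seed)
        net = random_bipartite(rng, 6, 7, p=0.5)
        if net.n_edges == 0:
            return
        core = extract_core(net, threshold=0.8)
        assert core.size == brute_force_core(net, 0.8)
        assert core.covered_edge_fraction >= 0.8
        # minimality: dropping the weakest core member breaks coverage
        deg = net.supplier_degree()
        weakest = min(core.core_suppliers, key=lambda u: (deg[u], u))
        remaining = sum(deg[u] for u in core.core_suppliers if u != weakest)
        assert remaining < 0.8 * net.n_edges

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_core_size_monotone_in_threshold(self, seed):
        rng = np.random.default_rng(seed)
        net = random_bipartite(rng, 6, 6, p=0.5)
        if net.n_edges == 0:
            return
        sizes = [extract_core(net, t).size for t in (0.3, 0.5, 0.8, 0.95, 1.0)]
        assert sizes == sorted(sizes)


# ---------------------------------------------------------------------------
# diversity


class TestDiversity:
    def test_counts_distinct_categories(self):
        suppliers = [
            make_supplier(1, category="wholesale_club"),
            make_supplier(2, category="snacks"),
            make_supplier(3, category="snacks"),
        ]
        net = bip([("a", "u01"), ("a", "u02"), ("a", "u03")], stores=["a", "iso"])
        assert diversity(net, "a", suppliers) == 2
        assert diversity(net, "iso", suppliers) == 0

    def test_all_seven_categories_reachable(self):
        from supplynet.io_model import CATEGORIES

        suppliers = [
            make_supplier(i + 1, category=c) for i, c in enumerate(CATEGORIES)
        ]
        net = bip([("a", u.supplier_id) for u in suppliers], stores=["a"])
        assert diversity(net, "a", suppliers) == 7

    def test_unknown_store_raises(self):
        net = bip([("a", "u01")])
        with pytest.raises(UsageError):
            diversity(net, "zz", [make_supplier(1)])


# ---------------------------------------------------------------------------
# projection, density, shared stats


def brute_force_projection(net):
    neigh = {s: net.neighbors_of_store(s) for s in net.store_nodes}
    weights = {}
    for a, b in itertools.combinations(sorted(net.store_nodes), 2):
        w = len(neigh[a] & neigh[b])
        if w:
            weights[(a, b)] = w
    return weights


class TestProjection:
    def test_single_shared_supplier(self):
        one = project_one_mode(bip([("a", "s"), ("b", "s")]))
        assert dict(one.weights) == {("a", "b"): 1}

    def test_disjoint_suppliers_no_edge(self):
        one = project_one_mode(bip([("a", "u1"), ("b", "u2")]))
        assert one.n_edges == 0

    @pytest.mark.parametrize("seed", range(10))
    def test_weights_match_brute_force_intersections(self, seed):
        rng = np.random.default_rng(200 + seed)
        net = random_bipartite(rng, 6, 5, p=0.5)
        assert dict(project_one_mode(net).weights) == brute_force_projection(net)


class TestDensity:
    def test_complete_graph_is_100(self):
        nodes = frozenset("abcd")
        weights = {tuple(sorted(p)): 1 for p in itertools.combinations(nodes, 2)}
        assert density(OneModeNetwork(nodes, weights)) == 100.0

    def test_two_of_six_pairs(self):
        net = OneModeNetwork(frozenset("abcd"), {("a", "b"): 1, ("a", "c"): 2})
        assert density(net) == pytest.approx(100.0 * 2 / 6)

    def test_star_projection_is_complete(self):
        bipn = bip([(s, "hub") for s in "abcde"], stores=list("abcde"))
        assert density(project_one_mode(bipn)) == 100.0

    def test_single_node_is_usage_error(self):
        with pytest.raises(UsageError):
            density(OneModeNetwork(frozenset("a"), {}))

    def test_relabel_invariance_and_monotonicity(self):
        net = OneModeNetwork(frozenset("abcd"), {("a", "b"): 1, ("c", "d"): 4})
        relabeled = OneModeNetwork(
            frozenset({"w", "x", "y", "z"}), {("w", "x"): 1, ("y", "z"): 4}
        )
        assert density(net) == density(relabeled)
        denser = OneModeNetwork(
            frozenset("abcd"), {("a", "b"): 1, ("c", "d"): 4, ("a", "c"): 1}
        )
        assert density(denser) > density(net)

    def test_global_supplier_saturates_centrality_and_density(self):
        rng = np.random.default_rng(5)
        net = random_bipartite(rng, 5, 4, p=0.4)
        with_hub = bip(
            list(net.edges) + [(s, "hub") for s in net.store_nodes],
            stores=sorted(net.store_nodes),
        )
        before = degree_centrality(net)
        after = degree_centrality(with_hub)
        if before.normalized_defined:
            assert (after.raw() == before.raw() + 1).all()
        assert density(project_one_mode(with_hub)) == 100.0


class TestSharedStats:
    def test_mean_and_range(self):
        net = OneModeNetwork(
            frozenset("abcd"), {("a", "b"): 3, ("a", "c"): 9, ("b", "c"): 15}
        )
        sh = shared_stats(net)
        assert sh.mean_shared == 9.0
        assert (sh.min_shared, sh.max_shared) == (3, 15)
        assert sh.n_isolates == 1

    def test_empty_edge_set_all_isolates(self):
        sh = shared_stats(OneModeNetwork(frozenset("abcde"), {}))
        assert sh.n_isolates == 5
        assert np.isnan(sh.mean_shared)
        assert sh.min_shared is None and sh.max_shared is None

    def test_one_disconnected_store(self):
        nodes = frozenset("abcd")
        weights = {
            tuple(sorted(p)): 1
            for p in itertools.combinations(sorted(nodes - {"d"}), 2)
        }
        assert shared_stats(OneModeNetwork(nodes, weights)).n_isolates == 1
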