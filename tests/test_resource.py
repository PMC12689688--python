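"""ResourceRank fixed point, connectivity classes, and resource validation."""

import numpy as np
import pytest

from kgvet.ontology import OntologyGraph, OntologyNode
from kgvet.resource import (
    connectivity_class,
    normalize_ranks,
    resource_rank,
    resource_validate,
    summarize_resource,
)
from kgvet.triples import Triple


def graph_of(edges, extra_nodes=(), relational=()):
    ids = {n for e in edges for n in e} | set(extra_nodes)
    ids |= {n for e in relational for n in e[:2]}
    nodes = {n: OntologyNode(n, n) for n in ids}
    return OntologyGraph(nodes, list(edges), list(relational))


def rank_oracle(graph, damping=0.85):
    """Direct linear-system solution of R = (1-d)·1 + d·MᵀR."""
    ids = sorted(graph.union_graph.nodes())
    idx = {n: i for i, n in enumerate(ids)}
    n = len(ids)
    mt = np.zeros((n, n))
    out = dict(graph.union_graph.out_degree())
    for u, v in graph.union_graph.edges():
        mt[idx[v], idx[u]] = 1.0 / out[u]
    sol = np.linalg.solve(np.eye(n) - damping * mt, (1 - damping) * np.ones(n))
    return {nid: sol[idx[nid]] for nid in ids}


class TestResourceRank:
    def test_directed_cycle_has_uniform_rank_one(self):
        g = graph_of([], relational=[("A", "B", "r"), ("B", "C", "r"), ("C", "A", "r")])
        rv = resource_rank(g)
        assert rv.converged
        for v in rv.ranks.values():
            assert v == pytest.approx(1.0, abs=1e-7)

    def test_single_edge_two_node_solution(self):
        g = graph_of([("A", "B")])
        rv = resource_rank(g)
        assert rv["A"] == pytest.approx(0.15, abs=1e-9)
        assert rv["B"] == pytest.approx(0.2775, abs=1e-9)

    def test_complete_digraph_uniform_rank_one(self):
        ids = ["A", "B", "C", "D"]
        edges = [(u, v) for u in ids for v in ids if u != v]
        nodes = {n: OntologyNode(n, n) for n in ids}
        # put the complete digraph in the relational layer (it is cyclic,
        # so it cannot be a hierarchy)
        g = OntologyGraph(nodes, [], [(u, v, "rel") for u, v in edges])
        rv = resource_rank(g)
        for v in rv.ranks.values():
            assert v == pytest.approx(1.0, abs=1e-7)

    def test_matches_linear_system_on_random_digraphs(self):
        rng = np.random.default_rng(17)
        for _ in range(100):
            n = int(rng.integers(2, 11))
            edges = [(f"n{i}", f"n{j}") for i in range(n) for j in range(n)
                     if i != j and rng.random() < 0.3]
            nodes = {f"n{i}": OntologyNode(f"n{i}", f"n{i}") for i in range(n)}
            g = OntologyGraph(nodes, [], [(u, v, "r") for u, v in edges])
            rv = resource_rank(g)
            oracle = rank_oracle(g)
            for nid, want in oracle.items():
                assert rv[nid] == pytest.approx(want, abs=1e-7)

    def test_every_rank_bounded_below_by_one_minus_d(self):
        rng = np.random.default_rng(3)
        edges = [(f"n{i}", f"n{j}") for i in range(12) for j in range(12)
                 if i != j and rng.random() < 0.2]
        g = graph_of([], extra_nodes=[f"n{i}" for i in range(12)],
                     relational=[(u, v, "r") for u, v in edges])
        rv = resource_rank(g, damping=0.85)
        assert all(v >= 0.15 - 1e-12 for v in rv.ranks.values())

    def test_hub_outranks_spokes(self):
        spokes = [f"s{i}" for i in range(6)]
        g = graph_of([], extra_nodes=["hub"] + spokes,
                     relational=[(s, "hub", "r") for s in spokes])
        rv = resource_rank(g)
        assert all(rv["hub"] > rv[s] for s in spokes)

    def test_dangling_mass_dropped_as_printed_but_redistributable(self):
        # A -> B with B dangling: as-printed total rank is 0.4275 < 2,
        # redistribution adds dangling mass back.
        g = graph_of([("A", "B")])
        printed = resource_rank(g, dangling="as_printed")
        redis = resource_rank(g, dangling="redistribute")
        assert sum(printed.ranks.values()) == pytest.approx(0.4275)
        assert sum(redis.ranks.values()) > sum(printed.ranks.values())

    def test_nonconvergence_warns_not_raises(self):
        # one-iteration budget cannot reach the fixed point from all-ones
        rv = resource_rank(graph_of([("A", "B")]), max_iterations=1)
        assert not rv.converged and rv.iterations_used == 1

    def test_invalid_damping_rejected(self, mini_graph):
        with pytest.raises(ValueError):
            resource_rank(mini_graph, damping=1.0)


class TestNormalizeRanks:
    def test_two_point_minmax(self):
        rv = resource_rank(graph_of([("A", "B")]))
        norm = normalize_ranks(rv)
        assert norm["A"] == 0.0 and norm["B"] == 1.0

    def test_uniform_ranks_normalize_to_one(self):
        rv = resource_rank(graph_of(
            [], relational=[("A", "B", "r"), ("B", "C", "r"), ("C", "A", "r")]))
        assert set(normalize_ranks(rv).values()) == {1.0}

    def test_three_point_minmax(self):
        from kgvet.resource import RankVector
        rv = RankVector({"a": 1.0, "b": 2.0, "c": 3.0}, 0.85, 1, True)
        norm = normalize_ranks(rv)
        assert (norm["a"], norm["b"], norm["c"]) == (0.0, 0.5, 1.0)


class TestConnectivity:
    def test_direct_edge_either_direction(self, mini_graph):
        assert connectivity_class("drug_a", "htn", mini_graph) == "direct"
        assert connectivity_class("htn", "drug_a", mini_graph) == "direct"
        # 1-hop is_a is also direct (precedence over hierarchy roles)
        assert connectivity_class("htn", "cond", mini_graph) == "direct"

    def test_sibling_via_shared_parent(self, mini_graph):
        assert connectivity_class("drug_a", "drug_b", mini_graph) == "sibling"

    def test_parent_and_child_roles_beyond_one_hop(self, mini_graph):
        assert connectivity_class("root", "htn", mini_graph) == "parent"
        assert connectivity_class("htn", "root", mini_graph) == "child"

    def test_indirect_two_hop_path(self):
        g = graph_of([], extra_nodes=["A", "X", "B"],
                     relational=[("A", "X", "r"), ("X", "B", "r")])
        assert connectivity_class("A", "B", g, max_hops=2) == "indirect"
        assert connectivity_class("A", "B", g, max_hops=1) == "none"

    def test_disconnected_components_are_none(self, mini_graph):
        assert connectivity_class("iso", "htn", mini_graph) == "none"

    def test_unknown_node_rejected(self, mini_graph):
        with pytest.raises(KeyError):
            connectivity_class("ghost", "htn", mini_graph)


class TestResourceValidate:
    def test_unmatched_endpoint_flags_and_zeroes(self, mini_graph):
        rv = resource_rank(mini_graph)
        res = resource_validate(Triple("nothing here", "r", "nor here"),
                                mini_graph, rv)
        assert res.flagged and not res.resource_valid and res.score == 0.0

    def test_matched_sibling_pair_scores_mean_of_norm_ranks(self, mini_graph):
        rv = resource_rank(mini_graph)
        norm = normalize_ranks(rv)
        res = resource_validate(Triple("ACE inhibitors", "similar to", "beta blockers"),
                                mini_graph, rv)
        assert not res.flagged and res.resource_valid
        assert res.connectivity == "sibling"
        want = (norm["drug_a"] + norm["drug_b"]) / 2
        assert res.score == pytest.approx(want)

    def test_min_combiner(self, mini_graph):
        rv = resource_rank(mini_graph)
        norm = normalize_ranks(rv)
        res = resource_validate(Triple("ACE inhibitors", "r", "Hypertension"),
                                mini_graph, rv, combiner="min")
        assert res.score == pytest.approx(min(norm["drug_a"], norm["htn"]))

    def test_disconnected_pair_not_resource_valid(self, mini_graph):
        rv = resource_rank(mini_graph)
        res = resource_validate(Triple("isolated thing", "r", "Hypertension"),
                                mini_graph, rv)
        assert not res.flagged
        assert res.connectivity == "none" and not res.resource_valid


class TestSummary:
    def test_counts_and_mean(self, mini_graph):
        rv = resource_rank(mini_graph)
        triples = [
            Triple("ACE inhibitors", "r", "beta blockers", triple_id="a"),
            Triple("ACE inhibitors", "r", "Hypertension", triple_id="b"),
            Triple("ACE inhibitors", "r", "mystery", triple_id="c"),
            Triple("isolated thing", "r", "Hypertension", triple_id="d"),
        ]
        results = [resource_validate(t, mini_graph, rv) for t in triples]
        s = summarize_resource(results)
        assert s.flagged_count == 1
        assert s.valid_fraction == 0.5  # a and b valid; c flagged; d disconnected
        assert s.scores.n == 3  # flagged excluded from score pool by default
        incl = summarize_resource(results, include_flagged=True)
        assert incl.scores.n == 4
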