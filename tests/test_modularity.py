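"""Modularity index, simulated annealing, consensus, and node roles."""

import numpy as np
import pytest

from hummnet import (
    Graph,
    Partition,
    SASchedule,
    bipartite_to_graph,
    classify_role,
    consensus_partition,
    modularity_index,
    modularity_significance,
    node_roles,
    sa_modularity,
)

from .conftest import best_partition_exhaustive, make_matrix, modularity_networkx

FAST = SASchedule(cooling=0.95)


class TestGraphConstruction:
    def test_bipartite_to_graph_counts(self):
        mat = make_matrix(np.ones((2, 2)))
        g = bipartite_to_graph(mat)
        assert g.n_nodes == 4 and g.n_edges == 4
        assert g.guild["fam01"] == "plant_family" and g.guild["clade01"] == "bird_clade"

    def test_edge_count_equals_links(self, rng):
        from .conftest import random_matrix

        mat = random_matrix(rng, 6, 5, 0.4)
        assert bipartite_to_graph(mat).n_edges == mat.n_links

    def test_self_loop_rejected(self):
        with pytest.raises(ValueError):
            Graph(("a", "b"), (("a", "a"),))


class TestModularityIndex:
    def test_single_module_is_zero(self, two_triangles):
        assert modularity_index(two_triangles, {n: 0 for n in two_triangles.nodes}) == pytest.approx(0.0)

    def test_two_triangles_closed_form(self, two_triangles):
        membership = dict(zip("abcdef", [0, 0, 0, 1, 1, 1]))
        assert modularity_index(two_triangles, membership) == pytest.approx(0.5)

    def test_split_single_edge(self):
        g = Graph(("u", "v"), (("u", "v"),))
        assert modularity_index(g, {"u": 0, "v": 1}) == pytest.approx(-0.5)

    def test_matches_networkx_on_random_partitions(self, rng):
        g = two_random_graph(rng, 10, 0.4)
        for _ in range(20):
            membership = {n: int(rng.integers(0, 3)) for n in g.nodes}
            blocks = {}
            for n, m in membership.items():
                blocks.setdefault(m, set()).add(n)
            assert modularity_index(g, membership) == pytest.approx(
                modularity_networkx(g.edges, list(blocks.values())), abs=1e-12
            )

    def test_edge_fractions_partition_unity(self, rng):
        g = two_random_graph(rng, 9, 0.5)
        membership = {n: int(rng.integers(0, 3)) for n in g.nodes}
        within = sum(1 for u, v in g.edges if membership[u] == membership[v])
        between = g.n_edges - within
        assert within / g.n_edges + between / g.n_edges == pytest.approx(1.0)


def two_random_graph(rng, n, p):
    nodes = tuple(f"n{i}" for i in range(n))
    edges = []
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < p:
                edges.append((nodes[i], nodes[j]))
    if not edges:
        edges = [(nodes[0], nodes[1])]
    return Graph(nodes, tuple(edges))


class TestSimulatedAnnealing:
    def test_two_triangles_recovered(self, two_triangles, rng):
        part = sa_modularity(two_triangles, rng, FAST)
        assert part.m_index == pytest.approx(0.5)
        assert part.n_modules == 2
        assert part.membership["a"] == part.membership["b"] == part.membership["c"]

    def test_complete_bipartite_cannot_beat_single_module(self, rng):
        g = bipartite_to_graph(make_matrix(np.ones((3, 3))))
        part = sa_modularity(g, rng, FAST)
        assert part.m_index == pytest.approx(0.0, abs=1e-12)

    def test_deterministic_under_seed(self, two_triangles):
        a = sa_modularity(two_triangles, np.random.default_rng(5), FAST)
        b = sa_modularity(two_triangles, np.random.default_rng(5), FAST)
        assert a.membership == b.membership and a.m_index == b.m_index

    def test_never_below_single_module(self, rng):
        for _ in range(10):
            g = two_random_graph(rng, 8, 0.4)
            assert sa_modularity(g, rng, FAST).m_index >= -1e-12

    def test_matches_exhaustive_optimum_small_graphs(self, rng):
        refined = SASchedule(cooling=0.95, kicks=10)
        for _ in range(15):
            n = int(rng.integers(4, 8))
            g = two_random_graph(rng, n, 0.45)
            best_m, _ = best_partition_exhaustive(g)
            part = sa_modularity(g, rng, refined)
            assert part.m_index == pytest.approx(best_m, abs=1e-9)

    def test_invalid_schedule_rejected(self):
        with pytest.raises(ValueError):
            SASchedule(cooling=1.2)

    def test_m_index_consistent_with_definition(self, rng):
        g = two_random_graph(rng, 10, 0.35)
        part = sa_modularity(g, rng, FAST)
        assert part.m_index == pytest.approx(modularity_index(g, part.membership))


class TestConsensus:
    def test_unanimous_runs_fully_assigned(self, two_triangles, rng):
        cons = consensus_partition(two_triangles, n_runs=8, rng=rng, schedule=FAST)
        assert cons.sd_m == pytest.approx(0.0)
        assert all(m is not None for m in cons.assigned_modules.values())
        assert cons.module_count_distribution == {2: 1.0}

    def test_unstable_node_unassigned(self):
        # synthetic runs: node x alternates between the two cores
        nodes = ("a", "b", "x", "c", "d")
        g = Graph(nodes, (("a", "b"), ("a", "x"), ("x", "c"), ("c", "d")))
        runs = []
        for k in range(10):
            side = 0 if k % 2 == 0 else 1
            membership = {"a": 0, "b": 0, "c": 1, "d": 1, "x": side}
            runs.append(Partition(membership, 2, modularity_index(g, membership)))
        cons = _consensus_from_runs(g, runs, threshold=0.9)
        assert cons.assigned_modules["x"] is None
        assert cons.assigned_modules["a"] is not None

    def test_label_permutation_invariant_co_membership(self):
        nodes = ("a", "b", "c", "d")
        g = Graph(nodes, (("a", "b"), ("c", "d"), ("b", "c")))
        m1 = {"a": 0, "b": 0, "c": 1, "d": 1}
        m2 = {"a": 5, "b": 5, "c": 2, "d": 2}  # same partition, relabeled
        runs = [Partition(m, 2, modularity_index(g, m)) for m in (m1, m2)]
        cons = _consensus_from_runs(g, runs, threshold=0.9)
        assert cons.co_membership[frozenset(("a", "b"))] == 1.0
        assert cons.co_membership[frozenset(("a", "c"))] == 0.0


def _consensus_from_runs(graph, runs, threshold):
    """Drive the consensus logic with pre-built runs via monkeypatched SA."""
    import hummnet.modules as mod

    calls = iter(runs)
    original = mod.sa_modularity
    mod.sa_modularity = lambda g, rng, schedule=None: next(calls)
    try:
        return consensus_partition(graph, n_runs=len(runs), threshold=threshold,
                                   rng=np.random.default_rng(0))
    finally:
        mod.sa_modularity = original


class TestNodeRoles:
    def test_internal_node_has_zero_participation(self, two_triangles, rng):
        part = sa_modularity(two_triangles, rng, FAST)
        roles = node_roles(two_triangles, part)
        assert all(r.c == 0.0 for r in roles.values())

    def test_even_split_participation(self):
        g = Graph(("hub", "a", "b"), (("hub", "a"), ("hub", "b")))
        part = Partition({"hub": 0, "a": 1, "b": 2}, 3, modularity_index(g, {"hub": 0, "a": 1, "b": 2}))
        roles = node_roles(g, part)
        assert roles["hub"].c == pytest.approx(0.5)

    def test_degenerate_module_z_is_zero(self, two_triangles, rng):
        part = sa_modularity(two_triangles, rng, FAST)
        roles = node_roles(two_triangles, part)
        assert all(r.z == 0.0 and r.role == "peripheral" for r in roles.values())

    @pytest.mark.parametrize(
        "z, c, expected",
        [
            (0.0, 0.0, "peripheral"),
            (2.5, 0.62, "peripheral"),  # ties fall low
            (1.0, 0.7, "connector"),
            (3.0, 0.3, "module_hub"),
            (3.0, 0.8, "network_hub"),
            (2.51, 0.63, "network_hub"),
        ],
    )
    def test_role_quadrants(self, z, c, expected):
        assert classify_role(z, c) == expected


class TestGeneralistRoles:
    def test_generalist_core_clades_are_network_hubs(self):
        # with a dense generalist core, the highest-degree guild nodes land
        # in the network-hub quadrant (z > 2.5 and c > 0.62)
        from hummnet.reconstruct import study_matrix

        mat = study_matrix(native_only=True)
        g = bipartite_to_graph(mat)
        schedule = SASchedule(cooling=0.9, t_final_factor=1e-2, moves_per_temp=2000)
        part = sa_modularity(g, np.random.default_rng(7), schedule)
        roles = node_roles(g, part)
        degrees = dict(zip(mat.cols, mat.col_degrees()))
        top_two = sorted(degrees, key=degrees.get, reverse=True)[:2]
        for clade in top_two:
            assert roles[clade].role == "network_hub", (clade, roles[clade])


class TestSignificance:
    def test_random_matrix_not_strongly_modular(self, rng):
        from .conftest import random_matrix

        mat = random_matrix(rng, 10, 8, 0.45)
        g = bipartite_to_graph(mat)
        cons = consensus_partition(g, n_runs=5, rng=rng, schedule=FAST)
        sig = modularity_significance(mat, cons, rng, n_er=15, n_ff=15, schedule=FAST)
        for ens in sig.values():
            assert abs(ens.ses) < 5  # no runaway effect on ER data
            assert 0 < ens.p_value <= 1

    def test_block_structure_detected(self, rng):
        # two disconnected bipartite blocks: strongly modular
        cells = np.zeros((8, 8), dtype=np.int8)
        cells[:4, :4] = 1
        cells[4:, 4:] = 1
        mat = make_matrix(cells)
        g = bipartite_to_graph(mat)
        cons = consensus_partition(g, n_runs=5, rng=rng, schedule=FAST)
        assert cons.mean_m == pytest.approx(0.5)
        sig = modularity_significance(mat, cons, rng, n_er=20, n_ff=2, schedule=FAST)
        assert sig["ER"].observed > sig["ER"].null_mean
        assert sig["ER"].p_value < 0.05
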