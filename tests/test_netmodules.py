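import itertools
import math

import networkx as nx
import numpy as np
import pytest

from adnet.graphio import GeneNetwork
from adnet.netmodules import (
    MclParams,
    McodeParams,
    ModulePartition,
    compare_partitions,
    mcl,
    mcode,
    module_score,
    network_entropy,
    partition_entropy,
    read_partition,
    write_partition,
)


class TestNetworkEntropy:
    def test_complete_graph_is_ln_n(self, k4):
        assert network_entropy(k4).entropy == pytest.approx(math.log(4), abs=1e-12)

    def test_star_hand_value(self):
        # K_{1,3}: I = (1/2, 1/6, 1/6, 1/6) -> E = 1.242453...
        net = GeneNetwork.from_edges([("H", "A"), ("H", "B"), ("H", "C")])
        expected = -(0.5 * math.log(0.5) + 3 * (1 / 6) * math.log(1 / 6))
        rep = network_entropy(net)
        assert rep.entropy == pytest.approx(expected, abs=1e-12)
        assert rep.entropy == pytest.approx(1.2425, abs=1e-4)

    def test_edgeless_errors(self):
        net = GeneNetwork()
        net.add_node("A")
        with pytest.raises(ValueError, match="entropy undefined"):
            network_entropy(net)

    def test_zero_degree_nodes_excluded_and_counted(self):
        net = GeneNetwork.from_edges([("A", "B")])
        net.add_node("C")
        rep = network_entropy(net)
        assert rep.n_zero_degree == 1 and rep.n_nodes == 2
        assert rep.entropy == pytest.approx(math.log(2), abs=1e-12)


class TestPartitionEntropy:
    def test_single_module_reduces_to_network_entropy(self, k4):
        part = ModulePartition(modules={"m": k4.nodes})
        assert partition_entropy(k4, part).entropy == pytest.approx(math.log(4))

    def test_two_triangle_modules(self, two_triangles):
        part = ModulePartition(
            modules={"1": {"A", "B", "C"}, "2": {"X", "Y", "Z"}}
        )
        # six nodes of uniform degree 2 -> ln 6
        assert partition_entropy(two_triangles, part).entropy == pytest.approx(
            math.log(6), abs=1e-12
        )

    def test_partial_partition_drops_absent_module(self, two_triangles):
        part = ModulePartition(modules={"1": {"A", "B", "C"}})
        assert partition_entropy(two_triangles, part).entropy == pytest.approx(
            math.log(3), abs=1e-12
        )

    def test_cross_module_edges_are_orphaned(self):
        net = GeneNetwork.from_edges([("A", "B"), ("B", "C"), ("C", "D"), ("D", "A")])
        part = ModulePartition(modules={"1": {"A", "B"}, "2": {"C", "D"}})
        # only edges AB and CD survive -> 4 nodes of degree 1 -> ln 4
        assert partition_entropy(net, part).entropy == pytest.approx(math.log(4))

    def test_foreign_member_errors(self, k4):
        part = ModulePartition(modules={"m": {"A", "NOPE"}})
        with pytest.raises(ValueError, match="absent"):
            partition_entropy(k4, part)


class TestMcode:
    def test_planted_clique_with_pendant_edges(self):
        clique = [f"K{i}" for i in range(6)]
        edges = list(itertools.combinations(clique, 2))
        edges += [(f"P{i}", f"Q{i}") for i in range(6)]  # pendant pairs, no 2-core
        part = mcode(GeneNetwork.from_edges(edges))
        assert part.modules["1"] == set(clique)
        assert part.scores["1"] == pytest.approx(6.0)
        assert part.n_modules == 1  # pendant edges removed by haircut

    def test_path_has_no_two_core(self):
        net = GeneNetwork.from_edges([("A", "B"), ("B", "C")])
        assert mcode(net).n_modules == 0

    def test_scores_equal_density_times_size(self):
        rng = np.random.default_rng(12)
        g = nx.gnp_random_graph(40, 0.2, seed=4)
        net = GeneNetwork.from_edges([(f"N{u}", f"N{v}") for u, v in g.edges])
        part = mcode(net)
        for mid, members in part.modules.items():
            sub = net.to_networkx().subgraph(members)
            n, e = sub.number_of_nodes(), sub.number_of_edges()
            assert part.scores[mid] == pytest.approx(2 * e / (n * (n - 1)) * n)

    def test_modules_pairwise_disjoint(self):
        g = nx.gnp_random_graph(60, 0.15, seed=9)
        net = GeneNetwork.from_edges([(f"N{u}", f"N{v}") for u, v in g.edges])
        part = mcode(net)
        seen = set()
        for members in part.modules.values():
            assert not (seen & members)
            seen |= members

    def test_haircut_off_keeps_pendant_pairs(self):
        net = GeneNetwork.from_edges([("A", "B")])
        part = mcode(net, McodeParams(haircut=False, min_core=1))
        assert part.modules["1"] == {"A", "B"}


class TestMcl:
    def test_disconnected_triangles_stay_separate(self, two_triangles):
        part = mcl(two_triangles)
        assert part.n_modules == 2
        assert {frozenset(m) for m in part.modules.values()} == {
            frozenset("ABC"), frozenset("XYZ")
        }

    def test_single_edge_is_one_cluster(self):
        part = mcl(GeneNetwork.from_edges([("A", "B")]))
        assert part.modules == {"1": {"A", "B"}}

    @pytest.mark.parametrize("inflation", [1.5, 2.0, 3.0])
    def test_k_disjoint_cliques_give_k_modules(self, inflation):
        edges = []
        truth = []
        for k in range(4):
            nodes = [f"C{k}_{i}" for i in range(5)]
            truth.append(frozenset(nodes))
            edges += itertools.combinations(nodes, 2)
        part = mcl(GeneNetwork.from_edges(edges), MclParams(inflation=inflation))
        assert {frozenset(m) for m in part.modules.values()} == set(truth)

    def test_planted_partition_recovery(self):
        # 2 blocks of 20, p_in 0.9, p_out 0.02: >=95% of node pairs
        # correctly co-clustered vs the planted labels
        g = nx.planted_partition_graph(2, 20, 0.9, 0.02, seed=1)
        net = GeneNetwork.from_edges([(f"N{u:02d}", f"N{v:02d}") for u, v in g.edges])
        part = mcl(net)
        cluster_of = {g_: mid for mid, mem in part.modules.items() for g_ in mem}
        correct = total = 0
        names = sorted(net.nodes)
        for a, b in itertools.combinations(names, 2):
            same_truth = (int(a[1:]) < 20) == (int(b[1:]) < 20)
            same_clust = cluster_of[a] == cluster_of[b]
            correct += same_truth == same_clust
            total += 1
        assert correct / total >= 0.95

    def test_singletons_retained(self):
        net = GeneNetwork.from_edges([("A", "B")])
        net.add_node("Z")
        part = mcl(net)
        assert {"Z"} in part.modules.values()


class TestComparePartitions:
    def test_single_partition_flagged_optimal(self, k4):
        part = ModulePartition(modules={"m": k4.nodes}, method="mcode")
        table = compare_partitions(k4, [part])
        assert bool(table.loc[0, "optimal"])

    def test_rows_sorted_ascending_and_minimum_flagged(self, two_triangles):
        whole = ModulePartition(
            modules={"1": {"A", "B", "C"}, "2": {"X", "Y", "Z"}}, method="both"
        )
        partial = ModulePartition(modules={"1": {"A", "B", "C"}}, method="one")
        table = compare_partitions(two_triangles, [whole, partial])
        assert list(table["method"]) == ["one", "both"]  # ln3 < ln6
        assert list(table["optimal"]) == [True, False]

    def test_tie_flags_both_in_method_order(self, two_triangles):
        a = ModulePartition(modules={"1": {"A", "B", "C"}}, method="zeta")
        b = ModulePartition(modules={"1": {"X", "Y", "Z"}}, method="alpha")
        table = compare_partitions(two_triangles, [a, b])
        assert list(table["method"]) == ["alpha", "zeta"]
        assert table["optimal"].all()


class TestPartitionIO:
    def test_roundtrip(self, tmp_path, two_triangles):
        part = ModulePartition(
            modules={"1": {"A", "B", "C"}, "2": {"X", "Y", "Z"}}, method="mcode",
            scores={"1": 3.0, "2": 3.0},
        )
        path = tmp_path / "part.tsv"
        write_partition(part, path)
        back = read_partition(path, method="external", net=two_triangles)
        assert back.modules == part.modules
        assert back.scores["1"] == pytest.approx(3.0)

    def test_empty_module_rejected(self):
        with pytest.raises(ValueError):
            ModulePartition(modules={"m": set()})

    def test_overlap_rejected_for_detector_methods(self):
        with pytest.raises(ValueError, match="disjoint"):
            ModulePartition(
                modules={"1": {"A", "B"}, "2": {"B", "C"}}, method="mcl"
            )


def test_module_score_of_complete_module(k4):
    assert module_score(k4, k4.nodes) == pytest.approx(4.0)
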