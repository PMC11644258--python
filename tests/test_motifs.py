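"""Motif canonicalization, census, randomization null and NMS scoring."""

from itertools import combinations, permutations

import networkx as nx
import numpy as np
import pytest

from conftest import random_digraph
from seedgrn.containers import DirectedGRN, GRNEdge
from seedgrn.motifs import (
    FFL,
    MOTIF_CLASSES,
    canonical_class,
    census,
    erdos_renyi_null,
    motif_enrichment,
    nms,
    randomize,
    total_motif_instances,
)


def brute_force_census(net: DirectedGRN) -> dict[str, int]:
    """O(n^3) reference: classify every node triple independently."""
    pairs = net.edge_pair_set()
    counts = {name: 0 for name in MOTIF_CLASSES}
    for triple in combinations(sorted(net.nodes), 3):
        arcs = {
            (i, j)
            for i, a in enumerate(triple)
            for j, b in enumerate(triple)
            if i != j and (a, b) in pairs
        }
        cls = canonical_class(arcs)
        if cls is not None:
            counts[cls] += 1
    return counts


class TestCanonicalClass:
    def test_path_isomorphism(self):
        # A->B->C relabeled in reverse is the same directed path class
        assert canonical_class({(0, 1), (1, 2)}) == canonical_class({(2, 1), (1, 0)})

    def test_ffl_differs_from_cycle(self):
        ffl = canonical_class({(0, 1), (0, 2), (1, 2)})
        cycle = canonical_class({(0, 1), (1, 2), (2, 0)})
        assert ffl == FFL
        assert cycle != ffl

    def test_exhaustive_enumeration_yields_13_classes(self):
        arcs_all = [(a, b) for a in range(3) for b in range(3) if a != b]
        classes = set()
        n_connected = 0
        for mask in range(64):
            arcs = {arcs_all[i] for i in range(6) if mask & (1 << i)}
            cls = canonical_class(arcs)
            if cls is not None:
                classes.add(cls)
                n_connected += 1
        assert len(classes) == 13
        assert classes == set(MOTIF_CLASSES)
        assert n_connected == 54  # 64 digraphs minus the 10 disconnected ones

    def test_invariant_under_all_relabelings(self):
        rng = np.random.default_rng(0)
        arcs_all = [(a, b) for a in range(3) for b in range(3) if a != b]
        for _ in range(20):
            mask = int(rng.integers(1, 64))
            arcs = {arcs_all[i] for i in range(6) if mask & (1 << i)}
            base = canonical_class(arcs)
            for perm in permutations(range(3)):
                relabeled = {(perm[a], perm[b]) for a, b in arcs}
                assert canonical_class(relabeled) == base

    def test_self_loop_rejected(self):
        with pytest.raises(ValueError):
            canonical_class({(0, 0), (0, 1)})


class TestCensus:
    def test_single_ffl(self, ffl_net):
        result = census(ffl_net)
        assert result[FFL][0] == 1
        assert result[FFL][1] == [("A", "B", "C")]
        assert sum(c for c, _ in result.values()) == 1

    def test_edgeless_network(self):
        net = DirectedGRN(edges=[], nodes={"A", "B", "C"})
        assert all(c == 0 for c, _ in census(net).values())

    def test_matches_brute_force_on_random_graphs(self):
        for seed in range(10):
            net = random_digraph(12, 25, seed)
            fast = {k: c for k, (c, _) in census(net).items()}
            assert fast == brute_force_census(net)

    def test_matches_networkx_triadic_census(self):
        # independent oracle: networkx's triad census restricted to the
        # 13 connected classes
        for seed in (3, 4):
            net = random_digraph(10, 20, seed)
            g = nx.DiGraph(net.edge_pairs)
            g.add_nodes_from(net.nodes)
            reference = nx.triadic_census(g)
            ours = {k: c for k, (c, _) in census(net).items()}
            for name in MOTIF_CLASSES:
                assert ours[name] == reference[name]

    def test_instances_have_role_consistent_ordering(self):
        # in a feed-forward loop the canonical ordering is
        # (driver, intermediate, common target)
        net = DirectedGRN([GRNEdge("X", "M"), GRNEdge("X", "T"), GRNEdge("M", "T")])
        assert census(net)[FFL][1] == [("X", "M", "T")]


class TestRandomize:
    def test_degree_sequences_conserved(self):
        net = random_digraph(20, 60, 1)
        rand = randomize(net, swap_factor=10, seed=5)
        for n in (net, rand):
            assert len(n.edges) == 60
        def degs(n):
            ins, outs = {}, {}
            for e in n.edges:
                outs[e.source] = outs.get(e.source, 0) + 1
                ins[e.target] = ins.get(e.target, 0) + 1
            return ins, outs
        assert degs(net) == degs(rand)
        assert rand.nodes == net.nodes

    def test_single_edge_pair_without_valid_swap_unchanged(self):
        net = DirectedGRN([GRNEdge("A", "B"), GRNEdge("B", "A")])
        rand = randomize(net, swap_factor=10, seed=0)
        assert rand.edge_pair_set() == {("A", "B"), ("B", "A")}

    def test_mixing_changes_most_edges(self):
        sims = []
        for seed in range(20):
            net = random_digraph(40, 200, 99)
            rand = randomize(net, swap_factor=10, seed=seed)
            a, b = net.edge_pair_set(), rand.edge_pair_set()
            sims.append(len(a & b) / len(a | b))
        assert np.median(sims) < 0.5

    def test_deterministic(self):
        net = random_digraph(15, 40, 2)
        a = randomize(net, 10, seed=3)
        b = randomize(net, 10, seed=3)
        assert a.edges == b.edges

    def test_too_small_rejected(self):
        with pytest.raises(ValueError):
            randomize(DirectedGRN([GRNEdge("A", "B")]), 10, 0)


class TestEnrichment:
    def test_planted_ffls_enriched(self):
        edges = []
        for i in range(30):
            a, b, c = f"a{i}", f"b{i}", f"c{i}"
            edges += [GRNEdge(a, b), GRNEdge(a, c), GRNEdge(b, c)]
        net = DirectedGRN(edges)
        enr = motif_enrichment(net, n_random=200, seed=1)
        by_class = {e.motif_class: e for e in enr}
        assert by_class[FFL].count_real == 30
        assert by_class[FFL].z_score > 3.0
        assert by_class[FFL].enriched

    def test_all_13_classes_reported(self):
        net = random_digraph(10, 15, 0)
        enr = motif_enrichment(net, n_random=20, seed=0)
        assert {e.motif_class for e in enr} == set(MOTIF_CLASSES)

    def test_absent_class_zero_sd_convention(self):
        # two disjoint paths: classes that never occur in network or
        # randomizations report z = 0 and are not enriched
        net = DirectedGRN([GRNEdge("A", "B"), GRNEdge("B", "C"),
                           GRNEdge("D", "E"), GRNEdge("E", "F")])
        enr = motif_enrichment(net, n_random=30, seed=2)
        triple_mutual = [e for e in enr if e.motif_class == "300"][0]
        assert triple_mutual.count_real == 0
        assert triple_mutual.z_score == 0.0
        assert not triple_mutual.enriched

    def test_relabeling_invariance(self):
        net = random_digraph(12, 30, 7)
        mapping = {n: f"node_{n}" for n in sorted(net.nodes)}
        relabeled = net.relabel(mapping)
        a = motif_enrichment(net, n_random=50, seed=11)
        b = motif_enrichment(relabeled, n_random=50, seed=11)
        assert [(e.motif_class, e.count_real, e.z_score) for e in a] == [
            (e.motif_class, e.count_real, e.z_score) for e in b
        ]

    def test_erdos_renyi_null_available(self):
        net = random_digraph(12, 30, 8)
        enr = motif_enrichment(net, n_random=30, seed=0, null_model="erdos_renyi")
        assert len(enr) == 13
        rand = erdos_renyi_null(net, seed=1)
        assert len(rand.edges) == len(net.edges)
        assert rand.nodes == net.nodes

    def test_small_ensemble_rejected(self):
        with pytest.raises(ValueError):
            motif_enrichment(random_digraph(6, 8, 0), n_random=1, seed=0)


class TestNMS:
    def _forced(self, enr, cls):
        out = []
        for e in enr:
            e.enriched = e.motif_class == cls
            out.append(e)
        return out

    def test_single_enriched_instance_scores_all_members(self, ffl_net):
        enr = self._forced(motif_enrichment(ffl_net, n_random=5, seed=0), FFL)
        scores = nms(ffl_net, enr)
        assert scores == {"A": 1, "B": 1, "C": 1}

    def test_shared_node_accumulates(self):
        net = DirectedGRN([
            GRNEdge("A", "B"), GRNEdge("A", "C"), GRNEdge("B", "C"),
            GRNEdge("A", "D"), GRNEdge("A", "E"), GRNEdge("D", "E"),
        ])
        enr = self._forced(motif_enrichment(net, n_random=5, seed=0), FFL)
        scores = nms(net, enr)
        assert scores["A"] >= 2
        assert scores["B"] >= 1 and scores["D"] >= 1

    def test_no_enriched_classes_gives_empty_table(self, ffl_net):
        enr = motif_enrichment(ffl_net, n_random=5, seed=0)
        for e in enr:
            e.enriched = False
        assert nms(ffl_net, enr) == {}


def test_total_instances_counts_connected_triples():
    net = random_digraph(14, 30, 5)
    total = total_motif_instances(net)
    assert total == sum(brute_force_census(net).values())
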