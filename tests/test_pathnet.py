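"""Pruning, membership clustering, network assembly and topology."""

import math

import numpy as np
import pytest

from gwaspathnet.errors import MatrixError
from gwaspathnet.pathnet import (
    Pathway,
    PathwayCollection,
    assemble_network,
    components,
    cut_clusters,
    hclust_complete,
    hub_genes,
    membership_matrix,
    prune_redundant,
    shared_cluster_pathways,
)
from gwaspathnet.snpmap import SnpGeneLink


def pw(pid, name, genes):
    return Pathway(pid, name, frozenset(genes))


def link(snp, gene):
    return SnpGeneLink(snp, gene, "within_gene_unresolved", 0)


class TestPruneRedundant:
    def test_identical_content_similar_name_removes_smaller(self):
        coll = PathwayCollection([
            pw("p1", "glycolysis", ["a", "b", "c"]),
            pw("p2", "glycolysis (minimal)", ["a", "b"]),
        ])
        pruned, removed = prune_redundant(coll, jaccard_min=0.6)
        assert removed == ["p2"]
        assert pruned.ids == ("p1",)

    def test_disjoint_sets_untouched(self):
        coll = PathwayCollection([
            pw("p1", "glycolysis", ["a", "b"]),
            pw("p2", "glycolysis two", ["c", "d"]),
        ])
        _, removed = prune_redundant(coll)
        assert removed == []

    def test_equal_size_tie_removes_larger_id(self):
        coll = PathwayCollection([
            pw("p1", "cycle", ["a", "b"]),
            pw("p2", "cycle copy", ["a", "b"]),
        ])
        _, removed = prune_redundant(coll)
        assert removed == ["p2"]

    def test_name_dissimilarity_blocks_removal(self):
        coll = PathwayCollection([
            pw("p1", "alpha", ["a", "b"]),
            pw("p2", "beta", ["a", "b"]),
        ])
        _, removed = prune_redundant(coll)
        assert removed == []

    def test_strict_jaccard_with_distinct_sets_removes_nothing(self):
        coll = PathwayCollection([
            pw("p1", "same name", ["a", "b", "c"]),
            pw("p2", "same name", ["a", "b"]),
        ])
        _, removed = prune_redundant(coll, jaccard_min=1.0)
        assert removed == []

    def test_lowering_threshold_never_removes_fewer(self):
        rng = np.random.default_rng(3)
        genes = [f"g{i}" for i in range(12)]
        coll = PathwayCollection([
            pw(f"p{i}", f"set {i % 3}", rng.choice(genes, size=5, replace=False))
            for i in range(8)
        ])
        previous = -1
        for j in (1.0, 0.8, 0.5, 0.2, 0.01):
            _, removed = prune_redundant(coll, jaccard_min=j)
            assert len(removed) >= previous
            previous = len(removed)

    def test_planted_redundancy_recovered(self, small_world):
        assert small_world["removed"] == sorted(
            small_world["pathways"].ground_truth["redundant_removed"]
        )
        assert len(small_world["pruned"]) == (
            small_world["pathways"].ground_truth["n_after_prune"]
        )


class TestMembershipMatrix:
    def test_single_pathway_over_universe(self):
        coll = PathwayCollection([pw("p1", "x", ["g1"])])
        m = membership_matrix(coll, gene_universe=["g1", "g2"])
        assert m.values.tolist() == [[1, 0]]
        assert m.gene_ids == ("g1", "g2")

    def test_identical_pathways_identical_rows(self):
        coll = PathwayCollection([pw("p1", "x", ["a", "b"]), pw("p2", "y", ["a", "b"])])
        m = membership_matrix(coll)
        assert (m.values[0] == m.values[1]).all()

    def test_row_sums_are_restricted_sizes(self, small_world):
        pruned = small_world["pruned"]
        universe = sorted(pruned.union_genes())
        m = membership_matrix(pruned, gene_universe=universe)
        for i, pid in enumerate(m.pathway_ids):
            assert m.values[i].sum() == len(pruned[pid].gene_ids & set(universe))

    def test_empty_universe_raises(self):
        coll = PathwayCollection([pw("p1", "x", ["g1"])])
        with pytest.raises(MatrixError):
            membership_matrix(coll, gene_universe=[])


def brute_force_complete_linkage(rows):
    """O(n^3) agglomerative oracle recomputing every cross-pair distance.

    Same tie rule as the implementation (smallest (min rep, max rep)); a
    cluster's representative is its smallest original row index.
    """
    rows = [tuple(r) for r in rows]

    def dist(a, b):
        return math.sqrt(sum((x - y) ** 2 for x, y in zip(rows[a], rows[b])))

    clusters = {i: {i} for i in range(len(rows))}
    merges = []
    while len(clusters) > 1:
        best = None
        for ra in sorted(clusters):
            for rb in sorted(clusters):
                if rb <= ra:
                    continue
                d = max(dist(a, b) for a in clusters[ra] for b in clusters[rb])
                key = (d, ra, rb)
                if best is None or key < best:
                    best = key
        d, ra, rb = best
        merges.append((ra, rb, d))
        clusters[ra] |= clusters.pop(rb)
    return merges


class TestHclustComplete:
    def test_identical_rows_merge_at_zero(self):
        d = hclust_complete(np.array([[1, 0, 1], [1, 0, 1]]))
        assert d.merges == ((0, 1, 0.0),)

    def test_four_bit_difference_height_two(self):
        d = hclust_complete(np.array([[1, 1, 1, 1, 0], [0, 0, 0, 0, 0]]))
        assert d.merges[0][2] == pytest.approx(2.0)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(17)
        for _ in range(200):
            n = int(rng.integers(2, 8))
            m = int(rng.integers(1, 8))
            rows = rng.integers(0, 2, size=(n, m))
            got = hclust_complete(rows).merges
            expected = brute_force_complete_linkage(rows.tolist())
            assert [(i, j) for i, j, _ in got] == [(i, j) for i, j, _ in expected]
            assert all(
                a[2] == pytest.approx(b[2], abs=1e-9) for a, b in zip(got, expected)
            )

    def test_heights_non_decreasing(self):
        rng = np.random.default_rng(23)
        rows = rng.integers(0, 2, size=(12, 6))
        heights = [h for _, _, h in hclust_complete(rows).merges]
        assert heights == sorted(heights)


class TestCutClusters:
    def collection(self):
        return PathwayCollection([
            pw("p1", "one", ["a"]), pw("p2", "two", ["b"]), pw("p3", "three", ["a", "b"]),
        ])

    def test_zero_cut_on_distinct_rows_gives_singletons(self):
        coll = self.collection()
        d = hclust_complete(membership_matrix(coll))
        cs = cut_clusters(d, 0.0, coll)
        assert len(cs) == 3 and cs.n_singleton == 3

    def test_infinite_cut_gives_one_cluster(self):
        coll = self.collection()
        d = hclust_complete(membership_matrix(coll))
        cs = cut_clusters(d, float("inf"), coll)
        assert len(cs) == 1
        (c,) = cs.clusters
        assert c.cluster_id == "cluster:p1"
        assert c.gene_ids == {"a", "b"}
        assert set(c.member_ids) == {"p1", "p2", "p3"}

    def test_clusters_partition_pathways(self, small_world):
        pruned = small_world["pruned"]
        d = hclust_complete(membership_matrix(pruned))
        cs = cut_clusters(d, 1.5, pruned)
        members = [p for c in cs for p in c.member_ids]
        assert sorted(members) == sorted(pruned.ids)


def toy_network():
    links = [link("rs1", "g1"), link("rs2", "g1"), link("rs2", "g2"), link("rs3", "g3")]
    coll = PathwayCollection([
        pw("p1", "one", ["g1", "g2"]), pw("p2", "two", ["g1"]),
        pw("p3", "three", ["g3"]), pw("p4", "unreached", ["gX"]),
    ])
    d = hclust_complete(membership_matrix(coll))
    cs = cut_clusters(d, 0.0, coll)
    return links, cs, assemble_network(links, cs)


class TestAssembleNetwork:
    def test_empty_inputs_empty_network(self):
        coll = PathwayCollection([pw("p1", "one", ["g1"])])
        cs = cut_clusters(hclust_complete(membership_matrix(coll)), 0.0, coll)
        net = assemble_network([], cs)
        assert net.graph.number_of_nodes() == 0

    def test_minimal_network_shape(self):
        coll = PathwayCollection([pw("p1", "one", ["g1"])])
        cs = cut_clusters(hclust_complete(membership_matrix(coll)), 0.0, coll)
        net = assemble_network([link("rs1", "g1")], cs)
        assert net.graph.number_of_nodes() == 3
        assert net.graph.number_of_edges() == 2

    def test_isolated_cluster_excluded(self):
        _, _, net = toy_network()
        assert "p4" not in net.cluster_ids

    def test_counts_match_brute_force_reconstruction(self, small_world):
        links, pruned = small_world["links"], small_world["pruned"]
        cs = cut_clusters(hclust_complete(membership_matrix(pruned)), 0.0, pruned)
        net = assemble_network(links, cs)
        linked_genes = {l.gene_id for l in links}
        expected_edges = len({(l.snp_id, l.gene_id) for l in links}) + sum(
            len(c.gene_ids & linked_genes) for c in cs
        )
        assert net.graph.number_of_edges() == expected_edges
        net.validate()

    def test_degree_conservation(self, small_world):
        links, pruned = small_world["links"], small_world["pruned"]
        cs = cut_clusters(hclust_complete(membership_matrix(pruned)), 0.0, pruned)
        net = assemble_network(links, cs)
        total = sum(net.gene_cluster_degree(g) for g in net.gene_ids)
        n_gc_edges = sum(
            1 for _, _, d in net.graph.edges(data=True)
            if d["relation"] == "gene_pathway"
        )
        assert total == n_gc_edges


class TestHubGenes:
    def build(self, n_clusters, member_gene="g1"):
        coll = PathwayCollection(
            [pw(f"p{i}", f"name{i}", [member_gene, f"f{i}"]) for i in range(n_clusters)]
        )
        cs = cut_clusters(hclust_complete(membership_matrix(coll)), 0.0, coll)
        return assemble_network([link("rs1", member_gene)], cs)

    def test_threshold_inclusive_at_ten(self):
        assert hub_genes(self.build(10)) == [("g1", 10)]
        assert hub_genes(self.build(9)) == []

    def test_planted_hubs_recovered_exactly(self, small_world):
        links, pruned = small_world["links"], small_world["pruned"]
        cs = cut_clusters(hclust_complete(membership_matrix(pruned)), 0.0, pruned)
        net = assemble_network(links, cs)
        hubs = dict(hub_genes(net, min_degree=10))
        assert hubs == small_world["pathways"].ground_truth["hub_memberships"]


class TestComponents:
    def test_partition_and_main_selection(self):
        _, _, net = toy_network()
        main, rest = components(net)
        all_nodes = set(main.graph.nodes)
        for r in rest:
            assert all_nodes.isdisjoint(r.graph.nodes)
            all_nodes |= set(r.graph.nodes)
        assert all_nodes == set(net.graph.nodes)
        assert len(main.graph.nodes) == max(
            len(c.graph.nodes) for c in [main] + rest
        )

    def test_fully_connected_has_no_disconnected(self):
        coll = PathwayCollection([pw("p1", "one", ["g1"])])
        cs = cut_clusters(hclust_complete(membership_matrix(coll)), 0.0, coll)
        net = assemble_network([link("rs1", "g1")], cs)
        _, rest = components(net)
        assert rest == []


class TestSharedClusterPathways:
    def test_single_gene_subset_below_min(self):
        _, _, net = toy_network()
        assert shared_cluster_pathways(net, ["g1"], min_genes=2) == []

    def test_two_genes_sharing_a_cluster(self):
        _, _, net = toy_network()
        rows = shared_cluster_pathways(net, ["g1", "g2"], min_genes=2)
        assert [(r[0], r[2]) for r in rows] == [("p1", 2)]

    def test_counts_match_recount(self, small_world):
        links, pruned = small_world["links"], small_world["pruned"]
        cs = cut_clusters(hclust_complete(membership_matrix(pruned)), 0.0, pruned)
        net = assemble_network(links, cs)
        subset = net.gene_ids[:10]
        for cid, _, count in shared_cluster_pathways(net, subset, min_genes=1):
            assert count == sum(
                1 for g in subset if net.graph.has_edge(g, cid)
            )
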