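"""LD proxy clustering, eQTL Venn partition, and evidence intersection."""

import pytest

from gwaspathnet.errors import ReferentialIntegrityError
from gwaspathnet.evidence import (
    EqtlRecord,
    GxeRecord,
    LdRecord,
    eqtl_venn,
    evidence_intersection,
    independent_snps_per_gene,
    intergenic_eqtl_records,
    ld_proxy_clusters,
    multigene_disease_check,
)
from gwaspathnet.snpmap import GeneSnpGeneModule, Snp, SnpGeneLink, SnpPanel


def panel(*specs):
    return SnpPanel(
        Snp(sid, chrom, pos, population=pop)
        for sid, chrom, pos, pop in specs
    )


THREE = panel(
    ("rsA", "chr1", 1000, "CEU"),
    ("rsB", "chr1", 2000, "CEU"),
    ("rsC", "chr1", 3000, "CEU"),
)


class TestLdProxyClusters:
    def test_no_edges_all_singletons(self):
        clusters = ld_proxy_clusters(THREE, [])
        assert sorted(len(c) for c in clusters) == [1, 1, 1]

    def test_transitive_chain_forms_one_cluster(self):
        ld = [LdRecord("rsA", "rsB", 0.9, 1000), LdRecord("rsB", "rsC", 0.95, 1000)]
        clusters = ld_proxy_clusters(THREE, ld)
        assert {"rsA", "rsB", "rsC"} in clusters
        assert len(clusters) == 1

    def test_r2_boundary_strictly_above(self):
        clusters = ld_proxy_clusters(THREE, [LdRecord("rsA", "rsB", 0.8, 1000)])
        assert len(clusters) == 3

    def test_distance_limit_excludes(self):
        clusters = ld_proxy_clusters(THREE, [LdRecord("rsA", "rsB", 0.99, 500_001)])
        assert len(clusters) == 3

    def test_cross_population_rejected_with_warning(self):
        mixed = panel(("rsA", "chr1", 1000, "CEU"), ("rsB", "chr1", 2000, "MEX"))
        with pytest.warns(UserWarning, match="cross-population"):
            clusters = ld_proxy_clusters(mixed, [LdRecord("rsA", "rsB", 0.95, 1000)])
        assert len(clusters) == 2

    def test_unknown_snp_raises(self):
        with pytest.raises(ReferentialIntegrityError):
            ld_proxy_clusters(THREE, [LdRecord("rsA", "rsZ", 0.9, 10)])

    def test_idempotent_on_representatives(self):
        ld = [LdRecord("rsA", "rsB", 0.9, 1000)]
        clusters = ld_proxy_clusters(THREE, ld)
        reps = sorted(min(c) for c in clusters)
        reclusters = ld_proxy_clusters(
            SnpPanel(s for s in THREE if s.snp_id in reps), []
        )
        assert all(len(c) == 1 for c in reclusters)

    def test_raising_r2_never_merges(self):
        ld = [LdRecord("rsA", "rsB", 0.85, 10), LdRecord("rsB", "rsC", 0.92, 10)]
        previous = 0
        for r2_min in (0.8, 0.84, 0.9, 0.99):
            n = len(ld_proxy_clusters(THREE, ld, r2_min=r2_min))
            assert n >= previous
            previous = n

    def test_planted_groups_recovered(self, small_world):
        clusters = ld_proxy_clusters(small_world["panel"], small_world["bundle"].ld)
        got = sorted(sorted(c) for c in clusters if len(c) > 1)
        assert got == sorted(
            sorted(g) for g in small_world["bundle"].ground_truth["ld_groups"]
        )


class TestIndependentSnpsPerGene:
    def test_one_cluster_counts_once(self):
        links = [SnpGeneLink(f"rs{i}", "g1", "within_gene_unresolved", 0) for i in range(12)]
        clusters = [frozenset(f"rs{i}" for i in range(12))]
        assert independent_snps_per_gene(links, clusters) == {"g1": 1}

    def test_singletons_count_each(self):
        links = [SnpGeneLink(f"rs{i}", "g1", "within_gene_unresolved", 0) for i in range(12)]
        clusters = [frozenset({f"rs{i}"}) for i in range(12)]
        assert independent_snps_per_gene(links, clusters) == {"g1": 12}


RECORDS = [
    EqtlRecord("rs1", "gShared", "pancreas", 0.3, 0.01),
    EqtlRecord("rs1", "gShared", "liver", 0.3, 0.02),
    EqtlRecord("rs2", "gPanc", "pancreas", -0.1, 0.05),   # boundary, included
    EqtlRecord("rs3", "gLiver", "liver", 0.2, 0.049),
    EqtlRecord("rs4", "gNone", "pancreas", 0.2, 0.051),   # above threshold
]


class TestEqtlVenn:
    def test_partition_and_boundary(self):
        venn = eqtl_venn(RECORDS, ["pancreas", "liver"])
        assert venn.region("pancreas", "liver") == {"gShared"}
        assert venn.region("pancreas") == {"gPanc"}
        assert venn.region("liver") == {"gLiver"}
        assert "gNone" not in venn.union

    def test_region_counts_sum_to_union(self):
        venn = eqtl_venn(RECORDS, ["pancreas", "liver"])
        assert sum(len(g) for g in venn.regions.values()) == len(venn.union)

    def test_raising_p_max_never_shrinks(self):
        previous = None
        for p_max in (0.001, 0.01, 0.05, 0.5):
            venn = eqtl_venn(RECORDS, ["pancreas", "liver"], p_max=p_max)
            sets = {t: venn.tissue_genes(t) for t in venn.tissues}
            if previous is not None:
                assert all(previous[t] <= sets[t] for t in sets)
            previous = sets

    def test_planted_center_recovered(self, small_world):
        bundle = small_world["bundle"]
        cfg = small_world["cfg"]
        venn = eqtl_venn(bundle.eqtl, cfg.tissues)
        got = {
            "+".join(sorted(combo)): sorted(genes)
            for combo, genes in venn.regions.items()
        }
        assert got == bundle.ground_truth["venn_regions"]
        center = venn.region(*cfg.tissues)
        assert len(center) == cfg.n_eqtl_shared_all


class TestEvidenceIntersection:
    def test_hub_only_listed_without_triple(self):
        venn = eqtl_venn(RECORDS, ["pancreas", "liver"])
        rows = evidence_intersection(["gHub"], venn, [], {})
        row = next(r for r in rows if r.gene_id == "gHub")
        assert row.in_hub_set and not row.triple

    def test_triple_requires_all_three(self):
        venn = eqtl_venn(RECORDS, ["pancreas", "liver"])
        gxe = [GxeRecord("rs2", "gPanc", "fat", "BMI")]
        rows = evidence_intersection(["gPanc", "gLiver"], venn, gxe, {"gPanc": 0.4})
        by_id = {r.gene_id: r for r in rows}
        assert by_id["gPanc"].triple
        assert not by_id["gLiver"].triple  # hub + eQTL but no GxE
        assert rows[0].gene_id == "gPanc"  # triple sorts first

    def test_empty_inputs_empty_table(self):
        venn = eqtl_venn(RECORDS[-1:], ["pancreas", "liver"])
        assert evidence_intersection([], venn, [], {}) == []

    def test_planted_triples_recovered(self, small_world):
        bundle = small_world["bundle"]
        cfg = small_world["cfg"]
        hubs = [
            small_world["genes"].genes[i].gene_id for i, _ in cfg.hub_spec
        ]
        venn = eqtl_venn(bundle.eqtl, cfg.tissues)
        rows = evidence_intersection(hubs, venn, bundle.gxe, bundle.disease_scores)
        triple = sorted(r.gene_id for r in rows if r.triple)
        assert triple == bundle.ground_truth["triple_genes"]


class TestMultigeneDiseaseCheck:
    def modules_41(self):
        # 19 modules over 41 genes: 16 pairs + 3 triples
        mods = []
        g = 0
        for _ in range(16):
            mods.append(GeneSnpGeneModule(
                snp_ids=frozenset({f"rs{g}"}),
                gene_ids=frozenset({f"m{g}", f"m{g+1}"}),
            ))
            g += 2
        for _ in range(3):
            mods.append(GeneSnpGeneModule(
                snp_ids=frozenset({f"rs{g}", f"rs{g+1}"}),
                gene_ids=frozenset({f"m{g}", f"m{g+1}", f"m{g+2}"}),
            ))
            g += 3
        return mods

    def test_thirteen_of_fortyone_truncates_to_31(self):
        mods = self.modules_41()
        scores = {f"m{i}": 0.2 for i in range(13)}
        report = multigene_disease_check(mods, scores)
        assert report.n_genes_total == 41
        assert report.n_genes_positive == 13
        assert report.pct_positive == 31

    def test_all_zero_scores(self):
        report = multigene_disease_check(self.modules_41(), {})
        assert report.pct_positive == 0

    def test_per_module_recount(self):
        mods = self.modules_41()
        scores = {f"m{i}": 0.5 for i in range(0, 41, 3)}
        report = multigene_disease_check(mods, scores)
        for row in report.rows:
            assert set(row.genes_positive) == {
                g for g in row.module_genes if scores.get(g, 0) > 0
            }

    def test_dual_only_flag(self):
        mods = [GeneSnpGeneModule(
            snp_ids=frozenset({"rsD"}), gene_ids=frozenset({"gKnown", "gOnly"})
        )]
        links = [
            SnpGeneLink("rsD", "gKnown", "within_gene_unresolved", 0),
            SnpGeneLink("rsD", "gOnly", "within_gene_unresolved", 0),
            SnpGeneLink("rsE", "gKnown", "within_gene_unresolved", 0),
        ]
        report = multigene_disease_check(mods, {"gKnown": 0.3}, links=links)
        assert report.dual_only_flags == (("rsD", "gOnly"),)


def test_intergenic_eqtl_filter():
    got = intergenic_eqtl_records(RECORDS, ["rs4", "rs1"])
    assert {r.snp_id for r in got} == {"rs4", "rs1"}
    assert len(got) == 3  # p-value is not filtered in this mode
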