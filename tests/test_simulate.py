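"""Generator determinism, invariants, and planted-truth bookkeeping."""

import dataclasses

import pytest

import gwaspathnet as gp
from gwaspathnet import io as gio
from gwaspathnet.errors import ConfigError
from gwaspathnet.simulate import SimConfig, realistic_scale


def serialize_genes(genes, path):
    gio.write_genes_tsv(genes, path)
    return path.read_bytes()


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"n_intergenic": 200, "n_snps": 100},
            {"n_multigene_snps": 120, "n_snps": 160, "n_intergenic": 50},
            {"gene_length_range": (0, 10)},
            {"gene_length_range": (50, 10)},
            {"hub_spec": ((0, 1000),)},
            {"n_pathways": 4, "n_redundant_pairs": 3},
            {"multigene_module_sizes": (1, 2), "n_multigene_snps": 1},
            {"tissues": ()},
        ],
    )
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ConfigError):
            SimConfig(**kwargs).validate()

    def test_short_gene_range_blocks_overlap_chains(self):
        cfg = SimConfig(gene_length_range=(100, 100), n_multigene_snps=2,
                        multigene_module_sizes=(2, 2))
        with pytest.raises(ConfigError):
            gp.generate_gene_models(cfg)


class TestGeneModels:
    def test_empty_gene_set(self):
        cfg = SimConfig(n_genes=0, n_multigene_snps=0, n_snps=10, n_intergenic=10,
                        hub_spec=())
        assert len(gp.generate_gene_models(cfg)) == 0

    def test_forced_length(self):
        cfg = SimConfig(n_genes=10, gene_length_range=(100, 100),
                        n_multigene_snps=0, n_snps=20, n_intergenic=10, hub_spec=())
        genes = gp.generate_gene_models(cfg)
        assert all(g.length == 100 for g in genes)

    def test_deterministic_serialization(self, tmp_path):
        cfg = SimConfig(seed=1, n_genes=10, n_multigene_snps=0, n_snps=10,
                        n_intergenic=5, hub_spec=(), chrom_length_bp=10**6)
        a = serialize_genes(gp.generate_gene_models(cfg), tmp_path / "a.tsv")
        b = serialize_genes(gp.generate_gene_models(cfg), tmp_path / "b.tsv")
        assert a == b

    def test_chromosome_too_short(self):
        cfg = SimConfig(chrom_length_bp=10_000, n_genes=40, n_chromosomes=1,
                        n_multigene_snps=0, n_snps=40, n_intergenic=0, hub_spec=())
        with pytest.raises(ConfigError, match="chr1"):
            gp.generate_gene_models(cfg)

    def test_overlaps_only_in_planted_chains(self, small_world):
        genes = sorted(small_world["genes"], key=lambda g: (g.chrom, g.start))
        chain_genes = {
            g for m in small_world["panel"].ground_truth["modules"] for g in m["genes"]
        }
        for a, b in zip(genes, genes[1:]):
            if a.chrom == b.chrom and b.start <= a.end:
                assert a.gene_id in chain_genes and b.gene_id in chain_genes


class TestSnpPanel:
    def test_all_intergenic(self):
        cfg = SimConfig(n_snps=30, n_intergenic=30, n_multigene_snps=0, hub_spec=())
        genes = gp.generate_gene_models(cfg)
        panel = gp.generate_snp_panel(cfg, genes)
        _, intergenic = gp.map_snps(panel, genes, cfg.window_bp)
        summary = gp.mapping_summary([], intergenic, panel)
        assert summary.pct_intergenic == 100

    def test_planted_counts_recovered(self, small_world):
        cfg, panel = small_world["cfg"], small_world["panel"]
        links, intergenic = small_world["links"], small_world["intergenic"]
        assert len(intergenic) == cfg.n_intergenic
        assert sorted(intergenic) == sorted(panel.ground_truth["intergenic"])
        multi = {l.snp_id for l in links} & set(panel.ground_truth["multigene"])
        assert len(multi) == cfg.n_multigene_snps
        # every multi-gene SNP maps to exactly its planted gene pair
        per_snp: dict = {}
        for l in links:
            per_snp.setdefault(l.snp_id, set()).add(l.gene_id)
        for sid, planted in panel.ground_truth["multigene"].items():
            assert per_snp[sid] == set(planted)
        for sid, gid in panel.ground_truth["single"].items():
            assert per_snp[sid] == {gid}

    def test_infeasible_multigene_placement(self):
        cfg = SimConfig(n_multigene_snps=0, hub_spec=())
        genes = gp.generate_gene_models(cfg)  # no overlapping genes
        bad = dataclasses.replace(cfg, n_multigene_snps=2,
                                  multigene_module_sizes=(2, 2))
        with pytest.raises(ConfigError, match="overlapping"):
            gp.generate_snp_panel(bad, genes)

    def test_deterministic(self, tmp_path):
        cfg = SimConfig(seed=3)
        genes = gp.generate_gene_models(cfg)
        for name in ("a", "b"):
            gio.write_snp_panel(gp.generate_snp_panel(cfg, genes), tmp_path / name)
        assert (tmp_path / "a").read_bytes() == (tmp_path / "b").read_bytes()


class TestPathways:
    def test_singleton_collection_gmt_roundtrip(self, tmp_path):
        cfg = SimConfig(n_pathways=1, n_redundant_pairs=0, hub_spec=())
        genes = gp.generate_gene_models(cfg)
        coll = gp.generate_pathways(cfg, genes)
        assert len(coll) == 1
        gio.write_gmt(coll, tmp_path / "p.gmt")
        back = gio.read_gmt(tmp_path / "p.gmt")
        assert back.ids == coll.ids
        assert back[coll.ids[0]].gene_ids == coll.pathways[0].gene_ids

    def test_redundant_pairs_share_ninety_pct(self, small_world):
        coll = small_world["pathways"]
        for src_id, dup_id in coll.ground_truth["redundant_pairs"]:
            src, dup = coll[src_id], coll[dup_id]
            assert dup.gene_ids <= src.gene_ids
            assert len(dup.gene_ids) >= 0.9 * len(src.gene_ids)

    def test_hub_membership_exact(self, small_world):
        coll = small_world["pathways"]
        for gid, m in coll.ground_truth["hub_memberships"].items():
            assert sum(1 for p in coll if gid in p.gene_ids) == m

    def test_referential_integrity(self, small_world):
        gene_ids = set(small_world["genes"].ids)
        for p in small_world["pathways"]:
            assert p.gene_ids <= gene_ids


class TestGo:
    def test_full_overlap_config_yields_zero_exclusive(self):
        cfg = SimConfig(go_terms_a=20, go_terms_shared=20)
        genes = gp.generate_gene_models(cfg)
        pw = gp.generate_pathways(cfg, genes)
        in_pw = sorted(pw.union_genes())
        without = sorted(set(genes.ids) - set(in_pw))
        dag, ann = gp.generate_go(cfg, in_pw, without)
        closed = gp.bp_closure(ann, dag)
        res = gp.group_term_comparison(
            {g: t for g, t in closed.items() if g in set(without)},
            {g: t for g, t in closed.items() if g in set(in_pw)},
        )
        assert res.terms_exclusive_A == frozenset()
        assert res.genes_A_exclusive == frozenset()

    def test_flat_dag_when_depth_one(self):
        cfg = SimConfig(go_depth=1)
        genes = gp.generate_gene_models(cfg)
        pw = gp.generate_pathways(cfg, genes)
        in_pw = sorted(pw.union_genes())
        without = sorted(set(genes.ids) - set(in_pw))
        dag, _ = gp.generate_go(cfg, in_pw, without)
        roots = set(dag.roots.values())
        for tid in dag.terms:
            if tid not in roots:
                assert set(dag.parents[tid]) <= roots

    def test_annotations_reference_known_genes_and_terms(self, small_world):
        cfg, genes = small_world["cfg"], small_world["genes"]
        pw = small_world["pathways"]
        in_pw = sorted(pw.union_genes())
        without = sorted(set(genes.ids) - set(in_pw))
        dag, ann = gp.generate_go(cfg, in_pw, without)
        gene_ids = set(genes.ids)
        for g, t in ann.records:
            assert g in gene_ids and t in dag


class TestEvidenceGeneration:
    def test_referential_integrity_enforced(self, small_world):
        small_world["bundle"].check_ids(
            small_world["panel"].ids, small_world["genes"].ids
        )

    def test_scores_in_unit_interval(self, small_world):
        assert all(0 <= s <= 1 for s in small_world["bundle"].disease_scores.values())

    def test_ld_r2_in_bounds(self, small_world):
        assert all(0 <= r.r2 <= 1 for r in small_world["bundle"].ld)

    def test_deterministic(self, small_world):
        again = gp.generate_evidence(
            small_world["cfg"], small_world["panel"], small_world["genes"]
        )
        assert again.eqtl == small_world["bundle"].eqtl
        assert again.ld == small_world["bundle"].ld
        assert again.gxe == small_world["bundle"].gxe
        assert again.disease_scores == small_world["bundle"].disease_scores


def test_realistic_scale_preset_marginals():
    cfg = realistic_scale()
    cfg.validate()
    assert cfg.n_snps == 1971 and cfg.n_intergenic == 716
    assert cfg.n_pathways == 460 and cfg.n_redundant_pairs == 36
    assert sum(m - 1 for m in cfg.multigene_module_sizes) == cfg.n_multigene_snps
    assert sum(cfg.multigene_module_sizes) == 41
    assert len(cfg.multigene_module_sizes) == 19
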