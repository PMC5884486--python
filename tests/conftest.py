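import time

import pytest

import gwaspathnet as gp
from gwaspathnet.pathnet import (
    assemble_network,
    cut_clusters,
    hclust_complete,
    membership_matrix,
)
from gwaspathnet.simulate import REALISTIC_SCALE_CUT_HEIGHT, realistic_scale


@pytest.fixture(scope="session")
def small_world():
    """Default-scale synthetic study with all stage outputs."""
    cfg = gp.SimConfig(seed=7)
    genes = gp.generate_gene_models(cfg)
    panel = gp.generate_snp_panel(cfg, genes)
    links, intergenic = gp.map_snps(panel, genes, cfg.window_bp)
    pathways = gp.generate_pathways(cfg, genes)
    pruned, removed = gp.prune_redundant(pathways)
    bundle = gp.generate_evidence(cfg, panel, genes)
    return {
        "cfg": cfg, "genes": genes, "panel": panel, "links": links,
        "intergenic": intergenic, "pathways": pathways, "pruned": pruned,
        "removed": removed, "bundle": bundle,
    }


@pytest.fixture(scope="session")
def study_world():
    """Realistic-scale synthetic study, computed once through every stage."""
    t0 = time.monotonic()
    cfg = realistic_scale()
    genes = gp.generate_gene_models(cfg)
    panel = gp.generate_snp_panel(cfg, genes)
    links, intergenic = gp.map_snps(panel, genes, cfg.window_bp)
    summary = gp.mapping_summary(links, intergenic, panel)
    modules = gp.multigene_structures(links)
    pathways = gp.generate_pathways(cfg, genes)
    pruned, removed = gp.prune_redundant(pathways)
    mapped = {l.gene_id for l in links}
    matrix = membership_matrix(pruned, gene_universe=sorted(pruned.union_genes() & mapped))
    dendro = hclust_complete(matrix)
    cluster_set = cut_clusters(dendro, REALISTIC_SCALE_CUT_HEIGHT, pruned)
    network = assemble_network(links, cluster_set)
    in_pw = sorted(pruned.union_genes() & set(genes.ids))
    without = sorted(set(genes.ids) - set(in_pw))
    dag, annotations = gp.generate_go(cfg, in_pw, without)
    closed = gp.bp_closure(annotations, dag)
    comparison = gp.group_term_comparison(
        {g: t for g, t in closed.items() if g in set(without)},
        {g: t for g, t in closed.items() if g in set(in_pw)},
    )
    bundle = gp.generate_evidence(cfg, panel, genes)
    disease = gp.multigene_disease_check(modules, bundle.disease_scores, links=links)
    elapsed = time.monotonic() - t0
    return {
        "cfg": cfg, "genes": genes, "panel": panel, "links": links,
        "intergenic": intergenic, "summary": summary, "modules": modules,
        "pathways": pathways, "pruned": pruned, "removed": removed,
        "cluster_set": cluster_set, "network": network, "dag": dag,
        "annotations": annotations, "closed": closed, "comparison": comparison,
        "bundle": bundle, "disease": disease, "elapsed_s": elapsed,
    }
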