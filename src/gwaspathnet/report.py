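"""Pipeline orchestration: one config in, all artifacts and a summary out.

Stages run in order simulate? -> snpmap -> pathnet -> gocompare ->
evidence.  Every intermediate table is written to the output directory,
and the final :class:`RunSummary` collects the headline counts — mapping
marginals, pathway/cluster counts, hub list, disconnected components,
gene-SNP-gene modules, GO comparison, eQTL Venn regions and the
triple-evidence genes — together with provenance (input hashes,
parameters, seed), so every number is re-derivable from the stage files
shipped alongside it.
"""

from __future__ import annotations

import hashlib
import logging
import time
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Optional

import yaml

from . import io as gio
from .errors import ConfigError
from .evidence import (
    eqtl_venn,
    evidence_intersection,
    independent_snps_per_gene,
    intergenic_eqtl_records,
    ld_proxy_clusters,
    multigene_disease_check,
)
from .gocompare import bp_closure, exclusive_bipartite, group_term_comparison
from .pathnet import (
    assemble_network,
    components,
    cut_clusters,
    hclust_complete,
    hub_genes,
    membership_matrix,
    prune_redundant,
)
from .simulate import (
    SimConfig,
    generate_evidence,
    generate_gene_models,
    generate_go,
    generate_pathways,
    generate_snp_panel,
)
from .snpmap import map_snps, mapping_summary, multigene_structures

logger = logging.getLogger("gwaspathnet")


@dataclass
class RunSummary:
    """Headline counts of one pipeline run; see the summary JSON artifact."""

    mapping: dict
    n_pathways_input: int
    n_pathways_pruned: int
    n_clusters: int
    n_clusters_multi: int
    n_clusters_singleton: int
    hub_genes: list
    n_disconnected: int
    n_modules: int
    module_disease_pct: Optional[int]
    go_comparison: Optional[dict]
    venn: Optional[dict]
    triple_genes: list
    provenance: dict

    def to_dict(self) -> dict:
        return asdict(self)

    def to_table(self) -> str:
        """Human-readable run summary, one category per line."""
        rows = [
            ("SNPs total", self.mapping.get("n_snps_total")),
            ("SNPs intergenic", f"{self.mapping.get('n_intergenic')} "
                                f"({self.mapping.get('pct_intergenic')}%)"),
            ("SNPs in/near genes", self.mapping.get("n_genic")),
            ("Genes hit", self.mapping.get("n_genes_hit")),
            ("Pathways (input)", self.n_pathways_input),
            ("Pathways after pruning", self.n_pathways_pruned),
            ("Pathway clusters", f"{self.n_clusters} "
                                 f"({self.n_clusters_multi} multi + "
                                 f"{self.n_clusters_singleton} singleton)"),
            ("Hub genes (>=10 clusters)", len(self.hub_genes)),
            ("Disconnected subnetworks", self.n_disconnected),
            ("Gene-SNP-gene modules", self.n_modules),
            ("Module genes with disease score", f"{self.module_disease_pct}%"
             if self.module_disease_pct is not None else "n/a"),
            ("Triple-evidence genes", ", ".join(self.triple_genes) or "none"),
        ]
        if self.go_comparison:
            rows += [
                ("GO terms (no-pathway group)", self.go_comparison["n_terms_A"]),
                ("GO terms shared", self.go_comparison["n_terms_shared"]),
                ("GO terms exclusive", self.go_comparison["n_terms_exclusive_A"]),
                ("Genes with exclusive terms", self.go_comparison["n_genes_A_exclusive"]),
            ]
        width = max(len(r[0]) for r in rows)
        return "\n".join(f"{k:<{width}}  {v}" for k, v in rows)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _load_config(config) -> dict:
    if isinstance(config, (str, Path)):
        with open(config) as fh:
            return yaml.safe_load(fh)
    return dict(config)


def default_cut_height(dendrogram) -> float:
    """Half the maximum merge height — the default dendrogram cut."""
    if not dendrogram.merges:
        return 0.0
    return 0.5 * max(h for _, _, h in dendrogram.merges)


def run_pipeline(config, out_dir, seed: Optional[int] = None) -> RunSummary:
    """Execute the full pipeline from a config dict or YAML path.

    ``config`` either contains a ``simulate`` section (a
    :class:`~gwaspathnet.simulate.SimConfig` field mapping) or an
    ``inputs`` section of file paths.  ``seed`` overrides the simulation
    seed.  All artifacts land in ``out_dir``; the summary is returned and
    written as ``summary.json`` plus a readable ``summary.txt``.
    """
    cfg = _load_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.monotonic()

    snp_cfg = cfg.get("snpmap", {}) or {}
    path_cfg = cfg.get("pathnet", {}) or {}
    go_cfg = cfg.get("gocompare", {}) or {}
    ev_cfg = cfg.get("evidence", {}) or {}
    window_bp = int(snp_cfg.get("window_bp", 1000))

    ground_truth = None
    if "simulate" in cfg:
        sim_fields = dict(cfg["simulate"] or {})
        if seed is not None:
            sim_fields["seed"] = seed
        for key in ("gene_length_range", "pathway_size_range", "tissues",
                    "ld_proxy_group_sizes", "multigene_module_sizes"):
            if key in sim_fields and sim_fields[key] is not None:
                sim_fields[key] = tuple(
                    tuple(x) if isinstance(x, list) else x for x in sim_fields[key]
                )
        if "hub_spec" in sim_fields and sim_fields["hub_spec"] is not None:
            sim_fields["hub_spec"] = tuple(tuple(h) for h in sim_fields["hub_spec"])
        sim = SimConfig(**sim_fields)
        window_bp = int(snp_cfg.get("window_bp", sim.window_bp))
        t = time.monotonic()
        genes = generate_gene_models(sim)
        panel = generate_snp_panel(sim, genes)
        pathways = generate_pathways(sim, genes)
        logger.info("stage=simulate elapsed=%.2fs", time.monotonic() - t)
        gio.write_snp_panel(panel, out / "snps.tsv")
        gio.write_genes_bed(genes, out / "genes.bed")
        gio.write_genes_tsv(genes, out / "genes.tsv")
        gio.write_gmt(pathways, out / "pathways.gmt")
        tissues = list(ev_cfg.get("tissues", sim.tissues))
    elif "inputs" in cfg:
        inp = cfg["inputs"]
        missing = [k for k in ("snps", "genes", "gmt") if k not in inp]
        if missing:
            raise ConfigError(f"inputs section missing: {missing}")
        for key, p in inp.items():
            if not Path(p).exists():
                raise ConfigError(f"input file for {key!r} not found: {p}")
        panel = gio.read_snp_panel(inp["snps"])
        gene_path = str(inp["genes"])
        genes = gio.read_genes_bed(gene_path) if gene_path.endswith(".bed") \
            else gio.read_genes_tsv(gene_path)
        pathways = gio.read_gmt(inp["gmt"])
        sim = None
        tissues = list(ev_cfg.get("tissues", ()))
    else:
        raise ConfigError("config needs a 'simulate' or an 'inputs' section")

    # ---- snpmap ------------------------------------------------------- #
    t = time.monotonic()
    if len(panel) == 0:
        links, intergenic = [], []
    else:
        links, intergenic = map_snps(panel, genes, window_bp)
    summary = mapping_summary(links, intergenic, panel)
    modules = multigene_structures(links)
    logger.info("stage=snpmap elapsed=%.2fs", time.monotonic() - t)
    gio.write_links(links, out / "links.tsv")
    (out / "intergenic.txt").write_text("".join(s + "\n" for s in intergenic))
    gio.write_json(summary.to_dict(), out / "mapping_summary.json")
    gio.write_modules(modules, out / "modules.tsv")

    # ---- pathnet ------------------------------------------------------ #
    t = time.monotonic()
    pruned, removed = prune_redundant(
        pathways,
        jaccard_min=float(path_cfg.get("jaccard_min", 0.9)),
        name_overlap_min=float(path_cfg.get("name_overlap_min", 0.5)),
    )
    mapped_genes = {l.gene_id for l in links}
    universe = sorted(pruned.union_genes() & mapped_genes)
    if universe:
        matrix = membership_matrix(pruned, gene_universe=universe)
        dendro = hclust_complete(matrix)
        cut = path_cfg.get("cut_height")
        cut = default_cut_height(dendro) if cut is None else float(cut)
        cluster_set = cut_clusters(dendro, cut, pruned)
        network = assemble_network(links, cluster_set)
        hubs = hub_genes(network, min_degree=int(path_cfg.get("hub_min_degree", 10)))
        main, disconnected = components(network)
        n_clusters = len(cluster_set)
        n_multi, n_single = cluster_set.n_multi, cluster_set.n_singleton
        gio.write_sif(network, out / "network.sif")
        gio.write_graphml(network, out / "network.graphml")
        gio.write_json(
            {
                "main": main.composition(),
                "disconnected": [c.composition() for c in disconnected],
            },
            out / "components.json",
        )
        with open(out / "hubs.tsv", "w") as fh:
            fh.write("gene_id\tcluster_degree\n")
            for g, d in hubs:
                fh.write(f"{g}\t{d}\n")
        with open(out / "clusters.tsv", "w") as fh:
            fh.write("cluster_id\tmember_pathways\tn_genes\n")
            for c in cluster_set:
                fh.write(f"{c.cluster_id}\t{';'.join(c.member_ids)}\t{len(c.gene_ids)}\n")
    else:
        network, hubs, disconnected = None, [], []
        n_clusters = n_multi = n_single = 0
    logger.info("stage=pathnet elapsed=%.2fs", time.monotonic() - t)

    # ---- gocompare ---------------------------------------------------- #
    t = time.monotonic()
    genes_in_pathways = sorted(pruned.union_genes() & set(genes.ids))
    genes_without = sorted(set(genes.ids) - set(genes_in_pathways))
    go_result = None
    if sim is not None:
        dag, annotations = generate_go(sim, genes_in_pathways, genes_without)
        gio.write_obo(dag, out / "go.obo")
        gio.write_gaf(annotations, dag, out / "annotations.gaf.tsv")
    elif "obo" in cfg.get("inputs", {}) and "gaf" in cfg["inputs"]:
        dag = gio.read_obo(cfg["inputs"]["obo"])
        annotations = gio.read_gaf(cfg["inputs"]["gaf"])
    else:
        dag = annotations = None
    if dag is not None:
        closed = bp_closure(annotations, dag, closure=bool(go_cfg.get("closure", True)))
        group_a = {g: ts for g, ts in closed.items() if g in set(genes_without)}
        group_b = {g: ts for g, ts in closed.items() if g in set(genes_in_pathways)}
        comparison = group_term_comparison(group_a, group_b)
        go_result = comparison.to_dict()
        bip = exclusive_bipartite(comparison, closed)
        gio.write_json(go_result, out / "go_comparison.json")
        gio.write_sif(bip, out / "go_exclusive.sif")
    logger.info("stage=gocompare elapsed=%.2fs", time.monotonic() - t)

    # ---- evidence ----------------------------------------------------- #
    t = time.monotonic()
    venn_dict = None
    triple: list[str] = []
    disease_pct = None
    if sim is not None:
        bundle = generate_evidence(sim, panel, genes)
        gio.write_eqtl(bundle.eqtl, out / "eqtl.tsv")
        gio.write_ld(bundle.ld, out / "ld.tsv")
        gio.write_scores(bundle.disease_scores, out / "disease_scores.tsv")
        gio.write_gxe(bundle.gxe, out / "gxe.tsv")
        truth = {
            "snp_panel": panel.ground_truth,
            "pathways": pathways.ground_truth,
            "evidence": bundle.ground_truth,
        }
        gio.write_json(truth, out / "ground_truth.json")
    elif all(k in cfg.get("inputs", {}) for k in ("eqtl", "ld", "scores", "gxe")):
        from .evidence import EvidenceBundle

        bundle = EvidenceBundle(
            eqtl=tuple(gio.read_eqtl(cfg["inputs"]["eqtl"])),
            ld=tuple(gio.read_ld(cfg["inputs"]["ld"])),
            disease_scores=gio.read_scores(cfg["inputs"]["scores"]),
            gxe=tuple(gio.read_gxe(cfg["inputs"]["gxe"])),
        )
    else:
        bundle = None
    if bundle is not None and len(panel) > 0:
        clusters = ld_proxy_clusters(
            panel, bundle.ld,
            r2_min=float(ev_cfg.get("r2_min", 0.8)),
            max_dist_bp=int(ev_cfg.get("max_dist_bp", 500_000)),
        )
        indep = independent_snps_per_gene(links, clusters)
        with open(out / "independent_snps.tsv", "w") as fh:
            fh.write("gene_id\tn_independent\n")
            for g, n in indep.items():
                fh.write(f"{g}\t{n}\n")
        if len(tissues) >= 2:
            venn = eqtl_venn(bundle.eqtl, tissues, p_max=float(ev_cfg.get("p_max", 0.05)))
            venn_dict = venn.to_dict()
            gio.write_json(venn_dict, out / "venn.json")
            priority = evidence_intersection(
                [g for g, _ in hubs], venn, bundle.gxe, bundle.disease_scores
            )
            triple = [r.gene_id for r in priority if r.triple]
            gio.write_priority_table(priority, out / "priority.tsv")
        disease = multigene_disease_check(modules, bundle.disease_scores, links=links)
        disease_pct = disease.pct_positive if modules else None
        gio.write_eqtl(
            intergenic_eqtl_records(bundle.eqtl, intergenic),
            out / "eqtl_intergenic.tsv",
        )
    logger.info("stage=evidence elapsed=%.2fs", time.monotonic() - t)

    provenance = {
        "seed": sim.seed if sim is not None else None,
        "parameters": {
            "window_bp": window_bp,
            "jaccard_min": float(path_cfg.get("jaccard_min", 0.9)),
            "cut_height": path_cfg.get("cut_height"),
            "tissues": list(tissues),
        },
        "input_hashes": {
            p.name: _sha256(p)
            for p in sorted(out.glob("*.tsv")) + sorted(out.glob("*.bed"))
            + sorted(out.glob("*.gmt")) + sorted(out.glob("*.obo"))
        },
    }
    run = RunSummary(
        mapping=summary.to_dict(),
        n_pathways_input=len(pathways),
        n_pathways_pruned=len(pruned),
        n_clusters=n_clusters,
        n_clusters_multi=n_multi,
        n_clusters_singleton=n_single,
        hub_genes=[list(h) for h in hubs],
        n_disconnected=len(disconnected),
        n_modules=len(modules),
        module_disease_pct=disease_pct,
        go_comparison=go_result,
        venn=venn_dict,
        triple_genes=triple,
        provenance=provenance,
    )
    gio.write_json(run.to_dict(), out / "summary.json")
    (out / "summary.txt").write_text(run.to_table() + "\n")
    logger.info("stage=pipeline elapsed=%.2fs", time.monotonic() - t0)
    return run


def export_network(network, fmt: str, path) -> None:
    """Write a network as SIF or GraphML (Cytoscape hand-off)."""
    if fmt == "sif":
        gio.write_sif(network, path)
    elif fmt == "graphml":
        gio.write_graphml(network, path)
    else:
        raise ConfigError(f"unknown export format {fmt!r} (use sif or graphml)")
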