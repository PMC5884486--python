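"""Flat-file readers and writers for every pipeline input and artifact.

Dialects:

* SNP panel TSV: ``snp_id  chrom  pos  population  pvalue`` (1-based pos).
* Gene models: BED (0-based half-open, converted on read) or TSV
  (1-based inclusive, flagged with a ``# coords=1-based-inclusive``
  header line).
* Pathways: GMT (name, description, tab-separated gene ids); the pathway
  id is stored in the description column, falling back to the name.
* GO DAG: minimal OBO ([Term] stanzas with id / name / namespace / is_a),
  readable by :mod:`obonet`.
* Annotations: GAF-like TSV ``gene_id  term_id  namespace``.
* Networks: SIF (``node<TAB>relation<TAB>node``) and GraphML via
  networkx, Cytoscape-loadable.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping, Sequence

import networkx as nx
import pandas as pd

from .evidence import EqtlRecord, GxeRecord, LdRecord, PriorityGene
from .gocompare import GoAnnotations, GoDag
from .pathnet import Pathway, PathwayCollection, TripartiteNetwork
from .snpmap import Gene, GeneSet, GeneSnpGeneModule, Snp, SnpGeneLink, SnpPanel

# ---------------------------------------------------------------------- #
# SNP panel


def write_snp_panel(panel: SnpPanel, path) -> None:
    df = pd.DataFrame(
        [(s.snp_id, s.chrom, s.pos, s.population, s.pvalue) for s in panel],
        columns=["snp_id", "chrom", "pos", "population", "pvalue"],
    )
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_snp_panel(path) -> SnpPanel:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str}, float_precision="round_trip")
    return SnpPanel(
        Snp(str(r.snp_id), str(r.chrom), int(r.pos), str(r.population), float(r.pvalue))
        for r in df.itertuples()
    )


# ---------------------------------------------------------------------- #
# gene models


def write_genes_bed(genes: GeneSet, path) -> None:
    """BED6: 0-based half-open, name = gene_id, score = 0."""
    with open(path, "w") as fh:
        for g in genes:
            fh.write(f"{g.chrom}\t{g.start - 1}\t{g.end}\t{g.gene_id}\t0\t{g.strand}\n")


def read_genes_bed(path) -> GeneSet:
    genes = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            chrom, start, end, name = fields[0], int(fields[1]), int(fields[2]), fields[3]
            strand = fields[5] if len(fields) > 5 else "+"
            genes.append(Gene(name, name, chrom, start + 1, end, strand))
    return GeneSet(genes)


def write_genes_tsv(genes: GeneSet, path) -> None:
    with open(path, "w") as fh:
        fh.write("# coords=1-based-inclusive\n")
        fh.write("gene_id\tsymbol\tchrom\tstart\tend\tstrand\n")
        for g in genes:
            fh.write(f"{g.gene_id}\t{g.symbol}\t{g.chrom}\t{g.start}\t{g.end}\t{g.strand}\n")


def read_genes_tsv(path) -> GeneSet:
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"chrom": str})
    return GeneSet(
        Gene(str(r.gene_id), str(r.symbol), str(r.chrom), int(r.start), int(r.end), str(r.strand))
        for r in df.itertuples()
    )


# ---------------------------------------------------------------------- #
# pathways (GMT)


def write_gmt(collection: PathwayCollection, path) -> None:
    with open(path, "w") as fh:
        for p in collection:
            genes = "\t".join(sorted(p.gene_ids))
            fh.write(f"{p.name}\t{p.pathway_id}\t{genes}\n")


def read_gmt(path) -> PathwayCollection:
    pathways = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            name, desc, genes = fields[0], fields[1], fields[2:]
            pid = desc if desc and desc != "na" else name
            pathways.append(Pathway(pid, name, frozenset(g for g in genes if g)))
    return PathwayCollection(pathways)


# ---------------------------------------------------------------------- #
# GO


def write_obo(dag: GoDag, path) -> None:
    """Minimal OBO: [Term] stanzas with id, name, namespace, is_a."""
    with open(path, "w") as fh:
        fh.write("format-version: 1.2\nontology: synthetic-go\n")
        for tid in sorted(dag.terms):
            term = dag.terms[tid]
            fh.write(f"\n[Term]\nid: {tid}\nname: {term.name}\n")
            fh.write(f"namespace: {term.namespace}\n")
            for p in dag.parents[tid]:
                fh.write(f"is_a: {p} ! {dag.terms[p].name}\n")


def read_obo(path) -> GoDag:
    return GoDag.from_obo(path)


def write_gaf(annotations: GoAnnotations, dag: GoDag, path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tterm_id\tnamespace\n")
        for gene, term in sorted(annotations.records):
            ns = dag.terms[term].namespace if term in dag else "unknown"
            fh.write(f"{gene}\t{term}\t{ns}\n")


def read_gaf(path) -> GoAnnotations:
    df = pd.read_csv(path, sep="\t", comment="!")
    return GoAnnotations(
        (str(r.gene_id), str(r.term_id)) for r in df.itertuples()
    )


# ---------------------------------------------------------------------- #
# evidence tables


def write_eqtl(records: Sequence[EqtlRecord], path) -> None:
    pd.DataFrame(
        [(r.snp_id, r.gene_id, r.tissue, r.effect_size, r.pvalue) for r in records],
        columns=["snp_id", "gene_id", "tissue", "effect_size", "pvalue"],
    ).to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_eqtl(path) -> list[EqtlRecord]:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    return [
        EqtlRecord(str(r.snp_id), str(r.gene_id), str(r.tissue),
                   float(r.effect_size), float(r.pvalue))
        for r in df.itertuples()
    ]


def write_ld(records: Sequence[LdRecord], path) -> None:
    pd.DataFrame(
        [(r.snp_a, r.snp_b, r.r2, r.distance_bp) for r in records],
        columns=["snp_a", "snp_b", "r2", "distance_bp"],
    ).to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_ld(path) -> list[LdRecord]:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    return [
        LdRecord(str(r.snp_a), str(r.snp_b), float(r.r2), int(r.distance_bp))
        for r in df.itertuples()
    ]


def write_scores(scores: Mapping[str, float], path) -> None:
    pd.DataFrame(
        sorted(scores.items()), columns=["gene_id", "score"]
    ).to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_scores(path) -> dict[str, float]:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    return {str(r.gene_id): float(r.score) for r in df.itertuples()}


def write_gxe(records: Sequence[GxeRecord], path) -> None:
    pd.DataFrame(
        [(r.snp_id, r.gene_id, r.environmental_factor, r.trait) for r in records],
        columns=["snp_id", "gene_id", "environmental_factor", "trait"],
    ).to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_gxe(path) -> list[GxeRecord]:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    return [
        GxeRecord(str(r.snp_id), str(r.gene_id), str(r.environmental_factor), str(r.trait))
        for r in df.itertuples()
    ]


# ---------------------------------------------------------------------- #
# mapping artifacts


def write_links(links: Sequence[SnpGeneLink], path) -> None:
    pd.DataFrame(
        [(l.snp_id, l.gene_id, l.location_class, l.distance_bp) for l in links],
        columns=["snp_id", "gene_id", "location_class", "distance_bp"],
    ).to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_links(path) -> list[SnpGeneLink]:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    return [
        SnpGeneLink(str(r.snp_id), str(r.gene_id), str(r.location_class), int(r.distance_bp))
        for r in df.itertuples()
    ]


def write_modules(modules: Sequence[GeneSnpGeneModule], path) -> None:
    with open(path, "w") as fh:
        fh.write("snp_ids\tgene_ids\tmerged\n")
        for m in modules:
            fh.write(
                ";".join(sorted(m.snp_ids)) + "\t"
                + ";".join(sorted(m.gene_ids)) + "\t"
                + str(int(m.merged)) + "\n"
            )


def write_priority_table(rows: Sequence[PriorityGene], path) -> None:
    pd.DataFrame(
        [
            (r.gene_id, int(r.in_hub_set), ";".join(sorted(r.eqtl_tissues)),
             ";".join(sorted(r.gxe_snp_ids)),
             "" if r.disease_score is None else r.disease_score, int(r.triple))
            for r in rows
        ],
        columns=["gene_id", "in_hub_set", "eqtl_tissues", "gxe_snps",
                 "disease_score", "triple"],
    ).to_csv(path, sep="\t", index=False, float_format="%.17g")


# ---------------------------------------------------------------------- #
# networks


def write_sif(network: TripartiteNetwork | nx.Graph, path) -> None:
    g = network.graph if isinstance(network, TripartiteNetwork) else network
    with open(path, "w") as fh:
        for u, v, d in sorted(g.edges(data=True), key=lambda e: (str(e[0]), str(e[1]))):
            fh.write(f"{u}\t{d.get('relation', 'link')}\t{v}\n")


def write_graphml(network: TripartiteNetwork | nx.Graph, path) -> None:
    g = network.graph if isinstance(network, TripartiteNetwork) else network
    out = nx.Graph()
    for n, d in g.nodes(data=True):
        attrs = {k: v for k, v in d.items() if v is not None}
        attrs["degree"] = g.degree(n)
        out.add_node(n, **attrs)
    for u, v, d in g.edges(data=True):
        out.add_edge(u, v, **{k: v2 for k, v2 in d.items() if v2 is not None})
    nx.write_graphml(out, path)


def read_graphml(path) -> TripartiteNetwork:
    g = nx.read_graphml(path)
    out = nx.Graph()
    for n, d in g.nodes(data=True):
        out.add_node(n, **d)
    for u, v, d in g.edges(data=True):
        out.add_edge(u, v, **d)
    return TripartiteNetwork(out)


# ---------------------------------------------------------------------- #


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def read_json(path):
    return json.loads(Path(path).read_text())
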