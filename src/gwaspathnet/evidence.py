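"""Evidence integration: LD proxies, tissue cis-eQTLs, GxE, disease scores.

Four independent lines of evidence are intersected over the gene ids of
the mapping stage: linkage-disequilibrium proxy structure collapses SNPs
into independent association signals; cis-eQTL records partition genes by
the tissues in which a variant modulates their expression; gene-
environment interaction records and gene-disease scores (DisGeNET-style,
in [0, 1]) complete the picture.  Genes carrying pathway-hub, eQTL and
GxE support simultaneously form the triple-evidence priority set.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import networkx as nx

from .errors import ReferentialIntegrityError
from .snpmap import GeneSnpGeneModule, SnpGeneLink, SnpPanel, round_half_up_pct, truncate_pct

R2_MIN_DEFAULT = 0.8
MAX_DIST_BP_DEFAULT = 500_000
P_MAX_DEFAULT = 0.05


@dataclass(frozen=True, slots=True)
class LdRecord:
    """One pairwise LD measurement; symmetric in (snp_a, snp_b)."""

    snp_a: str
    snp_b: str
    r2: float
    distance_bp: int

    def __post_init__(self) -> None:
        if not (0.0 <= self.r2 <= 1.0):
            raise ValueError(f"r2 out of [0,1]: {self.r2}")
        if self.distance_bp < 0:
            raise ValueError("distance_bp must be >= 0")


@dataclass(frozen=True, slots=True)
class EqtlRecord:
    snp_id: str
    gene_id: str
    tissue: str
    effect_size: float
    pvalue: float

    def __post_init__(self) -> None:
        if not (0.0 < self.pvalue <= 1.0):
            raise ValueError(f"eQTL p-value out of (0,1]: {self.pvalue}")


@dataclass(frozen=True, slots=True)
class GxeRecord:
    snp_id: str
    gene_id: str
    environmental_factor: str
    trait: str


@dataclass(frozen=True)
class EvidenceBundle:
    """All evidence inputs keyed to panel/gene-set ids."""

    eqtl: tuple[EqtlRecord, ...]
    ld: tuple[LdRecord, ...]
    disease_scores: dict[str, float]
    gxe: tuple[GxeRecord, ...]
    ground_truth: Optional[dict] = None

    def __post_init__(self) -> None:
        for g, s in self.disease_scores.items():
            if not (0.0 <= s <= 1.0):
                raise ValueError(f"disease score for {g} out of [0,1]: {s}")

    def check_ids(self, snp_ids: Iterable[str], gene_ids: Iterable[str]) -> None:
        """Referential integrity against the SNP panel and gene set."""
        snps, genes = set(snp_ids), set(gene_ids)
        for rec in self.eqtl:
            if rec.snp_id not in snps or rec.gene_id not in genes:
                raise ReferentialIntegrityError(f"eQTL record {rec} has unknown id")
        for rec in self.ld:
            if rec.snp_a not in snps or rec.snp_b not in snps:
                raise ReferentialIntegrityError(f"LD record {rec} has unknown snp")
        for g in self.disease_scores:
            if g not in genes:
                raise ReferentialIntegrityError(f"disease score for unknown gene {g}")
        for rec in self.gxe:
            if rec.snp_id not in snps or rec.gene_id not in genes:
                raise ReferentialIntegrityError(f"GxE record {rec} has unknown id")


def ld_proxy_clusters(
    snps: SnpPanel,
    ld: Sequence[LdRecord],
    r2_min: float = R2_MIN_DEFAULT,
    max_dist_bp: int = MAX_DIST_BP_DEFAULT,
) -> list[frozenset[str]]:
    """Group panel SNPs into LD proxy clusters, one population at a time.

    Edges require r² strictly above ``r2_min`` AND distance at most
    ``max_dist_bp``; clusters are connected components and every panel SNP
    appears (singletons included).  The number of clusters is the
    independent-signal count.  LD records joining SNPs of different
    populations are rejected with a warning; records naming SNPs absent
    from the panel raise.
    """
    graph = nx.Graph()
    graph.add_nodes_from(s.snp_id for s in snps)
    for rec in ld:
        if rec.snp_a not in snps or rec.snp_b not in snps:
            raise ReferentialIntegrityError(
                f"LD record references unknown SNP: {rec.snp_a}/{rec.snp_b}"
            )
        if snps[rec.snp_a].population != snps[rec.snp_b].population:
            warnings.warn(
                f"cross-population LD record {rec.snp_a}-{rec.snp_b} rejected",
                stacklevel=2,
            )
            continue
        if rec.r2 > r2_min and rec.distance_bp <= max_dist_bp:
            graph.add_edge(rec.snp_a, rec.snp_b)
    clusters = [frozenset(c) for c in nx.connected_components(graph)]
    clusters.sort(key=min)
    return clusters


def independent_snps_per_gene(
    links: Sequence[SnpGeneLink],
    clusters: Sequence[frozenset[str]],
) -> dict[str, int]:
    """Per gene, the number of distinct LD clusters among its linked SNPs."""
    cluster_of: dict[str, int] = {}
    for idx, cl in enumerate(clusters):
        for s in cl:
            cluster_of[s] = idx
    per_gene: dict[str, set[int]] = {}
    for l in links:
        if l.snp_id in cluster_of:
            per_gene.setdefault(l.gene_id, set()).add(cluster_of[l.snp_id])
    return {g: len(ix) for g, ix in sorted(per_gene.items())}


@dataclass(frozen=True)
class VennPartition:
    """Disjoint tissue-combination regions of the eQTL gene universe.

    ``regions`` maps each non-empty tissue combination (frozenset) to the
    genes whose significant-tissue set is exactly that combination; region
    counts therefore sum to the size of the union.
    """

    tissues: tuple[str, ...]
    regions: dict[frozenset[str], frozenset[str]]

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for combo, genes in self.regions.items():
            if seen & genes:
                raise ValueError("Venn regions are not disjoint")
            seen |= genes

    @property
    def union(self) -> frozenset[str]:
        out: set[str] = set()
        for genes in self.regions.values():
            out |= genes
        return frozenset(out)

    def region(self, *tissues: str) -> frozenset[str]:
        return self.regions.get(frozenset(tissues), frozenset())

    def tissue_genes(self, tissue: str) -> frozenset[str]:
        """All genes significant in a tissue (any region containing it)."""
        out: set[str] = set()
        for combo, genes in self.regions.items():
            if tissue in combo:
                out |= genes
        return frozenset(out)

    def specific_pct(self) -> dict[str, int]:
        """Per tissue, the tissue-only region as integer % of the union."""
        total = len(self.union)
        return {
            t: round_half_up_pct(len(self.region(t)), total) for t in self.tissues
        }

    def to_dict(self) -> dict:
        return {
            "tissues": list(self.tissues),
            "regions": {
                "+".join(sorted(combo)): sorted(genes)
                for combo, genes in sorted(self.regions.items(), key=lambda kv: sorted(kv[0]))
            },
            "specific_pct": self.specific_pct(),
        }


def eqtl_venn(
    records: Sequence[EqtlRecord],
    tissues: Sequence[str],
    p_max: float = P_MAX_DEFAULT,
) -> VennPartition:
    """Partition eQTL genes by the exact set of tissues hit at p <= p_max.

    A gene belongs to a tissue when it has at least one record in that
    tissue at or below the threshold (boundary inclusive: p = 0.05 counts).
    Only the configured tissues are considered; empty regions are omitted.
    """
    if not (2 <= len(tissues) <= 6):
        raise ValueError("tissues must list 2-6 names")
    tset = set(tissues)
    gene_tissues: dict[str, set[str]] = {}
    for rec in records:
        if rec.tissue in tset and rec.pvalue <= p_max:
            gene_tissues.setdefault(rec.gene_id, set()).add(rec.tissue)
    regions: dict[frozenset[str], set[str]] = {}
    for gene, ts in gene_tissues.items():
        regions.setdefault(frozenset(ts), set()).add(gene)
    return VennPartition(
        tissues=tuple(tissues),
        regions={c: frozenset(g) for c, g in regions.items()},
    )


@dataclass(frozen=True)
class PriorityGene:
    """One row of the evidence-intersection table."""

    gene_id: str
    in_hub_set: bool
    eqtl_tissues: frozenset[str]
    gxe_snp_ids: frozenset[str]
    disease_score: Optional[float]
    triple: bool

    def __post_init__(self) -> None:
        if not (self.in_hub_set or self.eqtl_tissues or self.gxe_snp_ids
                or self.disease_score is not None):
            raise ValueError(f"{self.gene_id} carries no evidence")


def evidence_intersection(
    hub: Iterable[str],
    venn: VennPartition,
    gxe: Sequence[GxeRecord],
    scores: Mapping[str, float],
) -> list[PriorityGene]:
    """Intersect hub membership, eQTL tissues, GxE support and scores.

    Every gene with at least one evidence source is listed; the ``triple``
    flag marks hub genes with eQTL support in any tissue AND at least one
    GxE record.  Sorted triple-first, then disease score descending, then
    gene id.
    """
    hub_set = set(hub)
    eqtl_map = {g: venn_tissues for g in venn.union
                if (venn_tissues := frozenset(
                    t for t in venn.tissues if g in venn.tissue_genes(t)))}
    gxe_map: dict[str, set[str]] = {}
    for rec in gxe:
        gxe_map.setdefault(rec.gene_id, set()).add(rec.snp_id)
    genes = hub_set | set(eqtl_map) | set(gxe_map) | set(scores)
    rows = []
    for g in sorted(genes):
        tissues = eqtl_map.get(g, frozenset())
        gxe_snps = frozenset(gxe_map.get(g, ()))
        is_hub = g in hub_set
        rows.append(
            PriorityGene(
                gene_id=g,
                in_hub_set=is_hub,
                eqtl_tissues=tissues,
                gxe_snp_ids=gxe_snps,
                disease_score=scores.get(g),
                triple=bool(is_hub and tissues and gxe_snps),
            )
        )
    rows.sort(
        key=lambda r: (
            not r.triple,
            -(r.disease_score if r.disease_score is not None else -1.0),
            r.gene_id,
        )
    )
    return rows


@dataclass(frozen=True)
class ModuleDiseaseRow:
    module_genes: tuple[str, ...]
    genes_positive: tuple[str, ...]
    genes_without: tuple[str, ...]


@dataclass(frozen=True)
class MultigeneDiseaseReport:
    """Disease-score audit of the gene-SNP-gene modules.

    ``pct_positive`` is the whole-number percent of module genes with a
    positive score, truncated toward zero (13 of 41 reports 31) — the one
    place truncation rather than round-half-up is used.
    ``dual_only_flags`` lists (snp_id, gene_id) pairs where a shared SNP is
    the only association behind a gene with no disease evidence of its
    own, the least trustworthy kind of assignment.
    """

    rows: tuple[ModuleDiseaseRow, ...]
    n_genes_total: int
    n_genes_positive: int
    pct_positive: int
    dual_only_flags: tuple[tuple[str, str], ...]


def multigene_disease_check(
    modules: Sequence[GeneSnpGeneModule],
    scores: Mapping[str, float],
    links: Optional[Sequence[SnpGeneLink]] = None,
) -> MultigeneDiseaseReport:
    """Tally known disease associations among multi-gene module genes.

    A gene counts positive when its score is strictly greater than 0
    (absent scores count as no evidence).  With ``links`` supplied, SNPs
    that connect a positive-score gene with a score-free gene for which
    that SNP is the only link are flagged as dual-only associations.
    """
    all_genes: set[str] = set()
    rows = []
    for m in modules:
        pos = tuple(sorted(g for g in m.gene_ids if scores.get(g, 0.0) > 0.0))
        neg = tuple(sorted(g for g in m.gene_ids if scores.get(g, 0.0) <= 0.0))
        rows.append(ModuleDiseaseRow(
            module_genes=tuple(sorted(m.gene_ids)),
            genes_positive=pos,
            genes_without=neg,
        ))
        all_genes |= m.gene_ids
    n_pos = sum(1 for g in all_genes if scores.get(g, 0.0) > 0.0)
    flags: list[tuple[str, str]] = []
    if links is not None:
        snps_of_gene: dict[str, set[str]] = {}
        genes_of_snp: dict[str, set[str]] = {}
        for l in links:
            snps_of_gene.setdefault(l.gene_id, set()).add(l.snp_id)
            genes_of_snp.setdefault(l.snp_id, set()).add(l.gene_id)
        for m in modules:
            for g in m.gene_ids:
                if scores.get(g, 0.0) > 0.0:
                    continue
                gsnps = snps_of_gene.get(g, set())
                if len(gsnps) != 1:
                    continue
                (snp,) = gsnps
                partners = genes_of_snp.get(snp, set()) - {g}
                if any(scores.get(p, 0.0) > 0.0 for p in partners):
                    flags.append((snp, g))
    return MultigeneDiseaseReport(
        rows=tuple(rows),
        n_genes_total=len(all_genes),
        n_genes_positive=n_pos,
        pct_positive=truncate_pct(n_pos, len(all_genes)),
        dual_only_flags=tuple(sorted(set(flags))),
    )


def intergenic_eqtl_records(
    records: Sequence[EqtlRecord],
    intergenic_snp_ids: Iterable[str],
) -> list[EqtlRecord]:
    """Any-tissue eQTL scan of the SNPs that map to no gene.

    Returns every record whose SNP is in the intergenic list, regardless
    of tissue or p-value — an eQTL hit is the only functional handle these
    variants have.
    """
    ids = set(intergenic_snp_ids)
    return [r for r in records if r.snp_id in ids]
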