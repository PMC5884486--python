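"""Synthetic input generator with planted, recoverable structure.

Every pipeline input — SNP panel, gene models, pathway collection, GO DAG
and annotations, eQTL/LD/score/GxE evidence — is generated from one
:class:`SimConfig` so that each downstream stage has an exact known truth:
how many SNPs are intergenic, which SNPs sit in two or more overlapping
genes, which pathway pairs are redundant duplicates, which genes are hubs,
which SNPs form LD proxy groups, which tissue-combination each eQTL gene
occupies, and which genes carry hub + eQTL + gene-environment evidence
simultaneously.

Distributions are deliberately simple (uniform placements, uniform gene
lengths): all downstream logic is combinatorial, not distribution-
sensitive, so testability wins over realism.

Randomness: one ``numpy`` SeedSequence derived from ``SimConfig.seed`` is
spawned into fixed-order per-stage child streams (genes, SNPs, pathways,
GO, evidence), so each ``generate_*`` function is deterministic on its own
and adding config fields never reshuffles another stage's output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Iterable, Optional, Sequence

import numpy as np

from .errors import ConfigError
from .evidence import EqtlRecord, EvidenceBundle, GxeRecord, LdRecord
from .gocompare import BP, GoAnnotations, GoDag, GoTerm
from .pathnet import Pathway, PathwayCollection
from .snpmap import Gene, GeneSet, Snp, SnpPanel

# stage indices into the spawned seed children; fixed forever
_STAGE_GENES, _STAGE_SNPS, _STAGE_PATHWAYS, _STAGE_GO, _STAGE_EVIDENCE = range(5)

ENV_FACTORS = (
    "energy intake", "whole-grain intake", "fiber intake", "carbohydrate",
    "fat", "polyunsaturated fatty acid", "monounsaturated fatty acid",
    "saturated fatty acid", "vitamin E", "vitamin A", "normal diet",
    "mediterranean diet", "physical activity",
)
TRAITS = ("BMI", "insulin", "triglyceride", "cholesterol")

GO_ROOTS = {
    "biological_process": "GO:0008150",
    "molecular_function": "GO:0003674",
    "cellular_component": "GO:0005575",
}


@dataclass(frozen=True)
class SimConfig:
    """All knobs of the synthetic study; see the methods note for units.

    The defaults describe a small but fully featured study; use
    :func:`realistic_scale` for the marginal counts of a realistic
    meta-analysis-sized panel.
    """

    seed: int = 0
    n_chromosomes: int = 4
    chrom_length_bp: int = 1_500_000
    n_genes: int = 60
    gene_length_range: tuple[int, int] = (2000, 6000)
    n_snps: int = 160
    n_intergenic: int = 50
    n_multigene_snps: int = 5
    # gene counts per gene-SNP-gene module; a module of m genes consumes
    # m-1 multi-gene SNPs (overlapping-gene chain). Default: all pairs.
    multigene_module_sizes: Optional[tuple[int, ...]] = None
    n_pathways: int = 24
    n_redundant_pairs: int = 3
    pathway_size_range: tuple[int, int] = (5, 8)
    n_pathway_gene_pool: Optional[int] = None  # default: n_genes // 2
    hub_spec: tuple[tuple[int, int], ...] = ((0, 12), (1, 10))
    # a non-hub gene joins at most this many pathway units (families or
    # standalone pathways); keeping it below the hub threshold makes hub
    # detection planted-exact
    max_background_memberships: int = 9
    # planted tight pathway families for cluster-cut recovery (0 = none)
    n_cluster_families: int = 0
    family_core_size: int = 16
    family_extra_genes: int = 0
    n_go_terms: int = 120
    go_depth: int = 3
    go_terms_a: int = 30          # BP terms of the no-pathway gene group
    go_terms_shared: int = 22     # ... of which also seen in the pathway group
    go_terms_b_only: int = 15
    go_n_genes_a: Optional[int] = None           # annotated A genes (default all)
    go_n_genes_a_shared_only: Optional[int] = None  # default 60% of A
    tissues: tuple[str, ...] = (
        "pancreas", "liver", "adipose_subcutaneous", "muscle_skeletal"
    )
    n_eqtl_genes: int = 10
    n_eqtl_shared_all: int = 1
    eqtl_frac_specific: float = 0.7
    ld_proxy_group_sizes: tuple[int, ...] = (3, 2)
    n_gxe: int = 4
    n_triple_evidence: int = 2
    n_module_genes_scored: Optional[int] = None  # default: a third of module genes
    window_bp: int = 1000

    # ------------------------------------------------------------------ #

    def module_sizes(self) -> tuple[int, ...]:
        if self.multigene_module_sizes is not None:
            return self.multigene_module_sizes
        return (2,) * self.n_multigene_snps

    @property
    def n_overlap_genes(self) -> int:
        return sum(self.module_sizes())

    @property
    def n_regular_genes(self) -> int:
        return self.n_genes - self.n_overlap_genes

    def validate(self) -> None:
        lo, hi = self.gene_length_range
        if not (1 <= lo <= hi):
            raise ConfigError("gene_length_range must satisfy 1 <= min <= max")
        if self.n_intergenic > self.n_snps:
            raise ConfigError("n_intergenic exceeds n_snps")
        if self.n_multigene_snps > self.n_snps - self.n_intergenic:
            raise ConfigError("n_multigene_snps exceeds genic SNP budget")
        sizes = self.module_sizes()
        if any(m < 2 for m in sizes):
            raise ConfigError("every multi-gene module needs >= 2 genes")
        if sum(m - 1 for m in sizes) != self.n_multigene_snps:
            raise ConfigError(
                "multigene_module_sizes inconsistent with n_multigene_snps "
                "(a module of m genes uses m-1 SNPs)"
            )
        if self.n_regular_genes < 0:
            raise ConfigError("n_genes too small for the requested modules")
        if sizes and hi < self.window_bp + 3:
            raise ConfigError(
                "gene_length_range too short to overlap genes without the "
                "shared SNP falling in a third window"
            )
        if self.n_pathways < 2 * self.n_redundant_pairs:
            raise ConfigError("n_pathways must be >= 2 * n_redundant_pairs")
        for idx, m in self.hub_spec:
            if not (0 <= idx < self.n_genes):
                raise ConfigError(f"hub gene index {idx} out of range")
            if m > self.n_pathways:
                raise ConfigError(
                    f"hub membership {m} exceeds n_pathways {self.n_pathways}"
                )
        if not self.tissues:
            raise ConfigError("tissues must be non-empty")

    def seeds(self) -> list[np.random.Generator]:
        children = np.random.SeedSequence(self.seed).spawn(5)
        return [np.random.default_rng(c) for c in children]


def _gene_id(i: int) -> str:
    return f"g{i:04d}"


# ---------------------------------------------------------------------- #
# gene models


def generate_gene_models(config: SimConfig) -> GeneSet:
    """Place gene models on chromosomes; overlaps only inside planted chains.

    Regular genes come first (indices 0 .. n_regular-1), then the genes of
    each multi-gene module as an overlapping chain.  Units are laid out
    left to right with at least ``2*window + 100`` bp between spans so no
    window overlaps a neighbouring unit and every inter-unit gap can host
    an intergenic SNP.
    """
    config.validate()
    rng = config.seeds()[_STAGE_GENES]
    lo, hi = config.gene_length_range
    w = config.window_bp
    chroms = [f"chr{i + 1}" for i in range(config.n_chromosomes)]
    cursors = {c: None for c in chroms}  # last span end per chromosome

    genes: list[Gene] = []
    idx = 0

    def place_unit(unit_idx: int, span: int) -> tuple[str, int]:
        chrom = chroms[unit_idx % len(chroms)]
        last = cursors[chrom]
        gap = int(rng.integers(0, 500)) + (0 if last is None else 2 * w + 100)
        start = (w + 1 if last is None else last + 1) + gap
        end = start + span - 1
        if end + w > config.chrom_length_bp:
            raise ConfigError(
                f"chromosome {chrom} too short ({config.chrom_length_bp} bp) "
                f"to place all genes"
            )
        cursors[chrom] = end
        return chrom, start

    n_regular = config.n_regular_genes
    for unit in range(n_regular):
        length = int(rng.integers(lo, hi + 1))
        chrom, start = place_unit(unit, length)
        strand = "+" if rng.random() < 0.5 else "-"
        genes.append(Gene(_gene_id(idx), f"GENE{idx}", chrom, start, start + length - 1, strand))
        idx += 1

    for k, m in enumerate(config.module_sizes()):
        length = int(rng.integers(max(lo, w + 3), hi + 1))
        overlap = min(length // 2, length - w - 2)
        if overlap < 1:
            raise ConfigError("gene length too small to build an overlap chain")
        span = length + (m - 1) * (length - overlap)
        chrom, start = place_unit(n_regular + k, span)
        for j in range(m):
            s = start + j * (length - overlap)
            strand = "+" if rng.random() < 0.5 else "-"
            genes.append(Gene(_gene_id(idx), f"GENE{idx}", chrom, s, s + length - 1, strand))
            idx += 1

    return GeneSet(genes)


def _overlap_chains(genes: GeneSet) -> tuple[list[list[Gene]], list[Gene]]:
    """Split a gene set into overlapping-span chains and regular genes."""
    by_chrom: dict[str, list[Gene]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    chains: list[list[Gene]] = []
    regular: list[Gene] = []
    for chrom in sorted(by_chrom):
        glist = sorted(by_chrom[chrom], key=lambda g: (g.start, g.gene_id))
        run = [glist[0]]
        for g in glist[1:]:
            if g.start <= run[-1].end:  # spans overlap
                run.append(g)
            else:
                (chains if len(run) > 1 else regular).append(run if len(run) > 1 else run[0])
                run = [g]
        (chains if len(run) > 1 else regular).append(run if len(run) > 1 else run[0])
    regular.sort(key=lambda g: g.gene_id)
    chains.sort(key=lambda c: c[0].gene_id)
    return chains, regular


# ---------------------------------------------------------------------- #
# SNP panel


def generate_snp_panel(config: SimConfig, genes: GeneSet) -> SnpPanel:
    """Plant genic, multi-gene and intergenic SNPs with known labels.

    Exactly ``n_intergenic`` SNPs fall more than ``window_bp`` from every
    gene span; exactly ``n_multigene_snps`` fall in the span overlap of a
    planted gene chain (mapping to both chain neighbours and nothing
    else); the rest sit within a single regular gene's window.  Hub genes
    from ``hub_spec`` are covered first so they always reach the network.
    """
    config.validate()
    rng = config.seeds()[_STAGE_SNPS]
    w = config.window_bp
    n_single = config.n_snps - config.n_intergenic - config.n_multigene_snps
    if n_single > 0 and len(genes) == 0:
        raise ConfigError("cannot place genic SNPs without genes")

    chains, regular = _overlap_chains(genes)
    pair_slots: list[tuple[list[Gene], int]] = [
        (chain, k) for chain in chains for k in range(len(chain) - 1)
    ]
    if config.n_multigene_snps > len(pair_slots):
        raise ConfigError(
            "no (or not enough) overlapping gene pairs available to place "
            f"{config.n_multigene_snps} multi-gene SNPs"
        )

    regular_ids = {g.gene_id for g in regular}
    hub_gene_ids: list[str] = []
    for gidx, _ in config.hub_spec:
        gid = genes.genes[gidx].gene_id
        if gid not in regular_ids:
            raise ConfigError(f"hub gene {gid} is part of an overlap chain")
        if gid not in hub_gene_ids:
            hub_gene_ids.append(gid)
    if n_single < len(hub_gene_ids):
        raise ConfigError("not enough genic SNPs to cover every hub gene")

    snps: list[Snp] = []
    truth: dict = {"single": {}, "multigene": {}, "modules": [], "intergenic": []}
    counter = 0

    def new_id() -> str:
        nonlocal counter
        counter += 1
        return f"rs{1000000 + counter}"

    # single-gene SNPs: hubs first, then the remaining regular genes, cycling
    targets = hub_gene_ids + [g.gene_id for g in regular if g.gene_id not in hub_gene_ids]
    if n_single > 0 and not targets:
        raise ConfigError("no single-span gene available for genic SNPs")
    for i in range(n_single):
        gene = genes[targets[i % len(targets)]]
        if rng.random() < 0.85:
            pos = int(rng.integers(gene.start, gene.end + 1))
        elif rng.random() < 0.5:
            pos = gene.start - int(rng.integers(1, w + 1))
        else:
            pos = gene.end + int(rng.integers(1, w + 1))
        sid = new_id()
        snps.append(Snp(sid, gene.chrom, pos, pvalue=10 ** rng.uniform(-12, -5)))
        truth["single"][sid] = gene.gene_id

    # multi-gene SNPs: fill chain pair slots in order
    module_edges: dict[int, list[tuple[str, frozenset[str]]]] = {}
    for slot in range(config.n_multigene_snps):
        chain, k = pair_slots[slot]
        ga, gb = chain[k], chain[k + 1]
        lo_pos = gb.start if k == 0 else max(gb.start, chain[k - 1].end + w + 1)
        hi_pos = ga.end if k + 2 >= len(chain) else min(ga.end, chain[k + 2].start - w - 1)
        if lo_pos > hi_pos:
            raise ConfigError(
                f"no room for a multi-gene SNP between {ga.gene_id} and {gb.gene_id}"
            )
        pos = int(rng.integers(lo_pos, hi_pos + 1))
        sid = new_id()
        snps.append(Snp(sid, ga.chrom, pos, pvalue=10 ** rng.uniform(-12, -5)))
        pair = frozenset((ga.gene_id, gb.gene_id))
        truth["multigene"][sid] = sorted(pair)
        module_edges.setdefault(chains.index(chain), []).append((sid, pair))

    for _, edges in sorted(module_edges.items()):
        mod_snps = sorted(s for s, _ in edges)
        mod_genes: set[str] = set()
        for _, pair in edges:
            mod_genes |= pair
        truth["modules"].append({"snps": mod_snps, "genes": sorted(mod_genes)})

    # intergenic SNPs: exact complement-interval sampling, > window from spans
    if config.n_intergenic > 0:
        allowed: list[tuple[str, int, int]] = []
        by_chrom: dict[str, list[Gene]] = {}
        for g in genes:
            by_chrom.setdefault(g.chrom, []).append(g)
        all_chroms = [f"chr{i + 1}" for i in range(config.n_chromosomes)]
        for chrom in all_chroms:
            forb = sorted(
                (g.start - w, g.end + w) for g in by_chrom.get(chrom, [])
            )
            cursor = 1
            for a, b in forb:
                if a > cursor:
                    allowed.append((chrom, cursor, min(a - 1, config.chrom_length_bp)))
                cursor = max(cursor, b + 1)
            if cursor <= config.chrom_length_bp:
                allowed.append((chrom, cursor, config.chrom_length_bp))
        lengths = np.array([b - a + 1 for _, a, b in allowed], dtype=np.float64)
        if lengths.sum() <= 0:
            raise ConfigError("no intergenic room left on any chromosome")
        probs = lengths / lengths.sum()
        for _ in range(config.n_intergenic):
            k = int(rng.choice(len(allowed), p=probs))
            chrom, a, b = allowed[k]
            pos = int(rng.integers(a, b + 1))
            sid = new_id()
            snps.append(Snp(sid, chrom, pos, pvalue=10 ** rng.uniform(-12, -5)))
            truth["intergenic"].append(sid)

    # populations, in one final deterministic pass (~20% MEX)
    final = []
    for s in snps:
        pop = "MEX" if rng.random() < 0.2 else "CEU"
        final.append(replace(s, population=pop))
    return SnpPanel(final, ground_truth=truth)


# ---------------------------------------------------------------------- #
# pathways


def _sample_capped(
    rng: np.random.Generator,
    pool: Sequence[str],
    size: int,
    registry: Sequence[frozenset[str]],
    cap: int,
    what: str,
    tries: int = 200,
) -> frozenset[str]:
    """Random gene subset whose overlap with every prior set is <= cap.

    The cap keeps planted pathway clusters separable: pairwise Euclidean
    distances between membership rows stay above the cluster cut by
    construction, for any seed.
    """
    if size > len(pool):
        raise ConfigError(f"{what}: pathway size {size} exceeds gene pool {len(pool)}")
    for _ in range(tries):
        cand = frozenset(rng.choice(len(pool), size=size, replace=False).tolist())
        cand_ids = frozenset(pool[i] for i in cand)
        if all(len(cand_ids & prev) <= cap for prev in registry):
            return cand_ids
    raise ConfigError(f"{what}: could not sample a sufficiently distinct gene set")


def generate_pathways(config: SimConfig, genes: GeneSet) -> PathwayCollection:
    """Build pathways with planted redundancy, hubs and cluster families.

    Each of the ``n_redundant_pairs`` duplicate pathways shares >= 90% of
    its (smaller) gene set with its source and a common name token, so the
    pruning stage removes exactly the duplicates.  Hub genes appear in
    exactly their specified number of pathways — spread over distinct
    families when families are planted — and nowhere else, while every
    other gene joins at most ``max_background_memberships`` pathway units,
    so hub detection at a threshold above that cap recovers exactly the
    planted hubs.  With ``n_cluster_families > 0`` the non-source pathways
    form families sharing a core gene set (members differ only in the hub
    genes planted on them); family rows merge under complete linkage well
    below the distance at which two families or two singleton sources
    could merge, so a dendrogram cut between those heights recovers
    exactly ``n_cluster_families`` multi-member clusters plus the sources
    as singletons, for any seed.
    """
    config.validate()
    rng = config.seeds()[_STAGE_PATHWAYS]
    n_pool = config.n_pathway_gene_pool or max(1, config.n_genes // 2)
    if n_pool > len(genes):
        raise ConfigError("n_pathway_gene_pool exceeds number of genes")
    pool_all = [g.gene_id for g in genes.genes[:n_pool]]
    hub_gene_ids = {genes.genes[i].gene_id for i, _ in config.hub_spec}
    pool = [g for g in pool_all if g not in hub_gene_ids]
    lo, hi = config.pathway_size_range
    if not (1 <= lo <= hi):
        raise ConfigError("pathway_size_range must satisfy 1 <= min <= max")
    if hi > len(pool):
        raise ConfigError("pathway_size_range max exceeds hub-free gene pool")

    n_dup = config.n_redundant_pairs
    n_base = config.n_pathways - n_dup
    nf = config.n_cluster_families
    unit_cap = config.max_background_memberships
    unit_load = {g: 0 for g in pool}

    def eligible_pool() -> list[str]:
        return [g for g in pool if unit_load[g] < unit_cap]

    base: list[Pathway] = []
    truth: dict = {"families": {}, "singletons": [], "redundant_pairs": [],
                   "redundant_removed": [], "hub_memberships": {}}
    registry: list[frozenset[str]] = []

    def pid(i: int) -> str:
        return f"pw{i:04d}"

    def pname(i: int) -> str:
        return f"pathway{i:04d}"

    family_of_pathway: dict[str, int] = {}
    if nf > 0:
        n_members = n_base - n_dup
        if n_members < 2 * nf:
            raise ConfigError("not enough pathways for the requested families")
        q, r = divmod(n_members, nf)
        fam_sizes = [q + 1] * r + [q] * (nf - r)
        i = 0
        for fam, fam_size in enumerate(fam_sizes):
            core = _sample_capped(rng, eligible_pool(), config.family_core_size,
                                  registry, cap=4, what=f"family {fam} core")
            registry.append(core)
            for g in core:
                unit_load[g] += 1
            rest = [g for g in eligible_pool() if g not in core]
            need = config.family_extra_genes * fam_size
            if need > len(rest):
                raise ConfigError("gene pool too small for family extras")
            extra_idx = rng.choice(len(rest), size=need, replace=False) if need else []
            fam_ids = []
            for m in range(fam_size):
                extras = frozenset(
                    rest[j] for j in extra_idx[m * config.family_extra_genes:
                                               (m + 1) * config.family_extra_genes]
                )
                for g in extras:
                    unit_load[g] += 1
                base.append(Pathway(pid(i), pname(i), core | extras))
                family_of_pathway[pid(i)] = fam
                fam_ids.append(pid(i))
                i += 1
            truth["families"][fam] = fam_ids
        for i in range(i, n_base):
            size = int(rng.integers(max(lo, 12), max(hi, 12) + 1))
            gset = _sample_capped(rng, eligible_pool(), size, registry,
                                  cap=3, what=f"source {i}")
            registry.append(gset)
            for g in gset:
                unit_load[g] += 1
            base.append(Pathway(pid(i), pname(i), gset))
            truth["singletons"].append(pid(i))
        sources = base[-n_dup:] if n_dup else []
    else:
        seen_sets: set[frozenset[str]] = set()
        for i in range(n_base):
            size = int(rng.integers(lo, hi + 1))
            for _ in range(200):
                elig = eligible_pool()
                if size > len(elig):
                    raise ConfigError(
                        "gene pool exhausted by membership cap; enlarge "
                        "n_pathway_gene_pool or max_background_memberships"
                    )
                gset = frozenset(
                    elig[j] for j in rng.choice(len(elig), size=size, replace=False)
                )
                if gset not in seen_sets:
                    break
            else:
                raise ConfigError("could not sample a fresh pathway gene set")
            seen_sets.add(gset)
            for g in gset:
                unit_load[g] += 1
            base.append(Pathway(pid(i), pname(i), gset))
        sources = base[:n_dup]

    # hub memberships: at most 3 hub genes per pathway (keeps family rows
    # within the cluster-cut margin), one pathway per family per hub
    source_ids = {p.pathway_id for p in sources}
    singleton_ids = set(truth["singletons"])
    eligible = [p for p in base
                if p.pathway_id not in source_ids and p.pathway_id not in singleton_ids]
    hub_load = {p.pathway_id: 0 for p in eligible}
    gene_adds: dict[str, set[str]] = {p.pathway_id: set() for p in base}
    for gidx, m in config.hub_spec:
        gid = genes.genes[gidx].gene_id
        if nf > 0:
            open_fams = sorted({
                family_of_pathway[p.pathway_id] for p in eligible
                if hub_load[p.pathway_id] < 3
            })
            if m > len(open_fams):
                raise ConfigError(f"hub gene {gid}: membership {m} infeasible")
            fams = [open_fams[j] for j in rng.choice(len(open_fams), size=m, replace=False)]
            for fam in fams:
                members = [p for p in eligible
                           if family_of_pathway[p.pathway_id] == fam
                           and hub_load[p.pathway_id] < 3]
                p = members[int(rng.integers(len(members)))]
                gene_adds[p.pathway_id].add(gid)
                hub_load[p.pathway_id] += 1
        else:
            candidates = [p for p in eligible if hub_load[p.pathway_id] < 3]
            if m > len(candidates):
                raise ConfigError(f"hub gene {gid}: membership {m} infeasible")
            for c in rng.choice(len(candidates), size=m, replace=False):
                p = candidates[c]
                gene_adds[p.pathway_id].add(gid)
                hub_load[p.pathway_id] += 1
        truth["hub_memberships"][gid] = m
    base = [
        Pathway(p.pathway_id, p.name, p.gene_ids | frozenset(gene_adds[p.pathway_id]))
        for p in base
    ]
    sources = [p for p in base if p.pathway_id in source_ids] if n_dup else []

    dups: list[Pathway] = []
    for src in sources:
        dup_size = max(1, math.ceil(0.9 * src.size))
        members = sorted(src.gene_ids)
        keep = rng.choice(len(members), size=dup_size, replace=False)
        dup = Pathway(
            src.pathway_id + "d", src.name + " variant",
            frozenset(members[j] for j in keep),
        )
        dups.append(dup)
        truth["redundant_pairs"].append((src.pathway_id, dup.pathway_id))
        truth["redundant_removed"].append(dup.pathway_id)
    truth["n_after_prune"] = n_base

    return PathwayCollection(base + dups, ground_truth=truth)


# ---------------------------------------------------------------------- #
# Gene Ontology


def generate_go(
    config: SimConfig,
    genes_in_pathways: Iterable[str] | GeneSet,
    genes_without: Iterable[str] | GeneSet,
) -> tuple[GoDag, GoAnnotations]:
    """Build a three-root GO DAG and group annotations with exact overlap.

    The annotations of the two comparison groups use only depth-1 children
    of the biological_process root, so ancestral closure (which would only
    add the excluded root) leaves the planted counts exact:
    ``go_terms_a`` terms in the no-pathway group, ``go_terms_shared`` of
    them also in the pathway group, and the remainder exclusive.  Deeper
    DAG levels exist (for closure machinery) but are left unannotated for
    these groups; molecular_function / cellular_component noise
    annotations exercise the namespace filter.

    Planted counts are attached as ``annotations.ground_truth``.
    """
    config.validate()
    if config.go_depth < 1:
        raise ConfigError("go_depth must be >= 1")
    if config.go_terms_shared > config.go_terms_a:
        raise ConfigError("go_terms_shared cannot exceed go_terms_a")
    rng = config.seeds()[_STAGE_GO]

    a_ids = sorted(genes_without.ids if isinstance(genes_without, GeneSet) else genes_without)
    b_ids = sorted(genes_in_pathways.ids if isinstance(genes_in_pathways, GeneSet)
                   else genes_in_pathways)
    if set(a_ids) & set(b_ids):
        raise ConfigError("gene groups must be disjoint")

    n_a = config.go_n_genes_a if config.go_n_genes_a is not None else len(a_ids)
    if n_a > len(a_ids):
        raise ConfigError("go_n_genes_a exceeds available no-pathway genes")
    a_sel = a_ids[:n_a]
    n_excl_terms = config.go_terms_a - config.go_terms_shared
    if config.go_n_genes_a_shared_only is not None:
        n_shared_only = config.go_n_genes_a_shared_only
    else:
        n_shared_only = n_a if n_excl_terms == 0 else int(0.6 * n_a)
    if n_shared_only > n_a:
        raise ConfigError("go_n_genes_a_shared_only exceeds annotated A genes")
    n_excl_genes = n_a - n_shared_only
    if n_excl_terms > 0 and n_a > 0 and n_excl_genes == 0:
        raise ConfigError("exclusive terms planted but no gene left to carry them")
    if n_excl_genes > 0 and n_excl_terms == 0:
        raise ConfigError("exclusive genes planted but no exclusive term exists")
    if n_shared_only > 0 and config.go_terms_shared == 0:
        raise ConfigError("shared-only genes planted but no shared term exists")
    if config.go_terms_shared > 0 and not b_ids:
        raise ConfigError("shared terms require a non-empty pathway gene group")

    required = 3 + config.go_terms_a + config.go_terms_b_only
    if config.n_go_terms < required:
        raise ConfigError(f"n_go_terms must be at least {required}")

    terms: dict[str, GoTerm] = {}
    parents: dict[str, list[str]] = {}
    for ns, root in GO_ROOTS.items():
        terms[root] = GoTerm(root, ns.replace("_", " "), ns)
        parents[root] = []
    counter = 0

    def new_term(ns: str, parent_ids: list[str]) -> str:
        nonlocal counter
        counter += 1
        tid = f"GO:{7000000 + counter}"
        terms[tid] = GoTerm(tid, f"synthetic process {counter}", ns)
        parents[tid] = parent_ids
        return tid

    bp_root = GO_ROOTS[BP]
    bp_l1 = [new_term(BP, [bp_root]) for _ in range(config.go_terms_a + config.go_terms_b_only)]
    extra = config.n_go_terms - required

    # spend the extra term budget round-robin: deeper BP levels, MF, CC
    levels: dict[str, list[list[str]]] = {
        ns: [[GO_ROOTS[ns]]] for ns in GO_ROOTS
    }
    levels[BP].append(list(bp_l1))
    order = [BP, "molecular_function", "cellular_component"]
    for k in range(extra):
        ns = order[k % 3]
        lv = levels[ns]
        # grow to full depth first, then cycle through the levels
        if len(lv) - 1 < config.go_depth:
            new_level = len(lv)
        else:
            new_level = 1 + (k // 3) % config.go_depth
        parent_pool = lv[new_level - 1]
        ps = [parent_pool[int(rng.integers(len(parent_pool)))]]
        if new_level >= 2 and rng.random() < 0.15 and len(lv[new_level - 1]) > 1:
            alt = lv[new_level - 1][int(rng.integers(len(lv[new_level - 1])))]
            if alt not in ps:
                ps.append(alt)
        tid = new_term(ns, ps)
        if new_level == len(lv):
            lv.append([tid])
        else:
            lv[new_level].append(tid)

    dag = GoDag(terms, parents)

    shared_terms = bp_l1[: config.go_terms_shared]
    excl_terms = bp_l1[config.go_terms_shared: config.go_terms_a]
    b_only_terms = bp_l1[config.go_terms_a: config.go_terms_a + config.go_terms_b_only]

    records: list[tuple[str, str]] = []
    shared_only_genes = a_sel[:n_shared_only]
    excl_genes = a_sel[n_shared_only:]
    # coverage round-robins in both directions guarantee every planted term
    # is used and every annotated gene keeps at least one BP term
    for k, t in enumerate(shared_terms):
        if shared_only_genes:
            records.append((shared_only_genes[k % len(shared_only_genes)], t))
    for i, g in enumerate(shared_only_genes):
        records.append((g, shared_terms[i % len(shared_terms)]))
        for _ in range(int(rng.integers(0, 3))):
            records.append((g, shared_terms[int(rng.integers(len(shared_terms)))]))
    for k, t in enumerate(excl_terms):
        records.append((excl_genes[k % len(excl_genes)], t))
    a_terms_all = shared_terms + excl_terms
    for i, g in enumerate(excl_genes):
        records.append((g, excl_terms[i % len(excl_terms)]))
        for _ in range(int(rng.integers(0, 3))):
            records.append((g, a_terms_all[int(rng.integers(len(a_terms_all)))]))
    b_terms_all = shared_terms + b_only_terms
    for k, t in enumerate(b_terms_all):
        if b_ids:
            records.append((b_ids[k % len(b_ids)], t))
    for i, g in enumerate(b_ids):
        if b_terms_all:
            records.append((g, b_terms_all[i % len(b_terms_all)]))
            if rng.random() < 0.5:
                records.append((g, b_terms_all[int(rng.integers(len(b_terms_all)))]))
    # namespace-filter noise: MF/CC annotations that closure must drop
    mf_terms = [t for lvl in levels["molecular_function"][1:] for t in lvl]
    cc_terms = [t for lvl in levels["cellular_component"][1:] for t in lvl]
    noise_pool = mf_terms + cc_terms
    all_genes = a_sel + b_ids
    if noise_pool and all_genes:
        for _ in range(min(10, len(all_genes))):
            g = all_genes[int(rng.integers(len(all_genes)))]
            records.append((g, noise_pool[int(rng.integers(len(noise_pool)))]))

    annotations = GoAnnotations(sorted(set(records)))
    annotations.ground_truth = {
        "terms_a": config.go_terms_a,
        "terms_shared": config.go_terms_shared,
        "terms_exclusive": n_excl_terms,
        "genes_a_annotated": n_a,
        "genes_a_shared_only": n_shared_only,
        "genes_a_exclusive": n_excl_genes,
        "exclusive_term_ids": sorted(excl_terms),
        "exclusive_gene_ids": sorted(excl_genes),
    }
    return dag, annotations


# ---------------------------------------------------------------------- #
# evidence


def generate_evidence(config: SimConfig, panel: SnpPanel, genes: GeneSet) -> EvidenceBundle:
    """Plant eQTL tissue regions, LD proxy groups, scores and GxE records.

    Ground truth (attached to the bundle) records the exact Venn region of
    every eQTL gene, the LD proxy groups, the module genes given positive
    disease scores, and the genes planted with hub + eQTL + GxE evidence.
    Non-significant decoy records (eQTL p > 0.05, LD r² <= 0.8 or beyond
    the distance limit) are mixed in to exercise the thresholds.
    """
    config.validate()
    if len(config.tissues) < 2:
        raise ConfigError("evidence generation needs at least 2 tissues")
    rng = config.seeds()[_STAGE_EVIDENCE]
    tissues = list(config.tissues)
    n_t = len(tissues)

    if panel.ground_truth is not None:
        gene_snps: dict[str, list[str]] = {}
        for sid, gid in panel.ground_truth["single"].items():
            gene_snps.setdefault(gid, []).append(sid)
        for sid, gids in panel.ground_truth["multigene"].items():
            for gid in gids:
                gene_snps.setdefault(gid, []).append(sid)
        intergenic = list(panel.ground_truth["intergenic"])
        module_genes = sorted(
            {g for m in panel.ground_truth["modules"] for g in m["genes"]}
        )
    else:
        from .snpmap import map_snps, multigene_structures

        links, intergenic = map_snps(panel, genes, config.window_bp)
        gene_snps = {}
        for l in links:
            gene_snps.setdefault(l.gene_id, []).append(l.snp_id)
        module_genes = sorted(
            {g for m in multigene_structures(links) for g in m.gene_ids}
        )
    gene_snps = {g: sorted(set(s)) for g, s in gene_snps.items()}

    hub_gene_ids = []
    for gidx, _ in config.hub_spec:
        gid = genes.genes[gidx].gene_id
        if gid not in hub_gene_ids:
            hub_gene_ids.append(gid)
    triple = [g for g in hub_gene_ids if g in gene_snps][: config.n_triple_evidence]
    if len(triple) < config.n_triple_evidence:
        raise ConfigError("not enough SNP-covered hub genes for triple evidence")

    # --- eQTL regions -------------------------------------------------- #
    candidates = sorted(g for g in gene_snps if g not in hub_gene_ids)
    if config.n_eqtl_genes > len(candidates):
        raise ConfigError("n_eqtl_genes exceeds SNP-mapped non-hub genes")
    sel = [candidates[j] for j in rng.choice(len(candidates),
                                             size=config.n_eqtl_genes, replace=False)]
    combos: dict[str, frozenset[str]] = {}
    for g in sel[: config.n_eqtl_shared_all]:
        combos[g] = frozenset(tissues)
    remaining = sel[config.n_eqtl_shared_all:]
    n_specific = int(round(config.eqtl_frac_specific * len(remaining)))
    for i, g in enumerate(remaining[:n_specific]):
        combos[g] = frozenset([tissues[i % n_t]])
    for g in remaining[n_specific:]:
        if n_t > 2:
            size = int(rng.integers(2, n_t))
            combos[g] = frozenset(
                tissues[j] for j in rng.choice(n_t, size=size, replace=False)
            )
        else:
            combos[g] = frozenset([tissues[int(rng.integers(n_t))]])
    for j, g in enumerate(triple):
        combos[g] = frozenset([tissues[j % n_t]])

    eqtl: list[EqtlRecord] = []
    for g in sorted(combos):
        snp = gene_snps[g][0]
        for t in sorted(combos[g]):
            eqtl.append(EqtlRecord(snp, g, t, float(rng.normal(0, 0.5)),
                                   float(rng.uniform(1e-8, 0.05))))
        off = sorted(set(tissues) - combos[g])
        if off:
            t = off[int(rng.integers(len(off)))]
            eqtl.append(EqtlRecord(snp, g, t, float(rng.normal(0, 0.5)),
                                   float(rng.uniform(0.051, 0.9))))
    # any-tissue records for intergenic SNPs, kept above the p threshold
    mapped = sorted(gene_snps)
    for sid in intergenic[: min(3, len(intergenic))]:
        g = mapped[int(rng.integers(len(mapped)))]
        t = tissues[int(rng.integers(n_t))]
        eqtl.append(EqtlRecord(sid, g, t, float(rng.normal(0, 0.5)),
                               float(rng.uniform(0.051, 0.5))))

    # --- LD proxy groups ----------------------------------------------- #
    ceu = sorted(
        (s for s in panel if s.population == "CEU"),
        key=lambda s: (s.chrom, s.pos, s.snp_id),
    )
    used: set[str] = set()
    ld: list[LdRecord] = []
    groups: list[list[str]] = []
    for size in config.ld_proxy_group_sizes:
        placed = False
        for i in range(len(ceu) - size + 1):
            run = ceu[i: i + size]
            if any(s.snp_id in used for s in run):
                continue
            if len({s.chrom for s in run}) != 1:
                continue
            if run[-1].pos - run[0].pos > 500_000:
                continue
            for a, b in zip(run, run[1:]):
                ld.append(LdRecord(a.snp_id, b.snp_id,
                                   float(rng.uniform(0.85, 0.99)),
                                   abs(b.pos - a.pos)))
            used.update(s.snp_id for s in run)
            groups.append([s.snp_id for s in run])
            placed = True
            break
        if not placed:
            raise ConfigError(
                f"cannot place an LD proxy group of size {size} within 500 kb"
            )
    free = [s for s in ceu if s.snp_id not in used]
    by_chrom: dict[str, list[Snp]] = {}
    for s in free:
        by_chrom.setdefault(s.chrom, []).append(s)
    decoys_placed = 0
    for chrom in sorted(by_chrom):
        slist = by_chrom[chrom]
        for a, b in zip(slist, slist[1:]):
            if decoys_placed >= 3:
                break
            r2 = 0.8 if decoys_placed == 0 else float(rng.uniform(0.1, 0.6))
            ld.append(LdRecord(a.snp_id, b.snp_id, r2, abs(b.pos - a.pos)))
            decoys_placed += 1

    # --- disease scores ------------------------------------------------ #
    scores: dict[str, float] = {}
    if config.n_module_genes_scored is not None:
        n_scored = config.n_module_genes_scored
    else:
        n_scored = len(module_genes) // 3
    if n_scored > len(module_genes):
        raise ConfigError("n_module_genes_scored exceeds module gene count")
    scored_modules = [
        module_genes[j]
        for j in rng.choice(len(module_genes), size=n_scored, replace=False)
    ] if module_genes and n_scored else []
    for g in scored_modules:
        scores[g] = float(rng.uniform(0.05, 0.5))
    for g in triple:
        scores[g] = float(rng.uniform(0.1, 0.6))
    other_hubs = [g for g in hub_gene_ids if g not in triple]
    for g in other_hubs[: math.ceil(0.6 * len(other_hubs))]:
        scores[g] = float(rng.uniform(0.001, 0.4))

    # --- gene-environment records -------------------------------------- #
    gxe: list[GxeRecord] = []
    for k, g in enumerate(triple):
        gxe.append(GxeRecord(gene_snps[g][0], g,
                             ENV_FACTORS[k % len(ENV_FACTORS)],
                             TRAITS[k % len(TRAITS)]))
    extra_gxe = config.n_gxe - len(triple)
    gxe_pool = [g for g in mapped
                if g not in hub_gene_ids and g not in combos]
    if extra_gxe > len(gxe_pool):
        raise ConfigError("not enough genes for the requested GxE records")
    for k in range(max(0, extra_gxe)):
        g = gxe_pool[k]
        gxe.append(GxeRecord(gene_snps[g][0], g,
                             ENV_FACTORS[(k + len(triple)) % len(ENV_FACTORS)],
                             TRAITS[(k + len(triple)) % len(TRAITS)]))

    truth = {
        "venn_regions": {
            "+".join(sorted(combo)): sorted(g for g, c in combos.items() if c == combo)
            for combo in set(combos.values())
        },
        "ld_groups": groups,
        "triple_genes": sorted(triple),
        "module_genes_scored": sorted(scored_modules),
        "eqtl_genes": sorted(combos),
    }
    bundle = EvidenceBundle(
        eqtl=tuple(eqtl), ld=tuple(ld), disease_scores=scores,
        gxe=tuple(gxe), ground_truth=truth,
    )
    bundle.check_ids(panel.ids, genes.ids)
    return bundle


# ---------------------------------------------------------------------- #


def realistic_scale(seed: int = 42) -> SimConfig:
    """Preset reproducing the marginal counts of a realistic T2DM panel.

    1,971 SNPs of which 716 intergenic (36%); 1,046 genes; 460 pathways
    with 36 planted redundant duplicates (424 survive pruning); 81 planted
    pathway families plus 36 singleton pathways (117 cluster nodes at the
    recommended cut height of 4.0); 27 hub genes; 19 gene-SNP-gene modules
    over 41 genes with 13 disease-scored (31%); GO comparison planted at
    1,503 / 1,255 / 248 terms and 196 / 122 / 74 genes; 4 T2DM tissues and
    3 triple-evidence genes.
    """
    return SimConfig(
        seed=seed,
        n_chromosomes=22,
        chrom_length_bp=3_000_000,
        n_genes=1046,
        gene_length_range=(2000, 6000),
        n_snps=1971,
        n_intergenic=716,
        n_multigene_snps=22,
        multigene_module_sizes=(2,) * 16 + (3,) * 3,
        n_pathways=460,
        n_redundant_pairs=36,
        pathway_size_range=(12, 18),
        n_pathway_gene_pool=368,
        hub_spec=tuple((i, 10 + (i % 11)) for i in range(27)),
        n_cluster_families=81,
        family_core_size=16,
        family_extra_genes=0,
        n_go_terms=2300,
        go_depth=3,
        go_terms_a=1503,
        go_terms_shared=1255,
        go_terms_b_only=300,
        go_n_genes_a=196,
        go_n_genes_a_shared_only=122,
        n_eqtl_genes=24,
        n_eqtl_shared_all=2,
        eqtl_frac_specific=0.7,
        ld_proxy_group_sizes=(4, 3, 3, 2, 2),
        n_gxe=6,
        n_triple_evidence=3,
        n_module_genes_scored=13,
    )


REALISTIC_SCALE_CUT_HEIGHT = 4.0
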