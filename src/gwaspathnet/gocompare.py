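"""Gene Ontology comparison of pathway-assigned vs unassigned gene groups.

Annotations are restricted to the biological_process namespace, extended
with all ``is_a`` ancestors (ancestral closure, namespace root excluded),
and the two groups' term sets are compared: terms seen only in the
no-pathway group are "new" biological-process knowledge contributed by
genes the pathway collection misses, and the genes carrying them form a
bipartite gene-term network for curation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import networkx as nx

from .errors import ClosureError, GroupingError

NAMESPACES = ("biological_process", "molecular_function", "cellular_component")
BP = "biological_process"


@dataclass(frozen=True)
class GoTerm:
    term_id: str
    name: str
    namespace: str


class GoDag:
    """An is_a-only GO DAG with the three namespace roots.

    ``parents`` maps each term to its direct is_a parents; ancestry queries
    are memoized.  Validation asserts acyclicity, namespace consistency
    along edges, and that every term reaches exactly one namespace root.
    """

    def __init__(self, terms: Mapping[str, GoTerm], parents: Mapping[str, Iterable[str]]):
        self.terms: dict[str, GoTerm] = dict(terms)
        self.parents: dict[str, tuple[str, ...]] = {
            t: tuple(sorted(set(parents.get(t, ())))) for t in self.terms
        }
        self._validate()
        self._anc_cache: dict[str, frozenset[str]] = {}

    def _validate(self) -> None:
        for t, ps in self.parents.items():
            for p in ps:
                if p not in self.terms:
                    raise ValueError(f"{t} has unknown parent {p}")
                if self.terms[p].namespace != self.terms[t].namespace:
                    raise ValueError(f"{t} -> {p} crosses namespaces")
        dg = nx.DiGraph()
        dg.add_nodes_from(self.terms)
        for t, ps in self.parents.items():
            for p in ps:
                dg.add_edge(t, p)
        if not nx.is_directed_acyclic_graph(dg):
            cycle = nx.find_cycle(dg)
            raise ValueError(f"is_a cycle detected: {cycle}")
        roots_by_ns = {}
        for t, term in self.terms.items():
            if not self.parents[t]:
                if term.namespace in roots_by_ns:
                    raise ValueError(f"multiple roots in namespace {term.namespace}")
                roots_by_ns[term.namespace] = t
        self.roots: dict[str, str] = roots_by_ns

    def __contains__(self, term_id: str) -> bool:
        return term_id in self.terms

    def __len__(self) -> int:
        return len(self.terms)

    def namespace(self, term_id: str) -> str:
        return self.terms[term_id].namespace

    def root(self, namespace: str) -> str:
        return self.roots[namespace]

    def ancestors(self, term_id: str) -> frozenset[str]:
        """All is_a ancestors of a term (the term itself excluded)."""
        cached = self._anc_cache.get(term_id)
        if cached is not None:
            return cached
        out: set[str] = set()
        stack = list(self.parents[term_id])
        while stack:
            p = stack.pop()
            if p not in out:
                out.add(p)
                stack.extend(self.parents[p])
        result = frozenset(out)
        self._anc_cache[term_id] = result
        return result

    @classmethod
    def from_obo(cls, path) -> "GoDag":
        """Read a (possibly minimal) OBO file via :mod:`obonet`."""
        import obonet

        graph = obonet.read_obo(path)
        terms = {}
        parents: dict[str, list[str]] = {}
        for node, data in graph.nodes(data=True):
            terms[node] = GoTerm(
                term_id=node,
                name=data.get("name", node),
                namespace=data.get("namespace", BP),
            )
            parents[node] = []
        # obonet orients edges child -> parent with key 'is_a'
        for child, parent, key in graph.edges(keys=True):
            if key == "is_a":
                parents[child].append(parent)
        return cls(terms, parents)


class GoAnnotations:
    """Direct gene-to-term annotations (GAF-like records).

    ``ground_truth`` holds planted comparison counts when the annotations
    come from the simulator.
    """

    def __init__(self, records: Iterable[tuple[str, str]], ground_truth=None):
        self.records: tuple[tuple[str, str], ...] = tuple(
            (str(g), str(t)) for g, t in records
        )
        self.ground_truth = ground_truth
        by_gene: dict[str, set[str]] = {}
        for g, t in self.records:
            by_gene.setdefault(g, set()).add(t)
        self.by_gene: dict[str, frozenset[str]] = {
            g: frozenset(ts) for g, ts in by_gene.items()
        }

    def __len__(self) -> int:
        return len(self.records)

    def genes(self) -> frozenset[str]:
        return frozenset(self.by_gene)


def bp_closure(
    annotations: GoAnnotations,
    dag: GoDag,
    closure: bool = True,
) -> dict[str, frozenset[str]]:
    """Per-gene biological_process term sets under ancestral closure.

    Keeps only BP-namespace annotations, unions in all is_a ancestors of
    each (closure can be switched off), and drops the namespace root,
    which every annotated gene would share trivially.  Genes left with an
    empty set are omitted.

    Raises :class:`ClosureError` naming the first annotated term missing
    from the DAG.
    """
    bp_root = dag.roots.get(BP)
    out: dict[str, frozenset[str]] = {}
    for gene, terms in sorted(annotations.by_gene.items()):
        closed: set[str] = set()
        for t in terms:
            if t not in dag:
                raise ClosureError(f"gene {gene} annotated to unknown term {t}")
            if dag.namespace(t) != BP:
                continue
            closed.add(t)
            if closure:
                closed |= dag.ancestors(t)
        closed.discard(bp_root)
        if closed:
            out[gene] = frozenset(closed)
    return out


@dataclass(frozen=True)
class ComparisonResult:
    """Set algebra of group A (no pathways) against group B (in pathways).

    ``terms_A`` is everything the no-pathway group annotates;
    ``terms_shared`` the part also seen in the pathway group; exclusive
    terms/genes are the novelty A contributes.  Count identities
    |exclusive terms| = |A| - |shared| and |exclusive genes| =
    |A genes| - |shared-only genes| hold by construction and are asserted.
    """

    terms_A: frozenset[str]
    terms_shared: frozenset[str]
    terms_exclusive_A: frozenset[str]
    genes_A_total: int
    genes_A_shared_only: int
    genes_A_exclusive: frozenset[str]

    def __post_init__(self) -> None:
        if self.terms_exclusive_A != self.terms_A - self.terms_shared:
            raise ValueError("exclusive terms != A - shared")
        if len(self.genes_A_exclusive) != self.genes_A_total - self.genes_A_shared_only:
            raise ValueError("exclusive gene count identity violated")

    def to_dict(self) -> dict:
        return {
            "n_terms_A": len(self.terms_A),
            "n_terms_shared": len(self.terms_shared),
            "n_terms_exclusive_A": len(self.terms_exclusive_A),
            "genes_A_total": self.genes_A_total,
            "genes_A_shared_only": self.genes_A_shared_only,
            "n_genes_A_exclusive": len(self.genes_A_exclusive),
            "terms_exclusive_A": sorted(self.terms_exclusive_A),
            "genes_A_exclusive": sorted(self.genes_A_exclusive),
        }


def group_term_comparison(
    group_without: Mapping[str, frozenset[str]],
    group_with: Mapping[str, frozenset[str]],
) -> ComparisonResult:
    """Compare closed BP term sets of the two disjoint gene groups.

    ``group_without`` (A) are genes absent from every pathway;
    ``group_with`` (B) are the pathway-network genes.  A gene of A counts
    as "shared only" when every one of its terms also occurs in B.
    """
    overlap = set(group_without) & set(group_with)
    if overlap:
        raise GroupingError(f"gene groups overlap: {sorted(overlap)[:5]}")
    terms_a: set[str] = set()
    for ts in group_without.values():
        terms_a |= ts
    terms_b: set[str] = set()
    for ts in group_with.values():
        terms_b |= ts
    shared = terms_a & terms_b
    exclusive = terms_a - shared
    exclusive_genes = frozenset(
        g for g, ts in group_without.items() if ts & exclusive
    )
    return ComparisonResult(
        terms_A=frozenset(terms_a),
        terms_shared=frozenset(shared),
        terms_exclusive_A=frozenset(exclusive),
        genes_A_total=len(group_without),
        genes_A_shared_only=len(group_without) - len(exclusive_genes),
        genes_A_exclusive=exclusive_genes,
    )


def exclusive_bipartite(
    result: ComparisonResult,
    closed_annotations: Mapping[str, frozenset[str]],
) -> nx.Graph:
    """Bipartite network of exclusive genes x exclusive terms.

    An edge joins gene and term iff the gene's closed BP set contains the
    exclusive term; every node carries degree >= 1.  Terms supported by a
    single gene get ``single_gene=True`` — one-gene processes are the
    least trustworthy disease links (false GWAS hit, pleiotropy, or a SNP
    acting at a distance).
    """
    g = nx.Graph()
    for gene in sorted(result.genes_A_exclusive):
        hits = closed_annotations.get(gene, frozenset()) & result.terms_exclusive_A
        for term in sorted(hits):
            g.add_node(gene, type="gene")
            g.add_node(term, type="term")
            g.add_edge(gene, term)
    for node, data in g.nodes(data=True):
        if data["type"] == "term":
            data["single_gene"] = g.degree(node) == 1
    return g


def slim_grouping(
    result: ComparisonResult,
    dag: GoDag,
    slim_terms: Iterable[str],
) -> dict[str, list[str]]:
    """Group each exclusive term under its slim-set ancestors.

    For every exclusive term, reports the intersection of its ancestors
    (plus itself) with a user-supplied slim term list; terms matching no
    slim term fall under ``"unassigned"``.
    """
    slim = set(slim_terms)
    out: dict[str, list[str]] = {}
    for term in sorted(result.terms_exclusive_A):
        frames = sorted(({term} | dag.ancestors(term)) & slim)
        if not frames:
            out.setdefault("unassigned", []).append(term)
        for f in frames:
            out.setdefault(f, []).append(term)
    return out
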