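"""SNP-gene-pathway tripartite network construction and topology analysis.

The pipeline stage: prune near-duplicate pathways (similar name, >= 90%
gene overlap, smaller one removed), cluster the survivors by hierarchical
agglomeration on their binary gene-membership vectors (Euclidean distance,
complete linkage), cut the dendrogram into pathway-cluster nodes, and wire
the tripartite network with SNP-gene and gene-cluster edges only.

The agglomerative clustering is implemented here rather than delegated so
that ties between equal merge distances break deterministically: among all
closest pairs the one with the lexicographically smallest (min id, max id)
of cluster representatives merges first, where a cluster's representative
is the smallest original row index it contains.  Binary rows make exact
distance ties common (distances are square roots of Hamming counts), so a
pinned tie order is required for reproducible dendrograms.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Iterator, Optional, Sequence

import networkx as nx
import numpy as np

from .errors import MatrixError
from .snpmap import SnpGeneLink

JACCARD_MIN_DEFAULT = 0.9
NAME_OVERLAP_MIN_DEFAULT = 0.5
HUB_MIN_DEGREE_DEFAULT = 10

RELATION_SNP_GENE = "snp_gene"
RELATION_GENE_PATHWAY = "gene_pathway"


@dataclass(frozen=True)
class Pathway:
    pathway_id: str
    name: str
    gene_ids: frozenset[str]

    def __post_init__(self) -> None:
        if not self.gene_ids:
            raise ValueError(f"pathway {self.pathway_id} has no genes")

    @property
    def size(self) -> int:
        return len(self.gene_ids)


class PathwayCollection:
    """Ordered, id-unique set of pathways (GMT semantics)."""

    def __init__(self, pathways: Iterable[Pathway], ground_truth: Optional[dict] = None):
        self.pathways: tuple[Pathway, ...] = tuple(pathways)
        seen: set[str] = set()
        for p in self.pathways:
            if p.pathway_id in seen:
                raise ValueError(f"duplicate pathway_id {p.pathway_id!r}")
            seen.add(p.pathway_id)
        self._by_id = {p.pathway_id: p for p in self.pathways}
        self.ground_truth = ground_truth

    def __len__(self) -> int:
        return len(self.pathways)

    def __iter__(self) -> Iterator[Pathway]:
        return iter(self.pathways)

    def __getitem__(self, pathway_id: str) -> Pathway:
        return self._by_id[pathway_id]

    def __contains__(self, pathway_id: str) -> bool:
        return pathway_id in self._by_id

    @property
    def ids(self) -> tuple[str, ...]:
        return tuple(p.pathway_id for p in self.pathways)

    def union_genes(self) -> frozenset[str]:
        out: set[str] = set()
        for p in self.pathways:
            out |= p.gene_ids
        return frozenset(out)


def _name_tokens(name: str) -> frozenset[str]:
    return frozenset(t for t in re.split(r"[^0-9a-z]+", name.lower()) if t)


def name_token_overlap(name_a: str, name_b: str) -> float:
    """Fraction of the smaller token set shared by the two names."""
    ta, tb = _name_tokens(name_a), _name_tokens(name_b)
    if not ta or not tb:
        return 0.0
    return len(ta & tb) / min(len(ta), len(tb))


def jaccard(a: frozenset, b: frozenset) -> float:
    union = len(a | b)
    return len(a & b) / union if union else 0.0


def prune_redundant(
    collection: PathwayCollection,
    jaccard_min: float = JACCARD_MIN_DEFAULT,
    name_overlap_min: float = NAME_OVERLAP_MIN_DEFAULT,
) -> tuple[PathwayCollection, list[str]]:
    """Remove the smaller member of every near-duplicate pathway pair.

    A pair is flagged when the Jaccard similarity of the gene sets reaches
    ``jaccard_min`` AND the token overlap of the lowercased names reaches
    ``name_overlap_min``.  For each flagged pair the pathway with fewer
    genes is removed (size ties: the lexicographically larger id goes).
    Flagging is evaluated once on the original collection; removals are
    applied in a single pass with no cascading re-evaluation.
    """
    if not (0.0 < jaccard_min <= 1.0):
        raise ValueError("jaccard_min must be in (0, 1]")
    ordered = sorted(collection, key=lambda p: p.pathway_id)
    removed: set[str] = set()
    for i, pa in enumerate(ordered):
        for pb in ordered[i + 1:]:
            if jaccard(pa.gene_ids, pb.gene_ids) < jaccard_min:
                continue
            if name_token_overlap(pa.name, pb.name) < name_overlap_min:
                continue
            if pa.size != pb.size:
                loser = pa if pa.size < pb.size else pb
            else:
                loser = pa if pa.pathway_id > pb.pathway_id else pb
            removed.add(loser.pathway_id)
    pruned = PathwayCollection(p for p in collection if p.pathway_id not in removed)
    return pruned, sorted(removed)


@dataclass(frozen=True)
class BinaryMatrix:
    """Pathway x gene membership indicator matrix with labeled axes."""

    values: np.ndarray  # shape (n_pathways, n_genes), dtype uint8
    pathway_ids: tuple[str, ...]
    gene_ids: tuple[str, ...]


def membership_matrix(
    collection: PathwayCollection,
    gene_universe: Optional[Iterable[str]] = None,
) -> BinaryMatrix:
    """Binary pathway-membership matrix over a gene universe.

    Rows follow sorted pathway ids, columns sorted gene ids.  The default
    universe is the union of all pathway gene sets; pass the SNP-mapped
    gene set to cluster pathways in the context of the mapped genes only.
    """
    if len(collection) == 0:
        raise MatrixError("empty pathway collection")
    if gene_universe is None:
        universe = sorted(collection.union_genes())
    else:
        universe = sorted(set(gene_universe))
    if not universe:
        raise MatrixError("empty gene universe")
    col = {g: j for j, g in enumerate(universe)}
    pids = sorted(collection.ids)
    values = np.zeros((len(pids), len(universe)), dtype=np.uint8)
    for i, pid in enumerate(pids):
        for g in collection[pid].gene_ids:
            j = col.get(g)
            if j is not None:
                values[i, j] = 1
    return BinaryMatrix(values=values, pathway_ids=tuple(pids), gene_ids=tuple(universe))


@dataclass(frozen=True)
class Dendrogram:
    """Agglomeration history: (rep_a, rep_b, height) per merge.

    Representatives are original row indices (a cluster is represented by
    the smallest row index it contains); ``labels`` maps row index to
    pathway id.  Merge heights are non-decreasing (complete linkage is
    monotone).
    """

    n_leaves: int
    merges: tuple[tuple[int, int, float], ...]
    labels: tuple[str, ...]


def hclust_complete(matrix: BinaryMatrix | np.ndarray) -> Dendrogram:
    """Complete-linkage agglomerative clustering of binary rows.

    Distance is Euclidean on the rows (the square root of the Hamming
    count for binary data).  Ties are broken on the lexicographically
    smallest (min representative, max representative) pair.
    """
    if isinstance(matrix, BinaryMatrix):
        rows = matrix.values.astype(np.float64)
        labels = matrix.pathway_ids
    else:
        rows = np.asarray(matrix, dtype=np.float64)
        if rows.ndim != 2:
            raise ValueError("matrix must be 2-D")
        labels = tuple(str(i) for i in range(rows.shape[0]))
    n = rows.shape[0]
    if n == 0:
        raise ValueError("need at least one row")
    if n == 1:
        return Dendrogram(n_leaves=1, merges=(), labels=labels)

    # squared distances keep ties exact in integer arithmetic for binary rows
    sq = ((rows[:, None, :] - rows[None, :, :]) ** 2).sum(axis=2)
    np.fill_diagonal(sq, np.inf)
    active = np.ones(n, dtype=bool)
    merges: list[tuple[int, int, float]] = []
    for _ in range(n - 1):
        masked = np.where(active[:, None] & active[None, :], sq, np.inf)
        dmin = masked.min()
        ti, tj = np.nonzero(masked == dmin)
        pairs = sorted((int(a), int(b)) for a, b in zip(ti, tj) if a < b)
        i, j = pairs[0]
        merges.append((i, j, float(np.sqrt(dmin))))
        # Lance-Williams complete linkage: d(new, k) = max(d(i,k), d(j,k))
        merged_row = np.maximum(sq[i], sq[j])
        sq[i, :] = merged_row
        sq[:, i] = merged_row
        sq[i, i] = np.inf
        active[j] = False
    return Dendrogram(n_leaves=n, merges=tuple(merges), labels=labels)


@dataclass(frozen=True)
class PathwayCluster:
    cluster_id: str
    member_ids: tuple[str, ...]
    gene_ids: frozenset[str]


@dataclass(frozen=True)
class PathwayClusterSet:
    """A partition of pathways into cluster nodes at a given cut height."""

    clusters: tuple[PathwayCluster, ...]
    cut_height: float

    def __len__(self) -> int:
        return len(self.clusters)

    def __iter__(self) -> Iterator[PathwayCluster]:
        return iter(self.clusters)

    @property
    def n_multi(self) -> int:
        return sum(1 for c in self.clusters if len(c.member_ids) > 1)

    @property
    def n_singleton(self) -> int:
        return sum(1 for c in self.clusters if len(c.member_ids) == 1)


def cut_clusters(
    dendrogram: Dendrogram,
    height: float,
    collection: PathwayCollection,
) -> PathwayClusterSet:
    """Cut the dendrogram: clusters are components of merges at height <= cut.

    Multi-member clusters are named ``cluster:<smallest member pathway id>``;
    singletons keep the pathway id.  Each cluster carries the union of its
    members' gene sets (taken from ``collection``).
    """
    if height < 0:
        raise ValueError("cut height must be >= 0")
    parent = list(range(dendrogram.n_leaves))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i, j, h in dendrogram.merges:
        if h <= height:
            ri, rj = find(i), find(j)
            if ri != rj:
                parent[max(ri, rj)] = min(ri, rj)
    groups: dict[int, list[int]] = {}
    for idx in range(dendrogram.n_leaves):
        groups.setdefault(find(idx), []).append(idx)
    clusters = []
    for members in groups.values():
        pids = tuple(sorted(dendrogram.labels[m] for m in members))
        union: set[str] = set()
        for pid in pids:
            union |= collection[pid].gene_ids
        cid = f"cluster:{pids[0]}" if len(pids) > 1 else pids[0]
        clusters.append(PathwayCluster(cluster_id=cid, member_ids=pids, gene_ids=frozenset(union)))
    clusters.sort(key=lambda c: c.member_ids[0])
    return PathwayClusterSet(clusters=tuple(clusters), cut_height=float(height))


NODE_SNP = "snp"
NODE_GENE = "gene"
NODE_CLUSTER = "pathway_cluster"


class TripartiteNetwork:
    """Typed SNP / gene / pathway-cluster graph with layer-adjacent edges only.

    Backed by an undirected :class:`networkx.Graph`; nodes carry a ``type``
    attribute, edges a ``relation`` attribute (``snp_gene`` or
    ``gene_pathway``).  :meth:`validate` asserts the tripartite discipline.
    """

    def __init__(self, graph: Optional[nx.Graph] = None):
        self.graph = graph if graph is not None else nx.Graph()

    def nodes_of_type(self, node_type: str) -> list[str]:
        return sorted(
            n for n, d in self.graph.nodes(data=True) if d.get("type") == node_type
        )

    @property
    def snp_ids(self) -> list[str]:
        return self.nodes_of_type(NODE_SNP)

    @property
    def gene_ids(self) -> list[str]:
        return self.nodes_of_type(NODE_GENE)

    @property
    def cluster_ids(self) -> list[str]:
        return self.nodes_of_type(NODE_CLUSTER)

    def validate(self) -> None:
        """Raise ``ValueError`` on any breach of the tripartite edge rules."""
        allowed = {
            frozenset((NODE_SNP, NODE_GENE)): RELATION_SNP_GENE,
            frozenset((NODE_GENE, NODE_CLUSTER)): RELATION_GENE_PATHWAY,
        }
        for n, d in self.graph.nodes(data=True):
            if d.get("type") not in (NODE_SNP, NODE_GENE, NODE_CLUSTER):
                raise ValueError(f"node {n!r} has no valid type")
        for u, v, d in self.graph.edges(data=True):
            tu = self.graph.nodes[u]["type"]
            tv = self.graph.nodes[v]["type"]
            key = frozenset((tu, tv))
            if key not in allowed:
                raise ValueError(f"forbidden edge {u!r}({tu}) -- {v!r}({tv})")
            if d.get("relation") != allowed[key]:
                raise ValueError(f"edge {u!r}--{v!r} has wrong relation {d.get('relation')!r}")
        for n in self.nodes_of_type(NODE_GENE):
            if self.graph.degree(n) == 0:
                raise ValueError(f"isolated gene node {n!r}")

    def gene_cluster_degree(self, gene_id: str) -> int:
        return sum(
            1
            for nbr in self.graph.neighbors(gene_id)
            if self.graph.nodes[nbr]["type"] == NODE_CLUSTER
        )

    def subnetwork(self, nodes: Iterable[str]) -> "TripartiteNetwork":
        return TripartiteNetwork(self.graph.subgraph(nodes).copy())

    def composition(self) -> dict:
        return {
            "n_snps": len(self.snp_ids),
            "n_genes": len(self.gene_ids),
            "n_clusters": len(self.cluster_ids),
            "n_edges": self.graph.number_of_edges(),
        }


def assemble_network(
    links: Sequence[SnpGeneLink],
    cluster_set: PathwayClusterSet,
) -> TripartiteNetwork:
    """Wire the tripartite network from mapping links and pathway clusters.

    SNP-gene edges are copied from the links.  A gene-cluster edge exists
    iff the gene is in the cluster's union gene set AND has at least one
    SNP link; cluster nodes with no such gene are dropped entirely.
    """
    net = TripartiteNetwork()
    g = net.graph
    linked_genes: set[str] = set()
    for l in links:
        g.add_node(l.snp_id, type=NODE_SNP)
        g.add_node(l.gene_id, type=NODE_GENE)
        g.add_edge(l.snp_id, l.gene_id, relation=RELATION_SNP_GENE)
        linked_genes.add(l.gene_id)
    for cluster in cluster_set:
        hits = sorted(cluster.gene_ids & linked_genes)
        if not hits:
            continue
        g.add_node(
            cluster.cluster_id,
            type=NODE_CLUSTER,
            members=";".join(cluster.member_ids),
        )
        for gene_id in hits:
            g.add_edge(gene_id, cluster.cluster_id, relation=RELATION_GENE_PATHWAY)
    net.validate()
    return net


def hub_genes(
    network: TripartiteNetwork,
    min_degree: int = HUB_MIN_DEGREE_DEFAULT,
) -> list[tuple[str, int]]:
    """Genes connected to at least ``min_degree`` pathway clusters.

    Degree counts gene-cluster edges only (SNP edges excluded); the
    threshold is inclusive.  Sorted by degree descending, then gene id.
    """
    if min_degree < 1:
        raise ValueError("min_degree must be >= 1")
    out = []
    for gene_id in network.gene_ids:
        deg = network.gene_cluster_degree(gene_id)
        if deg >= min_degree:
            out.append((gene_id, deg))
    out.sort(key=lambda t: (-t[1], t[0]))
    return out


def components(
    network: TripartiteNetwork,
) -> tuple[TripartiteNetwork, list[TripartiteNetwork]]:
    """Split the network into its main component and the disconnected rest.

    The main component is the largest by node count (ties: more edges,
    then smallest member node id); the remainder come back sorted the same
    way.
    """
    comps = list(nx.connected_components(network.graph))
    if not comps:
        return TripartiteNetwork(), []

    def key(nodes: set) -> tuple:
        sub = network.graph.subgraph(nodes)
        return (-len(nodes), -sub.number_of_edges(), min(str(n) for n in nodes))

    comps.sort(key=key)
    main = network.subnetwork(comps[0])
    rest = [network.subnetwork(c) for c in comps[1:]]
    return main, rest


def shared_cluster_pathways(
    network: TripartiteNetwork,
    gene_subset: Iterable[str],
    min_genes: int = 2,
) -> list[tuple[str, tuple[str, ...], int]]:
    """Clusters connected to >= ``min_genes`` genes of the subset.

    Returns (cluster_id, member pathway ids, count of subset genes hit),
    sorted by count descending then cluster id.
    """
    subset = set(gene_subset)
    missing = subset - set(network.gene_ids)
    if missing:
        raise ValueError(f"genes not in network: {sorted(missing)}")
    out = []
    for cid in network.cluster_ids:
        hits = sum(1 for nbr in network.graph.neighbors(cid) if nbr in subset)
        if hits >= min_genes:
            members = tuple(network.graph.nodes[cid].get("members", cid).split(";"))
            out.append((cid, members, hits))
    out.sort(key=lambda t: (-t[2], t[0]))
    return out
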