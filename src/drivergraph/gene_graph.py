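"""Directed gene graphs: construction, per-cell filtering and features.

The prior graph is an unweighted directed gene-gene network (an edge g1->g2
means g1 potentially regulates g2).  The encoder consumes two features
derived from it: per-gene in/out degrees (centrality encoding) and a matrix
of bucketed shortest-path distances (spatial encoding).  Distances are
clipped at ``d_max``; pairs with no directed path get a dedicated
UNREACHABLE bucket (stored as ``d_max + 1``).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import scipy.sparse
from scipy.sparse.csgraph import dijkstra

from .data_core import ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "DirectedGeneGraph",
    "DegreeTable",
    "DistanceBucketMatrix",
    "load_edge_list",
    "save_edge_list",
    "union_graphs",
    "cell_specific_subgraph",
    "compute_degrees",
    "shortest_path_buckets",
    "make_variant",
]


@dataclass
class DirectedGeneGraph:
    """Unweighted directed graph over an ordered gene vocabulary.

    Self-loops are allowed and count toward both degrees.  Edges are kept
    as a boolean CSR adjacency (row = source, column = target).
    """

    gene_ids: list[str]
    adjacency: scipy.sparse.csr_matrix

    @classmethod
    def from_edges(
        cls, gene_ids: list[str], edges: set[tuple[int, int]] | list[tuple[int, int]]
    ) -> "DirectedGeneGraph":
        n = len(gene_ids)
        edges = set(edges)
        for s, t in edges:
            if not (0 <= s < n and 0 <= t < n):
                raise ValidationError(f"edge ({s},{t}) outside vocabulary of size {n}")
        if edges:
            src, tgt = zip(*sorted(edges))
        else:
            src, tgt = (), ()
        adj = scipy.sparse.csr_matrix(
            (np.ones(len(edges), dtype=np.int8), (np.array(src, dtype=np.int64), np.array(tgt, dtype=np.int64))),
            shape=(n, n),
        )
        return cls(gene_ids, adj)

    def __post_init__(self) -> None:
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValidationError("duplicate gene ids in graph vocabulary")
        self.adjacency = scipy.sparse.csr_matrix(self.adjacency)
        self.adjacency.data = np.ones_like(self.adjacency.data)

    @property
    def n_nodes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.nnz)

    @property
    def edges(self) -> set[tuple[int, int]]:
        coo = self.adjacency.tocoo()
        return set(zip(coo.row.tolist(), coo.col.tolist()))

    def gene_index(self, gene_id: str) -> int:
        try:
            return self.gene_ids.index(gene_id)
        except ValueError:
            raise KeyError(f"unknown gene {gene_id!r}") from None


@dataclass
class DegreeTable:
    """Per-gene in/out degree; sums of both columns equal the edge count."""

    gene_ids: list[str]
    in_degree: np.ndarray
    out_degree: np.ndarray


@dataclass
class DistanceBucketMatrix:
    """Bucketed shortest directed distances over an ordered gene subset.

    Entries are in {0, ..., d_max, d_max+1}: reachable pairs carry their
    shortest-path length clipped at ``d_max``; ``d_max + 1`` is the
    UNREACHABLE sentinel.  The matrix need not be symmetric.
    """

    gene_indices: np.ndarray
    buckets: np.ndarray
    d_max: int

    @property
    def unreachable_value(self) -> int:
        return self.d_max + 1


def load_edge_list(
    path: str | Path, vocabulary: list[str] | str = "infer"
) -> DirectedGeneGraph:
    """Parse a two-column TSV of (source_gene, target_gene) symbols.

    With an explicit vocabulary, edges touching unknown genes are dropped
    (count logged); with ``"infer"`` the node set is the set of symbols
    seen, in first-appearance order.
    """
    path = Path(path)
    rows: list[tuple[str, str]] = []
    for ln, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) != 2:
            raise ValidationError(f"{path}:{ln}: expected 2 tab-separated fields")
        rows.append((parts[0], parts[1]))
    if not rows:
        raise ValidationError(f"empty edge list {path}")
    if vocabulary == "infer":
        seen: dict[str, int] = {}
        for s, t in rows:
            for g in (s, t):
                if g not in seen:
                    seen[g] = len(seen)
        vocab = list(seen)
        index = seen
    else:
        vocab = list(vocabulary)
        index = {g: i for i, g in enumerate(vocab)}
    edges: set[tuple[int, int]] = set()
    dropped = 0
    for s, t in rows:
        if s in index and t in index:
            edges.add((index[s], index[t]))
        else:
            dropped += 1
    if dropped:
        logger.warning("dropped %d edges touching genes outside the vocabulary", dropped)
    return DirectedGeneGraph.from_edges(vocab, edges)


def save_edge_list(graph: DirectedGeneGraph, path: str | Path) -> None:
    with open(path, "w") as fh:
        for s, t in sorted(graph.edges):
            fh.write(f"{graph.gene_ids[s]}\t{graph.gene_ids[t]}\n")


def union_graphs(graphs: list[DirectedGeneGraph]) -> DirectedGeneGraph:
    """Union of node sets; an edge is present iff present in any input."""
    if not graphs:
        raise ValidationError("union of zero graphs")
    vocab: dict[str, int] = {}
    for g in graphs:
        for gid in g.gene_ids:
            if gid not in vocab:
                vocab[gid] = len(vocab)
    edges: set[tuple[int, int]] = set()
    for g in graphs:
        remap = np.array([vocab[gid] for gid in g.gene_ids], dtype=np.int64)
        edges.update((int(remap[s]), int(remap[t])) for s, t in g.edges)
    return DirectedGeneGraph.from_edges(list(vocab), edges)


def cell_specific_subgraph(
    graph: DirectedGeneGraph, cell: np.ndarray
) -> DirectedGeneGraph:
    """Induced subgraph on genes with non-zero raw count in the cell.

    The cell must be aligned with the graph vocabulary (same length/order).
    Genes expressed in the cell stay as nodes even if isolated.
    """
    cell = np.asarray(cell)
    if cell.shape[0] != graph.n_nodes:
        raise ValidationError(
            f"cell has {cell.shape[0]} genes but graph has {graph.n_nodes}"
        )
    keep = np.flatnonzero(cell)
    if keep.size == 0:
        raise ValidationError("all-zero cell")
    sub = graph.adjacency[keep][:, keep]
    return DirectedGeneGraph([graph.gene_ids[i] for i in keep], sub)


def induced_adjacency(
    graph: DirectedGeneGraph, indices: np.ndarray
) -> scipy.sparse.csr_matrix:
    """Adjacency of the induced subgraph on ``indices`` (training helper)."""
    return graph.adjacency[indices][:, indices]


def compute_degrees(graph: DirectedGeneGraph) -> DegreeTable:
    """In/out degrees; a self-loop contributes to both."""
    out_deg = np.asarray(graph.adjacency.sum(axis=1)).ravel().astype(np.int64)
    in_deg = np.asarray(graph.adjacency.sum(axis=0)).ravel().astype(np.int64)
    return DegreeTable(list(graph.gene_ids), in_deg, out_deg)


def shortest_path_buckets(
    graph: DirectedGeneGraph, subset: np.ndarray | list[int], d_max: int = 8
) -> DistanceBucketMatrix:
    """Bucketed shortest directed distances between subset genes.

    BFS runs from each subset gene over the *whole* given graph (which may
    itself be a cell-specific subgraph), so paths may pass through genes
    outside the subset; only subset columns are kept.  Distances longer
    than ``d_max`` are clipped to ``d_max``; unreachable pairs get the
    sentinel ``d_max + 1``; the diagonal is 0.
    """
    subset = np.asarray(subset, dtype=np.int64)
    if subset.size == 0:
        raise ValidationError("empty gene subset")
    if d_max < 1:
        raise ValueError("d_max must be >= 1")
    if subset.min() < 0 or subset.max() >= graph.n_nodes:
        raise ValidationError("subset indices outside graph")
    dist = dijkstra(
        graph.adjacency, directed=True, unweighted=True, indices=subset
    )[:, subset]
    buckets = np.where(np.isinf(dist), d_max + 1, np.minimum(dist, d_max)).astype(
        np.int64
    )
    np.fill_diagonal(buckets, 0)
    return DistanceBucketMatrix(subset, buckets, d_max)


def make_variant(
    graph: DirectedGeneGraph,
    kind: str,
    fraction: float | None = None,
    seed: int | np.random.Generator | None = None,
) -> DirectedGeneGraph:
    """Graph ablation variants.

    fully_connected: every ordered pair (self-loops included).
    sparsified: uniform sample of round(fraction * |E|) edges, no replacement.
    randomized: same node and edge count, edges placed uniformly at random;
    self-loops of the input are preserved as such.
    """
    n = graph.n_nodes
    rng = np.random.default_rng(seed)
    if kind == "fully_connected":
        adj = scipy.sparse.csr_matrix(np.ones((n, n), dtype=np.int8))
        return DirectedGeneGraph(list(graph.gene_ids), adj)
    if kind == "sparsified":
        if fraction is None or not (0 < fraction < 1):
            raise ValueError("sparsified variant needs fraction in (0,1)")
        edges = sorted(graph.edges)
        k = int(round(fraction * len(edges)))
        chosen = rng.choice(len(edges), size=k, replace=False)
        return DirectedGeneGraph.from_edges(
            list(graph.gene_ids), [edges[i] for i in chosen]
        )
    if kind == "randomized":
        loops = {(s, t) for s, t in graph.edges if s == t}
        m = graph.n_edges - len(loops)
        edges: set[tuple[int, int]] = set(loops)
        target = len(loops) + m
        while len(edges) < target:
            s = int(rng.integers(n))
            t = int(rng.integers(n))
            if s != t:
                edges.add((s, t))
        return DirectedGeneGraph.from_edges(list(graph.gene_ids), edges)
    raise ValueError(f"unknown variant kind {kind!r}")
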