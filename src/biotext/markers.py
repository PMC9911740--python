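"""Marker-gene scoring and the cell-type–gene similarity network.

Two complementary marker scores for a (possibly never-annotated) cell type:

* **Correlation**: the Spearman rank correlation between a gene's expression
  across cells and the per-cell probability of belonging to the cell type.
  Works for unseen cell types because the probabilities themselves come from
  the zero-shot classifier.
* **Embedding**: ``sigmoid(F_gene^T W Y_CL)`` — the same bilinear score as
  novel-class annotation, with a gene's feature embedding against the cell
  type's description embedding.  Needs no expression data at all; ``W`` is
  taken from a gene-function model trained on protein annotations.

The network view connects cell types and genes whose embeddings have cosine
similarity above a threshold, partitions them into communities by modularity
optimization, and labels each community with the closest GO term whose
annotation count falls in a plausibility window (100–2500 genes), walking to
the nearest valid ancestor/descendant when the best match is too small or
too large.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy import stats

from .ontology import OntologyGraph, DEFAULT_RELATIONS
from .zero_shot import auroc, score

__all__ = [
    "MarkerScoreTable",
    "TypeGeneNetwork",
    "marker_by_correlation",
    "marker_by_embedding",
    "marker_auroc",
    "build_network",
    "community_enrichment",
]


@dataclass
class MarkerScoreTable:
    """Per-gene marker scores for one cell type, with the method recorded."""

    gene_ids: list[str]
    cell_type_id: str
    scores: np.ndarray
    method: str

    def __post_init__(self):
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.shape != (len(self.gene_ids),):
            raise ValueError("one score per gene required")
        if self.method not in ("spearman", "embedding"):
            raise ValueError(f"unknown method {self.method!r}")

    def to_tsv(self, stream) -> None:
        order = np.argsort(-self.scores, kind="stable")
        stream.write("gene\tscore\trank\n")
        for rank, k in enumerate(order, start=1):
            stream.write(f"{self.gene_ids[k]}\t{self.scores[k]:.6g}\t{rank}\n")


def marker_by_correlation(
    expr: np.ndarray,
    probs: np.ndarray,
    gene_ids: list[str] | None = None,
    cell_type_id: str = "cell_type",
) -> MarkerScoreTable:
    """Spearman correlation of each gene's expression with type probabilities.

    Genes with constant expression (or a constant probability vector) get
    score 0 rather than an undefined correlation.
    """
    expr = np.asarray(expr, dtype=float)
    probs = np.asarray(probs, dtype=float)
    if expr.ndim != 2 or expr.shape[0] != probs.shape[0]:
        raise ValueError("expression rows must match the probability vector")
    if expr.shape[0] < 3:
        raise ValueError("need at least 3 cells for a rank correlation")
    gene_ranks = stats.rankdata(expr, axis=0)
    prob_ranks = stats.rankdata(probs)
    gr = gene_ranks - gene_ranks.mean(axis=0)
    pr = prob_ranks - prob_ranks.mean()
    denom = np.sqrt((gr**2).sum(axis=0) * (pr**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = np.where(denom > 0, gr.T @ pr / np.where(denom > 0, denom, 1.0), 0.0)
    ids = gene_ids or [f"gene_{j}" for j in range(expr.shape[1])]
    return MarkerScoreTable(ids, cell_type_id, rho, method="spearman")


def marker_by_embedding(F_gene: np.ndarray, W: np.ndarray, Y_CL: np.ndarray) -> float:
    """Marker probability sigmoid(F_gene^T W Y_CL); shares the bilinear score
    code path with novel-class annotation."""
    return score(F_gene, W, Y_CL)


def marker_auroc(table: MarkerScoreTable, truth: np.ndarray) -> float:
    """AUROC of the marker scores against a binary ground-truth marker vector."""
    return auroc(table.scores, truth)


@dataclass
class TypeGeneNetwork:
    """Similarity network over typed (cell type / gene) nodes."""

    graph: nx.Graph
    embeddings: dict[str, np.ndarray]
    communities: list[set] = field(default_factory=list)
    community_annotations: dict[int, str | None] = field(default_factory=dict)

    def path_distance(self, a: str, b: str) -> int | None:
        try:
            return nx.shortest_path_length(self.graph, a, b)
        except nx.NetworkXNoPath:
            return None

    def write_edge_list(self, stream) -> None:
        stream.write("node_a\tnode_b\tcosine\n")
        for a, b, d in sorted(self.graph.edges(data=True)):
            stream.write(f"{a}\t{b}\t{d['weight']:.6g}\n")

    def write_graphml(self, path) -> None:
        nx.write_graphml(self.graph, path)


def _cosine(u: np.ndarray, v: np.ndarray) -> float:
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        return 0.0
    return float(u @ v / (nu * nv))


def build_network(
    embeddings: dict[str, tuple[str, np.ndarray]],
    similarity_threshold: float = 0.9,
    seed: int = 0,
) -> TypeGeneNetwork:
    """Connect nodes whose embedding cosine reaches the threshold.

    ``embeddings`` maps node id -> (kind, vector) with kind in
    {'cell_type', 'gene'}.  Communities come from seeded modularity
    (Louvain) optimization on the thresholded graph.
    """
    if len(embeddings) < 2:
        raise ValueError("need at least two nodes")
    g = nx.Graph()
    vectors = {}
    for node, (kind, vec) in embeddings.items():
        g.add_node(node, kind=kind)
        vectors[node] = np.asarray(vec, dtype=float)
    ids = sorted(vectors)
    for i, a in enumerate(ids):
        for b in ids[i + 1 :]:
            c = _cosine(vectors[a], vectors[b])
            if c >= similarity_threshold:
                g.add_edge(a, b, weight=c)
    if g.number_of_edges() == 0:
        warnings.warn("similarity threshold produced an empty edge set", stacklevel=2)
        communities = [{n} for n in ids]
    else:
        communities = [
            set(c) for c in nx.community.louvain_communities(g, seed=seed)
        ]
    return TypeGeneNetwork(graph=g, embeddings=vectors, communities=communities)


def community_enrichment(
    community_nodes,
    node_embeddings: dict[str, np.ndarray],
    go_embeddings: dict[str, np.ndarray],
    go_annotation_counts: dict[str, int],
    g: OntologyGraph,
    size_range: tuple[int, int] = (100, 2500),
    relations=DEFAULT_RELATIONS,
) -> str | None:
    """Label a community with its nearest adequately-sized GO term.

    The community embedding is the mean of member embeddings; candidate GO
    terms are ranked by cosine.  If the top term's annotation count lies
    outside ``size_range``, a breadth-first search over its ancestors and
    descendants (nearer level first, ties by id) returns the nearest term
    inside the window; ``None`` if no valid term is reachable.
    """
    community_nodes = list(community_nodes)
    if not community_nodes:
        raise ValueError("empty community")
    emb = np.mean([node_embeddings[n] for n in community_nodes], axis=0)
    lo, hi = size_range

    def valid(term: str) -> bool:
        return lo <= go_annotation_counts.get(term, 0) <= hi

    # deterministic argmax with lower-id tie-break
    best_sim = None
    best = None
    for term in sorted(go_embeddings):
        sim = _cosine(emb, go_embeddings[term])
        if best_sim is None or sim > best_sim + 1e-12:
            best_sim, best = sim, term
    if valid(best):
        return best

    digraph = g.graph(relations)
    undirected = digraph.to_undirected(as_view=True)
    if best not in undirected:
        return None
    seen = {best}
    frontier = [best]
    while frontier:
        nxt = sorted(
            {n for f in frontier for n in undirected.neighbors(f)} - seen
        )
        hits = [n for n in nxt if valid(n)]
        if hits:
            return hits[0]
        seen.update(nxt)
        frontier = nxt
    return None
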