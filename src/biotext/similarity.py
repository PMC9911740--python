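"""Text-, graph- and annotation-based similarity between ontology terms.

Three views of how related two controlled-vocabulary terms are:

* text: BLEU n-gram overlap (n = 1..4, geometric mean with brevity penalty)
  of their free-text descriptions — 1 for identical texts, 0 for disjoint;
* graph: shortest-path distance on the ontology, treating is_a/part_of
  edges as undirected;
* annotation: cosine of the two terms' true-path-propagated binary
  annotation vectors (Jaccard of member gene sets for pathways).

The binned association test quantifies the agreement between two such
views: pairs are grouped into bins of one similarity (default 0–0.2, …,
>0.8) and a one-way ANOVA asks whether the other similarity differs across
bins.  ``nearest_gene_sets`` retrieves the k existing gene sets closest to
a query by Jaccard (default k = 5).
"""

from __future__ import annotations

import math
import warnings
from collections import Counter

import networkx as nx
import numpy as np
from scipy import stats

from .ontology import AnnotationMatrix, OntologyGraph, DEFAULT_RELATIONS
from .text import tokenize

__all__ = [
    "bleu_similarity",
    "graph_distance",
    "annotation_cosine",
    "jaccard_gene_sets",
    "nearest_gene_sets",
    "binned_association_test",
    "read_gmt",
    "pairwise_similarity_records",
]

DEFAULT_BINS = (0.0, 0.2, 0.4, 0.6, 0.8)


def _ngrams(tokens: list[str], n: int) -> Counter:
    return Counter(tuple(tokens[i : i + n]) for i in range(len(tokens) - n + 1))


def bleu_similarity(
    candidate: str,
    reference: str,
    max_n: int = 4,
    smoothing: bool = False,
    symmetric: bool = False,
) -> float:
    """BLEU score of ``candidate`` against ``reference``.

    Geometric mean of modified (clipped) n-gram precisions with the brevity
    penalty.  Orders the candidate is too short to populate are dropped and
    the remaining orders weighted uniformly, so identical texts score 1 at
    any length.  Unsmoothed by default, so a zero match at any used order
    gives 0; ``smoothing=True`` applies add-one smoothing, useful for very
    short definitions.  BLEU is directional; ``symmetric=True`` returns the
    mean of both directions.
    """
    if symmetric:
        kw = dict(max_n=max_n, smoothing=smoothing)
        return 0.5 * (
            bleu_similarity(candidate, reference, **kw)
            + bleu_similarity(reference, candidate, **kw)
        )
    cand, ref = tokenize(candidate), tokenize(reference)
    if not cand or not ref:
        raise ValueError("both texts must contain at least one token")
    n_orders = min(max_n, len(cand))
    log_precisions = 0.0
    for n in range(1, n_orders + 1):
        cand_counts = _ngrams(cand, n)
        ref_counts = _ngrams(ref, n)
        total = sum(cand_counts.values())
        matched = sum(min(c, ref_counts[g]) for g, c in cand_counts.items())
        if smoothing:
            matched, total = matched + 1, total + 1
        if matched == 0:
            return 0.0
        log_precisions += math.log(matched / total) / n_orders
    bp = 1.0 if len(cand) >= len(ref) else math.exp(1.0 - len(ref) / len(cand))
    return bp * math.exp(log_precisions)


def graph_distance(
    a: str, b: str, g: OntologyGraph, relations=DEFAULT_RELATIONS
) -> int | None:
    """Shortest-path length between two terms, edges taken as undirected."""
    digraph = g.graph(relations)
    if a not in digraph or b not in digraph:
        raise KeyError(f"unknown term(s): {[t for t in (a, b) if t not in digraph]}")
    try:
        return nx.shortest_path_length(digraph.to_undirected(as_view=True), a, b)
    except nx.NetworkXNoPath:
        return None


def annotation_cosine(a: str, b: str, ann: AnnotationMatrix) -> float:
    """Cosine of two terms' binary annotation vectors (propagated table)."""
    va = ann.term_column(a).astype(float)
    vb = ann.term_column(b).astype(float)
    na, nb = np.linalg.norm(va), np.linalg.norm(vb)
    if na == 0 or nb == 0:
        raise ValueError("annotation similarity undefined for unannotated terms")
    return float(va @ vb / (na * nb))


def jaccard_gene_sets(s1, s2) -> float:
    """|intersection| / |union| of two gene sets."""
    s1, s2 = set(s1), set(s2)
    if not s1 or not s2:
        raise ValueError("gene sets must be non-empty")
    return len(s1 & s2) / len(s1 | s2)


def nearest_gene_sets(query, corpus: dict[str, set], k: int = 5) -> list[str]:
    """The k corpus gene sets closest to the query by Jaccard; ties by id."""
    if not corpus:
        raise ValueError("empty corpus")
    if k > len(corpus):
        warnings.warn("k exceeds corpus size; returning all sets", stacklevel=2)
        k = len(corpus)
    scored = sorted(
        ((-jaccard_gene_sets(query, members), sid) for sid, members in corpus.items())
    )
    return [sid for _, sid in scored[:k]]


def binned_association_test(
    x: np.ndarray, y: np.ndarray, bin_edges=DEFAULT_BINS
) -> tuple[float, float]:
    """One-way ANOVA of ``y`` across bins of ``x``.

    ``bin_edges`` are the left edges of half-open bins, the last bin open to
    the right (the default reproduces 0–0.2, 0.2–0.4, 0.4–0.6, 0.6–0.8,
    >0.8).  Empty bins are dropped; fewer than two non-empty bins is an
    error.  Returns (F statistic, p value).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    edges = np.asarray(bin_edges, dtype=float)
    which = np.digitize(x, edges[1:], right=False)
    mask = x >= edges[0]
    groups = [y[mask & (which == b)] for b in range(len(edges))]
    groups = [grp for grp in groups if grp.size > 0]
    if len(groups) < 2:
        raise ValueError("need at least two non-empty bins")
    f_stat, p = stats.f_oneway(*groups)
    return float(f_stat), float(p)


def read_gmt(path_or_handle) -> dict[str, dict]:
    """Read GMT gene sets: id -> {'description': str, 'genes': set}."""
    close = False
    if isinstance(path_or_handle, str):
        path_or_handle = open(path_or_handle)
        close = True
    try:
        out = {}
        for line in path_or_handle:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            out[parts[0]] = {"description": parts[1], "genes": set(parts[2:])}
        return out
    finally:
        if close:
            path_or_handle.close()


def pairwise_similarity_records(
    term_ids: list[str],
    g: OntologyGraph,
    ann: AnnotationMatrix | None = None,
    delimiter: str = ". ",
    relations=DEFAULT_RELATIONS,
):
    """All-pairs (id_a, id_b, text_sim, graph_dist, annotation_sim) records.

    Text similarity is the symmetrized BLEU of the two term descriptions;
    annotation similarity is ``None`` when no annotation table is given or a
    term is unannotated.  Suitable for writing straight to TSV.
    """
    desc = g.descriptions(delimiter=delimiter)
    records = []
    for i, a in enumerate(term_ids):
        for b in term_ids[i + 1 :]:
            try:
                ann_sim = annotation_cosine(a, b, ann) if ann is not None else None
            except ValueError:
                ann_sim = None
            records.append(
                {
                    "id_a": a,
                    "id_b": b,
                    "text_sim": bleu_similarity(desc[a], desc[b], symmetric=True),
                    "graph_dist": graph_distance(a, b, g, relations),
                    "annotation_sim": ann_sim,
                }
            )
    return records
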