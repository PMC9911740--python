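"""Cross-modal prediction through the shared text space, with no paired data.

Each non-text modality m (genes, drugs, phenotypes, pathways) gets its own
translator: an instance encoder followed by a bilinear matrix ``W_m`` that
projects encoded features into the text-embedding space.  A translator is
trained only on (feature, description) pairs from its own modality, with the
multi-label objective treating each item's own description as its positive
class.  Two modalities trained this way share the text space, so the
probability that an item of modality a pairs with an item of modality b is

    p = sigmoid( (W_a^T F_a')  .  (W_b^T F_b') )

— a dot product of the two text-space projections — computed without a
single cross-modal training pair.  Pathways are embedded by sum pooling
their member-gene projections (sum, not mean, so pathway size matters), and
phenotype networks get diffusion-based node features (random walk with
restart followed by a truncated eigendecomposition).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from ._optim import Adam
from .encoders import DenseBlock
from .text import TextEncoder
from .zero_shot import TrainConfig, _sigmoid

__all__ = [
    "PairedCorpus",
    "ModalityTranslator",
    "TranslatorModel",
    "cross_modal_score",
    "pathway_embedding",
    "graph_node_features",
    "rank_candidates",
    "write_predictions",
]


@dataclass
class PairedCorpus:
    """(features, textual description) pairs for one modality."""

    ids: list[str]
    features: np.ndarray
    descriptions: list[str]

    def __post_init__(self):
        self.features = np.asarray(self.features, dtype=float)
        if not (len(self.ids) == self.features.shape[0] == len(self.descriptions)):
            raise ValueError("ids, features and descriptions must align")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("duplicate ids in corpus")
        if any(not d for d in self.descriptions):
            raise ValueError("descriptions must be non-empty")

    def __len__(self) -> int:
        return len(self.ids)


@dataclass
class ModalityTranslator:
    """Fitted translator: modality encoder plus text-space projection W_m."""

    modality: str
    encoder_block: DenseBlock
    W: np.ndarray
    d_bio: int
    loss_history: list[float] = field(default_factory=list)

    def project(self, features: np.ndarray) -> np.ndarray:
        """Map raw features into the d_bio text-logit space: W_m^T F'."""
        F = self.encoder_block.forward(np.asarray(features, dtype=float))
        return F @ self.W

    def summary(self) -> str:
        lines = [
            f"Modality translator: {self.modality}",
            "=" * 40,
            f"encoder:   {self.encoder_block.W.shape[0]} -> {self.encoder_block.W.shape[1]} (ReLU)",
            f"W_m shape: {self.W.shape[0]} x {self.W.shape[1]}",
        ]
        if self.loss_history:
            lines += [
                f"first batch loss: {self.loss_history[0]:.4f}",
                f"final batch loss: {self.loss_history[-1]:.4f}",
            ]
        return "\n".join(lines)


class TranslatorModel:
    """Trains a modality encoder + W_m to land on the text embedding space.

    The objective is a regression: the projection ``W_m^T F'_i`` of item i's
    encoded features is fitted to its own description embedding ``Y_i`` by
    mean squared error.  Anchoring the projection to the text coordinates —
    rather than merely separating each item's description from the others' —
    is what lets two independently trained translators meet in the same
    space, so their projections can be compared across modalities with no
    paired training data.  Test-set descriptions are never consulted.
    """

    def __init__(self, corpus: PairedCorpus, encoder: TextEncoder, modality: str = "modality"):
        self.corpus = corpus
        self.encoder = encoder
        self.modality = modality

    def fit(self, cfg: TrainConfig | None = None) -> ModalityTranslator:
        cfg = cfg or TrainConfig(epochs=30)
        if len(self.corpus) < cfg.batch_size:
            cfg = TrainConfig(**{**vars(cfg), "batch_size": len(self.corpus)})
        rng = np.random.default_rng(cfg.seed)
        Y = self.encoder.encode(self.corpus.descriptions)   # (n, d_bio)
        d_bio = Y.shape[1]
        X = self.corpus.features
        n = X.shape[0]
        enc = DenseBlock(X.shape[1], cfg.hidden_dim, seed=int(rng.integers(2**31)))
        W = rng.normal(0.0, 0.1 / np.sqrt(d_bio), size=(cfg.hidden_dim, d_bio))

        opt = Adam({"W": W, "enc.W": enc.W, "enc.b": enc.b},
                   lr=cfg.learning_rate, weight_decay=cfg.weight_decay)
        history = []
        for _ in range(cfg.epochs):
            order = rng.permutation(n)
            for start in range(0, n, cfg.batch_size):
                idx = order[start : start + cfg.batch_size]
                x = X[idx]
                z = x @ enc.W + enc.b
                h = np.maximum(z, 0.0)
                pred = h @ W                       # (batch, d_bio)
                resid = pred - Y[idx]
                loss = float((resid**2).mean())
                if not np.isfinite(loss):
                    raise FloatingPointError("translator loss became non-finite")
                history.append(loss)
                G = 2.0 * resid / resid.size
                dz = (G @ W.T) * (z > 0)
                opt.step({
                    "W": h.T @ G,
                    "enc.W": x.T @ dz,
                    "enc.b": dz.sum(axis=0),
                })
        return ModalityTranslator(
            modality=self.modality, encoder_block=enc, W=W, d_bio=d_bio,
            loss_history=history,
        )


def cross_modal_score(
    t_a: ModalityTranslator, F_a: np.ndarray,
    t_b: ModalityTranslator, F_b: np.ndarray,
) -> float:
    """Pairing probability of one item of each modality; symmetric in (a, b)."""
    if t_a.d_bio != t_b.d_bio:
        raise ValueError("translators do not share a text dimension")
    za = t_a.project(np.atleast_2d(F_a))[0]
    zb = t_b.project(np.atleast_2d(F_b))[0]
    return float(_sigmoid(np.array(za @ zb)))


def cross_modal_score_matrix(
    t_a: ModalityTranslator, F_a: np.ndarray,
    t_b: ModalityTranslator, F_b: np.ndarray,
) -> np.ndarray:
    """All-pairs pairing probabilities, (n_a, n_b), strictly inside (0, 1)."""
    if t_a.d_bio != t_b.d_bio:
        raise ValueError("translators do not share a text dimension")
    p = _sigmoid(t_a.project(F_a) @ t_b.project(F_b).T)
    return np.clip(p, np.finfo(float).tiny, 1.0 - np.finfo(float).epsneg)


def pathway_embedding(gene_embeddings) -> np.ndarray:
    """Sum-pool member-gene projections (sum keeps pathway size information)."""
    gene_embeddings = list(gene_embeddings)
    if not gene_embeddings:
        raise ValueError("empty pathway")
    return np.sum(np.stack(gene_embeddings), axis=0)


def graph_node_features(
    g: nx.Graph, dim: int, restart: float = 0.5, seed: int = 0,
) -> tuple[list, np.ndarray]:
    """Diffusion node embeddings: RWR proximity + truncated factorization.

    The random-walk-with-restart proximity matrix
    ``R = r (I - (1-r) P)^{-1}`` (P the column-stochastic transition matrix)
    is symmetrized and factorized by eigendecomposition; nodes are embedded
    as the top-``dim`` components scaled by sqrt of the eigenvalue magnitude.
    Deterministic up to a fixed per-component sign convention.
    """
    nodes = sorted(g.nodes)
    n = len(nodes)
    if dim >= n:
        raise ValueError("dim must be smaller than the node count")
    A = nx.to_numpy_array(g, nodelist=nodes)
    deg = A.sum(axis=0)
    deg[deg == 0] = 1.0
    P = A / deg  # column-stochastic
    R = restart * np.linalg.inv(np.eye(n) - (1 - restart) * P)
    S = (R + R.T) / 2.0
    vals, vecs = np.linalg.eigh(S)
    order = np.argsort(-np.abs(vals))[:dim]
    comp = vecs[:, order] * np.sqrt(np.abs(vals[order]))
    # sign convention: largest-magnitude entry of each component is positive
    for j in range(comp.shape[1]):
        k = np.argmax(np.abs(comp[:, j]))
        if comp[k, j] < 0:
            comp[:, j] = -comp[:, j]
    return nodes, comp


def rank_candidates(query: np.ndarray, candidates: dict[str, np.ndarray]) -> list[str]:
    """Candidate ids by descending pairing score with the query projection.

    Ties break deterministically by id.  The query and candidate vectors are
    text-space projections (e.g. translator outputs); nearest-gene target
    prediction ranks gene projections against a drug projection.
    """
    if not candidates:
        raise ValueError("no candidates to rank")
    query = np.asarray(query, dtype=float)
    scored = sorted(
        ((-float(query @ np.asarray(v, float)), cid) for cid, v in candidates.items())
    )
    return [cid for _, cid in scored]


def write_predictions(
    stream, query_id: str, query: np.ndarray, candidates: dict[str, np.ndarray],
) -> None:
    """Emit ranked predictions as TSV: query_id, candidate_id, probability, rank."""
    order = rank_candidates(query, candidates)
    for rank, cid in enumerate(order, start=1):
        p = float(_sigmoid(np.array(np.asarray(query) @ np.asarray(candidates[cid]))))
        stream.write(f"{query_id}\t{cid}\t{p:.6g}\t{rank}\n")
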