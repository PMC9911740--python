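"""Text encoders and ontology-driven contrastive fine-tuning.

Class descriptions (ontology term name + definition) are embedded into a
fixed-dimension vector space.  The encoder contract is pluggable:

* :class:`HashingEncoder` — deterministic bag-of-tokens feature hashing with
  random signs; no trainable state.  Texts sharing more tokens get a higher
  cosine, which is exactly the structure the contrastive objective assumes.
* :class:`EmbeddingBagEncoder` — a small trainable token-embedding table read
  out by mean pooling; the backend used to exercise contrastive fine-tuning
  at CPU scale.  A pretrained-transformer backend can implement the same
  :class:`TextEncoder` interface.

Fine-tuning treats descriptions of adjacent ontology terms as positive pairs
and every other in-batch pairing as a negative: each batch of B pairs yields
a B x B cosine-similarity matrix, scaled by an inverse temperature, scored
against its diagonal with cross-entropy in both directions (the InfoNCE
form).  Terms that are close in the ontology are thereby pulled together in
the embedding space, which is what lets a classifier trained on seen classes
generalize to unseen ones through their descriptions.
"""

from __future__ import annotations

import copy
import hashlib
import re
from dataclasses import dataclass

import numpy as np

from ._optim import Adam
from .ontology import OntologyGraph, DEFAULT_RELATIONS

__all__ = [
    "EncoderConfig",
    "NeighborPairSet",
    "TextEncoder",
    "HashingEncoder",
    "EmbeddingBagEncoder",
    "tokenize",
    "build_neighbor_pairs",
    "contrastive_finetune",
    "info_nce_loss",
    "encode_texts",
]

_TOKEN_RE = re.compile(r"[a-z0-9]+")


def tokenize(text: str) -> list[str]:
    """Lowercase word split with punctuation stripped."""
    return _TOKEN_RE.findall(text.lower())


@dataclass
class EncoderConfig:
    """Fine-tuning hyperparameters.

    Defaults follow the training recipe for the text encoder: Adam at
    learning rate 1e-5, batch size 16, descriptions truncated to 256 tokens.
    """

    d_bio: int = 768
    max_tokens: int = 256
    learning_rate: float = 1e-5
    batch_size: int = 16
    epochs: int = 1
    temperature: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.max_tokens < 1:
            raise ValueError("max_tokens must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")


@dataclass
class NeighborPairSet:
    """Positive description pairs drawn from adjacent ontology terms."""

    pairs: list[tuple[str, str]]

    def __post_init__(self):
        for a, b in self.pairs:
            if not a or not b:
                raise ValueError("pair texts must be non-empty")

    def __len__(self) -> int:
        return len(self.pairs)


def _stable_bucket(token: str, n_buckets: int, salt: int) -> tuple[int, float]:
    """Deterministic (bucket, sign) for a token, independent of PYTHONHASHSEED."""
    digest = hashlib.md5(f"{salt}:{token}".encode()).digest()
    bucket = int.from_bytes(digest[:8], "little") % n_buckets
    sign = 1.0 if digest[8] % 2 == 0 else -1.0
    return bucket, sign


class TextEncoder:
    """Encoder contract: a pure function of (weights, text, max_tokens)."""

    dim: int
    max_tokens: int = 256

    def encode(self, texts: list[str]) -> np.ndarray:
        """Return an (n, dim) float array of L2-normalized embeddings."""
        raise NotImplementedError

    def encode_one(self, text: str) -> np.ndarray:
        return self.encode([text])[0]


class HashingEncoder(TextEncoder):
    """Signed bag-of-tokens feature hashing, L2-normalized; no trainable state."""

    def __init__(self, dim: int = 768, seed: int = 0, max_tokens: int = 256):
        if dim < 8:
            raise ValueError("dim must be >= 8")
        self.dim = dim
        self.seed = seed
        self.max_tokens = max_tokens

    def encode(self, texts: list[str]) -> np.ndarray:
        out = np.zeros((len(texts), self.dim))
        for i, text in enumerate(texts):
            if not text:
                raise ValueError("cannot encode empty text")
            for tok in tokenize(text)[: self.max_tokens]:
                bucket, sign = _stable_bucket(tok, self.dim, self.seed)
                out[i, bucket] += sign
            norm = np.linalg.norm(out[i])
            if norm == 0:
                # text with no alphanumeric tokens: fall back to a unit basis vector
                out[i, 0] = 1.0
            else:
                out[i] /= norm
        return out


class EmbeddingBagEncoder(TextEncoder):
    """Trainable token-embedding table with mean pooling and L2 readout.

    Tokens hash into ``vocab_size`` rows of an embedding matrix; a sentence is
    the mean of its token rows, normalized to unit length.  Small enough to
    fine-tune contrastively on a laptop CPU while exposing the same interface
    a transformer backend would.
    """

    def __init__(self, dim: int = 128, vocab_size: int = 4096, seed: int = 0,
                 max_tokens: int = 256):
        if dim < 8:
            raise ValueError("dim must be >= 8")
        self.dim = dim
        self.vocab_size = vocab_size
        self.seed = seed
        self.max_tokens = max_tokens
        rng = np.random.default_rng(seed)
        self.embedding = rng.normal(0.0, 1.0 / np.sqrt(dim), size=(vocab_size, dim))

    def _token_rows(self, text: str) -> np.ndarray:
        if not text:
            raise ValueError("cannot encode empty text")
        toks = tokenize(text)[: self.max_tokens]
        if not toks:
            return np.array([0], dtype=np.intp)
        return np.array(
            [_stable_bucket(t, self.vocab_size, self.seed)[0] for t in toks],
            dtype=np.intp,
        )

    def encode(self, texts: list[str]) -> np.ndarray:
        out = np.empty((len(texts), self.dim))
        for i, text in enumerate(texts):
            rows = self._token_rows(text)
            u = self.embedding[rows].mean(axis=0)
            norm = np.linalg.norm(u)
            out[i] = u / norm if norm > 0 else u
        return out


def encode_texts(texts: list[str], encoder: TextEncoder) -> np.ndarray:
    """Encode a batch of texts; errors on empty input or empty strings."""
    if not texts:
        raise ValueError("no texts to encode")
    return encoder.encode(list(texts))


def build_neighbor_pairs(
    g: OntologyGraph,
    seed: int = 0,
    relations=DEFAULT_RELATIONS,
    delimiter: str = ". ",
) -> NeighborPairSet:
    """One positive description pair per ontology edge, in seeded order."""
    digraph = g.graph(relations)
    desc = g.descriptions(delimiter=delimiter)
    pairs = [
        (desc[child], desc[parent])
        for child, parent in sorted(digraph.edges())
        if desc.get(child) and desc.get(parent)
    ]
    if not pairs:
        raise ValueError("ontology has no edges with described endpoints")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(pairs))
    return NeighborPairSet([pairs[k] for k in order])


def info_nce_loss(Z_a: np.ndarray, Z_b: np.ndarray, temperature: float = 1.0):
    """Symmetric in-batch contrastive loss and its gradient wrt the matrices.

    ``S = Z_a Z_b^T / temperature`` is scored against diagonal targets with
    softmax cross-entropy over rows and over columns; the two directions are
    averaged.  Returns ``(loss, dZ_a, dZ_b)``.
    """
    B = Z_a.shape[0]
    S = Z_a @ Z_b.T / temperature
    S_row = S - S.max(axis=1, keepdims=True)
    P_row = np.exp(S_row)
    P_row /= P_row.sum(axis=1, keepdims=True)
    S_col = S - S.max(axis=0, keepdims=True)
    P_col = np.exp(S_col)
    P_col /= P_col.sum(axis=0, keepdims=True)
    diag = np.arange(B)
    loss = -0.5 * (
        np.log(P_row[diag, diag] + 1e-300).mean()
        + np.log(P_col[diag, diag] + 1e-300).mean()
    )
    if not np.isfinite(loss):
        raise FloatingPointError("non-finite contrastive loss")
    eye = np.eye(B)
    dS = 0.5 * ((P_row - eye) + (P_col - eye)) / (B * temperature)
    return loss, dS @ Z_b, dS.T @ Z_a


def _normalize_backward(u: np.ndarray, z: np.ndarray, dz: np.ndarray) -> np.ndarray:
    """Backprop through z = u / ||u|| for one vector."""
    norm = np.linalg.norm(u)
    if norm == 0:
        return dz
    return (dz - z * (z @ dz)) / norm


def contrastive_finetune(
    encoder: EmbeddingBagEncoder,
    pairs: NeighborPairSet,
    cfg: EncoderConfig,
) -> EmbeddingBagEncoder:
    """Fine-tune a trainable encoder on neighbor-term description pairs.

    Returns a new encoder; the input encoder is left untouched.  With
    ``cfg.epochs == 0`` the returned weights equal the input weights.
    """
    if not isinstance(encoder, EmbeddingBagEncoder):
        raise TypeError("contrastive_finetune needs a trainable encoder backend")
    if cfg.batch_size > len(pairs):
        raise ValueError("batch_size exceeds the number of pairs")
    tuned = copy.deepcopy(encoder)
    if cfg.epochs == 0:
        return tuned
    opt = Adam({"E": tuned.embedding}, lr=cfg.learning_rate)
    rng = np.random.default_rng(cfg.seed)
    token_rows = [
        (tuned._token_rows(a), tuned._token_rows(b)) for a, b in pairs.pairs
    ]
    n = len(token_rows)
    for _ in range(cfg.epochs):
        order = rng.permutation(n)
        for start in range(0, n - cfg.batch_size + 1, cfg.batch_size):
            batch = order[start : start + cfg.batch_size]
            U_a = np.stack([tuned.embedding[token_rows[k][0]].mean(axis=0) for k in batch])
            U_b = np.stack([tuned.embedding[token_rows[k][1]].mean(axis=0) for k in batch])
            na = np.linalg.norm(U_a, axis=1, keepdims=True)
            nb = np.linalg.norm(U_b, axis=1, keepdims=True)
            Z_a = np.divide(U_a, na, out=U_a.copy(), where=na > 0)
            Z_b = np.divide(U_b, nb, out=U_b.copy(), where=nb > 0)
            _, dZ_a, dZ_b = info_nce_loss(Z_a, Z_b, cfg.temperature)
            dE = np.zeros_like(tuned.embedding)
            for i, k in enumerate(batch):
                rows_a, rows_b = token_rows[k]
                du_a = _normalize_backward(U_a[i], Z_a[i], dZ_a[i])
                du_b = _normalize_backward(U_b[i], Z_b[i], dZ_b[i])
                np.add.at(dE, rows_a, du_a / len(rows_a))
                np.add.at(dE, rows_b, du_b / len(rows_b))
            opt.step({"E": dE})
    return tuned


def neighbor_cosine_gap(
    encoder: TextEncoder,
    g: OntologyGraph,
    seed: int = 0,
    n_random: int = 200,
    relations=DEFAULT_RELATIONS,
) -> float:
    """Mean cosine of neighbor description pairs minus that of random pairs."""
    digraph = g.graph(relations)
    desc = g.descriptions()
    ids = sorted(desc)
    Z = {i: v for i, v in zip(ids, encoder.encode([desc[i] for i in ids]))}
    edge_set = {frozenset(e) for e in digraph.edges()}
    neigh = [float(Z[a] @ Z[b]) for a, b in digraph.edges()]
    rng = np.random.default_rng(seed)
    rand = []
    while len(rand) < n_random:
        a, b = rng.choice(ids, size=2, replace=False)
        if frozenset((a, b)) not in edge_set:
            rand.append(float(Z[a] @ Z[b]))
    return float(np.mean(neigh) - np.mean(rand))
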