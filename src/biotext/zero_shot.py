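"""Bi-nonlinear zero-shot classifier over the shared text space.

The classifier scores an instance embedding ``F`` against a class text
embedding ``Y`` through a learned bilinear form passed through a logistic:

    p(instance i annotated to class j) = sigmoid(F_i^T W Y_j)

Training minimizes the independent per-class binary cross-entropy between
those probabilities and the (true-path propagated) annotation matrix ``A``,
jointly over the instance-encoder weights and ``W``, with Adam.  Because a
class enters only through its description embedding ``Y_j``, a class never
seen in training is scored by simply embedding its free-text description —
this is what makes the model zero-shot.

Organized statsmodels-style: :class:`ZeroShotModel` holds the data and
architecture, ``fit()`` returns a :class:`ZeroShotResults` carrying the
learned weights, the loss trajectory, prediction methods and ``summary()``.
"""

from __future__ import annotations

import json
import pathlib
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import roc_auc_score

from ._optim import Adam
from .encoders import DenseBlock
from .ontology import AnnotationMatrix
from .text import TextEncoder

__all__ = [
    "TrainConfig",
    "ScoreMatrix",
    "score",
    "score_matrix",
    "bce_loss",
    "auroc",
    "ZeroShotModel",
    "ZeroShotResults",
]


@dataclass
class TrainConfig:
    """Optimization settings (Adam, lr 1e-4, batch 128; 30 epochs for protein
    function models, 15 for cell-type models)."""

    learning_rate: float = 1e-4
    batch_size: int = 128
    epochs: int = 15
    hidden_dim: int = 30
    weight_decay: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if min(self.learning_rate, self.batch_size, self.hidden_dim) <= 0:
            raise ValueError("learning_rate, batch_size and hidden_dim must be positive")
        if self.epochs < 0 or self.weight_decay < 0:
            raise ValueError("epochs and weight_decay must be >= 0")


@dataclass
class ScoreMatrix:
    """Instance x class probabilities, each strictly in (0, 1)."""

    probabilities: np.ndarray
    instance_ids: list[str]
    term_ids: list[str]

    def __post_init__(self):
        p = np.asarray(self.probabilities, dtype=float)
        if p.shape != (len(self.instance_ids), len(self.term_ids)):
            raise ValueError("probability shape does not match id lists")
        if not ((p > 0) & (p < 1)).all():
            raise ValueError("probabilities must lie strictly in (0, 1)")
        self.probabilities = p

    def to_tsv(self, stream) -> None:
        stream.write("instance_id\t" + "\t".join(self.term_ids) + "\n")
        for i, inst in enumerate(self.instance_ids):
            row = "\t".join(f"{v:.6g}" for v in self.probabilities[i])
            stream.write(f"{inst}\t{row}\n")


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x, dtype=float)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def score(F: np.ndarray, W: np.ndarray, Y: np.ndarray) -> float:
    """Probability sigmoid(F^T W Y) for one instance/class pair."""
    F, Y = np.asarray(F, dtype=float), np.asarray(Y, dtype=float)
    if F.shape[0] != W.shape[0] or Y.shape[0] != W.shape[1]:
        raise ValueError(
            f"shape mismatch: F {F.shape}, W {W.shape}, Y {Y.shape}"
        )
    return float(_sigmoid(np.array(F @ W @ Y)))


def score_matrix(F: np.ndarray, W: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Vectorized sigmoid(F W Y^T) for (n, dF) instances x (c, d_bio) classes."""
    logits = np.asarray(F) @ W @ np.asarray(Y).T
    # keep strictly inside (0, 1) even when the sigmoid saturates in float64
    tiny = np.finfo(float).tiny
    return np.clip(_sigmoid(logits), tiny, 1.0 - np.finfo(float).epsneg)


def _softplus(x: np.ndarray) -> np.ndarray:
    return np.logaddexp(0.0, x)


def bce_loss(
    F_batch: np.ndarray,
    Y_all: np.ndarray,
    A_batch: np.ndarray,
    W: np.ndarray,
    reduction: str = "sum",
) -> float:
    """Binary cross-entropy between A and sigmoid(F W Y^T).

    ``reduction='sum'`` is the plain double sum over instances and classes;
    ``'mean'`` divides by the number of entries (the training reduction).
    """
    A = np.asarray(A_batch)
    if not np.isin(A, (0, 1)).all():
        raise ValueError("annotation matrix must be binary")
    logits = np.asarray(F_batch) @ W @ np.asarray(Y_all).T
    # numerically stable: softplus(z) - a*z  ==  -a*log(p) - (1-a)*log(1-p)
    per_entry = _softplus(logits) - A * logits
    total = float(per_entry.sum())
    if reduction == "mean":
        return total / per_entry.size
    if reduction == "sum":
        return total
    raise ValueError(f"unknown reduction {reduction!r}")


def auroc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Rank-based AUROC with ties counted half."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("AUROC is undefined when labels contain a single class")
    return float(roc_auc_score(labels, np.asarray(scores, dtype=float)))


class ZeroShotModel:
    """Bi-nonlinear annotation model built from features, annotations and text.

    Parameters
    ----------
    features
    	Either an (n, d) array, or an ordered dict name -> (n, d_block) array
    	of per-block raw features encoded by separate dense layers.
    annotations
    	Binary :class:`AnnotationMatrix`; should already be true-path
    	propagated so ancestor classes receive positive examples.
    class_texts
    	Mapping term id -> free-text description for (at least) every
    	annotated class.
    encoder
    	A :class:`~biotext.text.TextEncoder`; class embeddings are computed
    	once from it and frozen during classifier training.
    """

    def __init__(
        self,
        features,
        annotations: AnnotationMatrix,
        class_texts: dict[str, str],
        encoder: TextEncoder,
    ):
        if isinstance(features, np.ndarray):
            features = {"features": features}
        self.blocks = {k: np.asarray(v, dtype=float) for k, v in features.items()}
        n_rows = {v.shape[0] for v in self.blocks.values()}
        if len(n_rows) != 1 or n_rows.pop() != len(annotations.instance_ids):
            raise ValueError("feature rows do not match annotation instances")
        self.annotations = annotations
        self.encoder = encoder
        self.class_texts = dict(class_texts)
        # training classes: annotated at least once, with a description
        counts = annotations.A.sum(axis=0)
        self.train_terms = [
            t for t, c in zip(annotations.term_ids, counts)
            if c > 0 and self.class_texts.get(t)
        ]
        missing = [
            t for t, c in zip(annotations.term_ids, counts)
            if c > 0 and not self.class_texts.get(t)
        ]
        if missing:
            raise ValueError(f"annotated classes lack descriptions: {missing[:5]}")
        if not self.train_terms:
            raise ValueError("no annotated classes to train on")

    def fit(self, cfg: TrainConfig | None = None) -> "ZeroShotResults":
        cfg = cfg or TrainConfig()
        rng = np.random.default_rng(cfg.seed)
        Y = self.encoder.encode([self.class_texts[t] for t in self.train_terms])
        d_bio = Y.shape[1]

        block_names = list(self.blocks)
        encoders = {
            name: DenseBlock(
                self.blocks[name].shape[1], cfg.hidden_dim,
                seed=int(rng.integers(2**31)),
            )
            for name in block_names
        }
        dF = cfg.hidden_dim * len(block_names)
        W = rng.normal(0.0, 0.1 / np.sqrt(d_bio), size=(dF, d_bio))

        cols = [self.annotations._term_index[t] for t in self.train_terms]
        A = self.annotations.A[:, cols].astype(float)
        n = A.shape[0]
        params = {"W": W}
        for name in block_names:
            params[f"{name}.W"] = encoders[name].W
            params[f"{name}.b"] = encoders[name].b
        opt = Adam(params, lr=cfg.learning_rate, weight_decay=cfg.weight_decay)

        history = []
        for _ in range(cfg.epochs):
            order = rng.permutation(n)
            for start in range(0, n, cfg.batch_size):
                idx = order[start : start + cfg.batch_size]
                xs = {name: self.blocks[name][idx] for name in block_names}
                zs = {name: xs[name] @ encoders[name].W + encoders[name].b
                      for name in block_names}
                hs = {name: np.maximum(zs[name], 0.0) for name in block_names}
                F = np.concatenate([hs[name] for name in block_names], axis=1)
                logits = F @ W @ Y.T
                P = _sigmoid(logits)
                loss = float((_softplus(logits) - A[idx] * logits).mean())
                if not np.isfinite(loss):
                    raise FloatingPointError("training loss became non-finite")
                history.append(loss)
                G = (P - A[idx]) / logits.size
                GY = G @ Y                      # (B, d_bio)
                grads = {"W": F.T @ GY}
                dF_full = GY @ W.T              # (B, dF)
                for k, name in enumerate(block_names):
                    sl = slice(k * cfg.hidden_dim, (k + 1) * cfg.hidden_dim)
                    dz = dF_full[:, sl] * (zs[name] > 0)
                    grads[f"{name}.W"] = xs[name].T @ dz
                    grads[f"{name}.b"] = dz.sum(axis=0)
                opt.step(grads)

        return ZeroShotResults(
            model=self, config=cfg, W=W, block_encoders=encoders,
            Y_train=Y, loss_history=history,
        )


@dataclass
class ZeroShotResults:
    """Fitted weights plus prediction, novel-class annotation and summary."""

    model: ZeroShotModel
    config: TrainConfig
    W: np.ndarray
    block_encoders: dict[str, DenseBlock]
    Y_train: np.ndarray
    loss_history: list[float] = field(default_factory=list)

    def embed_instances(self, features) -> np.ndarray:
        """Encode raw per-block features into instance embeddings F."""
        if isinstance(features, np.ndarray):
            features = {"features": features}
        names = list(self.model.blocks)
        if set(features) != set(names):
            raise ValueError(f"expected feature blocks {names}")
        return np.concatenate(
            [self.block_encoders[n].forward(np.asarray(features[n], float))
             for n in names],
            axis=1,
        )

    def predict(self, features, instance_ids: list[str] | None = None) -> ScoreMatrix:
        """Score instances against the training classes."""
        F = self.embed_instances(features)
        probs = score_matrix(F, self.W, self.Y_train)
        ids = instance_ids or [f"instance_{i}" for i in range(F.shape[0])]
        return ScoreMatrix(probs, ids, list(self.model.train_terms))

    def annotate_novel(
        self,
        features,
        novel_descriptions: dict[str, str],
        instance_ids: list[str] | None = None,
    ) -> ScoreMatrix:
        """Zero-shot scores against classes given only by free text.

        Only the description text of each novel class is consulted; no
        annotation of a novel class enters the computation.
        """
        terms = list(novel_descriptions)
        texts = [novel_descriptions[t] for t in terms]
        if not terms or any(not t for t in texts):
            raise ValueError("novel class descriptions must be non-empty")
        Y_novel = self.model.encoder.encode(texts)
        F = self.embed_instances(features)
        probs = score_matrix(F, self.W, Y_novel)
        ids = instance_ids or [f"instance_{i}" for i in range(F.shape[0])]
        return ScoreMatrix(probs, ids, terms)

    def summary(self) -> str:
        m = self.model
        lines = [
            "Zero-shot bi-nonlinear annotation model",
            "=" * 44,
            f"instances:        {len(m.annotations.instance_ids)}",
            f"training classes: {len(m.train_terms)}",
            f"feature blocks:   " + ", ".join(
                f"{n}({v.shape[1]}->{self.config.hidden_dim})"
                for n, v in m.blocks.items()
            ),
            f"text dimension:   {self.Y_train.shape[1]}",
            f"bilinear W shape: {self.W.shape[0]} x {self.W.shape[1]}",
            f"epochs / batch:   {self.config.epochs} / {self.config.batch_size}",
        ]
        if self.loss_history:
            lines.append(f"first batch loss: {self.loss_history[0]:.4f}")
            lines.append(f"final batch loss: {self.loss_history[-1]:.4f}")
        return "\n".join(lines)

    def save(self, directory) -> None:
        """Persist as a directory manifest: config JSON + npz weight file."""
        directory = pathlib.Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        manifest = {
            "config": vars(self.config),
            "train_terms": self.model.train_terms,
            "block_names": list(self.block_encoders),
        }
        (directory / "manifest.json").write_text(json.dumps(manifest, indent=1))
        arrays = {"W": self.W, "Y_train": self.Y_train}
        for name, enc in self.block_encoders.items():
            arrays[f"{name}.W"] = enc.W
            arrays[f"{name}.b"] = enc.b
        np.savez(directory / "weights.npz", **arrays)
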