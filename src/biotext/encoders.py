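"""Per-feature-block instance encoders and their concatenation.

A biological instance (a protein, a cell, a drug, ...) may carry several
heterogeneous feature blocks — an expression vector, a network-embedding
vector, an amino-acid sequence.  Each block is encoded by its own small
network into a hidden vector of width ``h_j`` and the results are
concatenated into the combined instance embedding ``F`` of length
``sum_j h_j``.  Dense blocks use a single fully connected layer with ReLU;
sequences go through a bank of 1-d convolutions with multiple kernel sizes
followed by global max pooling, so the default protein sequence embedding is
16 kernel sizes x 512 filters = 8192 wide.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from Bio import SeqIO

__all__ = [
    "DenseBlock",
    "FeatureBlock",
    "InstanceEmbedding",
    "SequenceEncoderConfig",
    "SequenceCNN",
    "encode_feature_block",
    "concat_blocks",
    "encode_sequence_cnn",
    "default_modality_configs",
    "read_fasta",
    "read_smiles",
    "smiles_fingerprint",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
PAD, UNKNOWN = "-", "X"
#: 20 standard residues + X (unknown) + pad channel
DEFAULT_ALPHABET = AMINO_ACIDS + UNKNOWN + PAD


@dataclass
class FeatureBlock:
    """One named raw feature (a real vector or a residue sequence)."""

    name: str
    raw: object
    hidden_dim: int

    def __post_init__(self):
        if self.hidden_dim < 1:
            raise ValueError("hidden_dim must be >= 1")


@dataclass
class InstanceEmbedding:
    """Concatenated per-block embedding F with its (name, width) layout."""

    vector: np.ndarray
    block_layout: list[tuple[str, int]]

    def __post_init__(self):
        expected = sum(h for _, h in self.block_layout)
        if self.vector.shape != (expected,):
            raise ValueError(
                f"vector length {self.vector.shape} != layout total {expected}"
            )


class DenseBlock:
    """Single fully connected layer with ReLU: h = relu(x W + b)."""

    def __init__(self, in_dim: int, out_dim: int, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.W = rng.normal(0.0, 1.0 / np.sqrt(in_dim), size=(in_dim, out_dim))
        self.b = np.zeros(out_dim)

    @property
    def params(self) -> dict[str, np.ndarray]:
        return {"W": self.W, "b": self.b}

    def forward(self, x: np.ndarray) -> np.ndarray:
        x = np.atleast_2d(x)
        if x.shape[1] != self.W.shape[0]:
            raise ValueError(
                f"input dim {x.shape[1]} does not match weights {self.W.shape[0]}"
            )
        return np.maximum(x @ self.W + self.b, 0.0)

    def forward_backward(self, x: np.ndarray, d_out: np.ndarray):
        """Return (output, grads dict, d_input) for upstream gradient d_out."""
        z = x @ self.W + self.b
        h = np.maximum(z, 0.0)
        dz = d_out * (z > 0)
        grads = {"W": x.T @ dz, "b": dz.sum(axis=0)}
        return h, grads, dz @ self.W.T


def encode_feature_block(block: FeatureBlock, weights: DenseBlock) -> np.ndarray:
    """Encode one real-vector feature block into its hidden vector."""
    raw = np.asarray(block.raw, dtype=float)
    if raw.ndim != 1:
        raise ValueError("feature block raw input must be a vector")
    if not np.all(np.isfinite(raw)):
        raise ValueError("feature block contains non-finite values")
    return weights.forward(raw)[0]


def concat_blocks(
    encoded: list[np.ndarray], layout: list[tuple[str, int]]
) -> InstanceEmbedding:
    """Concatenate per-block vectors in the fixed layout order."""
    if len(encoded) != len(layout):
        raise ValueError("number of encoded blocks does not match layout")
    for vec, (name, h) in zip(encoded, layout):
        if vec.shape != (h,):
            raise ValueError(f"block {name!r} has length {vec.shape}, expected {h}")
    return InstanceEmbedding(np.concatenate(encoded), list(layout))


@dataclass
class SequenceEncoderConfig:
    """Convolutional sequence-encoder architecture.

    Sixteen kernel sizes 8, 16, ..., 128 with 512 filters each; after global
    max pooling the concatenated embedding is 16 x 512 = 8192 wide.
    """

    kernel_sizes: tuple = tuple(range(8, 129, 8))
    filters_per_kernel: int = 512
    alphabet: str = DEFAULT_ALPHABET
    max_length: int = 2000

    def __post_init__(self):
        ks = tuple(self.kernel_sizes)
        if any(b <= a for a, b in zip(ks, ks[1:])):
            raise ValueError("kernel_sizes must be strictly increasing")
        self.kernel_sizes = ks

    @property
    def output_dim(self) -> int:
        return len(self.kernel_sizes) * self.filters_per_kernel


def one_hot_sequence(seq: str, cfg: SequenceEncoderConfig) -> np.ndarray:
    """One-hot (max_length, |alphabet|); unknown residues map to X, pad beyond."""
    if not seq:
        raise ValueError("empty sequence")
    alpha_index = {c: i for i, c in enumerate(cfg.alphabet)}
    unk = alpha_index[UNKNOWN]
    mat = np.zeros((cfg.max_length, len(cfg.alphabet)))
    pad_col = alpha_index[PAD]
    mat[:, pad_col] = 1.0
    for pos, residue in enumerate(seq[: cfg.max_length].upper()):
        mat[pos, pad_col] = 0.0
        mat[pos, alpha_index.get(residue, unk)] = 1.0
    return mat


class SequenceCNN:
    """Multi-kernel 1-d convolution bank with global max pooling.

    For each kernel size k the one-hot sequence is convolved with
    ``filters_per_kernel`` filters (ReLU) and max-pooled over all positions,
    so the pooled vector is position-invariant; the per-kernel vectors are
    concatenated.
    """

    def __init__(self, cfg: SequenceEncoderConfig | None = None, seed: int = 0):
        self.cfg = cfg or SequenceEncoderConfig()
        rng = np.random.default_rng(seed)
        width = len(self.cfg.alphabet)
        self.filters = {
            k: rng.normal(0.0, 1.0 / np.sqrt(k * width),
                          size=(k * width, self.cfg.filters_per_kernel))
            for k in self.cfg.kernel_sizes
        }
        self.biases = {
            k: np.zeros(self.cfg.filters_per_kernel) for k in self.cfg.kernel_sizes
        }

    @property
    def output_dim(self) -> int:
        return self.cfg.output_dim

    def encode(self, seq: str) -> np.ndarray:
        mat = one_hot_sequence(seq, self.cfg)
        pooled = []
        for k in self.cfg.kernel_sizes:
            windows = np.lib.stride_tricks.sliding_window_view(mat, (k, mat.shape[1]))
            flat = windows.reshape(windows.shape[0], -1)
            act = np.maximum(flat @ self.filters[k] + self.biases[k], 0.0)
            pooled.append(act.max(axis=0))
        return np.concatenate(pooled)


def encode_sequence_cnn(
    seq: str, cfg: SequenceEncoderConfig | None = None,
    weights: SequenceCNN | None = None, seed: int = 0,
) -> np.ndarray:
    """Convenience wrapper building a seeded :class:`SequenceCNN` if needed."""
    if weights is None:
        weights = SequenceCNN(cfg, seed=seed)
    elif cfg is not None and weights.cfg is not cfg:
        raise ValueError("cfg conflicts with the supplied weights")
    return weights.encode(seq)


# Per-modality feature-block layouts.  Protein instances carry sequence,
# free-text description and network-embedding blocks, each embedded to 1500;
# expression profiles use a single 30-wide dense block.  Widths for the
# drug / gene / phenotype translator modalities are not architecture
# constants of the method and default to 768.
_MODALITY_CONFIGS = {
    "protein": {
        "blocks": [("sequence", 1500), ("description", 1500), ("network", 1500)],
    },
    "expression": {"blocks": [("expression", 30)]},
    "drug": {"blocks": [("smiles_fingerprint", 768)]},
    "gene": {"blocks": [("network", 768)]},
    "phenotype": {"blocks": [("network", 768)]},
    "pathway": {"blocks": [("gene_pool", 768)]},
}


def default_modality_configs(modality: str | None = None) -> dict:
    """Default feature-block layout per modality (or the full table)."""
    if modality is None:
        return {k: {"blocks": list(v["blocks"])} for k, v in _MODALITY_CONFIGS.items()}
    try:
        entry = _MODALITY_CONFIGS[modality]
    except KeyError:
        raise KeyError(f"unknown modality {modality!r}") from None
    return {"blocks": list(entry["blocks"])}


def read_fasta(path_or_handle) -> dict[str, str]:
    """Read sequences from FASTA into an id -> sequence mapping."""
    return {
        rec.id: str(rec.seq) for rec in SeqIO.parse(path_or_handle, "fasta")
    }


def read_smiles(path_or_handle) -> dict[str, str]:
    """Read molecules as 'id<TAB>SMILES' (or bare SMILES) lines."""
    close = False
    if isinstance(path_or_handle, str):
        path_or_handle = open(path_or_handle)
        close = True
    try:
        out = {}
        for k, line in enumerate(path_or_handle):
            parts = line.strip().split("\t")
            if not parts or not parts[0]:
                continue
            if len(parts) >= 2:
                out[parts[0]] = parts[1]
            else:
                out[f"mol_{k}"] = parts[0]
        return out
    finally:
        if close:
            path_or_handle.close()


def smiles_fingerprint(smiles: str, n_bits: int = 2048, radius: int = 2) -> np.ndarray:
    """Morgan (ECFP-like) fingerprint as a dense 0/1 vector.

    A deterministic drug feature vector for translator training when no
    pretrained molecular encoder is configured.
    """
    from rdkit import Chem, RDLogger
    from rdkit.Chem import rdFingerprintGenerator

    RDLogger.DisableLog("rdApp.*")
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparsable SMILES: {smiles!r}")
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=n_bits)
    fp = gen.GetFingerprint(mol)
    arr = np.zeros(n_bits)
    arr[list(fp.GetOnBits())] = 1.0
    return arr


def log_normalize_expression(counts: np.ndarray, target_sum: float = 1e4) -> np.ndarray:
    """log1p of library-size-normalized counts (standard scRNA preprocessing)."""
    counts = np.asarray(counts, dtype=float)
    lib = counts.sum(axis=1, keepdims=True)
    lib[lib == 0] = 1.0
    return np.log1p(counts / lib * target_sum)
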