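"""A small DeepGOPlus-style CNN forward pass built from elementary scalar
operations, so that every FLOP is routed through an arithmetic backend.

Architecture (mirroring the protein-function CNN it emulates): parallel 1-D
convolution branches with different kernel lengths over one-hot encoded
amino-acid sequences, each followed by ReLU and a global max-pool; the
pooled features are concatenated and fed to a dense layer with a sigmoid,
producing one probability per ontology class.

Precision classes: all convolution and dense elementwise multiplies are
"single"-class; the dense-layer accumulation and the sigmoid are
"double"-class.  This mirrors the production model, where the bulk of the
arithmetic runs in single precision while the core dot-product accumulation
runs in double.  The assignment is configurable per stage.

The accumulation order of every sum is fixed (left-to-right over kernel
position, then alphabet, then feature index) so deterministic backends are
bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np

from .backends import ArithmeticBackend

__all__ = [
    "AA_ALPHABET",
    "ModelConfig",
    "ConvOpCount",
    "ForwardResult",
    "PredictionMatrix",
    "encode_sequences",
    "forward",
    "count_conv_ops",
    "branch_op_count",
    "DEFAULT_CLASS_ASSIGNMENT",
]

#: 20 standard amino acids plus 'X' for unknown residues.
AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWYX"

_AA_INDEX = np.full(256, len(AA_ALPHABET) - 1, dtype=np.int64)
for _i, _aa in enumerate(AA_ALPHABET):
    _AA_INDEX[ord(_aa)] = _i
    _AA_INDEX[ord(_aa.lower())] = _i


@dataclass(frozen=True)
class ModelConfig:
    """Shape of the CNN.

    The desk-scale default (4 branches, 8 filters each, 64 classes,
    256-residue input) runs in seconds; the production-scale model (16
    branches, 2000-residue input, millions of parameters) is expressible
    with the same fields but is not the default.
    """

    alphabet_size: int = len(AA_ALPHABET)
    max_seq_len: int = 256
    kernel_lengths: tuple = (5, 8, 12, 16)
    filters_per_branch: int = 8
    n_classes: int = 64
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_classes < 1:
            raise ValueError("n_classes must be >= 1")
        if len(set(self.kernel_lengths)) != len(self.kernel_lengths):
            raise ValueError("kernel_lengths must be distinct")
        for k in self.kernel_lengths:
            if not 1 <= k <= self.max_seq_len:
                raise ValueError(
                    f"kernel length {k} outside [1, max_seq_len={self.max_seq_len}]"
                )

    @property
    def n_features(self) -> int:
        return len(self.kernel_lengths) * self.filters_per_branch


@dataclass(frozen=True)
class ConvOpCount:
    """Multiplication count of a convolution, as the product of output
    feature-map size, channel counts and kernel size:

        total = O_h * O_w * C_o * C_i * K_h * K_w

    For the 1-D branches used here, O_h = K_h = 1.
    """

    O_h: int
    O_w: int
    C_o: int
    C_i: int
    K_h: int
    K_w: int

    def __post_init__(self) -> None:
        for name in ("O_h", "O_w", "C_o", "C_i", "K_h", "K_w"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")

    @property
    def total(self) -> int:
        return self.O_h * self.O_w * self.C_o * self.C_i * self.K_h * self.K_w


def count_conv_ops(O_h: int, O_w: int, C_o: int, C_i: int, K_h: int, K_w: int) -> ConvOpCount:
    """Arithmetic-operation count of a convolution from its dimensions."""
    return ConvOpCount(O_h, O_w, C_o, C_i, K_h, K_w)


def branch_op_count(cfg: ModelConfig, kernel_length: int) -> ConvOpCount:
    """Predicted multiply count for one 1-D branch, per protein."""
    return ConvOpCount(
        O_h=1,
        O_w=cfg.max_seq_len - kernel_length + 1,
        C_o=cfg.filters_per_branch,
        C_i=cfg.alphabet_size,
        K_h=1,
        K_w=kernel_length,
    )


def encode_sequences(records: Sequence, cfg: ModelConfig) -> np.ndarray:
    """One-hot encode protein sequences to a (n, max_seq_len, alphabet) array.

    ``records`` is a sequence of ``(id, sequence)`` pairs or objects with
    ``.id`` and ``.seq`` attributes (e.g. Biopython ``SeqRecord``).  Each
    sequence is right-padded with all-zero columns; sequences longer than
    ``max_seq_len`` are truncated.  Residues outside the 20-letter alphabet
    map to the unknown symbol 'X'.
    """
    ids, seqs = [], []
    for rec in records:
        if hasattr(rec, "id") and hasattr(rec, "seq"):
            ids.append(str(rec.id))
            seqs.append(str(rec.seq))
        else:
            rid, seq = rec
            ids.append(str(rid))
            seqs.append(str(seq))
    X = np.zeros((len(seqs), cfg.max_seq_len, cfg.alphabet_size), dtype=np.float64)
    for i, (rid, seq) in enumerate(zip(ids, seqs)):
        if len(seq) == 0:
            raise ValueError(f"empty sequence for record {rid!r}")
        idx = _AA_INDEX[np.frombuffer(seq[: cfg.max_seq_len].encode("ascii"), dtype=np.uint8)]
        X[i, np.arange(idx.size), idx] = 1.0
    return X


DEFAULT_CLASS_ASSIGNMENT: Mapping[str, str] = {
    "conv": "single",
    "dense_mul": "single",
    "dense_acc": "double",
    "sigmoid": "double",
}


@dataclass
class ForwardResult:
    """Outcome of one forward pass.

    ``scores`` are sigmoid outputs clipped to [0, 1] when the run completed;
    if any stage produced a non-finite value from finite inputs the run is
    marked ``crashed`` with the offending stage recorded and the raw scores
    are kept for inspection (they must not be used as predictions).
    """

    scores: np.ndarray
    crashed: bool
    crash_stage: Optional[str]
    op_counts: Mapping


@dataclass
class PredictionMatrix:
    """Protein x ontology-class probability scores from one backend run."""

    protein_ids: list
    class_ids: list
    scores: np.ndarray
    backend: str
    repetition: Optional[int] = None

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=np.float64)
        if self.scores.shape != (len(self.protein_ids), len(self.class_ids)):
            raise ValueError(
                f"scores shape {self.scores.shape} inconsistent with "
                f"{len(self.protein_ids)} proteins x {len(self.class_ids)} classes"
            )
        if not np.isfinite(self.scores).all():
            raise ValueError("prediction scores must be finite")
        if (self.scores < 0).any() or (self.scores > 1).any():
            raise ValueError("prediction scores must lie in [0, 1]")

    def to_frame(self):
        import pandas as pd

        n, c = self.scores.shape
        return pd.DataFrame(
            {
                "protein_id": np.repeat(self.protein_ids, c),
                "class_id": np.tile(self.class_ids, n),
                "score": self.scores.ravel(),
            }
        )


def forward(
    X: np.ndarray,
    weights: Mapping[str, np.ndarray],
    backend: ArithmeticBackend,
    cfg: ModelConfig,
    class_assignment: Optional[Mapping[str, str]] = None,
) -> ForwardResult:
    """Run the CNN forward pass with every FLOP routed through ``backend``.

    ``weights`` maps ``conv_k{K}_kernel`` (K, alphabet, filters) and
    ``conv_k{K}_bias`` (filters,) per branch, plus ``dense_w``
    (n_features, n_classes) and ``dense_b`` (n_classes,).  Use a fresh
    backend instance per run: operation counters and overflow flags
    accumulate on the backend.
    """
    ca = dict(DEFAULT_CLASS_ASSIGNMENT)
    if class_assignment:
        ca.update(class_assignment)
    B = X.shape[0]
    feats = []
    for K in cfg.kernel_lengths:
        stage = f"conv_k{K}"
        cls = ca["conv"]
        W = backend.prep_weights(weights[f"conv_k{K}_kernel"], cls)
        b = backend.prep_weights(weights[f"conv_k{K}_bias"], cls)
        if W.shape != (K, cfg.alphabet_size, cfg.filters_per_branch):
            raise ValueError(f"weights {stage}_kernel have shape {W.shape}, "
                             f"expected {(K, cfg.alphabet_size, cfg.filters_per_branch)}")
        P = cfg.max_seq_len - K + 1
        Xs = backend.prep_stage_input(X, cls, stage)
        acc = np.zeros((B, P, cfg.filters_per_branch), dtype=np.float64)
        for k in range(K):
            window = Xs[:, k : k + P, :]
            for a in range(cfg.alphabet_size):
                prod = backend.mul(window[:, :, a : a + 1], W[k, a], cls, stage)
                acc = backend.add(acc, prod, cls, stage)
        acc = backend.add(acc, b, cls, stage)
        acc = backend.relu(acc)
        feats.append(backend.maxpool(acc, axis=1))
    h = np.concatenate(feats, axis=1)  # (B, n_features)

    Wd = backend.prep_weights(weights["dense_w"], ca["dense_mul"])
    bd = backend.prep_weights(weights["dense_b"], ca["dense_acc"])
    if Wd.shape != (cfg.n_features, cfg.n_classes):
        raise ValueError(f"dense_w has shape {Wd.shape}, expected "
                         f"{(cfg.n_features, cfg.n_classes)}")
    h = backend.prep_stage_input(h, ca["dense_mul"], "dense")
    z = np.zeros((B, cfg.n_classes), dtype=np.float64)
    for j in range(cfg.n_features):
        prod = backend.mul(h[:, j : j + 1], Wd[j], ca["dense_mul"], "dense")
        z = backend.add(z, prod, ca["dense_acc"], "dense")
    z = backend.add(z, bd, ca["dense_acc"], "dense")

    # sigmoid(z) = 1 / (1 + exp(-z)); the sign flip is exact and not an
    # instrumented operation
    z = backend.prep_stage_input(z, ca["sigmoid"], "sigmoid")
    ez = backend.exp(np.negative(z), ca["sigmoid"], "sigmoid")
    den = backend.add(1.0, ez, ca["sigmoid"], "sigmoid")
    s = backend.div(1.0, den, ca["sigmoid"], "sigmoid")

    crashed = bool(backend.overflow_stages) or not np.isfinite(s).all()
    if crashed:
        stage = next(iter(backend.overflow_stages), "output")
        return ForwardResult(s, True, stage, dict(backend.op_counts))
    return ForwardResult(np.clip(s, 0.0, 1.0), False, None, dict(backend.op_counts))
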