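"""Synthetic benchmark generator.

Real evaluations of protein-function predictors need a trained model, a
curated ontology and an annotated sequence corpus.  For testing the
numerical-stability pipeline none of that is required — only data with the
same statistical structure:

* amino-acid sequences of realistic length (50-2000 residues);
* a DAG ontology with three namespace roots, every class reaching one root;
* truth annotation sets closed under ancestors (true-path rule);
* a *teacher* model whose class probabilities correlate with the truth, so
  that Fmax, Smin and AUPR are all non-degenerate.

The teacher plants one exact k-mer motif per annotated leaf class in the
protein sequence and wires the CNN to detect it: one convolution branch per
namespace (kernel length = that namespace's motif length) with one filter
per motif leaf, plus a distractor branch with dense random weights so that
every class probability carries smoothly varying arithmetic.  The teacher
is deliberately well-conditioned — filter outputs sit well away from
catastrophic cancellation — because the object under study is the
arithmetic, not the classifier.

Everything is a deterministic function of the config seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Tuple

import numpy as np
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .metrics import Ontology, propagate, propagate_scores
from .model import AA_ALPHABET, ModelConfig, PredictionMatrix, encode_sequences, forward
from .backends import IEEEBackend

__all__ = [
    "SyntheticConfig",
    "Benchmark",
    "make_ontology",
    "assign_motifs",
    "make_proteins_and_truth",
    "make_teacher_weights",
    "make_benchmark",
    "benchmark_config",
]

_NAMESPACES = ("bp", "mf", "cc")
_AA20 = AA_ALPHABET[:20]

# teacher wiring constants: a full motif match scores 1.0 at the filter,
# the bias keeps the ReLU margin at 0.25 (four binary digits away from
# cancellation), and the dense layer maps one detected motif to a logit of
# +1 against a background of -2
_MOTIF_BIAS = -0.75
_MOTIF_GAIN = 12.0
_DENSE_BIAS = -2.0
_DISTRACTOR_KERNEL_STD = 0.15
_DISTRACTOR_BIAS = 0.3
_DISTRACTOR_DENSE_STD = 0.15


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of the synthetic benchmark.

    ``motif_strength`` is the probability that an annotated leaf's motif is
    actually implanted in the sequence; ``label_noise`` is the probability
    that a truth leaf is swapped for a random other leaf of the same
    namespace after the sequence was built (mislabelling).
    """

    n_proteins: int = 200
    length_range: Tuple[int, int] = (50, 2000)
    n_classes: int = 64
    n_namespaces: int = 3
    internal_per_namespace: int = 4
    motif_lengths: Tuple[int, ...] = (8, 12, 16)
    motif_strength: float = 1.0
    label_noise: float = 0.0
    annotations_per_namespace: Tuple[int, int] = (1, 2)
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.length_range
        if lo < 1 or hi < lo:
            raise ValueError(f"invalid length_range {self.length_range}")
        if self.n_namespaces < 1 or self.n_namespaces > len(_NAMESPACES):
            raise ValueError("n_namespaces must be 1..3")
        if self.n_classes < self.n_namespaces:
            raise ValueError("need at least one class per namespace")
        if not 0.0 <= self.motif_strength <= 1.0:
            raise ValueError("motif_strength must be in [0, 1]")
        if not 0.0 <= self.label_noise <= 1.0:
            raise ValueError("label_noise must be in [0, 1]")


def benchmark_config(seed: int = 0) -> SyntheticConfig:
    """The packaged benchmark: 200 proteins, 64 classes, sequences capped
    at the model's 256-residue window, strong-but-imperfect motif signal
    and 10% label noise so every metric is strictly between its degenerate
    extremes."""
    return SyntheticConfig(
        n_proteins=200,
        length_range=(50, 250),
        n_classes=64,
        motif_strength=0.9,
        label_noise=0.1,
        seed=seed,
    )


def _namespace_sizes(cfg: SyntheticConfig) -> List[int]:
    base = cfg.n_classes // cfg.n_namespaces
    sizes = [base] * cfg.n_namespaces
    for i in range(cfg.n_classes - base * cfg.n_namespaces):
        sizes[i] += 1
    return sizes


def make_ontology(cfg: SyntheticConfig) -> Ontology:
    """Random DAG with ``n_namespaces`` roots; acyclic by construction
    (every node's parents are created before it) and each class reaches
    exactly its own namespace root."""
    rng = np.random.default_rng(cfg.seed)
    edges = []
    nodes = []
    for j, size in enumerate(_namespace_sizes(cfg)):
        ns = _NAMESPACES[j]
        root = f"{ns}:root"
        nodes.append(root)
        if size == 1:
            continue
        n_internal = min(cfg.internal_per_namespace, size - 1)
        internals = [f"{ns}:i{i:02d}" for i in range(n_internal)]
        for i, node in enumerate(internals):
            nodes.append(node)
            if i == 0:
                edges.append((node, root))
            else:
                parents = [root] + internals[:i]
                k = 2 if (len(parents) > 1 and rng.random() < 0.3) else 1
                for p in rng.choice(parents, size=k, replace=False):
                    edges.append((node, str(p)))
        n_leaves = size - 1 - n_internal
        pool = internals if internals else [root]
        for i in range(n_leaves):
            leaf = f"{ns}:l{i:02d}"
            nodes.append(leaf)
            k = 2 if (len(pool) > 1 and rng.random() < 0.4) else 1
            for p in rng.choice(pool, size=k, replace=False):
                edges.append((leaf, str(p)))
    return Ontology(edges, nodes=nodes)


def _motif_leaves(cfg: SyntheticConfig, ontology: Ontology, model_cfg: ModelConfig) -> Dict[str, List[str]]:
    """Per namespace root, the leaf classes that carry motifs (at most one
    per convolution filter)."""
    out = {}
    for j in range(cfg.n_namespaces):
        root = f"{_NAMESPACES[j]}:root"
        leaves = [c for c in ontology.leaves() if ontology.namespace_of(c) == root]
        out[root] = leaves[: model_cfg.filters_per_branch]
    return out


def assign_motifs(cfg: SyntheticConfig, ontology: Ontology, model_cfg: ModelConfig) -> Dict[str, str]:
    """Assign one distinct exact k-mer motif to every motif-bearing leaf;
    the motif length is the namespace's entry in ``cfg.motif_lengths``."""
    rng = np.random.default_rng(cfg.seed + 1)
    motifs: Dict[str, str] = {}
    seen = set()
    for j in range(cfg.n_namespaces):
        root = f"{_NAMESPACES[j]}:root"
        L = cfg.motif_lengths[j % len(cfg.motif_lengths)]
        for leaf in _motif_leaves(cfg, ontology, model_cfg)[root]:
            while True:
                m = "".join(rng.choice(list(_AA20), size=L))
                if m not in seen:
                    seen.add(m)
                    motifs[leaf] = m
                    break
    return motifs


def _implant(seq: np.ndarray, motif: str, occupied: List[Tuple[int, int]], rng) -> bool:
    L = len(motif)
    if L > seq.size:
        return False
    for _ in range(30):
        start = int(rng.integers(0, seq.size - L + 1))
        if all(start + L <= lo or start >= hi for lo, hi in occupied):
            seq[start : start + L] = list(motif)
            occupied.append((start, start + L))
            return True
    return False


def make_proteins_and_truth(
    cfg: SyntheticConfig,
    ontology: Ontology,
    motifs: Dict[str, str],
):
    """Generate sequences with implanted motifs and ancestor-closed truth.

    Each protein receives 1-2 truth leaves per namespace drawn from the
    motif-bearing leaves; each truth leaf's motif is implanted with
    probability ``motif_strength`` (at a position not overlapping earlier
    implants).  ``label_noise`` then swaps truth leaves for random other
    leaves of the same namespace without touching the sequence.  Returns
    ``(records, truth, truth_leaves)`` with ``truth`` propagated.
    """
    rng = np.random.default_rng(cfg.seed + 2)
    by_ns = {root: leaves for root, leaves in
             ((f"{_NAMESPACES[j]}:root", None) for j in range(cfg.n_namespaces))}
    ns_roots = list(by_ns)
    leaf_pool = {root: [c for c in motifs if ontology.namespace_of(c) == root]
                 for root in ns_roots}
    lo, hi = cfg.length_range
    k_lo, k_hi = cfg.annotations_per_namespace
    records = []
    truth_leaves: Dict[str, set] = {}
    for i in range(cfg.n_proteins):
        pid = f"P{i:04d}"
        length = int(rng.integers(lo, hi + 1))
        seq = rng.choice(list(_AA20), size=length)
        occupied: List[Tuple[int, int]] = []
        leaves = set()
        for root in ns_roots:
            pool = leaf_pool[root]
            if not pool:
                continue
            k = int(rng.integers(k_lo, min(k_hi, len(pool)) + 1))
            chosen = rng.choice(pool, size=k, replace=False)
            for leaf in chosen:
                leaf = str(leaf)
                leaves.add(leaf)
                if rng.random() < cfg.motif_strength:
                    _implant(seq, motifs[leaf], occupied, rng)
        noisy = set()
        for leaf in sorted(leaves):
            root = ontology.namespace_of(leaf)
            pool = leaf_pool[root]
            if cfg.label_noise > 0 and len(pool) > 1 and rng.random() < cfg.label_noise:
                others = [c for c in pool if c != leaf]
                noisy.add(str(rng.choice(others)))
            else:
                noisy.add(leaf)
        truth_leaves[pid] = noisy
        records.append(SeqRecord(Seq("".join(seq)), id=pid, description=""))
    truth = propagate(truth_leaves, ontology)
    return records, truth, truth_leaves


def make_teacher_weights(
    cfg: SyntheticConfig,
    model_cfg: ModelConfig,
    ontology: Ontology,
    motifs: Dict[str, str],
) -> Dict[str, np.ndarray]:
    """Wire the CNN so its class probabilities track the implanted motifs.

    Motif filters score 1.0 on a full k-mer match (1/K per matching
    residue) with bias -0.75, so the ReLU passes 0.25 exactly when the
    motif is present and 0 otherwise; the dense layer adds +12 * 0.25 = +3
    to the logit of every ancestor of the detected leaf against a -2
    background.  Branches without a matching motif length act as
    distractors with small dense random weights, giving every class
    probability a smoothly varying arithmetic path.
    """
    rng = np.random.default_rng(cfg.seed + 3)
    A = model_cfg.alphabet_size
    F = model_cfg.filters_per_branch
    class_ids = ontology.classes
    cidx = {c: i for i, c in enumerate(class_ids)}
    aa_idx = {aa: i for i, aa in enumerate(AA_ALPHABET)}

    used_lengths = {cfg.motif_lengths[j % len(cfg.motif_lengths)]: f"{_NAMESPACES[j]}:root"
                    for j in range(cfg.n_namespaces)}
    missing = set(used_lengths) - set(model_cfg.kernel_lengths)
    if missing:
        raise ValueError(
            f"model kernel_lengths {model_cfg.kernel_lengths} lack motif "
            f"lengths {sorted(missing)}"
        )

    weights: Dict[str, np.ndarray] = {}
    dense_w = np.zeros((model_cfg.n_features, model_cfg.n_classes))
    feat0 = 0
    ml = _motif_leaves(cfg, ontology, model_cfg)
    for K in model_cfg.kernel_lengths:
        kernel = rng.normal(0.0, _DISTRACTOR_KERNEL_STD, size=(K, A, F))
        bias = np.full(F, _DISTRACTOR_BIAS)
        dense_rows = rng.normal(0.0, _DISTRACTOR_DENSE_STD,
                                size=(F, model_cfg.n_classes))
        root = used_lengths.get(K)
        if root is not None:
            for f, leaf in enumerate(ml[root]):
                kernel[:, :, f] = 0.0
                for k, aa in enumerate(motifs[leaf]):
                    kernel[k, aa_idx[aa], f] = 1.0 / K
                bias[f] = _MOTIF_BIAS
                dense_rows[f] = 0.0
                for anc in ontology.ancestors(leaf):
                    dense_rows[f, cidx[anc]] = _MOTIF_GAIN
        weights[f"conv_k{K}_kernel"] = kernel
        weights[f"conv_k{K}_bias"] = bias
        dense_w[feat0 : feat0 + F] = dense_rows
        feat0 += F
    weights["dense_w"] = dense_w
    weights["dense_b"] = np.full(model_cfg.n_classes, _DENSE_BIAS)
    return weights


@dataclass
class Benchmark:
    """A complete, self-contained synthetic study: sequences, ontology,
    truth, teacher weights and the model configuration that ties them
    together.  ``class_ids`` fixes the column order of every score
    matrix."""

    cfg: SyntheticConfig
    model_cfg: ModelConfig
    ontology: Ontology
    motifs: Dict[str, str]
    records: list
    truth: Dict[str, frozenset]
    truth_leaves: Dict[str, set]
    weights: Dict[str, np.ndarray]

    @property
    def protein_ids(self) -> list:
        return [r.id for r in self.records]

    @property
    def class_ids(self) -> list:
        return self.ontology.classes

    def subset(self, n: int) -> "Benchmark":
        """First ``n`` proteins, everything else shared."""
        records = self.records[:n]
        keep = {r.id for r in records}
        return replace(
            self,
            records=records,
            truth={p: v for p, v in self.truth.items() if p in keep},
            truth_leaves={p: v for p, v in self.truth_leaves.items() if p in keep},
        )


def make_benchmark(
    cfg: SyntheticConfig,
    model_cfg: Optional[ModelConfig] = None,
    truth_mode: str = "motifs",
    tau: float = 0.5,
) -> Benchmark:
    """Build the full benchmark from a config.

    ``truth_mode="motifs"`` (default) labels proteins by the leaves whose
    motifs were planted; ``truth_mode="scores"`` instead derives truth from
    the unperturbed teacher itself — a class is true iff its propagated
    reference score reaches ``tau`` — which guarantees a perfectly
    separable benchmark (Fmax = 1 for the reference run).
    """
    if model_cfg is None:
        model_cfg = ModelConfig(n_classes=cfg.n_classes, seed=cfg.seed)
    if model_cfg.n_classes != cfg.n_classes:
        raise ValueError("model n_classes must match the ontology size")
    ontology = make_ontology(cfg)
    motifs = assign_motifs(cfg, ontology, model_cfg)
    records, truth, truth_leaves = make_proteins_and_truth(cfg, ontology, motifs)
    weights = make_teacher_weights(cfg, model_cfg, ontology, motifs)
    bench = Benchmark(cfg, model_cfg, ontology, motifs, records, truth,
                      truth_leaves, weights)
    if truth_mode == "scores":
        X = encode_sequences(records, model_cfg)
        res = forward(X, weights, IEEEBackend(), model_cfg)
        if res.crashed:
            raise RuntimeError("reference forward pass crashed while deriving truth")
        sc = propagate_scores(res.scores, bench.class_ids, ontology)
        class_ids = bench.class_ids
        truth = {}
        truth_leaves = {}
        for i, pid in enumerate(bench.protein_ids):
            chosen = {class_ids[j] for j in np.flatnonzero(sc[i] >= tau)}
            truth[pid] = frozenset().union(*(ontology.ancestors(c) for c in chosen)) \
                if chosen else frozenset()
            truth_leaves[pid] = chosen
        bench.truth = truth
        bench.truth_leaves = truth_leaves
    elif truth_mode != "motifs":
        raise ValueError(f"unknown truth_mode {truth_mode!r}")
    return bench
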