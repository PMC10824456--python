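"""CAFA-style evaluation of hierarchical function predictions.

Protein function classes live in a directed acyclic graph with three
namespace roots (the biological-process / molecular-function / cellular-
component split of the Gene Ontology).  Annotations obey the true-path
rule: a protein annotated with a class is implicitly annotated with every
ancestor.  Predictions are propagated the complementary way — a parent's
score is at least the maximum of its descendants' scores — before
thresholding.

Metrics over a threshold grid t in {0.01, ..., 1.00}:

* ``Fmax``: maximum over t of the harmonic mean of protein-averaged
  precision and recall (precision averaged only over proteins with at
  least one predicted term, the CAFA convention).
* ``Smin``: minimum over t of sqrt(ru(t)^2 + mi(t)^2), where ru is the
  information content of true-but-unpredicted classes (remaining
  uncertainty) and mi of predicted-but-untrue classes (misinformation),
  both averaged over proteins.
* ``AUPR``: trapezoidal integral of precision over recall along the same
  threshold grid, without extrapolation beyond the observed endpoints.

Information content is the namespace-conditional negative log2 frequency
of a class in an annotation corpus, with additive smoothing; roots carry
zero information.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, Mapping, Optional, Set

import networkx as nx
import numpy as np

__all__ = [
    "Ontology",
    "propagate",
    "information_content",
    "propagate_scores",
    "ThresholdCurve",
    "threshold_curve",
    "fmax",
    "smin",
    "aupr",
    "DEFAULT_THRESHOLDS",
]

#: Eq-style threshold grid: 0.01 steps over [0.01, 1.00].
DEFAULT_THRESHOLDS = np.arange(1, 101) / 100.0


class Ontology:
    """A DAG of function classes with directed is-a edges child -> parent.

    Every class must reach exactly one of the namespace roots (nodes
    without parents).  Ancestor closures are precomputed on construction.
    """

    def __init__(self, edges: Iterable[tuple], nodes: Optional[Iterable[str]] = None):
        g = nx.DiGraph()
        if nodes is not None:
            g.add_nodes_from(nodes)
        g.add_edges_from(edges)  # child -> parent
        if not nx.is_directed_acyclic_graph(g):
            raise ValueError("ontology contains a cycle")
        self.graph = g
        self.roots = sorted(n for n in g.nodes if g.out_degree(n) == 0)
        if not self.roots:
            raise ValueError("ontology has no root")
        self._closure: Dict[str, frozenset] = {}
        self._namespace: Dict[str, str] = {}
        for node in nx.topological_sort(g.reverse(copy=False)):  # roots first
            parents = list(g.successors(node))
            clo = frozenset({node}).union(*(self._closure[p] for p in parents)) \
                if parents else frozenset({node})
            self._closure[node] = clo
            reach = clo & set(self.roots)
            if len(reach) != 1:
                raise ValueError(
                    f"class {node!r} reaches {len(reach)} roots; every class "
                    "must reach exactly one namespace root"
                )
            self._namespace[node] = next(iter(reach))

    @property
    def classes(self) -> list:
        return sorted(self.graph.nodes)

    def __contains__(self, c: str) -> bool:
        return c in self.graph

    def ancestors(self, c: str) -> frozenset:
        """Ancestor closure of ``c``, including ``c`` itself."""
        return self._closure[c]

    def namespace_of(self, c: str) -> str:
        """The namespace root reached by class ``c``."""
        return self._namespace[c]

    def namespace_classes(self, root: str) -> list:
        return sorted(c for c, r in self._namespace.items() if r == root)

    def leaves(self) -> list:
        return sorted(n for n in self.graph.nodes if self.graph.in_degree(n) == 0
                      and self.graph.out_degree(n) > 0)

    def topological_leaf_to_root(self) -> list:
        return list(nx.topological_sort(self.graph))


def propagate(annotations: Mapping[str, Iterable[str]], ontology: Ontology) -> Dict[str, frozenset]:
    """Close each protein's annotation set under ancestors (true-path rule)."""
    out = {}
    for protein, classes in annotations.items():
        closed: Set[str] = set()
        for c in classes:
            if c not in ontology:
                raise ValueError(
                    f"protein {protein!r} annotated with unknown class {c!r}"
                )
            closed |= ontology.ancestors(c)
        out[protein] = frozenset(closed)
    return out


def information_content(
    corpus: Mapping[str, Iterable[str]],
    ontology: Ontology,
    eps: float = 1.0,
) -> Dict[str, float]:
    """Information content of every ontology class from an annotation corpus.

    IC(c) = -log2((n_c + eps) / (n_root(c) + eps)) where n_c counts corpus
    proteins annotated with c and n_root(c) those annotated with c's
    namespace root; the corpus must already be ancestor-closed.  Roots have
    IC exactly 0; additive smoothing (eps, default 1) keeps never-annotated
    classes finite.
    """
    if not corpus:
        raise ValueError("empty annotation corpus")
    counts: Dict[str, int] = {c: 0 for c in ontology.classes}
    for classes in corpus.values():
        for c in classes:
            counts[c] += 1
    ic = {}
    for c in ontology.classes:
        root = ontology.namespace_of(c)
        if c == root:
            ic[c] = 0.0
        else:
            ic[c] = float(-np.log2((counts[c] + eps) / (counts[root] + eps)))
    return ic


def propagate_scores(scores: np.ndarray, class_ids: list, ontology: Ontology) -> np.ndarray:
    """Propagate prediction scores to ancestors by maximum over descendants.

    A parent is at least as likely as any of its children, so each class's
    score becomes the maximum over its descendant closure (including
    itself).  ``scores`` is (n_proteins, n_classes) aligned with
    ``class_ids``.
    """
    idx = {c: i for i, c in enumerate(class_ids)}
    out = np.array(scores, dtype=np.float64, copy=True)
    for child in ontology.topological_leaf_to_root():  # children before parents
        if child not in idx:
            continue
        ci = idx[child]
        for parent in ontology.graph.successors(child):
            if parent in idx:
                pi = idx[parent]
                np.maximum(out[:, pi], out[:, ci], out=out[:, pi])
    return out


@dataclass
class ThresholdCurve:
    """Per-threshold precision/recall and semantic-distance components.

    ``n`` is the number of evaluated proteins; ``coverage`` counts, per
    threshold, the proteins with at least one predicted term (the
    denominator of the precision average).
    """

    thresholds: np.ndarray
    avg_pr: np.ndarray
    avg_rc: np.ndarray
    ru: np.ndarray
    mi: np.ndarray
    n: int
    coverage: np.ndarray


def threshold_curve(
    predictions,
    truth: Mapping[str, frozenset],
    ic: Mapping[str, float],
    ontology: Ontology,
    namespace: Optional[str] = None,
    thresholds: np.ndarray = DEFAULT_THRESHOLDS,
    propagated: bool = False,
) -> ThresholdCurve:
    """Compute the evaluation curve of a prediction matrix against truth.

    ``predictions`` is a :class:`~fuzzyfunc.model.PredictionMatrix` (or any
    object with ``protein_ids``, ``class_ids`` and ``scores``).  Scores are
    first propagated to ancestors by maximum unless ``propagated`` is set.
    If ``namespace`` is given (a root id), evaluation is restricted to that
    namespace's classes; proteins without any truth annotation among the
    evaluated classes are excluded, the CAFA convention.
    """
    protein_ids = list(predictions.protein_ids)
    class_ids = list(predictions.class_ids)
    for p in protein_ids:
        if p not in truth:
            raise ValueError(f"protein {p!r} present in predictions but absent from truth")
    scores = np.asarray(predictions.scores, dtype=np.float64)
    if not propagated:
        scores = propagate_scores(scores, class_ids, ontology)

    if namespace is not None:
        keep = [i for i, c in enumerate(class_ids) if ontology.namespace_of(c) == namespace]
        class_ids = [class_ids[i] for i in keep]
        scores = scores[:, keep]

    cset = set(class_ids)
    cidx = {c: i for i, c in enumerate(class_ids)}
    T = np.zeros((len(protein_ids), len(class_ids)), dtype=bool)
    for i, p in enumerate(protein_ids):
        for c in truth[p]:
            if c in cset:
                T[i, cidx[c]] = True
    has_truth = T.any(axis=1)
    T = T[has_truth]
    scores = scores[has_truth]
    n = int(has_truth.sum())
    if n == 0:
        raise ValueError("no protein has truth annotations among the evaluated classes")

    icv = np.array([ic[c] for c in class_ids], dtype=np.float64)
    nt = T.sum(axis=1).astype(np.float64)

    n_thr = len(thresholds)
    avg_pr = np.zeros(n_thr)
    avg_rc = np.zeros(n_thr)
    ru = np.zeros(n_thr)
    mi = np.zeros(n_thr)
    coverage = np.zeros(n_thr, dtype=int)
    for j, t in enumerate(thresholds):
        P = scores >= t
        tp = (P & T).sum(axis=1).astype(np.float64)
        npred = P.sum(axis=1).astype(np.float64)
        covered = npred > 0
        coverage[j] = int(covered.sum())
        avg_rc[j] = (tp / nt).mean()
        avg_pr[j] = (tp[covered] / npred[covered]).mean() if covered.any() else 0.0
        ru[j] = ((T & ~P) @ icv).sum() / n
        mi[j] = ((P & ~T) @ icv).sum() / n
    return ThresholdCurve(np.asarray(thresholds, float), avg_pr, avg_rc, ru, mi, n, coverage)


def fmax(curve: ThresholdCurve):
    """Maximum harmonic mean of averaged precision and recall over the
    threshold grid; returns ``(value, threshold)``.  A 0/0 harmonic mean is
    0; ties report the smallest maximising threshold."""
    pr, rc = curve.avg_pr, curve.avg_rc
    with np.errstate(invalid="ignore", divide="ignore"):
        f = np.where(pr + rc > 0, 2 * pr * rc / (pr + rc), 0.0)
    i = int(np.argmax(f))  # argmax returns the first (smallest-t) maximiser
    return float(f[i]), float(curve.thresholds[i])


def smin(curve: ThresholdCurve) -> float:
    """Minimum semantic distance sqrt(ru^2 + mi^2) over the threshold grid."""
    return float(np.min(np.sqrt(curve.ru**2 + curve.mi**2)))


def aupr(curve: ThresholdCurve) -> float:
    """Area under the precision-recall curve by the trapezoidal rule.

    Thresholds where nothing is predicted define no precision and are
    excluded.  The remaining points are sorted by recall and integrated as
    observed, with no extrapolation beyond the endpoints.  Fewer than two
    distinct recall values cannot span an area: a predictor pinned at the
    perfect corner (precision = recall = 1 everywhere) scores 1, anything
    else returns 0 with a warning.
    """
    covered = curve.coverage > 0
    rc = curve.avg_rc[covered]
    pr = curve.avg_pr[covered]
    if rc.size and np.unique(rc).size < 2:
        if (rc == 1.0).all() and (pr == 1.0).all():
            return 1.0
    if np.unique(rc).size < 2:
        warnings.warn("fewer than 2 distinct recall points; AUPR undefined, returning 0")
        return 0.0
    order = np.argsort(rc, kind="stable")
    return float(np.trapezoid(pr[order], rc[order]))
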