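"""End-to-end experiments: MCA stability quantification and reduced-
precision sweeps.

``run_mca_experiment`` runs one unperturbed reference forward pass plus n
Monte-Carlo-Arithmetic repetitions, then summarises the variability of
every class probability and of every classification metric (Fmax, Smin,
AUPR per namespace) as mean, standard deviation and significant digits.

``run_format_sweep`` evaluates the deterministic reduced-precision
backends over a grid of (double-class format x single-class format)
combinations — by default the sixteen pairs of float32 / float16 /
bfloat16 / bfloat8 — in inbound or outbound mode, recording per-cell
relative metric differences against the IEEE reference, with crashes
(non-finite propagation) captured as data rather than raised.

``run_precision_exponent_search`` sweeps custom (precision, exponent)
formats for the single-precision class while double precision is left
untouched, and reports the region where every metric stays within a
tolerance of the reference.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .backends import IEEEBackend, MCABackend, VprecBackend
from .formats import FloatFormat, parse_format, preset
from .mca import VirtualPrecision
from .metrics import information_content, threshold_curve, fmax, smin, aupr
from .model import PredictionMatrix, encode_sequences, forward
from .simulate import Benchmark
from .uncertainty import SampleSet, significant_bits_array, summarize, to_digits

__all__ = [
    "MCAExperimentResult",
    "SweepCell",
    "SweepResult",
    "PrecisionSearchResult",
    "evaluate_predictions",
    "run_mca_experiment",
    "run_format_sweep",
    "run_precision_exponent_search",
    "DEFAULT_SWEEP_FORMATS",
]

DEFAULT_SWEEP_FORMATS = ("float32", "float16", "bfloat16", "bfloat8")

METRICS = ("fmax", "smin", "aupr")


def evaluate_predictions(pred: PredictionMatrix, bench: Benchmark, ic) -> Dict[str, Dict[str, float]]:
    """Fmax/Smin/AUPR per namespace root for one prediction matrix."""
    out: Dict[str, Dict[str, float]] = {}
    for root in bench.ontology.roots:
        curve = threshold_curve(pred, bench.truth, ic, bench.ontology, namespace=root)
        fm, _ = fmax(curve)
        out[root] = {"fmax": fm, "smin": smin(curve), "aupr": aupr(curve)}
    return out


def _ieee_run(bench: Benchmark, X):
    res = forward(X, bench.weights, IEEEBackend(), bench.model_cfg)
    if res.crashed:
        raise RuntimeError(f"IEEE reference run crashed at stage {res.crash_stage}")
    return PredictionMatrix(bench.protein_ids, bench.class_ids, res.scores, "ieee")


@dataclass
class MCAExperimentResult:
    """Outputs of the MCA stability experiment.

    ``class_prob_report`` has one row per (protein, class) probability;
    ``metric_report`` one row per metric per namespace.  Both carry mean,
    population std, significant bits/digits across the repetitions,
    measured against the IEEE reference.  ``metric_samples`` keeps the raw
    per-repetition metric values.
    """

    class_prob_report: pd.DataFrame
    metric_report: pd.DataFrame
    reference_metrics: Dict[str, Dict[str, float]]
    metric_samples: Dict[Tuple[str, str], np.ndarray]
    config: Dict

    def median_class_prob_std(self) -> float:
        return float(self.class_prob_report["std"].median())


def run_mca_experiment(
    bench: Benchmark,
    n_repetitions: int = 10,
    seed: int = 0,
    t_single: int = 24,
    t_double: int = 53,
) -> MCAExperimentResult:
    """One IEEE reference run plus ``n_repetitions`` MCA-RR runs.

    Repetition i uses RNG seed ``seed + i`` (i = 1..n), so the samples are
    independent yet the whole experiment is bit-reproducible from ``seed``.
    A crash in any repetition is an error: Random Rounding must not crash
    the model.
    """
    if n_repetitions < 2:
        raise ValueError("need at least 2 repetitions to estimate a standard deviation")
    vp_s = VirtualPrecision(t_single, preset("float32"))
    vp_d = VirtualPrecision(t_double, preset("float64"))
    X = encode_sequences(bench.records, bench.model_cfg)
    ref = _ieee_run(bench, X)
    ic = information_content(bench.truth, bench.ontology)
    ref_metrics = evaluate_predictions(ref, bench, ic)

    score_samples = np.empty((n_repetitions,) + ref.scores.shape)
    metric_samples = {
        (root, m): np.empty(n_repetitions) for root in bench.ontology.roots for m in METRICS
    }
    for i in range(1, n_repetitions + 1):
        backend = MCABackend(seed + i, vp_s, vp_d)
        res = forward(X, bench.weights, backend, bench.model_cfg)
        if res.crashed:
            raise RuntimeError(
                f"MCA-RR repetition {i} crashed at stage {res.crash_stage}; "
                "Random Rounding is not expected to crash"
            )
        pred = PredictionMatrix(bench.protein_ids, bench.class_ids, res.scores,
                                "mca_rr", repetition=i)
        score_samples[i - 1] = pred.scores
        for root, vals in evaluate_predictions(pred, bench, ic).items():
            for m in METRICS:
                metric_samples[(root, m)][i - 1] = vals[m]

    # class probabilities: vectorised report (one row per protein x class)
    sb = significant_bits_array(ref.scores, score_samples, cap=53)
    n_prot, n_cls = ref.scores.shape
    class_prob_report = pd.DataFrame(
        {
            "quantity": [f"{p}:{c}" for p in bench.protein_ids for c in bench.class_ids],
            "reference": ref.scores.ravel(),
            "mean": score_samples.mean(axis=0).ravel(),
            "std": score_samples.std(axis=0).ravel(),
            "significant_bits": sb.ravel(),
            "significant_digits": to_digits(sb).ravel(),
            "n": n_repetitions,
        }
    )
    metric_sets = [
        SampleSet(f"{m}:{root}", ref_metrics[root][m], metric_samples[(root, m)], cap=53)
        for root in bench.ontology.roots
        for m in METRICS
    ]
    metric_report = summarize(metric_sets)
    metric_report.insert(1, "reference", [s.reference for s in metric_sets])
    return MCAExperimentResult(
        class_prob_report=class_prob_report,
        metric_report=metric_report,
        reference_metrics=ref_metrics,
        metric_samples=metric_samples,
        config={
            "n_repetitions": n_repetitions,
            "seed": seed,
            "t_single": t_single,
            "t_double": t_double,
            "n_proteins": n_prot,
            "n_classes": n_cls,
        },
    )


@dataclass
class SweepCell:
    """One grid cell of a reduced-precision sweep.

    ``diffs`` maps namespace root -> metric -> relative difference against
    the IEEE reference ((metric - metric_IEEE) / metric_IEEE); absent for
    crashed cells.
    """

    fmt_double: str
    fmt_single: str
    crashed: bool
    crash_stage: Optional[str]
    metrics: Optional[Dict[str, Dict[str, float]]]
    diffs: Optional[Dict[str, Dict[str, float]]]


@dataclass
class SweepResult:
    """A grid of reduced-precision runs compared against IEEE."""

    mode: str
    cells: List[SweepCell]
    reference_metrics: Dict[str, Dict[str, float]]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for c in self.cells:
            row = {
                "fmt_double": c.fmt_double,
                "fmt_single": c.fmt_single,
                "crashed": c.crashed,
                "crash_stage": c.crash_stage,
            }
            if c.diffs:
                for root, md in c.diffs.items():
                    for m, v in md.items():
                        row[f"{m}_{root.split(':')[0]}"] = v
            rows.append(row)
        return pd.DataFrame(rows)

    def mean_abs_diff(self) -> float:
        """Mean absolute relative metric difference over non-crashed cells."""
        vals = [
            abs(v)
            for c in self.cells
            if not c.crashed
            for md in c.diffs.values()
            for v in md.values()
        ]
        if not vals:
            return float("nan")
        return float(np.mean(vals))

    def cell(self, fmt_double: str, fmt_single: str) -> SweepCell:
        for c in self.cells:
            if c.fmt_double == fmt_double and c.fmt_single == fmt_single:
                return c
        raise KeyError((fmt_double, fmt_single))

    def to_json(self) -> str:
        return json.dumps(
            {
                "mode": self.mode,
                "reference_metrics": self.reference_metrics,
                "cells": [asdict(c) for c in self.cells],
            },
            indent=2,
            sort_keys=True,
        )

    @classmethod
    def from_json(cls, text: str) -> "SweepResult":
        d = json.loads(text)
        return cls(
            mode=d["mode"],
            cells=[SweepCell(**c) for c in d["cells"]],
            reference_metrics=d["reference_metrics"],
        )


def _rel_diffs(metrics, reference) -> Dict[str, Dict[str, float]]:
    # relative difference against IEEE; when the reference value is exactly
    # zero (e.g. Smin on a perfectly separable benchmark) the absolute
    # difference is reported instead
    def d(m, r):
        return (m - r) / r if r != 0.0 else m - r

    return {
        root: {m: d(metrics[root][m], reference[root][m]) for m in METRICS}
        for root in reference
    }


def _vprec_cell(bench, X, ic, reference, mode, fd: FloatFormat, fs: FloatFormat) -> SweepCell:
    backend = VprecBackend(mode, fmt_single=fs, fmt_double=fd)
    res = forward(X, bench.weights, backend, bench.model_cfg)
    if res.crashed:
        return SweepCell(fd.name, fs.name, True, res.crash_stage, None, None)
    pred = PredictionMatrix(bench.protein_ids, bench.class_ids, res.scores,
                            f"vprec_{mode}")
    metrics = evaluate_predictions(pred, bench, ic)
    return SweepCell(fd.name, fs.name, False, None, metrics,
                     _rel_diffs(metrics, reference))


def run_format_sweep(
    bench: Benchmark,
    mode: str,
    fmts_double: Sequence[str] = DEFAULT_SWEEP_FORMATS,
    fmts_single: Sequence[str] = DEFAULT_SWEEP_FORMATS,
) -> SweepResult:
    """Grid of reduced formats assigned to the double- and single-precision
    classes; each cell runs deterministically and crashes are recorded per
    cell, never raised."""
    if mode not in ("inbound", "outbound"):
        raise ValueError(f"mode must be 'inbound' or 'outbound', got {mode!r}")
    X = encode_sequences(bench.records, bench.model_cfg)
    ref = _ieee_run(bench, X)
    ic = information_content(bench.truth, bench.ontology)
    reference = evaluate_predictions(ref, bench, ic)
    cells = [
        _vprec_cell(bench, X, ic, reference, mode, parse_format(fd), parse_format(fs))
        for fd in fmts_double
        for fs in fmts_single
    ]
    return SweepResult(mode=mode, cells=cells, reference_metrics=reference)


@dataclass
class PrecisionSearchResult:
    """Precision/exponent grid search for the single-precision class.

    ``acceptable`` lists the (precision_bits, exponent_bits) cells whose
    metrics all stay within ``tolerance`` of the reference without
    crashing; ``pareto_minimal`` its componentwise-minimal elements.
    """

    sweep: SweepResult
    tolerance: float
    acceptable: List[Tuple[int, int]]
    pareto_minimal: List[Tuple[int, int]]

    @staticmethod
    def acceptable_from_cells(cells: Sequence[SweepCell], tolerance: float) -> List[Tuple[int, int]]:
        out = []
        for c in cells:
            if c.crashed:
                continue
            ok = all(abs(v) <= tolerance for md in c.diffs.values() for v in md.values())
            if ok:
                f = parse_format(c.fmt_single)
                out.append((f.precision_bits, f.exponent_bits))
        return sorted(out)


def _pareto_minimal(points: Sequence[Tuple[int, int]]) -> List[Tuple[int, int]]:
    return sorted(
        p for p in points
        if not any(q != p and q[0] <= p[0] and q[1] <= p[1] for q in points)
    )


def run_precision_exponent_search(
    bench: Benchmark,
    mode: str = "inbound",
    precisions: Sequence[int] = range(2, 53),
    exponents: Sequence[int] = range(5, 12),
    tolerance: float = 0.01,
    fmt_double: str = "float64",
) -> PrecisionSearchResult:
    """Sweep custom single-class formats p in [2, 52] x e in [5, 11] while
    the double class keeps ``fmt_double`` (untouched by default); a cell is
    acceptable iff no crash and every metric differs from IEEE by at most
    ``tolerance`` (relative)."""
    precisions = list(precisions)
    exponents = list(exponents)
    if not precisions or not exponents:
        raise ValueError("empty precision or exponent range")
    if min(precisions) < 2 or max(precisions) > 52:
        raise ValueError("precisions must lie within [2, 52]")
    if min(exponents) < 5 or max(exponents) > 11:
        raise ValueError("exponents must lie within [5, 11]")
    X = encode_sequences(bench.records, bench.model_cfg)
    ref = _ieee_run(bench, X)
    ic = information_content(bench.truth, bench.ontology)
    reference = evaluate_predictions(ref, bench, ic)
    fd = parse_format(fmt_double)
    cells = [
        _vprec_cell(bench, X, ic, reference, mode, fd, FloatFormat(f"p{p}e{e}", p, e))
        for p in precisions
        for e in exponents
    ]
    sweep = SweepResult(mode=mode, cells=cells, reference_metrics=reference)
    acceptable = PrecisionSearchResult.acceptable_from_cells(cells, tolerance)
    return PrecisionSearchResult(sweep, tolerance, acceptable, _pareto_minimal(acceptable))
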