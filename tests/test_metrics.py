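"""Ontology handling and the hierarchical classification metrics."""

import numpy as np
import pytest

from fuzzyfunc.metrics import (
    Ontology,
    ThresholdCurve,
    aupr,
    fmax,
    information_content,
    propagate,
    propagate_scores,
    smin,
    threshold_curve,
)
from fuzzyfunc.model import PredictionMatrix


@pytest.fixture
def chain_ontology():
    # a -> b -> c -> root
    return Ontology([("a", "b"), ("b", "c"), ("c", "root")])


@pytest.fixture
def two_class_ontology():
    return Ontology([("c1", "root"), ("c2", "root")])


def worked_example_curve(ic=None):
    """The hand-enumerated 2-protein example: truth P1={c1}, P2={c1,c2};
    scores P1: c1=0.9, c2=0.4; P2: c1=0.8, c2=0.3; IC(c1)=1, IC(c2)=2."""
    ont = Ontology([("c1", "root"), ("c2", "root")])
    pred = PredictionMatrix(["P1", "P2"], ["c1", "c2"],
                            [[0.9, 0.4], [0.8, 0.3]], "test")
    truth = {"P1": frozenset({"c1"}), "P2": frozenset({"c1", "c2"})}
    ic = ic or {"c1": 1.0, "c2": 2.0}
    return threshold_curve(pred, truth, ic, ont, propagated=True)


class TestOntology:
    def test_cycle_rejected(self):
        with pytest.raises(ValueError, match="cycle"):
            Ontology([("a", "b"), ("b", "a")])

    def test_class_reaching_two_roots_rejected(self):
        with pytest.raises(ValueError, match="exactly one"):
            Ontology([("x", "root1"), ("x", "root2")])

    def test_roots_and_namespaces(self, chain_ontology):
        assert chain_ontology.roots == ["root"]
        assert chain_ontology.namespace_of("a") == "root"
        assert chain_ontology.ancestors("a") == {"a", "b", "c", "root"}


class TestPropagate:
    def test_transitive_closure_of_chain(self, chain_ontology):
        out = propagate({"P": {"a"}}, chain_ontology)
        assert out["P"] == {"a", "b", "c", "root"}

    def test_leaf_with_two_parents(self):
        ont = Ontology([("c", "p"), ("c", "root"), ("p", "root")])
        assert propagate({"P": {"c"}}, ont)["P"] == {"c", "p", "root"}

    def test_idempotent_on_closed_sets(self, chain_ontology):
        closed = propagate({"P": {"b"}}, chain_ontology)
        assert propagate(closed, chain_ontology) == closed

    def test_unknown_class_names_protein_and_class(self, chain_ontology):
        with pytest.raises(ValueError, match=r"P7.*zz"):
            propagate({"P7": {"zz"}}, chain_ontology)


class TestInformationContent:
    def test_universal_class_has_zero_content(self, two_class_ontology):
        corpus = {f"P{i}": {"root", "c1"} for i in range(8)}
        ic = information_content(corpus, two_class_ontology)
        assert ic["c1"] == 0.0
        assert ic["root"] == 0.0

    def test_half_corpus_is_one_bit(self, two_class_ontology):
        corpus = {f"P{i}": ({"root", "c1"} if i < 4 else {"root"}) for i in range(8)}
        ic = information_content(corpus, two_class_ontology, eps=1e-12)
        assert ic["c1"] == pytest.approx(1.0, abs=1e-9)

    def test_monotone_parent_to_child(self, chain_ontology):
        corpus = {
            "P0": {"a", "b", "c", "root"},
            "P1": {"b", "c", "root"},
            "P2": {"c", "root"},
            "P3": {"root"},
        }
        ic = information_content(corpus, chain_ontology)
        assert ic["root"] <= ic["c"] <= ic["b"] <= ic["a"]

    def test_empty_corpus_rejected(self, chain_ontology):
        with pytest.raises(ValueError, match="empty"):
            information_content({}, chain_ontology)


class TestPropagateScores:
    def test_parent_takes_max_over_descendants(self, chain_ontology):
        out = propagate_scores(np.array([[0.9, 0.2, 0.5, 0.0]]),
                               ["a", "b", "c", "root"], chain_ontology)
        assert out.tolist() == [[0.9, 0.9, 0.9, 0.9]]


class TestThresholdCurve:
    def test_worked_example_at_half(self):
        curve = worked_example_curve()
        j = np.argwhere(np.isclose(curve.thresholds, 0.5))[0, 0]
        assert curve.avg_pr[j] == 1.0
        assert curve.avg_rc[j] == 0.75
        assert curve.ru[j] == 1.0
        assert curve.mi[j] == 0.0

    def test_perfect_predictions(self, two_class_ontology):
        pred = PredictionMatrix(["P1", "P2"], ["c1", "c2"],
                                [[1.0, 0.0], [1.0, 1.0]], "test")
        truth = {"P1": frozenset({"c1"}), "P2": frozenset({"c1", "c2"})}
        ic = {"c1": 1.0, "c2": 2.0}
        curve = threshold_curve(pred, truth, ic, two_class_ontology, propagated=True)
        assert (curve.avg_pr == 1.0).all()
        assert (curve.avg_rc == 1.0).all()
        assert (curve.ru == 0.0).all() and (curve.mi == 0.0).all()
        assert fmax(curve)[0] == 1.0
        assert smin(curve) == 0.0
        assert aupr(curve) == 1.0

    def test_all_zero_scores(self, two_class_ontology):
        pred = PredictionMatrix(["P1", "P2"], ["c1", "c2"],
                                np.zeros((2, 2)), "test")
        truth = {"P1": frozenset({"c1"}), "P2": frozenset({"c1", "c2"})}
        ic = {"c1": 1.0, "c2": 2.0}
        curve = threshold_curve(pred, truth, ic, two_class_ontology, propagated=True)
        assert (curve.avg_rc == 0.0).all()
        assert (curve.coverage == 0).all()
        assert (curve.avg_pr == 0.0).all()
        # remaining uncertainty = mean total truth information = (1 + 3) / 2
        assert np.allclose(curve.ru, 2.0)

    def test_recall_non_increasing_in_threshold(self):
        curve = worked_example_curve()
        assert (np.diff(curve.avg_rc) <= 0).all()

    def test_missing_protein_in_truth_rejected(self, two_class_ontology):
        pred = PredictionMatrix(["P1"], ["c1", "c2"], [[0.5, 0.5]], "test")
        with pytest.raises(ValueError, match="P1"):
            threshold_curve(pred, {}, {"c1": 1.0, "c2": 1.0}, two_class_ontology)


class TestFmaxSminAupr:
    def test_worked_example_values(self):
        curve = worked_example_curve()
        value, _ = fmax(curve)
        assert value == pytest.approx(6.0 / 7.0, rel=1e-12)
        # the same maximum is attained at t = 0.5 (the hand-enumerated cell)
        j = np.argwhere(np.isclose(curve.thresholds, 0.5))[0, 0]
        pr, rc = curve.avg_pr[j], curve.avg_rc[j]
        assert 2 * pr * rc / (pr + rc) == pytest.approx(6.0 / 7.0, rel=1e-12)
        assert smin(curve) == pytest.approx(1.0, rel=1e-12)

    def test_fmax_tie_reports_smallest_threshold(self):
        thr = np.array([0.1, 0.2, 0.3])
        curve = ThresholdCurve(thr, np.array([1.0, 1.0, 0.0]),
                               np.array([1.0, 1.0, 0.0]), np.zeros(3),
                               np.zeros(3), 2, np.ones(3, int))
        assert fmax(curve) == (1.0, 0.1)

    def test_smin_missing_class_of_ic_two(self, two_class_ontology):
        # predictions match truth except one missing IC=2 class for 1 of 2
        # proteins: min ru = 2/2 = 1 -> smin = 1
        pred = PredictionMatrix(["P1", "P2"], ["c1", "c2"],
                                [[1.0, 0.0], [1.0, 0.0]], "test")
        truth = {"P1": frozenset({"c1"}), "P2": frozenset({"c1", "c2"})}
        ic = {"c1": 1.0, "c2": 2.0}
        curve = threshold_curve(pred, truth, ic, two_class_ontology, propagated=True)
        assert smin(curve) == pytest.approx(1.0)

    def test_aupr_single_trapezoid(self):
        thr = np.array([0.4, 0.8])
        curve = ThresholdCurve(thr, np.array([0.5, 1.0]), np.array([1.0, 0.5]),
                               np.zeros(2), np.zeros(2), 2, np.ones(2, int))
        assert aupr(curve) == pytest.approx(0.375)

    def test_aupr_degenerate_recall_warns(self):
        thr = np.array([0.4, 0.8])
        curve = ThresholdCurve(thr, np.array([0.4, 0.4]), np.array([0.5, 0.5]),
                               np.zeros(2), np.zeros(2), 2, np.ones(2, int))
        with pytest.warns(UserWarning, match="distinct recall"):
            assert aupr(curve) == 0.0

    def test_protein_order_invariance(self, two_class_ontology):
        truth = {"P1": frozenset({"c1"}), "P2": frozenset({"c1", "c2"})}
        ic = {"c1": 1.0, "c2": 2.0}
        a = threshold_curve(
            PredictionMatrix(["P1", "P2"], ["c1", "c2"], [[0.9, 0.4], [0.8, 0.3]], "t"),
            truth, ic, two_class_ontology, propagated=True)
        b = threshold_curve(
            PredictionMatrix(["P2", "P1"], ["c1", "c2"], [[0.8, 0.3], [0.9, 0.4]], "t"),
            truth, ic, two_class_ontology, propagated=True)
        assert fmax(a) == fmax(b)
        assert smin(a) == smin(b)
        assert aupr(a) == aupr(b)

    def test_small_score_perturbation_leaves_fmax_smin_unchanged(self):
        # scores sit strictly between grid thresholds, so a perturbation
        # smaller than half the smallest score-to-grid gap cannot change any
        # thresholded set: max/min-based metrics are locally constant
        ont = Ontology([("c1", "root"), ("c2", "root")])
        truth = {"P1": frozenset({"c1"}), "P2": frozenset({"c1", "c2"})}
        ic = {"c1": 1.0, "c2": 2.0}
        base = np.array([[0.905, 0.405], [0.805, 0.305]])
        rng = np.random.default_rng(0)
        delta = rng.uniform(-1e-4, 1e-4, base.shape)
        a = threshold_curve(PredictionMatrix(["P1", "P2"], ["c1", "c2"], base, "t"),
                            truth, ic, ont, propagated=True)
        b = threshold_curve(PredictionMatrix(["P1", "P2"], ["c1", "c2"], base + delta, "t"),
                            truth, ic, ont, propagated=True)
        assert fmax(a) == fmax(b)
        assert smin(a) == smin(b)
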