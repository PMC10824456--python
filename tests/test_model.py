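"""Sequence encoding, the instrumented forward pass, and operation counts."""

import numpy as np
import pytest

from fuzzyfunc.backends import IEEEBackend, MCABackend, VprecBackend
from fuzzyfunc.formats import preset
from fuzzyfunc.model import (
    AA_ALPHABET,
    ConvOpCount,
    ModelConfig,
    PredictionMatrix,
    branch_op_count,
    count_conv_ops,
    encode_sequences,
    forward,
)


def small_cfg(**kw):
    base = dict(max_seq_len=48, kernel_lengths=(3, 5), filters_per_branch=4,
                n_classes=6, seed=0)
    base.update(kw)
    return ModelConfig(**base)


def random_weights(cfg, seed=0, scale=0.3):
    rng = np.random.default_rng(seed)
    w = {}
    for K in cfg.kernel_lengths:
        w[f"conv_k{K}_kernel"] = rng.normal(0, scale, (K, cfg.alphabet_size,
                                                       cfg.filters_per_branch))
        w[f"conv_k{K}_bias"] = rng.normal(0, scale, cfg.filters_per_branch)
    w["dense_w"] = rng.normal(0, scale, (cfg.n_features, cfg.n_classes))
    w["dense_b"] = rng.normal(0, scale, cfg.n_classes)
    return w


def random_records(cfg, n=6, seed=1):
    rng = np.random.default_rng(seed)
    return [(f"P{i}", "".join(rng.choice(list(AA_ALPHABET[:20]), size=40)))
            for i in range(n)]


class TestEncode:
    def test_one_bit_per_residue(self):
        cfg = ModelConfig(max_seq_len=5, kernel_lengths=(2,), n_classes=2)
        X = encode_sequences([("p", "ACD")], cfg)
        assert X.shape == (1, 5, len(AA_ALPHABET))
        assert X.sum() == 3
        assert (X.sum(axis=2)[0] == [1, 1, 1, 0, 0]).all()

    def test_truncation(self):
        cfg = ModelConfig(max_seq_len=5, kernel_lengths=(2,), n_classes=2)
        X = encode_sequences([("p", "A" * 15)], cfg)
        assert X.sum() == 5

    def test_argmax_roundtrip(self):
        cfg = ModelConfig(max_seq_len=10, kernel_lengths=(2,), n_classes=2)
        seq = "MKVLAWYX"
        X = encode_sequences([("p", seq)], cfg)
        decoded = "".join(AA_ALPHABET[j] for j in X[0, : len(seq)].argmax(axis=1))
        assert decoded == seq

    def test_unknown_residue_maps_to_x(self):
        cfg = ModelConfig(max_seq_len=4, kernel_lengths=(2,), n_classes=2)
        X = encode_sequences([("p", "AB")], cfg)  # B is not a standard residue
        assert X[0, 1, AA_ALPHABET.index("X")] == 1

    def test_empty_sequence_names_record(self):
        cfg = ModelConfig(max_seq_len=4, kernel_lengths=(2,), n_classes=2)
        with pytest.raises(ValueError, match="badrec"):
            encode_sequences([("badrec", "")], cfg)


class TestForward:
    def test_all_zero_weights_give_half(self):
        cfg = small_cfg()
        w = {k: np.zeros_like(v) for k, v in random_weights(cfg).items()}
        X = encode_sequences(random_records(cfg), cfg)
        res = forward(X, w, IEEEBackend(), cfg)
        assert not res.crashed
        assert (res.scores == 0.5).all()

    @pytest.mark.parametrize("mode", ["inbound", "outbound"])
    def test_identity_format_bit_exact_vs_ieee(self, mode):
        cfg = small_cfg()
        w = random_weights(cfg)
        X = encode_sequences(random_records(cfg), cfg)
        ref = forward(X, w, IEEEBackend(), cfg)
        f64 = preset("float64")
        got = forward(X, w, VprecBackend(mode, fmt_single=f64, fmt_double=f64), cfg)
        assert not got.crashed
        assert (got.scores == ref.scores).all()

    def test_mca_same_seed_bit_identical(self):
        cfg = small_cfg()
        w = random_weights(cfg)
        X = encode_sequences(random_records(cfg), cfg)
        a = forward(X, w, MCABackend(321), cfg)
        b = forward(X, w, MCABackend(321), cfg)
        c = forward(X, w, MCABackend(322), cfg)
        assert (a.scores == b.scores).all()
        assert not (a.scores == c.scores).all()

    def test_mca_scores_stay_probabilities(self):
        cfg = small_cfg()
        w = random_weights(cfg, scale=1.5)
        X = encode_sequences(random_records(cfg), cfg)
        res = forward(X, w, MCABackend(5), cfg)
        assert not res.crashed
        assert (res.scores >= 0).all() and (res.scores <= 1).all()

    def test_permutation_equivariance(self):
        cfg = small_cfg()
        w = random_weights(cfg)
        X = encode_sequences(random_records(cfg, n=8), cfg)
        perm = np.array([3, 1, 7, 0, 2, 6, 4, 5])
        a = forward(X, w, IEEEBackend(), cfg).scores
        b = forward(X[perm], w, IEEEBackend(), cfg).scores
        assert (a[perm] == b).all()

    def test_reduced_exponent_overflow_marks_crash(self):
        # weights far beyond the float16 range overflow while rounding
        cfg = small_cfg()
        w = random_weights(cfg)
        w["dense_w"] = w["dense_w"] * 1e6
        X = encode_sequences(random_records(cfg), cfg)
        be = VprecBackend("outbound", fmt_single=preset("float16"),
                          fmt_double=preset("float16"))
        res = forward(X, w, be, cfg)
        assert res.crashed
        assert res.crash_stage is not None

    def test_mca_noise_scale_not_amplified_in_shallow_net(self):
        # per-score std across repetitions stays within a decade of the
        # injected 2^-24 relative noise for this architecture
        cfg = small_cfg()
        w = random_weights(cfg)
        X = encode_sequences(random_records(cfg, n=4), cfg)
        runs = np.stack([forward(X, w, MCABackend(1000 + i), cfg).scores
                         for i in range(8)])
        med = np.median(runs.std(axis=0))
        assert 1e-9 < med < 1e-7


class TestOpCounts:
    def test_eq1_product_example(self):
        assert count_conv_ops(4, 4, 2, 3, 3, 3).total == 864

    def test_unit_dims_collapse_to_remaining_product(self):
        assert count_conv_ops(1, 7, 1, 5, 1, 3).total == 105

    def test_dims_below_one_rejected(self):
        with pytest.raises(ValueError):
            count_conv_ops(0, 4, 2, 3, 3, 3)

    def test_counter_matches_formula_per_branch(self):
        cfg = small_cfg()
        w = random_weights(cfg)
        n = 6
        X = encode_sequences(random_records(cfg, n=n), cfg)
        be = IEEEBackend()
        forward(X, w, be, cfg)
        for K in cfg.kernel_lengths:
            predicted = branch_op_count(cfg, K).total
            assert be.op_counts[(f"conv_k{K}", "mul")] == n * predicted


class TestPredictionMatrix:
    def test_shape_and_range_validation(self):
        with pytest.raises(ValueError, match="shape"):
            PredictionMatrix(["p"], ["c1", "c2"], np.zeros((2, 2)), "x")
        with pytest.raises(ValueError, match=r"\[0, 1\]"):
            PredictionMatrix(["p"], ["c"], np.array([[1.5]]), "x")
        with pytest.raises(ValueError, match="finite"):
            PredictionMatrix(["p"], ["c"], np.array([[np.nan]]), "x")

    def test_to_frame_long_form(self):
        pm = PredictionMatrix(["p1", "p2"], ["a", "b"],
                              np.array([[0.1, 0.2], [0.3, 0.4]]), "x")
        df = pm.to_frame()
        assert list(df.columns) == ["protein_id", "class_id", "score"]
        assert len(df) == 4
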