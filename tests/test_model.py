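"""Model wiring: activations, convolution, BLSTM encoding, variants, gradients."""

import numpy as np
import pytest

from sublocnet.encoding import EncodingConfig, one_hot_encode
from sublocnet.errors import GeometryError, ValidationError
from sublocnet.model import (
    ModelConfig,
    blstm_encode,
    build_model,
    convolve2d,
    load_model,
    predict_scores,
    relu,
    save_model,
    sigmoid,
)
from sublocnet.nn import sigmoid as nn_sigmoid
from sublocnet.training import EPS, bce_l2_loss


def small_config(variant, **over):
    """A small geometry that keeps every variant valid and fast."""
    base = dict(
        variant=variant,
        n_labels=3,
        l_max=20,
        lstm_layers=2,
        lstm_hidden_per_direction=6,
        conv_kernel_counts=(3, 3, 3, 3),
        conv_kernel_sizes=((4, 3), (3, 3), (3, 3), (3, 3)),
        pool_size=(1, 1),
        dtype="float64",
    )
    base.update(over)
    return ModelConfig(**base)


def random_onehot(rng, n, l_max, fill):
    oh = np.zeros((n, l_max, 23))
    for i in range(n):
        for t in range(fill):
            oh[i, t, rng.integers(0, 23)] = 1
    return oh


class TestActivations:
    def test_relu_piecewise(self):
        assert relu(-2) == 0
        assert relu(0) == 0
        assert relu(3.5) == 3.5
        np.testing.assert_array_equal(relu(np.array([-1.0, 2.0])), [0.0, 2.0])

    def test_sigmoid_values(self):
        assert sigmoid(0) == 0.5
        assert sigmoid(np.log(3)) == pytest.approx(0.75)
        assert sigmoid(1000.0) == 1.0  # saturates cleanly, no overflow error
        assert sigmoid(-1000.0) == 0.0


class TestConvolve2D:
    def test_ones_kernel_hand_sum(self):
        out = convolve2d(np.ones((3, 3)), np.ones((2, 2)))
        np.testing.assert_array_equal(out, np.full((2, 2), 4.0))

    def test_identity_and_zero_kernels(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=(4, 5))
        np.testing.assert_array_equal(convolve2d(x, np.array([[1.0]])), x)
        np.testing.assert_array_equal(convolve2d(x, np.zeros((2, 2))), np.zeros((3, 4)))

    def test_matches_triple_loop_oracle(self):
        rng = np.random.default_rng(1)
        for _ in range(10):
            x = rng.normal(size=(6, 6))
            w = rng.normal(size=(3, 3))
            ref = np.zeros((4, 4))
            for i in range(4):
                for j in range(4):
                    for m in range(3):
                        for k in range(3):
                            ref[i, j] += w[m, k] * x[i + m, j + k]
            np.testing.assert_allclose(convolve2d(x, w), ref, atol=1e-10)

    def test_kernel_larger_than_input_errors(self):
        with pytest.raises(ValidationError):
            convolve2d(np.ones((2, 2)), np.ones((3, 3)))


class TestBLSTMEncode:
    def test_output_bounded_open_unit_interval(self):
        rng = np.random.default_rng(2)
        cfg = small_config("blstm")
        model = build_model(cfg, seed=3)
        # inflate parameters to push activations toward saturation
        for p in model.params:
            p.value *= 20
        oh = one_hot_encode("MKVACDEFGHIK", EncodingConfig(l_max=cfg.l_max))
        enc = blstm_encode(model, oh)
        assert enc.shape == (cfg.l_max, 2 * cfg.lstm_hidden_per_direction)
        assert np.all(enc > -1) and np.all(enc < 1)

    def test_zero_parameters_give_zero_output(self):
        cfg = small_config("blstm", lstm_layers=1)
        model = build_model(cfg, seed=0)
        for p in model.params:
            p.value[...] = 0
        oh = one_hot_encode("ACDEF", EncodingConfig(l_max=cfg.l_max))
        enc = blstm_encode(model, oh)
        np.testing.assert_array_equal(enc, np.zeros_like(enc))

    def test_direction_tied_model_swaps_halves_on_reversal(self):
        cfg = small_config("blstm", lstm_layers=1, l_max=5)
        model = build_model(cfg, seed=7)
        layer = model.blstm_stack[0]
        for p_f, p_b in zip(layer.fwd.params, layer.bwd.params):
            p_b.value[...] = p_f.value
        h = cfg.lstm_hidden_per_direction
        enc_cfg = EncodingConfig(l_max=5)
        e1 = blstm_encode(model, one_hot_encode("ACDEF", enc_cfg))
        e2 = blstm_encode(model, one_hot_encode("FEDCA", enc_cfg))
        np.testing.assert_allclose(e2[:, :h], e1[::-1, h:], atol=1e-12)
        np.testing.assert_allclose(e2[:, h:], e1[::-1, :h], atol=1e-12)

    def test_variant_without_blstm_branch_errors(self):
        model = build_model(small_config("conv2"), seed=0)
        oh = one_hot_encode("ACD", EncodingConfig(l_max=20))
        with pytest.raises(ValidationError):
            blstm_encode(model, oh)


class TestBuildAndPredict:
    def test_full_variant_contract(self):
        cfg = small_config("full", n_labels=14)
        model = build_model(cfg, seed=5)
        enc = EncodingConfig(l_max=cfg.l_max)
        oh = one_hot_encode("MKVACDEFGHIKLMNP", enc)
        rng = np.random.default_rng(0)
        from sublocnet.encoding import normalize_pssm

        ps = normalize_pssm(rng.normal(size=(16, 42)), enc)
        scores = predict_scores(model, oh, ps)
        assert scores.shape == (14,)
        assert np.all((scores > 0) & (scores < 1))
        # multi-label contract: scores are not a probability simplex
        assert abs(float(scores.sum()) - 1.0) > 1e-3

    def test_same_seed_bitwise_identical_parameters(self):
        cfg = small_config("full")
        m1 = build_model(cfg, seed=11)
        m2 = build_model(cfg, seed=11)
        for (n1, p1), (n2, p2) in zip(m1.named_params(), m2.named_params()):
            assert n1 == n2
            np.testing.assert_array_equal(p1.value, p2.value)

    def test_geometry_error_on_spatial_collapse(self):
        with pytest.raises(GeometryError, match="conv layer|maxpool"):
            build_model(
                ModelConfig(variant="conv2", n_labels=3, l_max=4), seed=0
            )

    def test_conv_stack_shape_matches_closed_form(self):
        # walk the arithmetic by hand for the desk-scale preset
        cfg = ModelConfig.desk_scale("conv2", n_labels=5, l_max=400)
        model = build_model(cfg, seed=1)
        h, w = 400, 43
        for kh, kw in cfg.conv_kernel_sizes[:3]:
            h, w = (h - kh + 1) // cfg.pool_size[0], (w - kw + 1) // cfg.pool_size[1]
        kh, kw = cfg.conv_kernel_sizes[3]
        h, w = h - kh + 1, w - kw + 1
        expected = cfg.conv_kernel_counts[3] * h * w
        head = model.head[-1]
        assert head.W.value.shape == (expected, 5)

    def test_batch_prediction_equals_per_item(self):
        cfg = small_config("blstm_conv1")
        model = build_model(cfg, seed=9)
        rng = np.random.default_rng(3)
        oh = random_onehot(rng, 4, cfg.l_max, fill=15)
        batch = model.predict_batch(oh, None)
        for i in range(4):
            single = model.predict_batch(oh[i : i + 1], None)[0]
            np.testing.assert_allclose(batch[i], single, atol=1e-12)

    def test_label_head_permutation_equivariance(self):
        cfg = small_config("blstm")
        model = build_model(cfg, seed=13)
        rng = np.random.default_rng(5)
        oh = random_onehot(rng, 2, cfg.l_max, fill=10)
        base = model.predict_batch(oh, None)
        perm = rng.permutation(cfg.n_labels)
        head = model.head[-1]
        head.W.value[...] = head.W.value[:, perm]
        head.b.value[...] = head.b.value[perm]
        permuted = model.predict_batch(oh, None)
        np.testing.assert_allclose(permuted, base[:, perm], atol=1e-12)

    def test_missing_pssm_for_pssm_variant_errors(self):
        cfg = small_config("full")
        model = build_model(cfg, seed=1)
        oh = one_hot_encode("ACDEF", EncodingConfig(l_max=cfg.l_max))
        with pytest.raises(ValidationError):
            predict_scores(model, oh, None)

    def test_checkpoint_roundtrip(self, tmp_path):
        cfg = small_config("blstm_conv1")
        model = build_model(cfg, seed=21, vocabulary=("A", "B", "C"))
        rng = np.random.default_rng(8)
        oh = random_onehot(rng, 2, cfg.l_max, fill=12)
        before = model.predict_batch(oh, None)
        save_model(model, tmp_path / "ckpt.npz")
        loaded = load_model(tmp_path / "ckpt.npz")
        assert loaded.vocabulary == ("A", "B", "C")
        np.testing.assert_array_equal(loaded.predict_batch(oh, None), before)


class TestGradients:
    """Analytic backprop vs central finite differences.

    The BLSTM-only variant is smooth end to end, so agreement is tight.  The
    convolution variants contain ReLU/maxpool kinks; inputs and parameters
    are chosen away from the kinks (random continuous inputs, nudged biases)
    and checked at a correspondingly looser tolerance.
    """

    def _loss(self, model, oh, ps, y, lam):
        logits = model.forward(oh if model.config.uses_blstm else None, ps)
        probs = nn_sigmoid(logits)
        return bce_l2_loss(y, probs, [p.value for p in model.conv_kernel_params()], lam)

    def _check(self, variant, tol, n_coords=5, seed=0):
        rng = np.random.default_rng(seed)
        cfg = small_config(variant, l_max=16, l2_lambda=0.01)
        model = build_model(cfg, seed=1)
        for _, p in model.named_params():
            p.value += rng.normal(0, 1e-2, size=p.value.shape)
        oh = random_onehot(rng, 2, 16, fill=12)
        ps = rng.normal(size=(2, 16, 43))
        y = rng.integers(0, 2, size=(2, 3)).astype(float)
        y[:, 0] = 1
        lam = cfg.l2_lambda
        logits = model.forward(oh if cfg.uses_blstm else None, ps if cfg.uses_pssm else None)
        probs = nn_sigmoid(logits)
        for p in model.params:
            p.zero_grad()
        model.backward((np.clip(probs, EPS, 1 - EPS) - y) / y.size)
        for kp in model.conv_kernel_params():
            kp.grad += 2 * lam * kp.value
        worst = 0.0
        for _, p in model.named_params():
            flat = p.value.ravel()
            for ix in rng.choice(flat.size, size=min(n_coords, flat.size), replace=False):
                eps = 1e-6
                old = flat[ix]
                flat[ix] = old + eps
                lp = self._loss(model, oh, ps if cfg.uses_pssm else None, y, lam)
                flat[ix] = old - eps
                lm = self._loss(model, oh, ps if cfg.uses_pssm else None, y, lam)
                flat[ix] = old
                num = (lp - lm) / (2 * eps)
                ana = p.grad.ravel()[ix]
                worst = max(worst, abs(num - ana) / max(1e-4, abs(num) + abs(ana)))
        assert worst < tol, f"{variant}: worst relative gradient error {worst}"

    def test_blstm_gradients_tight(self):
        self._check("blstm", tol=1e-4)

    def test_conv2_gradients(self):
        self._check("conv2", tol=5e-4)

    def test_full_gradients(self):
        self._check("full", tol=5e-4)
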