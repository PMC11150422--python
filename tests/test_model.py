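"""Two-branch architecture tests: attention algebra, fusion, forward/backward."""

import numpy as np
import pytest

from fundusfair.losses import LossWeights, asl, asl_grad
from fundusfair.model import (
    AttentionParams,
    BaselineNet,
    ModelConfig,
    PathologyAwareNet,
    channel_attention,
    fuse,
    select_pathology,
)
from fundusfair.nn import sigmoid


def micro_config(**overrides):
    kwargs = dict(
        n_diseases=3, n_features=4, image_size=(8, 10),
        channels=(3, 4), kernels=(3, 3), strides=(2, 1),
    )
    kwargs.update(overrides)
    return ModelConfig(**kwargs)


class TestChannelAttention:
    def test_zero_params_give_exactly_half(self, rng):
        f_p = rng.normal(size=(5, 2, 3))
        params = AttentionParams(weight=np.zeros((5, 5)), bias=np.zeros(5))
        np.testing.assert_array_equal(channel_attention(f_p, params), np.full(5, 0.5))

    def test_hand_evaluated_two_channel_example(self):
        f_p = np.array([[[2.0]], [[-4.0]]])  # C=2, H=W=1
        params = AttentionParams(weight=np.eye(2), bias=np.zeros(2))
        w = channel_attention(f_p, params)
        assert w == pytest.approx([1 / (1 + np.exp(-2)), 0.5])
        assert w == pytest.approx([0.8808, 0.5], abs=1e-4)

    def test_range_is_half_inclusive_to_one_exclusive(self, rng):
        for _ in range(20):
            c = int(rng.integers(1, 6))
            f_p = rng.normal(scale=5, size=(c, 4, 4))
            params = AttentionParams(
                weight=rng.normal(size=(c, c)), bias=rng.normal(size=c)
            )
            w = channel_attention(f_p, params)
            assert np.all(w >= 0.5) and np.all(w < 1.0)

    def test_dimension_mismatch_names_shapes(self, rng):
        f_p = rng.normal(size=(3, 2, 2))
        params = AttentionParams(weight=np.eye(4), bias=np.zeros(4))
        with pytest.raises(ValueError, match="C=4"):
            channel_attention(f_p, params)


class TestSelectAndFuse:
    def test_ones_weight_is_identity(self, rng):
        f_p = rng.normal(size=(4, 3, 5))
        np.testing.assert_array_equal(select_pathology(f_p, np.ones(4)), f_p)

    def test_half_weight_halves(self, rng):
        f_p = rng.normal(size=(4, 3, 5))
        np.testing.assert_allclose(select_pathology(f_p, np.full(4, 0.5)), f_p / 2)

    def test_attention_then_select_hand_example(self):
        f_p = np.array([[[2.0]], [[-4.0]]])
        params = AttentionParams(weight=np.eye(2), bias=np.zeros(2))
        out = select_pathology(f_p, channel_attention(f_p, params))
        assert out.ravel() == pytest.approx([1.7616, -2.0], abs=1e-4)

    def test_fuse_additive_identity_and_commutativity(self, rng):
        a = rng.normal(size=(3, 2, 2))
        b = rng.normal(size=(3, 2, 2))
        np.testing.assert_array_equal(fuse(a, np.zeros_like(a)), a)
        np.testing.assert_array_equal(fuse(a, b), fuse(b, a))

    def test_fuse_equals_elementwise_loop(self, rng):
        a = rng.normal(size=(2, 3, 4))
        b = rng.normal(size=(2, 3, 4))
        out = fuse(a, b)
        for i in range(2):
            for j in range(3):
                for k in range(4):
                    assert out[i, j, k] == a[i, j, k] + b[i, j, k]

    def test_shape_mismatch_rejected(self, rng):
        with pytest.raises(ValueError, match="shapes"):
            fuse(rng.normal(size=(2, 3, 4)), rng.normal(size=(2, 3, 5)))
        with pytest.raises(ValueError):
            select_pathology(rng.normal(size=(3, 2, 2)), np.ones(4))


class TestForward:
    def test_output_widths_match_config(self, rng):
        for nd, nf in [(2, 5), (6, 8)]:
            net = PathologyAwareNet(micro_config(n_diseases=nd, n_features=nf), seed=0)
            out = net.forward(rng.normal(size=(3, 3, 8, 10)))
            assert out["patho_logits"].shape == (3, nf)
            assert out["disease_logits"].shape == (3, nd)
            assert out["F_p"].shape == out["F_d"].shape

    def test_zero_attention_gives_half_fp_plus_fd(self, rng):
        net = PathologyAwareNet(micro_config(), seed=0)
        net.attention.W.value[...] = 0.0
        net.attention.b.value[...] = 0.0
        out = net.forward(rng.normal(size=(2, 3, 8, 10)))
        np.testing.assert_allclose(out["F_e"], 0.5 * out["F_p"] + out["F_d"])

    def test_forward_deterministic_under_fixed_weights(self, rng):
        net = PathologyAwareNet(micro_config(), seed=3)
        x = rng.normal(size=(2, 3, 8, 10))
        out1 = net.forward(x)
        out2 = net.forward(x)
        np.testing.assert_array_equal(out1["disease_logits"], out2["disease_logits"])

    def test_same_seed_same_init(self):
        a = PathologyAwareNet(micro_config(), seed=11)
        b = PathologyAwareNet(micro_config(), seed=11)
        for pa, pb in zip(a.params(), b.params()):
            np.testing.assert_array_equal(pa.value, pb.value)

    def test_baseline_matches_disease_branch_shape(self, rng):
        net = BaselineNet(micro_config(), seed=0)
        out = net.forward(rng.normal(size=(4, 3, 8, 10)))
        assert out["disease_logits"].shape == (4, 3)

    def test_unsupported_backbone_rejected_at_build(self):
        with pytest.raises(ValueError, match="backbone"):
            micro_config(backbone="resnet101")


class TestBackward:
    def test_gradient_reaches_both_encoders(self, rng):
        net = PathologyAwareNet(micro_config(), seed=0)
        x = rng.normal(size=(4, 3, 8, 10))
        y = rng.integers(0, 2, (4, 3))
        out = net.forward(x)
        probs = sigmoid(out["disease_logits"])
        g = asl_grad(probs, y, LossWeights()) * probs * (1 - probs)
        for p in net.params():
            p.zero_grad()
        net.backward(np.zeros((4, 4)), g)  # disease loss only
        gp = max(np.abs(p.grad).max() for p in net.encoder_p.params())
        gd = max(np.abs(p.grad).max() for p in net.encoder_d.params())
        assert gp > 0 and gd > 0

    @pytest.mark.parametrize("spatial", [False, True])
    def test_full_objective_gradients_match_finite_differences(self, rng, spatial):
        from fundusfair.losses import (
            consis_grad, consis_loss, joint_grad, joint_loss, total_loss,
        )

        net = PathologyAwareNet(micro_config(spatial_attention=spatial), seed=1)
        x = rng.normal(size=(2, 3, 8, 10))
        yd = rng.integers(0, 2, (2, 3))
        yf = rng.integers(0, 2, (2, 4))
        rel = rng.integers(0, 2, (4, 3)).astype(float)
        rel[:, 0] = 1  # keep all diseases related
        w = LossWeights(lambda1=0.3, lambda2=1.0, lambda3=0.2, lambda4=0.1)

        def objective():
            out = net.forward(x)
            pp = sigmoid(out["patho_logits"])
            dp = sigmoid(out["disease_logits"])
            return total_loss(
                asl(pp, yf, w), asl(dp, yd, w),
                joint_loss(pp, dp, rel), consis_loss(out["F_p"], out["F_d"]), w,
            ).total

        out = net.forward(x)
        pp, dp = sigmoid(out["patho_logits"]), sigmoid(out["disease_logits"])
        jp, jd = joint_grad(pp, dp, rel)
        d_pp = w.lambda1 * asl_grad(pp, yf, w) + w.lambda3 * jp
        d_dp = w.lambda2 * asl_grad(dp, yd, w) + w.lambda3 * jd
        cp, cd = consis_grad(out["F_p"], out["F_d"])
        for p in net.params():
            p.zero_grad()
        net.backward(
            d_pp * pp * (1 - pp), d_dp * dp * (1 - dp),
            d_f_p=w.lambda4 * cp, d_f_d=w.lambda4 * cd,
        )

        eps = 1e-6
        for p in net.params():
            if "conv" in p.name and p.name.endswith(".b"):
                continue  # conv bias precedes batch norm; true gradient ~0
            flat = p.value.ravel()
            for i in rng.choice(flat.size, size=min(3, flat.size), replace=False):
                old = flat[i]
                flat[i] = old + eps
                lp = objective()
                flat[i] = old - eps
                lm = objective()
                flat[i] = old
                num = (lp - lm) / (2 * eps)
                ana = p.grad.ravel()[i]
                assert ana == pytest.approx(num, rel=2e-4, abs=1e-9), p.name
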