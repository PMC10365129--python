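import numpy as np
import pytest

from gazeguide.autodiff import Tensor
from gazeguide.network import Dense, ReLULayer, Sequential, SigmoidLayer
from gazeguide.saliency import (
    RULES,
    gradcam_map,
    relu_backward,
    saliency_graph,
    saliency_map,
)

from conftest import mlp_saliency_oracle, random_mlp


class TestReluBackward:
    @pytest.mark.parametrize(
        "rule, expected",
        [("backprop", [0.0, -2.0]), ("deconvnet", [1.0, 0.0]), ("gbp", [0.0, 0.0])],
    )
    def test_hand_worked_masks(self, rule, expected):
        out = relu_backward([1.0, -2.0], [-1.0, 4.0], rule)
        np.testing.assert_array_equal(out, expected)

    def test_all_positive_signals_pass_through_every_rule(self):
        g = np.array([0.5, 2.0, 1.0])
        x = np.array([1.0, 3.0, 0.1])
        for rule in RULES:
            np.testing.assert_array_equal(relu_backward(g, x, rule), g)

    def test_rule_mask_flags(self):
        assert RULES["backprop"].forward_mask_used and not RULES["backprop"].sign_mask_used
        assert not RULES["deconvnet"].forward_mask_used and RULES["deconvnet"].sign_mask_used
        assert RULES["gbp"].forward_mask_used and RULES["gbp"].sign_mask_used

    def test_shape_mismatch_and_unknown_rule(self):
        with pytest.raises(ValueError, match="shape"):
            relu_backward([1.0, 2.0], [1.0], "gbp")
        with pytest.raises(ValueError, match="unknown rule"):
            relu_backward([1.0], [1.0], "sobel")


def _two_layer_net():
    rng = np.random.default_rng(0)
    d1, d2 = Dense(2, 2, rng), Dense(2, 2, rng)
    d1.W.data = np.array([[1.0, -1.0], [2.0, 1.0]])
    d1.b.data[:] = 0.0
    d2.W.data = np.array([[1.0, -2.0], [0.0, 0.0]])
    d2.b.data[:] = 0.0
    return Sequential([d1, ReLULayer(), d2])


class TestSaliencyMap:
    @pytest.mark.parametrize(
        "method, expected",
        [("backprop", [-4.0, -2.0]), ("deconvnet", [1.0, -1.0]), ("gbp", [0.0, 0.0])],
    )
    def test_worked_two_layer_example(self, method, expected):
        sal = saliency_map(_two_layer_net(), np.array([1.0, 2.0]), 0, method=method)
        np.testing.assert_array_equal(sal.values, expected)
        assert sal.method == method and sal.class_index == 0

    def test_purely_linear_model_returns_weight_row(self):
        rng = np.random.default_rng(5)
        d = Dense(4, 3, rng)
        seq = Sequential([d])
        for method in ("backprop", "deconvnet", "gbp"):
            for cls in range(3):
                sal = saliency_map(seq, rng.uniform(-1, 1, 4), cls, method=method)
                np.testing.assert_allclose(sal.values, d.W.data[cls])

    def test_oracle_equivalence_on_random_networks(self):
        rng = np.random.default_rng(42)
        for _ in range(30):
            seq, mats, dims = random_mlp(rng)
            x = rng.normal(0, 1, dims[0])
            cls = int(rng.integers(3))
            for method in ("backprop", "deconvnet", "gbp"):
                got = saliency_map(seq, x, cls, method=method).values
                want = mlp_saliency_oracle(mats, x, cls, method)
                np.testing.assert_allclose(got, want, rtol=1e-6, atol=1e-12)

    def test_gbp_zero_dominance_over_deconvnet(self):
        rng = np.random.default_rng(7)
        for _ in range(30):
            seq, _, dims = random_mlp(rng)
            x = rng.normal(0, 1, dims[0])
            gbp = saliency_map(seq, x, 0, method="gbp").values
            dec = saliency_map(seq, x, 0, method="deconvnet").values
            assert np.sum(gbp == 0) >= np.sum(dec == 0)

    def test_all_positive_path_collapses_methods_to_plain_gradient(self):
        rng = np.random.default_rng(3)
        d1, d2 = Dense(3, 3, rng), Dense(3, 3, rng)
        d1.W.data = np.abs(d1.W.data) + 0.1
        d2.W.data = np.abs(d2.W.data) + 0.1
        d1.b.data[:] = d2.b.data[:] = 0.1
        seq = Sequential([d1, ReLULayer(), d2])
        x = np.array([0.5, 1.0, 0.2])
        maps = {m: saliency_map(seq, x, 1, method=m).values for m in RULES}
        np.testing.assert_allclose(maps["backprop"], maps["deconvnet"])
        np.testing.assert_allclose(maps["backprop"], maps["gbp"])

    def test_non_relu_activation_rejected_by_name(self):
        rng = np.random.default_rng(0)
        seq = Sequential([Dense(2, 2, rng), SigmoidLayer(), Dense(2, 3, rng)])
        with pytest.raises(TypeError, match="sigmoid"):
            saliency_map(seq, np.ones(2), 0, method="gbp")

    def test_invalid_class_index(self):
        seq, _, dims = random_mlp(np.random.default_rng(1))
        with pytest.raises(ValueError, match="class index"):
            saliency_map(seq, np.zeros(dims[0]), 7)

    def test_differentiable_map_supports_weight_gradients(self):
        """Central finite differences vs the frozen-mask analytic gradient."""
        rng = np.random.default_rng(9)
        seq, _, dims = random_mlp(rng, n_layers=2, width=4)
        x = rng.normal(0, 1, dims[0])

        def loss_value():
            s, _ = saliency_graph(seq, x[None], np.array([1]), "gbp")
            return ((s - 0.3) ** 2).mean()

        loss = loss_value()
        for p in seq.params():
            p.grad = None
        loss.backward()
        h = 1e-6
        checked = 0
        for p in seq.params():
            if p.grad is None or not np.abs(p.grad).max():
                continue
            idx = np.unravel_index(np.abs(p.grad).argmax(), p.shape)
            orig = p.data[idx]
            p.data[idx] = orig + h
            fp = loss_value().item()
            p.data[idx] = orig - h
            fm = loss_value().item()
            p.data[idx] = orig
            fd = (fp - fm) / (2 * h)
            assert abs(p.grad[idx] - fd) <= 1e-4 * max(abs(fd), 1e-8)
            checked += 1
        assert checked >= 1


class TestGradCam:
    def test_zero_map_when_class_is_independent_of_layer(self, small_unet):
        # zero the head weights: every logit is constant in the features
        small_unet.head.W.data[:] = 0.0
        img = np.random.default_rng(0).uniform(0, 1, (16, 16))
        cam = gradcam_map(small_unet, img, 0)
        assert cam.values.shape == (16, 16)
        np.testing.assert_array_equal(cam.values, 0.0)

    def test_weighted_feature_sum_oracle(self, small_unet):
        """With uniform per-feature gradients g_k the map is ReLU(sum g_k F_k)."""
        img = np.random.default_rng(1).uniform(0, 1, (16, 16))
        # make the head read features with known uniform weights
        small_unet.head.W.data[:] = 0.0
        small_unet.head.W.data[0, 0] = 1.0   # feature 0 weight +1
        small_unet.head.W.data[0, 1] = -1.0  # feature 1 weight -1
        cam = gradcam_map(small_unet, img, 0)

        feats = Tensor(img[None, None])
        for blk in small_unet.enc_blocks:
            for layer in blk:
                feats = layer.forward(feats)
        f = feats.data[0]
        h, w = f.shape[1:]
        expected_small = np.maximum((f[0] - f[1]) / (h * w), 0.0)
        from skimage.transform import resize

        expected = resize(expected_small, (16, 16), order=1, mode="edge",
                          anti_aliasing=False)
        np.testing.assert_allclose(cam.values, expected, atol=1e-12)

    def test_unknown_layer_lists_available(self, small_unet):
        with pytest.raises(ValueError, match="enc0"):
            gradcam_map(small_unet, np.zeros((16, 16)), 0, layer="bottleneck7")
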