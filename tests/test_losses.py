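import numpy as np
import pytest

from gazeguide.autodiff import Tensor
from gazeguide.losses import (
    LossSpec,
    bce_logits,
    classification_loss,
    normalize_derived,
    segmentation_loss,
    total_loss,
)


def bce_highprec_oracle(z, t):
    """50-digit evaluation of -[t log s + (1-t) log(1-s)] via sympy."""
    import sympy as sp

    vals = []
    for zi, ti in zip(np.ravel(z), np.ravel(t)):
        zi, ti = sp.Float(zi, 50), sp.Float(ti, 50)
        s = 1 / (1 + sp.exp(-zi))
        vals.append(-(ti * sp.log(s) + (1 - ti) * sp.log(1 - s)))
        # noqa: the naive form is fine at 50 digits
    return float(sum(vals) / len(vals))


class TestBceLogits:
    def test_symmetric_closed_form(self):
        assert bce_logits(np.zeros(5), np.full(5, 0.5)) == pytest.approx(np.log(2))
        assert bce_logits(np.array([0.0]), np.array([1.0])) == pytest.approx(np.log(2))

    def test_hand_worked_softplus_values(self):
        got = bce_logits(np.array([2.0, -1.0]), np.array([1.0, 0.0]))
        want = (np.log1p(np.exp(-2.0)) + np.log1p(np.exp(-1.0))) / 2
        assert got == pytest.approx(want, abs=1e-12)

    def test_matches_extended_precision_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(4):
            z = rng.uniform(-50, 50, 10)
            t = rng.uniform(0, 1, 10)
            assert bce_logits(z, t) == pytest.approx(bce_highprec_oracle(z, t), abs=1e-10)

    def test_stable_at_extreme_logits(self):
        big = np.array([1e4, -1e4])
        out = bce_logits(big, np.array([0.0, 1.0]))
        assert np.isfinite(out) and out == pytest.approx(1e4, rel=1e-12)

    def test_target_range_and_shape_validation(self):
        with pytest.raises(ValueError, match=r"\[0, 1\]"):
            bce_logits(np.zeros(2), np.array([0.5, 1.2]))
        with pytest.raises(ValueError, match="shape"):
            bce_logits(np.zeros(2), np.zeros(3))


class TestClassificationLoss:
    def test_zero_logits_give_log2(self):
        for label in range(3):
            assert classification_loss(np.zeros(3), label) == pytest.approx(np.log(2))

    def test_saturated_correct_prediction_is_near_zero(self):
        logits = np.array([-1e3, 1e3, -1e3])
        assert classification_loss(logits, 1) == pytest.approx(0.0, abs=1e-12)

    def test_hand_worked_mixed_logits(self):
        got = classification_loss(np.array([1.0, -1.0, 0.0]), 0)
        sp = lambda v: np.log1p(np.exp(-abs(v))) + max(v, 0)  # noqa: E731
        want = (sp(-1.0) + sp(-1.0) + sp(0.0)) / 3
        assert got == pytest.approx(want, abs=1e-12)

    def test_invalid_label_rejected(self):
        with pytest.raises(ValueError):
            classification_loss(np.zeros(3), 5)


class TestNormalizeDerived:
    def test_constant_map_collapses_to_zero(self):
        np.testing.assert_array_equal(normalize_derived(np.full((4, 4), 3.7)), 0.0)

    def test_two_point_population_standardization(self):
        np.testing.assert_allclose(normalize_derived(np.array([0.0, 2.0])), [-1.0, 1.0])

    def test_idempotence_on_standardized_maps(self):
        rng = np.random.default_rng(2)
        v = rng.normal(0, 1, (6, 6))
        z = normalize_derived(v)
        np.testing.assert_allclose(normalize_derived(z), z, atol=1e-12)

    def test_batched_matches_per_sample(self):
        rng = np.random.default_rng(3)
        batch = rng.normal(0, 2, (3, 1, 5, 5))
        batch[1] = 1.23  # one degenerate constant sample
        out = normalize_derived(Tensor(batch)).data
        for i in range(3):
            np.testing.assert_allclose(out[i], normalize_derived(batch[i, 0])[None], atol=1e-9)


class TestLossSpec:
    def test_invariants(self):
        with pytest.raises(ValueError):
            LossSpec(scheme="baseline", generator="gbp")
        with pytest.raises(ValueError):
            LossSpec(scheme="set1", generator="none")
        with pytest.raises(ValueError):
            LossSpec(scheme="set3", generator="gbp", lambda_mix=1.5)
        with pytest.raises(ValueError):
            LossSpec(scheme="nope")


class TestSegmentationSchemes:
    @pytest.fixture()
    def grids(self):
        rng = np.random.default_rng(4)
        decoder = Tensor(rng.normal(0, 1, (2, 2)))
        derived = Tensor(rng.normal(0, 2, (2, 2)))
        gaze = rng.uniform(0, 1, (2, 2))
        return decoder, derived, gaze

    def test_set3_endpoints_are_exact(self, grids):
        decoder, derived, gaze = grids
        seg1, _ = segmentation_loss(LossSpec("set1", "gbp"), decoder, derived, gaze)
        base, _ = segmentation_loss(LossSpec("baseline"), decoder, None, gaze)
        at1, _ = segmentation_loss(LossSpec("set3", "gbp", lambda_mix=1.0), decoder, derived, gaze)
        at0, _ = segmentation_loss(LossSpec("set3", "gbp", lambda_mix=0.0), decoder, derived, gaze)
        assert float(at1.data) == float(seg1.data)  # bit-exact endpoint identities
        assert float(at0.data) == float(base.data)

    def test_set3_midpoint_is_component_mean(self, grids):
        decoder, derived, gaze = grids
        seg, comps = segmentation_loss(
            LossSpec("set3", "deconvnet", lambda_mix=0.5), decoder, derived, gaze
        )
        mean = (comps["seg_derived_vs_gaze"] + comps["seg_decoder_vs_gaze"]) / 2
        assert float(seg.data) == pytest.approx(mean, abs=1e-15)

    def test_missing_derived_map_rejected(self, grids):
        decoder, _, gaze = grids
        with pytest.raises(ValueError, match="derived"):
            segmentation_loss(LossSpec("set2", "gbp"), decoder, None, gaze)

    def test_gaze_range_validated(self, grids):
        decoder, derived, _ = grids
        with pytest.raises(ValueError, match=r"\[0, 1\]"):
            segmentation_loss(LossSpec("baseline"), decoder, None, np.full((2, 2), 1.5))

    def test_set1_gradient_flows_through_derived_map(self, grids):
        decoder, _, gaze = grids
        w = Tensor(np.array([[1.0, -0.5], [0.3, 2.0]]), requires_grad=True)
        derived = w * 2.0  # stand-in for a weight-dependent saliency map
        seg, _ = segmentation_loss(LossSpec("set1", "gbp"), decoder, derived, gaze)
        seg.backward()
        assert w.grad is not None and np.abs(w.grad).max() > 0

    def test_set2_detaches_the_derived_target(self, grids):
        decoder_src = Tensor(np.array([[0.2, -0.4], [1.0, 0.1]]), requires_grad=True)
        decoder = decoder_src * 1.0
        w = Tensor(np.array([[1.0, -0.5], [0.3, 2.0]]), requires_grad=True)
        derived = w * 2.0
        seg, _ = segmentation_loss(LossSpec("set2", "gbp"), decoder, derived, None)
        seg.backward()
        assert w.grad is None  # no path into the generator weights
        assert decoder_src.grad is not None


class TestTotalLoss:
    def test_breakdown_is_exact_weighted_sum(self):
        rng = np.random.default_rng(6)
        spec = LossSpec("set3", "gbp", lambda_mix=0.3, w_cls=2.0, w_seg=0.5)
        total, bd = total_loss(
            spec,
            Tensor(rng.normal(0, 1, (4, 3))),
            rng.integers(0, 3, 4),
            Tensor(rng.normal(0, 1, (4, 1, 6, 6))),
            Tensor(rng.normal(0, 1, (4, 1, 6, 6))),
            rng.uniform(0, 1, (4, 1, 6, 6)),
        )
        assert bd.total == 2.0 * bd.classification + 0.5 * bd.segmentation
        assert bd.classification >= 0 and bd.segmentation >= 0
        assert np.isfinite(bd.total) and float(total.data) == bd.total
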