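"""Gradient-based heatmap generators.

Plain back-propagation, deconvNet and guided back-propagation (GBP)
differ only in how the ReLU sites treat the backward signal.  With
``g`` the upstream signal and ``x`` the forward input of the ReLU:

=========== ======================= =========================
rule        masks applied           result
=========== ======================= =========================
backprop    forward mask            ``g * 1[x > 0]``
deconvnet   sign mask               ``g * 1[g > 0]``
gbp         both                    ``g * 1[g > 0] * 1[x > 0]``
=========== ======================= =========================

Because GBP applies both masks, its maps have at least as many exact
zeros as the deconvNet map of the same (model, input, class).

The sweep is written as a *forward* computation in the autodiff graph:
the masks are constants of the current pass (they are piecewise
constant in the weights almost everywhere), while every linear layer
contributes its adjoint map with the weights kept symbolic.  A scalar
loss on the resulting map therefore yields weight gradients — this is
what lets the saliency map itself be supervised during training.

Grad-CAM is provided post-hoc only: feature maps of a chosen
convolutional layer, weighted by the spatial mean of their gradients,
rectified, bilinearly upsampled to input resolution.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image
from skimage.transform import resize

from .autodiff import Tensor
from .network import ReLULayer, Sequential, UNet

__all__ = [
    "ReluRule",
    "SaliencyMap",
    "RULES",
    "relu_backward",
    "saliency_map",
    "saliency_graph",
    "saliency_from_tape",
    "gradcam_map",
    "save_saliency_npz",
    "save_saliency_png",
]


@dataclass(frozen=True)
class ReluRule:
    """Which masks a backward rule applies at ReLU sites."""

    name: str
    forward_mask_used: bool
    sign_mask_used: bool


RULES: dict[str, ReluRule] = {
    "backprop": ReluRule("backprop", forward_mask_used=True, sign_mask_used=False),
    "deconvnet": ReluRule("deconvnet", forward_mask_used=False, sign_mask_used=True),
    "gbp": ReluRule("gbp", forward_mask_used=True, sign_mask_used=True),
}


@dataclass
class SaliencyMap:
    """Signed gradient map for one class under a named backward rule."""

    values: np.ndarray
    method: str
    class_index: int
    tensor: Tensor | None = None  # populated when differentiable=True


def _as_rule(rule: str | ReluRule) -> ReluRule:
    if isinstance(rule, ReluRule):
        return rule
    try:
        return RULES[rule]
    except KeyError:
        raise ValueError(f"unknown rule {rule!r}; choose from {sorted(RULES)}") from None


def _rule_mask(g: np.ndarray, x: np.ndarray, rule: ReluRule) -> np.ndarray:
    mask = np.ones_like(g)
    if rule.forward_mask_used:
        mask = mask * (x > 0)  # strict: ReLU'(0) taken as 0
    if rule.sign_mask_used:
        mask = mask * (g > 0)
    return mask


def relu_backward(upstream: np.ndarray, forward_input: np.ndarray, rule: str | ReluRule) -> np.ndarray:
    """Apply one ReLU site's backward rule to the upstream signal."""
    g = np.asarray(upstream, dtype=np.float64)
    x = np.asarray(forward_input, dtype=np.float64)
    if g.shape != x.shape:
        raise ValueError(f"shape mismatch: upstream {g.shape} vs forward input {x.shape}")
    return g * _rule_mask(g, x, _as_rule(rule))


def _classifier_path(model) -> Sequential:
    if isinstance(model, UNet):
        return model.classifier_path()
    if isinstance(model, Sequential):
        return model
    raise TypeError("model must be a UNet or a Sequential layer chain")


def saliency_from_tape(
    tape: list,
    logits: Tensor,
    class_indices: np.ndarray,
    method: str | ReluRule,
) -> Tensor:
    """Rule-masked adjoint sweep over a recorded forward tape.

    ``tape`` is the (layer, input) sequence of the input→logits chain of
    the *current* forward pass.  The returned map tensor is input-shaped
    and differentiable with respect to model weights (masks frozen for
    the pass).
    """
    rule = _as_rule(method)
    for i, (layer, _) in enumerate(tape):
        if layer.is_activation and not isinstance(layer, ReLULayer):
            raise TypeError(
                f"layer {i} ({layer.name}) is a non-ReLU activation; the "
                f"{rule.name} rule is only defined at ReLU sites"
            )
    n, n_cls = logits.shape
    class_indices = np.atleast_1d(np.asarray(class_indices, dtype=int))
    if class_indices.size == 1 and n > 1:
        class_indices = np.full(n, class_indices[0])
    if np.any((class_indices < 0) | (class_indices >= n_cls)):
        raise ValueError(f"class index out of range for {n_cls}-class head")
    onehot = np.zeros((n, n_cls))
    onehot[np.arange(n), class_indices] = 1.0

    s = Tensor(onehot)
    for layer, inp in reversed(tape):
        if isinstance(layer, ReLULayer):
            s = s * _rule_mask(s.data, inp.data, rule)  # masks are constants
        else:
            s = layer.transpose_apply(s, inp)
    return s


def saliency_graph(
    model,
    inputs: np.ndarray,
    class_indices: np.ndarray,
    method: str | ReluRule,
) -> tuple[Tensor, Tensor]:
    """Batched rule-masked sweep; returns (map tensor, class logits tensor)."""
    seq = _classifier_path(model)
    logits, tape = seq.forward_tape(Tensor(np.asarray(inputs)))
    return saliency_from_tape(tape, logits, class_indices, method), logits


def _reduce_channels(values: np.ndarray, how: str) -> np.ndarray:
    """(C, H, W) -> (H, W); signed abs-max keeps the dominant channel's sign."""
    if values.shape[0] == 1:
        return values[0]
    if how == "mean":
        return values.mean(axis=0)
    if how == "max":
        return values.max(axis=0)
    if how == "abs-max":
        idx = np.abs(values).argmax(axis=0)
        return np.take_along_axis(values, idx[None], axis=0)[0]
    raise ValueError(f"unknown channel reduction {how!r}")


def saliency_map(
    model,
    image: np.ndarray,
    class_index: int,
    method: str = "gbp",
    differentiable: bool = False,
    channel_reduce: str = "abs-max",
) -> SaliencyMap:
    """Gradient of one class logit w.r.t. the input under a backward rule.

    For image models the returned ``values`` are a 2-D signed map; for
    vector-input models they keep the input's shape.  With
    ``differentiable=True`` the graph node is attached as ``.tensor`` so
    a loss on the map can update the weights.
    """
    rule = _as_rule(method)
    x = np.asarray(image, dtype=np.float64)
    if isinstance(model, UNet):
        batched = model._check_input(x)
    else:
        batched = x[None] if x.ndim == 1 else x
    s, _ = saliency_graph(model, batched, np.array([class_index]), rule)
    raw = s.data[0]
    values = _reduce_channels(raw, channel_reduce) if raw.ndim == 3 else raw
    return SaliencyMap(
        values=values,
        method=rule.name,
        class_index=int(class_index),
        tensor=s if differentiable else None,
    )


def gradcam_map(
    model: UNet,
    image: np.ndarray,
    class_index: int,
    layer: str = "enc-1",
) -> SaliencyMap:
    """Grad-CAM at a named encoder block, upsampled to input resolution.

    ``layer`` is ``"enc0"`` … ``"enc{depth-1}"`` (``"enc-1"`` = last).
    Post-hoc only: the result carries no differentiability contract.
    """
    if not isinstance(model, UNet):
        raise TypeError("gradcam_map requires a UNet model")
    names = [f"enc{d}" for d in range(model.cfg.depth)]
    if layer == "enc-1":
        layer = names[-1]
    if layer not in names:
        raise ValueError(f"layer {layer!r} not found; available layers: {names}")
    level = names.index(layer)

    x = model._check_input(image)
    if x.shape[0] != 1:
        raise ValueError("gradcam_map takes a single image")
    t = Tensor(x)
    feature: Tensor | None = None
    for d, blk in enumerate(model.enc_blocks):
        for lay in blk:
            t = lay.forward(t)
        if d == level:
            feature = t
            feature.requires_grad = True  # capture d(logit)/d(feature)
    logits = model.head.forward(model.gap.forward(t))
    n_cls = logits.shape[1]
    if not 0 <= class_index < n_cls:
        raise ValueError(f"class index {class_index} out of range for {n_cls} classes")
    seed = np.zeros((1, n_cls))
    seed[0, class_index] = 1.0
    logits.backward(seed)
    grads = feature.grad  # (1, C, h, w)

    weights = grads.mean(axis=(2, 3))  # global average pooling of gradients
    cam = np.maximum((weights[0][:, None, None] * feature.data[0]).sum(axis=0), 0.0)
    up = resize(cam, model.image_size, order=1, mode="edge", anti_aliasing=False)
    return SaliencyMap(values=up, method="gradcam", class_index=int(class_index))


# ---------------------------------------------------------------------------
# Export: raw signed values as NPZ, min-max normalized PNG for figures.
# ---------------------------------------------------------------------------


def save_saliency_npz(sal: SaliencyMap, path: str | Path) -> None:
    with open(path, "wb") as fh:
        np.savez(fh, values=sal.values, method=np.array(sal.method),
                 class_index=np.array(sal.class_index))


def save_saliency_png(sal: SaliencyMap, path: str | Path) -> None:
    v = sal.values
    span = v.max() - v.min()
    norm = (v - v.min()) / span if span > 0 else np.zeros_like(v)
    Image.fromarray(np.round(255 * norm).astype(np.uint8), mode="L").save(path)
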