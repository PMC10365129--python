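"""Classification loss and the four segmentation-loss schemes.

All losses are binary cross-entropy with logits.  The classification
head is trained one-vs-all against the one-hot label.  The
"segmentation" loss is an attention-supervision term, one of:

* ``baseline`` — decoder logits vs the static gaze map;
* ``set1``     — the derived saliency map (GBP/deconvNet), z-scored into
  a logit role, vs the gaze map; differentiable *through* the map so
  the encoder weights are pushed to make their gradients mimic gaze;
* ``set2``     — decoder logits vs sigmoid(z-scored derived map), the
  derived map detached (it defines the target of the current step);
* ``set3``     — ``lambda_mix`` · set1-term + (1 − lambda_mix) · baseline-term.

``total = w_cls · classification + w_seg · segmentation`` exactly.

Raw gradient maps are unbounded and signed, so before entering the BCE
they are standardized to zero mean / unit sd over pixels (an all-constant
map maps to all-zeros).  z-scoring is preferred over min-max because the
max has unstable gradients; a sigmoid squashes the map into [0, 1] only
where it must serve as a BCE *target* (set2).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor, sigmoid, softplus

__all__ = [
    "LossSpec",
    "LossBreakdown",
    "bce_logits",
    "classification_loss",
    "normalize_derived",
    "segmentation_loss",
    "total_loss",
]

SCHEMES = ("baseline", "set1", "set2", "set3")
GENERATORS = ("gbp", "deconvnet", "none")


@dataclass
class LossSpec:
    """Which loss scheme to train with, and its mixing weights."""

    scheme: str = "baseline"
    generator: str = "none"
    lambda_mix: float = 0.5  # set3 only
    w_cls: float = 1.0
    w_seg: float = 1.0

    def __post_init__(self) -> None:
        if self.scheme not in SCHEMES:
            raise ValueError(f"scheme must be one of {SCHEMES}, got {self.scheme!r}")
        if self.generator not in GENERATORS:
            raise ValueError(
                f"generator must be one of {GENERATORS}, got {self.generator!r}"
            )
        if self.scheme == "baseline" and self.generator != "none":
            raise ValueError("baseline scheme takes generator='none'")
        if self.scheme != "baseline" and self.generator == "none":
            raise ValueError(f"scheme {self.scheme!r} requires a generator")
        if not 0.0 <= self.lambda_mix <= 1.0:
            raise ValueError("lambda_mix must be in [0, 1]")
        if self.w_cls < 0 or self.w_seg < 0:
            raise ValueError("loss weights must be >= 0")

    @property
    def needs_derived(self) -> bool:
        return self.scheme != "baseline"


@dataclass
class LossBreakdown:
    total: float
    classification: float
    segmentation: float
    seg_derived_vs_gaze: float | None = None
    seg_decoder_vs_gaze: float | None = None
    seg_decoder_vs_derived: float | None = None


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=np.float64))


def _maybe_float(out: Tensor, *inputs):
    """Mirror the caller's type: Tensors in -> Tensor out, arrays -> plain values."""
    if any(isinstance(i, Tensor) for i in inputs):
        return out
    return float(out.data) if out.data.size == 1 else out.data.copy()


def bce_logits(logits, targets):
    """Mean binary cross-entropy with logits; stable for |z| up to 1e4.

    mean over elements of softplus(z) − t·z, which equals
    −[t·log σ(z) + (1−t)·log(1−σ(z))].  Returns a float for plain-array
    inputs and a graph Tensor if either argument is a Tensor.
    """
    z, t = _as_tensor(logits), _as_tensor(targets)
    if z.shape != t.shape:
        raise ValueError(f"shape mismatch: logits {z.shape} vs targets {t.shape}")
    if np.any(t.data < 0) or np.any(t.data > 1):
        raise ValueError("BCE targets must lie in [0, 1]")
    out = (softplus(z) - t * z).mean()
    return _maybe_float(out, logits, targets)


def classification_loss(class_logits, label):
    """One-vs-all BCE of the 3 class logits against the one-hot label.

    Accepts a single logit vector with an int label, or a batch
    (N, n_classes) with a length-N label array.
    """
    z = _as_tensor(class_logits)
    labels = np.atleast_1d(np.asarray(label, dtype=int))
    batch = z.data.reshape(-1, z.shape[-1])
    n, n_cls = batch.shape
    if labels.size != n:
        raise ValueError(f"{labels.size} labels for batch of {n}")
    if np.any((labels < 0) | (labels >= n_cls)):
        raise ValueError(f"labels must be in [0, {n_cls})")
    onehot = np.zeros((n, n_cls))
    onehot[np.arange(n), labels] = 1.0
    out = bce_logits(z.reshape(n, n_cls), Tensor(onehot))
    return _maybe_float(out, class_logits)


def normalize_derived(derived):
    """z-score a derived map into a logit role (mean 0, population sd 1).

    An (almost) constant map standardizes to all-zeros.  Differentiable
    when given a Tensor.  Batched input (N, ...) is standardized per
    sample over its trailing axes.
    """
    t = _as_tensor(derived)
    if t.ndim <= 2:
        mean = t.mean()
        sd2 = ((t - mean) ** 2).mean()
        if float(sd2.data) < 1e-24:
            out = Tensor(np.zeros(t.shape))
        else:
            out = (t - mean) * sd2 ** -0.5
    else:
        axes = tuple(range(1, t.ndim))
        mean = t.mean(axis=axes, keepdims=True)
        sd2 = ((t - mean) ** 2).mean(axis=axes, keepdims=True)
        floor = np.maximum(sd2.data, 1e-24)  # constant-map samples -> zeros
        out = (t - mean) * (sd2 + (floor - sd2.data)) ** -0.5
        const = (sd2.data < 1e-24).reshape(-1)
        if const.any():
            keep = (~const).astype(float).reshape((-1,) + (1,) * (t.ndim - 1))
            out = out * keep
    return _maybe_float(out, derived)


def segmentation_loss(
    spec: LossSpec,
    decoder_logits,
    derived,
    gaze,
) -> tuple[Tensor, dict[str, float]]:
    """Scheme-specific segmentation term and its component values.

    Returns (seg Tensor, components dict).  ``derived`` must be the
    graph Tensor of the saliency sweep for set1/set3 (gradient flows
    through it) and may be a Tensor or array for set2 (it is detached
    into a fixed target either way).
    """
    if spec.needs_derived and derived is None:
        raise ValueError(f"scheme {spec.scheme!r} requires a derived saliency map")
    dec = _as_tensor(decoder_logits)
    gz = None
    if gaze is not None:
        gz = _as_tensor(gaze)
        if np.any(gz.data < 0) or np.any(gz.data > 1):
            raise ValueError("gaze heatmap values must lie in [0, 1]")

    comps: dict[str, float] = {}
    if spec.scheme == "baseline":
        seg = bce_logits(dec, gz)
        seg = _as_tensor(seg)
        comps["seg_decoder_vs_gaze"] = float(seg.data)
        return seg, comps

    if spec.scheme == "set1":
        seg = _as_tensor(bce_logits(normalize_derived(_as_tensor(derived)), gz))
        comps["seg_derived_vs_gaze"] = float(seg.data)
        return seg, comps

    if spec.scheme == "set2":
        target = sigmoid(_as_tensor(normalize_derived(_as_tensor(derived).detach())))
        seg = _as_tensor(bce_logits(dec, target.detach()))
        comps["seg_decoder_vs_derived"] = float(seg.data)
        return seg, comps

    # set3: weighted average of the set1 term and the baseline term
    lam = spec.lambda_mix
    derived_term = _as_tensor(bce_logits(normalize_derived(_as_tensor(derived)), gz))
    decoder_term = _as_tensor(bce_logits(dec, gz))
    comps["seg_derived_vs_gaze"] = float(derived_term.data)
    comps["seg_decoder_vs_gaze"] = float(decoder_term.data)
    if lam == 1.0:  # exact endpoint identities
        seg = derived_term
    elif lam == 0.0:
        seg = decoder_term
    else:
        seg = lam * derived_term + (1.0 - lam) * decoder_term
    return seg, comps


def total_loss(
    spec: LossSpec,
    class_logits,
    labels,
    decoder_logits,
    derived,
    gaze,
) -> tuple[Tensor, LossBreakdown]:
    """w_cls · classification + w_seg · segmentation, with a breakdown.

    With ``w_seg == 0`` the segmentation term is skipped entirely
    (pure-classification training; gaze and derived maps may be absent).
    """
    cls = _as_tensor(classification_loss(class_logits, labels))
    if spec.w_seg == 0:
        seg, comps = Tensor(np.zeros(())), {}
    else:
        seg, comps = segmentation_loss(spec, decoder_logits, derived, gaze)
    total = spec.w_cls * cls + spec.w_seg * seg
    breakdown = LossBreakdown(
        total=float(total.data),
        classification=float(cls.data),
        segmentation=float(seg.data),
        **comps,
    )
    return total, breakdown
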