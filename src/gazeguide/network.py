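"""Joint classification / heatmap-decoding U-Net.

The model maps a 1-channel image to three class logits (normal, CHF,
pneumonia) and a 1-channel decoder logit map at input resolution.  The
encoder is a small strided CNN ("smallnet") whose every hidden
nonlinearity is ReLU, so the saliency module can substitute modified
backward rules at each site.  Downsampling uses stride-2 convolutions
(no pooling switches to track), upsampling is nearest-neighbour + conv,
and skip connections concatenate encoder features into the decoder at
matching resolutions.

There are deliberately no batch-statistics layers: evaluation outputs
are batch-size invariant, which keeps the saliency and loss contracts
exactly testable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from .autodiff import (
    Tensor,
    concat,
    conv2d,
    conv2d_input_adjoint,
    upsample_nearest2x,
    relu,
)

__all__ = [
    "EncoderConfig",
    "ModelOutput",
    "Dense",
    "Conv2d",
    "ReLULayer",
    "SigmoidLayer",
    "GlobalAvgPool",
    "Sequential",
    "UNet",
    "build_model",
    "save_checkpoint",
    "load_checkpoint",
]

CLASS_NAMES = ("normal", "CHF", "pneumonia")
CHECKPOINT_SCHEMA = 1


@dataclass
class EncoderConfig:
    """Encoder family and geometry.

    ``smallnet`` is a 3-level, 8–32 channel CNN that trains at desk scale
    on one CPU; ``efficientnet-b0`` is accepted as a name for parity with
    larger deployments but requires a pretrained-model backend that this
    pure-NumPy build does not ship.
    """

    family: str = "smallnet"
    depth: int = 3
    base_channels: int = 8
    pretrained: bool = False

    def __post_init__(self) -> None:
        if self.depth < 2:
            raise ValueError("depth must be >= 2")
        if self.family not in ("smallnet", "efficientnet-b0"):
            raise ValueError(f"unknown encoder family {self.family!r}")


@dataclass
class ModelOutput:
    """Class logits (N, 3) and decoder logit map (N, H, W) as arrays."""

    class_logits: np.ndarray
    decoder_logits: np.ndarray


# ---------------------------------------------------------------------------
# Layers.  Each layer exposes an autodiff `forward`; linear layers also
# expose `transpose_apply`, the adjoint map used by the saliency sweep
# (expressed in graph ops so it stays differentiable in the weights).
# ---------------------------------------------------------------------------


class Layer:
    is_activation = False

    def params(self) -> list[Tensor]:
        return []

    def forward(self, x: Tensor) -> Tensor:  # pragma: no cover - interface
        raise NotImplementedError


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / n_in)
        self.W = Tensor(rng.normal(0.0, scale, (n_out, n_in)), requires_grad=True)
        self.b = Tensor(np.zeros(n_out), requires_grad=True)

    def params(self) -> list[Tensor]:
        return [self.W, self.b]

    def forward(self, x: Tensor) -> Tensor:
        return x @ self.W.transpose(1, 0) + self.b.reshape(1, -1)

    def transpose_apply(self, s: Tensor, inp: Tensor) -> Tensor:
        # adjoint of x -> x W^T is s -> s W; bias does not reach the input
        return s @ self.W


class Conv2d(Layer):
    """k×k convolution, 'same' padding, optional stride."""

    def __init__(
        self,
        c_in: int,
        c_out: int,
        k: int,
        rng: np.random.Generator,
        stride: int = 1,
    ):
        self.c_in, self.c_out, self.k, self.stride = c_in, c_out, k, stride
        self.pad = k // 2
        scale = np.sqrt(2.0 / (c_in * k * k))
        self.W = Tensor(
            rng.normal(0.0, scale, (c_out, c_in, k, k)), requires_grad=True
        )
        self.b = Tensor(np.zeros(c_out), requires_grad=True)

    def params(self) -> list[Tensor]:
        return [self.W, self.b]

    def n_params(self) -> int:
        return self.c_out * self.c_in * self.k * self.k + self.c_out

    def forward(self, x: Tensor) -> Tensor:
        out = conv2d(x, self.W, stride=self.stride, pad=self.pad)
        return out + self.b.reshape(1, self.c_out, 1, 1)

    def transpose_apply(self, s: Tensor, inp: Tensor) -> Tensor:
        # bias does not reach the input, so the adjoint is weights-only
        return conv2d_input_adjoint(s, self.W, inp.shape, self.stride, self.pad)


class ReLULayer(Layer):
    is_activation = True
    name = "relu"

    def forward(self, x: Tensor) -> Tensor:
        return relu(x)


class SigmoidLayer(Layer):
    """Non-ReLU activation; present so misuse is detectable, not used by UNet."""

    is_activation = True
    name = "sigmoid"

    def forward(self, x: Tensor) -> Tensor:
        from .autodiff import sigmoid

        return sigmoid(x)


class GlobalAvgPool(Layer):
    def forward(self, x: Tensor) -> Tensor:
        return x.mean(axis=(2, 3))

    def transpose_apply(self, s: Tensor, inp: Tensor) -> Tensor:
        n, c, h, w = inp.shape
        return s.reshape(n, c, 1, 1) * np.full((1, 1, h, w), 1.0 / (h * w))


class Sequential:
    """A flat layer chain ending in class logits; the saliency sweep's unit."""

    def __init__(self, layers: list[Layer]):
        self.layers = list(layers)

    def params(self) -> list[Tensor]:
        return [p for layer in self.layers for p in layer.params()]

    def forward_tape(self, x: Tensor) -> tuple[Tensor, list[tuple[Layer, Tensor]]]:
        """Run forward, recording each layer's input for the adjoint sweep."""
        tape: list[tuple[Layer, Tensor]] = []
        for layer in self.layers:
            tape.append((layer, x))
            x = layer.forward(x)
        return x, tape

    def forward(self, x: Tensor) -> Tensor:
        out, _ = self.forward_tape(x)
        return out

    def relu_sites(self) -> list[int]:
        return [i for i, l in enumerate(self.layers) if isinstance(l, ReLULayer)]


class UNet:
    """Encoder + classification head + skip-connected decoder."""

    def __init__(self, cfg: EncoderConfig, image_size: tuple[int, int], seed: int = 0):
        if cfg.family == "efficientnet-b0":
            raise NotImplementedError(
                "efficientnet-b0 requires a pretrained-model backend that is "
                "not available in this build; use family='smallnet'"
            )
        h, w = image_size
        mult = 2 ** (cfg.depth - 1)
        if h % mult or w % mult:
            raise ValueError(
                f"image size {image_size} must be divisible by {mult} "
                f"(2^(depth-1) with depth={cfg.depth})"
            )
        self.cfg = cfg
        self.image_size = (int(h), int(w))
        self.seed = int(seed)
        rng = np.random.default_rng(seed)

        chans = [cfg.base_channels * 2**d for d in range(cfg.depth)]
        self.channels = chans

        # encoder: per level, (strided) conv + relu + conv + relu
        self.enc_blocks: list[list[Layer]] = []
        c_prev = 1
        for d, c in enumerate(chans):
            stride = 1 if d == 0 else 2
            self.enc_blocks.append(
                [
                    Conv2d(c_prev, c, 3, rng, stride=stride),
                    ReLULayer(),
                    Conv2d(c, c, 3, rng),
                    ReLULayer(),
                ]
            )
            c_prev = c

        self.gap = GlobalAvgPool()
        self.head = Dense(chans[-1], len(CLASS_NAMES), rng)

        # decoder: upsample + conv + relu, concat skip, conv + relu
        self.dec_blocks: list[dict] = []
        for d in reversed(range(cfg.depth - 1)):
            self.dec_blocks.append(
                {
                    "up_conv": Conv2d(chans[d + 1], chans[d], 3, rng),
                    "up_relu": ReLULayer(),
                    "merge_conv": Conv2d(2 * chans[d], chans[d], 3, rng),
                    "merge_relu": ReLULayer(),
                    "skip_level": d,
                }
            )
        self.out_conv = Conv2d(chans[0], 1, 1, rng)
        self._ablate_skips: set[int] = set()  # test hook: zero these skip levels

    # -- parameter access ---------------------------------------------------

    def params(self) -> list[Tensor]:
        out = self.classifier_path().params()
        for blk in self.dec_blocks:
            out += blk["up_conv"].params() + blk["merge_conv"].params()
        out += self.out_conv.params()
        return out

    def classifier_path(self) -> Sequential:
        """The input→class-logits chain the saliency sweep walks."""
        layers: list[Layer] = [l for blk in self.enc_blocks for l in blk]
        return Sequential(layers + [self.gap, self.head])

    def relu_site_count(self) -> int:
        n = len(self.classifier_path().relu_sites())
        n += 2 * len(self.dec_blocks)
        return n

    def n_params(self) -> int:
        return sum(p.data.size for p in self.params())

    # -- forward ------------------------------------------------------------

    def forward_graph(
        self,
        images: np.ndarray,
        with_decoder: bool = True,
        with_tape: bool = False,
    ):
        """Graph-mode forward: (class_logits, decoder_logits[, classifier tape]).

        The tape records (layer, input) pairs along the input→logits
        chain so the saliency sweep can reuse this forward pass instead
        of recomputing the encoder.
        """
        x = self._check_input(images)
        t = Tensor(x)
        tape: list = []
        skips: list[Tensor] = []
        for blk in self.enc_blocks:
            for layer in blk:
                tape.append((layer, t))
                t = layer.forward(t)
            skips.append(t)
        tape.append((self.gap, t))
        pooled = self.gap.forward(t)
        tape.append((self.head, pooled))
        class_logits = self.head.forward(pooled)
        if not with_decoder:
            return (class_logits, None, tape) if with_tape else (class_logits, None)

        d = t  # bottleneck features
        for blk in self.dec_blocks:
            d = upsample_nearest2x(d)
            d = blk["up_relu"].forward(blk["up_conv"].forward(d))
            skip = skips[blk["skip_level"]]
            if blk["skip_level"] in self._ablate_skips:
                skip = Tensor(np.zeros_like(skip.data))
            d = concat([d, skip], axis=1)
            d = blk["merge_relu"].forward(blk["merge_conv"].forward(d))
        decoder_logits = self.out_conv.forward(d)
        if with_tape:
            return class_logits, decoder_logits, tape
        return class_logits, decoder_logits

    def forward(self, images: np.ndarray) -> ModelOutput:
        """Numpy-in / numpy-out evaluation forward."""
        cl, dl = self.forward_graph(images)
        return ModelOutput(
            class_logits=cl.data.copy(), decoder_logits=dl.data[:, 0].copy()
        )

    def _check_input(self, images: np.ndarray) -> np.ndarray:
        x = np.asarray(images, dtype=np.float64)
        if x.ndim == 2:
            x = x[None, None]
        elif x.ndim == 3:
            x = x[:, None]
        elif x.ndim != 4:
            raise ValueError("expected (H,W), (N,H,W) or (N,1,H,W) input")
        if x.shape[2:] != self.image_size:
            raise ValueError(
                f"spatial size {x.shape[2:]} does not match build size "
                f"{self.image_size}"
            )
        return x


def build_model(cfg: EncoderConfig, image_size: tuple[int, int], seed: int = 0) -> UNet:
    return UNet(cfg, image_size, seed=seed)


# ---------------------------------------------------------------------------
# Checkpointing: weights + config + image size + schema, bit-exact reload.
# ---------------------------------------------------------------------------


def save_checkpoint(model: UNet, path: str | Path) -> None:
    meta = {
        "schema": CHECKPOINT_SCHEMA,
        "config": asdict(model.cfg),
        "image_size": list(model.image_size),
        "seed": model.seed,
    }
    arrays = {f"param_{i}": p.data for i, p in enumerate(model.params())}
    with open(path, "wb") as fh:  # keep the exact filename (no .npz appended)
        np.savez(fh, meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8), **arrays)


def load_checkpoint(path: str | Path) -> UNet:
    with np.load(path) as z:
        meta = json.loads(bytes(z["meta"]).decode())
        if meta["schema"] != CHECKPOINT_SCHEMA:
            raise ValueError(f"unsupported checkpoint schema {meta['schema']}")
        model = UNet(
            EncoderConfig(**meta["config"]),
            tuple(meta["image_size"]),
            seed=meta["seed"],
        )
        for i, p in enumerate(model.params()):
            p.data = z[f"param_{i}"].astype(np.float64)
    return model
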