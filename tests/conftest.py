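import numpy as np
import pytest

from gazeguide import EncoderConfig, SynthConfig, build_model, generate
from gazeguide.network import Dense, ReLULayer, Sequential


@pytest.fixture(scope="session")
def tiny_dataset(tmp_path_factory):
    """15-image synthetic dataset (5 per class, 5 patients, 32x32)."""
    cfg = SynthConfig(
        n_per_class=5,
        image_size=(32, 32),
        n_patients=5,
        fixations_per_image=8,
        lesion_radius_px=3.0,
        seed=3,
    )
    out = tmp_path_factory.mktemp("tiny") / "ds"
    generate(cfg, out)
    return out


@pytest.fixture()
def small_unet():
    return build_model(EncoderConfig(depth=2, base_channels=4), (16, 16), seed=0)


def random_mlp(rng, n_layers=None, width=None, n_classes=3):
    """A random Dense/ReLU stack ending in class logits, plus its matrices."""
    n_layers = n_layers or int(rng.integers(1, 4))
    width = width or int(rng.integers(2, 9))
    dims = [int(rng.integers(2, 9))] + [width] * (n_layers - 1) + [n_classes]
    layers, mats = [], []
    for i in range(n_layers):
        d = Dense(dims[i], dims[i + 1], rng)
        d.W.data = rng.normal(0, 1, d.W.shape)
        d.b.data = rng.normal(0, 0.5, d.b.shape)
        mats.append((d.W.data.copy(), d.b.data.copy()))
        layers.append(d)
        if i < n_layers - 1:
            layers.append(ReLULayer())
    return Sequential(layers), mats, dims


def mlp_saliency_oracle(mats, x, class_index, rule):
    """Independent layer-by-layer chain rule with the three mask rules.

    Kept free of the package's sweep machinery: plain matrix products
    and explicit masks on the recorded pre-activations.
    """
    pres = []
    a = np.asarray(x, dtype=float)
    for i, (W, b) in enumerate(mats):
        z = W @ a + b
        if i < len(mats) - 1:
            pres.append(z)
            a = np.maximum(z, 0.0)
    g = np.zeros(mats[-1][0].shape[0])
    g[class_index] = 1.0
    for i in reversed(range(len(mats))):
        W, _ = mats[i]
        g = g @ W  # through the linear layer
        if i > 0:
            pre = pres[i - 1]
            if rule == "backprop":
                g = g * (pre > 0)
            elif rule == "deconvnet":
                g = g * (g > 0)
            elif rule == "gbp":
                g = g * (g > 0) * (pre > 0)
    return g
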