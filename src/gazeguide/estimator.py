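"""scikit-learn-style estimator facade over the training pipeline.

``SaliencyGuidedUNetClassifier`` is a classifier in the sklearn sense
(``fit`` / ``predict`` / ``predict_proba`` / ``get_params`` /
``set_params``), so it composes with pipelines and model selection.
Underneath it drives the same training loop as the file-based
``training.train``: a joint classification/heatmap U-Net whose loss can
inject rule-masked saliency maps (GBP or deconvNet) and eye-gaze
heatmaps, per the four loss schemes in :mod:`gazeguide.losses`.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from .losses import LossSpec
from .network import EncoderConfig
from .saliency import gradcam_map, saliency_map
from .training import TrainConfig, fit_arrays

__all__ = ["SaliencyGuidedUNetClassifier"]


def _sigmoid(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(z, -700, 700)))


class SaliencyGuidedUNetClassifier(ClassifierMixin, BaseEstimator):
    """Joint classification/heatmap U-Net trained with gaze supervision.

    Parameters
    ----------
    scheme : {"baseline", "set1", "set2", "set3"}
        How the segmentation (attention-supervision) loss is formed.
    generator : {"none", "gbp", "deconvnet"}
        Backward rule of the derived saliency map for set1/set2/set3.
    lambda_mix : float
        set3 only: weight of the derived-vs-gaze term (1 - lambda_mix
        goes to the decoder-vs-gaze term).
    w_cls, w_seg : float
        Weights of the classification and segmentation losses.
    depth, base_channels : int
        Smallnet encoder geometry.
    epochs, batch_size, learning_rate : training loop knobs (Adam).
    val_fraction : float
        Fraction of fit data held out (grouped by ``groups`` when given)
        for model selection by validation classification loss.
    random_state : int
        Seed for weight init, shuffling, and the validation split.

    Attributes
    ----------
    classes_ : ndarray of shape (n_classes,)
    model_ : the fitted :class:`gazeguide.network.UNet`
    history_ : DataFrame of per-step / per-epoch loss rows
    image_size_ : (height, width) the network was built for
    """

    def __init__(
        self,
        scheme: str = "set3",
        generator: str = "gbp",
        lambda_mix: float = 0.5,
        w_cls: float = 1.0,
        w_seg: float = 1.0,
        depth: int = 3,
        base_channels: int = 8,
        epochs: int = 4,
        batch_size: int = 16,
        learning_rate: float = 2e-3,
        val_fraction: float = 0.1,
        random_state: int = 0,
    ):
        self.scheme = scheme
        self.generator = generator
        self.lambda_mix = lambda_mix
        self.w_cls = w_cls
        self.w_seg = w_seg
        self.depth = depth
        self.base_channels = base_channels
        self.epochs = epochs
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.val_fraction = val_fraction
        self.random_state = random_state

    # -- internals ----------------------------------------------------------

    def _loss_spec(self) -> LossSpec:
        gen = self.generator
        if self.scheme == "baseline":
            gen = "none"
        return LossSpec(
            scheme=self.scheme,
            generator=gen,
            lambda_mix=self.lambda_mix,
            w_cls=self.w_cls,
            w_seg=self.w_seg,
        )

    def _validate_X(self, X: np.ndarray, fitted: bool = False) -> np.ndarray:
        X = np.asarray(X, dtype=np.float64)
        if X.ndim == 2:
            X = X[None]
        if X.ndim != 3:
            raise ValueError("X must be (n_samples, height, width) grayscale images")
        if fitted and X.shape[1:] != self.image_size_:
            raise ValueError(
                f"images of shape {X.shape[1:]} do not match fitted size "
                f"{self.image_size_}"
            )
        return X

    def _split_train_val(self, n: int, groups) -> tuple[np.ndarray, np.ndarray]:
        rng = np.random.default_rng(self.random_state)
        if groups is None:
            order = rng.permutation(n)
            n_val = max(1, int(round(self.val_fraction * n)))
            return order[n_val:], order[:n_val]
        groups = np.asarray(groups)
        uniq = rng.permutation(np.unique(groups))
        n_val_target = max(1, int(round(self.val_fraction * n)))
        val_groups, count = [], 0
        for g in uniq:
            if count >= n_val_target:
                break
            val_groups.append(g)
            count += int((groups == g).sum())
        val_mask = np.isin(groups, val_groups)
        if val_mask.all():
            raise ValueError("validation split consumed all groups")
        return np.where(~val_mask)[0], np.where(val_mask)[0]

    # -- sklearn API --------------------------------------------------------

    def fit(self, X, y, gaze=None, groups=None):
        """Fit on images X (n, H, W) with labels y and optional gaze maps.

        ``gaze`` is (n, H, W) in [0, 1]; required whenever the
        segmentation loss is active (w_seg > 0) with a gaze-based scheme.
        ``groups`` are patient ids; when given, the internal validation
        split never separates a group.
        """
        X = self._validate_X(X)
        y = np.asarray(y)
        if len(y) != len(X):
            raise ValueError("X and y length mismatch")
        self.classes_, y_idx = np.unique(y, return_inverse=True)
        if len(self.classes_) != 3:
            raise ValueError(
                f"this model has a 3-class head; got {len(self.classes_)} classes"
            )
        spec = self._loss_spec()
        if gaze is not None:
            gaze = np.asarray(gaze, dtype=np.float64)
            if gaze.shape != X.shape:
                raise ValueError("gaze must have the same shape as X")

        self.image_size_ = X.shape[1:]
        tr, va = self._split_train_val(len(X), groups)
        cfg = TrainConfig(
            loss_spec=spec,
            encoder=EncoderConfig(depth=self.depth, base_channels=self.base_channels),
            epochs=self.epochs,
            batch_size=self.batch_size,
            learning_rate=self.learning_rate,
            seed=self.random_state,
            image_size=self.image_size_,
        )
        self.model_, self.history_ = fit_arrays(
            X[tr], y_idx[tr], gaze[tr] if gaze is not None else None,
            X[va], y_idx[va], cfg,
        )
        return self

    def decision_function(self, X) -> np.ndarray:
        check_is_fitted(self, "model_")
        X = self._validate_X(X, fitted=True)
        return self.model_.forward(X).class_logits

    def score_matrix(self, X) -> np.ndarray:
        """Per-class one-vs-rest scores: sigmoid of each class logit."""
        return _sigmoid(self.decision_function(X))

    def predict_proba(self, X) -> np.ndarray:
        s = self.score_matrix(X)
        return s / s.sum(axis=1, keepdims=True)

    def predict(self, X) -> np.ndarray:
        logits = self.decision_function(X)
        return self.classes_[np.argmax(logits, axis=1)]

    # -- maps ---------------------------------------------------------------

    def decoder_maps(self, X) -> np.ndarray:
        """Decoder probability maps (sigmoid of decoder logits), (n, H, W)."""
        check_is_fitted(self, "model_")
        X = self._validate_X(X, fitted=True)
        return _sigmoid(self.model_.forward(X).decoder_logits)

    def saliency(self, image, class_index: int, method: str = "gbp"):
        """Post-hoc saliency map of one image for one class index."""
        check_is_fitted(self, "model_")
        return saliency_map(self.model_, image, class_index, method=method)

    def gradcam(self, image, class_index: int, layer: str = "enc-1"):
        check_is_fitted(self, "model_")
        return gradcam_map(self.model_, image, class_index, layer=layer)
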