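"""Patient-grouped splitting and the saliency-guided training loop.

Splitting assigns whole *patients* (never single images) to
train/validation/test so that no identity crosses folds; fold sizes are
matched to the 0.80/0.10/0.10 record fractions by minimizing the total
absolute deviation of record counts (exact enumeration for small
patient sets, largest-first greedy with a local-improvement pass
otherwise).

Training computes, per step: a forward pass; when the loss scheme
requires it, a fresh rule-masked saliency map of the true-class logit
(differentiable in the weights — maps depend on the current weights so
nothing is cached); the scheme-specific total loss; one Adam step.
Model selection is by validation classification loss.  Runs are
deterministic given the config seed (single-threaded NumPy).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image
from skimage.transform import resize

from .autodiff import compute_dtype
from .gaze_heatmaps import Fixation, read_fixations_csv, static_map_for
from .losses import LossSpec, total_loss
from .network import EncoderConfig, UNet, build_model
from .saliency import saliency_from_tape

__all__ = [
    "Record",
    "DatasetIndex",
    "TrainConfig",
    "Adam",
    "load_dataset",
    "patient_grouped_split",
    "train",
    "fit_arrays",
]

SPLITS = ("train", "val", "test")


@dataclass(frozen=True)
class Record:
    image_id: str
    image_path: Path | None
    label: int
    patient_id: str
    fixations: tuple[Fixation, ...] | None = None


@dataclass
class DatasetIndex:
    records: list[Record]
    split: list[str]  # per-record, "train" | "val" | "test"

    def indices(self, which: str) -> list[int]:
        if which not in SPLITS:
            raise ValueError(f"split must be one of {SPLITS}")
        return [i for i, s in enumerate(self.split) if s == which]

    def subset(self, which: str) -> list[Record]:
        return [self.records[i] for i in self.indices(which)]


@dataclass
class TrainConfig:
    loss_spec: LossSpec = field(default_factory=LossSpec)
    encoder: EncoderConfig = field(default_factory=EncoderConfig)
    epochs: int = 4
    batch_size: int = 16
    learning_rate: float = 2e-3
    seed: int = 0
    image_size: tuple[int, int] = (64, 64)
    gaze_sigma: float | None = None
    gaze_n_windows: int = 3
    dtype: str = "float32"  # engine precision during training

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")


# ---------------------------------------------------------------------------
# Patient-grouped splitting
# ---------------------------------------------------------------------------

_EXACT_SPLIT_MAX_PATIENTS = 10


def _deviation(counts: np.ndarray, targets: np.ndarray) -> float:
    return float(np.abs(counts - targets).sum())


def patient_grouped_split(
    records: list[Record],
    fractions: tuple[float, float, float] = (0.8, 0.1, 0.1),
    seed: int = 0,
) -> DatasetIndex:
    """Assign whole patients to splits, matching record-count fractions.

    Minimizes the total absolute deviation of per-split record counts
    from ``fractions * n_records``: exactly (enumeration over all 3^P
    assignments) for at most 10 patients, otherwise largest-patient-first
    greedy followed by single-move local improvement.  Deterministic for
    a given seed.
    """
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    patients: dict[str, list[int]] = {}
    for i, r in enumerate(records):
        patients.setdefault(r.patient_id, []).append(i)
    if len(patients) < 3:
        raise ValueError(f"need at least 3 patients, got {len(patients)}")

    rng = np.random.default_rng(seed)
    ids = sorted(patients)
    order = [ids[k] for k in rng.permutation(len(ids))]
    sizes = np.array([len(patients[p]) for p in order])
    targets = np.asarray(fractions) * float(len(records))

    n = len(order)
    if n <= _EXACT_SPLIT_MAX_PATIENTS:
        best, best_dev = None, np.inf
        for assign in itertools.product(range(3), repeat=n):
            counts = np.zeros(3)
            for a, s in zip(assign, sizes):
                counts[a] += s
            dev = _deviation(counts, targets)
            if dev < best_dev - 1e-12:
                best, best_dev = assign, dev
        assign = list(best)
    else:
        # greedy: largest patients first into the most-deficient split
        by_size = sorted(range(n), key=lambda k: (-sizes[k], k))
        assign = [0] * n
        counts = np.zeros(3)
        for k in by_size:
            deficit = targets - counts
            a = int(np.argmax(deficit))
            assign[k] = a
            counts[a] += sizes[k]
        # local improvement: single moves until no gain
        improved = True
        while improved:
            improved = False
            for k in range(n):
                cur = assign[k]
                for a in range(3):
                    if a == cur:
                        continue
                    trial = counts.copy()
                    trial[cur] -= sizes[k]
                    trial[a] += sizes[k]
                    if _deviation(trial, targets) < _deviation(counts, targets) - 1e-12:
                        counts, assign[k] = trial, a
                        improved = True

    split = [""] * len(records)
    for p, a in zip(order, assign):
        for i in patients[p]:
            split[i] = SPLITS[a]
    return DatasetIndex(records=list(records), split=split)


# ---------------------------------------------------------------------------
# Dataset loading (synthetic_data layout: images/, labels.csv, fixations.csv)
# ---------------------------------------------------------------------------


def load_dataset(data_dir: str | Path) -> list[Record]:
    data_dir = Path(data_dir)
    labels = pd.read_csv(data_dir / "labels.csv")
    fixmap = read_fixations_csv(data_dir / "fixations.csv")
    records = []
    for row in labels.itertuples(index=False):
        image_id = str(row.image_id)
        records.append(
            Record(
                image_id=image_id,
                image_path=data_dir / "images" / f"{image_id}.png",
                label=int(row.label),
                patient_id=str(row.patient_id),
                fixations=tuple(fixmap.get(image_id, ())) or None,
            )
        )
    return records


def _load_image(
    record: Record, image_size: tuple[int, int]
) -> tuple[np.ndarray, tuple[int, int]]:
    """Read a grayscale image, min-max normalize to [0,1], resize if needed.

    Returns the resized image and the native (pre-resize) shape, which is
    the coordinate frame of the record's fixations.
    """
    img = np.asarray(Image.open(record.image_path).convert("L"), dtype=np.float64)
    native = img.shape
    span = img.max() - img.min()
    img = (img - img.min()) / span if span > 0 else np.zeros_like(img)
    if img.shape != tuple(image_size):
        img = resize(img, image_size, order=1, mode="edge", anti_aliasing=True)
    return img, native


def _gaze_map(record: Record, cfg: TrainConfig, native_size: tuple[int, int]) -> np.ndarray:
    if record.fixations is None:
        raise ValueError(f"record {record.image_id} has no gaze fixations")
    hm = static_map_for(
        list(record.fixations), native_size,
        sigma=cfg.gaze_sigma, n_windows=cfg.gaze_n_windows,
    ).values
    if hm.shape != tuple(cfg.image_size):
        hm = resize(hm, cfg.image_size, order=1, mode="edge", anti_aliasing=False)
        peak = hm.max()
        hm = hm / peak if peak > 0 else hm
    return np.clip(hm, 0.0, 1.0)


# ---------------------------------------------------------------------------
# Optimizer
# ---------------------------------------------------------------------------


class Adam:
    def __init__(self, params, lr: float = 1e-3, betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr, self.betas, self.eps = lr, betas, eps
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.betas
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            self.m[i] = b1 * self.m[i] + (1 - b1) * p.grad
            self.v[i] = b2 * self.v[i] + (1 - b2) * p.grad**2
            m_hat = self.m[i] / (1 - b1**self.t)
            v_hat = self.v[i] / (1 - b2**self.t)
            p.data -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)


# ---------------------------------------------------------------------------
# Training loop
# ---------------------------------------------------------------------------


def _classification_loss_np(model: UNet, images: np.ndarray, labels: np.ndarray,
                            batch_size: int) -> float:
    from .losses import classification_loss

    losses, weights = [], []
    for lo in range(0, len(images), batch_size):
        xb = images[lo : lo + batch_size]
        out = model.forward(xb)
        losses.append(classification_loss(out.class_logits, labels[lo : lo + batch_size]))
        weights.append(len(xb))
    return float(np.average(losses, weights=weights))


def fit_arrays(
    train_images: np.ndarray,
    train_labels: np.ndarray,
    train_gaze: np.ndarray | None,
    val_images: np.ndarray,
    val_labels: np.ndarray,
    cfg: TrainConfig,
) -> tuple[UNet, pd.DataFrame]:
    """Core loop on in-memory arrays; returns (best model, training log).

    ``train_images``/``val_images`` are (N, H, W) in [0, 1];
    ``train_gaze`` is (N, H, W) in [0, 1] or None when w_seg == 0.
    """
    spec = cfg.loss_spec
    if len(train_images) == 0 or len(val_images) == 0:
        raise ValueError("train and val sets must be nonempty")
    if train_gaze is None and spec.w_seg > 0 and spec.scheme != "set2":
        raise ValueError("gaze maps are required when the segmentation loss is active")

    model = build_model(cfg.encoder, cfg.image_size, seed=cfg.seed)
    opt = Adam(model.params(), lr=cfg.learning_rate)
    rng = np.random.default_rng(cfg.seed)

    log_rows: list[dict] = []
    best_val, best_params, step = np.inf, None, 0
    n = len(train_images)
    dtype_ctx = compute_dtype(np.dtype(cfg.dtype))
    with dtype_ctx:
        for p in model.params():  # cast weights to the working precision
            p.data = p.data.astype(dtype_ctx.dtype)
    for epoch in range(cfg.epochs):
        order = rng.permutation(n)
        epoch_breakdowns = []
        for lo in range(0, n, cfg.batch_size):
            idx = order[lo : lo + cfg.batch_size]
            xb = train_images[idx]
            yb = train_labels[idx]
            gb = train_gaze[idx][:, None] if train_gaze is not None else None

            with dtype_ctx:
                out = model.forward_graph(xb, with_decoder=spec.w_seg > 0,
                                          with_tape=True)
                cl, dl, tape = out
                derived = None
                if spec.w_seg > 0 and spec.needs_derived:
                    derived = saliency_from_tape(tape, cl, yb, spec.generator)
                loss, breakdown = total_loss(spec, cl, yb, dl, derived, gb)
                if not np.isfinite(breakdown.total):
                    raise RuntimeError(
                        f"non-finite loss at epoch {epoch} step {step}: {breakdown}"
                    )
                opt.zero_grad()
                loss.backward()
                opt.step()

            step += 1
            epoch_breakdowns.append(breakdown)
            log_rows.append(
                {"kind": "step", "epoch": epoch, "step": step,
                 "total": breakdown.total,
                 "classification": breakdown.classification,
                 "segmentation": breakdown.segmentation,
                 "seg_derived_vs_gaze": breakdown.seg_derived_vs_gaze,
                 "seg_decoder_vs_gaze": breakdown.seg_decoder_vs_gaze,
                 "seg_decoder_vs_derived": breakdown.seg_decoder_vs_derived}
            )

        with dtype_ctx:
            val_loss = _classification_loss_np(
                model, val_images, val_labels, cfg.batch_size
            )
        means = {
            k: float(np.mean([getattr(b, k) for b in epoch_breakdowns]))
            for k in ("total", "classification", "segmentation")
        }
        log_rows.append({"kind": "epoch", "epoch": epoch, "step": step,
                         "val_classification": val_loss, **means})
        if val_loss < best_val:
            best_val = val_loss
            best_params = [p.data.copy() for p in model.params()]

    if best_params is not None:
        for p, saved in zip(model.params(), best_params):
            p.data = saved
    for p in model.params():  # hand back float64 weights for evaluation
        p.data = p.data.astype(np.float64)
    return model, pd.DataFrame(log_rows)


def train(cfg: TrainConfig, data: DatasetIndex) -> tuple[UNet, pd.DataFrame]:
    """File-backed wrapper: load train/val arrays from a DatasetIndex.

    Never touches records whose split is "test".
    """
    train_idx = data.indices("train")
    val_idx = data.indices("val")
    if not train_idx or not val_idx:
        raise ValueError("train and val splits must be nonempty")

    needs_gaze = cfg.loss_spec.w_seg > 0
    if needs_gaze:
        for i in train_idx:
            if data.records[i].fixations is None:
                raise ValueError(
                    f"missing gaze fixations for train record "
                    f"{data.records[i].image_id}"
                )

    def _arrays(indices, with_gaze):
        imgs, labels, gaze = [], [], []
        for i in indices:
            rec = data.records[i]
            img, native = _load_image(rec, cfg.image_size)
            imgs.append(img)
            labels.append(rec.label)
            if with_gaze:
                gaze.append(_gaze_map(rec, cfg, native))
        return (
            np.asarray(imgs),
            np.asarray(labels, dtype=int),
            np.asarray(gaze) if with_gaze else None,
        )

    tr_x, tr_y, tr_g = _arrays(train_idx, needs_gaze)
    va_x, va_y, _ = _arrays(val_idx, False)
    return fit_arrays(tr_x, tr_y, tr_g, va_x, va_y, cfg)
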