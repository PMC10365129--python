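"""Desk-scale synthetic image / label / gaze triplets.

The generator reproduces the *statistical structure* the gaze-guided
training method assumes — a localized class-discriminative structure on
which simulated gaze concentrates — without any pretence of
radiographic realism:

* class 0, "normal"-analog: a smooth chest-like background (two dark
  elliptical lung fields, a bright central mediastinum) plus Gaussian
  noise;
* class 1, "CHF"-analog: the central bright ellipse enlarged by ≥ 1.5×
  (cardiomegaly analog — a *global* structure change);
* class 2, "pneumonia"-analog: one bright disc inside a lung field at a
  random position (focal opacity).

The two disease analogs demand different spatial attention, mirroring
the label set on which gaze supervision helps most.  A configurable
fraction of fixations is drawn from a Gaussian centred on the
discriminative structure (the image centre for class 0); the remainder
is uniform over the image.  Patients are contiguous single-class
blocks, so patient-grouped splitting is exercised nontrivially.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict, replace
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

__all__ = ["SynthConfig", "generate", "difficulty_sweep", "render_image",
           "DIFFICULTY_INTENSITIES"]

# lesion-intensity grid of the difficulty sweep; the generator default
# sits at its midpoint
DIFFICULTY_INTENSITIES = (0.2, 0.35, 0.5, 0.65, 0.8)


@dataclass
class SynthConfig:
    n_per_class: int = 200
    image_size: tuple[int, int] = (64, 64)
    noise_sd: float = 0.12
    lesion_intensity: float = 0.5
    lesion_radius_px: float = 8.0
    gaze_on_target_frac: float = 0.8
    fixations_per_image: int = 20
    n_patients: int = 60
    seed: int = 0
    chf_enlargement: float = 1.6  # >= 1.5 per the class definition

    def __post_init__(self) -> None:
        if self.n_patients > 3 * self.n_per_class:
            raise ValueError("n_patients cannot exceed the number of images (3*n_per_class)")
        if self.n_patients < 3:
            raise ValueError("need at least one patient per class")
        if self.fixations_per_image < 1:
            raise ValueError("fixations_per_image must be >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not 0.0 <= self.gaze_on_target_frac <= 1.0:
            raise ValueError("gaze_on_target_frac must be in [0, 1]")
        if self.chf_enlargement < 1.5:
            raise ValueError("chf_enlargement must be >= 1.5")


# ---------------------------------------------------------------------------
# geometry of the chest-analog scene (fractions of image size)
# ---------------------------------------------------------------------------

_LUNG_CENTERS = ((0.50, 0.28), (0.50, 0.72))  # (row, col) fractions
_LUNG_AXES = (0.34, 0.17)  # (semi-row, semi-col) fractions
_HEART_CENTER = (0.52, 0.50)
_HEART_AXES = (0.30, 0.11)


def _ellipse_mask(shape, center, axes) -> np.ndarray:
    h, w = shape
    rr = np.arange(h)[:, None]
    cc = np.arange(w)[None, :]
    cy, cx = center[0] * h, center[1] * w
    ay, ax = axes[0] * h, axes[1] * w
    return ((rr - cy) / ay) ** 2 + ((cc - cx) / ax) ** 2 <= 1.0


def _background(shape) -> np.ndarray:
    img = np.full(shape, 0.45)
    for c in _LUNG_CENTERS:
        img[_ellipse_mask(shape, c, _LUNG_AXES)] -= 0.22
    return img


def _heart(shape, enlargement: float = 1.0) -> np.ndarray:
    axes = (_HEART_AXES[0], _HEART_AXES[1] * enlargement)
    return 0.30 * _ellipse_mask(shape, _HEART_CENTER, axes).astype(float)


def _lesion_position(shape, radius: float, rng: np.random.Generator) -> tuple[float, float]:
    """A disc centre strictly inside a lung ellipse, margin = radius."""
    h, w = shape
    side = int(rng.integers(2))
    cy, cx = _LUNG_CENTERS[side]
    ay, ax = _LUNG_AXES[0] * h, _LUNG_AXES[1] * w
    # shrink the ellipse so the whole disc fits
    ay_in, ax_in = ay - radius, ax - radius
    if ay_in <= 0 or ax_in <= 0:
        raise ValueError(
            f"lesion radius {radius} px cannot fit in a lung field of "
            f"semi-axes ({ay:.1f}, {ax:.1f}) px; use a smaller lesion_radius_px"
        )
    while True:
        u, v = rng.uniform(-1, 1, 2)
        if u * u + v * v <= 1.0:
            return cy * h + u * ay_in, cx * w + v * ax_in


def render_image(
    label: int, cfg: SynthConfig, rng: np.random.Generator
) -> tuple[np.ndarray, tuple[float, float]]:
    """One image and its attention-target centre (row, col), noise-free path
    kept separate so lesion amplitude scales cleanly with intensity."""
    shape = cfg.image_size
    h, w = shape
    img = _background(shape)
    if label == 0:
        img = img + _heart(shape)
        target = (_HEART_CENTER[0] * h, _HEART_CENTER[1] * w)
    elif label == 1:
        img = img + _heart(shape, cfg.chf_enlargement)
        target = (_HEART_CENTER[0] * h, _HEART_CENTER[1] * w)
    elif label == 2:
        img = img + _heart(shape)
        pos = _lesion_position(shape, cfg.lesion_radius_px, rng)
        rr = np.arange(h)[:, None] - pos[0]
        cc = np.arange(w)[None, :] - pos[1]
        disc = (rr**2 + cc**2) <= cfg.lesion_radius_px**2
        img = img + cfg.lesion_intensity * disc
        target = pos
    else:
        raise ValueError(f"label must be 0, 1 or 2, got {label}")
    noise = rng.normal(0.0, 1.0, shape)  # drawn regardless of noise_sd for
    img = img + cfg.noise_sd * noise     # intensity-/noise-invariant rng state
    return np.clip(img, 0.0, 1.0), target


def _simulate_fixations(
    target: tuple[float, float],
    cfg: SynthConfig,
    rng: np.random.Generator,
) -> list[dict]:
    """On-target fixations ~ N(target, sigma_gaze²), rest uniform."""
    h, w = cfg.image_size
    sigma_gaze = max(2.0, cfg.lesion_radius_px)
    rows = []
    t = 0.0
    for _ in range(cfg.fixations_per_image):
        on_target = rng.uniform() < cfg.gaze_on_target_frac
        if on_target:
            while True:
                y = rng.normal(target[0], sigma_gaze)
                x = rng.normal(target[1], sigma_gaze)
                if 0 <= x < w and 0 <= y < h:
                    break
        else:
            y = rng.uniform(0, h)
            x = rng.uniform(0, w)
        duration = float(np.exp(rng.normal(np.log(0.25), 0.4)))  # ~250 ms dwells
        rows.append({"x": x, "y": y, "t_start": t, "duration": duration})
        t += duration + float(rng.uniform(0.02, 0.08))  # saccade gap
    return rows


def _patient_blocks(cfg: SynthConfig) -> list[list[str]]:
    """Per class, contiguous blocks of image ids owned by one patient."""
    per_class = [cfg.n_patients // 3] * 3
    for i in range(cfg.n_patients % 3):
        per_class[i] += 1
    blocks = []
    for cls in range(3):
        ids = [f"img_{cls}_{i:04d}" for i in range(cfg.n_per_class)]
        n_p = per_class[cls]
        bounds = np.linspace(0, cfg.n_per_class, n_p + 1).astype(int)
        for p in range(n_p):
            blocks.append((cls, f"p{cls}_{p:03d}", ids[bounds[p]: bounds[p + 1]]))
    return blocks


def generate(cfg: SynthConfig, out_dir: str | Path) -> Path:
    """Write images/*.png, labels.csv, fixations.csv and manifest.json."""
    out = Path(out_dir)
    (out / "images").mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(cfg.seed)

    label_rows, fix_rows = [], []
    for cls, patient, image_ids in _patient_blocks(cfg):
        for image_id in image_ids:
            img, target = render_image(cls, cfg, rng)
            Image.fromarray(np.round(255 * img).astype(np.uint8), mode="L").save(
                out / "images" / f"{image_id}.png"
            )
            label_rows.append(
                {"image_id": image_id, "label": cls, "patient_id": patient}
            )
            for f in _simulate_fixations(target, cfg, rng):
                fix_rows.append({"image_id": image_id, **f})

    pd.DataFrame(label_rows).to_csv(out / "labels.csv", index=False)
    pd.DataFrame(
        fix_rows, columns=["image_id", "x", "y", "t_start", "duration"]
    ).to_csv(out / "fixations.csv", index=False)
    manifest = {"config": asdict(cfg), "seed": cfg.seed, "n_images": len(label_rows)}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return out


def difficulty_sweep(
    cfg: SynthConfig, intensities: list[float], out_root: str | Path
) -> list[Path]:
    """One dataset per lesion intensity, all else (and rng stream) fixed."""
    if any(i <= 0 for i in intensities) or list(intensities) != sorted(intensities):
        raise ValueError("intensities must be positive and ascending")
    dirs = []
    for inten in intensities:
        sub = Path(out_root) / f"intensity_{inten:g}"
        dirs.append(generate(replace(cfg, lesion_intensity=inten), sub))
    return dirs
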