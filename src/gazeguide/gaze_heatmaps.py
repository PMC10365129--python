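"""Eye-gaze fixation heatmaps.

Radiologist eye-tracking data arrives as discrete fixations — (x, y)
image coordinates with a dwell duration and onset time.  These are
turned into attention targets by placing an isotropic Gaussian at each
fixation, weighted by dwell duration (longer dwell = more attention,
the standard weighting in eye-tracking heatmaps).  *Temporal* maps bin
fixations into equal-duration time windows; the *static* map
accumulates the temporal maps into a single [0, 1] target used as the
ground truth of the decoder's segmentation loss.

Coordinates are 0-based with (row, col) = (y, x) and pixel centers at
integer coordinates.  Out-of-bounds fixations are dropped with a
warning rather than crashing: real gaze recordings contain alignment
errors.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

__all__ = [
    "Fixation",
    "GazeHeatmap",
    "fixation_to_temporal_maps",
    "temporal_to_static",
    "static_map_for",
    "read_fixations_csv",
    "save_heatmap_png",
    "save_heatmap_npz",
    "load_heatmap_npz",
]

logger = logging.getLogger(__name__)

TRUNCATE_SIGMAS = 4.0  # Gaussian support cut-off, in units of sigma


@dataclass(frozen=True)
class Fixation:
    """One gaze event: 0-based pixel position, dwell time, onset time."""

    x: float
    y: float
    duration: float
    t_start: float = 0.0

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("fixation duration must be > 0")
        if self.t_start < 0:
            raise ValueError("fixation t_start must be >= 0")


@dataclass
class GazeHeatmap:
    """A [0, 1] attention map the same size as its source image."""

    values: np.ndarray
    kind: str  # "temporal" | "static"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("heatmap must be 2-D")


def default_sigma(shape: tuple[int, int]) -> float:
    """Default Gaussian scale: image_width / 20 pixels."""
    return shape[1] / 20.0


def _max_normalize(grid: np.ndarray) -> np.ndarray:
    peak = grid.max()
    return grid / peak if peak > 0 else grid


def _add_gaussian(grid: np.ndarray, row: float, col: float, amp: float, sigma: float) -> None:
    """Accumulate a truncated isotropic Gaussian in place."""
    h, w = grid.shape
    r = TRUNCATE_SIGMAS * sigma
    r0, r1 = max(0, int(np.floor(row - r))), min(h, int(np.ceil(row + r)) + 1)
    c0, c1 = max(0, int(np.floor(col - r))), min(w, int(np.ceil(col + r)) + 1)
    if r0 >= r1 or c0 >= c1:
        return
    rr = np.arange(r0, r1)[:, None] - row
    cc = np.arange(c0, c1)[None, :] - col
    d2 = rr**2 + cc**2
    patch = amp * np.exp(-d2 / (2.0 * sigma**2))
    patch[d2 > r**2] = 0.0
    grid[r0:r1, c0:c1] += patch


def fixation_to_temporal_maps(
    fixations: list[Fixation],
    shape: tuple[int, int],
    sigma: float | None = None,
    n_windows: int = 1,
) -> list[GazeHeatmap]:
    """Bin fixations into equal time windows and render one map per window.

    Window ``w`` collects fixations whose ``t_start`` falls in the w-th
    equal-duration bin of [0, max t_start]; each fixation contributes a
    Gaussian of scale ``sigma`` with amplitude proportional to its
    duration.  Every map is max-normalized to [0, 1] (an all-zero map
    stays zero).
    """
    h, w = int(shape[0]), int(shape[1])
    if h <= 0 or w <= 0:
        raise ValueError("shape must be positive")
    if n_windows < 1:
        raise ValueError("n_windows must be >= 1")
    if sigma is None:
        sigma = default_sigma((h, w))
    if sigma <= 0:
        raise ValueError("sigma must be > 0")

    kept: list[Fixation] = []
    for i, f in enumerate(fixations):
        if 0 <= f.x < w and 0 <= f.y < h:
            kept.append(f)
        else:
            logger.warning(
                "dropping out-of-bounds fixation %d at (x=%.1f, y=%.1f) "
                "for %dx%d image",
                i, f.x, f.y, h, w,
            )

    grids = [np.zeros((h, w)) for _ in range(n_windows)]
    if kept:
        t_max = max(f.t_start for f in kept)
        bin_width = t_max / n_windows if t_max > 0 else np.inf
        for f in kept:
            idx = 0 if not np.isfinite(bin_width) else min(
                int(f.t_start / bin_width), n_windows - 1
            )
            _add_gaussian(grids[idx], f.y, f.x, f.duration, sigma)
    return [GazeHeatmap(_max_normalize(g), kind="temporal") for g in grids]


def temporal_to_static(maps: list[GazeHeatmap]) -> GazeHeatmap:
    """Accumulate temporal maps into one static map, re-normalized to [0,1].

    "Concatenation" of temporal attention into a static target is a
    pixelwise sum followed by max-normalization — a channel stack cannot
    serve as a 1-channel BCE target.
    """
    if not maps:
        raise ValueError("need at least one temporal map")
    shape = maps[0].values.shape
    for i, m in enumerate(maps):
        if m.values.shape != shape:
            raise ValueError(
                f"map {i} has shape {m.values.shape}, expected {shape}"
            )
    total = np.sum([m.values for m in maps], axis=0)
    return GazeHeatmap(_max_normalize(total), kind="static")


def static_map_for(
    fixations: list[Fixation],
    shape: tuple[int, int],
    sigma: float | None = None,
    n_windows: int = 1,
) -> GazeHeatmap:
    """Convenience: fixations → temporal maps → static map."""
    return temporal_to_static(
        fixation_to_temporal_maps(fixations, shape, sigma=sigma, n_windows=n_windows)
    )


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

FIXATION_COLUMNS = ("image_id", "x", "y", "t_start", "duration")


def read_fixations_csv(path: str | Path) -> dict[str, list[Fixation]]:
    """Read a fixation table (columns image_id,x,y,t_start,duration)."""
    df = pd.read_csv(path)
    missing = [c for c in FIXATION_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"fixation CSV {path} missing columns: {missing}")
    out: dict[str, list[Fixation]] = {}
    for row in df.itertuples(index=False):
        out.setdefault(str(row.image_id), []).append(
            Fixation(x=float(row.x), y=float(row.y),
                     duration=float(row.duration), t_start=float(row.t_start))
        )
    return out


def save_heatmap_png(hm: GazeHeatmap, path: str | Path) -> None:
    img = np.round(255.0 * np.clip(hm.values, 0.0, 1.0)).astype(np.uint8)
    Image.fromarray(img, mode="L").save(path)


def save_heatmap_npz(hm: GazeHeatmap, path: str | Path) -> None:
    with open(path, "wb") as fh:
        np.savez(fh, values=hm.values, kind=np.array(hm.kind))


def load_heatmap_npz(path: str | Path) -> GazeHeatmap:
    with np.load(path) as z:
        return GazeHeatmap(values=z["values"], kind=str(z["kind"]))
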