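"""AUC evaluation with bootstrap percentile CIs, and gaze alignment.

Classification quality is measured as one-vs-rest AUC per class
(Mann–Whitney: P(score_pos > score_neg) + ½ P(tie)).  Uncertainty
follows a bootstrap percentile protocol: each iteration resamples, with
replacement, a pool size drawn uniformly from a small range (55–60 by
default) from the held-out test set, computes the three one-vs-rest
AUCs and their mean, and the report gives the 50th / 2.5th / 97.5th
percentiles of each statistic across iterations.

``gaze_alignment`` quantifies how much of a map's absolute mass falls
inside the high-attention gaze region — the package's measurable proxy
for "the model looked where the radiologist looked".
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
from scipy.stats import rankdata

__all__ = [
    "AucReport",
    "AlignmentScore",
    "auc_ovr",
    "bootstrap_auc_ci",
    "gaze_alignment",
    "permutation_pvalue",
    "format_report_table",
    "save_panel_figure",
]

CLASS_NAMES = ("normal", "CHF", "pneumonia")


@dataclass
class AucReport:
    """Percentile triplets (p50, p2.5, p97.5) per class and averaged."""

    per_class: dict[str, tuple[float, float, float]]
    average: tuple[float, float, float]
    n_iterations: int
    resample_range: tuple[int, int]
    iterations: np.ndarray | None = None  # (n_iter, n_classes+1) raw statistics

    def to_json(self, path: str | Path | None = None) -> str:
        payload = asdict(self)
        payload.pop("iterations", None)  # summary only
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text


@dataclass
class AlignmentScore:
    mass_fraction: float
    record_id: str = ""


def auc_ovr(scores: np.ndarray, binary_labels: np.ndarray) -> float:
    """One-vs-rest AUC by the Mann–Whitney rank formulation."""
    s = np.asarray(scores, dtype=np.float64).ravel()
    y = np.asarray(binary_labels).ravel().astype(int)
    if s.shape != y.shape:
        raise ValueError("scores and labels must have the same length")
    n_pos = int(y.sum())
    n_neg = len(y) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present to compute AUC")
    ranks = rankdata(s)  # average ranks handle ties as ½
    return float((ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def _iteration_aucs(class_scores: np.ndarray, labels: np.ndarray) -> np.ndarray:
    return np.array(
        [auc_ovr(class_scores[:, k], labels == k) for k in range(class_scores.shape[1])]
    )


def bootstrap_auc_ci(
    class_scores: np.ndarray,
    labels: np.ndarray,
    n_iter: int = 30,
    resample_range: tuple[int, int] = (55, 60),
    seed: int = 0,
) -> AucReport:
    """Percentile bootstrap over resampled test pools.

    Each iteration draws m ~ U{resample_range} samples with replacement
    (redrawn until every class is present), computes per-class one-vs-rest
    AUCs and their mean; the report holds the 50/2.5/97.5 percentiles of
    each statistic across the ``n_iter`` iterations.
    """
    scores = np.asarray(class_scores, dtype=np.float64)
    y = np.asarray(labels).astype(int)
    n, n_cls = scores.shape
    lo, hi = resample_range
    if n < hi:
        raise ValueError(f"need at least {hi} samples in the pool, got {n}")
    present = np.unique(y)
    if len(present) < n_cls:
        raise ValueError(f"pool is missing classes: has only {present.tolist()}")

    rng = np.random.default_rng(seed)
    stats = np.empty((n_iter, n_cls + 1))
    for it in range(n_iter):
        while True:
            m = int(rng.integers(lo, hi + 1))
            idx = rng.choice(n, size=m, replace=True)
            if len(np.unique(y[idx])) == n_cls:
                break
        aucs = _iteration_aucs(scores[idx], y[idx])
        stats[it, :n_cls] = aucs
        stats[it, n_cls] = aucs.mean()

    def triplet(col: np.ndarray) -> tuple[float, float, float]:
        return (
            float(np.percentile(col, 50)),
            float(np.percentile(col, 2.5)),
            float(np.percentile(col, 97.5)),
        )

    per_class = {
        CLASS_NAMES[k] if k < len(CLASS_NAMES) else f"class{k}": triplet(stats[:, k])
        for k in range(n_cls)
    }
    return AucReport(
        per_class=per_class,
        average=triplet(stats[:, n_cls]),
        n_iterations=n_iter,
        resample_range=(int(lo), int(hi)),
        iterations=stats,
    )


def gaze_alignment(
    map_values: np.ndarray,
    gaze_values: np.ndarray,
    threshold: float = 0.75,
    record_id: str = "",
) -> AlignmentScore:
    """Fraction of the map's |mass| inside the gaze region.

    The region is the set of pixels where the gaze map is at or above
    its ``threshold``-quantile.  Invariant to positive rescaling of the
    map; an identically-zero map scores 0.
    """
    m = np.abs(np.asarray(map_values, dtype=np.float64))
    g = np.asarray(gaze_values, dtype=np.float64)
    if m.shape != g.shape:
        raise ValueError(f"shape mismatch: map {m.shape} vs gaze {g.shape}")
    total = m.sum()
    if total == 0:
        return AlignmentScore(0.0, record_id)
    region = g >= np.quantile(g, threshold)
    return AlignmentScore(float(m[region].sum() / total), record_id)


def permutation_pvalue(
    iter_aucs_a: np.ndarray, iter_aucs_b: np.ndarray, n_perm: int = 10000, seed: int = 0
) -> float:
    """Two-sided permutation test on mean iteration-AUC difference.

    Provided for model comparison only; this is NOT the (unstated)
    significance test used alongside published AUC tables.
    """
    a = np.asarray(iter_aucs_a, dtype=np.float64)
    b = np.asarray(iter_aucs_b, dtype=np.float64)
    obs = abs(a.mean() - b.mean())
    pooled = np.concatenate([a, b])
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(pooled)
        count += abs(perm[: len(a)].mean() - perm[len(a):].mean()) >= obs
    return float((count + 1) / (n_perm + 1))


def format_report_table(reports: dict[str, AucReport]) -> str:
    """Rows of 'p50 (p2.5, p97.5)' per model, like published AUC tables."""
    cols = ["Average"] + list(CLASS_NAMES)
    lines = ["\t".join(["Model"] + cols)]
    for name, rep in reports.items():
        cells = [rep.average] + [rep.per_class[c] for c in CLASS_NAMES]
        lines.append(
            "\t".join(
                [name] + [f"{p50:.3f} ({p025:.3f}, {p975:.3f})" for p50, p025, p975 in cells]
            )
        )
    return "\n".join(lines)


def save_panel_figure(
    panels: dict[str, np.ndarray], path: str | Path, title: str = ""
) -> None:
    """Side-by-side grayscale panels (input | grad-CAM | derived | gaze | decoder)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, len(panels), figsize=(3 * len(panels), 3.2))
    if len(panels) == 1:
        axes = [axes]
    for ax, (name, img) in zip(axes, panels.items()):
        ax.imshow(img, cmap="inferno" if name != "input" else "gray")
        ax.set_title(name, fontsize=9)
        ax.axis("off")
    if title:
        fig.suptitle(title, fontsize=10)
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)
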