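"""Mesoscale tissue-boundary triage: intensity recipe, ROC, coordinate maps.

Before high-resolution imaging, the tissue is covered by a grid of
low-resolution pre-scan tiles; tiles without tissue signal are dropped
so that only informative positions are re-imaged.  The intensity-based
classifier works on each tile's axial MIP: smooth with 20x20 and 40x40
uniform (box) filters, subtract to remove background, and score the
tile by the percentage of pixels in the difference image above an
absolute threshold of 2.5 counts.  Tiles scoring below 0.1% are
non-informative.

The box filters here are computed with integral images on the
integer-valued count image, so window sums are exact in float64 and the
score is bit-for-bit reproducible by any summation order — a property a
recursive moving-sum filter does not guarantee.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from sklearn.metrics import roc_curve as _sk_roc_curve

__all__ = [
    "TriageParams",
    "TriageResult",
    "RocResult",
    "box_mean",
    "intensity_score",
    "classify_intensity",
    "roc",
    "coordinate_map",
]


@dataclass(frozen=True)
class TriageParams:
    """Intensity-recipe parameters.

    ``informative_cutoff`` is a percentage: tiles with
    score >= cutoff are informative, score < cutoff non-informative.
    """

    kernel_small: int = 20
    kernel_large: int = 40
    intensity_threshold: float = 2.5
    informative_cutoff: float = 0.1

    def __post_init__(self) -> None:
        if not (0 < self.kernel_small < self.kernel_large):
            raise ValueError("need 0 < kernel_small < kernel_large")
        if not (0 < self.informative_cutoff < 100):
            raise ValueError("cutoff must be a percentage in (0, 100)")


@dataclass(frozen=True)
class TriageResult:
    tile_id: int
    score: float  # percent (intensity path) or probability (CNN path)
    label: str  # "informative" | "non-informative"


@dataclass(frozen=True)
class RocResult:
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc: float


def box_mean(image: np.ndarray, size: int) -> np.ndarray:
    """Uniform (box) filter mean with symmetric edge padding.

    For even ``size`` the window anchored at output pixel i covers
    input rows/cols [i - size//2, i + size//2 - 1]: the kernel origin is
    offset toward the lower index.  Window *sums* are computed on an
    integral image; for integer-valued input they are exact in float64
    (magnitudes stay far below 2**53), making the result independent of
    summation order.
    """
    if image.ndim != 2:
        raise ValueError("box_mean expects a 2D image")
    h, w = image.shape
    if size > h or size > w:
        raise ValueError(f"kernel {size} larger than image {image.shape}")
    lo = size // 2
    hi = size - 1 - lo
    padded = np.pad(np.asarray(image, dtype=np.float64), ((lo, hi), (lo, hi)),
                    mode="symmetric")
    ii = np.zeros((padded.shape[0] + 1, padded.shape[1] + 1))
    np.cumsum(padded, axis=0, out=ii[1:, 1:])
    np.cumsum(ii[1:, 1:], axis=1, out=ii[1:, 1:])
    s = (
        ii[size : size + h, size : size + w]
        - ii[0:h, size : size + w]
        - ii[size : size + h, 0:w]
        + ii[0:h, 0:w]
    )
    return s / float(size * size)


def intensity_score(tile: np.ndarray, params: TriageParams = TriageParams()) -> float:
    """Percent of MIP pixels whose difference-of-box-means exceeds threshold.

    Accepts a 3D tile (axial MIP is taken along axis 0) or a 2D MIP
    directly.  Score = 100 * #(smooth_small - smooth_large > threshold)
    / total pixels.  Adding a constant to every pixel leaves the score
    unchanged (box means have unit DC gain under symmetric padding);
    multiplying intensities does change it (absolute threshold).
    """
    tile = np.asarray(tile)
    if tile.ndim == 3:
        tile = tile.max(axis=0)
    if tile.ndim != 2:
        raise ValueError("tile must be a 3D stack or 2D MIP")
    if min(tile.shape) < params.kernel_large:
        raise ValueError(
            f"tile {tile.shape} smaller than the large kernel "
            f"({params.kernel_large})"
        )
    diff = box_mean(tile, params.kernel_small) - box_mean(tile, params.kernel_large)
    frac = np.count_nonzero(diff > params.intensity_threshold) / diff.size
    return 100.0 * frac


def classify_intensity(
    tiles: Iterable[np.ndarray], params: TriageParams = TriageParams()
) -> list[TriageResult]:
    """Label each tile informative iff its intensity score >= cutoff."""
    results = []
    for i, tile in enumerate(tiles):
        score = intensity_score(tile, params)
        label = "informative" if score >= params.informative_cutoff else "non-informative"
        results.append(TriageResult(tile_id=i, score=score, label=label))
    return results


def roc(labels: Sequence[int], scores: Sequence[float]) -> RocResult:
    """ROC curve by threshold sweep and AUC by the trapezoid rule."""
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    if len(np.unique(labels)) < 2:
        raise ValueError("ROC needs both classes present")
    fpr, tpr, thr = _sk_roc_curve(labels, scores)
    auc = float(np.trapezoid(tpr, fpr))
    return RocResult(fpr=fpr, tpr=tpr, thresholds=thr, auc=auc)


def coordinate_map(
    tile_grid: Sequence[tuple[float, float, float]],
    results: Sequence[TriageResult],
    path=None,
):
    """Stage positions of informative tiles, in acquisition order.

    ``tile_grid`` is a sequence of (x, y, z) starts, one per triage
    result (same order).  Optionally written as CSV with columns
    tile_id, x_um, y_um, z_um.
    """
    import pandas as pd

    if len(tile_grid) != len(results):
        raise ValueError(
            f"{len(tile_grid)} grid positions but {len(results)} triage results"
        )
    rows = [
        {"tile_id": r.tile_id, "x_um": p[0], "y_um": p[1], "z_um": p[2]}
        for p, r in zip(tile_grid, results)
        if r.label == "informative"
    ]
    frame = pd.DataFrame(rows, columns=["tile_id", "x_um", "y_um", "z_um"])
    if path is not None:
        frame.to_csv(path, index=False)
    return frame
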