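"""Evaluation metrics for voxel reconstructions and point clouds.

Voxel metrics binarize the predicted occupancy probabilities with a strict
threshold (occupied iff p > t) and compare against a binary ground truth:

* IoU  = |pred AND truth| / |pred OR truth|
* F1   = Dice overlap 2 TP / (2 TP + FP + FN)

Both are defined as 1 when prediction and truth are empty.  MAE/MSE/RMSE are
the usual elementwise error means.  Point-cloud metrics:

* Chamfer distance: sum over both directions of squared nearest-neighbour
  distances (unnormalized, plus a per-point-normalized companion value).
* Earth Mover's Distance: the exact optimal one-to-one assignment cost under
  Euclidean point distance (Hungarian algorithm); clouds of unequal size are
  reduced by seeded uniform subsampling of the larger cloud, flagged in the
  result.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
from scipy.optimize import linear_sum_assignment
from scipy.spatial import cKDTree
from scipy.spatial.distance import cdist

from .voxel_io import VoxelGrid, voxel_centers

__all__ = [
    "MetricReport",
    "voxel_iou",
    "voxel_f1",
    "mae",
    "mse",
    "rmse",
    "chamfer",
    "emd",
    "occupied_centers",
    "evaluate_grids",
]


def _binarize(p: np.ndarray, t: float) -> np.ndarray:
    return np.asarray(p) > t


def _check_pair(p, y):
    p = np.asarray(p, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if p.shape != y.shape:
        raise ValueError(f"shape mismatch: {p.shape} vs {y.shape}")
    return p, y


def voxel_iou(p, y, t: float = 0.5) -> float:
    """Intersection over union of thresholded prediction and binary truth."""
    p, y = _check_pair(p, y)
    pb = _binarize(p, t)
    yb = y > 0.5
    union = int(np.sum(pb | yb))
    if union == 0:
        return 1.0
    return float(np.sum(pb & yb)) / union


def voxel_f1(p, y, t: float = 0.5) -> float:
    """Dice overlap of thresholded prediction and binary truth."""
    p, y = _check_pair(p, y)
    pb = _binarize(p, t)
    yb = y > 0.5
    tp = int(np.sum(pb & yb))
    fp = int(np.sum(pb & ~yb))
    fn = int(np.sum(~pb & yb))
    if tp + fp + fn == 0:
        return 1.0
    return 2.0 * tp / (2.0 * tp + fp + fn)


def _check_vectors(y, y_hat):
    y = np.asarray(y, dtype=np.float64).reshape(-1)
    y_hat = np.asarray(y_hat, dtype=np.float64).reshape(-1)
    if y.shape != y_hat.shape:
        raise ValueError("length mismatch")
    if y.size == 0:
        raise ValueError("empty vectors")
    return y, y_hat


def mae(y, y_hat) -> float:
    y, y_hat = _check_vectors(y, y_hat)
    return float(np.mean(np.abs(y - y_hat)))


def mse(y, y_hat) -> float:
    y, y_hat = _check_vectors(y, y_hat)
    return float(np.mean((y - y_hat) ** 2))


def rmse(y, y_hat) -> float:
    return float(np.sqrt(mse(y, y_hat)))


def chamfer(x_pred, x_true, normalized: bool = False) -> float:
    """Two-sided sum of squared nearest-neighbour distances.

    With ``normalized=True`` each directional sum is divided by its cloud
    size before adding.
    """
    x_pred = np.asarray(x_pred, dtype=np.float64).reshape(-1, 3)
    x_true = np.asarray(x_true, dtype=np.float64).reshape(-1, 3)
    if len(x_pred) == 0 or len(x_true) == 0:
        raise ValueError("chamfer distance requires non-empty clouds")
    d_pt, _ = cKDTree(x_true).query(x_pred)
    d_tp, _ = cKDTree(x_pred).query(x_true)
    a = float(np.sum(d_pt**2))
    b = float(np.sum(d_tp**2))
    if normalized:
        return a / len(x_pred) + b / len(x_true)
    return a + b


def emd(x_pred, x_true, normalized: bool = False, seed: int = 0):
    """Exact one-to-one assignment cost with Euclidean point distances.

    For equal-size clouds this is the optimal-assignment minimum of
    ``sum ||p - phi(p)||``.  Unequal sizes are handled by seeded uniform
    subsampling of the larger cloud down to the smaller; the returned
    ``subsampled`` flag records when that happened.

    Returns ``(value, subsampled)``; with ``normalized=True`` the value is
    divided by the number of assigned pairs.
    """
    x_pred = np.asarray(x_pred, dtype=np.float64).reshape(-1, 3)
    x_true = np.asarray(x_true, dtype=np.float64).reshape(-1, 3)
    if len(x_pred) == 0 or len(x_true) == 0:
        raise ValueError("EMD requires non-empty clouds")
    subsampled = False
    if len(x_pred) != len(x_true):
        subsampled = True
        rng = np.random.default_rng(seed)
        m = min(len(x_pred), len(x_true))
        if len(x_pred) > m:
            x_pred = x_pred[rng.choice(len(x_pred), size=m, replace=False)]
        else:
            x_true = x_true[rng.choice(len(x_true), size=m, replace=False)]
    cost = cdist(x_pred, x_true)
    rows, cols = linear_sum_assignment(cost)
    value = float(cost[rows, cols].sum())
    if normalized:
        value /= len(rows)
    return value, subsampled


def occupied_centers(grid: VoxelGrid, t: float = 0.5) -> np.ndarray:
    """Model-space centers of cells with occupancy strictly above ``t``."""
    centers = voxel_centers(grid.resolution, grid.translate, grid.scale)
    mask = grid.occupancy > t
    return centers[mask].reshape(-1, 3)


@dataclass
class MetricReport:
    """All scalar metrics for one prediction/truth pair."""

    iou: float
    f1: float
    mae: float
    mse: float
    rmse: float
    chamfer: float
    chamfer_normalized: float
    emd: float
    emd_normalized: float
    emd_subsampled: bool
    threshold: float

    def as_dict(self) -> dict:
        return asdict(self)


def evaluate_grids(pred: VoxelGrid, truth: VoxelGrid, t: float = 0.5,
                   seed: int = 0) -> MetricReport:
    """Compute the full report for a predicted grid against ground truth.

    MAE/MSE/RMSE compare raw occupancy values voxelwise; the point-cloud
    metrics run on occupied-cell centers in model coordinates.  When either
    binarized grid is empty the point-cloud metrics are reported as NaN.
    """
    if pred.resolution != truth.resolution:
        raise ValueError("prediction and truth resolutions differ")
    p, y = pred.occupancy, truth.occupancy
    cloud_p = occupied_centers(pred, t)
    cloud_y = occupied_centers(truth, 0.5)
    if len(cloud_p) and len(cloud_y):
        cd = chamfer(cloud_p, cloud_y)
        cdn = chamfer(cloud_p, cloud_y, normalized=True)
        emd_raw, sub = emd(cloud_p, cloud_y, seed=seed)
        emd_norm, _ = emd(cloud_p, cloud_y, normalized=True, seed=seed)
    else:
        cd = cdn = emd_raw = emd_norm = float("nan")
        sub = False
    return MetricReport(
        iou=voxel_iou(p, y, t),
        f1=voxel_f1(p, y, t),
        mae=mae(y, p),
        mse=mse(y, p),
        rmse=rmse(y, p),
        chamfer=cd,
        chamfer_normalized=cdn,
        emd=emd_raw,
        emd_normalized=emd_norm,
        emd_subsampled=sub,
        threshold=t,
    )
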