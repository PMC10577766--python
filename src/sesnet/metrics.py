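"""Surface and field agreement metrics: Chamfer Distance, F-score, R², MAE.

Chamfer Distance is the symmetric mean of nearest-neighbor Euclidean distances
between two point clouds (Å; lower is better). The F-score at hit radius r is
the harmonic mean of precision (fraction of predicted points with a reference
point within r) and recall (the converse); 1 is perfect, 0 is disjoint beyond
r. R² and MAE grade the raw level-set regression on the grid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree
from sklearn.metrics import mean_absolute_error, r2_score

from .oracle import LevelSetField
from .surface import SurfacePointCloud, extract_surface

__all__ = [
    "MetricsReport",
    "chamfer",
    "fscore",
    "r_squared",
    "mae",
    "evaluate",
]

DEFAULT_F_RADIUS = 0.15  # Å


@dataclass(frozen=True)
class MetricsReport:
    cd: float
    f: float
    pr: float
    rc: float
    f_radius: float
    r2: float | None = None
    mae: float | None = None

    def as_dict(self) -> dict:
        return {
            "cd": self.cd,
            "f": self.f,
            "pr": self.pr,
            "rc": self.rc,
            "radius": self.f_radius,
            "r2": self.r2,
            "mae": self.mae,
        }


def _points(cloud) -> np.ndarray:
    if isinstance(cloud, SurfacePointCloud):
        return cloud.points
    return np.asarray(cloud, dtype=float).reshape(-1, 3)


def _nn_dists(a: np.ndarray, b: np.ndarray, method: str) -> np.ndarray:
    """For each point of ``a``, distance to its nearest neighbor in ``b``."""
    if method == "kdtree":
        dist, _ = cKDTree(b).query(a)
        return dist
    if method == "brute":
        return np.sqrt(
            ((a[:, None, :] - b[None, :, :]) ** 2).sum(axis=2)
        ).min(axis=1)
    raise ValueError(f"unknown method {method!r}")


def chamfer(pred, ref, method: str = "kdtree") -> float:
    """Symmetric-mean Chamfer Distance between two non-empty point clouds (Å)."""
    a = _points(pred)
    b = _points(ref)
    if a.shape[0] == 0 or b.shape[0] == 0:
        raise ValueError("Chamfer Distance requires non-empty point clouds")
    return 0.5 * (
        float(np.mean(_nn_dists(a, b, method))) + float(np.mean(_nn_dists(b, a, method)))
    )


def fscore(pred, ref, r: float = DEFAULT_F_RADIUS, method: str = "kdtree"):
    """(f, pr, rc) at hit radius ``r``; the 0/0 case yields f = 0."""
    if not r > 0:
        raise ValueError(f"hit radius must be positive, got {r}")
    a = _points(pred)
    b = _points(ref)
    if a.shape[0] == 0 or b.shape[0] == 0:
        raise ValueError("F-score requires non-empty point clouds")
    pr = float(np.mean(_nn_dists(a, b, method) <= r))
    rc = float(np.mean(_nn_dists(b, a, method) <= r))
    f = 0.0 if pr + rc == 0 else 2.0 * pr * rc / (pr + rc)
    return f, pr, rc


def r_squared(y_true, y_pred) -> float:
    """Coefficient of determination R² = 1 − SS_res / SS_tot."""
    y_true = np.asarray(y_true, dtype=float).ravel()
    y_pred = np.asarray(y_pred, dtype=float).ravel()
    if y_true.size == 0 or y_true.size != y_pred.size:
        raise ValueError("inputs must be equal-length and non-empty")
    if np.var(y_true) == 0:
        raise ValueError("R² undefined for zero-variance ground truth")
    return float(r2_score(y_true, y_pred))


def mae(y_true, y_pred) -> float:
    """Mean absolute error."""
    y_true = np.asarray(y_true, dtype=float).ravel()
    y_pred = np.asarray(y_pred, dtype=float).ravel()
    if y_true.size == 0 or y_true.size != y_pred.size:
        raise ValueError("inputs must be equal-length and non-empty")
    return float(mean_absolute_error(y_true, y_pred))


def evaluate(
    pred_field: LevelSetField,
    ref_field: LevelSetField,
    f_radius: float | str = "auto",
) -> MetricsReport:
    """Full surface + field comparison of two level-set fields on one grid.

    Extracts both zero-crossing surfaces, computes CD and F at ``f_radius``
    (``"auto"`` → 0.15 Å), and grades the raw values with R² and MAE.
    """
    ga, gb = pred_field.grid, ref_field.grid
    if (
        ga.dims != gb.dims
        or not np.allclose(ga.origin, gb.origin)
        or not np.isclose(ga.spacing, gb.spacing)
    ):
        raise ValueError("fields must share one grid")
    radius = DEFAULT_F_RADIUS if f_radius == "auto" else float(f_radius)
    pred_surf = extract_surface(pred_field)
    ref_surf = extract_surface(ref_field)
    cd = chamfer(pred_surf, ref_surf)
    f, pr, rc = fscore(pred_surf, ref_surf, radius)
    return MetricsReport(
        cd=cd,
        f=f,
        pr=pr,
        rc=rc,
        f_radius=radius,
        r2=r_squared(ref_field.flat, pred_field.flat),
        mae=mae(ref_field.flat, pred_field.flat),
    )
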