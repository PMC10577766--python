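"""Per-grid-point features from the k nearest atoms.

Each queried point g is described by its k nearest atom neighborhoods: slot j
holds the relative displacement d_j = a_j - g (Å) and the atom radius r_j, so a
row is (d_x, d_y, d_z, r) × k with slots ordered by non-decreasing |d| and
zero-padded when fewer than k atoms exist. With the default k = 24 the feature
dimension is 96. Relative displacements make the representation translation
invariant and independent of the grid spacing, which is what lets one trained
model transfer across lattice resolutions.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .molecules import MoleculePointCloud
from .oracle import LevelSetField

__all__ = [
    "FeatureMatrix",
    "extract_features",
    "feature_dataset",
    "save_dataset",
    "load_dataset",
]

LAYOUT = "slots sorted by |d| ascending; slot j = (d_x, d_y, d_z, r_j); zero-padded"


@dataclass(frozen=True)
class FeatureMatrix:
    """Feature rows for a batch of query points; ``rows.shape == (n, 4*k)``."""

    rows: np.ndarray
    k: int
    layout: str = LAYOUT

    def __post_init__(self) -> None:
        rows = np.asarray(self.rows, dtype=float)
        if rows.ndim != 2 or rows.shape[1] != 4 * self.k:
            raise ValueError(f"rows must have shape (n, {4 * self.k}), got {rows.shape}")
        object.__setattr__(self, "rows", rows)

    @property
    def d(self) -> int:
        return 4 * self.k


def extract_features(
    points,
    mol: MoleculePointCloud,
    k: int = 24,
    cutoff: float | None = None,
) -> FeatureMatrix:
    """Build the (n, 4k) feature matrix for query ``points``.

    Neighbors are the k nearest atoms (ties broken by atom index); if
    ``cutoff`` is given, atoms beyond that distance are dropped and their
    slots zero-padded instead.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if mol.n_atoms < 1:
        raise ValueError("molecule has no atoms")
    points = np.atleast_2d(np.asarray(points, dtype=float))
    if points.shape[1] != 3 or not np.all(np.isfinite(points)):
        raise ValueError("points must be finite 3-vectors")

    centers = mol.centers
    radii = mol.radii
    kk = min(k, mol.n_atoms)
    tree = cKDTree(centers)
    dist, idx = tree.query(points, k=kk)
    if kk == 1:
        dist = dist[:, None]
        idx = idx[:, None]
    # deterministic tie-break: sort each row by (distance, atom index)
    order = np.lexsort((idx, dist), axis=1)
    dist = np.take_along_axis(dist, order, axis=1)
    idx = np.take_along_axis(idx, order, axis=1)

    disp = centers[idx] - points[:, None, :]          # (n, kk, 3)
    slot_r = radii[idx]                               # (n, kk)
    if cutoff is not None:
        keep = dist <= cutoff
        disp = np.where(keep[:, :, None], disp, 0.0)
        slot_r = np.where(keep, slot_r, 0.0)

    n = points.shape[0]
    slots = np.zeros((n, k, 4))
    slots[:, :kk, :3] = disp
    slots[:, :kk, 3] = slot_r
    return FeatureMatrix(slots.reshape(n, 4 * k), k=k)


def feature_dataset(
    field: LevelSetField,
    mol: MoleculePointCloud,
    k: int = 24,
    subsample: float | int | None = None,
    seed: int = 0,
    balanced: bool = False,
    cutoff: float | None = None,
) -> tuple[FeatureMatrix, np.ndarray]:
    """Assemble aligned (features, level-set targets) pairs from a labeled grid.

    ``subsample`` is either a fraction in (0, 1], an absolute count, or None
    (all grid points). With ``balanced=True`` the sample is drawn in equal
    parts from three strata — interior points at the clamp floor, the
    near-surface band (|y| below the clamp, where the zero crossing lives),
    and far exterior points at the clamp ceiling — topping up from the other
    strata when one runs out. Uniform sampling would drown the thin surface
    band under the vastly more numerous far-field points.
    """
    grid = field.grid
    y = field.flat
    n_total = y.size
    if subsample is None or subsample == 1.0:
        sel = np.arange(n_total)
    else:
        n_want = int(round(subsample * n_total)) if isinstance(subsample, float) else int(subsample)
        if n_want < 1 or n_want > n_total:
            raise ValueError(f"subsample {subsample} out of range for {n_total} grid points")
        rng = np.random.default_rng(seed)
        if balanced:
            clamp = np.abs(y).max()
            strata = [
                np.flatnonzero(y <= -clamp),            # deep interior
                np.flatnonzero(np.abs(y) < clamp),      # near-surface band
                np.flatnonzero(y >= clamp),             # far exterior
            ]
            quota = [n_want // 3, n_want // 3, n_want - 2 * (n_want // 3)]
            # grant each stratum its quota; redistribute the shortfall
            take = [min(q, s.size) for q, s in zip(quota, strata)]
            shortfall = n_want - sum(take)
            for i in np.argsort([-(s.size) for s in strata]):
                extra = min(shortfall, strata[i].size - take[i])
                take[i] += extra
                shortfall -= extra
            sel = np.concatenate(
                [rng.choice(s, size=t, replace=False) for s, t in zip(strata, take) if t]
            )
            sel.sort()
        else:
            sel = np.sort(rng.choice(n_total, size=n_want, replace=False))
    points = grid.points()[sel]
    feats = extract_features(points, mol, k=k, cutoff=cutoff)
    return feats, y[sel]


def save_dataset(path, feats: FeatureMatrix, targets: np.ndarray, **metadata) -> None:
    """Serialize a training dataset to an .npz container with JSON metadata."""
    meta = dict(metadata)
    meta["k"] = feats.k
    meta["layout"] = feats.layout
    np.savez_compressed(
        path, features=feats.rows, targets=np.asarray(targets), meta=json.dumps(meta)
    )


def load_dataset(path) -> tuple[FeatureMatrix, np.ndarray, dict]:
    with np.load(path, allow_pickle=False) as npz:
        meta = json.loads(str(npz["meta"]))
        feats = FeatureMatrix(npz["features"], k=int(meta["k"]))
        targets = npz["targets"]
    return feats, targets, meta
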