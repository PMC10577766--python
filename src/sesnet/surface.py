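"""Surface extraction at the zero level set.

The surface ∂Ω is sampled where the level-set field changes sign: on every
axis-aligned grid edge whose endpoint values straddle zero, the linear
interpolant crosses at g_a + y_a/(y_a - y_b) · (g_b - g_a). Grid points with an
exactly zero value are themselves surface samples (emitted once). The result
is a point cloud, which is what the Chamfer/F-score metrics consume.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .oracle import LevelSetField

__all__ = [
    "SurfacePointCloud",
    "extract_surface",
    "write_surface",
    "read_surface",
]


@dataclass(frozen=True)
class SurfacePointCloud:
    """A finite set of surface samples (M, 3) in Å."""

    points: np.ndarray
    provenance: str = ""

    def __post_init__(self) -> None:
        points = np.asarray(self.points, dtype=float).reshape(-1, 3)
        object.__setattr__(self, "points", points)

    @property
    def n_points(self) -> int:
        return self.points.shape[0]

    def translated(self, shift) -> "SurfacePointCloud":
        return SurfacePointCloud(self.points + np.asarray(shift, dtype=float), self.provenance)


def extract_surface(field: LevelSetField, dedup_tol: float = 1e-9) -> SurfacePointCloud:
    """Linear-interpolation zero crossings of the field along grid edges.

    A field with no sign change yields an empty cloud and a warning (a molecule
    entirely between grid points, or an all-positive far-field).
    """
    vals = field.values
    grid = field.grid
    s = grid.spacing
    pieces = []

    # exact zeros are surface samples
    zero_idx = np.argwhere(vals == 0.0)
    if zero_idx.size:
        pieces.append(grid.origin + s * zero_idx)

    for axis in range(3):
        sl_a = [slice(None)] * 3
        sl_b = [slice(None)] * 3
        sl_a[axis] = slice(0, -1)
        sl_b[axis] = slice(1, None)
        a = vals[tuple(sl_a)]
        b = vals[tuple(sl_b)]
        crossing = (a * b) < 0  # strictly opposite signs; zeros handled above
        if not crossing.any():
            continue
        idx = np.argwhere(crossing)
        ya = a[crossing]
        yb = b[crossing]
        t = ya / (ya - yb)
        coords = grid.origin + s * idx.astype(float)
        coords[:, axis] += t * s
        pieces.append(coords)

    if not pieces:
        warnings.warn("level-set field has no zero crossing; surface is empty", stacklevel=2)
        return SurfacePointCloud(np.empty((0, 3)), provenance="empty")

    points = np.vstack(pieces)
    # deduplicate within tolerance (zero-valued grid points touch 6 edges)
    quant = np.round(points / dedup_tol).astype(np.int64)
    _, keep = np.unique(quant, axis=0, return_index=True)
    return SurfacePointCloud(points[np.sort(keep)], provenance="level-set zero crossing")


def write_surface(cloud: SurfacePointCloud, path, format: str | None = None) -> None:
    """Write a point cloud as XYZ (count header + coordinate lines) or ASCII PLY."""
    path_str = str(path)
    if format is None:
        format = path_str.rsplit(".", 1)[-1].lower()
    format = format.lower()
    pts = cloud.points
    if format == "xyz":
        with open(path, "w") as fh:
            fh.write(f"{cloud.n_points}\n")
            for p in pts:
                fh.write(f"{p[0]:.6f} {p[1]:.6f} {p[2]:.6f}\n")
    elif format == "ply":
        with open(path, "w") as fh:
            fh.write("ply\nformat ascii 1.0\n")
            fh.write(f"element vertex {cloud.n_points}\n")
            fh.write("property float x\nproperty float y\nproperty float z\n")
            fh.write("end_header\n")
            for p in pts:
                fh.write(f"{p[0]:.6f} {p[1]:.6f} {p[2]:.6f}\n")
    else:
        raise ValueError(f"unknown surface format {format!r} (expected 'xyz' or 'ply')")


def read_surface(path, format: str | None = None) -> SurfacePointCloud:
    path_str = str(path)
    if format is None:
        format = path_str.rsplit(".", 1)[-1].lower()
    format = format.lower()
    with open(path) as fh:
        lines = [ln.strip() for ln in fh if ln.strip()]
    try:
        if format == "xyz":
            n = int(lines[0])
            pts = [[float(t) for t in ln.split()[:3]] for ln in lines[1 : 1 + n]]
        elif format == "ply":
            if not lines or lines[0] != "ply":
                raise ValueError("missing ply magic")
            n = None
            for i, ln in enumerate(lines):
                if ln.startswith("element vertex"):
                    n = int(ln.split()[-1])
                if ln == "end_header":
                    body = lines[i + 1 :]
                    break
            else:
                raise ValueError("no end_header")
            if n is None:
                raise ValueError("no vertex element")
            pts = [[float(t) for t in ln.split()[:3]] for ln in body[:n]]
        else:
            raise ValueError(f"unknown surface format {format!r}")
        if len(pts) != n:
            raise ValueError(f"expected {n} points, found {len(pts)}")
    except (ValueError, IndexError) as exc:
        raise ValueError(f"cannot parse surface file {path}: {exc}") from exc
    return SurfacePointCloud(np.array(pts, dtype=float).reshape(-1, 3), provenance=path_str)
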