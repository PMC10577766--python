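"""Ground-truth signed level-set fields for the solvent-excluded surface (SES).

The SES is the boundary of the solute region a spherical solvent probe
(conventionally 1.4 Å for water) cannot reach while rolling over the van der
Waals spheres. On a grid it is recovered with the classic two-pass
classification:

1. a grid point is SAS-interior iff its distance to some atom center is
   below ``r_atom + r_probe`` (the probe *center* cannot sit there);
2. a SAS-interior point is re-classified exterior iff it lies within the probe
   radius of some SAS-exterior grid point — the probe, centered at an
   accessible position, re-enters and carves out the reentrant volume.

Remaining SAS-interior points form the SES interior Ω⁻. The level-set value is
the signed Euclidean distance to the opposite region, positive outside,
negative inside, clamped to ±``clamp`` so regression targets are bounded.
Distances (including the pass-2 probe test) are computed on the lattice with
Euclidean distance transforms; the approximation error is O(spacing).

Because that error is tied to the labeling lattice, a field labeled directly
at a coarse spacing carries lattice-phase noise of order half a voxel, and
zero-crossing surfaces extracted at different spacings would not agree with
each other. ``label_level_set`` therefore accepts an internal ``resolution``:
the classification runs once on a fine lattice and the result is trilinearly
resampled onto the requested grid, so every evaluation grid samples one and
the same underlying surface.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage

from .molecules import Grid, MoleculePointCloud

__all__ = [
    "ProbeParams",
    "LevelSetField",
    "CoverageError",
    "label_level_set",
    "resample_field",
    "analytic_sphere_field",
    "write_field",
    "read_field",
]


class CoverageError(ValueError):
    """The grid box does not cover the molecule plus the probe shell."""


@dataclass(frozen=True)
class ProbeParams:
    """Solvent probe: a sphere of ``probe_radius`` Å (default 1.4, water)."""

    probe_radius: float = 1.4

    def __post_init__(self) -> None:
        if not self.probe_radius > 0:
            raise ValueError(f"probe radius must be positive, got {self.probe_radius}")


@dataclass(frozen=True)
class LevelSetField:
    """Scalar level-set values on a grid: positive outside, negative inside.

    ``values`` has shape ``grid.dims``; ``values.ravel()`` aligns with
    ``grid.points()``.
    """

    grid: Grid
    values: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.shape != tuple(self.grid.dims):
            raise ValueError(
                f"values shape {values.shape} does not match grid dims {self.grid.dims}"
            )
        if not np.all(np.isfinite(values)):
            raise ValueError("level-set values must be finite")
        object.__setattr__(self, "values", values)

    @property
    def flat(self) -> np.ndarray:
        return self.values.ravel()


def _sas_interior_mask(mol: MoleculePointCloud, grid: Grid, probe_radius: float) -> np.ndarray:
    """Mark grid points whose distance to some atom center is < r_atom + probe."""
    dims = np.array(grid.dims)
    mask = np.zeros(grid.dims, dtype=bool)
    s = grid.spacing
    for center, radius in zip(mol.centers, mol.radii):
        reach = radius + probe_radius
        lo_idx = np.maximum(np.ceil((center - reach - grid.origin) / s - 1e-12), 0).astype(int)
        hi_idx = np.minimum(np.floor((center - grid.origin + reach) / s + 1e-12), dims - 1).astype(int)
        if np.any(lo_idx > hi_idx):
            continue
        axes = [
            grid.origin[d] + s * np.arange(lo_idx[d], hi_idx[d] + 1) - center[d]
            for d in range(3)
        ]
        d2 = (
            axes[0][:, None, None] ** 2
            + axes[1][None, :, None] ** 2
            + axes[2][None, None, :] ** 2
        )
        sub = mask[
            lo_idx[0] : hi_idx[0] + 1,
            lo_idx[1] : hi_idx[1] + 1,
            lo_idx[2] : hi_idx[2] + 1,
        ]
        sub |= d2 < reach * reach
    return mask


def label_level_set(
    mol: MoleculePointCloud,
    grid: Grid,
    probe: ProbeParams = ProbeParams(),
    clamp: float = 1.0,
    resolution: float | None = None,
) -> LevelSetField:
    """Label every grid point with the signed clamped distance to the SES.

    With ``resolution`` set (Å), the two-pass classification and distance
    transform run on an internal fine lattice of that spacing covering both
    the molecule's probe shell and the requested grid, and the fine field is
    trilinearly resampled onto ``grid``. This decouples the labeling accuracy
    from the evaluation grid, so surfaces extracted at different spacings
    agree with one another.

    Raises
    ------
    CoverageError
        If any atom's solvent-accessible sphere (radius ``r + probe``) pokes
        out of the grid box, which would corrupt the exterior classification.
    """
    pr = probe.probe_radius
    if resolution is not None:
        if not 0 < resolution:
            raise ValueError(f"resolution must be positive, got {resolution}")
        reach = mol.radii + pr
        lo = np.minimum(grid.origin, (mol.centers - reach[:, None]).min(axis=0)) - resolution
        hi = np.maximum(grid.upper, (mol.centers + reach[:, None]).max(axis=0)) + resolution
        dims = tuple(int(np.ceil(d / resolution - 1e-9)) + 1 for d in hi - lo)
        fine = Grid(lo, resolution, dims)
        fine_field = label_level_set(mol, fine, probe, clamp=clamp)
        return resample_field(fine_field, grid)
    reach = mol.radii + pr
    lo_needed = (mol.centers - reach[:, None]).min(axis=0)
    hi_needed = (mol.centers + reach[:, None]).max(axis=0)
    if np.any(lo_needed < grid.origin - 1e-9) or np.any(hi_needed > grid.upper + 1e-9):
        raise CoverageError(
            "grid box does not cover the molecule plus its probe shell; "
            "enlarge the margin"
        )

    s = grid.spacing
    sas_interior = _sas_interior_mask(mol, grid, pr)

    # pass 2: probe re-entry. Distance from each SAS-interior point to the
    # nearest SAS-exterior grid point (candidate probe centers).
    if sas_interior.any():
        d_to_sas_ext = ndimage.distance_transform_edt(sas_interior, sampling=s)
    else:
        d_to_sas_ext = np.zeros(grid.dims)
    interior = sas_interior & (d_to_sas_ext > pr)

    if not interior.any():
        values = np.full(grid.dims, clamp)
    else:
        d_to_interior = ndimage.distance_transform_edt(~interior, sampling=s)
        d_to_exterior = ndimage.distance_transform_edt(interior, sampling=s)
        values = np.where(interior, -d_to_exterior, d_to_interior)
        np.clip(values, -clamp, clamp, out=values)
    return LevelSetField(grid, values)


def resample_field(field: LevelSetField, grid: Grid) -> LevelSetField:
    """Trilinearly interpolate a field onto another grid inside its box."""
    src = field.grid
    if np.any(grid.origin < src.origin - 1e-9) or np.any(grid.upper > src.upper + 1e-9):
        raise CoverageError("target grid extends beyond the source field's box")
    pts = grid.points()
    coords = ((pts - src.origin) / src.spacing).T
    vals = ndimage.map_coordinates(field.values, coords, order=1, mode="nearest")
    return LevelSetField(grid, vals.reshape(grid.dims))


def analytic_sphere_field(center, radius: float, grid: Grid) -> LevelSetField:
    """Exact (unclamped) level set of a single sphere: ``|g - center| - radius``."""
    if not radius > 0:
        raise ValueError("radius must be positive")
    center = np.asarray(center, dtype=float).reshape(3)
    axes = [
        grid.origin[d] + grid.spacing * np.arange(grid.dims[d]) - center[d] for d in range(3)
    ]
    dist = np.sqrt(
        axes[0][:, None, None] ** 2
        + axes[1][None, :, None] ** 2
        + axes[2][None, None, :] ** 2
    )
    return LevelSetField(grid, dist - radius)


# ---------------------------------------------------------------------------
# OpenDX regular-grid scalar I/O
#
# Dialect: `object 1 class gridpositions counts nx ny nz`, origin + three
# axis-aligned delta records, `object 2 class gridconnections`, then an ASCII
# `data follows` array in C order (z varies fastest).


def write_field(field: LevelSetField, path) -> None:
    grid = field.grid
    nx, ny, nz = grid.dims
    s = grid.spacing
    with open(path, "w") as fh:
        fh.write("# level-set scalar field\n")
        fh.write(f"object 1 class gridpositions counts {nx} {ny} {nz}\n")
        fh.write(f"origin {grid.origin[0]:.6f} {grid.origin[1]:.6f} {grid.origin[2]:.6f}\n")
        fh.write(f"delta {s:.6f} 0.000000 0.000000\n")
        fh.write(f"delta 0.000000 {s:.6f} 0.000000\n")
        fh.write(f"delta 0.000000 0.000000 {s:.6f}\n")
        fh.write(f"object 2 class gridconnections counts {nx} {ny} {nz}\n")
        fh.write(
            f"object 3 class array type double rank 0 items {field.values.size} data follows\n"
        )
        flat = field.flat
        for i in range(0, flat.size, 3):
            fh.write(" ".join(f"{v:.6e}" for v in flat[i : i + 3]) + "\n")
        fh.write('attribute "dep" string "positions"\n')
        fh.write('object "field" class field\n')
        fh.write('component "positions" value 1\n')
        fh.write('component "connections" value 2\n')
        fh.write('component "data" value 3\n')


class DXFormatError(ValueError):
    """The file is not a regular-grid OpenDX scalar field."""


def read_field(path) -> LevelSetField:
    path = Path(path)
    counts = origin = None
    deltas: list[np.ndarray] = []
    n_items = None
    has_connections = False
    data: list[float] = []
    with open(path) as fh:
        in_data = False
        for line in fh:
            stripped = line.strip()
            if not stripped or stripped.startswith("#"):
                continue
            if in_data:
                if stripped.startswith(("attribute", "object", "component")):
                    in_data = False
                else:
                    data.extend(float(t) for t in stripped.split())
                    continue
            if m := re.match(r"object\s+\S+\s+class\s+gridpositions\s+counts\s+(\d+)\s+(\d+)\s+(\d+)", stripped):
                counts = tuple(int(g) for g in m.groups())
            elif stripped.startswith("origin"):
                origin = np.array([float(t) for t in stripped.split()[1:4]])
            elif stripped.startswith("delta"):
                deltas.append(np.array([float(t) for t in stripped.split()[1:4]]))
            elif "gridconnections" in stripped:
                has_connections = True
            elif m := re.match(r"object\s+\S+\s+class\s+array.*items\s+(\d+)\s+data\s+follows", stripped):
                n_items = int(m.group(1))
                in_data = True
    if counts is None or origin is None or len(deltas) != 3:
        raise DXFormatError(f"{path}: missing gridpositions/origin/delta records")
    if not has_connections:
        raise DXFormatError(f"{path}: no gridconnections record (non-regular grid?)")
    delta = np.array(deltas)
    if not np.allclose(delta, np.diag(np.diag(delta))):
        raise DXFormatError(f"{path}: deltas are not axis-aligned")
    spac = np.diag(delta)
    if not np.allclose(spac, spac[0]):
        raise DXFormatError(f"{path}: anisotropic spacing not supported")
    if n_items is None or len(data) != n_items or n_items != int(np.prod(counts)):
        raise DXFormatError(f"{path}: data item count mismatch")
    grid = Grid(origin, float(spac[0]), counts)
    return LevelSetField(grid, np.array(data).reshape(counts))
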