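"""Molecule point clouds, grids, structure I/O and synthetic molecule generators.

A molecule is represented digitally as a point cloud: one center ``a_i`` and one
radius ``r_i`` per atom. Grids are regular axis-aligned lattices with a single
spacing ``s`` (Å) on all three axes; grid indices are 0-based and the grid box
is the closed interval ``[origin, origin + s*(dims-1)]`` per axis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "Atom",
    "MoleculePointCloud",
    "Grid",
    "BONDI_RADII",
    "read_molecule",
    "write_molecule",
    "make_grid",
    "generate_synthetic",
]

#: Bondi-style van der Waals radii (Å) used for PDB input, keyed by element
#: symbol. PQR files carry explicit radii and never consult this table.
BONDI_RADII: dict[str, float] = {
    "H": 1.20,
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "F": 1.47,
    "P": 1.80,
    "S": 1.80,
    "CL": 1.75,
    "BR": 1.85,
    "I": 1.98,
    "NA": 2.27,
    "K": 2.75,
    "MG": 1.73,
    "CA": 2.31,
    "ZN": 1.39,
    "FE": 1.94,
}


@dataclass(frozen=True)
class Atom:
    """A single atom: center (Å), positive radius (Å), optional name."""

    center: np.ndarray
    radius: float
    name: str = ""

    def __post_init__(self) -> None:
        center = np.asarray(self.center, dtype=float).reshape(3)
        object.__setattr__(self, "center", center)
        if not np.all(np.isfinite(center)):
            raise ValueError(f"atom {self.name!r}: non-finite coordinates {center}")
        if not (self.radius > 0 and np.isfinite(self.radius)):
            raise ValueError(f"atom {self.name!r}: radius must be positive, got {self.radius}")


@dataclass(frozen=True)
class MoleculePointCloud:
    """Digital molecule: an ordered list of atoms.

    Attributes
    ----------
    atoms : list of Atom
        Atom order is preserved from the source file or generator; feature
        extraction uses it to break nearest-neighbor ties deterministically.
    """

    atoms: list[Atom] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.atoms) < 1:
            raise ValueError("a molecule must contain at least one atom")

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def centers(self) -> np.ndarray:
        """(N_a, 3) array of atom centers, Å."""
        return np.array([a.center for a in self.atoms], dtype=float)

    @property
    def radii(self) -> np.ndarray:
        """(N_a,) array of atom radii, Å."""
        return np.array([a.radius for a in self.atoms], dtype=float)

    def translated(self, shift) -> "MoleculePointCloud":
        shift = np.asarray(shift, dtype=float).reshape(3)
        return MoleculePointCloud(
            [Atom(a.center + shift, a.radius, a.name) for a in self.atoms]
        )


@dataclass(frozen=True)
class Grid:
    """Regular 3D lattice: ``point(ix,iy,iz) = origin + s*(ix,iy,iz)``."""

    origin: np.ndarray
    spacing: float
    dims: tuple[int, int, int]

    def __post_init__(self) -> None:
        origin = np.asarray(self.origin, dtype=float).reshape(3)
        object.__setattr__(self, "origin", origin)
        object.__setattr__(self, "dims", tuple(int(d) for d in self.dims))
        if not self.spacing > 0:
            raise ValueError(f"grid spacing must be positive, got {self.spacing}")
        if self.spacing > 1.0:
            warnings.warn(
                f"grid spacing {self.spacing} Å exceeds the usual (0, 1] range",
                stacklevel=2,
            )
        if any(d < 1 for d in self.dims):
            raise ValueError(f"grid dims must be positive, got {self.dims}")

    @property
    def n_points(self) -> int:
        nx, ny, nz = self.dims
        return nx * ny * nz

    @property
    def upper(self) -> np.ndarray:
        """Coordinate of the last grid point on each axis."""
        return self.origin + self.spacing * (np.array(self.dims) - 1)

    def points(self) -> np.ndarray:
        """All grid point coordinates, shape (N_g, 3), C order (x fastest last)."""
        axes = [self.origin[i] + self.spacing * np.arange(self.dims[i]) for i in range(3)]
        gx, gy, gz = np.meshgrid(*axes, indexing="ij")
        return np.stack([gx.ravel(), gy.ravel(), gz.ravel()], axis=1)

    def translated(self, shift) -> "Grid":
        return Grid(self.origin + np.asarray(shift, dtype=float), self.spacing, self.dims)


def make_grid(mol: MoleculePointCloud, spacing: float, margin: float | None = None) -> Grid:
    """Build the minimal grid covering the molecule plus ``margin`` on every side.

    Parameters
    ----------
    mol : MoleculePointCloud
    spacing : float
        Lattice spacing s in Å; must be positive (values > 1 Å warn).
    margin : float, optional
        Padding beyond the union of atom spheres, Å. Default is
        ``2 * (max radius + 1.4)``, which guarantees the solvent-excluded
        surface and a shell of exterior points fit inside the box.
    """
    if not spacing > 0:
        raise ValueError(f"spacing must be positive, got {spacing}")
    if margin is None:
        margin = 2.0 * (float(mol.radii.max()) + 1.4)
    if margin < 0:
        raise ValueError(f"margin must be non-negative, got {margin}")
    lo = (mol.centers - mol.radii[:, None]).min(axis=0) - margin
    hi = (mol.centers + mol.radii[:, None]).max(axis=0) + margin
    # minimal integer dims such that origin + s*(dims-1) >= hi
    span = hi - lo
    dims = tuple(int(np.ceil(s / spacing - 1e-9)) + 1 for s in span)
    return Grid(lo, spacing, dims)


# ---------------------------------------------------------------------------
# structure I/O


def _parse_pqr(path: Path) -> MoleculePointCloud:
    # Whitespace-delimited PQR: ATOM/HETATM ... x y z charge radius.
    # Field counts vary by dialect (chain id optional); the last five numeric
    # tokens are always x, y, z, charge, radius.
    atoms: list[Atom] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line.split()
            if not rec or rec[0] not in ("ATOM", "HETATM"):
                continue
            if len(rec) < 8:
                raise ValueError(f"{path}:{lineno}: malformed PQR record: {line.rstrip()!r}")
            try:
                x, y, z, _charge, radius = (float(t) for t in rec[-5:])
            except ValueError as exc:
                raise ValueError(
                    f"{path}:{lineno}: non-numeric PQR fields: {line.rstrip()!r}"
                ) from exc
            name = rec[2] if len(rec) > 2 else ""
            atoms.append(Atom(np.array([x, y, z]), radius, name))
    if not atoms:
        raise ValueError(f"{path}: no ATOM/HETATM records found")
    return MoleculePointCloud(atoms)


def _lookup_radius(name: str, element: str, table: dict[str, float]) -> float:
    for key in (name.upper(), element.upper()):
        if key and key in table:
            return table[key]
    # fall back to the first alphabetic character of the atom name
    for ch in name.upper():
        if ch.isalpha():
            if ch in table:
                return table[ch]
            break
    raise KeyError(f"atom name {name!r} (element {element!r}) not in radius table")


def _parse_pdb(path: Path, radius_table: dict[str, float]) -> MoleculePointCloud:
    from Bio.PDB import PDBParser

    parser = PDBParser(QUIET=True)
    structure = parser.get_structure("mol", str(path))
    atoms: list[Atom] = []
    for atom in structure.get_atoms():
        name = atom.get_name()
        element = atom.element or ""
        radius = _lookup_radius(name, element, radius_table)
        atoms.append(Atom(np.asarray(atom.get_coord(), dtype=float), radius, name))
    if not atoms:
        raise ValueError(f"{path}: no atoms found")
    return MoleculePointCloud(atoms)


def read_molecule(
    path,
    format: str | None = None,
    radius_table: dict[str, float] | None = None,
) -> MoleculePointCloud:
    """Read a molecule from a PQR or PDB file.

    PQR radii come from the file's radius column. PDB atoms are assigned radii
    by ``radius_table`` lookup (atom name, then element symbol, then leading
    letter of the name); the default table is a Bondi-style vdW set.
    """
    path = Path(path)
    if format is None:
        format = path.suffix.lstrip(".").lower()
    format = format.lower()
    if format == "pqr":
        return _parse_pqr(path)
    if format == "pdb":
        return _parse_pdb(path, radius_table or BONDI_RADII)
    raise ValueError(f"unknown molecule format {format!r} (expected 'pqr' or 'pdb')")


def write_molecule(mol: MoleculePointCloud, path, format: str | None = None) -> None:
    """Write a molecule as PQR (charge column written as 0) or XYZ."""
    path = Path(path)
    if format is None:
        format = path.suffix.lstrip(".").lower()
    format = format.lower()
    if format == "pqr":
        with open(path, "w") as fh:
            for i, a in enumerate(mol.atoms, start=1):
                name = a.name or "X"
                fh.write(
                    f"ATOM  {i:5d} {name:<4s} MOL {1:5d}    "
                    f"{a.center[0]:10.3f}{a.center[1]:10.3f}{a.center[2]:10.3f}"
                    f"{0.0:8.4f}{a.radius:8.3f}\n"
                )
            fh.write("END\n")
    elif format == "xyz":
        with open(path, "w") as fh:
            fh.write(f"{mol.n_atoms}\n")
            fh.write("atom centers (x y z), Å\n")
            for a in mol.atoms:
                name = a.name or "X"
                fh.write(f"{name} {a.center[0]:.6f} {a.center[1]:.6f} {a.center[2]:.6f}\n")
    else:
        raise ValueError(f"unknown output format {format!r} (expected 'pqr' or 'xyz')")


# ---------------------------------------------------------------------------
# synthetic molecules

_PRESETS = ("single", "diatomic", "cluster", "helix")


def generate_synthetic(
    preset: str,
    n_atoms: int = 1,
    seed: int = 0,
    **params,
) -> MoleculePointCloud:
    """Generate a deterministic synthetic molecule.

    Presets
    -------
    single
        One atom at the origin; ``radius`` (default 1.7 Å).
    diatomic
        Two atoms on the x axis; ``separation`` (default 3.0 Å), ``radius``.
    cluster
        ``n_atoms`` overlapping spheres grown by a bonded random walk: each new
        atom sits at a distance drawn from [1.2, 2.0] Å from a randomly chosen
        existing atom, with radii drawn from [1.2, 2.0] Å, so probe-inaccessible
        reentrant crevices occur as in covalently bonded molecules.
    helix
        ``n_atoms`` atoms on a helix; ``helix_radius`` (default 2.3 Å),
        ``pitch`` (rise per turn, default 5.4 Å), ``step_angle`` (default 100°),
        ``radius`` (atom radius, default 1.7 Å).

    The output is a pure function of ``(preset, n_atoms, seed, params)``.
    """
    if preset not in _PRESETS:
        raise ValueError(f"unknown preset {preset!r}; expected one of {_PRESETS}")
    if n_atoms < 1:
        raise ValueError("n_atoms must be >= 1")
    rng = np.random.default_rng(seed)

    if preset == "single":
        r = float(params.get("radius", 1.7))
        return MoleculePointCloud([Atom(np.zeros(3), r, "X1")])

    if preset == "diatomic":
        sep = float(params.get("separation", 3.0))
        r = float(params.get("radius", 1.7))
        return MoleculePointCloud(
            [
                Atom(np.zeros(3), r, "X1"),
                Atom(np.array([sep, 0.0, 0.0]), r, "X2"),
            ]
        )

    if preset == "helix":
        hr = float(params.get("helix_radius", 2.3))
        pitch = float(params.get("pitch", 5.4))
        step = np.deg2rad(float(params.get("step_angle", 100.0)))
        r = float(params.get("radius", 1.7))
        atoms = []
        for i in range(n_atoms):
            t = i * step
            atoms.append(
                Atom(
                    np.array([hr * np.cos(t), hr * np.sin(t), pitch * t / (2 * np.pi)]),
                    r,
                    f"X{i + 1}",
                )
            )
        return MoleculePointCloud(atoms)

    # cluster: bonded random walk with overlap rejection
    sep_lo, sep_hi = params.get("separation_range", (1.2, 2.0))
    rad_lo, rad_hi = params.get("radius_range", (1.2, 2.0))
    min_sep = float(params.get("min_separation", 1.2))
    centers = [np.zeros(3)]
    radii = [float(rng.uniform(rad_lo, rad_hi))]
    while len(centers) < n_atoms:
        for _ in range(1000):
            # a fresh anchor per attempt: buried anchors reject all directions
            anchor = centers[int(rng.integers(len(centers)))]
            direction = rng.normal(size=3)
            direction /= np.linalg.norm(direction)
            candidate = anchor + direction * rng.uniform(sep_lo, sep_hi)
            dists = np.linalg.norm(np.array(centers) - candidate, axis=1)
            if dists.min() >= min_sep:
                centers.append(candidate)
                radii.append(float(rng.uniform(rad_lo, rad_hi)))
                break
        else:  # pragma: no cover - extremely unlikely at these densities
            raise RuntimeError("cluster growth failed to place an atom")
    return MoleculePointCloud(
        [Atom(c, r, f"X{i + 1}") for i, (c, r) in enumerate(zip(centers, radii))]
    )
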