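"""Real-space electron-density observable: out-of-plane charge.

After ionisation the promoted shake-up electron occupies a diffuse
orbital extending away from the (planar) molecule. The observable here
is the time-dependent electron density integrated beyond two planes
parallel to the molecular plane:

    Q(t) = sum_k n_k(t) * Int_{|d(r)| > distance} |phi_k(r)|^2 dV

with ``d`` the signed distance to the plane and both half-spaces
included. Orbitals are carried on real-space grids in the Gaussian cube
format (Bohr per the standard dialect; a negative voxel count in the
header marks Angstrom units, and that dialect is honoured on read).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "GridOrbital",
    "read_cube",
    "write_cube",
    "out_of_plane_density",
    "best_fit_plane",
    "CubeParseError",
]

BOHR_PER_ANGSTROM = 1.0 / 0.529177210903


class CubeParseError(ValueError):
    def __init__(self, message, line=None):
        super().__init__(f"line {line}: {message}" if line else message)
        self.line = line


@dataclass
class GridOrbital:
    """A real orbital amplitude sampled on a regular 3D grid.

    ``origin`` (Angstrom), ``axes`` — three step vectors (Angstrom, rows),
    ``values`` with shape ``shape``. ``atoms`` is an optional list of
    ``(Z, x, y, z)`` records (Angstrom) used for plane fitting.
    """

    origin: np.ndarray
    axes: np.ndarray
    values: np.ndarray
    atoms: list | None = None

    def __post_init__(self):
        self.origin = np.asarray(self.origin, dtype=float)
        self.axes = np.asarray(self.axes, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.axes.shape != (3, 3):
            raise ValueError("axes must be a 3x3 matrix of step vectors")
        if self.values.ndim != 3:
            raise ValueError("values must be a 3D array")

    @property
    def shape(self):
        return self.values.shape

    @property
    def voxel_volume(self) -> float:
        """Voxel volume in Angstrom^3."""
        return float(abs(np.linalg.det(self.axes)))

    def voxel_centers(self) -> np.ndarray:
        """(nx, ny, nz, 3) array of voxel centre coordinates (Angstrom)."""
        nx, ny, nz = self.shape
        i, j, k = np.meshgrid(
            np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij"
        )
        idx = np.stack([i, j, k], axis=-1).astype(float)
        return self.origin + idx @ self.axes

    @property
    def norm(self) -> float:
        """Numeric integral of |phi|^2 over the grid."""
        return float(np.sum(self.values**2) * self.voxel_volume)

    def same_grid(self, other: "GridOrbital") -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.origin, other.origin, atol=1e-9)
            and np.allclose(self.axes, other.axes, atol=1e-9)
        )


def read_cube(path) -> GridOrbital:
    """Read a Gaussian cube file.

    Standard dialect: lengths in Bohr with positive voxel counts; a
    negative voxel count declares Angstrom units for the corresponding
    axis (all-or-nothing in practice; either is honoured). Returns a
    :class:`GridOrbital` in Angstrom.
    """
    with open(path) as fh:
        lines = fh.read().splitlines()
    if len(lines) < 6:
        raise CubeParseError("truncated header", line=len(lines))
    try:
        parts = lines[2].split()
        n_atoms = int(parts[0])
        origin = np.array([float(x) for x in parts[1:4]])
    except (ValueError, IndexError):
        raise CubeParseError("bad atom-count/origin record", line=3)
    counts, axes, angstrom = [], [], False
    for ax in range(3):
        try:
            parts = lines[3 + ax].split()
            n = int(parts[0])
            vec = np.array([float(x) for x in parts[1:4]])
        except (ValueError, IndexError):
            raise CubeParseError("bad axis record", line=4 + ax)
        if n < 0:
            angstrom = True
            n = -n
        counts.append(n)
        axes.append(vec)
    axes = np.array(axes)
    scale = 1.0 if angstrom else 1.0 / BOHR_PER_ANGSTROM
    atoms = []
    for a in range(abs(n_atoms)):
        try:
            parts = lines[6 + a].split()
            atoms.append((int(parts[0]),) + tuple(float(x) * scale for x in parts[2:5]))
        except (ValueError, IndexError):
            raise CubeParseError("bad atom record", line=7 + a)
    data = []
    for ln, line in enumerate(lines[6 + abs(n_atoms):], start=7 + abs(n_atoms)):
        for tok in line.split():
            try:
                data.append(float(tok))
            except ValueError:
                raise CubeParseError(f"bad value {tok!r}", line=ln)
    nx, ny, nz = counts
    if len(data) != nx * ny * nz:
        raise CubeParseError(
            f"value count {len(data)} != {nx}*{ny}*{nz}", line=len(lines)
        )
    values = np.array(data).reshape(nx, ny, nz)
    return GridOrbital(origin * scale, axes * scale, values, atoms=atoms or None)


def write_cube(orb: GridOrbital, path, comment="chargemig orbital"):
    """Write a standard-dialect (Bohr) Gaussian cube file."""
    b = BOHR_PER_ANGSTROM
    atoms = orb.atoms or []
    with open(path, "w") as fh:
        fh.write(f"{comment}\n")
        fh.write("cube written by chargemig\n")
        ox, oy, oz = orb.origin * b
        fh.write(f"{max(len(atoms), 1):5d} {ox:12.6f} {oy:12.6f} {oz:12.6f}\n")
        for n, vec in zip(orb.shape, orb.axes * b):
            fh.write(f"{n:5d} {vec[0]:12.6f} {vec[1]:12.6f} {vec[2]:12.6f}\n")
        if atoms:
            for (Z, x, y, z) in atoms:
                fh.write(f"{Z:5d} {0.0:12.6f} {x * b:12.6f} {y * b:12.6f} {z * b:12.6f}\n")
        else:
            fh.write(f"{1:5d} {0.0:12.6f} {0.0:12.6f} {0.0:12.6f} {0.0:12.6f}\n")
        flat = orb.values.reshape(orb.shape[0] * orb.shape[1], orb.shape[2])
        for row in flat:
            for start in range(0, row.size, 6):
                fh.write(" ".join(f"{v: .6e}" for v in row[start:start + 6]) + "\n")


def best_fit_plane(coords):
    """Best-fit plane of a set of points: returns (normal, centroid).

    The normal is the smallest principal axis of the centred coordinates.
    """
    x = np.asarray(coords, dtype=float)
    centroid = x.mean(axis=0)
    _, _, vt = np.linalg.svd(x - centroid)
    return vt[-1], centroid


def out_of_plane_density(orbitals, occupations, plane_normal=None, plane_point=None,
                         distance: float = 3.0):
    """Electron density integrated beyond ``distance`` (Angstrom) from a
    plane, as a function of time.

    ``orbitals`` — sequence of :class:`GridOrbital` on a common grid,
    one per (spatial) orbital; ``occupations`` — array ``(nt, n_orb)``
    (or ``(n_orb,)`` for a single time) of occupation numbers n_k(t).
    The plane defaults to the best-fit plane of the first orbital's atom
    records. Voxels count by their centre position; both half-spaces
    beyond ``+-distance`` are included. Returns Q with shape ``(nt,)``
    (or a scalar for 1D occupations).
    """
    orbitals = list(orbitals)
    if not orbitals:
        raise ValueError("no orbitals given")
    ref = orbitals[0]
    for o in orbitals[1:]:
        if not ref.same_grid(o):
            raise ValueError("orbitals must share one grid")
    if plane_normal is None:
        if not ref.atoms:
            raise ValueError("no plane given and no atoms to fit one")
        plane_normal, fitted_point = best_fit_plane([a[1:] for a in ref.atoms])
        if plane_point is None:
            plane_point = fitted_point
    plane_normal = np.asarray(plane_normal, dtype=float)
    nrm = np.linalg.norm(plane_normal)
    if nrm == 0:
        raise ValueError("plane normal must be nonzero")
    plane_normal = plane_normal / nrm
    plane_point = np.zeros(3) if plane_point is None else np.asarray(plane_point, float)

    d = (ref.voxel_centers() - plane_point) @ plane_normal
    mask = np.abs(d) >= distance  # distance 0 recovers the full integral
    dv = ref.voxel_volume
    fractions = np.array([float(np.sum(o.values[mask] ** 2) * dv) for o in orbitals])

    occ = np.asarray(occupations, dtype=float)
    if occ.ndim == 1:
        return float(occ @ fractions)
    return occ @ fractions
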