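"""Domain types shared across the pipeline.

Coordinates are right-handed physical coordinates in micrometers with z = 0 at
the glass substratum.  Arrays are indexed ``[z, y, x]`` (microscopy plane
order); voxel ``(k, j, i)`` spans the half-open box
``[i*dx, (i+1)*dx) x [j*dy, (j+1)*dy) x [k*dz, (k+1)*dz)`` and its center sits
at ``((i+0.5)*dx, (j+0.5)*dy, (k+0.5)*dz)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

__all__ = [
    "CellGeom",
    "VoxelSpec",
    "Region",
    "SceneGroundTruth",
    "cell_volume",
    "point_segment_distance",
    "segment_segment_distance",
    "segment_to_segments_distance",
]


@dataclass(frozen=True)
class CellGeom:
    """A spherocylindrical (capsule-shaped) cell.

    ``p0`` and ``p1`` are the endpoints of the cylinder axis in um; ``p0 == p1``
    degenerates to a sphere.  Volume is pi r^2 |p1-p0| + (4/3) pi r^3 > 0.
    """

    species_id: str
    p0: tuple[float, float, float]
    p1: tuple[float, float, float]
    radius: float

    def __post_init__(self) -> None:
        if not self.radius > 0:
            raise ValueError(f"cell radius must be > 0, got {self.radius}")

    @property
    def axis_length(self) -> float:
        return float(np.linalg.norm(np.subtract(self.p1, self.p0)))

    @property
    def volume(self) -> float:
        return cell_volume(self.axis_length, self.radius)

    @property
    def centroid(self) -> np.ndarray:
        return (np.asarray(self.p0) + np.asarray(self.p1)) / 2.0


def cell_volume(axis_length: float, radius: float) -> float:
    """Volume of a spherocylinder: cylinder part plus two hemispherical caps."""
    return float(np.pi * radius**2 * axis_length + 4.0 / 3.0 * np.pi * radius**3)


@dataclass(frozen=True)
class VoxelSpec:
    """Physical voxel geometry.

    ``dx, dy, dz`` are um per voxel (``dz >= dx`` typical: axial anisotropy).
    ``shape`` is stored in array (ZYX) order ``(nz, ny, nx)`` to match the
    ``[z, y, x]`` indexing of every image array in this package.
    """

    dx: float
    dy: float
    dz: float
    shape: tuple[int, int, int]  # (nz, ny, nx)

    def __post_init__(self) -> None:
        if min(self.dx, self.dy, self.dz) <= 0:
            raise ValueError("voxel spacings must be positive")
        if len(self.shape) != 3 or min(self.shape) < 1:
            raise ValueError(f"bad shape {self.shape}")

    @property
    def spacing_zyx(self) -> tuple[float, float, float]:
        return (self.dz, self.dy, self.dx)

    @property
    def voxel_volume(self) -> float:
        return self.dx * self.dy * self.dz

    @property
    def extent(self) -> tuple[float, float, float]:
        """Physical domain size (Lx, Ly, Lz) in um."""
        nz, ny, nx = self.shape
        return (nx * self.dx, ny * self.dy, nz * self.dz)

    def centers(self, axis: str) -> np.ndarray:
        """Voxel-center coordinates (um) along ``axis`` in {'x','y','z'}."""
        n = {"x": self.shape[2], "y": self.shape[1], "z": self.shape[0]}[axis]
        d = {"x": self.dx, "y": self.dy, "z": self.dz}[axis]
        return (np.arange(n) + 0.5) * d

    @classmethod
    def for_domain(
        cls, domain_size: Sequence[float], dx: float = 0.2, dy: float = 0.2, dz: float = 0.5
    ) -> "VoxelSpec":
        lx, ly, lz = domain_size
        shape = (int(round(lz / dz)), int(round(ly / dy)), int(round(lx / dx)))
        return cls(dx=dx, dy=dy, dz=dz, shape=shape)


ARCHITECTURES = (
    "dense_cluster",
    "loose_cluster",
    "embedded_basal_layer",
    "scattered_singletons",
)


@dataclass(frozen=True)
class Region:
    """An axis-aligned region of the scene with a target packing fraction.

    ``species`` semantics depend on the architecture: for ``dense_cluster`` /
    ``loose_cluster`` / ``scattered_singletons`` it lists the species mixed by
    the scene-level ratio (empty means all); for ``embedded_basal_layer`` it is
    ``(overlay_species, basal_species)`` — the basal species occupies the bottom
    ``basal_height_um`` (<= 4 um) and is overgrown by the overlay species.
    """

    name: str
    lo: tuple[float, float, float]  # (x, y, z) um
    hi: tuple[float, float, float]
    target_packing: float
    architecture: str
    species: tuple[str, ...] = ()
    basal_height_um: float = 2.0
    placement: str = "auto"  # auto | rsa | lattice

    def __post_init__(self) -> None:
        if self.architecture not in ARCHITECTURES:
            raise ValueError(
                f"unknown architecture {self.architecture!r}; expected one of {ARCHITECTURES}"
            )
        if not 0.0 <= self.target_packing <= 1.0:
            raise ValueError("target_packing must lie in [0, 1]")
        if any(h <= l for l, h in zip(self.lo, self.hi)):
            raise ValueError(f"region {self.name!r} has empty extent")
        if self.basal_height_um > 4.0:
            raise ValueError("basal layer is restricted to the bottom <= 4 um")
        if self.placement not in ("auto", "rsa", "lattice"):
            raise ValueError(f"unknown placement {self.placement!r}")

    @property
    def size(self) -> tuple[float, float, float]:
        return tuple(h - l for l, h in zip(self.lo, self.hi))

    @property
    def volume(self) -> float:
        sx, sy, sz = self.size
        return sx * sy * sz

    def contains(self, pts: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(pts)
        lo = np.asarray(self.lo)
        hi = np.asarray(self.hi)
        return np.all((pts >= lo) & (pts <= hi), axis=1)

    def overlaps(self, other: "Region") -> bool:
        return all(l1 < h2 and l2 < h1 for l1, h1, l2, h2 in zip(self.lo, self.hi, other.lo, other.hi))


@dataclass
class SceneGroundTruth:
    """Ground truth for one synthetic biofilm snapshot.

    ``cells`` is the full list of placed spherocylinders; ``regions`` the
    placement plan; ``realized_packing`` the generator's occupancy-grid estimate
    of the union volume fraction achieved per region.
    """

    cells: list[CellGeom]
    domain_size: tuple[float, float, float]  # (Lx, Ly, Lz) um
    regions: list[Region] = field(default_factory=list)
    rng_seed: int = 0
    realized_packing: dict[str, float] = field(default_factory=dict)

    @property
    def species(self) -> list[str]:
        seen: dict[str, None] = {}
        for c in self.cells:
            seen.setdefault(c.species_id, None)
        return list(seen)

    def cells_of(self, species_id: str) -> list[CellGeom]:
        return [c for c in self.cells if c.species_id == species_id]

    def filtered(self, keep: Sequence[bool]) -> "SceneGroundTruth":
        cells = [c for c, k in zip(self.cells, keep) if k]
        return replace(self, cells=cells)


def point_segment_distance(points: np.ndarray, a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Euclidean distance from ``points`` (N, 3) to segment ``a``-``b``."""
    points = np.atleast_2d(points)
    a = np.asarray(a, dtype=float)
    d = np.asarray(b, dtype=float) - a
    dd = float(d @ d)
    if dd == 0.0:
        return np.linalg.norm(points - a, axis=1)
    t = np.clip((points - a) @ d / dd, 0.0, 1.0)
    closest = a + t[:, None] * d
    return np.linalg.norm(points - closest, axis=1)


def segment_to_segments_distance(p0, p1, q0s: np.ndarray, q1s: np.ndarray) -> np.ndarray:
    """Distances from segment p0-p1 to each segment in (q0s, q1s) — vectorized
    version of :func:`segment_segment_distance` (same clamping scheme)."""
    p0 = np.asarray(p0, float)
    u = np.asarray(p1, float) - p0
    q0s = np.asarray(q0s, float).reshape(-1, 3)
    v = np.asarray(q1s, float).reshape(-1, 3) - q0s
    w = p0 - q0s
    a = float(u @ u)
    b = v @ u
    c = np.einsum("ij,ij->i", v, v)
    d = w @ u
    e = np.einsum("ij,ij->i", v, w)
    denom = a * c - b * b
    with np.errstate(divide="ignore", invalid="ignore"):
        s = np.where(denom > 1e-14, (b * e - c * d) / np.where(denom > 1e-14, denom, 1.0), 0.0)
    s = np.clip(s, 0.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(c > 1e-14, (b * s + e) / np.where(c > 1e-14, c, 1.0), 0.0)
    t = np.clip(t, 0.0, 1.0)
    if a > 1e-14:
        s = np.clip((b * t - d) / a, 0.0, 1.0)
    diff = w + s[:, None] * u - t[:, None] * v
    return np.linalg.norm(diff, axis=1)


def segment_segment_distance(p0, p1, q0, q1) -> float:
    """Minimum distance between segments p0-p1 and q0-q1 (um).

    Standard clamped closest-point computation; degenerate (point) segments are
    handled by the zero-denominator branches.
    """
    p0 = np.asarray(p0, float)
    q0 = np.asarray(q0, float)
    u = np.asarray(p1, float) - p0
    v = np.asarray(q1, float) - q0
    w = p0 - q0
    a = u @ u
    b = u @ v
    c = v @ v
    d = u @ w
    e = v @ w
    denom = a * c - b * b
    if denom > 1e-14:
        s = np.clip((b * e - c * d) / denom, 0.0, 1.0)
    else:
        s = 0.0
    t_num = b * s + e
    if c > 1e-14:
        t = np.clip(t_num / c, 0.0, 1.0)
    else:
        t = 0.0
    # re-clamp s against the clamped t
    if a > 1e-14:
        s = np.clip((b * t - d) / a, 0.0, 1.0)
    diff = w + s * u - t * v
    return float(np.linalg.norm(diff))
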