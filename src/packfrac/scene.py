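"""Synthetic multispecies biofilm scenes with known ground truth.

Scenes are static snapshots of spherocylindrical cells placed inside named
regions, each with a target biovolume (packing) fraction.  Two placement modes
cover the two packing regimes observed in dual-species biofilms:

* loose (target <= 0.55): overlap-tolerant random sequential addition.  Cells
  are dropped at random orientations; the minimum axis-axis separation starts
  at the sum of radii (no overlap) and relaxes in stages when placement stalls,
  mimicking the touching/merged biomass that segmentation unions produce.  The
  realized union fraction is tracked on an occupancy grid and placement stops
  at the target.
* dense (target > 0.55): lines of pole-to-pole cells along the region's longest
  axis, hexagonally packed in cross-section.  The lattice spacing is solved
  numerically from a 2D disc-union coverage model so the union fraction hits
  the target; this is the only way static hard-ish particles reach the > 0.9
  packing regime of mature, matrix-compacted clusters.

``true_local_fraction`` is the module-independent oracle for the downstream
neighborhood-packing metric: supersampled point-in-spherocylinder membership
within a ball, at a pitch much finer than the analysis voxel.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy.ndimage import gaussian_filter
from scipy.signal import fftconvolve
from scipy.spatial import cKDTree

from .geometry import (
    CellGeom,
    Region,
    SceneGroundTruth,
    VoxelSpec,
    point_segment_distance,
    segment_to_segments_distance,
)
from .stack import ImageStack

__all__ = [
    "CellParams",
    "DEFAULT_CELL_PARAMS",
    "OpticsParams",
    "generate_scene",
    "rasterize_scene",
    "scene_occupancy",
    "add_phage_channel",
    "true_local_fraction",
    "local_packing_field",
    "remove_unprotected",
]

RSA_MAX_TARGET = 0.74  # random placement cannot exceed sphere-packing-like bounds
LATTICE_MIN_TARGET = 0.55  # above this, auto placement switches to the lattice

PHAGE_MODES = ("uniform", "excluded_from_dense", "basal_glass_layer", "on_species_mask")


class CellParams:
    """Per-species default cell geometry (um)."""

    def __init__(self, radius: float = 0.4, length: float = 2.0):
        if radius <= 0 or length < 0:
            raise ValueError("radius must be > 0 and length >= 0")
        self.radius = radius
        self.length = length  # axis (pole-to-pole minus caps) length

    def __repr__(self) -> str:  # pragma: no cover
        return f"CellParams(radius={self.radius}, length={self.length})"


#: Vibrio-like short curved rods (modeled straight) and E. coli-like longer rods.
DEFAULT_CELL_PARAMS: dict[str, CellParams] = {
    "vibrio": CellParams(radius=0.35, length=1.2),
    "ecoli": CellParams(radius=0.40, length=2.0),
}
_GENERIC_CELL = CellParams(radius=0.40, length=2.0)


class OpticsParams:
    """Confocal-like rendering parameters.

    ``psf_sigma`` are per-axis Gaussian blur sigmas in um (x, y, z); the
    defaults emulate a post-deconvolution line-scanning confocal stack.  Signal
    is ``blur(occupancy) * photon_scale + background`` followed by Poisson shot
    noise and additive Gaussian read noise (both switchable off).
    """

    def __init__(
        self,
        psf_sigma: tuple[float, float, float] = (0.10, 0.10, 0.25),
        background: float = 5.0,
        photon_scale: float = 150.0,
        read_noise_sigma: float = 2.0,
        noise: bool = True,
    ):
        if min(psf_sigma) < 0 or background < 0 or photon_scale <= 0 or read_noise_sigma < 0:
            raise ValueError("invalid optics parameters")
        self.psf_sigma = tuple(float(s) for s in psf_sigma)
        self.background = float(background)
        self.photon_scale = float(photon_scale)
        self.read_noise_sigma = float(read_noise_sigma)
        self.noise = bool(noise)

    @classmethod
    def ideal(cls) -> "OpticsParams":
        """No blur, no background, no noise: channel = occupancy * photon_scale."""
        return cls(psf_sigma=(0.0, 0.0, 0.0), background=0.0, read_noise_sigma=0.0, noise=False)


# --------------------------------------------------------------------------- #
# scene generation
# --------------------------------------------------------------------------- #


def generate_scene(
    domain_size: tuple[float, float, float],
    region_plan: list[Region],
    species_ratio: dict[str, float] | None = None,
    rng_seed: int = 0,
    cell_params: dict[str, CellParams] | None = None,
) -> SceneGroundTruth:
    """Place cells for every region of the plan; reproducible given the seed.

    ``species_ratio`` (e.g. ``{"vibrio": 2, "ecoli": 1}``, the standard 2:1
    inoculation) sets the label mixture inside mixed regions.  Region boxes
    must be disjoint and lie inside the domain.
    """
    species_ratio = dict(species_ratio or {"vibrio": 2.0, "ecoli": 1.0})
    if any(v <= 0 for v in species_ratio.values()):
        raise ValueError("species_ratio entries must be positive")
    params = dict(DEFAULT_CELL_PARAMS)
    if cell_params:
        params.update(cell_params)

    domain = np.asarray(domain_size, float)
    if np.any(domain <= 0):
        raise ValueError("domain_size must be positive")
    for i, r in enumerate(region_plan):
        if np.any(np.asarray(r.lo) < -1e-9) or np.any(np.asarray(r.hi) > domain + 1e-9):
            raise ValueError(f"region {r.name!r} does not lie inside the domain")
        for r2 in region_plan[i + 1 :]:
            if r.overlaps(r2):
                raise ValueError(f"regions {r.name!r} and {r2.name!r} overlap")
        if r.placement == "rsa" and r.target_packing > RSA_MAX_TARGET:
            raise ValueError(
                f"region {r.name!r}: target packing {r.target_packing} exceeds the "
                f"random-placement bound {RSA_MAX_TARGET}; use placement='lattice' "
                "(jittered hexagonal lines) for dense targets"
            )

    rng = np.random.default_rng(rng_seed)
    cells: list[CellGeom] = []
    realized: dict[str, float] = {}
    for region in region_plan:
        sub_rng = np.random.default_rng(rng.integers(0, 2**31))
        placed, frac = _fill_region(region, species_ratio, params, sub_rng)
        cells.extend(placed)
        realized[region.name] = frac
    return SceneGroundTruth(
        cells=cells,
        domain_size=tuple(float(v) for v in domain),
        regions=list(region_plan),
        rng_seed=rng_seed,
        realized_packing=realized,
    )


def _region_species(region: Region, species_ratio: dict[str, float]) -> tuple[list[str], np.ndarray]:
    labels = list(region.species) if region.species else list(species_ratio)
    weights = np.asarray([species_ratio.get(lbl, 1.0) for lbl in labels], float)
    return labels, weights / weights.sum()


def _fill_region(
    region: Region,
    species_ratio: dict[str, float],
    params: dict[str, CellParams],
    rng: np.random.Generator,
) -> tuple[list[CellGeom], float]:
    if region.target_packing == 0.0:
        return [], 0.0
    arch = region.architecture
    if arch == "embedded_basal_layer":
        return _fill_embedded(region, params, rng)
    labels, probs = _region_species(region, species_ratio)
    use_lattice = region.placement == "lattice" or (
        region.placement == "auto" and region.target_packing > LATTICE_MIN_TARGET
    )
    if arch == "scattered_singletons":
        return _fill_loose(
            region.lo, region.hi, region.target_packing, labels, probs, params, rng,
            min_clearance=1.5,
        )
    if use_lattice:
        # dense lattice regions are effectively single-species cell groups;
        # draw the species once from the mixture
        label = labels[int(rng.choice(len(labels), p=probs))]
        return _fill_dense(region.lo, region.hi, region.target_packing, label, params, rng)
    return _fill_loose(region.lo, region.hi, region.target_packing, labels, probs, params, rng)


def _fill_embedded(
    region: Region, params: dict[str, CellParams], rng: np.random.Generator
) -> tuple[list[CellGeom], float]:
    """Basal species in the bottom layer, overgrown by a dense overlay species."""
    if len(region.species) != 2:
        raise ValueError(
            "embedded_basal_layer regions need species=(overlay, basal)"
        )
    overlay, basal = region.species
    lo = np.asarray(region.lo, float)
    hi = np.asarray(region.hi, float)
    hb = min(region.basal_height_um, (hi[2] - lo[2]) / 2.0)
    basal_hi = hi.copy()
    basal_hi[2] = lo[2] + hb
    over_lo = lo.copy()
    over_lo[2] = lo[2] + hb
    t = region.target_packing
    dense = region.placement == "lattice" or (
        region.placement == "auto" and t > LATTICE_MIN_TARGET
    )
    cells: list[CellGeom] = []
    fracs = []
    for (l, h, lbl) in ((lo, basal_hi, basal), (over_lo, hi, overlay)):
        if dense:
            # a thin basal slab may not geometrically reach the overlay target;
            # fill it as densely as feasible (its 6-um neighborhoods are
            # dominated by the overlay above it anyway)
            placed, f = _fill_dense(tuple(l), tuple(h), t, lbl, params, rng, cap_to_feasible=True)
        else:
            placed, f = _fill_loose(tuple(l), tuple(h), t, [lbl], np.array([1.0]), params, rng)
        cells.extend(placed)
        vol = float(np.prod(h - l))
        fracs.append((f, vol))
    total = sum(v for _, v in fracs)
    return cells, sum(f * v for f, v in fracs) / total


# ---- loose placement (overlap-tolerant RSA) -------------------------------- #


def _random_cell_in_box(
    lo: np.ndarray, hi: np.ndarray, cp: CellParams, label: str, rng: np.random.Generator
) -> CellGeom:
    """A random cell whose whole body (axis +- radius) fits in the box."""
    r = cp.radius
    size = hi - lo
    length = min(cp.length, max(0.0, float(size.min()) - 2 * r))
    for _ in range(200):
        u = rng.normal(size=3)
        n = np.linalg.norm(u)
        if n < 1e-9:
            continue
        u /= n
        half = u * (length / 2.0)
        c_lo = lo + r + np.abs(half)
        c_hi = hi - r - np.abs(half)
        if np.any(c_hi < c_lo):
            continue
        c = rng.uniform(c_lo, c_hi)
        return CellGeom(label, tuple(c - half), tuple(c + half), r)
    # fall back to a sphere if the box is too tight for a rod
    c = rng.uniform(lo + r, np.maximum(lo + r, hi - r))
    return CellGeom(label, tuple(c), tuple(c), r)


class _OccupancyTracker:
    """Coarse occupancy grid tracking the realized union fraction of a box."""

    def __init__(self, lo: np.ndarray, hi: np.ndarray, pitch: float):
        self.lo = lo
        self.pitch = pitch
        self.n = np.maximum(1, np.round((hi - lo) / pitch).astype(int))
        self.grid = np.zeros(tuple(self.n), dtype=bool)  # indexed [x, y, z]
        self.axes = [lo[i] + (np.arange(self.n[i]) + 0.5) * pitch for i in range(3)]
        self._occupied = 0

    def add(self, cell: CellGeom) -> None:
        r = cell.radius
        lo_c = np.minimum(cell.p0, cell.p1) - r
        hi_c = np.maximum(cell.p0, cell.p1) + r
        sl = []
        for i in range(3):
            a = np.searchsorted(self.axes[i], lo_c[i], "left")
            b = np.searchsorted(self.axes[i], hi_c[i], "right")
            sl.append(slice(a, b))
        xs, ys, zs = (self.axes[i][sl[i]] for i in range(3))
        if min(len(xs), len(ys), len(zs)) == 0:
            return
        pts = np.stack(np.meshgrid(xs, ys, zs, indexing="ij"), axis=-1).reshape(-1, 3)
        inside = point_segment_distance(pts, np.asarray(cell.p0), np.asarray(cell.p1)) <= r
        sub = self.grid[sl[0], sl[1], sl[2]]
        new = sub | inside.reshape(sub.shape)
        self._occupied += int(new.sum()) - int(sub.sum())
        self.grid[sl[0], sl[1], sl[2]] = new

    @property
    def fraction(self) -> float:
        return self._occupied / self.grid.size


def _fill_loose(
    lo,
    hi,
    target: float,
    labels: list[str],
    probs: np.ndarray,
    params: dict[str, CellParams],
    rng: np.random.Generator,
    min_clearance: float = 0.0,
) -> tuple[list[CellGeom], float]:
    """Overlap-tolerant random sequential addition up to the target fraction.

    Separation stages: axis-axis distance >= f * (r_i + r_j) with f stepping
    down 1.0 -> 0.7 when a stage stalls.  ``min_clearance`` (um of surface gap)
    keeps scattered singletons isolated.
    """
    lo = np.asarray(lo, float)
    hi = np.asarray(hi, float)
    r_min = min(params.get(l, _GENERIC_CELL).radius for l in labels)
    tracker = _OccupancyTracker(lo, hi, pitch=r_min / 3.0)
    cells: list[CellGeom] = []
    p0s = np.empty((0, 3))
    p1s = np.empty((0, 3))
    radii = np.empty((0,))
    stages = [1.0, 0.9, 0.8, 0.7, 0.6, 0.5]
    stage = 0
    stall = 0
    max_stall = 300
    while tracker.fraction < target:
        lbl = labels[int(rng.choice(len(labels), p=probs))]
        cp = params.get(lbl, _GENERIC_CELL)
        cand = _random_cell_in_box(lo, hi, cp, lbl, rng)
        if len(cells):
            d = segment_to_segments_distance(cand.p0, cand.p1, p0s, p1s)
            ok = bool(np.all(d >= stages[stage] * (cand.radius + radii) + min_clearance))
        else:
            ok = True
        if ok:
            cells.append(cand)
            p0s = np.vstack([p0s, cand.p0])
            p1s = np.vstack([p1s, cand.p1])
            radii = np.append(radii, cand.radius)
            tracker.add(cand)
            stall = 0
        else:
            stall += 1
            if stall >= max_stall:
                if stage + 1 < len(stages) and min_clearance == 0.0:
                    stage += 1
                    stall = 0
                else:
                    warnings.warn(
                        f"loose placement stalled at fraction {tracker.fraction:.3f} "
                        f"(target {target:.3f})",
                        stacklevel=2,
                    )
                    break
    return cells, tracker.fraction


# ---- dense placement (hexagonal lines) ------------------------------------- #


def _disc_union_coverage(centers_2d: np.ndarray, rho: float, w: float, h: float, pitch: float) -> float:
    """Fraction of the w x h cross-section covered by discs of radius rho."""
    if rho <= 0 or len(centers_2d) == 0:
        return 0.0
    xs = (np.arange(max(1, int(round(w / pitch)))) + 0.5) * pitch
    ys = (np.arange(max(1, int(round(h / pitch)))) + 0.5) * pitch
    tree = cKDTree(centers_2d)
    pts = np.stack(np.meshgrid(xs, ys, indexing="ij"), axis=-1).reshape(-1, 2)
    d, _ = tree.query(pts, k=1)
    return float((d <= rho).mean())


def _hex_centers(w: float, h: float, s: float, r: float) -> np.ndarray:
    """Hexagonal lattice centers within [r, w-r] x [r, h-r]."""
    row_sep = s * np.sqrt(3.0) / 2.0
    rows = []
    y = r
    j = 0
    while y <= h - r + 1e-9:
        x0 = r + (s / 2.0 if j % 2 else 0.0)
        xs = np.arange(x0, w - r + 1e-9, s)
        if len(xs):
            rows.append(np.stack([xs, np.full_like(xs, y)], axis=1))
        y += row_sep
        j += 1
    if not rows:
        return np.empty((0, 2))
    return np.concatenate(rows)


def _dense_fraction_for_spacing(s: float, w: float, h: float, length: float, r: float) -> float:
    """Predicted union fraction of hex lines of pole-to-pole capsules."""
    centers = _hex_centers(w, h, s, r)
    pitch = r / 8.0
    cov_full = _disc_union_coverage(centers, r, w, h, pitch)
    # end caps: effective radius shrinks over the last r of each line end
    us = (np.arange(4) + 0.5) / 4.0 * r
    cap = 0.0
    for u in us:
        rho = np.sqrt(max(r**2 - (r - u) ** 2, 0.0))
        cap += _disc_union_coverage(centers, rho, w, h, pitch) * (r / 4.0)
    body = max(length - 2 * r, 0.0)
    return (cov_full * body + 2 * cap) / length


def _fill_dense(
    lo,
    hi,
    target: float,
    label: str,
    params: dict[str, CellParams],
    rng: np.random.Generator,
    jitter_factor: float = 0.1,
    cap_to_feasible: bool = False,
) -> tuple[list[CellGeom], float]:
    """Jittered hexagonal lines of pole-to-pole cells hitting a dense target.

    Lines run along the box's longest axis; lattice spacing in the orthogonal
    cross-section is solved by bisection of the coverage model.  Per-line
    jitter is <= ``jitter_factor * radius``.
    """
    lo = np.asarray(lo, float)
    hi = np.asarray(hi, float)
    size = hi - lo
    cp = params.get(label, _GENERIC_CELL)
    r = cp.radius
    axis = int(np.argmax(size))
    o1, o2 = [i for i in range(3) if i != axis]
    w, h = size[o1], size[o2]
    length = size[axis]
    if w < 2 * r or h < 2 * r or length < 2 * r:
        raise ValueError("dense region thinner than one cell diameter")

    s_lo, s_hi = 1.0 * r, 2.2 * r
    f_hi = _dense_fraction_for_spacing(s_lo, w, h, length, r)
    if target > f_hi + 1e-6:
        if not cap_to_feasible:
            raise ValueError(
                f"dense target {target} unreachable in this region "
                f"(max ~{f_hi:.3f} for radius {r} um); enlarge the region or lower the target"
            )
        target = f_hi - 0.005
    for _ in range(40):
        s_mid = 0.5 * (s_lo + s_hi)
        if _dense_fraction_for_spacing(s_mid, w, h, length, r) >= target:
            s_lo = s_mid
        else:
            s_hi = s_mid
    s = 0.5 * (s_lo + s_hi)

    centers = _hex_centers(w, h, s, r)
    cells: list[CellGeom] = []
    cell_len = min(cp.length, length - 2 * r)
    for cx, cy in centers:
        jit = rng.uniform(-jitter_factor * r, jitter_factor * r, size=2)
        c1 = float(np.clip(cx + jit[0], r, w - r))
        c2 = float(np.clip(cy + jit[1], r, h - r))
        # chain pole-to-pole cells along the line: shared axis endpoints keep
        # the union a continuous capsule
        u = r + rng.uniform(0.0, 0.25 * cell_len)  # random phase per line
        start = u
        if start > r:  # leading partial cell down to the box face
            seg0 = max(r, start - cell_len)
            cells.append(_axis_cell(label, lo, axis, o1, o2, c1, c2, seg0, start, r))
        while start < length - r - 1e-9:
            end = min(start + cell_len, length - r)
            if end - start > 1e-6:
                cells.append(_axis_cell(label, lo, axis, o1, o2, c1, c2, start, end, r))
            start = end
    tracker = _OccupancyTracker(lo, hi, pitch=r / 3.0)
    for c in cells:
        tracker.add(c)
    return cells, tracker.fraction


def _axis_cell(label, lo, axis, o1, o2, c1, c2, a, b, r) -> CellGeom:
    p0 = np.zeros(3)
    p1 = np.zeros(3)
    p0[axis], p1[axis] = a, b
    for p in (p0, p1):
        p[o1] = c1
        p[o2] = c2
    return CellGeom(label, tuple(lo + p0), tuple(lo + p1), r)


# --------------------------------------------------------------------------- #
# rasterization
# --------------------------------------------------------------------------- #


def scene_occupancy(scene: SceneGroundTruth, voxel: VoxelSpec) -> dict[str, np.ndarray]:
    """Boolean voxel occupancy per species (voxel center inside any cell)."""
    occ = {sp: np.zeros(voxel.shape, dtype=bool) for sp in scene.species}
    zs, ys, xs = (voxel.centers(a) for a in ("z", "y", "x"))
    for cell in scene.cells:
        r = cell.radius
        lo = np.minimum(cell.p0, cell.p1) - r
        hi = np.maximum(cell.p0, cell.p1) + r
        iz = slice(np.searchsorted(zs, lo[2]), np.searchsorted(zs, hi[2], "right"))
        iy = slice(np.searchsorted(ys, lo[1]), np.searchsorted(ys, hi[1], "right"))
        ix = slice(np.searchsorted(xs, lo[0]), np.searchsorted(xs, hi[0], "right"))
        if iz.start >= iz.stop or iy.start >= iy.stop or ix.start >= ix.stop:
            continue
        zz, yy, xx = np.meshgrid(zs[iz], ys[iy], xs[ix], indexing="ij")
        pts = np.stack([xx.ravel(), yy.ravel(), zz.ravel()], axis=1)
        inside = point_segment_distance(pts, np.asarray(cell.p0), np.asarray(cell.p1)) <= r
        occ[cell.species_id][iz, iy, ix] |= inside.reshape(zz.shape)
    return occ


def rasterize_scene(
    scene: SceneGroundTruth,
    voxel_spec: VoxelSpec | None = None,
    optics_params: OpticsParams | None = None,
    rng_seed: int = 0,
) -> ImageStack:
    """Render the scene into a noisy multichannel stack, one channel per species.

    Channel intensity is ``blur(occupancy) * photon_scale + background``, then
    Poisson shot noise and Gaussian read noise (if enabled).  With zero sigmas
    and noise off the channel is the exact binary occupancy scaled.  One seed
    stream is split per channel so channels are independently noisy but the
    whole stack is reproducible.
    """
    voxel = voxel_spec or VoxelSpec.for_domain(scene.domain_size)
    optics = optics_params or OpticsParams()
    min_r = min((c.radius for c in scene.cells), default=np.inf)
    if max(voxel.dx, voxel.dy, voxel.dz) > min_r:
        warnings.warn(
            f"voxel spacing exceeds the smallest cell radius ({min_r:.2f} um): "
            "geometry is undersampled",
            stacklevel=2,
        )
    occ = scene_occupancy(scene, voxel)
    seeds = np.random.SeedSequence(rng_seed).spawn(max(len(occ), 1))
    channels: dict[str, np.ndarray] = {}
    for (name, o), seed in zip(sorted(occ.items()), seeds):
        channels[name] = _render_channel(o.astype(np.float64), voxel, optics, seed)
    if not channels:  # empty scene: all-background stack
        rng = np.random.default_rng(np.random.SeedSequence(rng_seed))
        channels["empty"] = _render_noise_only(voxel, optics, rng)
    return ImageStack(channels=channels, voxel=voxel)


def _render_channel(
    occupancy: np.ndarray, voxel: VoxelSpec, optics: OpticsParams, seed: np.random.SeedSequence
) -> np.ndarray:
    sx, sy, sz = optics.psf_sigma
    sigma_vox = (sz / voxel.dz, sy / voxel.dy, sx / voxel.dx)
    signal = occupancy
    if any(s > 0 for s in sigma_vox):
        signal = gaussian_filter(signal, sigma=sigma_vox)
    img = signal * optics.photon_scale + optics.background
    if optics.noise:
        rng = np.random.default_rng(seed)
        img = rng.poisson(img).astype(np.float64)
        if optics.read_noise_sigma > 0:
            img += rng.normal(0.0, optics.read_noise_sigma, size=img.shape)
        img = np.maximum(img, 0.0)
    return img


def _render_noise_only(voxel, optics, rng) -> np.ndarray:
    img = np.full(voxel.shape, optics.background, dtype=np.float64)
    if optics.noise:
        img = rng.poisson(img).astype(np.float64)
        if optics.read_noise_sigma > 0:
            img += rng.normal(0.0, optics.read_noise_sigma, size=img.shape)
        img = np.maximum(img, 0.0)
    return img


# --------------------------------------------------------------------------- #
# phage channel
# --------------------------------------------------------------------------- #


def add_phage_channel(
    stack: ImageStack,
    scene: SceneGroundTruth,
    mode: str,
    density: float,
    rng_seed: int = 0,
    species: str | None = None,
    spot_sigma: float = 0.25,
    amplitude: float = 300.0,
    packing_threshold: float = 0.7,
    neighborhood_radius: float = 6.0,
    channel_name: str = "phage",
) -> tuple[ImageStack, np.ndarray]:
    """Add a puncta (labeled phage capsid) channel; returns (stack, centers).

    Modes: ``uniform`` anywhere in the domain; ``excluded_from_dense`` only
    where the ground-truth local packing (ball of ``neighborhood_radius``) is
    <= ``packing_threshold``; ``basal_glass_layer`` with z <= 2 um; and
    ``on_species_mask`` with centers inside cells of ``species``.  ``density``
    is spots per um^3 of the eligible volume.
    """
    if mode not in PHAGE_MODES:
        raise ValueError(f"unknown phage mode {mode!r}; expected one of {PHAGE_MODES}")
    rng = np.random.default_rng(rng_seed)
    domain = np.asarray(scene.domain_size, float)

    if mode == "on_species_mask":
        if species is None:
            raise ValueError("mode='on_species_mask' requires species=")
        centers = _centers_in_cells(scene.cells_of(species), density, rng)
    elif mode == "basal_glass_layer":
        vol = domain[0] * domain[1] * min(2.0, domain[2])
        n = rng.poisson(density * vol)
        centers = rng.uniform([0, 0, 0], [domain[0], domain[1], min(2.0, domain[2])], size=(n, 3))
    elif mode == "uniform":
        n = rng.poisson(density * float(np.prod(domain)))
        centers = rng.uniform(0, domain, size=(n, 3))
    else:  # excluded_from_dense
        field, pitch, origin = local_packing_field(scene, radius=neighborhood_radius)
        n = rng.poisson(density * float(np.prod(domain)))
        centers = []
        attempts = 0
        while len(centers) < n and attempts < 50 * max(n, 1):
            p = rng.uniform(0, domain)
            idx = np.minimum(((p - origin) / pitch).astype(int), np.asarray(field.shape) - 1)
            if field[tuple(idx)] <= packing_threshold:
                centers.append(p)
            attempts += 1
        centers = np.asarray(centers).reshape(-1, 3)

    channel = _render_spots(centers, stack.voxel, spot_sigma, amplitude)
    return stack.with_channel(channel_name, channel), centers


def _centers_in_cells(cells, density: float, rng: np.random.Generator) -> np.ndarray:
    if not cells:
        return np.empty((0, 3))
    vols = np.asarray([c.volume for c in cells])
    n = rng.poisson(density * vols.sum())
    picks = rng.choice(len(cells), size=n, p=vols / vols.sum())
    out = []
    for i in picks:
        c = cells[i]
        lo = np.minimum(c.p0, c.p1) - c.radius
        hi = np.maximum(c.p0, c.p1) + c.radius
        for _ in range(100):
            p = rng.uniform(lo, hi)
            if point_segment_distance(p[None], np.asarray(c.p0), np.asarray(c.p1))[0] <= c.radius:
                out.append(p)
                break
    return np.asarray(out).reshape(-1, 3)


def _render_spots(centers: np.ndarray, voxel: VoxelSpec, sigma: float, amplitude: float) -> np.ndarray:
    img = np.zeros(voxel.shape, dtype=np.float64)
    zs, ys, xs = (voxel.centers(a) for a in ("z", "y", "x"))
    reach = 3.0 * sigma
    for cx, cy, cz in centers:
        iz = slice(np.searchsorted(zs, cz - reach), np.searchsorted(zs, cz + reach, "right"))
        iy = slice(np.searchsorted(ys, cy - reach), np.searchsorted(ys, cy + reach, "right"))
        ix = slice(np.searchsorted(xs, cx - reach), np.searchsorted(xs, cx + reach, "right"))
        zz, yy, xx = np.meshgrid(zs[iz], ys[iy], xs[ix], indexing="ij")
        d2 = (xx - cx) ** 2 + (yy - cy) ** 2 + (zz - cz) ** 2
        img[iz, iy, ix] += amplitude * np.exp(-d2 / (2.0 * sigma**2))
    return img


# --------------------------------------------------------------------------- #
# ground-truth local packing
# --------------------------------------------------------------------------- #


def true_local_fraction(
    scene: SceneGroundTruth,
    point,
    radius: float,
    pitch: float = 0.1,
) -> float:
    """Oracle local biovolume fraction: supersampled point-membership tests.

    Fraction of the ball of ``radius`` around ``point`` (clipped to the
    domain) occupied by any cell, evaluated on a grid of ``pitch`` um — at
    least 5x finer than the default 0.5 um axial analysis voxel.  This is the
    module-independent reference for the cube neighborhood-packing metric.
    """
    if radius <= 0:
        raise ValueError("radius must be > 0")
    point = np.asarray(point, float)
    domain = np.asarray(scene.domain_size, float)
    if np.any(point < 0) or np.any(point > domain):
        raise ValueError(f"point {tuple(point)} lies outside the domain {tuple(domain)}")

    lo = np.maximum(point - radius, 0.0)
    hi = np.minimum(point + radius, domain)
    tracker = _OccupancyTracker(lo, hi, pitch)
    reach = radius + max((c.radius + c.axis_length / 2 for c in scene.cells), default=0.0)
    for cell in scene.cells:
        if np.linalg.norm(cell.centroid - point) <= reach:
            tracker.add(cell)
    xx, yy, zz = np.meshgrid(*tracker.axes, indexing="ij")
    in_ball = (xx - point[0]) ** 2 + (yy - point[1]) ** 2 + (zz - point[2]) ** 2 <= radius**2
    n_ball = int(in_ball.sum())
    if n_ball == 0:
        return 0.0
    return float(tracker.grid[in_ball].sum() / n_ball)


def local_packing_field(
    scene: SceneGroundTruth, radius: float = 6.0, pitch: float = 0.25
) -> tuple[np.ndarray, float, np.ndarray]:
    """Grid of ground-truth local packing fractions over the whole domain.

    Occupancy is rasterized at ``pitch`` and convolved with a ball kernel; the
    denominator is the in-bounds ball volume.  Returns ``(field, pitch,
    origin)`` with the field indexed ``[x, y, z]`` from ``origin``.  A fast
    approximation used where per-point supersampling would be too costly
    (phage placement, survivor filtering); tests check it against
    :func:`true_local_fraction`.
    """
    domain = np.asarray(scene.domain_size, float)
    n = np.maximum(1, np.round(domain / pitch).astype(int))
    tracker = _OccupancyTracker(np.zeros(3), domain, pitch)
    for c in scene.cells:
        tracker.add(c)
    occ = tracker.grid.astype(np.float64)
    k = int(np.floor(radius / pitch))
    ax = (np.arange(-k, k + 1)) * pitch
    kx, ky, kz = np.meshgrid(ax, ax, ax, indexing="ij")
    kernel = ((kx**2 + ky**2 + kz**2) <= radius**2).astype(np.float64)
    num = fftconvolve(occ, kernel, mode="same")
    den = fftconvolve(np.ones_like(occ), kernel, mode="same")
    field = np.clip(num / den, 0.0, 1.0)
    return field, pitch, np.zeros(3)


def remove_unprotected(
    scene: SceneGroundTruth,
    species: str,
    packing_threshold: float = 0.7,
    radius: float = 6.0,
) -> SceneGroundTruth:
    """Phage-killing filter: drop focal-species cells outside dense shelter.

    Cells of ``species`` whose ground-truth local packing (ball of ``radius``)
    at the cell centroid is <= ``packing_threshold`` are removed — emulating
    phage exposure sparing only cells embedded in highly packed clusters.
    """
    field, pitch, origin = local_packing_field(scene, radius=radius)
    shape = np.asarray(field.shape)
    keep = []
    for c in scene.cells:
        if c.species_id != species:
            keep.append(True)
            continue
        idx = np.minimum(((c.centroid - origin) / pitch).astype(int), shape - 1)
        keep.append(bool(field[tuple(idx)] > packing_threshold))
    return scene.filtered(keep)
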