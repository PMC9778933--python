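"""Thresholding, mask cleanup, species-mask merging, and grid-cube dissection.

Segmentation here is deliberately simple (Otsu or fixed threshold per
channel) because every downstream metric is mask- or cube-based rather than
single-cell-resolved.  Thresholds and cleanup parameters are returned as a
provenance record so runs can be logged and reproduced.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage as ndi
from skimage.filters import threshold_otsu

from .stack import GridCubeSet, ImageStack, SpeciesMask

__all__ = [
    "threshold_channel",
    "clean_mask",
    "merge_masks",
    "dissect_grid",
    "resolve_species_overlaps",
    "segment_stack",
]

#: 26-connectivity structuring element for components and hole filling.
STRUCT_26 = np.ones((3, 3, 3), dtype=bool)


def threshold_channel(
    stack: ImageStack,
    channel: str,
    method: str = "otsu",
    manual_value: float | None = None,
) -> tuple[SpeciesMask, dict]:
    """Binarize one channel; returns (mask, provenance).

    ``method='otsu'`` picks the threshold automatically (parameter-free and
    reproducible); ``method='fixed'`` requires ``manual_value``.  A voxel is
    foreground when intensity >= threshold.
    """
    data = stack.channel(channel)
    if method == "otsu":
        if float(data.max()) == float(data.min()):
            raise ValueError(
                f"channel {channel!r} has constant intensity; Otsu is undefined — "
                "use method='fixed' with an explicit threshold"
            )
        thr = float(threshold_otsu(data))
    elif method == "fixed":
        if manual_value is None:
            raise ValueError("method='fixed' requires manual_value")
        thr = float(manual_value)
    else:
        raise ValueError(f"unknown threshold method {method!r}")
    mask = SpeciesMask(label=channel, voxels=data >= thr, voxel=stack.voxel)
    return mask, {"channel": channel, "method": method, "threshold": thr}


def clean_mask(
    mask: SpeciesMask, min_volume_um3: float = 0.0, fill_holes: bool = False
) -> SpeciesMask:
    """Drop 26-connected components smaller than ``min_volume_um3``; optionally
    fill enclosed 3D cavities.  Biovolume is non-increasing unless holes are
    filled."""
    if min_volume_um3 < 0:
        raise ValueError("min_volume_um3 must be >= 0")
    out = mask.voxels.copy()
    if min_volume_um3 > 0:
        labels, n = ndi.label(out, structure=STRUCT_26)
        if n:
            sizes = np.bincount(labels.ravel())
            min_vox = min_volume_um3 / mask.voxel.voxel_volume
            drop = sizes < min_vox
            drop[0] = False
            out[drop[labels]] = False
    if fill_holes:
        out = ndi.binary_fill_holes(out, structure=STRUCT_26)
    return SpeciesMask(label=mask.label, voxels=out, voxel=mask.voxel)


def merge_masks(masks: list[SpeciesMask], label: str = "joint") -> SpeciesMask:
    """Voxelwise OR of all masks — the merged all-species biomass."""
    if not masks:
        raise ValueError("merge_masks needs at least one mask")
    voxel = masks[0].voxel
    out = np.zeros(voxel.shape, dtype=bool)
    for m in masks:
        if m.voxels.shape != out.shape or m.voxel != voxel:
            raise ValueError(
                f"mask {m.label!r} geometry {m.voxels.shape} does not match {out.shape}"
            )
        out |= m.voxels
    return SpeciesMask(label=label, voxels=out, voxel=voxel)


def resolve_species_overlaps(
    stack: ImageStack, masks: dict[str, SpeciesMask]
) -> dict[str, SpeciesMask]:
    """Make per-species masks exclusive where several channels crossed threshold.

    A contested voxel goes to the channel with the higher background-normalized
    intensity (channel median as background proxy), so per-species biovolumes
    stay additive.  The joint mask should be built from the pre-resolution
    masks (space occupied by anything is not double-counted either way).
    """
    names = list(masks)
    if len(names) < 2:
        return dict(masks)
    norm = {}
    for n in names:
        ch = stack.channel(n).astype(np.float64)
        bg = float(np.median(ch))
        norm[n] = ch / max(bg, 1e-12)
    stackmask = np.stack([masks[n].voxels for n in names])
    contested = stackmask.sum(axis=0) > 1
    if not contested.any():
        return dict(masks)
    scores = np.stack([np.where(masks[n].voxels, norm[n], -np.inf) for n in names])
    winner = np.argmax(scores, axis=0)
    out = {}
    for i, n in enumerate(names):
        vox = masks[n].voxels & (~contested | (winner == i))
        out[n] = SpeciesMask(label=n, voxels=vox, voxel=masks[n].voxel)
    return out


def dissect_grid(mask: SpeciesMask, cube_edge_um: float = 0.8) -> GridCubeSet:
    """Partition foreground voxels into cubes of ``cube_edge_um`` (default the
    standard 0.8 um grid node).

    Voxels are binned by ``floor(center / edge)`` per axis; the union of cube
    members is exactly the mask foreground and every reported cube is
    non-empty.  ``cube_edge_um`` must resolve the voxel grid (>= max spacing).
    """
    v = mask.voxel
    if cube_edge_um < max(v.dx, v.dy, v.dz) - 1e-12:
        raise ValueError(
            f"cube edge {cube_edge_um} um is smaller than the largest voxel "
            f"spacing {max(v.dx, v.dy, v.dz)} um and cannot be resolved"
        )
    zz, yy, xx = np.nonzero(mask.voxels)
    coords = np.stack([zz, yy, xx], axis=1)
    cx_um = (xx + 0.5) * v.dx
    cy_um = (yy + 0.5) * v.dy
    cz_um = (zz + 0.5) * v.dz
    bins = np.stack(
        [
            np.floor(cx_um / cube_edge_um).astype(np.int64),
            np.floor(cy_um / cube_edge_um).astype(np.int64),
            np.floor(cz_um / cube_edge_um).astype(np.int64),
        ],
        axis=1,
    )
    if len(bins) == 0:
        return GridCubeSet(
            cube_edge=cube_edge_um,
            parent_label=mask.label,
            voxel=v,
            cube_indices=np.empty((0, 3), np.int64),
            centroids_um=np.empty((0, 3)),
            voxel_zyx=coords,
            cube_id=np.empty((0,), np.int64),
        )
    uniq, cube_id = np.unique(bins, axis=0, return_inverse=True)
    pos = np.stack([cx_um, cy_um, cz_um], axis=1)
    n = len(uniq)
    centroids = np.zeros((n, 3))
    counts = np.bincount(cube_id, minlength=n).astype(np.float64)
    for k in range(3):
        centroids[:, k] = np.bincount(cube_id, weights=pos[:, k], minlength=n) / counts
    return GridCubeSet(
        cube_edge=cube_edge_um,
        parent_label=mask.label,
        voxel=v,
        cube_indices=uniq,
        centroids_um=centroids,
        voxel_zyx=coords,
        cube_id=cube_id,
    )


def segment_stack(
    stack: ImageStack,
    channels: list[str],
    method: str = "otsu",
    manual_values: dict[str, float] | None = None,
    min_volume_um3: float = 0.0,
    fill_holes: bool = False,
    exclusive: bool = True,
) -> tuple[dict[str, SpeciesMask], SpeciesMask, dict]:
    """Segment several species channels and build the joint biomass mask.

    Returns ``(species_masks, joint_mask, provenance)``.  The joint mask is the
    OR of the raw (pre-exclusivity) masks; per-species masks are made exclusive
    by relative brightness when ``exclusive``.
    """
    manual_values = manual_values or {}
    raw: dict[str, SpeciesMask] = {}
    prov: dict = {"channels": {}}
    for ch in channels:
        m, p = threshold_channel(stack, ch, method=method, manual_value=manual_values.get(ch))
        m = clean_mask(m, min_volume_um3=min_volume_um3, fill_holes=fill_holes)
        raw[ch] = m
        prov["channels"][ch] = p
    prov["min_volume_um3"] = min_volume_um3
    prov["fill_holes"] = fill_holes
    prov["exclusive"] = exclusive
    joint = merge_masks(list(raw.values()))
    species = resolve_species_overlaps(stack, raw) if exclusive else raw
    return species, joint, prov
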