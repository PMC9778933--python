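"""Image containers: multichannel stacks, binary species masks, grid cubes.

All image arrays are ``[z, y, x]``; physical geometry travels with the data as
a :class:`~packfrac.geometry.VoxelSpec`.  Stacks round-trip through OME-TIFF
(``tifffile``) with PhysicalSizeX/Y/Z and channel names set.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import tifffile

from .geometry import VoxelSpec

__all__ = ["ImageStack", "SpeciesMask", "GridCubeSet"]


@dataclass
class ImageStack:
    """Named 3D intensity channels sharing one voxel geometry."""

    channels: dict[str, np.ndarray]
    voxel: VoxelSpec
    timepoint: float | None = None  # hours

    def __post_init__(self) -> None:
        for name, arr in self.channels.items():
            if arr.shape != self.voxel.shape:
                raise ValueError(
                    f"channel {name!r} shape {arr.shape} != voxel shape {self.voxel.shape}"
                )
            if arr.size and float(arr.min()) < 0:
                raise ValueError(f"channel {name!r} has negative intensities")

    @property
    def channel_names(self) -> list[str]:
        return list(self.channels)

    def channel(self, name: str) -> np.ndarray:
        try:
            return self.channels[name]
        except KeyError:
            raise KeyError(
                f"no channel {name!r}; available: {self.channel_names}"
            ) from None

    def with_channel(self, name: str, data: np.ndarray) -> "ImageStack":
        ch = dict(self.channels)
        ch[name] = data
        return ImageStack(channels=ch, voxel=self.voxel, timepoint=self.timepoint)

    # --- I/O -----------------------------------------------------------------

    def to_tiff(self, path: str | Path) -> None:
        """Write an OME-TIFF (CZYX) with physical voxel sizes and channel names."""
        data = np.stack([self.channels[n] for n in self.channel_names])
        tifffile.imwrite(
            str(path),
            data.astype(np.float32),
            ome=True,
            metadata={
                "axes": "CZYX",
                "PhysicalSizeX": self.voxel.dx,
                "PhysicalSizeY": self.voxel.dy,
                "PhysicalSizeZ": self.voxel.dz,
                "Channel": {"Name": self.channel_names},
            },
        )

    @classmethod
    def from_tiff(
        cls,
        path: str | Path,
        channel_names: list[str] | None = None,
        voxel: VoxelSpec | None = None,
    ) -> "ImageStack":
        """Read a (OME-)TIFF stack.

        Channel names and voxel sizes are taken from OME metadata when present;
        ``channel_names`` / ``voxel`` override or supply them for plain TIFFs.
        """
        with tifffile.TiffFile(str(path)) as tf:
            series = tf.series[0]
            data = series.asarray()
            axes = series.axes
            meta_names: list[str] | None = None
            sizes = None
            if tf.ome_metadata:
                ome = tifffile.xml2dict(tf.ome_metadata)
                img = ome["OME"]["Image"]
                if isinstance(img, list):
                    img = img[0]
                px = img["Pixels"]
                sizes = (
                    float(px.get("PhysicalSizeX", 0) or 0),
                    float(px.get("PhysicalSizeY", 0) or 0),
                    float(px.get("PhysicalSizeZ", 0) or 0),
                )
                chans = px.get("Channel", [])
                if isinstance(chans, dict):
                    chans = [chans]
                names = [c.get("Name") for c in chans]
                if names and all(names):
                    meta_names = [str(n) for n in names]
        if axes == "ZYX":
            data = data[None]
        elif axes == "CZYX":
            pass
        elif axes == "ZCYX":
            data = np.moveaxis(data, 1, 0)
        else:
            raise ValueError(f"unsupported TIFF axes {axes!r}")
        n_ch = data.shape[0]
        names = channel_names or meta_names or [f"ch{i}" for i in range(n_ch)]
        if len(names) != n_ch:
            raise ValueError(f"{len(names)} channel names for {n_ch} channels")
        if voxel is None:
            if not sizes or min(sizes) <= 0:
                raise ValueError(
                    "voxel sizes not found in metadata; pass voxel= explicitly"
                )
            voxel = VoxelSpec(dx=sizes[0], dy=sizes[1], dz=sizes[2], shape=data.shape[1:])
        return cls(channels={n: data[i] for i, n in enumerate(names)}, voxel=voxel)


@dataclass
class SpeciesMask:
    """Binary foreground mask for one species (or the merged joint biomass)."""

    label: str
    voxels: np.ndarray  # bool, [z, y, x]
    voxel: VoxelSpec

    def __post_init__(self) -> None:
        if self.voxels.shape != self.voxel.shape:
            raise ValueError(
                f"mask shape {self.voxels.shape} != voxel shape {self.voxel.shape}"
            )
        if self.voxels.dtype != bool:
            self.voxels = self.voxels.astype(bool)

    @property
    def biovolume(self) -> float:
        """Foreground voxel count times voxel volume (um^3)."""
        return float(self.voxels.sum()) * self.voxel.voxel_volume

    def to_tiff(self, path: str | Path) -> None:
        tifffile.imwrite(
            str(path),
            self.voxels.astype(np.uint8) * 255,
            ome=True,
            metadata={
                "axes": "ZYX",
                "PhysicalSizeX": self.voxel.dx,
                "PhysicalSizeY": self.voxel.dy,
                "PhysicalSizeZ": self.voxel.dz,
                "Channel": {"Name": [self.label]},
            },
        )


@dataclass
class GridCubeSet:
    """Foreground voxels of one mask partitioned into axis-aligned cubes.

    ``cube_indices`` holds the integer grid index ``(cx, cy, cz)`` of each cube
    (cube c spans ``[c*edge, (c+1)*edge)`` per axis); ``centroids_um`` the mean
    position ``(x, y, z)`` of its member voxel centers.  ``voxel_zyx`` /
    ``cube_id`` map every foreground voxel to its cube: together the cubes
    partition the foreground exactly (disjoint and covering).
    """

    cube_edge: float
    parent_label: str
    voxel: VoxelSpec
    cube_indices: np.ndarray  # (N, 3) int, (cx, cy, cz)
    centroids_um: np.ndarray  # (N, 3) float, (x, y, z)
    voxel_zyx: np.ndarray  # (M, 3) int
    cube_id: np.ndarray  # (M,) int into cubes

    @property
    def n_cubes(self) -> int:
        return len(self.cube_indices)

    @property
    def counts(self) -> np.ndarray:
        return np.bincount(self.cube_id, minlength=self.n_cubes)

    def members(self, i: int) -> np.ndarray:
        """Voxel coordinates (zyx) belonging to cube ``i``."""
        return self.voxel_zyx[self.cube_id == i]

    def member_lists(self) -> list[np.ndarray]:
        order = np.argsort(self.cube_id, kind="stable")
        split = np.searchsorted(self.cube_id[order], np.arange(1, self.n_cubes))
        return np.split(self.voxel_zyx[order], split)
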