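"""Text-format exports: ground-truth CSV/JSON, metric fields as TIFF and VTK."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .geometry import CellGeom, Region, SceneGroundTruth, VoxelSpec

__all__ = [
    "scene_to_csv",
    "scene_from_csv",
    "regions_to_json",
    "regions_from_json",
    "fraction_field_to_tiff",
    "field_to_vtk",
]


def scene_to_csv(scene: SceneGroundTruth, path: str | Path) -> None:
    """One row per cell: species, axis endpoints, radius (all um)."""
    rows = [
        {
            "species": c.species_id,
            "p0x": c.p0[0], "p0y": c.p0[1], "p0z": c.p0[2],
            "p1x": c.p1[0], "p1y": c.p1[1], "p1z": c.p1[2],
            "radius": c.radius,
        }
        for c in scene.cells
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def scene_from_csv(
    path: str | Path, domain_size: tuple[float, float, float]
) -> SceneGroundTruth:
    df = pd.read_csv(path)
    cells = [
        CellGeom(
            str(r.species),
            (r.p0x, r.p0y, r.p0z),
            (r.p1x, r.p1y, r.p1z),
            float(r.radius),
        )
        for r in df.itertuples()
    ]
    return SceneGroundTruth(cells=cells, domain_size=domain_size)


def regions_to_json(scene: SceneGroundTruth, path: str | Path) -> None:
    """Region manifest: plan plus realized packing per region."""
    payload = {
        "domain_size": list(scene.domain_size),
        "rng_seed": scene.rng_seed,
        "regions": [
            {
                "name": r.name,
                "lo": list(r.lo),
                "hi": list(r.hi),
                "target_packing": r.target_packing,
                "architecture": r.architecture,
                "species": list(r.species),
                "basal_height_um": r.basal_height_um,
                "placement": r.placement,
                "realized_packing": scene.realized_packing.get(r.name),
            }
            for r in scene.regions
        ],
    }
    Path(path).write_text(json.dumps(payload, indent=2))


def regions_from_json(path: str | Path) -> list[Region]:
    payload = json.loads(Path(path).read_text())
    return [
        Region(
            name=r["name"],
            lo=tuple(r["lo"]),
            hi=tuple(r["hi"]),
            target_packing=r["target_packing"],
            architecture=r["architecture"],
            species=tuple(r.get("species", ())),
            basal_height_um=r.get("basal_height_um", 2.0),
            placement=r.get("placement", "auto"),
        )
        for r in payload["regions"]
    ]


def fraction_field_to_tiff(field: np.ndarray, voxel: VoxelSpec, path: str | Path) -> None:
    """Fraction field in [0, 1] stored as 16-bit (x 1e4) single-channel TIFF."""
    data = np.clip(np.nan_to_num(field, nan=0.0), 0.0, 1.0)
    tifffile.imwrite(
        str(path),
        np.round(data * 1e4).astype(np.uint16),
        ome=True,
        metadata={
            "axes": "ZYX",
            "PhysicalSizeX": voxel.dx,
            "PhysicalSizeY": voxel.dy,
            "PhysicalSizeZ": voxel.dz,
        },
    )


def field_to_vtk(field: np.ndarray, voxel: VoxelSpec, path: str | Path, name: str = "fraction") -> None:
    """Legacy ASCII VTK structured-points export for 3D rendering tools.

    The field is written in VTK's x-fastest order from the ``[z, y, x]``
    array; spacing carries the physical voxel sizes.
    """
    nz, ny, nx = field.shape
    values = np.nan_to_num(np.asarray(field, dtype=np.float32), nan=0.0)
    lines = [
        "# vtk DataFile Version 3.0",
        name,
        "ASCII",
        "DATASET STRUCTURED_POINTS",
        f"DIMENSIONS {nx} {ny} {nz}",
        f"ORIGIN 0 0 0",
        f"SPACING {voxel.dx} {voxel.dy} {voxel.dz}",
        f"POINT_DATA {nx * ny * nz}",
        f"SCALARS {name} float 1",
        "LOOKUP_TABLE default",
    ]
    flat = values.transpose(0, 1, 2).ravel()  # z slowest, x fastest
    lines.extend(" ".join(f"{v:.6g}" for v in flat[i : i + 9]) for i in range(0, len(flat), 9))
    Path(path).write_text("\n".join(lines) + "\n")
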