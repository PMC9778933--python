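import warnings

import numpy as np
import pytest

from packfrac.geometry import Region, VoxelSpec
from packfrac.scene import OpticsParams, generate_scene, rasterize_scene

warnings.filterwarnings("ignore", message="neighborhood radius")
warnings.filterwarnings("ignore", message="voxel spacing exceeds")


@pytest.fixture(scope="session")
def loose_scene():
    """One loose mixed cluster spanning a 12x12x6 um chamber, target 0.45."""
    region = Region("loose", (0, 0, 0), (12, 12, 6), 0.45, "loose_cluster")
    return generate_scene((12, 12, 6), [region], rng_seed=7)


@pytest.fixture(scope="session")
def embedded_scene():
    """Embedded-basal-layer architecture at the dense (0.9) packing target."""
    region = Region(
        "emb",
        (0, 0, 0),
        (16, 16, 8),
        0.9,
        "embedded_basal_layer",
        species=("vibrio", "ecoli"),
        basal_height_um=2.0,
    )
    return generate_scene((16, 16, 8), [region], rng_seed=3)


@pytest.fixture(scope="session")
def loose_stack(loose_scene):
    voxel = VoxelSpec.for_domain(loose_scene.domain_size)
    return rasterize_scene(loose_scene, voxel, OpticsParams(), rng_seed=8)


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def make_mask(arr, dx=1.0, dy=1.0, dz=1.0, label="test"):
    """Convenience wrapper: boolean array + voxel geometry -> SpeciesMask."""
    from packfrac.stack import SpeciesMask

    arr = np.asarray(arr, dtype=bool)
    return SpeciesMask(
        label=label, voxels=arr, voxel=VoxelSpec(dx=dx, dy=dy, dz=dz, shape=arr.shape)
    )
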