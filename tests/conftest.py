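import numpy as np
import pytest

from bametrics.phantoms import (BrainPhantomSpec, LesionSeed, TubePhantomSpec,
                                lesion_center_for, make_brain_phantom,
                                make_tube_phantom)


@pytest.fixture(scope="session")
def straight_tube():
    spec = TubePhantomSpec(centerline_kind="straight", length_mm=50.0, seed=2)
    return spec, *make_tube_phantom(spec)


@pytest.fixture(scope="session")
def helix_tube():
    spec = TubePhantomSpec(centerline_kind="helix", helix_radius_mm=8.0,
                           helix_pitch_mm=10.0, helix_turns=1.0, seed=1)
    return spec, *make_tube_phantom(spec)


@pytest.fixture(scope="session")
def two_lesion_phantom():
    spec = BrainPhantomSpec(seed=3)
    spec.lesions = [
        LesionSeed(lesion_center_for(spec, "frontal", 2), 3.0, "frontal", 2),
        LesionSeed(lesion_center_for(spec, "occipital", 3), 3.0, "occipital", 3),
    ]
    return spec, make_brain_phantom(spec)


@pytest.fixture(scope="session")
def concentric_sphere_masks():
    """Odd-sized grid so an exact mid-surface voxel exists (r = 40 on axis)."""
    from bametrics.grids import VoxelGrid, axis_aligned_affine

    n = 131
    aff = axis_aligned_affine((1.0, 1.0, 1.0))
    c = (n - 1) / 2
    idx = np.indices((n, n, n)).astype(float)
    r = np.sqrt(((idx - c) ** 2).sum(axis=0))
    vent = VoxelGrid((r <= 20).astype(np.uint8), aff)
    ctx = VoxelGrid((r >= 60).astype(np.uint8), aff)
    return vent, ctx, r
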