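"""Voxel grids and landmark sets.

All geometry in this package lives in world millimetres. A :class:`VoxelGrid`
couples a 3D scalar (or label) array with an invertible affine mapping 0-based
voxel indices to world mm, exactly as a NIfTI-1 header does. Voxel spacing is
anisotropic in general (time-of-flight angiography is acquired at
0.357 x 0.357 x 0.5 mm), so no computation may treat index space as metric.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import nibabel as nib
import numpy as np

#: Canonical names of the four basilar-artery landmarks, annotated caudally:
#: the basilar apex, the AICA origin, the vertebral fusion point, and the PICA
#: origin in the larger vertebral artery.
LANDMARK_NAMES = ("BA_apex", "AICA_origin", "VA_fusion", "PICA_origin")


@dataclass
class VoxelGrid:
    """A 3D scalar volume with an affine voxel-to-world transform.

    Parameters
    ----------
    values
        3D array of intensities or labels.
    affine
        4x4 voxel-index (0-based) to world-mm transform. Must be invertible.
    """

    values: np.ndarray
    affine: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise ValueError(f"expected a 3D array, got shape {self.values.shape}")
        self.affine = np.asarray(self.affine, dtype=float)
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if abs(np.linalg.det(self.affine[:3, :3])) < 1e-12:
            raise ValueError("affine is singular")
        if np.any(self.spacing <= 0):
            raise ValueError("voxel spacing must be strictly positive")

    @property
    def spacing(self) -> np.ndarray:
        """Physical voxel size (mm) along each array axis."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    @property
    def voxel_volume_ml(self) -> float:
        """Volume of a single voxel in millilitres."""
        return float(abs(np.linalg.det(self.affine[:3, :3]))) / 1000.0

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    def voxel_to_world(self, idx: np.ndarray) -> np.ndarray:
        """Map (..., 3) voxel indices to world mm."""
        idx = np.asarray(idx, dtype=float)
        return idx @ self.affine[:3, :3].T + self.affine[:3, 3]

    def world_to_voxel(self, xyz: np.ndarray) -> np.ndarray:
        """Map (..., 3) world-mm points to (fractional) voxel indices."""
        xyz = np.asarray(xyz, dtype=float)
        inv = np.linalg.inv(self.affine)
        return xyz @ inv[:3, :3].T + inv[:3, 3]

    def contains_world(self, xyz: np.ndarray) -> np.ndarray:
        """True where world points fall inside the voxel lattice."""
        v = self.world_to_voxel(xyz)
        lo = v >= -0.5
        hi = v <= np.asarray(self.shape) - 0.5
        return np.all(lo & hi, axis=-1)

    # -- NIfTI round trip ---------------------------------------------------
    def to_nifti(self) -> nib.Nifti1Image:
        return nib.Nifti1Image(self.values, self.affine)

    def save(self, path) -> None:
        nib.save(self.to_nifti(), str(path))

    @classmethod
    def load(cls, path) -> "VoxelGrid":
        img = nib.load(str(path))
        return cls(np.asarray(img.dataobj), img.affine)


@dataclass
class LandmarkSet:
    """The four named basilar-artery landmarks, in world mm.

    Order follows the caudal annotation direction: apex (1), AICA origin (2),
    vertebral fusion (3), PICA origin (4).
    """

    points: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [n for n in LANDMARK_NAMES if n not in self.points]
        if missing:
            raise ValueError(f"missing landmarks: {missing}")
        self.points = {n: np.asarray(self.points[n], dtype=float) for n in LANDMARK_NAMES}
        arr = self.as_array()
        d = np.linalg.norm(arr[:, None] - arr[None, :], axis=-1)
        if np.any(d[np.triu_indices(4, 1)] < 1e-9):
            raise ValueError("landmarks must be pairwise distinct")

    def __getitem__(self, name: str) -> np.ndarray:
        return self.points[name]

    def as_array(self) -> np.ndarray:
        """(4, 3) array in canonical order."""
        return np.stack([self.points[n] for n in LANDMARK_NAMES])

    def to_json_dict(self) -> dict:
        return {n: [float(v) for v in self.points[n]] for n in LANDMARK_NAMES}

    @classmethod
    def from_json_dict(cls, d: dict) -> "LandmarkSet":
        return cls({k: np.asarray(v, dtype=float) for k, v in d.items()})


def axis_aligned_affine(spacing, origin=(0.0, 0.0, 0.0)) -> np.ndarray:
    """RAS-like axis-aligned affine with positive spacing."""
    a = np.eye(4)
    a[0, 0], a[1, 1], a[2, 2] = spacing
    a[:3, 3] = origin
    return a
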