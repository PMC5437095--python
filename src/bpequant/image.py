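"""Volumetric image containers and NIfTI I/O.

Axis convention throughout the package: axis 0 = slice (superior-inferior),
axis 1 = row (anterior -> posterior), axis 2 = column (right -> left).
All physical volumes are reported in cm^3; spacing is in mm per axis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import nibabel as nib
import numpy as np

from .errors import GridMismatchError

__all__ = ["ImageVolume", "DceStudy", "BreastMask", "FgtMask", "voxel_volume_cm3"]


def voxel_volume_cm3(spacing_mm: tuple[float, float, float]) -> float:
    """Physical volume of one voxel in cm^3 (product of spacings / 1000)."""
    return float(np.prod(spacing_mm)) / 1000.0


@dataclass
class ImageVolume:
    """A 3D scalar grid with physical voxel spacing.

    Parameters
    ----------
    voxels : ndarray, shape (n_slices, n_rows, n_cols)
        Scalar signal values in arbitrary units.
    spacing_mm : tuple of float
        Per-axis voxel size in millimetres (slice, row, column).
    """

    voxels: np.ndarray
    spacing_mm: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=np.float64)
        if self.voxels.ndim != 3:
            raise ValueError(f"expected a 3D grid, got ndim={self.voxels.ndim}")
        self.spacing_mm = tuple(float(s) for s in self.spacing_mm)
        if len(self.spacing_mm) != 3 or any(s <= 0 for s in self.spacing_mm):
            raise ValueError(f"spacing must be three positive values, got {self.spacing_mm}")
        if not np.all(np.isfinite(self.voxels)):
            raise ValueError("voxel values must be finite")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    @property
    def voxel_volume_cm3(self) -> float:
        return voxel_volume_cm3(self.spacing_mm)

    def same_grid(self, other: "ImageVolume") -> bool:
        return self.shape == other.shape and np.allclose(self.spacing_mm, other.spacing_mm)

    def require_same_grid(self, other: "ImageVolume") -> None:
        if not self.same_grid(other):
            raise GridMismatchError(
                f"grids differ: {self.shape}/{self.spacing_mm} vs {other.shape}/{other.spacing_mm}"
            )

    # --- NIfTI round trip -------------------------------------------------
    def to_nifti(self, path) -> None:
        affine = np.diag(list(self.spacing_mm) + [1.0])
        nib.save(nib.Nifti1Image(self.voxels.astype(np.float32), affine), str(path))

    @classmethod
    def from_nifti(cls, path) -> "ImageVolume":
        img = nib.load(str(path))
        spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
        return cls(np.asanyarray(img.dataobj, dtype=np.float64), spacing)


@dataclass
class DceStudy:
    """One pre-contrast volume plus three post-contrast volumes on a common grid."""

    pre: ImageVolume
    posts: tuple[ImageVolume, ImageVolume, ImageVolume]

    def __post_init__(self) -> None:
        self.posts = tuple(self.posts)
        if len(self.posts) != 3:
            raise ValueError(f"a DCE study needs exactly 3 post-contrast volumes, got {len(self.posts)}")
        for p in self.posts:
            self.pre.require_same_grid(p)

    def subtraction(self, sub_index: int) -> ImageVolume:
        """Subtraction volume SUB<k> = post_k - pre (k in 1..3)."""
        if sub_index not in (1, 2, 3):
            raise ValueError(f"sub_index must be 1, 2 or 3, got {sub_index}")
        post = self.posts[sub_index - 1]
        return ImageVolume(post.voxels - self.pre.voxels, self.pre.spacing_mm)


@dataclass
class BreastMask:
    """Binary breast-region mask with physical volume bookkeeping.

    ``breast_volume_cm3`` is always voxel count x voxel volume; it is a
    derived property rather than a stored field so the invariant holds by
    construction.
    """

    mask: np.ndarray
    side: str  # "left" | "right" | "bilateral"
    spacing_mm: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.side not in ("left", "right", "bilateral"):
            raise ValueError(f"side must be left/right/bilateral, got {self.side!r}")
        self.spacing_mm = tuple(float(s) for s in self.spacing_mm)

    @property
    def voxel_count(self) -> int:
        return int(np.count_nonzero(self.mask))

    @property
    def breast_volume_cm3(self) -> float:
        return self.voxel_count * voxel_volume_cm3(self.spacing_mm)

    @property
    def is_empty(self) -> bool:
        return self.voxel_count == 0

    def to_nifti(self, path) -> None:
        affine = np.diag(list(self.spacing_mm) + [1.0])
        nib.save(nib.Nifti1Image(self.mask.astype(np.uint8), affine), str(path))


@dataclass
class FgtMask:
    """Fibroglandular-tissue mask nested inside its parent breast mask."""

    mask: np.ndarray
    parent: BreastMask = field(repr=False)

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if np.any(self.mask & ~self.parent.mask):
            raise ValueError("FGT mask must be a subset of its parent breast mask")

    @property
    def voxel_count(self) -> int:
        return int(np.count_nonzero(self.mask))

    def to_nifti(self, path) -> None:
        affine = np.diag(list(self.parent.spacing_mm) + [1.0])
        nib.save(nib.Nifti1Image(self.mask.astype(np.uint8), affine), str(path))
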