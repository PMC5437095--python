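"""Subtraction, enhancement-ratio maps and BPE/FGT volumetric measures.

The voxel-wise enhancement ratio is

    R% = (I_post - I_pre) / I_pre * 100 = I_sub / I_pre * 100

and a voxel counts as enhancing when R% >= R%_cutoff (inclusive).  The
absolute BPE volume |BPE| is the physical volume of enhancing voxels inside
the breast mask, and BPE% = |BPE| / |Breast| * 100.  FGT measures follow
the same bookkeeping on the fibroglandular mask.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from skimage.registration import phase_cross_correlation

from .image import BreastMask, DceStudy, FgtMask, ImageVolume, voxel_volume_cm3

__all__ = [
    "EnhancementMap",
    "BpeMeasures",
    "FgtMeasures",
    "RigidAlignment",
    "subtract",
    "rigid_align",
    "enhancement_ratio_map",
    "compute_bpe",
    "compute_fgt",
    "quantify_study",
]


@dataclass
class EnhancementMap:
    """Per-voxel R% values on the breast grid.

    ``r_percent`` is NaN outside ``valid_mask``; ``valid_mask`` excludes
    voxels outside the breast and voxels whose pre-contrast signal is at or
    below the noise floor (division guard).
    """

    r_percent: np.ndarray
    valid_mask: np.ndarray
    sub_index: int


@dataclass
class BpeMeasures:
    sub_index: int
    r_cutoff: float
    abs_volume_cm3: float
    percent: float
    breast_volume_cm3: float


@dataclass
class FgtMeasures:
    abs_volume_cm3: float
    percent: float


@dataclass
class RigidAlignment:
    """A moving volume aligned to a reference by integer-voxel translation."""

    aligned: ImageVolume
    translation_voxels: tuple[int, int, int]
    converged: bool


def subtract(pre: ImageVolume, post: ImageVolume) -> ImageVolume:
    """Voxel-wise post minus pre on a shared grid."""
    pre.require_same_grid(post)
    return ImageVolume(post.voxels - pre.voxels, pre.spacing_mm)


def rigid_align(reference: ImageVolume, moving: ImageVolume) -> RigidAlignment:
    """Align ``moving`` to ``reference`` by an integer-voxel translation.

    The translation maximises the FFT cross-correlation of the two volumes;
    it is applied with circular boundary handling, so grid shape and spacing
    never change.  A flat (constant) volume cannot be localised: the
    identity translation is returned with ``converged=False`` and a warning.
    """
    reference.require_same_grid(moving)
    if np.ptp(moving.voxels) == 0 or np.ptp(reference.voxels) == 0:
        warnings.warn("flat correlation surface; returning identity alignment", stacklevel=2)
        return RigidAlignment(ImageVolume(moving.voxels.copy(), moving.spacing_mm), (0, 0, 0), False)
    shift, _, _ = phase_cross_correlation(
        reference.voxels, moving.voxels, upsample_factor=1, normalization=None
    )
    shift = tuple(int(s) for s in shift)
    aligned = np.roll(moving.voxels, shift, axis=(0, 1, 2))
    return RigidAlignment(ImageVolume(aligned, moving.spacing_mm), shift, True)


def enhancement_ratio_map(
    pre: ImageVolume,
    post: ImageVolume,
    breast: BreastMask,
    pre_floor: float = 0.0,
    sub_index: int = 1,
) -> EnhancementMap:
    """Compute R% per voxel inside the breast mask.

    Voxels with pre-contrast signal <= ``pre_floor`` are excluded from the
    valid mask (they still count toward |Breast| but can never qualify as
    enhancing).
    """
    pre.require_same_grid(post)
    if pre_floor < 0:
        raise ValueError("pre_floor must be >= 0")
    if breast.is_empty:
        raise ValueError("breast mask is empty")
    valid = breast.mask & (pre.voxels > pre_floor)
    r = np.full(pre.shape, np.nan)
    r[valid] = (post.voxels[valid] - pre.voxels[valid]) / pre.voxels[valid] * 100.0
    return EnhancementMap(r, valid, sub_index)


def compute_bpe(emap: EnhancementMap, breast: BreastMask, r_cutoff: float = 20.0) -> BpeMeasures:
    """Thresholded enhancing volume |BPE| and BPE% for one subtraction.

    The threshold is inclusive: a voxel with R% exactly equal to the cutoff
    counts as enhancing.
    """
    if r_cutoff <= 0:
        raise ValueError("r_cutoff must be positive")
    if breast.is_empty:
        raise ValueError("breast mask is empty")
    qualifying = emap.valid_mask & breast.mask & (
        np.nan_to_num(emap.r_percent, nan=-np.inf) >= r_cutoff
    )
    count = int(np.count_nonzero(qualifying))
    vv = voxel_volume_cm3(breast.spacing_mm)
    return BpeMeasures(
        sub_index=emap.sub_index,
        r_cutoff=float(r_cutoff),
        abs_volume_cm3=count * vv,
        percent=100.0 * count / breast.voxel_count,
        breast_volume_cm3=breast.breast_volume_cm3,
    )


def compute_fgt(fgt: FgtMask, breast: BreastMask) -> FgtMeasures:
    """|FGT| and FGT% from nested masks."""
    if breast.is_empty:
        raise ValueError("breast mask is empty")
    if np.any(fgt.mask & ~breast.mask):
        raise ValueError("FGT mask is not nested inside the breast mask")
    vv = voxel_volume_cm3(breast.spacing_mm)
    return FgtMeasures(
        abs_volume_cm3=fgt.voxel_count * vv,
        percent=100.0 * fgt.voxel_count / breast.voxel_count,
    )


def quantify_study(
    study: DceStudy,
    breasts: dict[str, BreastMask],
    fgt_masks: dict[str, FgtMask] | None = None,
    r_cutoffs: tuple[float, ...] = (20.0, 30.0, 40.0),
    pre_floor: float = 0.0,
    align: bool = True,
) -> list[dict]:
    """Run the full per-breast, per-SUB, per-cutoff quantification.

    Post-contrast volumes are first rigidly aligned to the first
    post-contrast grid (SUB1 is the reference), then R% maps are computed
    against the pre-contrast volume and thresholded at each cutoff.
    Returns flat records ready for a DataFrame/CSV.
    """
    posts = list(study.posts)
    if align:
        ref = posts[0]
        posts = [posts[0]] + [rigid_align(ref, p).aligned for p in posts[1:]]
    records = []
    for side, breast in breasts.items():
        if breast.is_empty:
            continue
        fgt_m = None
        if fgt_masks is not None and side in fgt_masks:
            fgt_m = compute_fgt(fgt_masks[side], breast)
        for k, post in enumerate(posts, start=1):
            emap = enhancement_ratio_map(study.pre, post, breast, pre_floor, sub_index=k)
            for cutoff in r_cutoffs:
                bpe = compute_bpe(emap, breast, cutoff)
                records.append(
                    dict(
                        side=side,
                        sub_index=k,
                        r_cutoff=float(cutoff),
                        breast_cm3=breast.breast_volume_cm3,
                        bpe_cm3=bpe.abs_volume_cm3,
                        bpe_pct=bpe.percent,
                        fgt_cm3=fgt_m.abs_volume_cm3 if fgt_m else np.nan,
                        fgt_pct=fgt_m.percent if fgt_m else np.nan,
                    )
                )
    return records
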