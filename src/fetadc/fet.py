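"""Pathological FET volume segmentation and tumor-to-background ratios.

The pathological FET volume (FET_vol/pat) is the set of voxels whose uptake
is at least ``threshold_multiplier`` (default 1.6) times the mean activity
of a contralateral background VOI — the biopsy-validated cut-off separating
tumoral from non-tumoral tissue in amino-acid PET. TBR_mean and TBR_max are
the mean and maximum uptake of that volume normalized by the background
mean.

The protocol's visual refinement step (removal of non-specific spillover in
vessels, bone and meninges) is operationalized as two explicit, logged
inputs: an optional refinement mask restricting the search region, and
seed-based retention of 26-connected components.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage

from .errors import EmptyMaskError, ValidationError
from .volumes import ScalarVolume, VoxelMask, check_congruent, mask_statistics

#: default tumor-to-background threshold multiplier
DEFAULT_TBR_THRESHOLD = 1.6

#: 26-connectivity structuring element for 3D lesion components
CONNECTIVITY_26 = np.ones((3, 3, 3), dtype=bool)


@dataclass(frozen=True)
class FetSegmentation:
    """Result of thresholding the PET volume at a multiple of background.

    ``tbr_mean``/``tbr_max`` are NaN when the segmentation is empty (a
    sub-threshold lesion is a valid outcome, not an error).
    """

    bg_mean_suv: float
    threshold_multiplier: float
    threshold_suv: float
    fet_vol_pat: VoxelMask
    fet_volume_mm3: float
    tbr_mean: float
    tbr_max: float
    empty: bool
    warning: str | None = None


def fet_background(pet: ScalarVolume, bg_voi: VoxelMask) -> float:
    """Mean SUV over the contralateral background VOI.

    Raises on an empty VOI or a non-positive mean (TBR would be undefined).
    """
    stats = mask_statistics(pet, bg_voi)
    if stats["mean"] <= 0:
        raise ValidationError(
            f"background mean SUV must be positive, got {stats['mean']:g}"
        )
    return stats["mean"]


def segment_fet(
    pet: ScalarVolume,
    bg_mean_suv: float,
    refinement_mask: VoxelMask | None = None,
    threshold_multiplier: float = DEFAULT_TBR_THRESHOLD,
) -> FetSegmentation:
    """Threshold the PET volume at ``threshold_multiplier`` x background.

    A voxel belongs to FET_vol/pat iff its SUV is >= the threshold
    (inclusive) and, when a refinement mask is given, lies inside it. An
    empty result is returned with ``empty=True`` and NaN TBRs.
    """
    if bg_mean_suv <= 0:
        raise ValidationError("bg_mean_suv must be positive")
    if threshold_multiplier <= 0:
        raise ValidationError("threshold_multiplier must be positive")
    threshold = threshold_multiplier * bg_mean_suv
    flags = pet.values >= threshold
    if refinement_mask is not None:
        check_congruent(pet, refinement_mask)
        flags = flags & refinement_mask.flags
    mask = VoxelMask(flags, pet.voxel_spacing_mm)
    return _finalize(pet, bg_mean_suv, threshold_multiplier, threshold, mask)


def _finalize(pet, bg_mean_suv, multiplier, threshold, mask, warning=None):
    if mask.n_voxels == 0:
        return FetSegmentation(
            bg_mean_suv=bg_mean_suv,
            threshold_multiplier=multiplier,
            threshold_suv=threshold,
            fet_vol_pat=mask,
            fet_volume_mm3=0.0,
            tbr_mean=float("nan"),
            tbr_max=float("nan"),
            empty=True,
            warning=warning,
        )
    stats = mask_statistics(pet, mask)
    return FetSegmentation(
        bg_mean_suv=bg_mean_suv,
        threshold_multiplier=multiplier,
        threshold_suv=threshold,
        fet_vol_pat=mask,
        fet_volume_mm3=mask.volume_mm3,
        tbr_mean=stats["mean"] / bg_mean_suv,
        tbr_max=stats["max"] / bg_mean_suv,
        empty=False,
        warning=warning,
    )


def refine_components(
    pet: ScalarVolume, seg: FetSegmentation, seed_mask: VoxelMask
) -> FetSegmentation:
    """Keep only 26-connected components of the segmentation touching the seed.

    Components of FET_vol/pat disjoint from ``seed_mask`` are discarded and
    metrics are recomputed. If no component overlaps the seed the result is
    empty and carries a warning flag rather than raising.
    """
    check_congruent(seg.fet_vol_pat, seed_mask)
    labels, n = ndimage.label(seg.fet_vol_pat.flags, structure=CONNECTIVITY_26)
    keep_labels = np.unique(labels[seed_mask.flags])
    keep_labels = keep_labels[keep_labels > 0]
    warning = None
    if keep_labels.size == 0:
        flags = np.zeros(seg.fet_vol_pat.shape, dtype=bool)
        warning = "seed mask overlaps no connected component; segmentation emptied"
    else:
        flags = np.isin(labels, keep_labels)
    mask = VoxelMask(flags, seg.fet_vol_pat.voxel_spacing_mm)
    return _finalize(
        pet, seg.bg_mean_suv, seg.threshold_multiplier, seg.threshold_suv, mask, warning
    )
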