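"""ADC-side quantification: VOI transfer, CSF stripping, pathological volume.

The segmented FET volume is superimposed onto the co-registered ADC map.
Two subtractions yield ADC_vol: voxels outside the brain parenchyma are
removed, as are voxels with non-specifically high ADC (CSF-like values,
distortion artefacts). The pathological ADC volume, ADC_vol/pat, is then
the subset of ADC_vol with ADC strictly below the mean of a contralateral
5 mm-radius background sphere (BG_ADC) placed in normal parenchyma.

Low ADC within the FET-positive lesion is a surrogate for densely packed
tumor cells, so ADC_vol/pat quantifies the diffusion-restricted, presumably
most cellular, part of the metabolically active tumor.

An empty ADC_vol/pat is a first-class missing value (some patients retain
no sub-background voxels), not a zero volume: downstream summaries exclude
such records listwise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

from .errors import ValidationError
from .volumes import ScalarVolume, VoxelMask, check_congruent, mask_statistics

#: radius of the standard contralateral background sphere, mm
BG_SPHERE_RADIUS_MM = 5.0

#: default width multiplier for the CSF cutoff rule (mean - k * SD)
DEFAULT_CSF_K_SD = 2.0


@dataclass(frozen=True)
class AdcResult:
    """Pathological ADC volume and its summary metrics for one timepoint."""

    adc_vol: VoxelMask
    bg_adc_mean: float
    adc_vol_pat: VoxelMask
    adc_vol_pat_mm3: float | None
    mean_adc_vol_pat: float | None
    empty: bool


def adc_background(
    adc: ScalarVolume,
    sphere_voi: VoxelMask,
    ventricle_mask: VoxelMask | None = None,
) -> float:
    """Mean ADC over the background sphere.

    If a ventricle mask is supplied and the sphere overlaps it, a warning is
    emitted (the sphere should sit in normal parenchyma) but the mean is
    still returned.
    """
    stats = mask_statistics(adc, sphere_voi)
    if ventricle_mask is not None:
        check_congruent(sphere_voi, ventricle_mask)
        if (sphere_voi.flags & ventricle_mask.flags).any():
            warnings.warn(
                "ADC background VOI overlaps the ventricle mask; the mean may be "
                "contaminated by CSF",
                stacklevel=2,
            )
    return stats["mean"]


def csf_cutoff_from_voi(
    adc: ScalarVolume,
    ventricle_voi: VoxelMask,
    k_sd: float = DEFAULT_CSF_K_SD,
    floor: float | None = None,
) -> float:
    """CSF cutoff from a ventricular VOI: mean - k_sd * SD.

    Voxels at or above the cutoff are treated as CSF-like and removed from
    ADC_vol. With ``floor`` (typically the parenchymal background mean) the
    cutoff never drops below it, guarding against degenerate cutoffs when
    the ventricular sample is wide.
    """
    stats = mask_statistics(adc, ventricle_voi)
    sd = stats["sd"] if stats["n"] > 1 else 0.0
    cutoff = stats["mean"] - k_sd * sd
    if floor is not None:
        cutoff = max(cutoff, floor)
    return float(cutoff)


def build_adc_volume(
    fet_mask: VoxelMask,
    adc: ScalarVolume,
    brain_mask: VoxelMask,
    csf_cutoff: float,
) -> VoxelMask:
    """ADC_vol: the FET mask minus extra-parenchymal and CSF-like voxels."""
    check_congruent(fet_mask, adc)
    check_congruent(fet_mask, brain_mask)
    if csf_cutoff <= 0:
        raise ValidationError("csf_cutoff must be positive")
    flags = fet_mask.flags & brain_mask.flags & (adc.values < csf_cutoff)
    return VoxelMask(flags, fet_mask.voxel_spacing_mm)


def pathological_adc(
    adc_vol: VoxelMask, adc: ScalarVolume, bg_adc_mean: float
) -> AdcResult:
    """ADC_vol/pat: voxels of ADC_vol with ADC strictly below background.

    "Below" is a strict inequality; a voxel exactly at the background mean
    is excluded (measure-zero in real maps, deterministic on phantoms). An
    empty result sets ``empty=True`` and records the volume and mean as
    missing rather than zero.
    """
    check_congruent(adc_vol, adc)
    if bg_adc_mean <= 0:
        raise ValidationError("bg_adc_mean must be positive")
    flags = adc_vol.flags & (adc.values < bg_adc_mean)
    mask = VoxelMask(flags, adc_vol.voxel_spacing_mm)
    if mask.n_voxels == 0:
        return AdcResult(
            adc_vol=adc_vol,
            bg_adc_mean=bg_adc_mean,
            adc_vol_pat=mask,
            adc_vol_pat_mm3=None,
            mean_adc_vol_pat=None,
            empty=True,
        )
    stats = mask_statistics(adc, mask)
    return AdcResult(
        adc_vol=adc_vol,
        bg_adc_mean=bg_adc_mean,
        adc_vol_pat=mask,
        adc_vol_pat_mm3=mask.volume_mm3,
        mean_adc_vol_pat=stats["mean"],
        empty=False,
    )
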