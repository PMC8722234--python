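"""Seeded digital brain phantom: co-registered FET-PET and ADC volumes.

The phantom emulates, at desk scale, the imaging substrate the pipeline was
designed for: a brain-shaped background, a tumor with a configurable
FET uptake ratio over background, a diffusion-restricted tumor core (ADC
below parenchymal background), vasogenic edema in the remainder of the
lesion (elevated ADC), and CSF-filled lateral ventricles (highest ADC).
Ground-truth compartment masks and analytically computed lesion metrics are
exported alongside the images, so every downstream stage can be validated
voxel-for-voxel.

Geometry is deliberately simple: the brain is an axis-aligned ellipsoid,
ventricles are two mirrored interior ellipsoids, the tumor is a sphere. The
background reference regions the study protocol draws by hand are emitted
as generator outputs: a crescent-shaped half-shell VOI contralateral to the
tumor for the FET background, and a 5 mm sphere at the mirrored tumor
position for the ADC background. Noise is additive Gaussian on both
modalities; PET count statistics and scanner point-spread are out of scope.

Default ADC compartment values are on the 10^-6 mm^2/s scale typical of
b=0/1000 clinical maps: ~750 for normal parenchyma, ~500 for densely
cellular tumor core, ~1300 for vasogenic edema, ~3100 for ventricular CSF.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .errors import GeometryError, IOFailure, ValidationError
from .volumes import ScalarVolume, VoxelMask, write_mask, write_volume

#: voxel size of the PET reconstruction the pipeline targets, in mm
DEFAULT_SPACING = (2.32, 2.32, 2.03)


@dataclass(frozen=True)
class PhantomSpec:
    """Full parameterization of one synthetic patient volume pair.

    ``tbr_true`` is the tumor-to-background FET uptake ratio built into the
    image; a segmentation threshold of 1.6x background recovers the tumor
    exactly when ``tbr_true > 1.6`` and the noise is zero. ADC values are on
    the 10^-6 mm^2/s scale and must be strictly ordered
    core < background < edema < csf.
    """

    grid_shape: tuple[int, int, int] = (64, 64, 64)
    voxel_spacing_mm: tuple[float, float, float] = DEFAULT_SPACING
    tumor_center_mm: tuple[float, float, float] | None = None
    tumor_radius_mm: float = 12.0
    tbr_true: float = 2.0
    core_fraction: float = 0.6
    adc_background: float = 750.0
    adc_core: float = 500.0
    adc_edema: float = 1300.0
    adc_csf: float = 3100.0
    pet_background_suv: float = 1.0
    noise_sd_pet: float = 0.0
    noise_sd_adc: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if not (self.adc_core < self.adc_background < self.adc_edema < self.adc_csf):
            raise ValidationError(
                "ADC compartments must satisfy core < background < edema < csf"
            )
        if self.tbr_true <= 0 or self.pet_background_suv <= 0:
            raise ValidationError("tbr_true and pet_background_suv must be positive")
        if not (0.0 <= self.core_fraction <= 1.0):
            raise ValidationError("core_fraction must lie in [0, 1]")
        if self.noise_sd_pet < 0 or self.noise_sd_adc < 0:
            raise ValidationError("noise SDs must be non-negative")
        if self.tumor_radius_mm <= 0:
            raise ValidationError("tumor_radius_mm must be positive")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["grid_shape"] = list(self.grid_shape)
        d["voxel_spacing_mm"] = list(self.voxel_spacing_mm)
        if d["tumor_center_mm"] is not None:
            d["tumor_center_mm"] = list(d["tumor_center_mm"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PhantomSpec":
        d = dict(d)
        for key in ("grid_shape", "voxel_spacing_mm", "tumor_center_mm"):
            if d.get(key) is not None:
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass(frozen=True)
class PhantomBundle:
    """Generated volumes, ground-truth masks and analytic truth metrics."""

    spec: PhantomSpec
    pet: ScalarVolume
    adc: ScalarVolume
    brain_mask: VoxelMask
    ventricle_mask: VoxelMask
    tumor_mask: VoxelMask
    core_mask: VoxelMask
    bg_fet_voi: VoxelMask
    bg_adc_voi: VoxelMask
    truth: dict


def _physical_grid(shape, spacing):
    axes = [(np.arange(n) + 0.5) * s for n, s in zip(shape, spacing)]
    return np.meshgrid(*axes, indexing="ij")


def _ellipsoid(grid, center, semi_axes):
    x, y, z = grid
    cx, cy, cz = center
    ax, ay, az = semi_axes
    return ((x - cx) / ax) ** 2 + ((y - cy) / ay) ** 2 + ((z - cz) / az) ** 2 <= 1.0


def _sphere(grid, center, radius):
    x, y, z = grid
    cx, cy, cz = center
    return (x - cx) ** 2 + (y - cy) ** 2 + (z - cz) ** 2 <= radius**2


def generate_phantom(spec: PhantomSpec) -> PhantomBundle:
    """Rasterize the phantom described by ``spec``.

    Deterministic: the same spec (including seed) yields a bit-identical
    bundle. Raises :class:`GeometryError` if the tumor sphere does not fit
    inside the brain ellipsoid or collides with a ventricle.
    """
    shape = tuple(int(n) for n in spec.grid_shape)
    spacing = tuple(float(s) for s in spec.voxel_spacing_mm)
    grid = _physical_grid(shape, spacing)
    extent = np.array([n * s for n, s in zip(shape, spacing)])
    brain_center = extent / 2.0
    brain_semi = extent * 0.45  # ellipsoid fills 90% of the field of view

    brain = _ellipsoid(grid, brain_center, brain_semi)

    # two mirrored lateral ventricles, elongated front-to-back
    vent_semi = np.minimum(np.array([6.0, 20.0, 9.0]), brain_semi * 0.45)
    vent_offset = np.array([brain_semi[0] * 0.22, 0.0, 0.0])
    vent_l = _ellipsoid(grid, brain_center - vent_offset, vent_semi)
    vent_r = _ellipsoid(grid, brain_center + vent_offset, vent_semi)
    ventricles = (vent_l | vent_r) & brain

    if spec.tumor_center_mm is None:
        tumor_center = brain_center + np.array([brain_semi[0] * 0.55, 0.0, 0.0])
    else:
        tumor_center = np.asarray(spec.tumor_center_mm, dtype=float)
    tumor = _sphere(grid, tumor_center, spec.tumor_radius_mm) & ~ventricles
    if not tumor.any():
        raise GeometryError("tumor sphere rasterizes to zero voxels")
    if np.any(tumor & ~brain):
        raise GeometryError("tumor sphere extends outside the brain ellipsoid")
    core = _sphere(grid, tumor_center, spec.core_fraction * spec.tumor_radius_mm) & tumor

    # contralateral background VOIs: mirror about the mid-sagittal plane
    side = np.sign(tumor_center[0] - brain_center[0]) or 1.0
    x = grid[0]
    contralateral = (x - brain_center[0]) * side < 0
    rho = (
        ((x - brain_center[0]) / brain_semi[0]) ** 2
        + ((grid[1] - brain_center[1]) / brain_semi[1]) ** 2
        + ((grid[2] - brain_center[2]) / brain_semi[2]) ** 2
    )
    bg_fet = brain & contralateral & (rho >= 0.45**2) & (rho <= 0.80**2) & ~ventricles

    mirror_center = 2 * brain_center - tumor_center  # reflect through brain center
    bg_adc = _sphere(grid, mirror_center, 5.0) & brain & ~ventricles
    if not bg_fet.any() or not bg_adc.any():
        raise GeometryError("background VOI rasterizes to zero voxels")

    pet = np.zeros(shape, dtype=float)
    pet[brain] = spec.pet_background_suv
    pet[tumor] = spec.tbr_true * spec.pet_background_suv

    adc = np.full(shape, 300.0)  # extracranial: skull/scalp-like low ADC
    adc[brain] = spec.adc_background
    adc[ventricles] = spec.adc_csf
    adc[tumor] = spec.adc_edema
    adc[core] = spec.adc_core

    rng = np.random.default_rng(spec.seed)
    if spec.noise_sd_pet > 0:
        pet = pet + rng.normal(0.0, spec.noise_sd_pet, size=shape)
    if spec.noise_sd_adc > 0:
        adc = adc + rng.normal(0.0, spec.noise_sd_adc, size=shape)

    vv = float(np.prod(spacing))
    lesion_detectable = spec.tbr_true >= 1.6
    n_tumor = int(tumor.sum())
    n_core = int(core.sum())
    truth = {
        "fet_vol_pat_mm3": n_tumor * vv if lesion_detectable else 0.0,
        "tbr_mean": spec.tbr_true if lesion_detectable else None,
        "tbr_max": spec.tbr_true if lesion_detectable else None,
        # noise-free: core < background, edema/csf above, so the pathological
        # ADC volume is exactly the core (when the lesion is detectable)
        "adc_vol_pat_mm3": n_core * vv if lesion_detectable else None,
        "mean_adc_vol_pat": spec.adc_core if (lesion_detectable and n_core) else None,
        "bg_fet_mean_suv": spec.pet_background_suv,
        "bg_adc_mean": spec.adc_background,
        "n_tumor_voxels": n_tumor,
        "n_core_voxels": n_core,
    }

    mk = lambda flags: VoxelMask(flags, spacing)
    return PhantomBundle(
        spec=spec,
        pet=ScalarVolume(pet, spacing, modality="FET_SUV", units="SUV"),
        adc=ScalarVolume(adc, spacing, modality="ADC", units="1e-6 mm^2/s"),
        brain_mask=mk(brain),
        ventricle_mask=mk(ventricles),
        tumor_mask=mk(tumor),
        core_mask=mk(core),
        bg_fet_voi=mk(bg_fet),
        bg_adc_voi=mk(bg_adc),
        truth=truth,
    )


_BUNDLE_FILES = {
    "pet": "pet.nii.gz",
    "adc": "adc.nii.gz",
    "brain_mask": "brain_mask.nii.gz",
    "ventricle_mask": "ventricle_mask.nii.gz",
    "tumor_mask": "tumor_mask.nii.gz",
    "core_mask": "core_mask.nii.gz",
    "bg_fet_voi": "bg_fet_voi.nii.gz",
    "bg_adc_voi": "bg_adc_voi.nii.gz",
}


def write_bundle(bundle: PhantomBundle, directory) -> Path:
    """Write all volumes/masks as NIfTI plus a JSON manifest; returns manifest path."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for attr, fname in _BUNDLE_FILES.items():
        obj = getattr(bundle, attr)
        if isinstance(obj, ScalarVolume):
            write_volume(obj, directory / fname)
        else:
            write_mask(obj, directory / fname)
    manifest = {
        "files": dict(_BUNDLE_FILES),
        "spec": bundle.spec.to_dict(),
        "truth": bundle.truth,
    }
    mpath = directory / "manifest.json"
    try:
        mpath.write_text(json.dumps(manifest, indent=2))
    except OSError as exc:
        raise IOFailure(mpath, f"failed to write manifest ({exc})") from None
    return mpath


def read_bundle(directory) -> PhantomBundle:
    """Load a bundle previously written by :func:`write_bundle`."""
    from .volumes import read_mask, read_volume

    directory = Path(directory)
    mpath = directory / "manifest.json"
    if not mpath.exists():
        raise IOFailure(mpath, "manifest not found")
    manifest = json.loads(mpath.read_text())
    spec = PhantomSpec.from_dict(manifest["spec"])
    files = manifest["files"]
    kwargs = {}
    for attr, fname in files.items():
        path = directory / fname
        if attr == "pet":
            kwargs[attr] = read_volume(path, modality="FET_SUV", units="SUV")
        elif attr == "adc":
            kwargs[attr] = read_volume(path, modality="ADC", units="1e-6 mm^2/s")
        else:
            kwargs[attr] = read_mask(path)
    return PhantomBundle(spec=spec, truth=manifest["truth"], **kwargs)
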