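"""Per-patient pipeline composition and cohort-level orchestration.

``run_patient`` chains the stages for one timepoint:

    FET background -> 1.6x threshold segmentation -> (optional) refinement
    -> CSF cutoff from the ventricular VOI -> ADC_vol construction
    -> below-background pathological ADC extraction

and returns the lesion metrics together with the masks and a log of every
threshold actually used, so a rerun with the same configuration is
bit-identical and auditable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

from . import __version__
from .adc import (
    DEFAULT_CSF_K_SD,
    adc_background,
    build_adc_volume,
    csf_cutoff_from_voi,
    pathological_adc,
)
from .errors import FetAdcError, ValidationError
from .fet import DEFAULT_TBR_THRESHOLD, fet_background, refine_components, segment_fet
from .longitudinal import DEFAULT_DOUBLING_MULTIPLIER, LesionMetrics
from .volumes import read_mask, read_volume, write_mask


@dataclass
class RunConfig:
    """Paths and constants for one patient-timepoint run.

    Defaults encode the study protocol: 1.6x background FET threshold,
    CSF cutoff at ventricular mean - 2 SD (floored at the ADC background),
    twofold FET-volume increase as the response-defining flag.
    """

    pet_path: str | Path = ""
    adc_path: str | Path = ""
    brain_mask_path: str | Path = ""
    ventricle_voi_path: str | Path = ""
    bg_fet_voi_path: str | Path = ""
    bg_adc_voi_path: str | Path = ""
    refinement_mask_path: str | Path | None = None
    seed_mask_path: str | Path | None = None
    tbr_threshold: float = DEFAULT_TBR_THRESHOLD
    csf_k_sd: float = DEFAULT_CSF_K_SD
    doubling_multiplier: float = DEFAULT_DOUBLING_MULTIPLIER
    split_rule: str = "median"
    seed: int = 0
    out_dir: str | Path = "."

    @classmethod
    def from_json(cls, path, **overrides) -> "RunConfig":
        data = json.loads(Path(path).read_text())
        data.update({k: v for k, v in overrides.items() if v is not None})
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


class StageError(FetAdcError):
    """An error in a named pipeline stage."""

    def __init__(self, stage, original):
        self.stage = stage
        self.original = original
        super().__init__(f"stage '{stage}' failed: {original}")


def _stage(name, fn, *args, **kwargs):
    try:
        return fn(*args, **kwargs)
    except FetAdcError as exc:
        raise StageError(name, exc) from exc


def run_patient(config: RunConfig, write_outputs: bool = True) -> dict:
    """Execute the full single-timepoint pipeline described by ``config``.

    Returns a dict with ``metrics`` (:class:`LesionMetrics`), the masks, and
    ``log`` recording every threshold used. Any stage failure raises
    :class:`StageError` naming the stage.
    """
    pet = _stage("load_pet", read_volume, config.pet_path, "FET_SUV", "SUV")
    adc = _stage("load_adc", read_volume, config.adc_path, "ADC", "1e-6 mm^2/s")
    brain = _stage("load_brain_mask", read_mask, config.brain_mask_path)
    ventricles = _stage("load_ventricle_voi", read_mask, config.ventricle_voi_path)
    bg_fet_voi = _stage("load_bg_fet_voi", read_mask, config.bg_fet_voi_path)
    bg_adc_voi = _stage("load_bg_adc_voi", read_mask, config.bg_adc_voi_path)
    refinement = (
        _stage("load_refinement_mask", read_mask, config.refinement_mask_path)
        if config.refinement_mask_path
        else None
    )
    seed_mask = (
        _stage("load_seed_mask", read_mask, config.seed_mask_path)
        if config.seed_mask_path
        else None
    )

    bg_suv = _stage("fet_background", fet_background, pet, bg_fet_voi)
    seg = _stage(
        "segment_fet", segment_fet, pet, bg_suv, refinement, config.tbr_threshold
    )
    if seed_mask is not None:
        seg = _stage("refine_components", refine_components, pet, seg, seed_mask)

    bg_adc = _stage("adc_background", adc_background, adc, bg_adc_voi, ventricles)
    cutoff = _stage(
        "csf_cutoff", csf_cutoff_from_voi, adc, ventricles, config.csf_k_sd, bg_adc
    )
    adc_vol = _stage(
        "build_adc_volume", build_adc_volume, seg.fet_vol_pat, adc, brain, cutoff
    )
    result = _stage("pathological_adc", pathological_adc, adc_vol, adc, bg_adc)

    metrics = LesionMetrics(
        fet_vol_pat_mm3=seg.fet_volume_mm3,
        tbr_mean=seg.tbr_mean,
        tbr_max=seg.tbr_max,
        adc_vol_pat_mm3=result.adc_vol_pat_mm3,
        mean_adc_vol_pat=result.mean_adc_vol_pat,
    )
    log = {
        "version": __version__,
        "tbr_threshold": config.tbr_threshold,
        "bg_fet_mean_suv": bg_suv,
        "threshold_suv": seg.threshold_suv,
        "csf_k_sd": config.csf_k_sd,
        "csf_cutoff": cutoff,
        "bg_adc_mean": bg_adc,
        "fet_empty": seg.empty,
        "adc_empty": result.empty,
        "warning": seg.warning,
        "inputs": {
            "pet": str(config.pet_path),
            "adc": str(config.adc_path),
            "brain_mask": str(config.brain_mask_path),
            "ventricle_voi": str(config.ventricle_voi_path),
            "bg_fet_voi": str(config.bg_fet_voi_path),
            "bg_adc_voi": str(config.bg_adc_voi_path),
            "refinement_mask": str(config.refinement_mask_path or ""),
            "seed_mask": str(config.seed_mask_path or ""),
        },
    }
    out = {
        "metrics": metrics,
        "fet_segmentation": seg,
        "adc_result": result,
        "log": log,
    }
    if write_outputs:
        outdir = Path(config.out_dir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_mask(seg.fet_vol_pat, outdir / "fet_vol_pat.nii.gz")
        write_mask(result.adc_vol, outdir / "adc_vol.nii.gz")
        write_mask(result.adc_vol_pat, outdir / "adc_vol_pat.nii.gz")
        payload = {
            "metrics": {
                "fet_vol_pat_mm3": metrics.fet_vol_pat_mm3,
                "tbr_mean": None if seg.empty else metrics.tbr_mean,
                "tbr_max": None if seg.empty else metrics.tbr_max,
                "adc_vol_pat_mm3": metrics.adc_vol_pat_mm3,
                "mean_adc_vol_pat": metrics.mean_adc_vol_pat,
            },
            "log": log,
        }
        (outdir / "metrics.json").write_text(json.dumps(payload, indent=2))
    return out


def run_cohort(records, survival=None, split_rule="median"):
    """Cohort statistics over longitudinal records (plus optional survival).

    ``records`` is a list of :class:`LongitudinalRecord`; ``survival`` is an
    optional DataFrame with columns ``id, time_days, event``. Duplicate
    patient ids are rejected.
    """
    import numpy as np

    from .stats import SurvivalStratification, km_logrank, pearson_r, rank_test, split_by_rule

    ids = [r.patient_id for r in records]
    if len(set(ids)) != len(ids):
        raise ValidationError("duplicate patient ids in cohort")
    if len(records) < 2:
        raise ValidationError("cohort needs at least two patients")

    nan = float("nan")
    dfet = [r.delta_pct["fet_vol_pat_mm3"] if r.delta_pct["fet_vol_pat_mm3"] is not None else nan
            for r in records]
    dadc = [r.delta_pct["adc_vol_pat_mm3"] if r.delta_pct["adc_vol_pat_mm3"] is not None else nan
            for r in records]
    report = {"n": len(records)}
    try:
        r, n = pearson_r(dfet, dadc)
        report["correlation_dfet_dadc_pct"] = {"r": r, "n": n}
    except ValidationError as exc:
        report["correlation_dfet_dadc_pct"] = {"error": str(exc)}

    doubled = [v for r, v in zip(records, dadc) if r.fet_doubled and not np.isnan(v)]
    rest = [v for r, v in zip(records, dadc) if not r.fet_doubled and not np.isnan(v)]
    if doubled and rest:
        comp = rank_test(doubled, rest, metric="delta_adc_vol_pat_pct",
                         labels=("fet_doubled", "rest"))
        report["doubling_comparison"] = {
            "test": comp.test, "statistic": comp.statistic, "p": comp.p_value,
        }

    if survival is not None:
        sv = survival.set_index(survival["id"].astype(str))
        times, events, values, flags, rano = [], [], [], [], []
        for rec in records:
            if rec.patient_id not in sv.index:
                raise ValidationError(f"no survival row for patient {rec.patient_id}")
            row = sv.loc[rec.patient_id]
            times.append(float(row["time_days"]))
            events.append(int(row["event"]))
            values.append(rec.delta_pct["fet_vol_pat_mm3"])
            flags.append(rec.fet_doubled)
            rano.append(rec.rano)
        groups = split_by_rule(values, split_rule, doubling_flags=flags, rano=rano)
        strat = SurvivalStratification(tuple(times), tuple(events), tuple(groups),
                                       split_rule=split_rule)
        report["survival"] = km_logrank(strat)
    return report
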