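"""Pairing of baseline/post-treatment lesion metrics into Δ records.

For every metric X the absolute and percentage changes are
ΔX = X(T1) − X(T0) and ΔX% = (X(T1) − X(T0)) / X(T0) × 100. A missing
value at either timepoint (or a zero baseline, for the percentage) makes
the corresponding Δ missing — never zero — and the missingness propagates
listwise into cohort statistics.

The response-defining flag of the analysis is ``fet_doubled``: true when
the post-treatment pathological FET volume is at least twice the baseline
volume (inclusive boundary; the multiplier is configurable).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .errors import ValidationError

#: metrics carried per timepoint, in canonical column order
METRICS = (
    "fet_vol_pat_mm3",
    "tbr_mean",
    "tbr_max",
    "adc_vol_pat_mm3",
    "mean_adc_vol_pat",
)

RANO_CATEGORIES = ("CR", "PR", "SD", "PD")

#: default "at least a twofold increase" multiplier
DEFAULT_DOUBLING_MULTIPLIER = 2.0


def _is_missing(x) -> bool:
    return x is None or (isinstance(x, float) and math.isnan(x))


@dataclass(frozen=True)
class LesionMetrics:
    """Per-timepoint lesion metrics; ADC entries may be missing (NaN/None)."""

    fet_vol_pat_mm3: float
    tbr_mean: float
    tbr_max: float
    adc_vol_pat_mm3: float | None = None
    mean_adc_vol_pat: float | None = None

    def __post_init__(self):
        for name in ("fet_vol_pat_mm3", "adc_vol_pat_mm3"):
            v = getattr(self, name)
            if not _is_missing(v) and v < 0:
                raise ValidationError(f"{name} must be non-negative, got {v}")

    def get(self, name: str):
        v = getattr(self, name)
        return None if _is_missing(v) else float(v)


@dataclass(frozen=True)
class LongitudinalRecord:
    """One patient's paired-timepoint record with Δ metrics and flags."""

    patient_id: str
    baseline: LesionMetrics
    post: LesionMetrics
    rano: str
    delta_abs: dict = field(default_factory=dict)
    delta_pct: dict = field(default_factory=dict)
    fet_doubled: bool | None = None
    tp3: LesionMetrics | None = None


def flag_doubling(
    baseline_fet: float,
    post_fet: float,
    multiplier: float = DEFAULT_DOUBLING_MULTIPLIER,
) -> bool:
    """True iff post >= multiplier x baseline (inclusive boundary)."""
    if _is_missing(baseline_fet) or _is_missing(post_fet):
        raise ValidationError("FET volumes must be present to evaluate doubling")
    return post_fet >= multiplier * baseline_fet


def make_record(
    patient_id,
    baseline: LesionMetrics,
    post: LesionMetrics,
    rano: str,
    doubling_multiplier: float = DEFAULT_DOUBLING_MULTIPLIER,
    tp3: LesionMetrics | None = None,
) -> LongitudinalRecord:
    """Pair two timepoints into a record with all Δ metrics and flags."""
    if rano not in RANO_CATEGORIES:
        raise ValidationError(f"rano must be one of {RANO_CATEGORIES}, got {rano!r}")
    delta_abs = {}
    delta_pct = {}
    for name in METRICS:
        b, p = baseline.get(name), post.get(name)
        if b is None or p is None:
            delta_abs[name] = None
            delta_pct[name] = None
        else:
            delta_abs[name] = p - b
            delta_pct[name] = (p - b) / b * 100.0 if b > 0 else None
    return LongitudinalRecord(
        patient_id=str(patient_id),
        baseline=baseline,
        post=post,
        rano=rano,
        delta_abs=delta_abs,
        delta_pct=delta_pct,
        fet_doubled=flag_doubling(
            baseline.fet_vol_pat_mm3, post.fet_vol_pat_mm3, doubling_multiplier
        ),
        tp3=tp3,
    )


# ---------------------------------------------------------------------------
# CSV interchange: long format, one row per patient-timepoint

_CSV_COLUMNS = ["id", "timepoint"] + list(METRICS) + ["rano"]


def records_to_frame(records) -> pd.DataFrame:
    rows = []
    for rec in records:
        for tp, m in (("baseline", rec.baseline), ("post", rec.post)):
            row = {"id": rec.patient_id, "timepoint": tp, "rano": rec.rano}
            for name in METRICS:
                row[name] = m.get(name)
            rows.append(row)
    return pd.DataFrame(rows, columns=_CSV_COLUMNS)


def write_records_csv(records, path) -> None:
    records_to_frame(records).to_csv(path, index=False)


def frame_to_records(df: pd.DataFrame, doubling_multiplier=DEFAULT_DOUBLING_MULTIPLIER):
    """Rebuild records from a long-format table (missing cells stay missing)."""
    records = []
    for pid, grp in df.groupby("id", sort=False):
        by_tp = {row["timepoint"]: row for _, row in grp.iterrows()}
        if "baseline" not in by_tp or "post" not in by_tp:
            raise ValidationError(f"patient {pid}: need both baseline and post rows")

        def metrics_of(row):
            kwargs = {}
            for name in METRICS:
                v = row[name]
                kwargs[name] = None if pd.isna(v) else float(v)
            return LesionMetrics(**kwargs)

        rano = str(by_tp["baseline"]["rano"])
        records.append(
            make_record(
                pid,
                metrics_of(by_tp["baseline"]),
                metrics_of(by_tp["post"]),
                rano,
                doubling_multiplier=doubling_multiplier,
            )
        )
    return records


def read_records_csv(path, doubling_multiplier=DEFAULT_DOUBLING_MULTIPLIER):
    df = pd.read_csv(path)
    missing = [c for c in _CSV_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing columns {missing}")
    return frame_to_records(df, doubling_multiplier=doubling_multiplier)
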