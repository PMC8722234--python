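"""Packaged 16-patient cohort and recomputation of its published summaries.

The fixture transcribes the study's per-patient parameter table: 16
recurrent-glioblastoma patients imaged with FET-PET/MR at baseline and
after two cycles of regorafenib, with the pathological FET volume
(FET_vol/pat, mm^3), TBR_mean, TBR_max, the pathological ADC volume
(ADC_vol/pat, mm^3), its mean ADC (10^-6 mm^2/s) and the RANO response
category (7 SD / 9 PD). "/" cells — timepoints where no voxel survived the
below-background ADC criterion — are stored as missing values, and the raw
printed strings (including the source's typographic comma artifacts, e.g.
"1,0370" for 10370) are kept alongside the comma-normalized numbers.

``summarize_cohort`` recomputes the per-timepoint summary (mean +/- SD and
range per parameter) and the RANO-split Δ summaries with listwise exclusion
of missing values per parameter; ``correlations`` recomputes the
ΔFET%—ΔADC% association; ``render_report`` writes the tables, the scatter
and box plots and the follow-up trajectory figure.

Four patients underwent a third PET/MR (after another four cycles); no
numeric third-timepoint values are published, so the fixture carries only
qualitative direction labels for those four patients.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ValidationError
from .longitudinal import (
    METRICS,
    LesionMetrics,
    LongitudinalRecord,
    make_record,
)
from .stats import GroupComparison, pearson_r, rank_test

FIXTURE_NAME = "cohort_table2.csv"
FIXTURE_SHA256 = "c6685b3037a7aa78d8f261ef6d4bd51bbc190ac02c07614853dbb4c7d368c086"

#: qualitative third-timepoint course for the four followed-up patients
TP3_FOLLOWUP = {
    "5": {"fet": "up", "adc": "up", "outcome": "PD at later MR"},
    "8": {"fet": "up", "adc": "up", "outcome": "PD"},
    "9": {"fet": "down", "adc": "down", "outcome": "SD"},
    "16": {"fet": "up", "adc": "up", "outcome": "PD"},
}

#: parameters summarized per timepoint, in report order
_TABLE3_ORDER = ("fet_vol_pat_mm3", "tbr_max", "tbr_mean", "adc_vol_pat_mm3", "mean_adc_vol_pat")


@dataclass(frozen=True)
class CohortTable:
    """The fixture cohort: records plus the raw long-format frame."""

    records: tuple[LongitudinalRecord, ...]
    frame: pd.DataFrame

    def record(self, patient_id) -> LongitudinalRecord:
        pid = str(patient_id)
        for rec in self.records:
            if rec.patient_id == pid:
                return rec
        raise KeyError(pid)


def _fixture_bytes() -> bytes:
    return resources.files("fetadc.data").joinpath(FIXTURE_NAME).read_bytes()


def load_fixture() -> CohortTable:
    """Load and verify the packaged cohort table.

    Raises :class:`ValidationError` if the packaged file's checksum does not
    match the frozen value (guarding against silent fixture corruption), or
    if comma-normalization of any raw cell disagrees with the stored number.
    """
    raw = _fixture_bytes()
    digest = hashlib.sha256(raw).hexdigest()
    if digest != FIXTURE_SHA256:
        raise ValidationError(
            f"cohort fixture checksum mismatch: {digest} != {FIXTURE_SHA256}"
        )
    import io

    df = pd.read_csv(io.BytesIO(raw), dtype={"patient": str})
    # comma-normalization audit: deleting commas from the raw string must
    # reproduce the numeric column ("/" maps to missing)
    for raw_col, num_col in (
        ("fet_vol_pat_raw", "fet_vol_pat_mm3"),
        ("adc_vol_pat_raw", "adc_vol_pat_mm3"),
    ):
        for raw_val, num_val in zip(df[raw_col], df[num_col]):
            s = str(raw_val).strip()
            if s == "/":
                if not pd.isna(num_val):
                    raise ValidationError(f"'/' cell carries a number: {num_val}")
                continue
            if float(s.replace(",", "")) != float(num_val):
                raise ValidationError(
                    f"comma-normalization mismatch: {raw_val!r} vs {num_val!r}"
                )

    records = []
    for pid, grp in df.groupby("patient", sort=False):
        by_tp = {row["timepoint"]: row for _, row in grp.iterrows()}

        def metrics_of(row):
            kw = {}
            for name in METRICS:
                v = row[name]
                kw[name] = None if pd.isna(v) else float(v)
            return LesionMetrics(**kw)

        records.append(
            make_record(pid, metrics_of(by_tp["baseline"]), metrics_of(by_tp["post"]),
                        str(by_tp["baseline"]["rano"]))
        )
    return CohortTable(records=tuple(records), frame=df)


# ---------------------------------------------------------------------------
# summaries


def _summary(values) -> dict:
    """mean/sd(n-1)/range over the non-missing entries (listwise per metric)."""
    x = np.asarray([v for v in values if v is not None], dtype=float)
    if x.size == 0:
        return {"mean": None, "sd": None, "min": None, "max": None, "n": 0}
    return {
        "mean": float(x.mean()),
        "sd": float(x.std(ddof=1)) if x.size > 1 else None,
        "min": float(x.min()),
        "max": float(x.max()),
        "n": int(x.size),
    }


def timepoint_summary(table: CohortTable) -> pd.DataFrame:
    """Per-parameter mean +/- SD and range at each timepoint."""
    rows = []
    for name in _TABLE3_ORDER:
        for tp in ("baseline", "post"):
            vals = [getattr(r, tp).get(name) for r in table.records]
            rows.append({"parameter": name, "timepoint": tp, **_summary(vals)})
    return pd.DataFrame(rows)


def rano_summary(table: CohortTable) -> pd.DataFrame:
    """Δ (absolute and %) summaries split by RANO category."""
    rows = []
    groups = sorted({r.rano for r in table.records})
    for name in _TABLE3_ORDER:
        for kind, store in (("delta_abs", "abs"), ("delta_pct", "pct")):
            for g in groups:
                vals = [getattr(r, kind)[name] for r in table.records if r.rano == g]
                rows.append(
                    {"parameter": name, "delta": store, "rano": g, **_summary(vals)}
                )
    return pd.DataFrame(rows)


def summarize_cohort(table: CohortTable) -> dict:
    return {"timepoints": timepoint_summary(table), "rano_split": rano_summary(table)}


def correlations(table: CohortTable) -> dict:
    """ΔFET% vs ΔADC% and ΔFET% vs Δmean-ADC% over complete pairs."""
    dfet = [r.delta_pct["fet_vol_pat_mm3"] for r in table.records]
    dadc = [r.delta_pct["adc_vol_pat_mm3"] for r in table.records]
    dmadc = [r.delta_pct["mean_adc_vol_pat"] for r in table.records]
    nan = float("nan")
    f = [v if v is not None else nan for v in dfet]
    r1, n1 = pearson_r(f, [v if v is not None else nan for v in dadc])
    r2, n2 = pearson_r(f, [v if v is not None else nan for v in dmadc])
    return {
        "dfet_pct_vs_dadc_pct": {"r": r1, "n": n1},
        "dfet_pct_vs_dmean_adc_pct": {"r": r2, "n": n2},
    }


def doubling_comparison(table: CohortTable) -> GroupComparison:
    """ΔADC% in patients with >= 2x FET increase vs the remaining subjects."""
    doubled, rest = [], []
    for r in table.records:
        v = r.delta_pct["adc_vol_pat_mm3"]
        if v is None:
            continue
        (doubled if r.fet_doubled else rest).append(v)
    return rank_test(doubled, rest, mode="rank_sum", metric="delta_adc_vol_pat_pct",
                     labels=("fet_doubled", "rest"))


def rano_comparisons(table: CohortTable) -> dict:
    """PD-vs-SD rank-sum contrasts for ΔFET% and ΔADC%."""
    out = {}
    for name in ("fet_vol_pat_mm3", "adc_vol_pat_mm3"):
        pd_vals = [r.delta_pct[name] for r in table.records
                   if r.rano == "PD" and r.delta_pct[name] is not None]
        sd_vals = [r.delta_pct[name] for r in table.records
                   if r.rano == "SD" and r.delta_pct[name] is not None]
        out[name] = rank_test(pd_vals, sd_vals, mode="rank_sum",
                              metric=f"delta_{name}_pct", labels=("PD", "SD"))
    return out


def narrative_deltas(table: CohortTable) -> pd.DataFrame:
    """Per-patient Δ metrics (abs and %), one row per patient."""
    rows = []
    for r in table.records:
        row = {"patient": r.patient_id, "rano": r.rano, "fet_doubled": r.fet_doubled}
        for name in METRICS:
            row[f"d_{name}"] = r.delta_abs[name]
            row[f"d_{name}_pct"] = r.delta_pct[name]
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# report rendering


def _fmt(value, ndigits=0):
    """Report rounding: int(toward zero) for volumes/%, 2 dp for ratios."""
    if value is None:
        return "/"
    if ndigits == 0:
        return str(int(value))  # truncation toward zero, as in the source tables
    return f"{value:.{ndigits}f}"


def render_report(table: CohortTable, outdir) -> dict:
    """Write CSV tables, the correlation JSON and the figures; returns paths."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}

    summ = summarize_cohort(table)
    paths["table3"] = outdir / "timepoint_summary.csv"
    summ["timepoints"].to_csv(paths["table3"], index=False)
    paths["table4"] = outdir / "rano_split_summary.csv"
    summ["rano_split"].to_csv(paths["table4"], index=False)
    paths["deltas"] = outdir / "per_patient_deltas.csv"
    narrative_deltas(table).to_csv(paths["deltas"], index=False)

    corr = correlations(table)
    comp = doubling_comparison(table)
    corr["doubling_split_rank_sum"] = {
        "test": comp.test, "statistic": comp.statistic, "p": comp.p_value,
        "n": [len(g) for g in comp.group_values],
    }
    paths["correlations"] = outdir / "correlations.json"
    paths["correlations"].write_text(json.dumps(corr, indent=2))

    # scatter of complete ΔFET%/ΔADC% pairs with least-squares line
    pairs = [(r.delta_pct["fet_vol_pat_mm3"], r.delta_pct["adc_vol_pat_mm3"], r.rano)
             for r in table.records if r.delta_pct["adc_vol_pat_mm3"] is not None]
    x = np.array([p[0] for p in pairs])
    y = np.array([p[1] for p in pairs])
    slope, intercept = np.polyfit(x, y, 1)
    fig, ax = plt.subplots(figsize=(5, 4))
    for cat, color in (("PD", "tab:red"), ("SD", "tab:green")):
        sel = [p[2] == cat for p in pairs]
        ax.scatter(x[sel], y[sel], c=color, label=cat)
    xs = np.linspace(x.min(), x.max(), 50)
    ax.plot(xs, slope * xs + intercept, color="tab:blue")
    ax.set_xlabel("ΔFET_vol/pat (%)")
    ax.set_ylabel("ΔADC_vol/pat (%)")
    ax.legend()
    fig.tight_layout()
    paths["scatter"] = outdir / "scatter_delta_fet_adc.png"
    fig.savefig(paths["scatter"], dpi=110)
    plt.close(fig)

    # box plots by RANO and by the doubling split
    fig, axes = plt.subplots(1, 2, figsize=(8, 4))
    for ax, (name, title) in zip(
        axes,
        (("adc_vol_pat_mm3", "ΔADC_vol/pat % by RANO"),
         ("fet_vol_pat_mm3", "ΔFET_vol/pat % by RANO")),
    ):
        data = [
            [r.delta_pct[name] for r in table.records
             if r.rano == g and r.delta_pct[name] is not None]
            for g in ("SD", "PD")
        ]
        ax.boxplot(data, tick_labels=["SD", "PD"])
        ax.set_title(title, fontsize=9)
    fig.tight_layout()
    paths["box_rano"] = outdir / "box_rano.png"
    fig.savefig(paths["box_rano"], dpi=110)
    plt.close(fig)

    fig, ax = plt.subplots(figsize=(4.5, 4))
    data = [
        [g for g in comp.group_values[0]],
        [g for g in comp.group_values[1]],
    ]
    ax.boxplot(data, tick_labels=["FET >= 2x", "rest"])
    ax.set_ylabel("ΔADC_vol/pat (%)")
    fig.tight_layout()
    paths["box_doubling"] = outdir / "box_doubling.png"
    fig.savefig(paths["box_doubling"], dpi=110)
    plt.close(fig)

    # follow-up trajectories: numeric TP1/TP2 values, qualitative TP3 arrows
    fig, axes = plt.subplots(1, 2, figsize=(8, 4), sharex=True)
    followed = [table.record(pid) for pid in TP3_FOLLOWUP]
    for ax, name, lab in zip(
        axes, ("fet_vol_pat_mm3", "adc_vol_pat_mm3"),
        ("FET_vol/pat (mm³)", "ADC_vol/pat (mm³)"),
    ):
        for rec in followed:
            b, p = rec.baseline.get(name), rec.post.get(name)
            ax.plot([1, 2], [b, p], marker="o", label=f"#{rec.patient_id}")
            if p is not None:
                direction = TP3_FOLLOWUP[rec.patient_id]["fet" if "fet" in name else "adc"]
                dy = 0.12 * p if direction == "up" else -0.12 * p
                ax.annotate("", xy=(2.35, p + dy), xytext=(2.05, p),
                            arrowprops={"arrowstyle": "->"})
        ax.set_xticks([1, 2])
        ax.set_xticklabels(["TP1", "TP2"])
        ax.set_ylabel(lab)
    axes[0].legend(fontsize=8)
    fig.suptitle("Followed-up patients (TP3 direction shown as arrows)", fontsize=9)
    fig.tight_layout()
    paths["trajectories"] = outdir / "followup_trajectories.png"
    fig.savefig(paths["trajectories"], dpi=110)
    plt.close(fig)

    return {k: str(v) for k, v in paths.items()}
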