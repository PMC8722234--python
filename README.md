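# fetadc

FET-PET guided quantification of apparent diffusion coefficient (ADC) maps
for response assessment in recurrent glioblastoma.

## The problem

Response assessment in glioblastoma patients on anti-angiogenic or
multi-kinase therapy (e.g. regorafenib) is hard: the RANO criteria rest on
contrast enhancement and T2/FLAIR signal, both of which these drugs perturb
independently of tumor burden. Hybrid PET/MR offers two semi-quantitative
alternatives acquired in intrinsic co-registration:

- **[¹⁸F]FET PET** — an amino-acid tracer accumulating in glioma tissue.
  The *pathological FET volume* (FET_vol/pat) is the set of voxels with
  standardized uptake ≥ 1.6 × the mean of a contralateral background VOI
  (BG_FET), a biopsy-validated cut-off. TBR_mean and TBR_max are the mean
  and maximum uptake of that volume normalized by the background mean.
- **DWI/ADC** — low ADC marks restricted water diffusion, a surrogate for
  high tumor cellularity. FET_vol/pat is transferred onto the ADC map;
  extra-parenchymal voxels and non-specifically high (CSF-like) values are
  subtracted, giving ADC_vol; the *pathological ADC volume* (ADC_vol/pat)
  is its subset with ADC strictly below the mean of a contralateral 5 mm
  background sphere (BG_ADC).

Longitudinal change is summarized per metric X as
ΔX = X(T1) − X(T0) and ΔX% = (X(T1) − X(T0)) / X(T0) × 100,
and patients with at least a twofold FET-volume increase form the
response-defining split. The cohort layer provides Shapiro–Wilk screening,
Pearson correlation, exact-permutation rank-sum contrasts and
Kaplan–Meier / log-rank survival stratification.

The package ships a seeded digital brain phantom (brain ellipsoid,
ventricles, tumor with diffusion-restricted core and edematous rim, plus
ground-truth masks) and a packaged 16-patient cohort table
(baseline + post-treatment metrics with RANO labels) whose published
summaries the code recomputes.

## Worked example

```python
from fetadc import load_fixture, summarize_cohort
from fetadc.reproduce import correlations, doubling_comparison

cohort = load_fixture()                      # 16 patients, 7 SD / 9 PD
tp = summarize_cohort(cohort)["timepoints"]
fet = tp[tp.parameter == "fet_vol_pat_mm3"]
print(fet[["timepoint", "mean", "sd", "n"]].to_string(index=False))

corr = correlations(cohort)
print("r(dFET%, dADC%) =", round(corr["dfet_pct_vs_dadc_pct"]["r"], 2),
      "over", corr["dfet_pct_vs_dadc_pct"]["n"], "complete pairs")

comp = doubling_comparison(cohort)
print("doubling split:", comp.test, "p =", round(comp.p_value, 4))
```

prints

```
timepoint       mean           sd  n
 baseline 14161.9375 15387.891891 16
     post 25807.1875 34547.777523 16
r(dFET%, dADC%) = 0.54 over 13 complete pairs
doubling split: rank_sum_exact p = 0.0023
```

i.e. the mean pathological FET volume rises from ~14.2 to ~25.8 cm³ after
two treatment cycles, the percentage changes in FET and ADC pathological
volumes correlate moderately (r = 0.54; pairs with a missing ADC volume are
dropped listwise), and patients whose FET volume at least doubled show a
significantly larger ADC_vol/pat increase than the rest (exact two-sided
rank-sum p = 0.0023).

The same pipeline runs on image volumes from the shell:

```bash
fetadc simulate --out phantom/ --seed 1      # synthetic patient + truth masks
fetadc run --config config.json              # FET bg → segment → ADC_vol/pat
fetadc reproduce --out report/               # cohort tables, plots, stats
```

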