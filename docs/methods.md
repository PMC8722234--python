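# Methods

## Measurement model

The pipeline quantifies a glioma lesion on co-registered FET-PET and ADC
volumes in five steps.

1. **FET background.** The mean SUV over a background VOI in the
   hemisphere contralateral to the tumor (BG_FET). The protocol this
   package operationalizes draws that VOI as a crescent by hand; here it is
   an explicit mask input, and the phantom generator emits a contralateral
   half-shell for it.
2. **Threshold segmentation.** FET_vol/pat = voxels with
   SUV ≥ *m* × BG_FET, *m* = 1.6 by default. The comparison is inclusive
   (≥): the rule excludes voxels with uptake *less than* 1.6 × background,
   so a voxel exactly at threshold belongs to the lesion. TBR_mean and
   TBR_max are the mean and maximum SUV of the segmented volume divided by
   BG_FET; an empty segmentation is a valid outcome with NaN TBRs.
   Visual spillover refinement is operationalized as (a) an optional
   restriction mask applied during thresholding and (b) retention of the
   26-connected components intersecting a seed mask. 26-connectivity is the
   standard choice for 3D lesion masks; a seed disjoint from every
   component empties the segmentation and sets a warning flag instead of
   raising.
3. **ADC_vol construction.** The FET mask is transferred to the ADC grid
   (grids must be congruent — registration is upstream tooling, and
   mismatched grids raise rather than resample). Voxels outside the brain
   mask and voxels with ADC ≥ a CSF cutoff are subtracted. The cutoff is
   derived from a ventricular VOI as mean − *k*·SD (*k* = 2 by default):
   the source protocol only "pinpoints" ventricular CSF values without
   stating a rule, so an explicit, configurable rule replaces interactive
   erasure. The cutoff is floored at the parenchymal background mean to
   avoid degenerate cutoffs when the ventricular sample is wide.
4. **Pathological ADC volume.** BG_ADC is the mean ADC of a contralateral
   5 mm-radius sphere in normal parenchyma (a warning is emitted if the
   sphere touches the ventricle mask). ADC_vol/pat = voxels of ADC_vol with
   ADC **strictly below** BG_ADC; ties are excluded (measure-zero on real
   maps, deterministic on phantoms). An empty ADC_vol/pat is recorded as a
   missing value, not a zero volume — this is load-bearing: the cohort
   group means are only reproducible when such patients are excluded
   listwise rather than zero-filled.
5. **Longitudinal deltas.** ΔX = X(T1) − X(T0), ΔX% = ΔX / X(T0) × 100.
   Missing or zero baselines propagate missing deltas. The doubling flag
   is post ≥ 2 × baseline, *inclusive*: "at least a twofold increase" is
   read as a ratio bound, and this reading reproduces the published
   doubling-split group contrast exactly (exact rank-sum p = 0.0023), which
   the Δ% ≥ +200 % reading does not.

## Statistics

- Shapiro–Wilk screening at α = 0.05 selects parametric vs non-parametric
  branches (the cohort metrics are non-normal, so everything downstream is
  rank-based).
- Pearson correlation with listwise deletion of incomplete pairs; at least
  3 complete pairs and non-zero variance required.
- Two-group contrasts use the Wilcoxon rank-sum (Mann–Whitney) test. For
  combined n ≤ 20 the null is enumerated exactly over all C(n, n_a)
  assignments with midranked ties, and the two-sided p is
  min(1, 2·min(P(W ≤ w), P(W ≥ w))); larger samples fall back to the
  tie-corrected normal approximation. A paired signed-rank variant is
  provided; the unpaired exact rank-sum is the default because the cohort
  contrasts (doubling split, SD vs PD) compare independent groups, and its
  exact p-values reproduce the published 0.0023 / 0.17 / 0.53.
- Survival stratification: Kaplan–Meier estimation and the log-rank test
  (lifelines), with split rules `median`, `doubling`, `rano` or
  `threshold:X`. The published survival p-values cannot be recomputed —
  the underlying survival times are not published — so the survival layer
  is validated by property tests instead: agreement with a hand life-table
  oracle, invariance under time rescaling, calibration on identical
  groups, and >80 % power at a threefold hazard ratio with 100 subjects
  per arm over 200 replicates.

## Cohort fixture

The packaged table carries the 16-patient cohort (both timepoints of
FET_vol/pat, TBR_mean, TBR_max, ADC_vol/pat, mean ADC_vol/pat and the RANO
label). The source table's typographic comma artifacts ("1,0370" for
10370) are normalized by comma deletion; the fixture stores raw and
normalized columns side by side and the loader audits both against a
frozen SHA-256 checksum. "/" cells (no voxel below the ADC background
after normalization: three baselines, one post) are stored as missing.
Summary statistics use the n−1 standard deviation. Report rendering
truncates volume and percentage means toward zero and rounds correlations
to 2 decimals, matching the precision conventions of the source tables.
Four patients have a third examination; no numeric values for it are
published, so the fixture stores qualitative direction labels only and the
trajectory figure annotates them as arrows.

## Phantom

The generator emulates only what the pipeline needs to be validated
voxel-for-voxel: a brain ellipsoid (90 % of the field of view), two
mirrored ventricular ellipsoids, a spherical tumor whose core
(`core_fraction` × radius, default 0.6) is diffusion-restricted and whose
rim carries edema-like elevated ADC, and contralateral background VOIs
(half-shell for FET, 5 mm sphere for ADC). Defaults: 64³ voxels at
2.32 × 2.32 × 2.03 mm (the PET reconstruction grid this pipeline targets),
tumor radius 12 mm, TBR 2.0, ADC 500 / 750 / 1300 / 3100 ×10⁻⁶ mm²/s for
core / parenchyma / edema / CSF — values in the range of clinical
b = 0/1000 maps. Noise is additive Gaussian per modality from a single
seeded generator; PET count statistics, point-spread/partial-volume
effects, anatomy beyond ellipsoids and registration error are *not*
modeled, so phantom-based tests demonstrate correctness of the
thresholding/masking arithmetic, not robustness to scanner physics.
Noise-free, the compartments are piecewise constant, so segmentation at
1.6 × background recovers the tumor mask exactly for TBR > 1.6 and the
pathological ADC volume equals the core mask; these identities are the
ground-truth acceptance checks. Monte-Carlo checks use 20 seeds at 40–48³
grids and a 5 % background-SD PET noise level.

## Numerical and design notes

- All masks are boolean grids with volume = voxel count × voxel volume;
  congruence (shape + spacing) is checked before any computation.
- NIfTI I/O writes a diagonal affine encoding the spacing; orientation
  metadata beyond that is out of scope, and 4D or non-finite inputs are
  rejected.
- Mask statistics use the n−1 SD (NaN for single-voxel masks); empty masks
  raise a dedicated error so callers choose a policy explicitly.
- Determinism: phantom generation, the pipeline and report rendering are
  bit-reproducible for a fixed spec/config; the per-patient run log records
  every threshold, input path and the package version.
- Known limitations: no registration/resampling, no partial-volume
  correction, no dynamic (time-activity) PET analysis, no ADC histogram
  mixture modeling, no DICOM.
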