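# Methods

This note documents the models, parameters and numerical choices behind
`bpequant`, and what the phantom-based validation does and does not show.

## Enhancement model and measures

Each study consists of one pre-contrast and three post-contrast
fat-suppressed T1 volumes on a common grid; the subtraction sequences
SUB1–SUB3 are post − pre in acquisition order. The voxel-wise enhancement
ratio is R% = (I_post − I_pre)/I_pre × 100, computed only inside the breast
mask. A voxel is enhancing when R% ≥ R%_cutoff, with the threshold
**inclusive** (a voxel exactly at the cutoff counts). The default cutoff is
20%, with 30% and 40% as robustness settings; |BPE| is the physical volume
of enhancing voxels and BPE% its fraction of |Breast|. Voxel volume is
`prod(spacing_mm)/1000` cm³; anisotropic grids (e.g. 2 mm slices, 1 mm
in-plane) are supported, and all percentage measures are computed from
voxel counts so that mask-derived identities hold to machine precision.

Division guard: voxels with pre-contrast signal ≤ `pre_floor` are removed
from the valid mask — they still count toward |Breast| but can never
qualify as enhancing. The default floor is 0 (appropriate for noiseless
phantoms); real data with signal noise near zero should raise it. This
guard is a design choice of the package: some convention is required to
avoid division by noise, and excluding rather than clamping keeps |Breast|
bookkeeping untouched.

Alignment: the three post-contrast volumes are aligned to the first
post-contrast grid before R% is computed (the first sequence is the
conventional reference for BPE reading). `rigid_align` finds the
integer-voxel translation maximizing FFT cross-correlation and applies it
with circular boundary handling; a constant volume yields a flat
correlation surface and falls back to the identity with a warning.
Alignment never changes grid shape or spacing. Computing R% on native
(unaligned) grids is available by passing `align=False`.

## Segmentation

The breast/FGT segmentation is a deliberately simple, deterministic
stand-in for clinical-grade tools, validated on phantoms only:

1. global Otsu threshold on the pre-contrast volume (foreground = above);
2. morphological closing with a radius-1 ball;
3. per-slice posterior chest-wall cut: the most anterior row whose
   foreground fraction reaches 0.9 starts the body slab, and everything at
   or behind it is removed;
4. left/right split at the mid-grid sagittal plane, largest connected
   component per side;
5. FGT = the brighter Otsu class inside each breast mask (fat-suppressed
   convention: fat dark, fibroglandular tissue bright).

One numerical subtlety: histogram-based Otsu returns the *centre* of the
lower class's top bin, and a discrete intensity can sit above that centre,
leaking the lower class into `intensity > threshold`. The threshold is
therefore snapped to the midpoint between the largest lower-class sample
and the smallest upper-class sample, which makes binarization exact for
well-separated classes. Degenerate inputs raise typed errors: an all-zero
volume has no foreground; a constant-intensity breast has no two-class
structure.

## The digital phantom

`generate_phantom` builds two half-ellipsoid breasts (default semi-axes
40 × 55 × 28 mm) attached anteriorly to a full-width body slab, on a
64 × 128 × 128 grid with 2 × 1 × 1 mm spacing — emulating a bilateral
axial acquisition with 2 mm slices. The chest-wall plane sits *between*
voxel rows and each ellipsoid is centred on it, so every breast is an
exact half ellipsoid with analytic volume (2/3)πabc, used as a closed-form
oracle for segmentation.

FGT and enhancing voxel sets are chosen by deterministic ranking: the FGT
set is the innermost `round(fgt_fraction/100 × n_breast)` voxels by
normalized ellipsoid radius, and the enhancing set is the same count rule
applied to a radius about a centre shifted one third of the breast depth
anteriorly (so the two regions overlap but are not nested). Because the
counts are exact, the designed measures (|Breast|, |FGT|, FGT%, per-SUB
|BPE|, BPE%) are exact rational numbers, and the quantification stage
reproduces them to machine precision at zero noise.

Enhancement is multiplicative: post-contrast sequence k multiplies the
pre-contrast signal of enhancing voxels by 1 + r_k/100, with non-decreasing
design ratios (default 30/40/50%), so the designed R% is exact by
construction and |BPE| is non-decreasing across SUBs at any cutoff below
r_1. Noise is additive Gaussian, independent across voxels and sequences;
the stream order is pre-contrast first, then the three post-contrast
volumes, all from one root seed. Default intensities are fat 60, FGT 200
(arbitrary units) — far enough apart that small noise (SDs of a few
percent of the fat signal) leaves thresholding stable.

What the phantom does **not** emulate: pharmacokinetic uptake curves, coil
bias fields, spatially correlated noise, motion other than global
translation, and anatomy beyond smooth ellipsoids. Passing phantom tests
therefore demonstrates correctness of the *measurement machinery*, not
segmentation performance on clinical images.

## The simulated cohort

`generate_cohort` draws 1:1 matched case-control tables. Defaults encode a
51-pair screening-age cohort: per-SUB BPE% means/SDs 45/58/62 ± 9/11/11
(cases) and 40/51/56 ± 11/13/14 (controls); FGT% 13.5 ± 7.5 for both
groups (FGT does not separate the groups by design); ages uniform on
31–60 with controls matched within ±3 years; postmenopausal proportion
0.43; family-history proportion 0.56; ordinal density category
probabilities (0.03, 0.26, 0.64, 0.07). |Breast| is drawn as 1000 ±
250 cm³ (truncated at 200), the value range implied by the ratio of
absolute to percentage BPE summaries above; |BPE| and |FGT| are derived as
percentage × volume/100, so the table is internally consistent.

Correlation structure: BPE% across the three SUBs is equicorrelated
(ρ = 0.8, reflecting that the three subtraction measures are near-ordered
repeat measurements); a control's two breasts (benign-lesion side and
contralateral side) are drawn jointly with bilateral correlation 0.56 for
BPE% and 0.86 for FGT% and breast volume, matching the strong bilateral
symmetry of breast composition. Percentages are clipped to [0, 100]
after drawing; at the default parameters clipping is negligible.

For estimator validation the generator has a second mode: when
`effect_log_or_per_unit` is set, both pair members are drawn from the
control distribution and case status is assigned by the 1:1 conditional
logistic model at that log-odds (per SUB1 BPE% point), so the true
conditional coefficient is known exactly. Setting it to 0 produces exact
null cohorts for calibration studies.

## Statistics

* **Conditional logistic regression** (1:1 pairs) is fitted as an
  intercept-free binary logistic model on case-minus-control covariate
  differences: Newton–Raphson with step-halving on standardized
  covariates, gradient max-norm tolerance 1e-8, at most 100 iterations.
  Wald SEs come from the observed information on the natural scale.
  Separation is detected either by standardized coefficients exceeding 30
  or by every informative pair being fitted at probability ~1 (monotone
  likelihood); a separated fit carries a `separation` flag and refuses to
  report odds ratios. All-zero difference columns are pinned at zero with
  a `flat` flag. Odds ratios are reported per increment — 200 cm³ for
  volume measures, 20 percentage points for percentage measures —
  while coefficients are always stored per natural unit.
* **Multivariable adjustment set**: menopausal status (0/1), family
  history (0/1), ordinal density (1–4), |FGT| and FGT%.
* **FDR**: Benjamini–Hochberg step-up, applied within each six-test family
  (two BPE measures × three SUBs, separately for univariate and
  multivariable models and for each comparison).
* **AUCs** come from unconditional logistic regression fitted
  probabilities scored by the Mann–Whitney estimator (ties credited 0.5);
  "combination" predictors mean both |BPE| and BPE% entered jointly in one
  model — the natural reading where a combined discriminator is needed.
  Correlated AUCs on the same subjects are compared with DeLong's
  placement-value (structural-component) test; a zero-variance difference
  returns p = 1 with a degenerate flag. Nested unconditional models are
  compared by the likelihood-ratio chi-square.
* **Comparison A vs B** is a breast-selection policy, not duplicated code:
  A uses the contralateral (disease-free) breast of both groups, B swaps
  in the benign-lesion breast for controls. Benign lesions are treated as
  normal tissue; the diseased breast of cases is never quantified.

## Problem sizes used in validation

The test and acceptance runs use: a 64 × 128 × 128 phantom for exactness
and segmentation checks (plus a 24 × 48 × 48 phantom for fast unit tests);
32³ volumes for voxel-loop oracle equality; 200 replicate cohorts of 500
pairs for coefficient-recovery coverage; 500 null cohorts of 100 pairs for
Wald calibration; 500 replicates for LRT calibration and 1000 for DeLong
calibration. These sizes give Monte-Carlo standard errors comfortably
inside the asserted bands while keeping a full run to a few minutes.

## Known limitations

* Segmentation is validated only on phantoms; clinical use should supply
  externally derived masks or a dedicated segmentation tool.
* Rigid alignment is translation-only with circular boundary handling;
  rotations and non-rigid motion are out of scope.
* The cohort generator draws covariates independently of age and of each
  other, which is simpler than real epidemiology; it is designed to test
  estimators, not to emulate confounding structure.
* Subgroup analyses (e.g. by menopausal status) and exact conditional
  inference for small discordant counts are not implemented.
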