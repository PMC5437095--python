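# bpequant

Fully automated quantification of **background parenchymal enhancement
(BPE)** in breast dynamic contrast-enhanced MRI, with the matched
case-control statistics needed to relate BPE to breast cancer presence.

BPE is the contrast uptake of *normal* fibroglandular breast tissue in
DCE-MRI. Radiologists grade it visually on a four-level scale, which is
subjective and poorly reproducible; this package instead measures it
volumetrically. It is aimed at quantitative-imaging researchers who want a
tested, scriptable reference pipeline — from volumes to odds ratios — plus
a synthetic phantom/cohort generator with exact ground truth, so every
stage can be validated without patient data.

## What it computes

Given a pre-contrast volume and three post-contrast volumes (subtraction
sequences SUB1–SUB3), each voxel's enhancement ratio is

    R% = (I_post − I_pre) / I_pre × 100 = I_sub / I_pre × 100

and a voxel is *enhancing* when R% ≥ R%_cutoff (default 20%, robustness
values 30% and 40%). Per breast:

* |Breast| — breast volume (cm³) from automated segmentation,
* |BPE| — volume of enhancing voxels (cm³); BPE% = |BPE| / |Breast| × 100,
* |FGT| — fibroglandular tissue volume; FGT% = |FGT| / |Breast| × 100.

For a 1:1 age-matched case-control cohort the statistics module fits
conditional logistic regression on within-pair differences (odds ratios
reported per 200 cm³ of |BPE| or per 20 percentage points of BPE%, with
Wald CIs and Benjamini–Hochberg FDR adjustment across the six BPE
analyses), unconditional logistic regression with ROC AUCs, DeLong's test
for correlated AUCs, likelihood-ratio tests for nested models, Spearman
correlations and paired t-tests.

## Worked example

```python
import numpy as np
from bpequant import (PhantomParams, CohortParams, generate_phantom,
                      generate_cohort, segment_breast, enhancement_ratio_map,
                      compute_bpe, ConditionalLogit)
from bpequant.image import BreastMask

# a zero-noise digital phantom with designed BPE% = 40 at R% ratios 30/40/50
study, truth = generate_phantom(PhantomParams(seed=0))
left = BreastMask(truth.breast_mask["left"], "left", (2.0, 1.0, 1.0))
emap = enhancement_ratio_map(study.pre, study.posts[0], left, sub_index=1)
bpe = compute_bpe(emap, left, r_cutoff=20.0)
print(f"|Breast| = {bpe.breast_volume_cm3:.1f} cm3, BPE% = {bpe.percent:.2f}")

# a simulated 51-pair matched cohort and its SUB1 BPE% odds ratio
cohort = generate_cohort(CohortParams(n_pairs=51, seed=1))
fit = ConditionalLogit.from_cohort(cohort, "bpe_pct_sub1").fit()
print(fit.summary())
```

prints

```
|Breast| = 129.1 cm3, BPE% = 40.00
Conditional logistic regression (1:1 matched pairs)
  pairs used: 51   log-likelihood: -31.5552
  converged: True   flags: none
  covariate                   coef        se         p     OR/incr
  bpe_pct_sub1             0.06500   0.02639    0.0138       3.669
```

The phantom's measured BPE% equals its designed enhancing fraction exactly
(zero noise makes the design analytic), and the simulated cohort — whose
case/control BPE% distributions are 45 ± 9 vs 40 ± 11 — yields an odds
ratio of 3.7 per 20 BPE% points for this draw (0.0138 is the two-sided
Wald p-value; the OR column is per the 20-point reporting increment).

A thin CLI wraps the same functions: `bpequant phantom|cohort|segment|
quantify|stats|run` (see `bpequant --help`).

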