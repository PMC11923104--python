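# stromaprog

Automated tumor/stroma/lymphocyte quantification on H&E histology images
and prognostic stratification of surgical cohorts by the resulting tissue
fractions.

## The problem

In stroma-rich carcinomas such as pancreatic ductal adenocarcinoma, the
proportion of desmoplastic stroma and the degree of lymphocyte infiltration
within the tumor region carry prognostic information that routine pathology
does not quantify.  This package implements a complete, desk-scale version
of that analysis for digitized H&E slides:

1. **Tile-based semantic segmentation.**  A pathologist-outlined region of
   interest (ROI) is tessellated into square tiles (396 px per side at
   0.25 μm/px, i.e. 99 μm of tissue).  A *valid-convolution U-Net* labels
   every ROI pixel as stroma, tumor or lymphocyte.  Because the network
   uses only unpadded 3×3 convolutions, a 396-px input yields a 212-px
   output; seamless slide-level maps are produced with the *overlapping
   tile strategy*: output windows tile the ROI disjointly while each input
   window carries a 92-px mirror-padded context border.  Tiles are color
   normalized with the Macenko method (optical-density conversion, SVD
   stain-plane estimation, percentile angle extremes) before training and
   inference.
2. **Quantification.**  Per slide, with `A_ROI` the ROI pixel area,

       A_Stroma = A_ROI − (A_Tumor + A_Lymphocytes)

   and the fractions SIP = A_Stroma/A_ROI (stroma in percentage),
   LIP = A_Lymphocytes/A_ROI, TIP = A_Tumor/A_ROI, with
   SIP + LIP + TIP = 1 exactly.
3. **Cutpoint statistics.**  SIP is split into three groups
   (low/intermediate/high) by an X-tile-style exhaustive two-threshold
   search maximizing the 3-group log-rank χ²; LIP is dichotomized by the
   maximally selected rank statistic (maximum standardized log-rank
   statistic over candidate cuts, Lausen–Schumacher adjusted p).  SIP-low
   and SIP-high — both unfavourable — are merged into SIP-LH, and patients
   are classified into combined risk groups: **Group 1** = SIP-intermediate
   ∧ LIP-high, **Group 3** = SIP-LH ∧ LIP-low, **Group 2** = the rest.
4. **Survival analysis.**  Perioperative deaths (≤30 days) are excluded;
   Kaplan–Meier curves with median OS and 95% CIs, log-rank tests,
   group-1 hazard-ratio contrasts, and a univariate → multivariate Cox
   screen (p < 0.05 carry-forward) report whether SIP and LIP are
   independent predictors.

Because clinical slides cannot ship with a software package, the
`synthetic` module generates H&E-like scenes (gland structures, fibrous
stroma, basophilic lymphocyte clusters) with *pixel-exact* ground-truth
masks, and survival cohorts whose hazard depends on SIP (U-shaped: the
intermediate band is protective) and LIP (high infiltration protective).
Every stage of the pipeline is exercised and tested end-to-end on these
synthetic data.

## Worked example

```python
import stromaprog as sp

# simulate a cohort with known prognostic structure and stratify it
cohort = sp.generate_cohort(sp.CohortParams(n_patients=600, seed=42))
res = sp.SipLipStratification(cohort).fit()
print(res.summary())
```

prints (abridged):

```
SIP/LIP prognostic stratification
================================================
patients analysed: 573 (excluded by filtering: 27)
SIP cuts (low | intermediate | high): 0.5391, 0.7250 (chi2 = 26.37)
LIP cut (low vs high): 0.0197 (|Z| = 7.58, p = 4.51e-12)

combined groups (1 = SIP-intermediate & LIP-high, 3 = SIP-LH & LIP-low):
  group 1: n = 78, median OS 43.7 months (95% CI 33.4-60.9)
  group 2: n = 297, median OS 24.4 months (95% CI 21.7-27.3)
  group 3: n = 198, median OS 13.6 months (95% CI 10.2-15.7)
log-rank across groups: chi2 = 86.23, p = 1.89e-19

hazard-ratio contrasts (group 1 as reference):
  1 vs 2: HR = 0.50 (95% CI 0.37-0.68), p = 6.09e-06
  1 vs 3: HR = 0.26 (95% CI 0.19-0.37), p = 3.4e-15
  1 vs others: HR = 0.42 (95% CI 0.31-0.56), p = 2.74e-09

multivariate Cox (variables with univariate p < 0.05):
  sip_intermediate: HR = 0.56 (95% CI 0.46-0.70), p = 1.07e-07 [independent predictor]
  lip_high: HR = 0.48 (95% CI 0.40-0.58), p = 1.03e-14 [independent predictor]
```

The search recovers the generating truth: the cohort was simulated with
SIP cuts (0.54, 0.75), LIP cut 0.02, and exponential hazards making the
intermediate-SIP/high-LIP group's event rate roughly half that of the
mixed groups (group medians ≈ 46/24/12 months); the 27 excluded records
are simulated deaths within the first month, matching the perioperative
rule.

The imaging side is exercised the same way:

```python
params = sp.SceneParams(seed=0)                      # one 396-px scene
rgb, mask = sp.generate_tile_scene(params)           # image + exact mask
slide, roi, full_mask = sp.generate_slide((2, 2), params)
q = sp.quantify(full_mask, roi)
print(q.sip, q.lip, q.tip)                           # area fractions
```

A narrow U-Net trained on 200 such scenes reaches per-class Dice
0.99/0.98/0.82 (stroma/tumor/lymphocyte) on held-out scenes — see
`tests/test_acceptance.py`.

## Layout

| module | contents |
| --- | --- |
| `stromaprog.synthetic` | H&E-like scene/slide generator with exact masks; survival cohort simulator |
| `stromaprog.tiling` | ROI rasterization, tile planning, mirror-padded extraction, stitching |
| `stromaprog.stain` | Macenko stain estimation and normalization |
| `stromaprog.segmentation` | numpy valid-convolution U-Net, training schedule, IoU/Dice metrics |
| `stromaprog.quantify` | class areas and SIP/LIP/TIP per slide and per patient |
| `stromaprog.cutpoints` | maximally selected rank statistic; X-tile-style two-cut search; group algebra |
| `stromaprog.survival` | filtering, Kaplan–Meier, log-rank, Cox screens, baseline tables |
| `stromaprog.model` | `SipLipStratification` / `SipLipResults`: the end-to-end fit |
| `stromaprog.cli` | `stromaprog simulate-slide / segment / quantify / cutpoint / stratify` |
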