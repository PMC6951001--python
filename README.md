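# t1quant

Hyper-acute cardiac MRI infarct characterisation on quantitative parametric
maps: threshold-based segmentation of the oedematous **area-at-risk (AAR)**
on native T1 maps, delineation of infarct (**LGE**), no-reflow
(**microvascular obstruction, MVO**) and haemorrhage (**IMH**) compartments,
the **myocardial salvage index**, and the cohort statistics that link the
hyper-acute T1 severity of injury to final infarct size.

## Who this is for

Imaging scientists working on ST-elevation myocardial infarction (STEMI)
who need a tested, deterministic reference implementation of the standard
remote-ROI threshold rules — and a way to exercise them end-to-end without
patient data. The package ships a digital short-axis phantom generator with
pixel-level ground truth and a cohort simulator parameterised from
published group summaries, so every stage is verifiable.

## The rules implemented

With remote-reference statistics (mean `μ_R`, sample SD `σ_R`) taken from a
myocardial sector placed 180° opposite the injured sector:

* **AAR (native T1)** — pixels with `T1 > μ_R + 2 σ_R`; the severity of
  injury is the pixelwise mean T1 over the delineated area, and subjects
  split into **high** (≥ 1400 ms) and **low** (< 1400 ms) severity groups.
* **LGE (signal intensity)** — pixels with `SI > μ_R + 5 σ_R`; enclosed
  hypointense MVO cores (`SI < μ_R + 2 σ_R`, topologically walled in by the
  enhanced region and the LV cavity) are added back into the infarct mask.
* **IMH (T2\*)** — connected components darker than the AAR periphery by
  2 SD *and* with mean T2\* < 20 ms (dual criterion).
* **Salvage** — `MSI = 100 × (oedema% − infarct%) / oedema%` from the 24 h
  T1-derived oedema and the 6-month infarct extent; a final infarct
  > 9.5 %LV counts as *large*.
* **Statistics** — Shapiro-Wilk-routed group tests (Welch t / Mann-Whitney,
  χ² / Fisher), a p < 0.05 univariate screen feeding an OLS model of
  outcome on mean T1 per 10 ms (VIF collinearity flags), and rank-based ROC
  with the Youden-optimal threshold under a `score ≥ threshold` rule.

All extents are area ratios over the imaged slices (uniform density
assumption); ties at a threshold are never lesion.

## Worked example

```python
from t1quant import (PhantomSpec, MvoCoreSpec, ImhCoreSpec, generate_phantom,
                     segment_study, extent_pct_lv, mean_t1_of_aar,
                     imh_extent_mm2, classify_t1_group, compute_msi)

spec = PhantomSpec(mvo_core=MvoCoreSpec(), imh_core=ImhCoreSpec(), seed=42)
ph = generate_phantom(spec)
seg = segment_study(ph.t1, ph.t2star, ph.lge_si, ph.myocardium, injured_center=90.0)
sp = ph.t1.pixel_spacing
aar_pct = extent_pct_lv(seg.aar, ph.myocardium, sp)
mean_t1 = mean_t1_of_aar(ph.t1, seg.aar)
```

prints, via the obvious f-strings:

```
AAR threshold : 1257.4 ms
LGE threshold : 153.5 a.u.
AAR extent    : 37.2 %LV (ground truth 39.8)
mean T1 of AAR: 1473 ms -> group HIGH
LGE extent    : 26.2 %LV   MVO extent: 7.3 %LV
IMH area      : 93.2 mm^2 (core mean T2* 12.3 ms)
MSI if final infarct were 19 %LV: 48.9 %
```

The AAR threshold is the remote mean (≈1200 ms) plus twice the remote SD
(noise 30 ms); the recovered extent sits within ~2.5 points of the
constructed 40 %LV sector and the mean T1 within a few ms of the
constructed oedema (1500 ms, pulled down slightly by the −250 ms no-reflow
step-down the mask legitimately contains).

At the cohort level:

```python
from t1quant import CohortSimSpec, generate_cohort, CohortAnalysis

df = generate_cohort(CohortSimSpec(seed=0))       # 24 low / 15 high subjects
print(CohortAnalysis(df).fit().summary())
```

ends with

```
univariate screen (p < 0.05): ['ischaemia_time_min']
mean T1 per 10 ms: beta = 1.081 (95% CI 0.635 to 1.527), p = 2.058e-05
adjusted for: ['ischaemia_time_min', 'aar_pct_lv']

ROC: mean T1 vs large final infarct
AUC = 0.84 (p = 0.0004777); optimal threshold 1371 ms; sens 0.71, spec 1.00, PPV 1.00, NPV 0.68
```

i.e. in a simulated 39-subject cohort the mean T1 of the AAR independently
predicts final infarct size and discriminates large infarcts with perfect
positive predictive value at a threshold close to the 1400 ms grouping
cut-off — the qualitative pattern the statistics layer is designed to
detect.

A `t1quant` console command exposes the same stages
(`simulate-phantom`, `simulate-cohort`, `segment`, `quantify`, `analyze`,
`run`) over NIfTI maps, CSV cohorts and YAML configs.

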