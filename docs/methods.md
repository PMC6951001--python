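# Methods

## Problem and scope

After reperfused ST-elevation myocardial infarction, quantitative CMR maps
acquired within hours of the intervention carry prognostic information: the
extent of the oedematous area-at-risk (AAR, native T1), the severity of
injury (mean T1 of the AAR, dichotomised at 1400 ms), the infarcted
fraction (late gadolinium enhancement, LGE), no-reflow (microvascular
obstruction, MVO), haemorrhage (IMH, T2\*), and the salvage index derived
from their evolution. `t1quant` implements the threshold-based delineation
rules, the per-subject scalar metrics and the cohort statistics of this
analysis chain, together with synthetic data generators that make every
stage testable at pixel level. MR physics (pulse sequences, B1/coil
effects, partial volume, motion), cine-derived ventricular volumetry and
angiographic/ECG scoring are out of scope; volumes, ejection fraction and
procedural covariates appear only as simulated scalar columns.

## Geometry and conventions

Grids are 2-D `(row, col)`, 0-based, pixel-centre; angles are degrees in
[0, 360) about the myocardial centroid, measured from the +col axis toward
the +row axis in physical (mm) coordinates, so sectors are circular even
under anisotropic spacing. "% of LV mass" is an area ratio — lesion pixel
area over myocardial pixel area, summed over the imaged slices — under a
uniform-density, uniform-thickness assumption; only the targeted slices
enter the denominator (whole-LV coverage is not assumed). Ties are fixed:
hyperintense rules use strict `>`, hypointense rules strict `<` (a pixel
exactly at a threshold is never lesion — the strict-`<` choice is forced by
the noiseless degenerate case, where an SD of zero puts every remote-valued
pixel exactly at the threshold); the 1400 ms grouping uses `≥` (ties are
HIGH) and the 9.5 %LV large-infarct rule uses strict `>`. Sample SDs use
the n−1 denominator everywhere.

## Segmentation operators

* **Remote ROI** — the transmural sector (default width 60°) centred 180°
  opposite the injured-sector centre; the injured angle is an input (visual
  wall-motion assessment is not modelled). A 360° width degenerates to the
  whole ring and is warned about.
* **AAR** — threshold `remote mean + 2 SD` on T1; the mask excludes the
  reference sector itself, keeping ROI and AAR disjoint by construction.
  By default the raw threshold mask is reported ("no exclusion applied" to
  enclosed cores, but none added either); `fill_aar_holes=True` adds
  enclosed low-T1 pockets, the behaviour appropriate when a no-reflow
  "step-down" core must count as injured tissue.
* **LGE** — threshold `remote mean + 5 SD` on signal intensity; enclosed
  hypointense cores are merged into the final infarct mask.
* **MVO** — an automated, deterministic surrogate for manual dark-core
  delineation: the topological holes of the supra-threshold LGE mask
  (computed with the LV cavity counted as enclosing, so subendocardial
  pockets qualify while the border-connected remote myocardium never does),
  intersected with pixels below `remote mean + 2 SD`. An earlier
  neighbour-based enclosure rule was rejected: it is vacuously true for the
  ring complement and a single high-noise pixel inside the core breaks it.
* **IMH** — periphery = the 1-pixel 4-connected inner morphological
  boundary of the AAR; candidates are AAR pixels below
  `periphery mean − 2 SD`; a 4-connected component is haemorrhage only if
  its mean T2\* is below 20 ms. The search region is always the hole-filled
  AAR: a no-reflow step-down punches a hole in the raw 2SD mask, and
  without filling, the periphery statistic would run through the
  haemorrhage core itself.

Remote statistics are computed per slice (pooling across slices is a
caller-level choice). The operators are vectorised but verified
bit-identical against naive per-pixel double-loop reference
implementations on randomised phantoms.

## Phantoms

A phantom is an annular ring (default endocardial/epicardial radii
22/32 mm) on a 96×96 grid at 0.9 mm spacing — the reconstructed in-plane
resolution of ShMOLLI T1 maps, which gives the ring and the reference ROI
realistic pixel counts (~2100 and ~350). Tissue values: remote T1 1200 ms,
oedema +300 ms over a 144°-wide sector (~40 %LV, the typical acute AAR
burden); remote T2\* 35 ms with haemorrhage cores at 12 ms; LGE signal
100 (remote) vs 300 (infarct, transmural fraction 0.7 of the sector), with
a subendocadial MVO core carrying a −250 ms T1 step-down and hypointense
signal (80). Per-map i.i.d. Gaussian noise defaults to 30 ms (T1), 2 ms
(T2\*) and 10 a.u. (LGE, i.e. SNR 10 against the remote signal). All
randomness flows from one explicit integer seed through
`numpy.random.default_rng`; maps are drawn in a fixed order so identical
seeds give bit-identical phantoms.

What the phantoms deliberately omit: partial-volume blur at compartment
boundaries, surface-coil intensity gradients, spatially correlated noise,
through-plane effects and irregular lesion shapes. Passing the recovery
tests therefore demonstrates correctness of the threshold logic under the
stated noise model, not clinical-grade robustness on real maps.

## Distributions and the simulated cohort

Lesion burdens reported as median (IQR) with frequent exact zeros are
modelled as zero-inflated log-normals: a point mass `p_zero` (one minus the
published incidence) plus a log-normal positive part. `fit_zi_lognormal`
follows the convention that the stated quantiles describe the positive
part: `μ = ln(median)` exactly and `σ = ln(q3/q1)/(2 z₀.₇₅)`, the
least-squares solution on the log scale. When printed quantiles reach into
the zero mass (a median or lower quartile of 0), the overall quantiles are
mapped through the zero mass to positive-part levels and fitted by
regression; with only one informative quantile the shape is
underdetermined and `σ` defaults to 1.0.

The cohort simulator draws one row per subject, stratified into the
low/high T1-severity groups (default sizes 24/15, the hyper-acute cohort),
with every variable drawn independently within its group from the
published group summary: Normals for mean ± SD rows, zero-inflated
log-normals for median (IQR) rows, Bernoullis for incidences. Presence
columns (`mvo_present`, `imh_present`) are derived from extent > 0 so the
published incidences enter exactly once, as the zero mass. Two quantities
have no published distribution and are **synthetic choices**: the
per-group mean T1 of the AAR (Normal(1340, 40) truncated below 1400 vs
Normal(1460, 50) truncated at/above it, keeping the group invariant exact)
and troponin (log-normal, median 2000, IQR 700–5500). Percentages are
clipped to [0, 100]; the `mvo ≤ lge` constraint is enforced by bounded
resampling of the MVO draw. Because rejected positive draws re-expose the
zero mass, the post-constraint MVO incidence runs ~2 points below the raw
rate — an accepted interaction of the published marginals with the
constraint. Dropout across timepoints is not simulated (every subject has
complete data). An optional Gaussian-copula hook can impose rank
correlations between chosen columns; it is off by default since no
correlation structure is published.

## Statistics layer

Continuous group comparisons are routed by per-group Shapiro-Wilk at
α = 0.05: both non-rejected → two-sample t-test, else Mann-Whitney U.
The t-test is Welch (unequal variances) by default — a deliberate
robustness choice over the classic pooled test, which remains available
via `pooled=True`. Groups too small or constant for Shapiro-Wilk route
non-parametrically; two identical constant samples compare equal with
p = 1 by convention. Categorical comparisons use chi-squared unless an
expected cell is below 5, then Fisher's exact test (2×2). The univariate
screen regresses the outcome on each candidate covariate (binary
covariates coded 0/1 — regression rather than group tests, one of two
defensible readings) and keeps p < 0.05; the multivariate model is OLS of
the outcome on mean T1 divided by 10 (so the coefficient reads per 10 ms)
plus the screened covariates and optionally the AAR extent, with VIF > 5
flagged and exactly singular designs rejected by name. ROC analysis uses
the tie-corrected rank (Mann-Whitney) AUC; its p-value tests AUC = 0.5 via
the normal approximation to U with tie-adjusted variance (DeLong was
considered and not needed at these sample sizes). The operating threshold
maximises Youden's J over observed scores, ties resolved toward the lowest
threshold, with `score ≥ threshold` counted positive — consistent with the
≥ 1400 ms grouping rule. Degenerate predictive values (zero denominators)
are reported as absent, never as 0. No multiple-testing correction is
applied anywhere in this layer, matching common practice for cohort
description tables; interpret the comparison table accordingly.

## Problem sizes and numerical checks

The test suite runs the oracle-equivalence check on ten randomised 64×64
phantoms, the recovery check on twenty 96×96 phantoms at the default noise,
2 000 replicates per route for test calibration and power, 1 000
replicates for CI coverage, and 500 label permutations for the ROC null —
sizes chosen to give tight Monte-Carlo bands while keeping the whole suite
under half a minute on one core. The acceptance script draws 100 000
deviates for the distribution-consistency target; the sample-median
standard error there is ≈ 0.035, an order of magnitude inside the ±0.2
comparison band.

## Known limitations

* The enclosure surrogate for MVO is deterministic but not the manual
  delineation it stands in for; its agreement is demonstrated on phantoms
  only.
* Mean T1 of the AAR is biased a few ms low under noise (supra-threshold
  false positives near the threshold average cooler than true oedema);
  the bias shrinks with ROI size and is inside ±15 ms at the default
  geometry.
* The salvage index is undefined for zero oedema (raised as an error) and
  may legitimately be negative (infarct expansion); negative values are
  logged, not clamped.
* Independence between simulated cohort columns means multivariate
  adjustment sets in simulated data are weaker confounders than in real
  cohorts; the copula hook exists for sensitivity analyses.
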