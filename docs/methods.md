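# Methods

## SUV quantitation and segmentation

SUV uses the body-weight convention, `SUV = C[kBq/mL] × weight[kg] /
dose[MBq]` (the unit factors cancel).  Volumes carry voxel spacing in mm;
derived volumes are reported in cm³ (spacing product / 1000).

Tumour segmentation is a fixed inclusive threshold, SUV ≥ 2.5 by default,
applied after removing voxels covered by a user-supplied *edit mask* — the
programmatic stand-in for manual removal of physiological uptake
(myocardium, bladder, brain).  Above-threshold voxels are joined into
lesions by **26-connectivity** in 3-D; the threshold rule in the literature
does not fix a connectivity, and 26 is the standard choice for lesion
joining (8-connectivity's 3-D analogue).  No minimum component size is
applied by default (`min_voxels=1`).

Per lesion we report voxel count, volume, SUVmean and SUVmax; cohort-level
totals are MTV (sum of lesion volumes), SUVmean (voxel-weighted over *all*
labelled voxels, not lesion-weighted), SUVmax (max over lesions) and
TLG = MTV × SUVmean, which holds exactly by construction.  The equivalent
per-lesion form Σ volumeᵢ × meanᵢ agrees to floating-point tolerance.

The alternative relative mode (`segment_mtv_pct`) detects lesions at the
fixed threshold and then re-thresholds each lesion at a fraction (default
41 %) of its own SUVmax.  Lesion identity is preserved, so the retained
volume is monotone non-increasing in the fraction.  This mode is exposed for
method comparison only and is not validated as the primary measurement.

Maximum tumour dimension (MTD) is the largest Euclidean distance between
voxel centres of the same lesion, in cm; a convex hull prunes the pairwise
search for large lesions (exact all-pairs below 2000 voxels, and the hull is
exact for the diameter whenever it exists).

## Deauville scoring and response

With T the residual SUVmax, M the mediastinal SUVmax and L the liver SUVmax:
DS 1 if no residual segmented uptake; DS 2 if T ≤ M; DS 3 if M < T ≤ L; DS 4
if L < T < 3L; DS 5 if T ≥ 3L.  Only the DS-5 rule (≥ 3× liver) is fixed by
the source protocol; the 2–4 boundaries follow the standard five-point
scale, with boundaries at a reference value resolving to the lower score,
matching clinical convention.  References come from user-supplied liver and
blood-pool masks (SUVmax of the masked voxels); liver masks are checked to
be disjoint from the tumour label map.

Percentage change is `100 × (post − pre)/pre` (reduction negative; division
performed before scaling so complete resolution is exactly −100 %).
Response categories: CMR = DS 1–3; PMR = DS 4–5 with improvement;
no-response/progression = DS 4–5 without improvement.  "Improvement" is not
quantitatively defined in the source protocol; it is operationalised here as
any SUVmax reduction (ΔSUVmax < 0).  This is a design choice; callers can
apply their own rule via `classify_response(ds, improved)`.

## Survival statistics

Kaplan–Meier, log-rank and Cox PH fits are lifelines; Cox ties use Efron's
method (good small-sample behaviour).  `KMCurve.at(t)` is the standard
right-continuous product-limit step value, and year-mark read-outs
(e.g. 5-year PFS) use it; for continuous simulated times the left/right
convention is immaterial.  The trend test over ordered groups is the
log-rank trend (score) test with the level index as ordinal score and the
hypergeometric tie correction — equivalent to the Cox partial-likelihood
score test at β = 0; it tracks the lifelines likelihood-ratio statistic on
the same data (verified in the tests).

Tertiles split at the empirical 1/3 and 2/3 quantiles with ties assigned to
the lower group; fewer than three distinct values triggers a degeneracy
warning.

ROC optimal cut-offs maximise Youden's J = sensitivity + specificity − 1
with candidate thresholds at midpoints between sorted distinct values (plus
open extremes), positive calls at value ≥ cutoff, and ties resolved to the
lowest cutoff.  The positive class is "PFS event ever observed"; the source
analysis does not state its ROC outcome dichotomy, and this simplest choice
is used throughout.  Significance is read at p < 0.05 with no multiplicity
correction, matching the evaluation layer it reimplements.

## Prognostic model

`stratify_mtv_ds` uses MTV-0 ≥ 400 cm³ as "high burden" (the boundary is
high-inclusive: the ≥ form is the one that defines the model groups, even
though dichotomised KM analyses are often printed as "<400 vs >400") and
DS ≤ 3 as CMR.  Alternative groupings substitute ΔSUVmax (good response iff
the reduction strictly exceeds 66 %), TLG-0 (4500) or IPI (0–1 vs 2–5).
Rounded clinical cut-offs (400/4500) are the defaults; the exact ROC optima
(396/4541) are available via `Cutoffs.roc_optimal()`.  Bulky disease is
MTD ≥ 10 cm.

`PrognosticModel.fit()` reports per-group n, share, events, KM survival at
the landmark (default 5 years), Cox HRs versus the low-MTV/CMR reference
with 95 % CIs, a log-rank test across the groups, the three-tier collapse
and the worst group's share of all events.  Groups with no members are
reported empty without an HR.

## Synthetic data

**Phantoms.**  A phantom is a uniform background (SUV 1.0) plus ellipsoidal
(or box) regions: lesions, liver (SUV 2.2), mediastinal blood pool (1.8) and
physiological structures (e.g. bladder at 9.0), optionally degraded by a
Gaussian point-spread blur (FWHM in mm) and additive Gaussian noise
truncated at zero.  Ground truth is voxel-centre-in-region membership
evaluated *before* blur and noise, so true MTV is exactly voxel count ×
voxel volume and the generator is oracle-checkable; with no degradation,
threshold segmentation recovers the truth masks voxel for voxel.  What the
phantom does **not** emulate: attenuation/reconstruction artefacts, spatially
varying noise, respiratory motion and heterogeneous lesion texture — so
passing tests demonstrate correctness of the measurement chain, not clinical
segmentation accuracy on real scans.  Blur deliberately produces the real
effect that inflates fixed-threshold MTV (counts spill beyond boundaries).

**Cohorts.**  Patients are assigned to the four prognostic groups with
probabilities (0.31, 0.14, 0.24, 0.31).  MTV-0 is a two-stratum truncated
lognormal — low stratum median 160 cm³ (log-sd 1.1) on [1.5, 400), high
stratum median 1300 cm³ (log-sd 0.75) on [400, 7360) — calibrated so the
cohort median sits near 595 cm³ with the observed range; SUVmax-0 is
lognormal (median 27, log-sd 0.5) truncated to [5.3, 111).  TLG-0 is MTV-0
times a simulated within-volume mean SUV (lognormal median 7.8, log-sd 0.35,
capped below SUVmax), which reproduces the strong MTV–TLG correlation
(r ≈ 0.91) as an emergent property.  Deauville scores within each response
arm follow the observed score frequencies (34/18/30 for 1–3; 47/18 for 4–5),
and interim SUVmax is drawn inside the score's admissible band against fixed
references (mediastinum 2.0, liver 3.0), so re-scoring the simulated uptake
recovers the simulated score exactly.  Residual MTV-2 is a log-uniform
fraction of MTV-0 per score.  MTD is the sphere-equivalent diameter of MTV-0
with multiplicative lognormal noise (log-sd 0.2), giving bulk/MTV
concordance in the observed range.  IPI and stage are drawn from the
published marginals, independent of group — the joint distribution is not
published, so no dependence is invented.

Survival is exponential per group (proportional hazards hold exactly, giving
closed-form oracles), with censoring uniform over 1.3–7.9 years of
follow-up.  The reference hazard is −ln(0.95)/5 per year (95 % 5-year PFS)
and the default hazard ratios are (1, 0.49, 4.7, 10.1).  Note these two
published anchors are mutually inconsistent under an exponential model
(0.95^4.7 ≈ 0.79, not 0.585), so a second constructor
`CohortSpec.from_five_year_pfs()` derives per-group hazards directly from
target 5-year survivals (0.95, 0.909, 0.585, 0.297) when survival-level
recovery is the quantity of interest; hazard-ratio recovery uses the HR
parameterisation.  One configuration cannot exhibit both sets of numbers.

## Numerical choices and problem sizes

Segmentation thresholds are inclusive (≥); labels are assigned in scan
order and relabelled 1..k after size filtering, so outputs are deterministic.
All randomness flows through `numpy.random.default_rng` seeded from the spec
or CLI seed; fixed seeds give bit-identical phantoms, cohorts and pipeline
artefacts.  Statistical recovery checks use cohorts of 2 000–20 000 and KM
closed-form checks 5 000 samples — large enough that Monte-Carlo error
(assessed as 3× the Greenwood/Wald standard error) is well inside the
tolerances asserted, while the whole suite runs in seconds.

## Known limitations

* No DICOM ingestion, PVE correction or scanner-harmonisation QC; volumes
  are assumed already SUV-scaled (or converted via `compute_suv`).
* The 41 %-of-SUVmax mode is a convenience implementation, not a validated
  alternative measurement.
* The cohort generator reproduces marginal distributions and the group-wise
  hazard structure, not patient-level covariance beyond MTV→TLG and
  MTV→MTD; absolute Cox χ² values from simulated cohorts are not comparable
  to any specific clinical dataset.
* The prognostic model is a stratification + estimation tool; it issues no
  treatment recommendations.
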