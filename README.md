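# petdlbcl

Quantitative FDG-PET/CT prognostics for diffuse large B-cell lymphoma
(DLBCL): metabolic tumour volume segmentation, Deauville response scoring,
and survival stratification with a combined baseline-burden + early-response
prognostic model.

## The problem

Interim FDG-PET after two cycles of RCHOP identifies early responders in
DLBCL, but response alone (Deauville score or ΔSUVmax) does not isolate a
group with a prognosis poor enough to justify changing treatment.  Baseline
metabolic tumour burden does better: combining the baseline metabolic tumour
volume (MTV-0, dichotomised at 400 cm³) with the interim Deauville score
(DS 1–3 vs 4–5) separates patients into three tiers — good (MTV-0 < 400),
intermediate (MTV-0 ≥ 400, DS 1–3) and poor (MTV-0 ≥ 400, DS 4–5) — with the
poor tier concentrating most progression events.

This package implements that analysis end to end, for imaging scientists and
biostatisticians who want a tested, scriptable version of the pipeline:

* **SUV quantitation** — body-weight SUV (`SUV = C·w/D`), threshold
  segmentation of all voxels with SUV ≥ 2.5 into 26-connected lesions,
  MTV (cm³), voxel-weighted SUVmean, SUVmax, TLG = MTV × SUVmean, and the
  maximum tumour dimension (MTD, cm).  A per-lesion 41 %-of-SUVmax mode is
  included for method comparison.
* **Response scoring** — Deauville 1–5 against mediastinal blood pool and
  liver SUVmax (score 5 at ≥ 3× liver), percentage changes ΔSUVmax/ΔMTV/ΔTLG,
  and CMR/PMR/no-response categories.
* **Survival statistics** — Kaplan–Meier, log-rank, tertile Cox regression
  with an ordinal trend test (lifelines, Efron ties), ROC/Youden optimal
  cut-offs, Pearson correlation.
* **Prognostic model** — `PrognosticModel(...).fit()` returns a results
  object with per-group n/share/events, KM 5-year PFS, hazard ratios versus
  the low-MTV/low-DS reference, the three-tier collapse and a `summary()`.
* **Synthetic data** — phantom SUV volumes with voxel-exact ground truth and
  cohort simulation with a known proportional-hazards structure, so every
  stage is testable without patient data.

## Worked example

```python
import petdlbcl as p

# Imaging: phantom -> segmentation -> quantities
vol, truth = p.generate_phantom(p.demo_phantom_spec(seed=0))
vol.edit_mask = truth.region_masks["bladder"]          # physiological uptake
seg = p.segment_mtv(vol, threshold=2.5)
print(f"MTV={seg.mtv_total:.1f} cm3  SUVmean={seg.suv_mean_total:.2f}  "
      f"SUVmax={seg.suv_max_total:.2f}  TLG={seg.tlg_total:.1f}")
# MTV=28.4 cm3  SUVmean=6.07  SUVmax=12.08  TLG=172.4
# (true lesion MTV is 15.7 cm3: the 6 mm reconstruction blur spreads counts
#  beyond the lesion boundary, inflating threshold segmentation - the usual
#  partial-volume behaviour)

# Cohort: simulate -> stratify -> fit
df = p.simulate_cohort_df(p.CohortSpec.from_five_year_pfs(n=5000, seed=7))
print(p.PrognosticModel(df).fit().summary())
```

```
Prognostic stratification (mtv_ds), n = 5000 (0 skipped), events = 1540
log-rank chi2 = 1916.80 (p = 0); KM read-out at 5 years

                 n  share_pct  events  km_landmark_pfs_pct      HR  CI95_low  CI95_high
group
lowMTV_DS13   1591      31.82      54               96.296   1.000       NaN        NaN
lowMTV_DS45    728      14.56      50               92.931   2.104     1.432      3.091
highMTV_DS13  1135      22.70     439               56.373  14.996    11.301     19.899
highMTV_DS45  1546      30.92     997               28.509  33.583    25.512     44.208
...
worst-group share of events: 64.7 %
```

The per-group 5-year PFS recovers the generating values (95.0 / 90.9 /
58.5 / 29.7 %) within Monte-Carlo error; the hazard ratios here are the
cohort's own Cox estimates (large because this generator derives hazards
from the 5-year survivals, not from the reference HRs — see
`docs/methods.md`).

A command-line interface mirrors the library:

```bash
petdlbcl run --seed 3 --out results/demo          # full pipeline
petdlbcl quantify scan.nii --threshold 2.5 --out seg.json
petdlbcl model cohort.csv --out model.json
```

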