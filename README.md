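# gistvol

Volumetric tumor-response assessment for imatinib-treated GIST liver
metastases, as a reusable, tested analysis pipeline:

* **Four response criteria** on per-patient target-lesion summaries:
  RECIST 1.1 (sum of longest diameters, PR ≤ −30% / PD ≥ +20% or new
  lesion), **3D-sphere** (cube-law converted cut-offs −65.7% / +72.8%),
  **3D-ellipsoid** (volumetric changes against −30% / +20%, motivated by
  prolate spheroids whose only changing axis carries the measured
  diameter), and **Choi** (size ±10% combined with a −15% mean CT-density
  change).
* **1D-vs-3D change detection**: per-timepoint 3×3 cross-classification
  of ≥20% diameter versus volume changes.
* **Exact test of table symmetry** for paired categorical calls
  (probability-ordering over conditional Binomial(n, ½) off-diagonal
  pairs, computed in exact rational arithmetic), plus the asymptotic
  Bowker statistic, Bland–Altman limits of agreement, and Spearman rank
  correlation with exact small-sample permutation p-values.
* **Landmark survival analysis**: Kaplan–Meier curves, log-rank tests and
  Mantel–Haenszel hazard ratios by response group at a 3/6/12-month
  landmark, with pre-landmark deaths excluded.
* **Synthetic cohort generator**: prolate-spheroid lesions with latent
  response classes (isotropic/anisotropic responders, stable,
  progressors), anisotropic shrinkage, density decline in responders,
  log-normal reader/method measurement noise, and class-linked
  exponential survival — so every pipeline stage is testable without
  patient data.

The published cross-classification tables ship as packaged CSV fixtures;
`reproduce-tables` re-runs the exact symmetry test on all 24 of them and
verifies every printed P value and derived percentage.

## CLI

```sh
# generate a synthetic cohort (CSV files) into a directory
gistvol simulate --out cohort/ --n 84 --seed 1

# classify every eligible patient/timepoint under all four criteria
gistvol classify --cohort cohort/ --out calls.csv

# change-detection + response-comparison tables with exact p-values
gistvol compare --cohort cohort/ --out report.json

# landmark survival by response group
gistvol survival --cohort cohort/ --criteria ELLIPSOID --landmark 6

# re-analyse the packaged reference tables (non-zero exit on mismatch)
gistvol reproduce-tables --out manifest.json
```

Cohort directories hold `measurements.csv`, `survival.csv`, `scans.csv`
and optionally `events.csv` (new-lesion / new-nodule flags); column
schemas are documented in `gistvol.cohort` and emitted by the simulator.

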