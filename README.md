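# hrvcohort

Heart-rate-variability (HRV) analysis for ambulatory (24 h Holter) cohorts:
from raw RR-interval recordings to reference ranges and survival models.

Autonomic dysfunction is central to heart failure: sympathetic overdrive
and vagal withdrawal leave fingerprints in the beat-to-beat variation of
the heart rhythm. `hrvcohort` implements the full computation path an
epidemiological HRV study needs, for biostatisticians and physiologists
working with Holter-derived interval data:

1. **Preprocessing** — eligibility rules (pacemaker, predominant atrial
   fibrillation, heart transplant), artifact filtering of RR series to
   normal-to-normal (NN) intervals, and uniform resampling to a tachogram.
2. **20 HRV markers** in three domains:
   - *time*: mean HR, SDNN, SDANN, rMSSD, pNN50;
   - *frequency*: ULF/VLF/LF/HF band powers (Welch), total power, LF/HF,
     plus two time-resolved ULF summaries (IQR of a short-time Fourier
     track; median of a MODWT wavelet track);
   - *non-linear*: acceleration and deceleration capacity (phase-rectified
     signal averaging), time lag, embedding dimension (Cao), correlation
     dimension (Grassberger–Procaccia), sample entropy, maximal Lyapunov
     exponent (Rosenstein, radius 100 ms).
3. **Reference ranges** — 5th–95th percentile bounds of each marker in the
   healthy/at-risk subgroup, with below/inside/above classification,
   tertiles, and Table-style distribution summaries.
4. **Marker selection** — a literature hit-count ranking combined with a
   random survival forest (log-rank splitting, minimal-depth importance,
   age and sex forced into every node); the selected set is the union of
   the two top-10 lists.
5. **Outcome models** — per-marker multivariable linear models
   (standardized marker ~ clinical profile) and Cox proportional-hazards
   batteries reporting per-SD hazard ratios
   `HR = exp(β·σ)` with Wald 95% CIs under age/sex and fully adjusted
   tiers, plus Kaplan–Meier cumulative-incidence curves by tertile.
6. **Synthetic cohorts** — a generator producing NN series with LF/HF
   sinusoidal modulation, circadian ULF drift, AR(1) noise, ectopy and
   artifacts, and cohorts whose Weibull survival times depend on marker
   z-scores through a proportional-hazards model, with ground truth saved
   separately.

Statistical models follow the statsmodels idiom: `CoxPH(...)` /
`SurvivalForest(...)` are model objects whose `fit()` returns a results
object with estimates, standard errors, and a `summary()` table.

## Worked example

```python
import math
from hrvcohort import *

# one synthetic 22.49 h recording, filtered to NN intervals
p = RRGenParams(seed=7)
nn = filter_to_nn(gen_rr_record(p, record_id="demo"))

td = time_domain_markers(nn)
fm = band_powers(resample_tachogram(nn, 4.0, method="cubic"))
dc, prof = prsa_capacity(nn, "deceleration")

# a synthetic heart-failure cohort whose hazard rises with acceleration
# capacity at HR 1.53 per SD, recovered by the standardized Cox battery
b = gen_cohort(CohortGenParams(n_subjects=1500, healthy_fraction=0.0,
                               log_hr_per_sd={"ac": math.log(1.53)}, seed=3))
cohort = b.markers.merge(b.covariates, on="record_id")
tbl = run_model_battery(b.markers[["record_id", "ac"]], cohort,
                        AdjustmentSet("age_sex", ("age", "sex")))
```

printed quantities (seed 7 / seed 3):

```
105841 beats recorded, 0 rejected -> 105841 NN intervals
mean HR 78.4 /min, SDNN 78.4 ms, SDANN 75.1 ms, rMSSD 15.9 ms, pNN50 0.00 %
LF 355 ms^2, HF 124 ms^2, LF/HF 2.87
DC 9.105 ms (53038 anchors), AC -9.295 ms
AC per-SD HR 1.45 (95% CI 1.28-1.63), p=2.2e-09, 259 events / 1500 subjects
```

The LF/HF ratio of 2.87 recovers the generator's amplitude-squared ratio
(25/15)² ≈ 2.78 within a few percent; the Cox battery's per-SD hazard
ratio for AC brackets the configured 1.53 set-point.

## Command line

```sh
hrvcohort simulate --n-subjects 50 --mode full --seed 1 --out sim/
hrvcohort run-all --config pipeline.yaml
```

Verbs `preprocess`, `markers`, `ranges`, `select`, `models` run single
stages; `run-all` executes the whole path from a YAML config and writes
CSV/JSON artifacts with run metadata (effective config, hash, seed).

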