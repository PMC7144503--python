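# suddengains

Rule-based detection and matched-control analysis of **sudden gains** —
large, stable symptom improvements between two consecutive therapy
sessions — in weekly questionnaire trajectories, as collected in routine
trauma-focused treatment for PTSD. The package is aimed at clinical
researchers who want a tested, reproducible implementation of the whole
analysis chain: detection, control matching, longitudinal modelling and
cross-sample pooling, plus a synthetic cohort generator for validating
every stage against known ground truth.

## The method

A sudden gain between sessions *N* (pregain) and *N*+1 (postgain) on a
0–51 symptom scale must satisfy three joint criteria:

1. **absolute magnitude** — `score_N − score_{N+1} ≥ 6.15`, where 6.15 is
   the standard error of the difference score from the reliable change
   index, `s_diff = sd·√(2(1−r))`;
2. **relative magnitude** — the drop is at least 25 % of the pregain
   score;
3. **stability** — `mean(pre) − mean(post) > t_crit(df) · s_pooled`,
   comparing up to three scores before (*N*−2…*N*) and after
   (*N*+1…*N*+3) the interval with
   `s_pooled = √((sd_pre² + sd_post²)/2)`; the critical value adjusts for
   missing scores via the two-sample *t* test
   (df 4 → 2.776, df 3 → 3.182, df 2 → 4.303).

Sudden losses are the mirror events; a gain is *reversed* when ≥ 50 % of
its magnitude is lost later in treatment.

Each gainer is paired to one similar non-gainer by greedy
Mahalanobis-distance matching within calipers of 0.25 SD of the linear
propensity (a logistic model of gain status on ten baseline covariates);
the control inherits the gainer's pregain session as its *matched
session*. Process scores at sessions *N*−2…*N*+2 are modelled with a
random-intercept linear model (categorical time × group, ML), giving for
each adjacent-session interval the within-gainer change δ₁, the
within-control change δ₂ and their difference Δ₃ = δ₁ − δ₂. Per sample,
Δ₃ is standardized by the pooled SD of the raw interval difference
scores, and the per-sample SMDs are combined with an inverse-variance
fixed-effects meta-analysis.

## Worked example

```python
import numpy as np
from suddengains import (CohortConfig, generate_cohort,
                         identify_sudden_gains, cohort_gain_summary)

cohort = generate_cohort(CohortConfig(n_patients=248, seed=1))
summary = cohort_gain_summary(cohort)
print(summary["n_gainers"], summary["pct_gainers"],
      round(summary["mean_gain_magnitude"], 2))
```

prints `82 33.06 11.57`: 82 of 248 simulated patients (33.06 %) show at
least one sudden gain, with a mean detected magnitude of 11.57 points —
close to the embedded step distribution (mean 12.3, noise-attenuated).

The full pipeline (detect → match → model → pool) runs from the command
line:

```sh
suddengains run-all --seed 1 --out run/
```

which writes eight CSV artifacts (`byperson`, `bygain`, `pairs`,
`balance`, `outcomes`, `contrasts`, `smd`, `pooled`) plus a JSON run
report. For the same seed the `pooled.csv` row for negative appraisals
over the pregain interval (*N*−1 → *N*) reads β = −2.32 (p < .001): with
the generator's default one-session process lead, appraisal change
precedes the symptom step, and the pooled contrast recovers exactly that
precedence.

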