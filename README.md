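# prefmap

Mapping **FACT-H&N** quality-of-life scores to **SF-6D** health
utilities.

Cost-utility analysis needs utilities (for QALYs), but clinical studies
of head-and-neck / thyroid cancer patients usually administer the
disease-specific FACT-H&N questionnaire rather than a preference-based
instrument. A *mapping* (crosswalk) model predicts the SF-6D utility
from FACT-H&N scores so such studies can still feed economic
evaluation. `prefmap` provides:

* the instrument layer: FACT-H&N domain scoring and an SF-6D
  health-state/tariff engine (any value set conforming to a small JSON
  schema; the packaged tariff is a synthetic stand-in with the Hong Kong
  set's structure — floor 0.315, 18,000 states);
* four estimation families over five nested predictor sets (M1–M5):
  **OLS**, **Tobit** (right-censored at full health),
  **ordered-probit response mapping** (six per-dimension models whose
  level probabilities are combined with the tariff into an expected
  utility, `E[U|x] = Σ_s tariff(s)·Π_d p_d(s_d|x)`), and a two-part
  **beta-mixture** with probability mass at utility 1 and an optional
  truncation at the best non-perfect feasible value 0.965;
* model selection by fit statistics (RMSE, MAE, AE>0.05/0.10 %, Lin's
  CCC, AIC/BIC) and the **average rank value** (ARV — rank each
  statistic across models, midranks on ties, average; lowest wins),
  with fivefold cross-validation and 70/30 holdout validation;
* the **published crosswalk coefficients** (OLS/Tobit M1–M5,
  ordered-probit M5, beta-mixture M5a), ready to apply to new data;
* a calibrated **synthetic cohort generator** emulating the development
  sample's structure (n = 1,050; FACT total 109.2 ± 15.5; utility
  0.690 ± ~0.12, ~0.3 % ceiling, no floor; Spearman(total, utility)
  ≈ 0.65; 76 % female; age 40.8 ± 11.3), so the whole pipeline is
  testable without patient data.

## Worked example

Predict utilities for new patients with the published OLS model 5
(domains, squared domains, age, gender). Because the source tables never
state their gender coding, you must declare the coding of *your* data:

```python
import pandas as pd
from prefmap.crosswalk import crosswalk_predict

patients = pd.DataFrame({
    "pwb": [22.0], "swb": [21.0], "ewb": [20.0], "fwb": [18.0],
    "hncs": [28.0], "age": [40.0], "gender": [1],   # 1 = female
})
print(crosswalk_predict(patients, "ols:M5", gender_coding="female1"))
# [0.69006]

# the published M1 line at the development sample's mean total score
print(crosswalk_predict(pd.DataFrame({"total": [109.152]}), "ols:M1"))
# [0.68976816]  -> 0.690, the sample's published mean utility
```

The second call is the crosswalk's anchor check: the published
regression evaluated at the published mean input returns the published
mean utility at three decimals.

From the shell, the same via the CLI:

```sh
prefmap simulate --n 1050 --seed 7 --out cohort.csv
prefmap fit --cohort cohort.csv --family ols --spec M5 --out ols_m5.json
prefmap predict --in patients.csv --model ols:M5 --gender-coding female1 --out utilities.csv
prefmap validate --cohort cohort.csv --seed 7 --out report.json
```

## Analysis pipeline

The `analysis/` scripts re-run the study's analysis sequence on a
synthetic cohort and write their tables under `results/`:

1. `01_simulate_cohort.py` — generate and describe the cohort;
2. `02_fit_models.py` — fit all four families × five specifications,
   rank each family pool by ARV, Bland–Altman agreement for the M5
   models;
3. `03_validate_models.py` — fivefold CV + 70/30 holdout over the eight
   candidate models, combined ARV, final selection;
4. `04_published_crosswalk.py` — recompute the published ARV arithmetic
   from the published metric tables and apply every published crosswalk
   model to example patients.

On the synthetic cohort the selection lands where the published analysis
landed — OLS M5 wins the combined validation ARV (2.70 in the shipped
run) — and the recomputed published ARVs match the printed ones for all
31 full-sample rows and all 8 validation rows.

## Layout

```
src/prefmap/
  instruments.py        FACT-H&N scoring, SF-6D states, tariff engine
  synthetic_cohort.py   calibrated cohort generator + exact-DGP truths
  design.py             M1–M5 design matrices
  estimators.py         OLS / Tobit / ordered probit / beta-mixture
  response_mapping.py   indirect mapping (6 probits -> expected utility)
  evaluation.py         metrics, CCC, Bland–Altman, ARV
  validation.py         K-fold, holdout, combined selection
  crosswalk.py          published-coefficient prediction
  published.py          transcribed coefficient and metric tables
  cli.py                `prefmap` command-line interface
```

See `docs/methods.md` for the statistical details, calibration choices
and limitations.
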