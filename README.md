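# weightmix

Multi-year body-weight forecasting from annual health-checkup records with a
**tree-gated mixture of sparse linear experts**, plus everything needed to
study that model without access to the original (private) checkup data: a
calibrated synthetic-cohort generator, a learner that re-discovers the gated
structure from data, and an evaluation/recovery layer.

## The problem and the model

Annual Japanese occupational health checkups record weight, height, age, sex,
blood chemistry, and an eleven-item lifestyle questionnaire with a
three-level "intention to improve lifestyle" item.  A practical question in
preventive care is: *given two observed years, what will this person weigh in
one, two and three years — and how would changing one lifestyle habit bend
that trajectory?*

The core model answers with a small piecewise-linear structure.  A binary
gating tree routes each person by baseline state,

```
BMI ≥ 29.93 ──yes──> sex:  male -> formula 1,  female -> formula 2
     └──no──> BMI ≥ 23.44 ──yes──> age ≤ 24 -> formula 3, else formula 4
                   └──────────no──> formula 5
```

and each leaf predicts next-year weight with a sparse linear formula

```
w(t+1) = β₀ + β_w·w(t) + β_Δ·(w(t) − w(t−1)) + β_h·height + β_a·age + Σⱼ βⱼ·xⱼ
```

where the xⱼ are lifestyle indicators: answers given at baseline, and answers
planned for the predictive year, the latter switched on only for the
matching intention level.  Three-year forecasts are **chained**: each year's
prediction becomes the next year's baseline weight and updates the
weight-difference covariate, with scenario lifestyle held fixed.  The
published fitted model (five formulas, the gate thresholds above) ships as a
checksummed JSON fixture and is executable as-is.

Because the source cohort is private, the package treats the published model
as a *generative truth*: the synthetic generator simulates cohorts from it
(sex ratio 66/34, sex-specific height/weight marginals, age 48 ± 12 in
19–91, questionnaire dynamics, MCAR person-level missingness), and the
learner — a surrogate for heterogeneous mixture learning built from greedy
penalized-likelihood split search with forward-selection OLS leaves — must
re-discover the structure from those cohorts.  Agreement is quantified by a
recovery report (leaf count, gate boundaries, coefficients).

## Worked example

```python
from weightmix import (LifestyleProfile, load_published_model,
                       scenario_compare)
from weightmix.cohort import CheckupRecord

model = load_published_model()
rec = lambda y: CheckupRecord("demo", y, "male", 48, 172.0, 95.0,
                              lifestyle=LifestyleProfile())
eats  = LifestyleProfile(skips_breakfast=0, intention_level=1)
skips = LifestyleProfile(skips_breakfast=1, intention_level=1)
t_eats, t_skips = scenario_compare((rec(-1), rec(0)), eats, skips, model)
print(t_eats.predicted)   # (95.71, 96.30, 96.89)
print(t_skips.predicted)  # (95.95, 96.57, 97.21)
```

A 95 kg, 172 cm man (BMI 32.1 → formula 1) is forecast to gain weight under
both scenarios, but eating breakfast bends the three-year trajectory about
0.3 kg below the skipping scenario — the qualitative pattern that healthy
answers (breakfast, fast walking) carry negative coefficients in the
higher-BMI formulas.

The analysis is organised as numbered drivers over the library:

| script | what it does |
| --- | --- |
| `analysis/01_simulate_cohort.py` | study-scale cohort (67,021), filtering to ~55,000 complete cases, 50,000/5,000 split, baseline comparison tables |
| `analysis/02_fit_mixture.py` | ten-seed structure/parameter recovery study |
| `analysis/03_evaluate.py` | chained-forecast RMSE of mixture vs multiple regression on held-out persons |
| `analysis/04_scenarios.py` | breakfast / walking-speed scenario trajectories |

A `weightmix` CLI exposes the same stages (`simulate`, `fit`, `predict`,
`scenario`, `evaluate`, `run-all`); see `weightmix --help`.

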