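"""Feature encoding for one-year weight-transition models.

A single transition (year *t* → *t+1*) is described by:

* the anthropometric state at *t*: current weight, the weight change from the
  previous year, height, age and sex;
* the questionnaire answered at *t* ("baseline interview" indicators);
* the questionnaire planned/answered for *t+1* ("predictive year"
  indicators).  Most predictive-year indicators are *gated* by the three-level
  intention-to-improve item: a level-specific indicator fires only when the
  answer matches the listed level **and** the person's intention level matches
  that column.

Every indicator fires iff the answer equals the level named in the feature
key (e.g. ``base_heavy_smoker_no`` is 1 for non-heavy-smokers at baseline).
Drinking enters as a numeric frequency/quantity score, once per interview.
The vocabulary is fixed so that the published model, the synthetic-cohort
generator and the mixture learner all agree column-for-column.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .lifestyle import LIFESTYLE_COLUMNS, LifestyleProfile

# --------------------------------------------------------------------------
# vocabulary

CONTINUOUS_FEATURES = ("weight_baseline", "weight_diff", "height", "age", "sex_male")

# (key, item column, required coded value); value None -> numeric passthrough
_BASE_INDICATORS = (
    ("base_wants_instruction_no", "wants_instruction", 0),
    ("base_heavy_smoker_no", "heavy_smoker", 0),
    ("base_drinking", "drinking_score", None),
    ("base_fast_walker_no", "fast_walker", 0),
    ("base_daily_activity_no", "daily_activity", 0),
    ("base_exercise_no", "exercise_habit", 0),
    ("base_skips_breakfast_yes", "skips_breakfast", 1),
    ("base_eating_quicker", "eating_speed", 0),
    ("base_eating_normal", "eating_speed", 1),
    ("base_late_supper_yes", "late_supper", 1),
    ("base_snacks_yes", "snacks", 1),
    ("base_sleeps_well_no", "sleeps_well", 0),
)

_PRED_UNGATED = (
    ("pred_wants_instruction_yes", "wants_instruction", 1),
    ("pred_drinking", "drinking_score", None),
)

# predictive-year indicator families expanded over intention levels 1..3
_PRED_GATED = (
    ("pred_heavy_smoker_no", "heavy_smoker", 0),
    ("pred_fast_walker_yes", "fast_walker", 1),
    ("pred_daily_activity_yes", "daily_activity", 1),
    ("pred_exercise_yes", "exercise_habit", 1),
    ("pred_exercise_no", "exercise_habit", 0),
    ("pred_skips_breakfast_no", "skips_breakfast", 0),
    ("pred_eating_normal", "eating_speed", 1),
    ("pred_eating_slower", "eating_speed", 2),
    ("pred_late_supper_no", "late_supper", 0),
    ("pred_snacks_no", "snacks", 0),
    ("pred_sleeps_well_yes", "sleeps_well", 1),
)

FEATURE_NAMES: tuple = (
    CONTINUOUS_FEATURES
    + tuple(k for k, _, _ in _BASE_INDICATORS)
    + tuple(k for k, _, _ in _PRED_UNGATED)
    + tuple(f"{k}_i{lvl}" for k, _, _ in _PRED_GATED for lvl in (1, 2, 3))
)

FEATURE_INDEX = {name: i for i, name in enumerate(FEATURE_NAMES)}

#: laboratory columns (optional decoy predictors; never gate variables)
LAB_COLUMNS = (
    "sbp", "dbp", "hba1c", "tg", "hdl_c", "ldl_c", "fbg",
    "ast", "alt", "ggtp", "waist_cm",
)


# --------------------------------------------------------------------------
# vectorised encoding

def encode_matrix(base, pred, weight_t, weight_tm1, height_cm, age_years, sex_male):
    """Encode n transitions into an (n, len(FEATURE_NAMES)) float matrix.

    Parameters
    ----------
    base, pred : mapping of lifestyle column name -> array of length n
        Questionnaire answers at the baseline year and at the predictive year.
    weight_t, weight_tm1, height_cm, age_years, sex_male : arrays of length n
    """
    weight_t = np.asarray(weight_t, dtype=float)
    n = weight_t.shape[0]
    X = np.zeros((n, len(FEATURE_NAMES)))
    X[:, 0] = weight_t
    X[:, 1] = weight_t - np.asarray(weight_tm1, dtype=float)
    X[:, 2] = np.asarray(height_cm, dtype=float)
    X[:, 3] = np.asarray(age_years, dtype=float)
    X[:, 4] = np.asarray(sex_male, dtype=float)

    col = len(CONTINUOUS_FEATURES)
    for _, item, value in _BASE_INDICATORS:
        v = np.asarray(base[item], dtype=float)
        X[:, col] = v if value is None else (v == value)
        col += 1
    for _, item, value in _PRED_UNGATED:
        v = np.asarray(pred[item], dtype=float)
        X[:, col] = v if value is None else (v == value)
        col += 1
    intention = np.asarray(pred["intention_level"], dtype=float)
    for _, item, value in _PRED_GATED:
        fires = np.asarray(pred[item], dtype=float) == value
        for lvl in (1, 2, 3):
            X[:, col] = fires & (intention == lvl)
            col += 1
    return X


def encode_features(record_t, record_t_minus_1, lifestyle_pred: LifestyleProfile):
    """Encode a single transition as an ordered ``{feature: value}`` dict.

    ``record_t`` supplies the anthropometric state and the baseline
    interview; ``record_t_minus_1`` supplies only the previous weight;
    ``lifestyle_pred`` is the predictive-year questionnaire.
    """
    if record_t.weight_kg is None or record_t_minus_1.weight_kg is None:
        raise ValueError("weights at t and t-1 are required")
    if record_t.lifestyle is None:
        raise ValueError("baseline lifestyle profile is missing")
    if lifestyle_pred is None:
        raise ValueError("predictive-year lifestyle profile is missing")
    base = {c: np.array([v]) for c, v in record_t.lifestyle.as_dict().items()}
    pred = {c: np.array([v]) for c, v in lifestyle_pred.as_dict().items()}
    row = encode_matrix(
        base,
        pred,
        np.array([record_t.weight_kg]),
        np.array([record_t_minus_1.weight_kg]),
        np.array([record_t.height_cm]),
        np.array([record_t.age_years]),
        np.array([1.0 if record_t.sex == "male" else 0.0]),
    )[0]
    return dict(zip(FEATURE_NAMES, row))


# --------------------------------------------------------------------------
# cohort -> training table

class TrainingTable:
    """One-year transitions pooled over follow-up years.

    Attributes
    ----------
    X : (n, p) design matrix, columns ``feature_names``
    y : next-year weight (kg)
    gates : DataFrame with the gate candidates ``bmi``, ``age``, ``sex_male``
    person_id, step : row provenance (step = baseline year of the transition)
    """

    def __init__(self, X, y, gates, person_id, step, feature_names):
        self.X = X
        self.y = y
        self.gates = gates
        self.person_id = person_id
        self.step = step
        self.feature_names = list(feature_names)

    @property
    def n(self) -> int:
        return self.X.shape[0]


def build_training_table(df: pd.DataFrame, include_labs: bool = True,
                         steps=(0, 1, 2)) -> TrainingTable:
    """Pool year t → t+1 transitions from a complete-case long-format cohort.

    For each person and each baseline year ``t`` in ``steps`` the row uses the
    year-``t`` interview as baseline answers and the year-``t+1`` interview as
    predictive-year answers, with next-year weight as the target.
    """
    need_years = sorted({-1, *steps, *(t + 1 for t in steps)})
    piv = {}
    for colname in ("weight_kg", "age_years", *LIFESTYLE_COLUMNS):
        piv[colname] = df.pivot(index="person_id", columns="year_index",
                                values=colname)
    if include_labs:
        for colname in LAB_COLUMNS:
            if colname in df.columns:
                piv[colname] = df.pivot(index="person_id", columns="year_index",
                                        values=colname)
    base_rows = df[df["year_index"] == 0].set_index("person_id")
    persons = piv["weight_kg"].index
    height = base_rows.loc[persons, "height_cm"].to_numpy(dtype=float)
    sex_male = (base_rows.loc[persons, "sex"] == "male").to_numpy(dtype=float)

    blocks, ys, gate_rows, pids, steps_out = [], [], [], [], []
    lab_cols = [c for c in LAB_COLUMNS if c in piv]
    for t in steps:
        for y_needed in (t - 1, t, t + 1):
            if y_needed not in piv["weight_kg"].columns:
                raise ValueError(f"cohort lacks year_index {y_needed}")
        w_t = piv["weight_kg"][t].to_numpy(dtype=float)
        w_tm1 = piv["weight_kg"][t - 1].to_numpy(dtype=float)
        w_tp1 = piv["weight_kg"][t + 1].to_numpy(dtype=float)
        age_t = piv["age_years"][t].to_numpy(dtype=float)
        base = {c: piv[c][t].to_numpy(dtype=float) for c in LIFESTYLE_COLUMNS}
        pred = {c: piv[c][t + 1].to_numpy(dtype=float) for c in LIFESTYLE_COLUMNS}
        X = encode_matrix(base, pred, w_t, w_tm1, height, age_t, sex_male)
        if lab_cols:
            labs = np.column_stack([piv[c][t].to_numpy(dtype=float)
                                    for c in lab_cols])
            X = np.hstack([X, labs])
        keep = ~np.isnan(X).any(axis=1) & ~np.isnan(w_tp1)
        blocks.append(X[keep])
        ys.append(w_tp1[keep])
        bmi_t = w_t[keep] / (height[keep] / 100.0) ** 2
        gate_rows.append(np.column_stack([bmi_t, age_t[keep], sex_male[keep]]))
        pids.append(np.asarray(persons)[keep])
        steps_out.append(np.full(keep.sum(), t))

    names = list(FEATURE_NAMES) + lab_cols
    gates = pd.DataFrame(np.vstack(gate_rows), columns=["bmi", "age", "sex_male"])
    return TrainingTable(
        X=np.vstack(blocks),
        y=np.concatenate(ys),
        gates=gates,
        person_id=np.concatenate(pids),
        step=np.concatenate(steps_out),
        feature_names=names,
    )
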