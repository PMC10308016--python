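"""Longitudinal checkup cohorts: records, filtering, splitting, comparison.

A cohort is a long-format :class:`pandas.DataFrame` with one row per
person-year, years indexed relative to baseline (−1 = the year before
baseline, 0 = baseline, 1..3 = follow-up).  Missing values are empty cells in
CSV / NaN in memory.  :class:`CheckupRecord` offers a record-level view of
the same rows for single-person operations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np
import pandas as pd
from scipy import stats

from .lifestyle import BINARY_ITEMS, LIFESTYLE_COLUMNS, LifestyleProfile
from .features import LAB_COLUMNS

COHORT_COLUMNS = (
    "person_id", "year_index", "sex", "age_years", "height_cm", "weight_kg",
    *LAB_COLUMNS, *LIFESTYLE_COLUMNS,
)

#: relative years over which each default required field must be observed
DEFAULT_FIELD_YEARS = {
    "weight_kg": tuple(range(-1, 4)),
    "height_cm": tuple(range(-1, 4)),
    "age_years": tuple(range(-1, 4)),
    "sex": tuple(range(-1, 4)),
    **{c: tuple(range(0, 4)) for c in LIFESTYLE_COLUMNS},
}

DEFAULT_REQUIRED_FIELDS = tuple(DEFAULT_FIELD_YEARS)

#: variables treated as categorical in cohort comparisons
CATEGORICAL_VARIABLES = frozenset({"sex", "eating_speed", "intention_level",
                                   *BINARY_ITEMS})


@dataclass
class CheckupRecord:
    """One person-year of measurements and questionnaire answers."""

    person_id: str
    year_index: int
    sex: str
    age_years: int
    height_cm: float
    weight_kg: Optional[float] = None
    labs: dict = field(default_factory=dict)
    lifestyle: Optional[LifestyleProfile] = None

    @property
    def bmi(self) -> Optional[float]:
        if self.weight_kg is None:
            return None
        return compute_bmi(self.height_cm, self.weight_kg)


def compute_bmi(height_cm, weight_kg):
    """Body mass index, kg/m^2.  Accepts scalars or arrays; inputs > 0."""
    height_cm = np.asarray(height_cm, dtype=float)
    weight_kg = np.asarray(weight_kg, dtype=float)
    if np.any(height_cm <= 0) or np.any(weight_kg <= 0):
        raise ValueError("height and weight must be positive")
    out = weight_kg / (height_cm / 100.0) ** 2
    return float(out) if out.ndim == 0 else out


def records_from_frame(df: pd.DataFrame) -> list[CheckupRecord]:
    """Record-level view of a long-format cohort frame."""
    out = []
    for _, row in df.iterrows():
        try:
            profile = LifestyleProfile.from_row(row)
        except (ValueError, KeyError):
            profile = None
        labs = {c: float(row[c]) for c in LAB_COLUMNS
                if c in row and pd.notna(row[c])}
        w = row.get("weight_kg")
        out.append(CheckupRecord(
            person_id=str(row["person_id"]),
            year_index=int(row["year_index"]),
            sex=str(row["sex"]),
            age_years=int(row["age_years"]),
            height_cm=float(row["height_cm"]),
            weight_kg=float(w) if pd.notna(w) else None,
            labs=labs,
            lifestyle=profile,
        ))
    return out


# --------------------------------------------------------------------------
# filtering and splitting

def filter_complete_cases(df: pd.DataFrame, required_fields=None):
    """Drop persons with any missing required field in any required year.

    Retention is all-or-nothing per person: a single missing cell (or a
    missing person-year row) among the required fields removes the whole
    person, mirroring a single study-level exclusion count.

    Returns ``(retained_frame, n_excluded_persons)``.
    """
    if required_fields is None:
        required_fields = DEFAULT_REQUIRED_FIELDS
    if not len(required_fields):
        raise ValueError("required_fields must be non-empty")
    if df.empty:
        return df.copy(), 0
    ok = None
    for fld in required_fields:
        years = DEFAULT_FIELD_YEARS.get(fld, tuple(range(-1, 4)))
        years = [y for y in years if y in df["year_index"].unique()]
        piv = df.pivot(index="person_id", columns="year_index", values=fld)
        missing_year = [y for y in years if y not in piv.columns]
        if missing_year:
            field_ok = pd.Series(False, index=piv.index)
        else:
            field_ok = piv[years].notna().all(axis=1)
        ok = field_ok if ok is None else (ok & field_ok)
    keep = set(ok.index[ok])
    retained = df[df["person_id"].isin(keep)].copy()
    n_excluded = int(df["person_id"].nunique() - len(keep))
    return retained, n_excluded


def split_learning_validation(df: pd.DataFrame, n_learning: int,
                              n_validation: int, seed: int):
    """Disjoint person-level random split into learning/validation cohorts."""
    persons = np.sort(df["person_id"].unique())
    if n_learning + n_validation > len(persons):
        raise ValueError(
            f"requested {n_learning}+{n_validation} persons but only "
            f"{len(persons)} available")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(persons))
    learn_ids = set(persons[perm[:n_learning]])
    valid_ids = set(persons[perm[n_learning:n_learning + n_validation]])
    return (df[df["person_id"].isin(learn_ids)].copy(),
            df[df["person_id"].isin(valid_ids)].copy())


# --------------------------------------------------------------------------
# cohort comparison

def compare_cohorts(a: pd.DataFrame, b: pd.DataFrame, variables: Iterable[str],
                    continuity_correction: bool = False,
                    equal_var: bool = True) -> pd.DataFrame:
    """Baseline-characteristics comparison between two cohorts.

    Continuous variables are compared with the two-sample Student t test
    (``equal_var=False`` switches to Welch), categorical variables with the
    chi-squared test (no Yates correction by default).  Uses baseline
    (year 0) rows when a ``year_index`` column is present.  Degenerate
    variables (zero variance in both groups) are flagged, not raised.
    """
    if a.empty or b.empty:
        raise ValueError("both cohorts must be non-empty")
    if "year_index" in a.columns:
        a = a[a["year_index"] == 0]
        b = b[b["year_index"] == 0]
    rows = []
    for var in variables:
        xa = a[var].dropna()
        xb = b[var].dropna()
        if var in CATEGORICAL_VARIABLES or xa.dtype == object:
            levels = sorted(set(xa.unique()) | set(xb.unique()))
            table = np.array([[int((xa == lv).sum()) for lv in levels],
                              [int((xb == lv).sum()) for lv in levels]])
            summary_a = "; ".join(
                f"{lv}: {c} ({100 * c / len(xa):.0f}%)"
                for lv, c in zip(levels, table[0]))
            summary_b = "; ".join(
                f"{lv}: {c} ({100 * c / len(xb):.0f}%)"
                for lv, c in zip(levels, table[1]))
            if len(levels) < 2:
                rows.append((var, "chi-squared", np.nan, np.nan,
                             summary_a, summary_b, "degenerate"))
                continue
            res = stats.chi2_contingency(table, correction=continuity_correction)
            rows.append((var, "chi-squared", float(res[0]), float(res[1]),
                         summary_a, summary_b, ""))
        else:
            xa = xa.astype(float)
            xb = xb.astype(float)
            summary_a = f"{xa.mean():.2f} ± {xa.std(ddof=1):.2f}"
            summary_b = f"{xb.mean():.2f} ± {xb.std(ddof=1):.2f}"
            if xa.std(ddof=1) == 0 and xb.std(ddof=1) == 0:
                stat = 0.0 if xa.mean() == xb.mean() else np.nan
                rows.append((var, "two-sample t", stat, np.nan,
                             summary_a, summary_b, "degenerate"))
                continue
            stat, p = stats.ttest_ind(xa, xb, equal_var=equal_var)
            rows.append((var, "two-sample t", float(stat), float(p),
                         summary_a, summary_b, ""))
    out = pd.DataFrame(rows, columns=["variable", "test", "statistic",
                                      "p_value", "group_a", "group_b", "note"])
    bad = out["p_value"].dropna()
    assert ((bad >= 0) & (bad <= 1)).all()
    return out


# --------------------------------------------------------------------------
# CSV dialect

def write_cohort(df: pd.DataFrame, path) -> None:
    cols = [c for c in COHORT_COLUMNS if c in df.columns]
    df[cols].to_csv(path, index=False)


def read_cohort(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = {"person_id", "year_index", "sex", "height_cm"} - set(df.columns)
    if missing:
        raise ValueError(f"cohort CSV lacks required columns: {sorted(missing)}")
    return df
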