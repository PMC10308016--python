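"""Accuracy evaluation, regression baseline and structure-recovery reports.

The accuracy metric is the root mean square error of chained multi-year
weight forecasts on held-out persons, compared against a single global
multiple-regression model that uses the identical feature encoding and the
identical chained forecasting procedure.  Structure recovery quantifies how
well a fitted mixture reproduces a known generative model: leaf count, gate
boundaries and per-leaf coefficients, with fitted leaves matched to true
leaves by gate-region overlap so the diagnostics are invariant to leaf
labelling and to the (non-identifiable) order of nested splits.
"""

from __future__ import annotations

import warnings
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import linear_sum_assignment

from .features import FEATURE_NAMES, LAB_COLUMNS, TrainingTable
from .lifestyle import LIFESTYLE_COLUMNS
from .model import GateRule, LeafFormula, PiecewiseLinearModel, chain_predict
from .simulate import TABLE1_ANTHROPOMETRY


class PredictionPair(NamedTuple):
    y_true: float
    y_pred: float


# --------------------------------------------------------------------------
# RMSE

def rmse(pairs) -> float:
    """Root mean square error over (observed, predicted) pairs."""
    arr = np.asarray(pairs, dtype=float)
    if arr.size == 0:
        raise ValueError("rmse of an empty set is undefined")
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("pairs must be an (n, 2) array of (y_true, y_pred)")
    if not np.all(np.isfinite(arr)):
        raise ValueError("pairs must be finite")
    err = arr[:, 0] - arr[:, 1]
    return float(np.sqrt(np.mean(err * err)))


# --------------------------------------------------------------------------
# global multiple-regression baseline

def fit_multiple_regression(table: TrainingTable) -> PiecewiseLinearModel:
    """Single dense OLS model over the full feature encoding (no gating).

    Collinear columns are dropped (pivoted-QR rank detection) with a
    warning; dropped features simply get no term.  The result is packaged as
    a one-leaf piecewise model so every downstream step (chained forecasting,
    serialization, RMSE) is model-agnostic.
    """
    X1 = np.hstack([np.ones((table.n, 1)), table.X])
    from scipy.linalg import qr
    R = qr(X1, mode="r", pivoting=True)
    r_diag = np.abs(np.diag(R[0]))
    tol = r_diag.max() * max(X1.shape) * np.finfo(float).eps
    rank = int((r_diag > tol).sum())
    keep = list(np.sort(R[1][:rank]))
    if 0 not in keep:  # intercept always stays; drop the weakest pivot
        keep = sorted([0] + keep[:-1])
    if rank < X1.shape[1]:
        dropped = [table.feature_names[j - 1]
                   for j in range(1, X1.shape[1]) if j not in keep]
        warnings.warn(f"multiple regression: dropped collinear columns "
                      f"{dropped}")
    keep = np.asarray(keep)
    beta, *_ = np.linalg.lstsq(X1[:, keep], table.y, rcond=None)
    terms = {table.feature_names[j - 1]: float(b)
             for j, b in zip(keep, beta) if j != 0}
    bias = float(beta[list(keep).index(0)])
    leaf = LeafFormula(formula_id=1, bias=bias, terms=terms)
    return PiecewiseLinearModel(tree=1, leaves={1: leaf},
                                meta={"version": "multiple-regression"})


# --------------------------------------------------------------------------
# chained validation

def evaluate_model(model: PiecewiseLinearModel, validation: pd.DataFrame,
                   horizon: int = 3, reassign_leaf: bool = True,
                   advance_age: bool = True) -> pd.DataFrame:
    """Chained forecasts vs observed weights on a complete-case cohort.

    Each person is forecast from the measured years −1..0 with the realised
    yearly questionnaires as predictive-year input; forecast weights (not
    the observed ones) are fed forward.  Returns one row per person and
    horizon with observed and predicted weight.
    """
    piv = {c: validation.pivot(index="person_id", columns="year_index",
                               values=c)
           for c in ("weight_kg", "age_years", *LIFESTYLE_COLUMNS)}
    persons = piv["weight_kg"].index
    base = validation[validation["year_index"] == 0].set_index("person_id")
    height = base.loc[persons, "height_cm"].to_numpy(float)
    sex_male = (base.loc[persons, "sex"] == "male").to_numpy(float)
    age0 = piv["age_years"][0].to_numpy(float)
    profiles = {y: {c: piv[c][y].to_numpy(float) for c in LIFESTYLE_COLUMNS}
                for y in range(0, horizon + 1)}

    needs_labs = any(k in LAB_COLUMNS
                     for leaf in model.leaves.values() for k in leaf.terms)
    names = list(FEATURE_NAMES)
    labs = None
    if needs_labs:
        lab_cols = [c for c in LAB_COLUMNS if c in validation.columns]
        names += lab_cols
        piv_labs = {c: validation.pivot(index="person_id",
                                        columns="year_index", values=c)
                    for c in lab_cols}
        # labs are baseline covariates for every chained step
        labs = np.column_stack([piv_labs[c][0].to_numpy(float)
                                for c in lab_cols])

    preds = chain_predict(
        model,
        piv["weight_kg"][-1].to_numpy(float), piv["weight_kg"][0].to_numpy(float),
        height, age0, sex_male, profiles, horizon=horizon,
        reassign_leaf=reassign_leaf, advance_age=advance_age,
        feature_names=names, labs=labs,
    )
    rows = []
    for h in range(1, horizon + 1):
        obs = piv["weight_kg"][h].to_numpy(float)
        rows.append(pd.DataFrame({
            "person_id": persons, "horizon": h,
            "y_true": obs, "y_pred": preds[:, h - 1],
        }))
    return pd.concat(rows, ignore_index=True)


def rmse_report(pred_frame: pd.DataFrame) -> dict:
    """Pooled and per-horizon RMSE from an evaluate_model frame."""
    out = {"rmse_pooled": rmse(pred_frame[["y_true", "y_pred"]].to_numpy())}
    for h, grp in pred_frame.groupby("horizon"):
        out[f"rmse_h{h}"] = rmse(grp[["y_true", "y_pred"]].to_numpy())
    out["n"] = int(pred_frame["person_id"].nunique())
    return out


def squared_errors_by_person(pred_frame: pd.DataFrame) -> pd.Series:
    se = (pred_frame["y_true"] - pred_frame["y_pred"]) ** 2
    return se.groupby(pred_frame["person_id"]).mean()


def compare_models(squared_errors_a, squared_errors_b, paired: bool = False):
    """Two-sample t test on per-person squared forecast errors.

    Unpaired Student form by default; ``paired=True`` uses the paired test
    (statistically preferable when both models are evaluated on the same
    persons — surfaced in reports, not the default).  Zero variance in both
    samples is flagged (NaN, NaN) rather than raised.
    """
    a = np.asarray(squared_errors_a, dtype=float)
    b = np.asarray(squared_errors_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both error samples must be non-empty")
    if a.std(ddof=1 if a.size > 1 else 0) == 0 and \
            b.std(ddof=1 if b.size > 1 else 0) == 0:
        if np.allclose(a.mean(), b.mean()):
            return 0.0, np.nan
        warnings.warn("compare_models: degenerate zero-variance samples")
        return np.nan, np.nan
    if paired:
        stat, p = stats.ttest_rel(a, b)
    else:
        stat, p = stats.ttest_ind(a, b, equal_var=True)
    return float(stat), float(p)


# --------------------------------------------------------------------------
# structure recovery

def _numeric_cuts(node, feature):
    if isinstance(node, int):
        return []
    own = [float(node.threshold)] if node.feature == feature else []
    return own + _numeric_cuts(node.if_true, feature) + \
        _numeric_cuts(node.if_false, feature)


def _has_sex_gate(node):
    if isinstance(node, int):
        return False
    return node.feature == "sex" or _has_sex_gate(node.if_true) or \
        _has_sex_gate(node.if_false)


def _reference_points(n_points, seed):
    """Random (bmi, age, sex) triples from the cohort-shaped marginals."""
    rng = np.random.default_rng(seed)
    sex_male = (rng.random(n_points) < 0.66).astype(float)
    hm, hs, hf, hfs = TABLE1_ANTHROPOMETRY["height_cm"]
    wm, ws, wf, wfs = TABLE1_ANTHROPOMETRY["weight_kg"]
    height = np.where(sex_male == 1, rng.normal(hm, hs, n_points),
                      rng.normal(hf, hfs, n_points)).clip(min=130)
    weight = np.where(sex_male == 1, rng.normal(wm, ws, n_points),
                      rng.normal(wf, wfs, n_points)).clip(min=30)
    bmi = weight / (height / 100.0) ** 2
    age = np.clip(np.round(rng.normal(48, 12, n_points)), 19, 91)
    return bmi, age, sex_male


def _match_cuts(true_cuts, fitted_cuts):
    """One-to-one nearest-value pairing of gate boundaries on one feature."""
    entries = []
    if true_cuts and fitted_cuts:
        cost = np.abs(np.subtract.outer(true_cuts, fitted_cuts))
        ri, ci = linear_sum_assignment(cost)
        paired = dict(zip(ri, ci))
    else:
        paired = {}
    for i, t in enumerate(true_cuts):
        if i in paired:
            f = fitted_cuts[paired[i]]
            entries.append({"true": t, "fitted": f, "abs_error": abs(t - f)})
        else:
            entries.append({"true": t, "fitted": None, "abs_error": None})
    return entries


def recovery_report(true_model: PiecewiseLinearModel, fitted,
                    n_points: int = 20000, seed: int = 0) -> dict:
    """Structure/parameter-recovery diagnostics of a fitted mixture.

    ``fitted`` is a FitResult or a PiecewiseLinearModel.  Fitted leaves are
    matched to true leaves by region overlap on a reference sample of
    (BMI, age, sex) triples; gate boundaries are matched per feature by
    nearest value.  Both choices make the report invariant to leaf IDs and
    to the order of nested splits, which carry no information about the
    fitted function.
    """
    fitted_model = getattr(fitted, "model", fitted)
    true_keys = {k for lf in true_model.leaves.values() for k in lf.terms}
    fit_keys = {k for lf in fitted_model.leaves.values() for k in lf.terms}
    if true_keys and fit_keys and not (true_keys & fit_keys):
        raise ValueError("true and fitted models share no feature vocabulary")

    bmi, age, sex_male = _reference_points(n_points, seed)
    t_leaf = true_model.assign_array(bmi, age, sex_male)
    f_leaf = fitted_model.assign_array(bmi, age, sex_male)
    t_ids = sorted(true_model.leaves)
    f_ids = sorted(fitted_model.leaves)
    overlap = np.zeros((len(t_ids), len(f_ids)))
    for i, ti in enumerate(t_ids):
        for j, fj in enumerate(f_ids):
            overlap[i, j] = np.sum((t_leaf == ti) & (f_leaf == fj))
    ri, ci = linear_sum_assignment(-overlap)
    matching = {int(t_ids[i]): int(f_ids[j]) for i, j in zip(ri, ci)}
    agree = sum(overlap[i, j] for i, j in zip(ri, ci)) / n_points

    gate_cuts = {}
    for feat in ("bmi", "age"):
        gate_cuts[feat] = _match_cuts(
            sorted(_numeric_cuts(true_model.tree, feat), reverse=True),
            _numeric_cuts(fitted_model.tree, feat))
    gate_cuts["sex"] = {"true_present": _has_sex_gate(true_model.tree),
                        "fitted_present": _has_sex_gate(fitted_model.tree)}

    coef_errors = {}
    weight_baseline_coefs = []
    for ti, fj in matching.items():
        t_terms = true_model.leaves[ti].terms
        f_terms = fitted_model.leaves[fj].terms
        keys = set(t_terms) | set(f_terms)
        errs = {k: abs(t_terms.get(k, 0.0) - f_terms.get(k, 0.0))
                for k in keys}
        coef_errors[ti] = {
            "fitted_leaf": fj,
            "max_abs_error": max(errs.values()) if errs else 0.0,
            "bias_abs_error": abs(true_model.leaves[ti].bias
                                  - fitted_model.leaves[fj].bias),
            "weight_baseline_fitted": f_terms.get("weight_baseline", 0.0),
            "weight_diff_fitted": f_terms.get("weight_diff", 0.0),
        }
        weight_baseline_coefs.append(f_terms.get("weight_baseline", 0.0))

    root = fitted_model.tree
    fitted_root = None if isinstance(root, int) else {
        "feature": root.feature,
        "threshold": root.threshold, "category": root.category}

    return {
        "leaf_count_true": len(t_ids),
        "leaf_count_fitted": len(f_ids),
        "leaf_count_match": len(t_ids) == len(f_ids),
        "leaf_matching": matching,
        "region_agreement": float(agree),
        "gate_cuts": gate_cuts,
        "fitted_root": fitted_root,
        "coef_errors": coef_errors,
        "weight_baseline_coefs": weight_baseline_coefs,
        "weight_diff_formula1": (
            coef_errors[1]["weight_diff_fitted"] if 1 in coef_errors else None),
    }
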