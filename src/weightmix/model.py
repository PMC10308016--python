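"""Tree-gated piecewise-linear weight prediction.

A :class:`PiecewiseLinearModel` routes each person through a small binary
gating tree on baseline BMI, age and sex, then applies the sparse linear
formula of the selected leaf to predict next-year weight.  Multi-year
forecasts are produced by *chaining*: each year's prediction becomes the next
year's baseline weight and updates the one-year weight-difference covariate,
with the predictive-year questionnaire held fixed for scenario forecasts.

The fitted model reported by the source study ships with the package as a
machine-readable JSON fixture (five leaf formulas; BMI gates at 29.93 and
23.44 kg/m^2, an age gate at 24 years and a sex gate) and loads through
:func:`load_published_model`, which verifies a checksum so that any drift in
the transcribed coefficients is detected.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field as dc_field
from importlib import resources
from typing import Optional, Union

import numpy as np

from .features import FEATURE_NAMES, encode_matrix, encode_features
from .lifestyle import LIFESTYLE_COLUMNS, LifestyleProfile

GATE_FEATURES = ("bmi", "age", "sex")


# --------------------------------------------------------------------------
# model structure

@dataclass
class GateRule:
    """One binary gate.  ``if_true`` is taken when the condition holds.

    Numeric ops partition the real line exactly: ``ge`` sends x >= threshold
    to ``if_true`` and x < threshold to ``if_false``; ``le`` symmetrically.
    ``eq`` compares sex against a category.
    """

    feature: str
    op: str  # "ge" | "le" | "eq"
    threshold: Optional[float] = None
    category: Optional[str] = None
    if_true: Union["GateRule", int, None] = None
    if_false: Union["GateRule", int, None] = None

    def condition(self, bmi, age, sex_male):
        if self.feature == "bmi":
            x = bmi
        elif self.feature == "age":
            x = age
        elif self.feature == "sex":
            want = 1.0 if self.category == "male" else 0.0
            return np.asarray(sex_male, dtype=float) == want
        else:
            raise ValueError(f"unknown gate feature {self.feature!r}")
        x = np.asarray(x, dtype=float)
        return x >= self.threshold if self.op == "ge" else x <= self.threshold


@dataclass
class LeafFormula:
    """Sparse linear one-year formula: bias + sum coef * feature.

    ``terms`` holds only selected features; everything absent is an exact 0.
    ``selected_zero`` records features the source model selected with a
    printed coefficient of 0.00 — numerically identical to unselected, but
    kept distinct for structure-recovery bookkeeping.
    """

    formula_id: int
    bias: float
    terms: dict = dc_field(default_factory=dict)
    selected_zero: tuple = ()

    def evaluate(self, fv: dict) -> float:
        return float(self.bias + sum(c * fv.get(k, 0.0)
                                     for k, c in self.terms.items()))


@dataclass
class PiecewiseLinearModel:
    tree: Union[GateRule, int]
    leaves: dict  # formula_id -> LeafFormula
    meta: dict = dc_field(default_factory=dict)

    # -- routing ------------------------------------------------------------
    def assign_array(self, bmi, age, sex_male) -> np.ndarray:
        bmi = np.asarray(bmi, dtype=float)
        out = np.zeros(bmi.shape, dtype=int)

        def walk(node, mask):
            if isinstance(node, int):
                out[mask] = node
                return
            cond = node.condition(bmi, age, sex_male)
            walk(node.if_true, mask & cond)
            walk(node.if_false, mask & ~cond)

        walk(self.tree, np.ones(bmi.shape, dtype=bool))
        return out

    def assign(self, bmi: float, age: float, sex) -> int:
        sex_male = 1.0 if sex in ("male", 1, 1.0, True) else 0.0
        return int(self.assign_array(np.array([bmi]), np.array([float(age)]),
                                     np.array([sex_male]))[0])

    # -- evaluation ---------------------------------------------------------
    def coef_arrays(self, feature_names=FEATURE_NAMES):
        """(ids, C, b): leaf order, coefficient matrix and bias vector."""
        ids = sorted(self.leaves)
        p = len(feature_names)
        index = {name: j for j, name in enumerate(feature_names)}
        C = np.zeros((len(ids), p))
        b = np.zeros(len(ids))
        for i, lid in enumerate(ids):
            leaf = self.leaves[lid]
            b[i] = leaf.bias
            for key, coef in leaf.terms.items():
                if key not in index:
                    raise KeyError(f"leaf {lid} term {key!r} not in feature "
                                   f"vocabulary")
                C[i, index[key]] = coef
        return ids, C, b

    # -- serialization ------------------------------------------------------
    def to_dict(self) -> dict:
        def node_dict(node):
            if isinstance(node, int):
                return {"leaf": node}
            d = {"feature": node.feature, "op": node.op}
            if node.op == "eq":
                d["category"] = node.category
            else:
                d["threshold"] = node.threshold
            d["if_true"] = node_dict(node.if_true)
            d["if_false"] = node_dict(node.if_false)
            return d

        return {
            "tree": node_dict(self.tree),
            "leaves": [
                {"id": lid, "bias": leaf.bias, "terms": dict(leaf.terms),
                 "selected_zero": list(leaf.selected_zero)}
                for lid, leaf in sorted(self.leaves.items())
            ],
            "meta": dict(self.meta),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PiecewiseLinearModel":
        def parse_node(nd, path="tree"):
            if "leaf" in nd:
                return int(nd["leaf"])
            for key in ("feature", "op", "if_true", "if_false"):
                if key not in nd:
                    raise ValueError(f"model schema: {path} lacks {key!r}")
            if nd["op"] not in ("ge", "le", "eq"):
                raise ValueError(f"model schema: bad op {nd['op']!r} at {path}")
            return GateRule(
                feature=nd["feature"], op=nd["op"],
                threshold=nd.get("threshold"), category=nd.get("category"),
                if_true=parse_node(nd["if_true"], path + ".if_true"),
                if_false=parse_node(nd["if_false"], path + ".if_false"),
            )

        leaves = {}
        for entry in d["leaves"]:
            if "id" not in entry or "bias" not in entry:
                raise ValueError(f"model schema: malformed leaf entry {entry}")
            leaves[int(entry["id"])] = LeafFormula(
                formula_id=int(entry["id"]),
                bias=float(entry["bias"]),
                terms={k: float(v) for k, v in entry.get("terms", {}).items()},
                selected_zero=tuple(entry.get("selected_zero", ())),
            )
        model = cls(tree=parse_node(d["tree"]), leaves=leaves,
                    meta=dict(d.get("meta", {})))
        leaf_ids_in_tree = _tree_leaf_ids(model.tree)
        if set(leaf_ids_in_tree) != set(leaves):
            raise ValueError("model schema: tree paths and leaf list disagree")
        return model

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_json(cls, path) -> "PiecewiseLinearModel":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))

    def checksum(self) -> str:
        d = self.to_dict()
        payload = json.dumps({"tree": d["tree"], "leaves": d["leaves"]},
                             sort_keys=True, separators=(",", ":"))
        return hashlib.sha256(payload.encode()).hexdigest()


def _tree_leaf_ids(node) -> list:
    if isinstance(node, int):
        return [node]
    return _tree_leaf_ids(node.if_true) + _tree_leaf_ids(node.if_false)


# --------------------------------------------------------------------------
# published fixture

def load_published_model(path=None) -> PiecewiseLinearModel:
    """Load the packaged published model (or a compatible JSON file).

    For the packaged fixture the recomputed checksum must equal the stored
    one; any transcription drift raises.
    """
    if path is None:
        src = resources.files("weightmix").joinpath("published_model.json")
        d = json.loads(src.read_text())
    else:
        with open(path) as fh:
            d = json.load(fh)
    model = PiecewiseLinearModel.from_dict(d)
    stored = model.meta.get("checksum")
    if stored is not None and stored != model.checksum():
        raise ValueError("published model fixture failed checksum validation "
                         "(coefficient drift?)")
    return model


def assign_leaf(bmi: float, age_years: float, sex,
                tree: Union[GateRule, int, PiecewiseLinearModel]) -> int:
    """Deterministic leaf membership for one person."""
    if bmi <= 0:
        raise ValueError("bmi must be positive")
    model = tree if isinstance(tree, PiecewiseLinearModel) else \
        PiecewiseLinearModel(tree=tree, leaves={i: LeafFormula(i, 0.0)
                                                for i in _tree_leaf_ids(tree)})
    return model.assign(bmi, age_years, sex)


def predict_one_year(fv: dict, leaf: LeafFormula) -> float:
    """Next-year weight from an encoded feature dict and one leaf formula."""
    return leaf.evaluate(fv)


# --------------------------------------------------------------------------
# chained prediction

def chain_predict(model: PiecewiseLinearModel, weight_m1, weight_0, height_cm,
                  age_0, sex_male, profiles_by_year, horizon: int = 3,
                  reassign_leaf: bool = True, advance_age: bool = True,
                  noise_sd: float = 0.0, rng=None, feature_names=None,
                  labs=None):
    """Vectorised chained forecast for ``horizon`` years.

    ``profiles_by_year`` maps relative year (0..horizon) to a dict of
    lifestyle-column arrays; step *t* uses year *t* as the baseline interview
    and year *t+1* as the predictive-year interview.  With ``noise_sd`` > 0
    and an ``rng``, Gaussian noise is added to each realised yearly weight
    before it is fed forward (the synthetic data-generating process).

    Returns an (n, horizon) array of weights for years 1..horizon.
    """
    if horizon < 1:
        raise ValueError("horizon must be >= 1")
    names = list(feature_names) if feature_names is not None else list(FEATURE_NAMES)
    w_prev = np.asarray(weight_m1, dtype=float).copy()
    w_cur = np.asarray(weight_0, dtype=float).copy()
    height_cm = np.asarray(height_cm, dtype=float)
    age_0 = np.asarray(age_0, dtype=float)
    sex_male = np.asarray(sex_male, dtype=float)
    n = w_cur.shape[0]
    ids, C, b = model.coef_arrays(names)
    pos = {lid: i for i, lid in enumerate(ids)}

    frozen_leaf = None
    if not reassign_leaf:
        bmi0 = w_cur / (height_cm / 100.0) ** 2
        frozen_leaf = model.assign_array(bmi0, age_0, sex_male)

    out = np.empty((n, horizon))
    for t in range(horizon):
        age_t = age_0 + t if advance_age else age_0
        if reassign_leaf:
            bmi_t = w_cur / (height_cm / 100.0) ** 2
            leaf_of_row = model.assign_array(bmi_t, age_t, sex_male)
        else:
            leaf_of_row = frozen_leaf
        X = encode_matrix(profiles_by_year[t], profiles_by_year[t + 1],
                          w_cur, w_prev, height_cm, age_t, sex_male)
        if labs is not None:
            X = np.hstack([X, labs])
        y = np.empty(n)
        for lid in ids:
            m = leaf_of_row == lid
            if m.any():
                # einsum keeps a fixed reduction order, so forecasts are
                # bitwise identical whether computed per person or in batch
                y[m] = np.einsum("ij,j->i", X[m], C[pos[lid]]) + b[pos[lid]]
        if noise_sd > 0:
            if rng is None:
                raise ValueError("noise_sd > 0 requires an rng")
            y = y + rng.normal(0.0, noise_sd, n)
        w_prev, w_cur = w_cur, y
        out[:, t] = y
    return out


@dataclass
class PredictionTrajectory:
    """Two measured weights plus chained predictions under one scenario."""

    person_id: str
    measured: tuple  # (year -1, year 0)
    predicted: tuple  # years 1..horizon
    scenario: str = ""

    @property
    def years(self):
        return tuple(range(-1, len(self.predicted) + 1))

    @property
    def weights(self):
        return self.measured + self.predicted


def _profile_arrays(profile: LifestyleProfile) -> dict:
    return {c: np.array([getattr(profile, c)], dtype=float)
            for c in LIFESTYLE_COLUMNS}


def predict_trajectory(history, lifestyle_scenario: LifestyleProfile,
                       model: PiecewiseLinearModel, horizon: int = 3,
                       reassign_leaf: bool = True, advance_age: bool = True,
                       scenario: str = "") -> PredictionTrajectory:
    """Chained forecast for one person under a fixed lifestyle scenario.

    ``history`` is the pair of CheckupRecords for years −1 and 0.  The
    year-0 interview is the baseline interview of the first step; from the
    second step on the scenario serves as both interviews, reflecting
    answers that "continue without change" over the forecast.
    """
    rec_m1, rec_0 = sorted(history, key=lambda r: r.year_index)
    if rec_m1.weight_kg is None or rec_0.weight_kg is None:
        raise ValueError("measured weights at years -1 and 0 are required")
    if rec_0.lifestyle is None:
        raise ValueError("baseline lifestyle profile is required")
    profiles = {0: _profile_arrays(rec_0.lifestyle)}
    for year in range(1, horizon + 1):
        profiles[year] = _profile_arrays(lifestyle_scenario)
    preds = chain_predict(
        model,
        np.array([rec_m1.weight_kg]), np.array([rec_0.weight_kg]),
        np.array([rec_0.height_cm]), np.array([float(rec_0.age_years)]),
        np.array([1.0 if rec_0.sex == "male" else 0.0]),
        profiles, horizon=horizon, reassign_leaf=reassign_leaf,
        advance_age=advance_age,
    )
    traj = PredictionTrajectory(
        person_id=rec_0.person_id,
        measured=(float(rec_m1.weight_kg), float(rec_0.weight_kg)),
        predicted=tuple(float(v) for v in preds[0]),
        scenario=scenario,
    )
    assert np.all(np.isfinite(traj.predicted))
    return traj


def scenario_compare(history, scenario_a: LifestyleProfile,
                     scenario_b: LifestyleProfile, model: PiecewiseLinearModel,
                     horizon: int = 3, labels=("A", "B"), **kwargs):
    """Two chained forecasts from identical history, differing lifestyles."""
    if scenario_a == scenario_b:
        warnings.warn("scenario_compare called with identical scenarios")
    ta = predict_trajectory(history, scenario_a, model, horizon=horizon,
                            scenario=labels[0], **kwargs)
    tb = predict_trajectory(history, scenario_b, model, horizon=horizon,
                            scenario=labels[1], **kwargs)
    return ta, tb
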