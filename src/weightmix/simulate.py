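"""Synthetic longitudinal health-checkup cohorts.

The generator emulates the statistical shape of a large Japanese
occupational-health checkup population: sex ratio and sex-specific
height/weight marginals, an age distribution of 48 ± 12 years truncated to
19–91, annual questionnaire answers with year-to-year persistence, optional
laboratory decoy variables, and person-level missingness at a configurable
rate.  Longitudinal weights follow a ground-truth piecewise-linear model
(default: the packaged published model) iterated one year at a time with
additive Gaussian noise — the same chaining the predictor uses, so in the
noise-free limit generated trajectories coincide exactly with model
forecasts.

All randomness flows from a single seed through named substreams
(demographics / lifestyle / labs / weight noise / missingness), so any one
stage is reproducible in isolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd

from .features import LAB_COLUMNS
from .lifestyle import BINARY_ITEMS, LIFESTYLE_COLUMNS, LifestyleProfile
from .model import PiecewiseLinearModel, chain_predict, load_published_model

#: cohort marginals: (male mean, male SD, female mean, female SD)
TABLE1_ANTHROPOMETRY = {
    "height_cm": (170.8, 6.2, 157.8, 5.7),
    "weight_kg": (68.3, 11.1, 54.4, 9.6),
}
TABLE1_LABS = {
    "sbp": (124, 16, 117, 16),
    "dbp": (78, 11, 72, 11),
    "hba1c": (5.6, 0.5, 5.6, 0.4),
    "tg": (122, 79, 87, 51),
    "hdl_c": (59, 15, 70, 16),
    "ldl_c": (123, 30, 119, 30),
    "fbg": (99, 14, 94, 11),
    "ast": (25, 10, 21, 7),
    "alt": (26, 16, 16, 9),
    "ggtp": (49, 43, 25, 20),
    "waist_cm": (83.5, 9.3, 78.4, 9.6),
}

#: questionnaire "yes" marginals (plausible checkup-population assumptions)
DEFAULT_LIFESTYLE_MARGINALS = {
    "wants_instruction": 0.30,
    "heavy_smoker": 0.25,
    "fast_walker": 0.50,
    "daily_activity": 0.35,
    "exercise_habit": 0.25,
    "skips_breakfast": 0.20,
    "late_supper": 0.35,
    "snacks": 0.35,
    "sleeps_well": 0.70,
}
DEFAULT_EATING_SPEED_PROBS = (0.30, 0.55, 0.15)  # quicker / normal / slower
DEFAULT_INTENTION_PROBS = (0.30, 0.40, 0.30)     # levels 1 / 2 / 3

DEFAULT_MISSINGNESS = 12021 / 67021


@dataclass
class GeneratorConfig:
    n_persons: int = 1000
    seed: int = 0
    male_fraction: float = 0.66
    age_mean: float = 48.0
    age_sd: float = 12.0
    age_range: tuple = (19, 91)
    initial_diff_sd: float = 2.0  # SD of weight change from year -1 to 0
    lifestyle_marginals: dict = field(
        default_factory=lambda: dict(DEFAULT_LIFESTYLE_MARGINALS))
    eating_speed_probs: tuple = DEFAULT_EATING_SPEED_PROBS
    intention_probs: tuple = DEFAULT_INTENTION_PROBS
    drinking_n: int = 10          # drinking score ~ Binomial(n, p), range 0-10
    drinking_p: float = 0.30
    flip_prob: float = 0.10       # yearly probability an answer changes
    noise_sd_kg: float = 1.9
    missingness_prob: float = DEFAULT_MISSINGNESS
    include_labs: bool = True
    advance_age: bool = True
    reassign_leaf: bool = True
    ground_truth_model: Optional[PiecewiseLinearModel] = None

    def validate(self) -> None:
        probs = [self.male_fraction, self.flip_prob, self.missingness_prob,
                 self.drinking_p, *self.lifestyle_marginals.values(),
                 *self.eating_speed_probs, *self.intention_probs]
        if any(not (0.0 <= p <= 1.0) for p in probs):
            raise ValueError("all probabilities must lie in [0, 1]")
        if self.noise_sd_kg < 0 or self.initial_diff_sd < 0:
            raise ValueError("noise SDs must be >= 0")
        if self.n_persons < 1:
            raise ValueError("n_persons must be >= 1")

    def with_overrides(self, **kw) -> "GeneratorConfig":
        return replace(self, **kw)


def _truncated_normal_ages(rng, n, mean, sd, lo, hi):
    out = np.empty(n)
    todo = np.arange(n)
    while todo.size:
        draw = rng.normal(mean, sd, todo.size)
        ok = (draw >= lo) & (draw <= hi)
        out[todo[ok]] = draw[ok]
        todo = todo[~ok]
    return np.round(out)


def _categorical(rng, probs, n):
    return rng.choice(len(probs), size=n, p=np.asarray(probs) / np.sum(probs))


def _draw_profile_year0(rng, cfg, n):
    prof = {item: (rng.random(n) < p).astype(float)
            for item, p in cfg.lifestyle_marginals.items()}
    prof["eating_speed"] = _categorical(rng, cfg.eating_speed_probs, n).astype(float)
    prof["intention_level"] = (
        _categorical(rng, cfg.intention_probs, n) + 1).astype(float)
    prof["drinking_score"] = rng.binomial(cfg.drinking_n, cfg.drinking_p,
                                          n).astype(float)
    return prof


def _transition_profile(rng, cfg, prev):
    """Answers persist; with flip_prob they change (multi-level: to another
    level uniformly, drinking: redrawn from its marginal)."""
    n = prev["eating_speed"].shape[0]
    new = {}
    for item in BINARY_ITEMS:
        flip = rng.random(n) < cfg.flip_prob
        new[item] = np.where(flip, 1.0 - prev[item], prev[item])
    for item, k in (("eating_speed", 3), ("intention_level", 3)):
        flip = rng.random(n) < cfg.flip_prob
        base = prev[item] - (1.0 if item == "intention_level" else 0.0)
        shift = rng.integers(1, k, n)
        moved = (base + shift) % k
        out = np.where(flip, moved, base)
        new[item] = out + (1.0 if item == "intention_level" else 0.0)
    flip = rng.random(n) < cfg.flip_prob
    redraw = rng.binomial(cfg.drinking_n, cfg.drinking_p, n).astype(float)
    new["drinking_score"] = np.where(flip, redraw, prev["drinking_score"])
    return new


def generate_cohort(config: GeneratorConfig) -> pd.DataFrame:
    """Generate a long-format cohort with years −1..3 per person."""
    config.validate()
    cfg = config
    n = cfg.n_persons
    ss = np.random.SeedSequence(cfg.seed).spawn(5)
    rng_demo, rng_life, rng_labs, rng_noise, rng_miss = \
        (np.random.default_rng(s) for s in ss)
    model = cfg.ground_truth_model or load_published_model()

    sex_male = (rng_demo.random(n) < cfg.male_fraction).astype(float)
    hm, hs, hf, hfs = TABLE1_ANTHROPOMETRY["height_cm"]
    wm, ws, wf, wfs = TABLE1_ANTHROPOMETRY["weight_kg"]
    height = np.where(sex_male == 1, rng_demo.normal(hm, hs, n),
                      rng_demo.normal(hf, hfs, n)).clip(min=130.0)
    weight0 = np.where(sex_male == 1, rng_demo.normal(wm, ws, n),
                       rng_demo.normal(wf, wfs, n)).clip(min=30.0)
    age0 = _truncated_normal_ages(rng_demo, n, cfg.age_mean, cfg.age_sd,
                                  *cfg.age_range)
    weight_m1 = (weight0 - rng_demo.normal(0.0, cfg.initial_diff_sd, n)
                 ).clip(min=30.0)

    profiles = {0: _draw_profile_year0(rng_life, cfg, n)}
    for year in (1, 2, 3):
        profiles[year] = _transition_profile(rng_life, cfg, profiles[year - 1])

    future = chain_predict(
        model, weight_m1, weight0, height, age0, sex_male, profiles,
        horizon=3, reassign_leaf=cfg.reassign_leaf,
        advance_age=cfg.advance_age,
        noise_sd=cfg.noise_sd_kg, rng=(rng_noise if cfg.noise_sd_kg > 0 else None),
    )
    weights = {-1: weight_m1, 0: weight0,
               1: future[:, 0], 2: future[:, 1], 3: future[:, 2]}

    # person-level MCAR missingness: blank the weight of one random year
    weights = {y: w.copy() for y, w in weights.items()}
    flagged = rng_miss.random(n) < cfg.missingness_prob
    miss_year = rng_miss.integers(-1, 4, n)
    for y in range(-1, 4):
        weights[y][flagged & (miss_year == y)] = np.nan

    person_id = np.array([f"p{i:06d}" for i in range(n)])
    frames = []
    for y in range(-1, 4):
        cols = {
            "person_id": person_id,
            "year_index": np.full(n, y),
            "sex": np.where(sex_male == 1, "male", "female"),
            "age_years": (age0 + y if cfg.advance_age else age0).astype(int),
            "height_cm": height,
            "weight_kg": weights[y],
        }
        if cfg.include_labs:
            for lab, (m_m, s_m, m_f, s_f) in TABLE1_LABS.items():
                cols[lab] = np.where(sex_male == 1,
                                     rng_labs.normal(m_m, s_m, n),
                                     rng_labs.normal(m_f, s_f, n))
        for c in LIFESTYLE_COLUMNS:
            cols[c] = profiles[y][c] if y >= 0 else np.full(n, np.nan)
        frames.append(pd.DataFrame(cols))
    df = pd.concat(frames, ignore_index=True)
    return df.sort_values(["person_id", "year_index"], kind="stable",
                          ignore_index=True)


def simulate_weight_trajectory(history, lifestyle, model: PiecewiseLinearModel,
                               noise_sd_kg: float, rng, horizon: int = 3,
                               **chain_kwargs) -> np.ndarray:
    """Forward-simulate one person's weights for years 1..horizon.

    ``history`` is the (year −1, year 0) record pair; ``lifestyle`` is either
    a single :class:`LifestyleProfile` held fixed over the horizon or a
    mapping year → profile for years 0..horizon.  Realised (noisy) weights
    are fed forward, as in the cohort generator.
    """
    rec_m1, rec_0 = sorted(history, key=lambda r: r.year_index)
    if rec_m1.weight_kg is None or rec_0.weight_kg is None:
        raise ValueError("weights at years -1 and 0 are required")
    if isinstance(lifestyle, LifestyleProfile):
        by_year = {0: rec_0.lifestyle or lifestyle}
        for y in range(1, horizon + 1):
            by_year[y] = lifestyle
    else:
        by_year = dict(lifestyle)
    profiles = {y: {c: np.array([getattr(p, c)], dtype=float)
                    for c in LIFESTYLE_COLUMNS}
                for y, p in by_year.items()}
    out = chain_predict(
        model,
        np.array([rec_m1.weight_kg]), np.array([rec_0.weight_kg]),
        np.array([rec_0.height_cm]), np.array([float(rec_0.age_years)]),
        np.array([1.0 if rec_0.sex == "male" else 0.0]),
        profiles, horizon=horizon,
        noise_sd=noise_sd_kg, rng=(rng if noise_sd_kg > 0 else None),
        **chain_kwargs,
    )
    return out[0]
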