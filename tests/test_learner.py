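"""Mixture learner: sparse leaf fits, split scoring, greedy tree growth."""

import numpy as np
import pandas as pd
import pytest

from weightmix import (FitConfig, brute_force_best_split, fit_leaf_regression,
                       fit_partition, score_split)
from weightmix.features import TrainingTable
from weightmix.learner import SplitCandidate
from weightmix.model import GateRule


def make_table(X, y, bmi=None, age=None, sex=None, names=None):
    n = len(y)
    gates = pd.DataFrame({
        "bmi": bmi if bmi is not None else np.zeros(n),
        "age": age if age is not None else np.zeros(n),
        "sex_male": sex if sex is not None else np.zeros(n),
    })
    names = names or [f"x{j}" for j in range(X.shape[1])]
    return TrainingTable(X=np.asarray(X, float), y=np.asarray(y, float),
                         gates=gates, person_id=np.arange(n),
                         step=np.zeros(n, int), feature_names=names)


def small_config(**kw):
    kw.setdefault("min_leaf_n", 20)
    kw.setdefault("threshold_grid", 8)
    return FitConfig(**kw)


class TestFitLeafRegression:
    def test_recovers_slope_and_bias(self):
        g = np.random.default_rng(1)
        w = g.normal(70, 10, 5000)
        decoys = g.normal(0, 1, (5000, 4))
        X = np.column_stack([w, decoys])
        y = 2.12 + 1.0 * w + g.normal(0, 0.01, 5000)
        cfg = FitConfig(min_leaf_n=200)
        leaf = fit_leaf_regression(X, y, cfg, ["weight_baseline", "d1", "d2",
                                               "d3", "d4"])
        assert leaf.terms["weight_baseline"] == pytest.approx(1.00, abs=0.02)
        assert leaf.bias == pytest.approx(2.12, abs=0.1)

    def test_pure_noise_decoys_rarely_selected(self):
        """Decoy selection stays near the BIC's nominal false-entry rate."""
        g = np.random.default_rng(2)
        n_sel, any_sel = 0, 0
        reps = 100
        for _ in range(reps):
            X = g.normal(0, 1, (500, 20))
            y = 5.0 + g.normal(0, 1, 500)
            leaf = fit_leaf_regression(X, y, FitConfig(min_leaf_n=100),
                                       [f"d{j}" for j in range(20)])
            n_sel += len(leaf.terms)
            any_sel += bool(leaf.terms)
        # P(best of 20 chi2_1 stats exceeds log 500) ~ 0.23
        assert any_sel / reps <= 0.4
        assert n_sel / reps <= 0.6

    def test_rejects_undersized_leaf(self):
        X = np.zeros((10, 2))
        with pytest.raises(ValueError, match="min_leaf_n"):
            fit_leaf_regression(X, np.zeros(10), FitConfig(min_leaf_n=200),
                                ["a", "b"])

    def test_constant_target_keeps_only_bias(self):
        g = np.random.default_rng(3)
        X = g.normal(0, 1, (400, 5))
        leaf = fit_leaf_regression(X, np.full(400, 72.0),
                                   small_config(), list("abcde"))
        assert leaf.terms == {}
        assert leaf.bias == pytest.approx(72.0)


class TestScoreSplit:
    def test_deterministic(self):
        g = np.random.default_rng(4)
        X = g.normal(0, 1, (200, 2))
        y = g.normal(0, 1, 200)
        gate = g.normal(25, 4, 200)
        cand = SplitCandidate(feature="bmi", threshold=25.0)
        g1 = score_split(X, y, gate, cand, small_config())
        g2 = score_split(X, y, gate, SplitCandidate("bmi", 25.0),
                         small_config())
        assert g1 == g2

    def test_undersized_child_marked_infeasible(self):
        g = np.random.default_rng(5)
        X = g.normal(0, 1, (100, 2))
        y = g.normal(0, 1, 100)
        gate = np.arange(100.0)
        cand = SplitCandidate(feature="bmi", threshold=5.0)
        gain = score_split(X, y, gate, cand, small_config())
        assert gain == -np.inf and not cand.feasible

    def test_true_regime_split_gains(self):
        """A genuine two-regime difference yields a positive gain."""
        g = np.random.default_rng(6)
        x = g.normal(70, 10, 2000)
        bmi = g.normal(25, 4, 2000)
        y = np.where(bmi >= 27, 5.0 + 1.0 * x, -5.0 + 0.8 * x) \
            + g.normal(0, 1, 2000)
        gain = score_split(x[:, None], y, bmi,
                           SplitCandidate("bmi", 27.0), small_config())
        assert gain > 0


class TestFitPartition:
    def test_single_regime_gives_one_leaf(self):
        g = np.random.default_rng(7)
        x = g.normal(70, 10, 1500)
        y = 1.0 * x + 0.5 + g.normal(0, 1, 1500)
        table = make_table(x[:, None], y, bmi=g.normal(25, 4, 1500),
                           age=g.integers(20, 70, 1500).astype(float))
        res = fit_partition(table, small_config(min_leaf_n=60))
        assert len(res.model.leaves) == 1
        assert isinstance(res.model.tree, int)

    def test_null_split_acceptance_rate_low(self):
        """Data from one global linear model: splits almost never accepted."""
        g = np.random.default_rng(8)
        accepted = 0
        reps = 50
        for _ in range(reps):
            x = g.normal(70, 10, 600)
            y = 0.9 * x + g.normal(0, 1, 600)
            table = make_table(x[:, None], y, bmi=g.normal(25, 4, 600),
                               age=g.integers(20, 70, 600).astype(float),
                               sex=(g.random(600) < 0.5).astype(float))
            res = fit_partition(table, small_config(min_leaf_n=40))
            accepted += len(res.model.leaves) > 1
        assert accepted / reps <= 0.1

    def test_two_regime_threshold_recovered(self):
        g = np.random.default_rng(9)
        n = 4000
        x = g.normal(70, 10, n)
        bmi = g.normal(26, 4, n)
        y = np.where(bmi >= 27.5, 8.0 + 1.0 * x, -8.0 + 1.0 * x) \
            + g.normal(0, 1, n)
        table = make_table(x[:, None], y, bmi=bmi)
        cfg = small_config(min_leaf_n=60, threshold_grid=64, max_depth=1)
        res = fit_partition(table, cfg)
        assert isinstance(res.model.tree, GateRule)
        grid_step = np.diff(np.quantile(bmi, np.arange(1, 64) / 64)).max()
        assert abs(res.model.tree.threshold - 27.5) <= grid_step

    def test_criterion_gains_all_positive(self):
        g = np.random.default_rng(10)
        n = 3000
        x = g.normal(70, 10, n)
        bmi = g.normal(26, 4, n)
        age = g.integers(20, 70, n).astype(float)
        y = np.where(bmi >= 27, 6.0, np.where(age >= 45, -6.0, 0.0)) \
            + 1.0 * x + g.normal(0, 1, n)
        res = fit_partition(make_table(x[:, None], y, bmi=bmi, age=age),
                            small_config(min_leaf_n=60))
        gains = [t["accepted"]["gain"] for t in res.trace if t["accepted"]]
        assert gains and all(gn > 0 for gn in gains)

    def test_deterministic(self):
        g = np.random.default_rng(11)
        x = g.normal(70, 10, 1000)
        bmi = g.normal(26, 4, 1000)
        y = np.where(bmi >= 26, 4.0, -4.0) + x + g.normal(0, 1, 1000)
        table = make_table(x[:, None], y, bmi=bmi)
        d1 = fit_partition(table, small_config(min_leaf_n=50)).model.to_dict()
        d2 = fit_partition(table, small_config(min_leaf_n=50)).model.to_dict()
        assert d1 == d2

    def test_empty_and_config_validation(self):
        table = make_table(np.zeros((0, 1)), np.zeros(0))
        with pytest.raises(ValueError):
            fit_partition(table, small_config())
        with pytest.raises(ValueError, match="min_leaf_n"):
            FitConfig(min_leaf_n=3).validate(n_features=5)

    def test_constant_target_no_splits(self):
        g = np.random.default_rng(12)
        table = make_table(g.normal(0, 1, (800, 2)), np.full(800, 70.0),
                           bmi=g.normal(25, 4, 800))
        res = fit_partition(table, small_config(min_leaf_n=40))
        assert len(res.model.leaves) == 1
        assert res.model.leaves[1].terms == {}


class TestBruteForceOracle:
    @staticmethod
    def random_instance(g):
        n = int(g.integers(80, 200))
        p = int(g.integers(1, 4))
        X = g.normal(0, 1, (n, p))
        bmi = g.normal(26, 4, n)
        age = g.integers(20, 70, n).astype(float)
        sex = (g.random(n) < 0.5).astype(float)
        shift = g.normal(0, 3)
        thr = g.normal(26, 2)
        y = X @ g.normal(0, 1, p) + np.where(bmi >= thr, shift, 0.0) \
            + g.normal(0, 1, n)
        return make_table(X, y, bmi=bmi, age=age, sex=sex)

    def test_greedy_root_matches_exhaustive_argmax(self):
        g = np.random.default_rng(13)
        cfg = small_config(min_leaf_n=15, threshold_grid=8, max_depth=1)
        n_checked = 0
        for _ in range(15):
            table = self.random_instance(g)
            oracle = brute_force_best_split(
                table.X, table.y,
                {"bmi": table.gates["bmi"], "age": table.gates["age"],
                 "sex_male": table.gates["sex_male"]}, cfg)
            fitted = fit_partition(table, cfg).model.tree
            if isinstance(fitted, GateRule):
                assert oracle is not None and oracle.gain > 0
                assert fitted.feature == oracle.feature
                if oracle.threshold is not None:
                    assert fitted.threshold == pytest.approx(oracle.threshold)
                n_checked += 1
            else:
                assert oracle is None or oracle.gain <= 1e-6
        assert n_checked >= 5  # most instances contain a real split

    def test_single_and_no_feasible_candidate(self):
        g = np.random.default_rng(14)
        X = g.normal(0, 1, (60, 1))
        y = g.normal(0, 1, 60)
        cfg = small_config(min_leaf_n=25, threshold_grid=2)
        out = brute_force_best_split(X, y, {"bmi": g.normal(25, 4, 60),
                                            "age": np.zeros(60),
                                            "sex_male": np.zeros(60)}, cfg)
        assert out is None or isinstance(out, SplitCandidate)
        none_out = brute_force_best_split(
            X, y, {"bmi": np.zeros(60), "age": np.zeros(60),
                   "sex_male": np.zeros(60)}, cfg)
        assert none_out is None  # constant gates: no feasible split

    def test_large_instance_rejected(self):
        with pytest.raises(ValueError):
            brute_force_best_split(np.zeros((600, 1)), np.zeros(600),
                                   {"bmi": np.zeros(600)}, small_config())
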