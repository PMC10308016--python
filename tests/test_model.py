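"""Published-model fixture, feature encoding, prediction and scenarios."""

import json
import warnings

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from weightmix import (LifestyleProfile, assign_leaf, encode_features,
                       predict_one_year, predict_trajectory, scenario_compare)
from weightmix.model import PiecewiseLinearModel, load_published_model

from conftest import (FORMULA1_SILENT_BASE, FORMULA1_SILENT_PRED,
                      make_history, single_leaf_model)


class TestPublishedFixture:
    def test_five_leaves_and_root_gate(self, published):
        assert sorted(published.leaves) == [1, 2, 3, 4, 5]
        assert published.tree.feature == "bmi"
        assert published.tree.threshold == pytest.approx(29.93)

    def test_key_coefficients(self, published):
        assert published.leaves[1].bias == pytest.approx(2.12)
        for lid in range(1, 6):
            assert published.leaves[lid].terms["weight_baseline"] == 1.00
        assert published.leaves[1].terms["weight_diff"] == pytest.approx(-0.14)
        assert published.leaves[5].terms["height"] == pytest.approx(0.02)

    def test_checksum_rejects_drift(self, published, tmp_path):
        d = published.to_dict()
        d["leaves"][0]["terms"]["weight_baseline"] = 1.01
        path = tmp_path / "tampered.json"
        path.write_text(json.dumps(d))
        with pytest.raises(ValueError, match="checksum"):
            load_published_model(path)

    def test_schema_violation_is_reported(self, published, tmp_path):
        d = published.to_dict()
        del d["tree"]["op"]
        path = tmp_path / "broken.json"
        path.write_text(json.dumps(d))
        with pytest.raises(ValueError, match="op"):
            load_published_model(path)

    def test_json_round_trip_is_identity(self, published, tmp_path):
        path = tmp_path / "model.json"
        published.to_json(path)
        again = load_published_model(path)
        assert again.to_dict() == published.to_dict()
        assert again.checksum() == published.checksum()


class TestLeafAssignment:
    @pytest.mark.parametrize("bmi,age,sex,leaf", [
        (31.0, 50, "male", 1),
        (31.0, 50, "female", 2),
        (29.93, 50, "female", 2),   # boundary goes to the high-BMI side
        (29.92, 50, "female", 4),
        (25.0, 24, "male", 3),      # age boundary inclusive on young side
        (25.0, 25, "male", 4),
        (23.44, 70, "female", 4),
        (22.0, 20, "male", 5),
    ])
    def test_published_routing(self, published, bmi, age, sex, leaf):
        assert assign_leaf(bmi, age, sex, published) == leaf

    def test_rejects_nonpositive_bmi(self, published):
        with pytest.raises(ValueError):
            assign_leaf(0.0, 40, "male", published)

    @settings(max_examples=200, deadline=None)
    @given(bmi=st.floats(10.0, 60.0), age=st.integers(19, 91),
           male=st.booleans())
    def test_partition_matches_published_rule(self, published, bmi, age, male):
        """Routing equals the stated stratification rule (independent oracle)."""
        if bmi >= 29.93:
            want = 1 if male else 2
        elif bmi >= 23.44:
            want = 3 if age <= 24 else 4
        else:
            want = 5
        got = assign_leaf(bmi, age, "male" if male else "female", published)
        assert got == want


class TestEncoding:
    def test_intention_gates_predictive_indicators(self):
        hist = make_history(profile=LifestyleProfile())
        pred = LifestyleProfile(heavy_smoker=0, intention_level=1)
        fv = encode_features(hist[1], hist[0], pred)
        assert fv["pred_heavy_smoker_no_i1"] == 1.0
        assert fv["pred_heavy_smoker_no_i2"] == 0.0
        assert fv["pred_heavy_smoker_no_i3"] == 0.0

    def test_silent_profiles_zero_all_indicators(self):
        hist = make_history(profile=FORMULA1_SILENT_BASE)
        fv = encode_features(hist[1], hist[0], FORMULA1_SILENT_PRED)
        continuous = {"weight_baseline", "weight_diff", "height", "age",
                      "sex_male", "base_drinking", "pred_drinking"}
        fired = {k for k, v in fv.items()
                 if v != 0.0 and k not in continuous
                 and not k.startswith("pred_exercise_no")
                 and not k.startswith("pred_eating_slower")
                 and k != "base_eating_quicker"}
        # only indicators without a formula-1 coefficient may fire
        assert fired == set()

    def test_weight_diff_and_missing_lifestyle(self):
        hist = make_history(weight_m1=70.0, weight_0=70.0)
        fv = encode_features(hist[1], hist[0], LifestyleProfile())
        assert fv["weight_diff"] == 0.0
        hist[1].lifestyle = None
        with pytest.raises(ValueError, match="lifestyle"):
            encode_features(hist[1], hist[0], LifestyleProfile())

    def test_at_most_one_intention_indicator_per_item(self):
        hist = make_history()
        for level in (1, 2, 3):
            fv = encode_features(hist[1], hist[0],
                                 LifestyleProfile(intention_level=level))
            for stem in ("pred_heavy_smoker_no", "pred_snacks_no",
                         "pred_sleeps_well_yes"):
                fired = [fv[f"{stem}_i{l}"] for l in (1, 2, 3)]
                assert sum(fired) <= 1


class TestPredictOneYear:
    def test_formula1_dot_product(self, published):
        fv = {"weight_baseline": 90.0, "weight_diff": 0.0, "height": 170.0,
              "age": 40.0}
        got = predict_one_year(fv, published.leaves[1])
        assert got == pytest.approx(93.02, abs=0.005)

    def test_formula5_dot_product_age_absent(self, published):
        fv = {"weight_baseline": 60.0, "weight_diff": 0.0, "height": 160.0,
              "age": 99.0}  # age carries no coefficient in formula 5
        got = predict_one_year(fv, published.leaves[5])
        assert got == pytest.approx(63.38, abs=0.005)

    def test_all_zero_features_give_bias(self, published):
        for leaf in published.leaves.values():
            assert predict_one_year({}, leaf) == pytest.approx(leaf.bias)

    @settings(max_examples=50, deadline=None)
    @given(alpha=st.floats(-3, 3), w=st.floats(40, 120))
    def test_linearity_in_continuous_block(self, published, alpha, w):
        leaf = published.leaves[1]
        f0 = predict_one_year({"weight_baseline": 0.0}, leaf)
        f1 = predict_one_year({"weight_baseline": w}, leaf)
        fa = predict_one_year({"weight_baseline": alpha * w}, leaf)
        assert fa - f0 == pytest.approx(alpha * (f1 - f0), rel=1e-9, abs=1e-9)


class TestTrajectory:
    def test_shape_contract(self, published):
        traj = predict_trajectory(make_history(), LifestyleProfile(),
                                  published)
        assert len(traj.measured) == 2 and len(traj.predicted) == 3
        assert np.all(np.isfinite(traj.weights))
        assert traj.years == (-1, 0, 1, 2, 3)

    def test_horizon_one_equals_single_step(self, published):
        hist = make_history(profile=FORMULA1_SILENT_BASE)
        traj = predict_trajectory(hist, FORMULA1_SILENT_PRED, published,
                                  horizon=1, advance_age=False)
        assert traj.predicted[0] == pytest.approx(93.02, abs=0.005)

    def test_identity_model_closed_form(self):
        """bias b with unit weight coefficient: year-k forecast = w0 + k*b."""
        model = single_leaf_model(bias=1.5)
        traj = predict_trajectory(make_history(weight_0=80.0), LifestyleProfile(),
                                  model, horizon=3)
        np.testing.assert_allclose(traj.predicted,
                                   [80.0 + 1.5 * k for k in (1, 2, 3)])

    def test_rejects_bad_horizon_and_missing_weight(self, published):
        with pytest.raises(ValueError):
            predict_trajectory(make_history(), LifestyleProfile(), published,
                               horizon=0)
        hist = make_history()
        hist[0].weight_kg = None
        with pytest.raises(ValueError):
            predict_trajectory(hist, LifestyleProfile(), published)

    def test_freeze_leaf_mode_differs_when_bmi_crosses(self, published):
        # subject just under the 29.93 gate whose predicted weight rises
        hist = make_history(weight_m1=92.0, weight_0=86.3, height=170.0)
        scen = LifestyleProfile(skips_breakfast=1, intention_level=1)
        t_re = predict_trajectory(hist, scen, published, reassign_leaf=True)
        t_fr = predict_trajectory(hist, scen, published, reassign_leaf=False)
        assert t_re.predicted[0] == t_fr.predicted[0]


class TestScenarioCompare:
    def test_breakfast_scenarios_order(self, published):
        """Not skipping breakfast never predicts more weight (formula 1)."""
        hist = make_history(weight_0=95.0)  # BMI 32.9 -> formula 1
        eats = LifestyleProfile(skips_breakfast=0, intention_level=1)
        skips = LifestyleProfile(skips_breakfast=1, intention_level=1)
        t_eats, t_skips = scenario_compare(hist, eats, skips, published)
        assert t_eats.predicted[-1] <= t_skips.predicted[-1]

    def test_walking_scenarios_order(self, published):
        hist = make_history(weight_0=95.0)
        fast = LifestyleProfile(fast_walker=1, intention_level=1)
        slow = LifestyleProfile(fast_walker=0, intention_level=1)
        t_fast, t_slow = scenario_compare(hist, fast, slow, published)
        assert all(a <= b for a, b in zip(t_fast.predicted, t_slow.predicted))

    def test_identical_scenarios_warn_and_match(self, published):
        hist = make_history()
        scen = LifestyleProfile()
        with pytest.warns(UserWarning):
            ta, tb = scenario_compare(hist, scen, scen, published)
        assert ta.predicted == tb.predicted


def test_serialization_round_trip_all_coefficients(published, tmp_path):
    d = published.to_dict()
    again = PiecewiseLinearModel.from_dict(d)
    for lid, leaf in published.leaves.items():
        assert again.leaves[lid].terms == leaf.terms
        assert again.leaves[lid].bias == leaf.bias
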