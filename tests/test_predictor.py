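"""Threshold calibration, online class elimination and predictive power."""

import numpy as np
import pytest

from esec import predictor
from esec.predictor import (
    ClassModel,
    calibrate_threshold,
    column_offset,
    predict_online,
    predictive_power,
    train_models,
)


class TestPredictivePower:
    def test_half_way_prediction_gives_fifty(self):
        for tot in (1.0, 11.7, 100.0):
            assert predictive_power(tot / 2, tot) == pytest.approx(50.0)

    def test_prediction_at_completion_gives_zero(self):
        assert predictive_power(12.0, 12.0) == pytest.approx(0.0)

    def test_immediate_prediction_gives_hundred(self):
        assert predictive_power(0.0, 9.0) == pytest.approx(100.0)

    def test_take_down_average_timing(self):
        # 3.3 s prediction moment of an 11.7 s action
        assert predictive_power(3.3, 11.7) == pytest.approx(71.794871, abs=1e-5)

    def test_strictly_decreasing_in_prediction_moment(self):
        tot = 10.0
        values = [predictive_power(t, tot) for t in np.linspace(0, tot, 25)]
        assert all(a > b for a, b in zip(values, values[1:]))

    @pytest.mark.parametrize("t, tot", [(5.0, 4.0), (-1.0, 4.0), (1.0, 0.0)])
    def test_domain_errors(self, t, tot):
        with pytest.raises(ValueError):
            predictive_power(t, tot)


class TestColumnOffset:
    def test_same_column_is_zero(self):
        assert column_offset(4, 4) == 0

    def test_later_is_positive(self):
        assert column_offset(5, 4) == +1

    def test_earlier_is_negative(self):
        assert column_offset(3, 4) == -1

    def test_indices_start_at_one(self):
        with pytest.raises(ValueError):
            column_offset(0, 4)


class TestCalibration:
    def test_pair_counts_for_default_parameters(self, dataset_tables):
        members = [t for t in dataset_tables if t.action_label == "Hide"]
        theta, meta = calibrate_threshold(
            members, m=20, repeats=20, rng=np.random.default_rng(0)
        )
        assert meta["pairs_per_repeat"] == 190  # m(m-1)/2 with m = 20
        assert meta["n_values"] == 3800  # 20 repeats averaged
        assert 0 < theta <= 100

    def test_identical_members_give_threshold_100(self, fixture_tables):
        members = [fixture_tables["Stir"]] * 5
        theta, _ = calibrate_threshold(members, m=4, repeats=3,
                                       rng=np.random.default_rng(0))
        assert theta == pytest.approx(100.0)

    def test_small_class_caps_m_at_class_size(self, fixture_tables):
        members = [fixture_tables["Lay"], fixture_tables["Push"], fixture_tables["Stir"]]
        theta, meta = calibrate_threshold(members, m=20, repeats=2,
                                          rng=np.random.default_rng(0))
        assert meta["m"] == 3
        assert meta["pairs_per_repeat"] == 3

    def test_singleton_class_rejected(self, fixture_tables):
        with pytest.raises(ValueError):
            calibrate_threshold([fixture_tables["Hide"]])

    def test_calibration_reproducible_from_seed(self, dataset_tables):
        members = [t for t in dataset_tables if t.action_label == "Take down"]
        t1, _ = calibrate_threshold(members, rng=np.random.default_rng(42))
        t2, _ = calibrate_threshold(members, rng=np.random.default_rng(42))
        assert t1 == t2


class TestOnlinePrediction:
    def test_canonical_hide_recognized_at_column_four(self, singleton_models):
        gamma = singleton_models["Hide"].members[0]
        res = predict_online(gamma, singleton_models, deterministic=True)
        assert res.predicted == "Hide"
        assert res.deciding_column == 4
        assert res.prediction_moment == pytest.approx(gamma.timestamps[4])

    def test_every_canonical_action_recognizes_itself(self, singleton_models):
        for action, model in singleton_models.items():
            res = predict_online(model.members[0], singleton_models,
                                 deterministic=True)
            assert res.predicted == action, f"{action} -> {res.predicted}"

    def test_model_order_does_not_matter(self, singleton_models):
        gamma = singleton_models["Stir"].members[0]
        shuffled = dict(reversed(list(singleton_models.items())))
        a = predict_online(gamma, singleton_models, deterministic=True)
        b = predict_online(gamma, shuffled, deterministic=True)
        assert (a.predicted, a.deciding_column) == (b.predicted, b.deciding_column)

    def test_survivor_set_is_non_increasing(self, singleton_models):
        gamma = singleton_models["Chop"].members[0]
        res = predict_online(gamma, singleton_models, deterministic=True)
        sets = [set(s) for s in res.survivor_trace]
        assert all(b <= a for a, b in zip(sets, sets[1:]))

    def test_two_models_minimum(self, singleton_models):
        gamma = singleton_models["Hide"].members[0]
        with pytest.raises(ValueError):
            predict_online(gamma, {"Hide": singleton_models["Hide"]})

    def test_obvious_class_recognized_at_first_column(self, fixture_tables):
        # gamma identical to one class, maximally unlike the other (every
        # channel of every pair differs already at the first event column)
        gamma = fixture_tables["Hide"]
        other = fixture_tables["Hide"].prefix(gamma.n_columns - 1)
        other.cells = other.cells.copy()
        other.cells[:, 0, 1:] = "A"
        other.cells[:, 1, 1:] = "Bw"
        other.cells[:, 2, 1:] = "Q"
        models = {
            "match": ClassModel("match", [gamma], 100.0),
            "other": ClassModel("other", [other], 100.0),
        }
        res = predict_online(gamma, models, deterministic=True)
        assert res.predicted == "match"
        assert res.deciding_column == 1

    def test_all_classes_eliminated_reports_unrecognized(self, fixture_tables):
        gamma = fixture_tables["Stir"]
        models = {
            "a": ClassModel("a", [fixture_tables["Push"]], 100.0),
            "b": ClassModel("b", [fixture_tables["Lay"]], 100.0),
        }
        res = predict_online(gamma, models, deterministic=True)
        assert res.predicted == "unrecognized"
        assert res.survivors == []
        assert res.predictive_power is None


class TestLabelRecovery:
    def test_dataset_classification(self, dataset_tables):
        """At least 95 % of the 300 synthetic actions are recognized as
        their generating class; failures are flagged, never another
        class."""
        by_class = {}
        for t in dataset_tables:
            by_class.setdefault(t.action_label, []).append(t)
        rng = np.random.default_rng(1)
        models = train_models(by_class, rng=rng)
        n_correct = 0
        for t in dataset_tables:
            res = predict_online(t, models, rng=rng)
            if res.predicted == t.action_label:
                n_correct += 1
            else:
                assert res.predicted in ("unrecognized", "ambiguous")
        assert n_correct / len(dataset_tables) >= 0.95

    def test_canonical_fixtures_never_cross_classified(
        self, fixture_tables, singleton_models
    ):
        for action, table in fixture_tables.items():
            res = predict_online(table, singleton_models, deterministic=True)
            assert res.predicted == action
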