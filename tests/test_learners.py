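import math

import numpy as np
import pytest

from bioidkit import LearnerSpec, default_spec, evaluate, hyperband, hyperband_tune, train_learner
from bioidkit.learners import DEFAULT_SPACES, _make_sampler


def expected_bracket_sizes(eta: int, stages: int) -> list[int]:
    """Independent oracle: configurations sampled per bracket."""
    s_max = stages - 1
    return [math.ceil((s_max + 1) / (s + 1) * eta**s) for s in range(s_max, -1, -1)]


def quadratic_objective(cfg: dict, fraction: float) -> float:
    return (cfg["x"] - 0.3) ** 2 + 0.1 * (1 - fraction)


def sample_x(rng) -> dict:
    return {"x": float(rng.uniform(0, 1))}


class TestHyperband:
    def test_reference_run_samples_49_configurations(self):
        """eta=3 with four stages samples 27+12+6+4 = 49 configurations."""
        _, _, schedule = hyperband(sample_x, quadratic_objective, eta=3, stages=4, seed=0)
        assert schedule.n_sampled == 49
        sizes = schedule.stage_sizes()
        first = sizes[sizes["stage"] == 0].sort_values("bracket", ascending=False)
        assert first["n_configs"].tolist() == [27, 12, 6, 4]

    @pytest.mark.parametrize("eta, stages", [(2, 3), (3, 4), (4, 2), (3, 1)])
    def test_bracket_arithmetic_matches_formula(self, eta, stages):
        _, _, schedule = hyperband(sample_x, quadratic_objective, eta=eta, stages=stages, seed=1)
        sizes = schedule.stage_sizes()
        first = sizes[sizes["stage"] == 0].sort_values("bracket", ascending=False)
        assert first["n_configs"].tolist() == expected_bracket_sizes(eta, stages)
        assert schedule.n_sampled == sum(expected_bracket_sizes(eta, stages))

    def test_survivors_are_lowest_loss_third(self):
        _, _, schedule = hyperband(sample_x, quadratic_objective, eta=3, stages=4, seed=2)
        rec = schedule.records
        for bracket, grp in rec.groupby("bracket"):
            for stage in range(int(grp["stage"].max())):
                now = grp[grp["stage"] == stage].sort_values("loss", kind="stable")
                nxt = set(grp[grp["stage"] == stage + 1]["config_id"])
                assert len(nxt) == len(now) // 3
                assert nxt == set(now["config_id"].head(len(nxt)))

    def test_resource_grows_eta_fold_within_bracket(self):
        _, _, schedule = hyperband(sample_x, quadratic_objective, eta=3, stages=4, seed=3)
        sizes = schedule.stage_sizes()
        big = sizes[sizes["bracket"] == 3].sort_values("stage")
        assert np.allclose(big["resource"], [1 / 27, 3 / 27, 9 / 27, 1.0])

    def test_best_configuration_minimizes_recorded_loss(self):
        best, loss, schedule = hyperband(sample_x, quadratic_objective, eta=3, stages=4, seed=4)
        assert loss == schedule.records["loss"].min()
        assert quadratic_objective(best, 1.0) >= (best["x"] - 0.3) ** 2

    def test_empty_space_rejected(self):
        with pytest.raises(ValueError):
            _make_sampler({})

    def test_sampler_respects_bounds(self):
        rng = np.random.default_rng(0)
        sampler = _make_sampler(DEFAULT_SPACES["xgb"])
        for _ in range(20):
            cfg = sampler(rng)
            assert 0.05 <= cfg["eta"] <= 0.5
            assert 3 <= cfg["max_depth"] <= 10


@pytest.fixture(scope="module")
def toy_data():
    """Two linearly separable classes in two integer features."""
    rng = np.random.default_rng(1)
    X = np.vstack([rng.integers(0, 5, (60, 2)), rng.integers(10, 15, (60, 2))])
    y = np.array(["low"] * 60 + ["high"] * 60)
    return X, y


class TestTraining:
    def test_rf_fits_separable_data_perfectly(self, toy_data):
        X, y = toy_data
        model = train_learner(default_spec("rf").with_params(n_trees=25), X, y, seed=0)
        assert (model.predict(X) == y).all()

    def test_cart_is_seed_deterministic(self, toy_data):
        X, y = toy_data
        a = train_learner(default_spec("cart"), X, y, seed=5).predict(X)
        b = train_learner(default_spec("cart"), X, y, seed=5).predict(X)
        assert (a == b).all()

    def test_mlp_loss_decreases_over_epochs(self, toy_data):
        X, y = toy_data
        spec = default_spec("mlp").with_params(epochs=15, batch_size=16)
        model = train_learner(spec, X, y, seed=0)
        curve = model.estimator[-1].loss_curve_
        assert curve[-1] < curve[0]

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            train_learner(default_spec("cart"), np.zeros((4, 2)), np.repeat("a", 4))

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError):
            LearnerSpec("svm")

    def test_probability_output_shape(self, toy_data):
        X, y = toy_data
        model = train_learner(default_spec("xgb"), X, y, seed=0)
        proba = model.predict_proba(X[:5])
        assert proba.shape == (5, 2)
        assert np.allclose(proba.sum(axis=1), 1.0)


class TestEvaluate:
    def test_perfect_predictions_give_diagonal_cm_and_unit_f1(self, toy_data):
        X, y = toy_data
        model = train_learner(default_spec("rf").with_params(n_trees=25), X, y, seed=0)
        bundle = evaluate(model, X, y)
        assert (np.diag(bundle.cm) == [60, 60]).all()
        assert bundle.cm.to_numpy().sum() == len(y)
        assert (bundle.f1 == 1.0).all()
        assert bundle.accuracy == 1.0

    def test_misclass_rows_sum_to_one_for_present_classes(self, toy_data):
        X, y = toy_data
        model = train_learner(default_spec("cart"), X, y, seed=0)
        bundle = evaluate(model, X, y)
        assert np.allclose(bundle.misclass.sum(axis=1), 1.0)

    def test_class_absent_from_test_gives_nan_misclass_row(self, toy_data):
        X, y = toy_data
        model = train_learner(default_spec("cart"), X, y, seed=0)
        mask = y == "low"
        bundle = evaluate(model, X[mask], y[mask])
        assert bundle.misclass.loc["high"].isna().all()
        assert np.allclose(bundle.misclass.loc["low"].sum(), 1.0)

    def test_unseen_test_class_rejected(self, toy_data):
        X, y = toy_data
        model = train_learner(default_spec("cart"), X, y, seed=0)
        with pytest.raises(ValueError, match="unseen"):
            evaluate(model, X[:3], np.array(["mystery"] * 3))

    def test_macro_f1_within_unit_interval(self, toy_data):
        X, y = toy_data
        model = train_learner(default_spec("xgb"), X, y, seed=0)
        bundle = evaluate(model, X, y)
        assert 0.0 <= bundle.macro_f1 <= 1.0


class TestHyperbandTune:
    def test_tuned_spec_improves_on_tiny_corpus(self, registry):
        table = registry.generate_dataset({"ChEMBL": 60, "HGNC": 60, "Rfam": 60}, seed=2)
        from bioidkit import encode_table

        enc = encode_table(table)
        spec, schedule = hyperband_tune("cart", enc.X, enc.y, seed=0)
        assert schedule.n_sampled == 49
        assert spec.kind == "cart"
        assert set(DEFAULT_SPACES["cart"]) <= set(spec.params)
        # winning configuration achieves the minimum recorded loss
        assert schedule.records["loss"].min() <= schedule.records["loss"].mean()
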