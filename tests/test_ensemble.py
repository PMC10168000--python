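import numpy as np
import pandas as pd
import pytest

from bioidkit import (
    EnsembleModel,
    RunConfig,
    ScoreContext,
    ensemble_predict,
    predict_batch,
    run_pipeline,
    score_model,
)


def make_context(c=0.5, classes=("A", "B"), models=("rf", "xgb", "mlp", "cart")):
    """Uniform, fully specified context the tests then override."""
    f1 = {m: pd.Series(0.8, index=list(classes)) for m in models}
    mis = {
        m: pd.DataFrame(
            np.full((len(classes), len(classes)), 1.0 / len(classes)),
            index=list(classes),
            columns=list(classes),
        )
        for m in models
    }
    macro = {m: 0.8 for m in models}
    return ScoreContext(c=c, f1=f1, misclass=mis, macro_f1=macro)


class TestScoreModel:
    def test_hand_computed_score(self):
        """F1 = 0.9, c = 0.5, two dissenters with P = 0.2 and 0.0 give
        0.9 * 0.6 * 0.5 = 0.27."""
        ctx = make_context(c=0.5, classes=("x", "y1", "y2"), models=("m1", "m2", "m3"))
        ctx.f1["m1"].loc["x"] = 0.9
        ctx.misclass["m2"].loc["x"] = [0.8, 0.2, 0.0]
        ctx.misclass["m3"].loc["x"] = [1.0, 0.0, 0.0]
        score = score_model("m1", "x", [("m2", "y1"), ("m3", "y2")], ctx)
        assert score == pytest.approx(0.27)

    def test_c_equal_one_collapses_to_f1(self):
        ctx = make_context(c=1.0, classes=("x", "y"), models=("m1", "m2", "m3"))
        ctx.f1["m1"].loc["x"] = 0.77
        score = score_model("m1", "x", [("m2", "y"), ("m3", "y")], ctx)
        assert score == 0.77

    def test_unanimous_agreement_with_perfect_diagonal_returns_f1(self):
        ctx = make_context(c=0.5, classes=("x", "y"), models=("m1", "m2", "m3"))
        for m in ("m2", "m3"):
            ctx.misclass[m].loc["x"] = [1.0, 0.0]
        ctx.f1["m1"].loc["x"] = 0.85
        score = score_model("m1", "x", [("m2", "x"), ("m3", "x")], ctx)
        assert score == pytest.approx(0.85)

    def test_score_is_affine_and_nondecreasing_in_dissenter_probability(self):
        """Slope w.r.t. one P(y|x) equals F1 * (1-c) * (other factors)."""
        values = []
        for p in [0.0, 0.25, 0.5, 1.0]:
            ctx = make_context(c=0.3, classes=("x", "y"), models=("m1", "m2", "m3"))
            ctx.f1["m1"].loc["x"] = 0.9
            ctx.misclass["m2"].loc["x"] = [1 - p, p]
            ctx.misclass["m3"].loc["x"] = [1.0, 0.0]
            values.append(score_model("m1", "x", [("m2", "y"), ("m3", "x")], ctx))
        diffs = np.diff(values) / np.diff([0.0, 0.25, 0.5, 1.0])
        assert np.allclose(diffs, diffs[0])  # affine
        assert diffs[0] == pytest.approx(0.9 * 0.7 * (0.3 + 0.7 * 1.0))

    def test_missing_class_signals_coverage_gap(self):
        ctx = make_context()
        with pytest.raises(KeyError):
            score_model("rf", "unknown-class", [], ctx)

    def test_scores_stay_in_unit_interval(self):
        ctx = make_context(c=0.2)
        score = score_model("rf", "A", [("xgb", "B"), ("mlp", "B"), ("cart", "A")], ctx)
        assert 0.0 <= score <= 1.0


class TestEnsemblePredict:
    def test_three_to_one_majority(self):
        ctx = make_context()
        votes = {"rf": "A", "xgb": "A", "mlp": "A", "cart": "B"}
        pred = ensemble_predict(votes, ctx)
        assert pred.label == "A" and pred.path == "majority" and pred.scores is None

    def test_unanimous_votes_win_directly(self):
        ctx = make_context()
        pred = ensemble_predict({m: "B" for m in ("rf", "xgb", "mlp", "cart")}, ctx)
        assert pred.label == "B" and pred.path == "majority"

    def test_two_two_split_goes_to_scoring(self):
        ctx = make_context()
        ctx.f1["rf"].loc["A"] = 0.95  # rf's vote should win
        votes = {"rf": "A", "xgb": "A", "mlp": "B", "cart": "B"}
        pred = ensemble_predict(votes, ctx)
        assert pred.path == "scored"
        assert pred.label == "A"
        assert pred.label in votes.values()
        assert all(0 <= s <= 1 for s in pred.scores.values())

    def test_exact_ties_break_by_fixed_model_order(self):
        ctx = make_context()  # all F1 and misclass identical -> all scores equal
        votes = {"rf": "A", "xgb": "B", "mlp": "A", "cart": "B"}
        pred = ensemble_predict(votes, ctx)
        assert pred.path == "scored"
        assert pred.label == "A"  # rf is first in the fixed order

    def test_vote_set_mismatch_rejected(self):
        ctx = make_context()
        with pytest.raises(ValueError):
            ensemble_predict({"rf": "A"}, ctx)

    def test_c_outside_unit_interval_rejected(self):
        with pytest.raises(ValueError):
            make_context(c=1.2)


@pytest.fixture(scope="module")
def trained_run(tmp_path_factory):
    """Small end-to-end run shared by the prediction tests."""
    out = tmp_path_factory.mktemp("run")
    config = RunConfig(
        profile={name: 80 for name in ["ChEMBL", "Ensembl gene", "HGNC", "Pfam", "Rfam"]},
        out_dir=str(out),
        learner_overrides={"mlp": {"epochs": 12}},
        feature_trees=20,
        seed=21,
    )
    run_dir = run_pipeline(config)
    return EnsembleModel.load(run_dir / "models" / "ensemble.joblib")


class TestPredictBatch:
    def test_empty_input_gives_empty_output(self, trained_run):
        out = predict_batch(pd.DataFrame({"id": []}), trained_run)
        assert len(out) == 0
        assert "class" in out.columns and "path" in out.columns

    def test_row_order_preserved(self, trained_run, registry):
        ids = registry.generate_ids("HGNC", 10, seed=3) + registry.generate_ids("Pfam", 10, seed=3)
        out = predict_batch(pd.DataFrame({"id": ids}), trained_run)
        assert out["id"].tolist() == ids

    def test_single_class_input_mostly_recovered(self, trained_run, registry):
        ids = registry.generate_ids("ChEMBL", 200, seed=99)
        out = predict_batch(pd.DataFrame({"id": ids}), trained_run)
        assert (out["class"] == "ChEMBL").mean() >= 0.99

    def test_final_label_is_always_someones_vote(self, trained_run, registry):
        ids = registry.generate_ids("Rfam", 50, seed=1)
        out = predict_batch(pd.DataFrame({"id": ids}), trained_run)
        vote_cols = [c for c in out.columns if c.startswith("vote_")]
        for _, row in out.iterrows():
            assert row["class"] in {row[c] for c in vote_cols}

    def test_oversized_and_unknown_characters_still_predicted(self, trained_run):
        weird = pd.DataFrame({"id": ["CHEMBL25#%", "X" * 40]})
        with pytest.warns(UserWarning):
            out = predict_batch(weird, trained_run)
        assert len(out) == 2
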