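import numpy as np
import pandas as pd
import pytest

from petrad.models import (
    ModelSpec,
    default_grid,
    predict_risk,
    predict_risk_batch,
    train_model,
)
from petrad.models import _ELM, _Forest


@pytest.fixture()
def separable_toy(rng):
    """20 points in 2D, linearly separable by construction."""
    X = np.vstack(
        [rng.normal([0, 0], 0.3, (10, 2)), rng.normal([4, 4], 0.3, (10, 2))]
    )
    y = np.array([0] * 10 + [1] * 10)
    return pd.DataFrame(X, columns=["u", "v"]), y


class TestGrids:
    def test_published_grid_sizes(self):
        assert len(default_grid("rf")) == 40  # 4 p-values x 10 q-values
        assert len(default_grid("svm")) == 110  # 11 C x 10 sigma
        assert len(default_grid("elm")) == 12  # 6 hidden x 2 activations
        assert len(default_grid("lr")) == 1

    def test_unknown_family_rejected(self):
        with pytest.raises(ValueError, match="family"):
            ModelSpec(family="xgboost")

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError, match="grid"):
            ModelSpec(family="rf", grid=())


class TestForest:
    def test_single_class_training_unanimous_votes(self, rng):
        X = pd.DataFrame(rng.random((8, 3)), columns=list("abc"))
        y = np.ones(8, dtype=int)
        model = train_model(ModelSpec("rf", seed=0), X, y)
        preds = predict_risk_batch(model, X)
        assert all(p.risk_score in (0.0, 1.0) for p in preds)

    def test_risk_score_is_vote_fraction(self, separable_toy):
        X, y = separable_toy
        model = train_model(
            ModelSpec("rf", grid=({"p": 10, "q": 2},), seed=1), X, y
        )
        votes = model._state._tree_votes(X.to_numpy())
        np.testing.assert_allclose(
            [p.risk_score for p in predict_risk_batch(model, X)],
            votes.mean(axis=0),
        )

    def test_group_rule_strictly_above_half(self):
        from petrad.models import TrainedModel

        # 73 of 100 trees voting failure -> 0.73, high risk
        class Stub:
            def vote_fraction(self, X):
                return np.array([0.73, 0.5])

        model = TrainedModel("rf", {}, ["a"], 0, Stub(), None)
        preds = predict_risk_batch(model, np.zeros((2, 1)))
        assert preds[0].risk_score == 0.73 and preds[0].group == "high"
        assert preds[1].group == "low"  # exactly 0.5 is low risk

    def test_reproducible_given_seed(self, separable_toy):
        X, y = separable_toy
        a = train_model(ModelSpec("rf", seed=3), X, y)
        b = train_model(ModelSpec("rf", seed=3), X, y)
        assert a.params == b.params
        sa = [p.risk_score for p in predict_risk_batch(a, X)]
        sb = [p.risk_score for p in predict_risk_batch(b, X)]
        assert sa == sb


class TestSVMAndLR:
    @pytest.mark.parametrize("family", ["svm", "lr"])
    def test_separable_training_accuracy_one(self, separable_toy, family):
        X, y = separable_toy
        model = train_model(ModelSpec(family, seed=0), X, y)
        preds = predict_risk_batch(model, X)
        assert [1 if p.group == "high" else 0 for p in preds] == list(y)

    def test_lr_score_half_is_low_risk(self):
        from petrad.models import TrainedModel

        class Stub:
            def predict_proba(self, X):
                return np.array([[0.5, 0.5], [0.4, 0.6]])

        model = TrainedModel("lr", {}, ["a"], 0, Stub(), None)
        preds = predict_risk_batch(model, np.zeros((2, 1)))
        assert preds[0].group == "low"  # rule is strictly > 0.5
        assert preds[1].group == "high"

    def test_svm_zero_distance_is_high_risk(self):
        from petrad.models import TrainedModel

        class Stub:
            def decision_function(self, X):
                return np.array([0.0, -1.0, 1.0])

        model = TrainedModel("svm", {}, ["a"], 0, Stub(), None)
        preds = predict_risk_batch(model, np.zeros((3, 1)))
        assert preds[0].group == "high"  # distance <= 0 -> progression
        assert preds[1].group == "low"
        assert preds[2].group == "high"

    @pytest.mark.parametrize("family", ["svm", "lr", "elm"])
    def test_single_class_rejected(self, family, rng):
        X = pd.DataFrame(rng.random((6, 2)), columns=["a", "b"])
        with pytest.raises(ValueError, match="class"):
            train_model(ModelSpec(family, seed=0), X, np.zeros(6, dtype=int))


class TestELM:
    def test_output_weights_solve_least_squares(self, rng):
        X = rng.normal(size=(12, 4))
        y = np.array([0, 1] * 6)
        elm = _ELM(hidden=6, activation="sigmoid", seed=0).fit(X, y)
        H = elm._hidden_layer(X, 4)
        T = np.column_stack([1 - y, y]).astype(float)
        beta, *_ = np.linalg.lstsq(H, T, rcond=None)
        np.testing.assert_allclose(elm.beta_, beta, atol=1e-10)

    def test_training_error_monotone_in_hidden_nodes(self, rng):
        """With nested hidden layers per seed, adding nodes cannot increase
        the least-squares training error."""
        X = rng.normal(size=(20, 5))
        y = (rng.random(20) < 0.5).astype(int)
        y[:2] = [0, 1]
        T = np.column_stack([1 - y, y]).astype(float)
        for seed in range(10):
            errors = []
            for hidden in (5, 10, 15, 20, 25, 30):
                elm = _ELM(hidden=hidden, activation="sigmoid", seed=seed).fit(X, y)
                resid = elm.outputs(X) - T
                errors.append(float((resid**2).sum()))
            assert all(b <= a + 1e-8 for a, b in zip(errors, errors[1:]))

    def test_group_rule_second_node_wins_ties(self, separable_toy):
        X, y = separable_toy
        model = train_model(ModelSpec("elm", seed=0), X, y)
        for pred in predict_risk_batch(model, X):
            assert pred.group == ("high" if pred.risk_score >= 0 else "low")


class TestPredictRisk:
    def test_single_row(self, separable_toy):
        X, y = separable_toy
        model = train_model(ModelSpec("lr", seed=0), X, y)
        pred = predict_risk(model, X.iloc[0])
        assert pred.group == "low"

    def test_feature_name_mismatch_rejected(self, separable_toy):
        X, y = separable_toy
        model = train_model(ModelSpec("lr", seed=0), X, y)
        wrong = X.rename(columns={"u": "w"})
        with pytest.raises(ValueError, match="feature names"):
            predict_risk_batch(model, wrong)

    def test_wrong_width_rejected(self, separable_toy):
        X, y = separable_toy
        model = train_model(ModelSpec("lr", seed=0), X, y)
        with pytest.raises(ValueError, match="features"):
            predict_risk_batch(model, np.zeros((2, 5)))
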