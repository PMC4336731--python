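"""Ridge-logistic base learner: fit contracts, oracle equivalence, prediction
arithmetic, and ROC AUC."""

import numpy as np
import pandas as pd
import pytest
from sklearn.linear_model import LogisticRegression

import stentstrat as ss
from stentstrat.cohort import DesignSpec, EligibleSample
from stentstrat.logistic import _fit_matrix, _sigmoid, penalized_loglik

from conftest import make_flat_cohort


def _sample_from(frame, features, endpoint="angio_restenosis_6m", catalog=None):
    catalog = catalog or ss.FeatureCatalog.default()
    y = (frame[endpoint] == "event").to_numpy().astype(int)
    return EligibleSample(
        features=frame[list(features)],
        y=y,
        subgroup=ss.SubgroupSpec(),
        feature_pair=("C1", "B1"),
        treatment_arm="BMS",
        endpoint=endpoint,
        index=np.arange(len(frame)),
    )


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------


def test_antisymmetric_data_gives_zero_intercept(catalog):
    # {(-1, 0), (+1, 1)} repeated: by symmetry the intercept is 0 and the
    # predicted probability at x=0 is 1/2
    X = np.array([[-1.0], [1.0]] * 100)
    y = np.array([0.0, 1.0] * 100)
    b0, b = _fit_matrix(X, y, penalty=0.01)
    assert b0 == pytest.approx(0, abs=1e-6)
    assert _sigmoid(np.array([b0])) == pytest.approx(0.5, abs=1e-6)


def test_huge_penalty_shrinks_to_base_rate(catalog):
    rng = np.random.default_rng(0)
    X = rng.standard_normal((200, 3))
    y = (rng.random(200) < 0.5).astype(float)
    b0, b = _fit_matrix(X, y, penalty=1e6)
    assert np.abs(b).max() < 1e-3
    assert _sigmoid(np.array([b0]))[0] == pytest.approx(y.mean(), abs=1e-3)


def test_fit_matches_dense_grid_oracle():
    # 1-D sample: exhaustively scan the 2-parameter penalized likelihood on a
    # coarse-then-refined dense grid and compare with the optimizer's solution
    rng = np.random.default_rng(5)
    x = rng.standard_normal(120)
    y = (rng.random(120) < _sigmoid(0.5 + 1.2 * x)).astype(float)
    X = x[:, None]
    b0, b = _fit_matrix(X, y, penalty=0.01)

    def grid_max(a_grid, c_grid):
        return max(
            (penalized_loglik(np.array([a, c]), X, y, 0.01), a, c)
            for a in a_grid
            for c in c_grid
        )

    _, a1, c1 = grid_max(np.linspace(-3, 3, 121), np.linspace(-3, 3, 121))
    best = grid_max(np.linspace(a1 - 0.1, a1 + 0.1, 201), np.linspace(c1 - 0.1, c1 + 0.1, 201))
    assert b0 == pytest.approx(best[1], abs=1e-3)
    assert b[0] == pytest.approx(best[2], abs=1e-3)
    # the optimizer's objective must dominate every grid cell
    assert penalized_loglik(np.array([b0, b[0]]), X, y, 0.01) >= best[0] - 1e-9


def test_fit_matches_sklearn_ridge_convention():
    # independent route: sklearn minimizes 0.5*||b||^2 + C*logloss, so our
    # penalty lambda corresponds to C = 1/(2*lambda)
    rng = np.random.default_rng(7)
    X = rng.standard_normal((300, 4))
    z = X @ np.array([1.0, -0.5, 0.0, 0.8]) - 0.3
    y = (rng.random(300) < _sigmoid(z)).astype(float)
    b0, b = _fit_matrix(X, y, penalty=0.01)
    ref = LogisticRegression(C=1 / (2 * 0.01), solver="lbfgs", max_iter=2000, tol=1e-10)
    ref.fit(X, y)
    np.testing.assert_allclose(b, ref.coef_[0], atol=2e-4)
    assert b0 == pytest.approx(ref.intercept_[0], abs=2e-4)


def test_gradient_norm_small_at_solution():
    frame = make_flat_cohort(300, 60, seed=2)
    sample = _sample_from(frame, ["bmi", "crp", "hypertension"])
    model = ss.fit_l2_logistic(sample)
    from stentstrat.logistic import _neg_obj_and_grad

    X = model.design.transform(sample.features)
    params = np.concatenate([[model.intercept], model.coefficients])
    _, grad = _neg_obj_and_grad(params, X, sample.y.astype(float), 0.01)
    assert np.max(np.abs(grad)) <= 1e-6


def test_local_optimality_under_random_perturbations():
    frame = make_flat_cohort(200, 50, seed=4)
    sample = _sample_from(frame, ["bmi", "crp"])
    model = ss.fit_l2_logistic(sample)
    X = model.design.transform(sample.features)
    y = sample.y.astype(float)
    params = np.concatenate([[model.intercept], model.coefficients])
    at_solution = penalized_loglik(params, X, y, 0.01)
    rng = np.random.default_rng(0)
    for _ in range(25):
        direction = rng.standard_normal(params.shape)
        perturbed = params + 1e-3 * direction / np.linalg.norm(direction)
        assert penalized_loglik(perturbed, X, y, 0.01) <= at_solution + 1e-12


def test_separable_data_keeps_coefficients_finite():
    X = np.concatenate([np.full(50, -1.0), np.full(50, 1.0)])[:, None]
    y = np.concatenate([np.zeros(50), np.ones(50)])
    b0, b = _fit_matrix(X, y, penalty=0.01)
    assert np.isfinite(b).all() and np.isfinite(b0)
    assert abs(b[0]) < 50


def test_single_class_sample_errors():
    frame = make_flat_cohort(150, 0)
    sample = _sample_from(frame, ["bmi"])
    with pytest.raises(ValueError):
        ss.fit_l2_logistic(sample)


# ---------------------------------------------------------------------------
# Prediction
# ---------------------------------------------------------------------------


def test_predict_prob_hand_computed(catalog):
    frame = make_flat_cohort(200, 40, seed=9)
    sample = _sample_from(frame, ["bmi", "crp"])
    model = ss.fit_l2_logistic(sample)
    record = ss.frame_to_cohort(frame.iloc[:1], catalog)[0]
    # by hand: sigmoid(b0 + b . z) with z the train-standardized features
    mu, sd = model.design.cont_params["mean"], model.design.cont_params["sd"]
    z = (np.array([frame["bmi"][0], frame["crp"][0]]) - mu) / sd
    expected = 1 / (1 + np.exp(-(model.intercept + model.coefficients @ z)))
    assert ss.predict_prob(model, record, catalog) == pytest.approx(expected, abs=1e-12)


def test_predict_missing_feature_names_it(catalog):
    frame = make_flat_cohort(200, 40)
    sample = _sample_from(frame, ["bmi", "crp"])
    model = ss.fit_l2_logistic(sample)
    record = ss.frame_to_cohort(frame.iloc[:1], catalog)[0]
    record.biomarkers["crp"] = None
    with pytest.raises(ss.MissingFeatureError, match="crp"):
        ss.predict_prob(model, record, catalog)


def test_probability_monotone_in_intercept(catalog):
    frame = make_flat_cohort(150, 30)
    sample = _sample_from(frame, ["bmi"])
    model = ss.fit_l2_logistic(sample)
    record = ss.frame_to_cohort(frame.iloc[:1], catalog)[0]
    probs = []
    for shift in [0.0, 1.0, 5.0, 20.0]:
        model.intercept += shift
        probs.append(ss.predict_prob(model, record, catalog))
    assert all(a < b for a, b in zip(probs, probs[1:]))
    assert probs[-1] > 0.999


# ---------------------------------------------------------------------------
# AUC
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "scores,labels,expected",
    [
        ((0.1, 0.2, 0.8, 0.9), (0, 0, 1, 1), 1.0),  # perfect separation
        ((0.5, 0.5, 0.5, 0.5), (0, 1, 0, 1), 0.5),  # all ties -> 1/2
        ((0.1, 0.4, 0.35, 0.8), (0, 0, 1, 1), 0.75),  # 3 of 4 pairs concordant
    ],
)
def test_roc_auc_examples(scores, labels, expected):
    assert ss.roc_auc(ss.ScoreSet(np.array(scores), np.array(labels))) == pytest.approx(expected)


def test_roc_auc_single_class_errors():
    with pytest.raises(ValueError):
        ss.roc_auc(np.array([0.2, 0.3]), np.array([1, 1]))


def test_roc_auc_invariant_under_monotone_transform():
    rng = np.random.default_rng(1)
    scores = rng.random(200)
    labels = (rng.random(200) < scores).astype(int)
    base = ss.roc_auc(scores, labels)
    for f in (lambda s: 2 * s + 3, np.exp, lambda s: s**3):
        assert ss.roc_auc(f(scores), labels) == pytest.approx(base, abs=1e-12)


def test_model_round_trip_through_json(tmp_path, catalog):
    frame = make_flat_cohort(150, 30)
    sample = _sample_from(frame, ["bmi", "crp", "aha_lesion_class"])
    model = ss.fit_l2_logistic(sample)
    path = tmp_path / "model.json"
    model.save(path)
    back = ss.LogisticModel.load(path)
    np.testing.assert_allclose(back.coefficients, model.coefficients)
    np.testing.assert_allclose(
        back.predict_frame(frame.iloc[:20]), model.predict_frame(frame.iloc[:20])
    )
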