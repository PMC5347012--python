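"""Algebraic checks of the OPLS fit, projection, cross-validation and ranking.

The independent oracle is a literal, loop-by-loop transcription of the
orthogonal-deflation recipe (``naive_opls`` below), kept free of any
code shared with the implementation under test.
"""

import numpy as np
import pytest

from dsindex.io import FeatureMatrix
from dsindex.opls import (DegenerateLabelError, cross_validate, fit_opls,
                          project, select_orthogonal_components,
                          variable_importance, OplsModel)
from dsindex.schema import ROISchema


def naive_opls(X, y, n_orth):
    """Step-by-step transcription of the deflation recipe (test oracle)."""
    X = np.array(X, float)
    yc = y - y.mean()
    Wo, Po = [], []
    for _ in range(n_orth):
        w = X.T @ yc
        w = w / np.linalg.norm(w)
        t = X @ w
        p = X.T @ t / (t @ t)
        wo = p - (w @ p) * w
        wo = wo / np.linalg.norm(wo)
        to = X @ wo
        po = X.T @ to / (to @ to)
        X = X - np.outer(to, po)
        Wo.append(wo)
        Po.append(po)
    w = X.T @ yc
    w = w / np.linalg.norm(w)
    t = X @ w
    p = X.T @ t / (t @ t)
    c = yc @ t / (t @ t)
    return w, p, c, Wo, Po, X


def _standardized(rng, n, p):
    X = rng.standard_normal((n, p))
    X = (X - X.mean(0)) / X.std(0, ddof=1)
    return X


@pytest.mark.parametrize("n,p,n_orth", [(6, 3, 1), (12, 5, 2), (20, 8, 0)])
def test_fit_matches_naive_deflation_recipe(n, p, n_orth):
    rng = np.random.default_rng(42)
    X = _standardized(rng, n, p)
    y = (np.arange(n) % 2).astype(float)
    model = fit_opls(X, y, n_orth=n_orth)
    w, pl, c, Wo, Po, Xd = naive_opls(X, y, n_orth)
    assert np.allclose(model.w, w, atol=1e-10)
    assert np.allclose(model.p, pl, atol=1e-10)
    assert model.c == pytest.approx(c, abs=1e-10)
    for got_w, got_p, exp_w, exp_p in zip(model.W_orth, model.P_orth, Wo, Po):
        assert np.allclose(got_w, exp_w, atol=1e-10)
        assert np.allclose(got_p, exp_p, atol=1e-10)
    # prediction agrees with the oracle's deflated single component
    yhat = c * (Xd @ w) + y.mean()
    assert np.allclose(model.predict(X), yhat, atol=1e-10)


def test_n_orth_zero_reduces_to_closed_form_pls1():
    rng = np.random.default_rng(7)
    for _ in range(5):
        X = _standardized(rng, 15, 6)
        y = rng.integers(0, 2, 15).astype(float)
        if len(np.unique(y)) < 2:
            continue
        model = fit_opls(X, y, n_orth=0)
        yc = y - y.mean()
        w = X.T @ yc
        w /= np.linalg.norm(w)
        assert np.allclose(model.w, w, atol=1e-12)


def test_perfect_predictor_column_gets_all_weight():
    y = np.array([0, 0, 0, 1, 1, 1], float)
    rngx = np.random.default_rng(3)
    X = np.column_stack([y - y.mean(), np.zeros(6), np.zeros(6)])
    model = fit_opls(X, y, n_orth=0)
    assert abs(model.w[0]) == pytest.approx(1.0, abs=1e-12)
    assert np.allclose(model.w[1:], 0, atol=1e-12)
    assert np.allclose(model.predict(X), y, atol=1e-10)


def test_zero_covariance_column_gets_zero_weight():
    rng = np.random.default_rng(11)
    y = np.array([0, 0, 0, 0, 1, 1, 1, 1], float)
    signal = np.kron(y - y.mean(), np.ones(1))
    dead = np.array([1, -1, 1, -1, 1, -1, 1, -1], float)  # orthogonal to yc
    X = np.column_stack([signal, dead])
    model = fit_opls(X, y, n_orth=0)
    assert model.w[1] == pytest.approx(0.0, abs=1e-12)


def test_orthogonal_scores_uncorrelated_with_y():
    rng = np.random.default_rng(5)
    X = _standardized(rng, 30, 12)
    y = np.r_[np.zeros(15), np.ones(15)]
    model = fit_opls(X, y, n_orth=3)
    yc = y - y.mean()
    Xd = X.copy()
    for wo, po in zip(model.W_orth, model.P_orth):
        to = Xd @ wo
        assert abs(np.cov(to, yc, ddof=1)[0, 1]) < 1e-8
        assert abs(to @ yc) < 1e-8
        Xd -= np.outer(to, po)
    # predictive score orthogonal to every orthogonal score
    t = Xd @ model.w
    Xc = X.copy()
    for wo, po in zip(model.W_orth, model.P_orth):
        to = Xc @ wo
        assert abs(t @ to) < 1e-6
        Xc -= np.outer(to, po)


def test_index_invariant_to_orthogonal_loading_perturbations():
    rng = np.random.default_rng(9)
    X = _standardized(rng, 24, 10)
    y = np.r_[np.zeros(12), np.ones(12)]
    model = fit_opls(X, y, n_orth=2)
    x = rng.standard_normal(10)
    base = model.predict(x[None, :])[0]
    for alpha in (-3.0, 0.7, 12.0):
        combo = alpha * model.P_orth[0] - 2 * alpha * model.P_orth[1]
        shifted = model.predict((x + combo)[None, :])[0]
        assert shifted == pytest.approx(base, abs=1e-8)


def test_projection_reproduces_training_fit_and_centering_identity():
    rng = np.random.default_rng(13)
    X = _standardized(rng, 20, 7)
    y = np.r_[np.zeros(8), np.ones(12)]
    model = fit_opls(X, y, n_orth=1)
    assert np.allclose(project(model, X), model.predict(X), atol=1e-12)
    # all-mean (standardized zero) profile maps to the training class proportion
    assert project(model, np.zeros((1, 7)))[0] == pytest.approx(y.mean(), abs=1e-12)


def test_single_class_labels_rejected():
    X = np.random.default_rng(0).standard_normal((8, 3))
    with pytest.raises(DegenerateLabelError):
        fit_opls(X, np.ones(8), n_orth=0)


def _plain_matrix(X):
    return FeatureMatrix(X, [f"s{i}" for i in range(X.shape[0])],
                         [f"f{j}" for j in range(X.shape[1])])


def _plain_schema(p):
    return ROISchema.from_rows([(f"f{j}", "thickness", "none") for j in range(p)])


def test_cv_press_matches_explicit_loop_oracle():
    """PRESS from cross_validate equals a from-scratch per-fold loop."""
    rng = np.random.default_rng(21)
    n, p = 28, 6
    X = rng.standard_normal((n, p)) + 0.8 * np.r_[np.zeros(14), np.ones(14)][:, None]
    y = np.r_[np.zeros(14), np.ones(14)]
    feats = _plain_matrix(X)
    schema = _plain_schema(p)
    res = cross_validate(feats, y, schema, k=4, n_orth=1, seed=5, icv_mode="none")
    press = 0.0
    for f in np.unique(res.fold_assignment):
        tr = res.fold_assignment != f
        mu, sd = X[tr].mean(0), X[tr].std(0, ddof=1)
        Ztr, Zte = (X[tr] - mu) / sd, (X[~tr] - mu) / sd
        w, pl, c, Wo, Po, _ = naive_opls(Ztr, y[tr], 1)
        Z = Zte.copy()
        for wo, po in zip(Wo, Po):
            Z = Z - np.outer(Z @ wo, po)
        yhat = c * (Z @ w) + y[tr].mean()
        press += float(np.sum((y[~tr] - yhat) ** 2))
        assert np.allclose(res.y_pred_cv[~tr], yhat, atol=1e-10)
    assert res.press == pytest.approx(press, abs=1e-10)
    assert res.q2 == pytest.approx(1 - press / np.sum((y - y.mean()) ** 2), abs=1e-12)


def test_cv_fold_structure_and_stratification():
    rng = np.random.default_rng(2)
    X = rng.standard_normal((26, 5))
    y = np.r_[np.zeros(14), np.ones(12)]
    res = cross_validate(_plain_matrix(X), y, _plain_schema(5), k=4, seed=0,
                         icv_mode="none")
    sizes = np.bincount(res.fold_assignment)
    assert sizes.max() - sizes.min() <= 1
    assert np.all(np.isfinite(res.y_pred_cv))  # each subject predicted once
    with pytest.raises(ValueError):
        cross_validate(_plain_matrix(X[:6]), np.r_[np.zeros(3), np.ones(3)],
                       _plain_schema(5), k=4, icv_mode="none")


def test_pure_noise_q2_stays_at_chance_level():
    """Null behaviour: noise-only predictors give Q2 near or below zero."""
    ok = 0
    for seed in range(10):
        rng = np.random.default_rng(100 + seed)
        X = rng.standard_normal((60, 187))
        y = np.r_[np.zeros(30), np.ones(30)]
        res = cross_validate(_plain_matrix(X), y, _plain_schema(187), k=7,
                             n_orth=0, seed=seed, icv_mode="none")
        assert res.q2 <= 1.0
        if res.q2 <= 0.05:
            ok += 1
    assert ok >= 9


def test_label_permutation_q2_non_positive_on_average():
    rng = np.random.default_rng(31)
    X = rng.standard_normal((40, 30))
    y = np.r_[np.zeros(20), np.ones(20)]
    q2s = []
    for i in range(20):
        yp = rng.permutation(y)
        res = cross_validate(_plain_matrix(X), yp, _plain_schema(30), k=5,
                             n_orth=0, seed=i, icv_mode="none")
        q2s.append(res.q2)
    assert np.mean(q2s) <= 0.0


def test_component_selection_finds_planted_confounder():
    """A strong class-independent factor should earn >= 1 orthogonal component."""
    rng = np.random.default_rng(17)
    n, p = 60, 40
    y = np.r_[np.zeros(30), np.ones(30)]
    a = rng.standard_normal(p)
    b = rng.standard_normal(p)
    b -= (a @ b) / (a @ a) * a          # confounder direction orthogonal to signal
    g = rng.standard_normal(n)           # confounder scores, independent of y
    X = (np.outer(y - y.mean(), a) + 6 * np.outer(g, b)
         + 0.5 * rng.standard_normal((n, p)))
    feats, schema = _plain_matrix(X), _plain_schema(p)
    n_sel = select_orthogonal_components(feats, y, schema, k=5, seed=3,
                                         max_orth=3, icv_mode="none")
    assert n_sel >= 1
    q0 = cross_validate(feats, y, schema, k=5, n_orth=0, seed=3,
                        icv_mode="none").q2
    q1 = cross_validate(feats, y, schema, k=5, n_orth=1, seed=3,
                        icv_mode="none").q2
    assert q1 > q0


def test_component_selection_bounds():
    rng = np.random.default_rng(23)
    X = rng.standard_normal((40, 20))
    y = np.r_[np.zeros(20), np.ones(20)]
    feats, schema = _plain_matrix(X), _plain_schema(20)
    assert select_orthogonal_components(feats, y, schema, k=5, seed=1,
                                        max_orth=0, icv_mode="none") == 0
    # pure noise: no gain beyond the threshold in expectation
    picks = [select_orthogonal_components(feats, y, schema, k=5, seed=s,
                                          max_orth=3, icv_mode="none")
             for s in range(3)]
    assert max(picks) == 0


def test_variable_importance_orientation_and_ranking():
    rng = np.random.default_rng(41)
    n = 60
    y = np.r_[np.zeros(30), np.ones(30)]
    atrophied = -1.5 * (y - y.mean()) + 0.3 * rng.standard_normal(n)  # low in disease
    enlarged = 1.5 * (y - y.mean()) + 0.3 * rng.standard_normal(n)    # high in disease
    dead = rng.standard_normal(n)
    X = np.column_stack([atrophied, enlarged, dead])
    X = (X - X.mean(0)) / X.std(0, ddof=1)
    model = fit_opls(X, y, n_orth=0)
    ranked = variable_importance(model, X, top_k=3)
    by_name = {name: cov for name, cov, _ in ranked}
    assert by_name[0] > 0          # larger in controls → positive
    assert by_name[1] < 0          # ventricle-like, larger in disease → negative
    assert ranked[-1][0] == 2      # unrelated feature ranks last
    assert abs(ranked[-1][1]) < abs(ranked[0][1])


def test_model_json_round_trip(tmp_path):
    rng = np.random.default_rng(19)
    X = _standardized(rng, 18, 5)
    y = np.r_[np.zeros(9), np.ones(9)]
    model = fit_opls(X, y, n_orth=1)
    model.y_coding = {"HC": 0, "AD": 1}
    model.schema_fingerprint = "abc"
    model.train_ids = ["a", "b"]
    path = tmp_path / "m.json"
    model.save(path)
    back = OplsModel.load(path)
    assert np.array_equal(back.w, model.w)
    assert np.array_equal(back.P_orth, model.P_orth)
    assert back.c == model.c and back.y_mean == model.y_mean
    assert back.y_coding == model.y_coding
    assert np.allclose(back.predict(X), model.predict(X), atol=0)
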