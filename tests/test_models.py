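"""The four integration models and their cross-validation."""

import numpy as np
import pandas as pd
import pytest

from ispip import (
    CVPlan,
    GradientBoostedInterfaceScorer,
    LinearInterfaceScorer,
    LogisticInterfaceScorer,
    RandomForestInterfaceScorer,
    ScoreTable,
    cross_validate,
    fit_boosted,
    fit_forest,
    fit_linear,
    fit_logistic,
    predict,
)
from ispip.models import assign_folds, cv_candidate_regression
from ispip.simulate import generate_interaction_dataset

from conftest import make_table


def _table_from_arrays(X, y):
    n, k = X.shape
    df = pd.DataFrame(X, columns=[f"x{j + 1}" for j in range(k)])
    df.insert(0, "icode", "")
    df.insert(0, "resnum", np.arange(1, n + 1))
    df.insert(0, "chain", "A")
    df.insert(0, "protein_id", "P1")
    df["label"] = y
    return ScoreTable(df)


# -- linear ----------------------------------------------------------------

def test_linear_perfect_fit():
    # predictor equals the label exactly -> identity fit
    y = (np.arange(50) % 3 == 0).astype(int)
    model = fit_linear(_table_from_arrays(y[:, None].astype(float), y))
    assert model.intercept_ == pytest.approx(0.0, abs=1e-10)
    assert model.coef_[0] == pytest.approx(1.0, abs=1e-10)


def test_linear_single_class_warns_intercept_only():
    X = np.random.default_rng(0).random((20, 2))
    with pytest.warns(UserWarning, match="intercept-only"):
        model = fit_linear(_table_from_arrays(X, np.zeros(20, int)))
    assert model.intercept_ == 0.0
    assert np.all(model.coef_ == 0.0)
    assert np.all(model.predict(X) == 0.0)


def test_linear_matches_normal_equations():
    rng = np.random.default_rng(7)
    X = rng.random((500, 3))
    y = (rng.random(500) < 0.4 + 0.3 * X[:, 0]).astype(int)
    model = fit_linear(_table_from_arrays(X, y))
    design = np.c_[np.ones(len(X)), X]
    beta = np.linalg.solve(design.T @ design, design.T @ y)
    assert model.intercept_ == pytest.approx(beta[0], abs=1e-8)
    np.testing.assert_allclose(model.coef_, beta[1:], atol=1e-8)


def test_linear_prediction_clipped():
    model = LinearInterfaceScorer()
    model.fit(np.array([[0.0], [1.0]]), np.array([0, 1]))
    out = model.predict(np.array([[-5.0], [5.0]]))
    assert out.min() >= 0.0 and out.max() <= 1.0


# -- logistic --------------------------------------------------------------

def test_logistic_no_signal_limit():
    rng = np.random.default_rng(11)
    n = 20_000
    X = rng.random((n, 2))
    y = (rng.random(n) < 0.3).astype(int)  # independent of X
    model = fit_logistic(_table_from_arrays(X, y))
    np.testing.assert_allclose(model.coef_, 0.0, atol=0.15)
    assert model.intercept_ == pytest.approx(np.log(0.3 / 0.7), abs=0.15)


def test_logistic_separation_handled():
    X = np.linspace(0, 1, 40)[:, None]
    y = (X[:, 0] > 0.5).astype(int)
    model = fit_logistic(_table_from_arrays(X, y))
    assert model.separation_
    assert np.isfinite(model.coef_).all()
    p = model.predict(X)
    assert np.all(np.diff(p) >= 0)  # monotone in the separating feature


def test_logistic_single_class_rejected():
    with pytest.raises(ValueError, match="both classes"):
        fit_logistic(_table_from_arrays(np.random.rand(10, 1), np.ones(10, int)))


def _logistic_draw(seed, n=20_000, b0=-2.0, b=(1.3, 2.8, 1.4)):
    rng = np.random.default_rng(seed)
    b = np.asarray(b)
    X = rng.random((n, len(b)))
    p = 1 / (1 + np.exp(-(b0 + X @ b)))
    y = (rng.random(n) < p).astype(int)
    return X, y


def test_logistic_parameter_recovery():
    # average the MLE over a few fixed draws to control Monte Carlo noise
    estimates = []
    for seed in (0, 1, 2):
        X, y = _logistic_draw(seed)
        model = fit_logistic(_table_from_arrays(X, y))
        estimates.append(np.r_[model.intercept_, model.coef_])
    mean = np.mean(estimates, axis=0)
    np.testing.assert_allclose(mean, [-2.0, 1.3, 2.8, 1.4], atol=0.15)


def test_logistic_matches_statsmodels_mle():
    import statsmodels.api as sm

    X, y = _logistic_draw(42, n=5_000)
    model = fit_logistic(_table_from_arrays(X, y))
    ref = sm.Logit(y, sm.add_constant(X)).fit(disp=0)
    assert model.intercept_ == pytest.approx(ref.params[0], abs=1e-4)
    np.testing.assert_allclose(model.coef_, ref.params[1:], atol=1e-4)


# -- fixed-coefficient consensus predictions -------------------------------
# Reference coefficient sets for a (template-based, template-free, docking)
# predictor triple; intercept 0.

def _manual(model_cls, coef):
    m = model_cls()
    m.coef_ = np.asarray(coef)
    m.intercept_ = 0.0
    m.n_features_in_ = 3
    return m


def test_logistic_consensus_formula():
    m = _manual(LogisticInterfaceScorer, [1.28, 2.821, 1.424])
    assert m.predict(np.zeros((1, 3)))[0] == pytest.approx(0.5)
    assert m.predict(np.ones((1, 3)))[0] == pytest.approx(1 / (1 + np.exp(-5.525)), abs=1e-12)
    assert m.predict(np.ones((1, 3)))[0] == pytest.approx(0.9960, abs=5e-4)


def test_linear_consensus_formula():
    m = _manual(LinearInterfaceScorer, [0.196, 0.313, 0.313])
    assert m.predict(np.ones((1, 3)))[0] == pytest.approx(0.822, abs=1e-12)


# -- random forest ---------------------------------------------------------

def test_forest_stump_predicts_leaf_fractions():
    X = np.r_[np.zeros(40), np.ones(40)][:, None]
    y = np.r_[(np.arange(40) < 8).astype(int), (np.arange(40) < 32).astype(int)]
    model = RandomForestInterfaceScorer(n_trees=1, max_depth=1, random_state=0)
    model.fit(X, y)
    left, right = model.predict(np.array([[0.0], [1.0]]))
    # single stump: predictions are the bootstrap leaf class fractions
    tree = model.forest_.estimators_[0].tree_
    values = tree.value.squeeze()
    assert {round(left, 6), round(right, 6)} == {
        round(v[1] / v.sum(), 6) for v in values[1:]
    }


def test_forest_duplicate_feature_invariance():
    t = make_table(n=400, k=1, seed=5)
    X = t.X()
    y = t.y()
    single = RandomForestInterfaceScorer(random_state=0).fit(X, y).predict(X)
    doubled = (
        RandomForestInterfaceScorer(random_state=0)
        .fit(np.c_[X, X], y)
        .predict(np.c_[X, X])
    )
    # same information either way: predictions agree up to bootstrap noise
    assert np.mean(np.abs(single - doubled)) < 0.05


def test_forest_pure_noise_pr_auc_near_prevalence():
    from ispip import roc_pr_curves

    aucs = []
    for seed in range(10):
        rng = np.random.default_rng(seed)
        X = rng.random((800, 3))
        y = (rng.random(800) < 0.2).astype(int)
        Xt = rng.random((800, 3))
        yt = (rng.random(800) < 0.2).astype(int)
        model = RandomForestInterfaceScorer(n_trees=50, random_state=seed).fit(X, y)
        aucs.append(roc_pr_curves(model.predict(Xt), yt)[1].auc)
    assert np.mean(aucs) == pytest.approx(0.2, abs=0.05)


def test_forest_param_validation():
    with pytest.raises(ValueError):
        RandomForestInterfaceScorer(n_trees=0).fit(np.random.rand(10, 1), np.arange(10) % 2)
    with pytest.raises(ValueError):
        RandomForestInterfaceScorer(max_depth=0).fit(np.random.rand(10, 1), np.arange(10) % 2)


# -- gradient boosting -----------------------------------------------------

def test_boosted_zero_iterations_is_base_rate():
    t = make_table(n=200, seed=6, prevalence=0.25)
    model = fit_boosted(t, iterations=0)
    np.testing.assert_allclose(model.predict(t.X()), t.y().mean())


def test_boosted_training_loss_non_increasing():
    rng = np.random.default_rng(9)
    X = rng.random((600, 1))
    y = (X[:, 0] > 0.6).astype(int)
    model = GradientBoostedInterfaceScorer(max_iter=60, random_state=0).fit(X, y)
    losses = model.staged_train_log_loss(X, y)
    assert np.all(np.diff(losses) <= 1e-9)


def test_boosted_beats_linear_on_interaction():
    from ispip import roc_pr_curves

    gaps = []
    for seed in range(5):
        table, _ = generate_interaction_dataset(n_proteins=25, seed=seed)
        y = table.y()
        n = len(y)
        train = np.arange(n) < int(0.7 * n)
        Xtr, ytr, Xte, yte = table.X()[train], y[train], table.X()[~train], y[~train]
        lin = LinearInterfaceScorer().fit(Xtr, ytr)
        gbt = GradientBoostedInterfaceScorer(random_state=seed).fit(Xtr, ytr)
        pr_lin = roc_pr_curves(lin.predict(Xte), yte)[1].auc
        pr_gbt = roc_pr_curves(gbt.predict(Xte), yte)[1].auc
        gaps.append(pr_gbt - pr_lin)
    assert min(gaps) >= 0.1


# -- shared contracts ------------------------------------------------------

@pytest.mark.parametrize(
    "fit", [fit_linear, fit_logistic, fit_forest, fit_boosted]
)
def test_predictions_always_in_unit_interval(fit, small_table):
    model = fit(small_table)
    p = model.predict(small_table.X())
    assert p.min() >= 0.0 and p.max() <= 1.0


def test_logistic_monotone_in_positive_coefficient_features(small_table):
    model = fit_logistic(small_table)
    X = small_table.X().copy()
    base = model.predict(X)
    for j in np.flatnonzero(model.coef_ > 0):
        Xp = X.copy()
        Xp[:, j] = np.minimum(1.0, Xp[:, j] + 0.05)
        assert np.all(model.predict(Xp) >= base - 1e-12)


def test_predict_missing_column_named(small_table):
    model = fit_linear(small_table)
    broken = ScoreTable(
        small_table.frame.drop(columns=["x2"]), predictors=["x1", "x3"]
    )
    with pytest.raises(ValueError, match="predictor columns"):
        model.predict(broken.X())
    with pytest.raises(ValueError, match="absent"):
        ScoreTable(small_table.frame, predictors=["x1", "x2", "missing"])


def test_sklearn_protocol(small_table):
    from sklearn.base import clone

    model = LogisticInterfaceScorer(C=100.0)
    params = model.get_params()
    assert params["C"] == 100.0
    cloned = clone(model).set_params(C=10.0)
    assert cloned.get_params()["C"] == 10.0
    fitted = model.fit(small_table.X(), small_table.y())
    assert hasattr(fitted, "coef_") and hasattr(fitted, "intercept_")


# -- cross-validation ------------------------------------------------------

def _surface_for(table, fraction=0.7):
    return {
        pid: max(1, round(fraction * (table.frame["protein_id"] == pid).sum()))
        for pid in table.protein_ids()
    }


def test_fold_assignment_groups_by_protein():
    ids = [f"P{i}" for i in range(10)]
    folds = assign_folds(ids, k=5, seed=0)
    assert set(folds) == set(ids)
    sizes = pd.Series(list(folds.values())).value_counts()
    assert sizes.min() == sizes.max() == 2
    assert assign_folds(ids, k=5, seed=0) == folds  # deterministic
    with pytest.raises(ValueError):
        assign_folds(["A", "A", "B", "C", "D"], k=2)


def test_cv_single_grid_point_returned(multi_protein_table):
    res = cross_validate(
        multi_protein_table,
        _surface_for(multi_protein_table),
        "rf",
        folds=4,
        seed=0,
        grid=[{"n_trees": 10, "max_depth": 3}],
    )
    assert res.best_params == {"n_trees": 10, "max_depth": 3}


def test_cv_deterministic(multi_protein_table):
    kwargs = dict(
        table=multi_protein_table,
        surface_counts=_surface_for(multi_protein_table),
        family="gbt",
        folds=4,
        seed=3,
        grid=[{"max_iter": 20, "max_depth": 2}, {"max_iter": 20, "max_depth": 4}],
    )
    a = cross_validate(**kwargs)
    b = cross_validate(**kwargs)
    assert a.best_params == b.best_params
    assert a.scores == b.scores


def test_cv_selects_depth_for_interaction():
    table, surface = generate_interaction_dataset(n_proteins=12, seed=1)
    res = cross_validate(
        table,
        surface,
        "gbt",
        folds=4,
        seed=0,
        grid=[{"max_depth": 1, "max_iter": 50}, {"max_depth": 6, "max_iter": 50}],
    )
    # stumps cannot express the two-feature interaction; deeper trees can
    assert res.best_params["max_depth"] == 6


def test_cv_candidate_regression(multi_protein_table):
    res = cv_candidate_regression(
        multi_protein_table, _surface_for(multi_protein_table), "logistic", folds=4, seed=0
    )
    assert "candidate_fold" in res.best_params
    assert 0.0 <= res.best_score <= 1.0
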