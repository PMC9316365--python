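"""The four score-integration models.

Each estimator consumes the per-residue likelihoods of the upstream
predictors (template-based, template-free, docking-based) as features
x_1..x_k and emits a consensus interface likelihood in [0, 1]:

* logistic regression,  P(i|x) = 1 / (1 + exp(-(b0 + Σ b_j x_j))),
  fit by maximum likelihood;
* linear regression,    I(x) = b0 + Σ b_j x_j,  fit by ordinary least
  squares, predictions clipped to [0, 1];
* random forest — bootstrap ensemble of depth-bounded classification trees
  (defaults: 100 trees, depth 10, cost-complexity pruning alpha 0); the
  likelihood is the mean terminal-node positive fraction across trees;
* gradient-boosted trees — histogram-binned stagewise additive ensemble.

All four follow the scikit-learn estimator protocol (``fit(X, y)``,
``get_params``/``set_params``, fitted attributes with a trailing
underscore) so they compose with pipelines and model selection, but
``predict`` deliberately returns the continuous likelihood rather than a
class: binarization happens downstream through the per-protein dynamic
top-N cutoff, never through a fixed 0.5 threshold.

Hyperparameters are selected by grouped five-fold cross-validation that
splits by protein (residues of one protein never straddle folds) and scores
each candidate by the average per-protein F-score under the dynamic cutoff.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin, clone
from sklearn.ensemble import (
    HistGradientBoostingClassifier,
    HistGradientBoostingRegressor,
    RandomForestClassifier,
)
from sklearn.linear_model import LinearRegression, LogisticRegression, Ridge
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y

from .evaluation import classify_top_n, confusion, dynamic_cutoff, metrics
from .table import ScoreTable

__all__ = [
    "LinearInterfaceScorer",
    "LogisticInterfaceScorer",
    "RandomForestInterfaceScorer",
    "GradientBoostedInterfaceScorer",
    "CVPlan",
    "CVResult",
    "MODEL_FAMILIES",
    "DEFAULT_GRIDS",
    "make_model",
    "fit_linear",
    "fit_logistic",
    "fit_forest",
    "fit_boosted",
    "predict",
    "assign_folds",
    "cross_validate",
]


class _LikelihoodScorer(RegressorMixin, BaseEstimator):
    """Shared plumbing: validation and the [0,1] likelihood contract."""

    def _validate_fit(self, X, y, require_both_classes: bool):
        X, y = check_X_y(X, y, dtype=float)
        classes = np.unique(y)
        if not np.isin(classes, [0, 1]).all():
            raise ValueError("labels must be binary 0/1")
        if require_both_classes and len(classes) < 2:
            raise ValueError("both classes must be present to fit this model")
        self.n_features_in_ = X.shape[1]
        return X, y.astype(float)

    def _validate_predict(self, X):
        check_is_fitted(self)
        X = check_array(X, dtype=float)
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"expected {self.n_features_in_} predictor columns, got {X.shape[1]}"
            )
        return X


class LinearInterfaceScorer(_LikelihoodScorer):
    """Ordinary-least-squares consensus: I(x) = b0 + Σ b_j x_j, clipped to [0,1].

    On a rank-deficient design the fit falls back to a lightly ridge-penalized
    solution (``ridge_alpha``) so coefficients remain finite and reproducible.
    With single-class labels the model degrades to intercept-only with a
    warning rather than failing: a constant column of labels carries no slope
    information.
    """

    def __init__(self, clip: bool = True, ridge_alpha: float = 1e-6):
        self.clip = clip
        self.ridge_alpha = ridge_alpha

    def fit(self, X, y):
        X, y = self._validate_fit(X, y, require_both_classes=False)
        if np.unique(y).size == 1:
            warnings.warn(
                "all labels identical; fitting an intercept-only linear model",
                UserWarning,
                stacklevel=2,
            )
            self.intercept_ = float(y[0])
            self.coef_ = np.zeros(X.shape[1])
            self.rank_deficient_ = False
            return self
        design = np.c_[np.ones(len(X)), X]
        rank = np.linalg.matrix_rank(design)
        self.rank_deficient_ = rank < design.shape[1]
        est = (
            Ridge(alpha=self.ridge_alpha) if self.rank_deficient_ else LinearRegression()
        )
        est.fit(X, y)
        self.intercept_ = float(est.intercept_)
        self.coef_ = np.asarray(est.coef_, dtype=float)
        return self

    def predict(self, X):
        X = self._validate_predict(X)
        out = self.intercept_ + X @ self.coef_
        return np.clip(out, 0.0, 1.0) if self.clip else out


class LogisticInterfaceScorer(_LikelihoodScorer):
    """Maximum-likelihood logistic consensus.

    ``C`` is the inverse L2 strength; the default is large enough that the
    fit is effectively unpenalized maximum likelihood.  If the data are
    (quasi-)separable the unpenalized coefficients diverge; that is detected
    by a coefficient-magnitude check and the model silently refits at
    ``separation_C``, preserving the monotone score ordering with finite
    coefficients.  ``separation_`` records whether this happened.
    """

    def __init__(
        self,
        C: float = 1e6,
        max_iter: int = 1000,
        tol: float = 1e-8,
        separation_coef: float = 30.0,
        separation_C: float = 1.0,
    ):
        self.C = C
        self.max_iter = max_iter
        self.tol = tol
        self.separation_coef = separation_coef
        self.separation_C = separation_C

    def _fit_at(self, X, y, C):
        est = LogisticRegression(
            C=C, solver="lbfgs", max_iter=self.max_iter, tol=self.tol
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # lbfgs iteration-cap chatter
            est.fit(X, y)
        return est

    def fit(self, X, y):
        X, y = self._validate_fit(X, y, require_both_classes=True)
        est = self._fit_at(X, y, self.C)
        coef = est.coef_.ravel()
        self.separation_ = bool(
            np.abs(np.r_[coef, est.intercept_]).max() > self.separation_coef
        )
        if self.separation_:
            est = self._fit_at(X, y, self.separation_C)
            coef = est.coef_.ravel()
        self.intercept_ = float(est.intercept_[0])
        self.coef_ = np.asarray(coef, dtype=float)
        return self

    def predict(self, X):
        X = self._validate_predict(X)
        z = self.intercept_ + X @ self.coef_
        # clip the linear predictor, not the probability: exp overflow guard
        return 1.0 / (1.0 + np.exp(-np.clip(z, -500, 500)))


class RandomForestInterfaceScorer(_LikelihoodScorer):
    """Random-forest consensus: likelihood = average terminal-node positive
    fraction across a bootstrap ensemble of depth-bounded trees."""

    def __init__(
        self,
        n_trees: int = 100,
        max_depth: int = 10,
        ccp_alpha: float = 0.0,
        random_state: int = 0,
    ):
        self.n_trees = n_trees
        self.max_depth = max_depth
        self.ccp_alpha = ccp_alpha
        self.random_state = random_state

    def fit(self, X, y):
        if self.n_trees < 1 or self.max_depth < 1:
            raise ValueError("n_trees and max_depth must be >= 1")
        X, y = self._validate_fit(X, y, require_both_classes=True)
        self.forest_ = RandomForestClassifier(
            n_estimators=self.n_trees,
            max_depth=self.max_depth,
            ccp_alpha=self.ccp_alpha,
            random_state=self.random_state,
        ).fit(X, y.astype(int))
        return self

    def predict(self, X):
        X = self._validate_predict(X)
        return self.forest_.predict_proba(X)[:, 1]


class GradientBoostedInterfaceScorer(_LikelihoodScorer):
    """Histogram-based gradient-boosted tree consensus.

    ``loss`` selects the stagewise objective: ``"log_loss"`` boosts a
    classifier whose predicted positive-class probability is the likelihood;
    ``"squared_error"`` boosts a regressor on the 0/1 labels, clipped to
    [0, 1].  ``max_iter=0`` yields the constant base-rate model.
    """

    def __init__(
        self,
        loss: str = "log_loss",
        learning_rate: float = 0.1,
        max_iter: int = 100,
        max_depth: int = 6,
        random_state: int = 0,
    ):
        self.loss = loss
        self.learning_rate = learning_rate
        self.max_iter = max_iter
        self.max_depth = max_depth
        self.random_state = random_state

    def fit(self, X, y):
        if self.loss not in ("log_loss", "squared_error"):
            raise ValueError(f"unknown loss {self.loss!r}")
        if self.max_iter < 0:
            raise ValueError("max_iter must be >= 0")
        X, y = self._validate_fit(X, y, require_both_classes=True)
        self.base_rate_ = float(np.mean(y))
        if self.max_iter == 0:
            self.booster_ = None
            return self
        common = dict(
            learning_rate=self.learning_rate,
            max_iter=self.max_iter,
            max_depth=self.max_depth,
            random_state=self.random_state,
            early_stopping=False,
        )
        if self.loss == "log_loss":
            self.booster_ = HistGradientBoostingClassifier(**common).fit(
                X, y.astype(int)
            )
        else:
            self.booster_ = HistGradientBoostingRegressor(
                loss="squared_error", **common
            ).fit(X, y)
        return self

    def predict(self, X):
        X = self._validate_predict(X)
        if self.booster_ is None:
            return np.full(len(X), self.base_rate_)
        if self.loss == "log_loss":
            return self.booster_.predict_proba(X)[:, 1]
        return np.clip(self.booster_.predict(X), 0.0, 1.0)

    def staged_train_log_loss(self, X, y):
        """Training log-loss after each boosting stage (log_loss only)."""
        check_is_fitted(self)
        if self.loss != "log_loss":
            raise ValueError("staged loss only defined for log_loss boosting")
        X = check_array(X, dtype=float)
        y = np.asarray(y, dtype=float)
        out = []
        for proba in self.booster_.staged_predict_proba(X):
            p = np.clip(proba[:, 1], 1e-12, 1 - 1e-12)
            out.append(float(-np.mean(y * np.log(p) + (1 - y) * np.log(1 - p))))
        return np.asarray(out)


MODEL_FAMILIES = {
    "linear": LinearInterfaceScorer,
    "logistic": LogisticInterfaceScorer,
    "rf": RandomForestInterfaceScorer,
    "gbt": GradientBoostedInterfaceScorer,
}

# Grid defaults; the regressions have no free hyperparameters, and the tree
# ensembles search around the defaults reported to work for this problem
# (100 trees / 10 levels / no pruning for the forest).
DEFAULT_GRIDS: dict[str, list[dict]] = {
    "linear": [{}],
    "logistic": [{}],
    "rf": [
        {"n_trees": t, "max_depth": d, "ccp_alpha": a}
        for t, d, a in itertools.product([100], [5, 10], [0.0])
    ],
    "gbt": [
        {"loss": l, "learning_rate": lr, "max_iter": it, "max_depth": d}
        for l, lr, it, d in itertools.product(
            ["log_loss", "squared_error"], [0.1], [100], [3, 6]
        )
    ],
}

# Tie-break order for grid search: simplest first.
_SIMPLICITY_KEYS = ("n_trees", "max_iter", "max_depth", "ccp_alpha", "learning_rate")


def make_model(family: str, seed: int = 0, **params):
    if family not in MODEL_FAMILIES:
        raise ValueError(f"unknown model family {family!r}; choose from {sorted(MODEL_FAMILIES)}")
    cls = MODEL_FAMILIES[family]
    if family in ("rf", "gbt"):
        params.setdefault("random_state", seed)
    return cls(**params)


# -- table-level convenience wrappers -------------------------------------

def fit_linear(table: ScoreTable) -> LinearInterfaceScorer:
    return LinearInterfaceScorer().fit(table.X(), table.y())


def fit_logistic(table: ScoreTable) -> LogisticInterfaceScorer:
    return LogisticInterfaceScorer().fit(table.X(), table.y())


def fit_forest(
    table: ScoreTable, trees: int = 100, max_depth: int = 10, alpha: float = 0.0, seed: int = 0
) -> RandomForestInterfaceScorer:
    return RandomForestInterfaceScorer(
        n_trees=trees, max_depth=max_depth, ccp_alpha=alpha, random_state=seed
    ).fit(table.X(), table.y())


def fit_boosted(
    table: ScoreTable,
    loss: str = "log_loss",
    learning_rate: float = 0.1,
    iterations: int = 100,
    max_depth: int = 6,
    seed: int = 0,
) -> GradientBoostedInterfaceScorer:
    return GradientBoostedInterfaceScorer(
        loss=loss,
        learning_rate=learning_rate,
        max_iter=iterations,
        max_depth=max_depth,
        random_state=seed,
    ).fit(table.X(), table.y())


def predict(model, table: ScoreTable) -> np.ndarray:
    """Apply a fitted integration model to a score table."""
    missing = [c for c in table.predictors if c not in table.frame.columns]
    if missing:
        raise ValueError(f"missing predictor column(s): {missing}")
    return np.asarray(model.predict(table.X()), dtype=float)


# -- grouped cross-validation ---------------------------------------------

@dataclass
class CVPlan:
    """Fold assignment (protein id -> fold index in 1..k) plus the candidate
    hyperparameter grid; the selection objective is the average per-protein
    F-score under the dynamic cutoff."""

    folds: dict[str, int]
    grid: list[dict] = field(default_factory=lambda: [{}])
    rounding: str = "round"

    def n_folds(self) -> int:
        return len(set(self.folds.values()))


@dataclass
class CVResult:
    best_params: dict
    best_score: float
    model: object
    scores: "dict[str, float]"  # mean held-out F per grid point (repr key)
    plan: CVPlan


def assign_folds(protein_ids: Sequence[str], k: int = 5, seed: int = 0) -> dict[str, int]:
    """Randomly partition proteins into k near-equal folds (deterministic
    given seed); remainders go to the lowest-numbered folds."""
    ids = list(protein_ids)
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate protein ids")
    if len(ids) < k:
        raise ValueError(f"need at least {k} proteins for {k} folds")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(ids))
    return {ids[j]: (i % k) + 1 for i, j in enumerate(order)}


def _mean_heldout_fscore(
    table: ScoreTable,
    surface_counts: Mapping[str, int],
    plan: CVPlan,
    template,
    seed: int,
) -> float:
    """Mean per-protein held-out F over the k fold rotations."""
    fscores: list[float] = []
    fold_of = plan.folds
    for fold in sorted(set(fold_of.values())):
        train_ids = [p for p, f in fold_of.items() if f != fold]
        test_ids = [p for p, f in fold_of.items() if f == fold]
        train = table.subset(train_ids)
        model = clone(template).fit(train.X(), train.y())
        for pid in test_ids:
            part = table.subset([pid])
            N = dynamic_cutoff(int(surface_counts[pid]), plan.rounding)
            calls = classify_top_n(model.predict(part.X()), N)
            labels = part.y()
            if labels.sum() == 0:
                fscores.append(0.0)  # no positive residues: F defined 0, flagged
                continue
            fscores.append(metrics(confusion(calls, labels)).fscore)
    return float(np.mean(fscores))


def cross_validate(
    table: ScoreTable,
    surface_counts: Mapping[str, int],
    family: str,
    plan: CVPlan | None = None,
    folds: int = 5,
    seed: int = 0,
    grid: list[dict] | None = None,
) -> CVResult:
    """Grid search by grouped k-fold CV, scored by average per-protein
    F-score under the dynamic cutoff; ties prefer the simpler model.

    The selected hyperparameters are refit on all training proteins and the
    refit model is returned.
    """
    ids = table.protein_ids()
    if plan is None:
        g = grid if grid is not None else DEFAULT_GRIDS[family]
        plan = CVPlan(folds=assign_folds(ids, folds, seed), grid=list(g))
    missing_R = [p for p in ids if p not in surface_counts]
    if missing_R:
        raise ValueError(f"proteins missing surface counts: {missing_R[:3]}")

    def simplicity(params: dict):
        return tuple(params.get(k, 0) for k in _SIMPLICITY_KEYS) + (
            tuple(sorted(params.items())),
        )

    scores: dict[str, float] = {}
    best: tuple[float, dict] | None = None
    for params in sorted(plan.grid, key=simplicity):
        template = make_model(family, seed=seed, **params)
        f = _mean_heldout_fscore(table, surface_counts, plan, template, seed)
        scores[repr(params)] = f
        if best is None or f > best[0]:  # strict >: first (simplest) wins ties
            best = (f, params)
    assert best is not None
    model = make_model(family, seed=seed, **best[1]).fit(table.X(), table.y())
    return CVResult(best_params=best[1], best_score=best[0], model=model, scores=scores, plan=plan)


def cv_candidate_regression(
    table: ScoreTable,
    surface_counts: Mapping[str, int],
    family: str,
    folds: int = 5,
    seed: int = 0,
) -> CVResult:
    """Alternative CV reading for the closed-form regressions: fit one
    candidate coefficient vector per fold rotation (on its 4 training
    folds), score each candidate by its held-out-fold average F, and keep
    the winning candidate as-is (no refit).

    OLS/MLE determine regression coefficients in closed form, so a
    hyperparameter grid is empty for these families; this procedure instead
    selects among the fold-fitted parameter vectors themselves.  The plain
    refit-on-everything alternative is ``cross_validate``.
    """
    if family not in ("linear", "logistic"):
        raise ValueError("candidate-selection CV applies to the regressions only")
    ids = table.protein_ids()
    fold_of = assign_folds(ids, folds, seed)
    plan = CVPlan(folds=fold_of, grid=[{}])
    best: tuple[float, object, int] | None = None
    scores: dict[str, float] = {}
    for fold in sorted(set(fold_of.values())):
        train_ids = [p for p, f in fold_of.items() if f != fold]
        test_ids = [p for p, f in fold_of.items() if f == fold]
        model = make_model(family, seed=seed)
        train = table.subset(train_ids)
        model.fit(train.X(), train.y())
        fs = []
        for pid in test_ids:
            part = table.subset([pid])
            N = dynamic_cutoff(int(surface_counts[pid]))
            calls = classify_top_n(model.predict(part.X()), N)
            fs.append(metrics(confusion(calls, part.y())).fscore)
        f = float(np.mean(fs))
        scores[f"fold_{fold}"] = f
        if best is None or f > best[0]:
            best = (f, model, fold)
    assert best is not None
    return CVResult(
        best_params={"candidate_fold": best[2]},
        best_score=best[0],
        model=best[1],
        scores=scores,
        plan=plan,
    )
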