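"""Clock construction: Random-Forest LOOCV, feature minimization, hybrids, LASSO.

The core estimator is :class:`LoocvForestClock`: a Random-Forest regressor
evaluated by leave-one-out cross-validation (LOOCV), the standard protocol
for small methylation cohorts.  Each of the N folds trains on N-1 samples
and predicts the held-out one; MAE and R² are computed on the pooled
held-out predictions, and per-fold impurity importances are accumulated
into a cumulative importance per feature.

:class:`ImportanceSweepClock` minimizes a clock: it ranks features by
cumulative importance (after discarding features no fold ever used), then
re-scores LOOCV models on growing prefixes of the ranking and keeps the
size with the lowest MAE.

:class:`LassoHoldoutClock` is the large-cohort variant: an 80/20 hold-out
split with the LASSO penalty chosen by 10-fold cross-validation on the
training split only.

All estimators follow scikit-learn conventions (``get_params`` /
``set_params``, trailing-underscore fitted attributes) and accept either
DataFrames (feature names preserved) or plain arrays.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.ensemble import RandomForestRegressor
from sklearn.linear_model import Lasso
from sklearn.model_selection import GridSearchCV, KFold, train_test_split
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.utils.validation import check_is_fitted

logger = logging.getLogger(__name__)


def evaluate(y_true, y_pred) -> tuple[float, float]:
    """Mean absolute error and coefficient of determination.

    R² = 1 − SS_res/SS_tot on the given predictions (can be negative for
    cross-validated predictions); NaN when the truth is constant.
    """
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_true.shape != y_pred.shape or y_true.size < 2:
        raise ValueError("evaluate needs two equal-length vectors of size >= 2")
    mae = float(np.mean(np.abs(y_true - y_pred)))
    ss_tot = float(np.sum((y_true - y_true.mean()) ** 2))
    if ss_tot == 0.0:
        return mae, float("nan")
    ss_res = float(np.sum((y_true - y_pred) ** 2))
    return mae, 1.0 - ss_res / ss_tot


def _as_frame(X) -> pd.DataFrame:
    if isinstance(X, pd.DataFrame):
        return X
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("X must be 2-dimensional")
    return pd.DataFrame(X, columns=[f"f{i}" for i in range(X.shape[1])])


def _drop_missing_rows(X: pd.DataFrame, y: pd.Series) -> tuple[pd.DataFrame, pd.Series]:
    # imputation would leak across LOOCV folds; drop incomplete samples instead
    mask = X.notna().all(axis=1) & y.notna()
    if not mask.all():
        dropped = list(X.index[~mask])
        logger.warning("dropping %d sample(s) with missing values: %s", len(dropped), dropped)
    return X.loc[mask], y.loc[mask]


class LoocvForestClock(RegressorMixin, BaseEstimator):
    """Random-Forest passage/age clock scored by leave-one-out CV.

    Parameters
    ----------
    n_estimators : int
        Trees per forest (default 500 for stable importances on small n).
    random_state : int
        Seed for every fold's forest and for the final refit.

    Fitted attributes
    -----------------
    oof_prediction_ : pd.Series
        Held-out prediction for every sample.
    mae_, r2_ : float
        Pooled LOOCV mean absolute error and R².
    cumulative_importance_ : pd.Series
        Per-feature impurity importances summed over folds (each fold's
        importances sum to 1, so the total sums to the number of folds).
    config_fingerprint_ : str
        Hash of the hyperparameters and feature list, for provenance.
    """

    def __init__(self, n_estimators: int = 500, random_state: int = 0):
        self.n_estimators = n_estimators
        self.random_state = random_state

    def _make_forest(self) -> RandomForestRegressor:
        return RandomForestRegressor(
            n_estimators=self.n_estimators, random_state=self.random_state, n_jobs=1
        )

    def fit(self, X, y):
        X = _as_frame(X)
        y = pd.Series(np.asarray(y, dtype=float), index=X.index)
        X, y = _drop_missing_rows(X, y)
        n = len(X)
        if n < 3:
            raise ValueError("LOOCV needs at least 3 complete samples")
        if X.shape[1] < 1:
            raise ValueError("need at least one feature")
        const = X.columns[X.nunique() <= 1]
        if len(const):
            logger.info("feature(s) constant across samples kept: %s", list(const))

        preds = np.empty(n)
        importances = np.zeros(X.shape[1])
        Xv = X.to_numpy(dtype=float)
        yv = y.to_numpy(dtype=float)
        for i in range(n):
            train = np.arange(n) != i
            forest = self._make_forest()
            forest.fit(Xv[train], yv[train])
            preds[i] = forest.predict(Xv[i : i + 1])[0]
            importances += forest.feature_importances_
        self.oof_prediction_ = pd.Series(preds, index=X.index, name="prediction")
        self.mae_, self.r2_ = evaluate(yv, preds)
        self.cumulative_importance_ = pd.Series(importances, index=X.columns)
        self.feature_names_in_ = np.asarray(X.columns, dtype=object)
        self.n_features_in_ = X.shape[1]
        self.n_folds_ = n
        self.config_fingerprint_ = hashlib.sha1(
            json.dumps(
                {
                    "n_estimators": self.n_estimators,
                    "random_state": self.random_state,
                    "features": list(map(str, X.columns)),
                    "n_samples": n,
                },
                sort_keys=True,
            ).encode()
        ).hexdigest()[:16]
        self.estimator_ = self._make_forest().fit(Xv, yv)
        return self

    def predict(self, X):
        check_is_fitted(self, "estimator_")
        X = _as_frame(X)
        if list(X.columns) != list(self.feature_names_in_):
            X = X.loc[:, list(self.feature_names_in_)]
        return self.estimator_.predict(X.to_numpy(dtype=float))


def prune_zero_importance(clock: LoocvForestClock, X: pd.DataFrame) -> pd.DataFrame:
    """Drop features no LOOCV fold ever used (cumulative importance exactly 0)."""
    check_is_fitted(clock, "cumulative_importance_")
    imp = clock.cumulative_importance_
    keep = imp.index[imp > 0]
    if len(keep) == 0:
        raise ValueError("all features have zero cumulative importance (degenerate model)")
    return _as_frame(X).loc[:, list(keep)]


@dataclass
class SweepResult:
    """Outcome of the cumulative-importance minimization sweep."""

    per_size: pd.DataFrame  # index n_features, columns mae / r2
    best_n: int
    ranked_features: list[str]

    @property
    def best_features(self) -> list[str]:
        return self.ranked_features[: self.best_n]


class ImportanceSweepClock(RegressorMixin, BaseEstimator):
    """Minimized clock: LOOCV models on growing prefixes of the importance ranking.

    Fits a full-feature :class:`LoocvForestClock`, removes zero-importance
    features, ranks the rest by cumulative importance (most important
    first), then evaluates a LOOCV model for each prefix size and keeps the
    size with minimum MAE (ties broken toward fewer features).  Beyond
    ``sweep_cap`` features the sweep uses a logarithmic size grid.
    """

    def __init__(self, n_estimators: int = 500, random_state: int = 0, sweep_cap: int = 256):
        self.n_estimators = n_estimators
        self.random_state = random_state
        self.sweep_cap = sweep_cap

    def fit(self, X, y):
        X = _as_frame(X)
        y = pd.Series(np.asarray(y, dtype=float), index=X.index)
        base = LoocvForestClock(self.n_estimators, self.random_state).fit(X, y)
        Xp = prune_zero_importance(base, X)
        imp = base.cumulative_importance_.loc[Xp.columns]
        ranked = list(imp.sort_values(ascending=False, kind="mergesort").index)
        K = len(ranked)
        if K <= self.sweep_cap:
            sizes = list(range(1, K + 1))
        else:
            sizes = sorted(
                set(np.unique(np.geomspace(1, K, num=self.sweep_cap).round().astype(int))) | {K}
            )
            logger.info("sweeping %d features on a log grid of %d sizes", K, len(sizes))
        rows = []
        self._prefix_clocks: dict[int, LoocvForestClock] = {}
        for k in sizes:
            clock = LoocvForestClock(self.n_estimators, self.random_state)
            clock.fit(X.loc[:, ranked[:k]], y)
            self._prefix_clocks[k] = clock
            rows.append((k, clock.mae_, clock.r2_))
        per_size = pd.DataFrame(rows, columns=["n_features", "mae", "r2"]).set_index("n_features")
        best_n = int(per_size["mae"].idxmin())  # idxmin returns the first (smallest) minimizer
        self.sweep_ = SweepResult(per_size, best_n, ranked)
        self.best_n_ = best_n
        self.ranked_features_ = ranked
        self.best_clock_ = self._prefix_clocks[best_n]
        self.mae_ = self.best_clock_.mae_
        self.r2_ = self.best_clock_.r2_
        self.feature_names_in_ = np.asarray(X.columns, dtype=object)
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X):
        check_is_fitted(self, "best_clock_")
        return self.best_clock_.predict(_as_frame(X))


def build_hybrid(parts: list[tuple[pd.DataFrame, str]]) -> pd.DataFrame:
    """Column-concatenate feature matrices of different provenance.

    ``parts`` is a list of (matrix, tag) with identical sample sets; the
    provenance tag (mean_beta, MHL, PDR, ...) prefixes every column so
    identical feature ids from different metrics stay distinct.
    """
    if not parts:
        raise ValueError("need at least one feature matrix")
    ref_index = parts[0][0].index
    for matrix, tag in parts[1:]:
        if set(matrix.index) != set(ref_index):
            only_a = sorted(set(ref_index) - set(matrix.index))
            only_b = sorted(set(matrix.index) - set(ref_index))
            raise ValueError(
                f"sample sets differ for part {tag!r}: "
                f"missing {only_b or '-'} / extra {only_a or '-'}"
            )
    tagged = [
        matrix.reindex(ref_index).rename(columns=lambda c: f"{tag}:{c}")
        for matrix, tag in parts
    ]
    return pd.concat(tagged, axis=1)


class LassoHoldoutClock(RegressorMixin, BaseEstimator):
    """LASSO clock with an 80/20 hold-out and CV-selected penalty.

    Features are standardized on the training split only; the penalty
    ``alpha`` is chosen on a log grid by ``cv_folds``-fold CV mean absolute
    error within the training split; the refit model is scored once on the
    untouched test split (``holdout_mae_``, ``holdout_r2_``).  ``coef_`` is
    reported on the original feature scale.
    """

    def __init__(
        self,
        train_fraction: float = 0.8,
        cv_folds: int = 10,
        random_state: int = 0,
        alphas=None,
    ):
        self.train_fraction = train_fraction
        self.cv_folds = cv_folds
        self.random_state = random_state
        self.alphas = alphas

    def fit(self, X, y):
        X = _as_frame(X)
        y = pd.Series(np.asarray(y, dtype=float), index=X.index)
        X, y = _drop_missing_rows(X, y)
        if not 0 < self.train_fraction < 1:
            raise ValueError("train_fraction must be in (0, 1): the test split may not be empty")
        n_train = int(round(len(X) * self.train_fraction))
        if n_train < self.cv_folds + 2:
            raise ValueError(
                f"{n_train} training samples cannot support {self.cv_folds}-fold CV; "
                "reduce cv_folds"
            )
        alphas = self.alphas if self.alphas is not None else np.logspace(-4, 1, 50)
        X_tr, X_te, y_tr, y_te = train_test_split(
            X, y, train_size=self.train_fraction, random_state=self.random_state
        )
        pipe = Pipeline(
            [("scale", StandardScaler()), ("lasso", Lasso(max_iter=100_000))]
        )
        search = GridSearchCV(
            pipe,
            {"lasso__alpha": list(alphas)},
            scoring="neg_mean_absolute_error",
            cv=KFold(self.cv_folds, shuffle=True, random_state=self.random_state),
        )
        search.fit(X_tr, y_tr)
        self.alpha_ = float(search.best_params_["lasso__alpha"])
        self.model_ = search.best_estimator_
        y_hat = self.model_.predict(X_te)
        self.holdout_mae_, self.holdout_r2_ = evaluate(y_te, y_hat)
        scaler: StandardScaler = self.model_.named_steps["scale"]
        lasso: Lasso = self.model_.named_steps["lasso"]
        self.coef_ = pd.Series(lasso.coef_ / scaler.scale_, index=X.columns)
        self.intercept_ = float(
            lasso.intercept_ - np.sum(lasso.coef_ * scaler.mean_ / scaler.scale_)
        )
        self.train_index_ = list(X_tr.index)
        self.test_index_ = list(X_te.index)
        self.feature_names_in_ = np.asarray(X.columns, dtype=object)
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X):
        check_is_fitted(self, "model_")
        X = _as_frame(X)
        if list(X.columns) != list(self.feature_names_in_):
            X = X.loc[:, list(self.feature_names_in_)]
        return self.model_.predict(X)


# ---------------------------------------------------------------------------
# Thin functional wrappers


def rfr_loocv(X, y, seed: int = 0, n_trees: int = 500) -> LoocvForestClock:
    return LoocvForestClock(n_estimators=n_trees, random_state=seed).fit(X, y)


def importance_sweep(X, y, seed: int = 0, n_trees: int = 500, sweep_cap: int = 256) -> SweepResult:
    return ImportanceSweepClock(n_trees, seed, sweep_cap).fit(X, y).sweep_


def lasso_holdout(
    X, y, split: float = 0.8, cv_folds: int = 10, seed: int = 0
) -> LassoHoldoutClock:
    return LassoHoldoutClock(split, cv_folds, seed).fit(X, y)
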