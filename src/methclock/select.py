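"""Correlation-based feature selection with multiple-testing control.

Features (mean beta values or WSH scores) are tested one at a time for
Pearson or Spearman correlation with the target (culture passage or donor
age), p-values are adjusted by Benjamini–Hochberg across all testable
features of the matrix, and predictors are selected by adjusted
significance — optionally excluding any feature that also tracks a
confounding target (chronological age, when building a passage-only clock).
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

_STAT_FNS = {"pearson": stats.pearsonr, "spearman": stats.spearmanr}
_ADJUST_METHODS = {"bh": "fdr_bh", "bonferroni": "bonferroni"}


def correlate(
    matrix: pd.DataFrame,
    target: pd.Series,
    statistic: str = "pearson",
    adjust: str = "bh",
    min_n: int = 3,
) -> pd.DataFrame:
    """Per-feature correlation of a samples x features matrix with a target.

    Uses pairwise-complete observations per feature.  Returns a DataFrame
    indexed by feature id with columns ``statistic``, ``p_value``, ``p_adj``,
    ``n_used`` and ``undefined``.  Constant features (or features with fewer
    than ``min_n`` paired observations) are flagged undefined and excluded
    from the adjustment denominator.
    """
    if statistic not in _STAT_FNS:
        raise ValueError(f"statistic must be one of {sorted(_STAT_FNS)}")
    if adjust not in _ADJUST_METHODS:
        raise ValueError(f"adjust must be one of {sorted(_ADJUST_METHODS)}")
    fn = _STAT_FNS[statistic]
    target = target.reindex(matrix.index).astype(float)

    rows = []
    for feature in matrix.columns:
        x = matrix[feature].astype(float)
        mask = x.notna() & target.notna()
        n = int(mask.sum())
        if n < min_n or x[mask].nunique() < 2 or target[mask].nunique() < 2:
            rows.append((feature, np.nan, np.nan, n, True))
            continue
        res = fn(x[mask], target[mask])
        rows.append((feature, float(res.statistic), float(res.pvalue), n, False))
    out = pd.DataFrame(
        rows, columns=["feature_id", "statistic", "p_value", "n_used", "undefined"]
    ).set_index("feature_id")
    out["statistic_type"] = "pearson_r" if statistic == "pearson" else "spearman_rho"
    out["p_adj"] = np.nan
    defined = ~out["undefined"]
    if defined.any():
        out.loc[defined, "p_adj"] = multipletests(
            out.loc[defined, "p_value"], method=_ADJUST_METHODS[adjust]
        )[1]
    return out


def select_passage_features(
    passage_assoc: pd.DataFrame,
    age_assoc: pd.DataFrame | None,
    alpha: float = 0.05,
) -> list[str]:
    """Features significant for passage but not for age, ordered by |statistic|.

    Any feature whose methylation also tracks chronological age is discarded
    so the resulting clock measures culture time only.  When no age
    associations are available (too few aged samples) the confound filter is
    skipped with a warning.
    """
    sig = passage_assoc[(~passage_assoc["undefined"]) & (passage_assoc["p_adj"] < alpha)]
    if age_assoc is not None:
        if not passage_assoc.index.equals(age_assoc.index) and set(passage_assoc.index) != set(
            age_assoc.index
        ):
            raise ValueError("passage and age associations must cover the same features")
        age_sig = age_assoc[(~age_assoc["undefined"]) & (age_assoc["p_adj"] < alpha)].index
        sig = sig.drop(index=[f for f in sig.index if f in set(age_sig)])
    else:
        logger.warning("no age associations given; age-confound exclusion skipped")
    if sig.empty:
        logger.warning("no features pass the passage selection at alpha=%g", alpha)
        return []
    order = sig["statistic"].abs().sort_values(ascending=False, kind="mergesort")
    return list(order.index)


def select_top_wsh(
    assoc: pd.DataFrame, alpha: float = 0.05, top_k: int | None = None
) -> list[str]:
    """Significant WSH features ranked by |rho| descending, optionally truncated."""
    sig = assoc[(~assoc["undefined"]) & (assoc["p_adj"] < alpha)]
    order = sig["statistic"].abs().sort_values(ascending=False, kind="mergesort")
    selected = list(order.index)
    if top_k is not None:
        selected = selected[:top_k]
    return selected


class CorrelationSelector(TransformerMixin, BaseEstimator):
    """Select features correlated with the fit target, sklearn-style.

    Parameters
    ----------
    statistic : {"pearson", "spearman"}
        Correlation statistic; mean-methylation clocks conventionally use
        Pearson, WSH-score clocks Spearman rank correlation.
    alpha : float
        Adjusted-significance threshold.
    adjust : {"bh", "bonferroni"}
        Multiple-testing correction across the matrix's features.
    top_k : int or None
        Keep at most this many features, best |statistic| first.

    After ``fit(X, y, confound=...)`` the fitted attributes are
    ``results_`` (the association table for y), ``confound_results_`` (for
    the confound target, if given) and ``selected_features_``.  Features
    significant for the confound are excluded.
    """

    def __init__(
        self,
        statistic: str = "pearson",
        alpha: float = 0.05,
        adjust: str = "bh",
        top_k: int | None = None,
    ):
        self.statistic = statistic
        self.alpha = alpha
        self.adjust = adjust
        self.top_k = top_k

    def fit(self, X: pd.DataFrame, y, confound=None):
        X = _as_frame(X)
        y = pd.Series(np.asarray(y, dtype=float), index=X.index)
        self.results_ = correlate(X, y, statistic=self.statistic, adjust=self.adjust)
        if confound is not None:
            confound = pd.Series(np.asarray(confound, dtype=float), index=X.index)
            if confound.notna().sum() >= 3:
                self.confound_results_ = correlate(
                    X, confound, statistic=self.statistic, adjust=self.adjust
                )
            else:
                logger.warning("confound available for <3 samples; exclusion skipped")
                self.confound_results_ = None
        else:
            self.confound_results_ = None
        selected = select_passage_features(self.results_, self.confound_results_, self.alpha)
        if self.top_k is not None:
            selected = selected[: self.top_k]
        self.selected_features_ = selected
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        check_is_fitted(self, "selected_features_")
        return _as_frame(X).loc[:, self.selected_features_]

    def get_support(self) -> list[str]:
        check_is_fitted(self, "selected_features_")
        return list(self.selected_features_)


def _as_frame(X) -> pd.DataFrame:
    if isinstance(X, pd.DataFrame):
        return X
    X = np.asarray(X, dtype=float)
    return pd.DataFrame(X, columns=[f"f{i}" for i in range(X.shape[1])])
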