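"""End-to-end workflows: from read patterns to a minimized passage clock.

These helpers chain the stages exactly as a user of the command line
would: compute beta values and heterogeneity scores from a
:class:`~methclock.io.PatternSet`, select passage-associated features with
the age-confound exclusion, and score Random-Forest LOOCV clocks on the
mean-methylation, WSH-only and hybrid feature sets.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .io import PatternSet, SampleRecord, compute_beta, sample_sheet_to_frame
from .model import LoocvForestClock, build_hybrid
from .select import correlate, select_passage_features, select_top_wsh
from .wsh import compute_score_matrix


def targets_from_samples(samples: list[SampleRecord]) -> pd.DataFrame:
    return sample_sheet_to_frame(samples)[["passage", "donor_age"]].astype(float)


def select_mean_features(
    ps: PatternSet,
    samples: list[SampleRecord],
    alpha: float = 0.05,
    min_coverage: int = 10,
) -> tuple[pd.DataFrame, list[str]]:
    """Beta matrix plus the passage-but-not-age CpG selection.

    Returns the full beta DataFrame and the ordered selected CpG ids.
    """
    sheet = targets_from_samples(samples)
    beta = compute_beta(ps, min_coverage=min_coverage).values
    beta = beta.reindex(sheet.index)
    passage_assoc = correlate(beta, sheet["passage"], statistic="pearson")
    age_assoc = None
    if sheet["donor_age"].notna().sum() >= 3:
        age_assoc = correlate(beta, sheet["donor_age"], statistic="pearson")
    selected = select_passage_features(passage_assoc, age_assoc, alpha=alpha)
    return beta, selected


def select_wsh_features(
    ps: PatternSet,
    samples: list[SampleRecord],
    metric: str,
    alpha: float = 0.05,
    top_k: int | None = None,
    seed: int = 0,
    **metric_params,
) -> tuple[pd.DataFrame, list[str]]:
    """Score matrix for one WSH metric plus its Spearman-vs-passage selection."""
    sheet = targets_from_samples(samples)
    scores = compute_score_matrix(ps, metric, seed=seed, **metric_params).values
    scores = scores.reindex(sheet.index)
    assoc = correlate(scores, sheet["passage"], statistic="spearman")
    selected = select_top_wsh(assoc, alpha=alpha, top_k=top_k)
    return scores, selected


@dataclass
class ClockReport:
    """LOOCV performance of one feature set."""

    name: str
    n_features: int
    mae: float
    r2: float
    predictions: pd.Series


def score_clock(
    name: str, X: pd.DataFrame, y: pd.Series, n_trees: int = 500, seed: int = 0
) -> tuple[ClockReport, LoocvForestClock]:
    clock = LoocvForestClock(n_estimators=n_trees, random_state=seed).fit(X, y)
    return ClockReport(name, X.shape[1], clock.mae_, clock.r2_, clock.oof_prediction_), clock


def run_clock_comparison(
    ps: PatternSet,
    samples: list[SampleRecord],
    metrics: tuple[str, ...] = ("MHL",),
    alpha: float = 0.05,
    n_trees: int = 500,
    seed: int = 0,
    min_coverage: int = 10,
    min_reads: int = 10,
) -> dict[str, ClockReport]:
    """Mean-methylation, WSH-only and hybrid LOOCV clocks on one cohort.

    Returns reports keyed ``mean``, one per WSH metric, and
    ``mean+<metric>`` hybrids, mirroring the standard comparison a
    targeted-panel clock study runs.
    """
    sheet = targets_from_samples(samples)
    y = sheet["passage"]
    beta, mean_sel = select_mean_features(ps, samples, alpha=alpha, min_coverage=min_coverage)
    reports: dict[str, ClockReport] = {}
    mean_X = beta.loc[:, mean_sel]
    if mean_sel:
        reports["mean"], _ = score_clock("mean", mean_X, y, n_trees, seed)
    wsh_parts: dict[str, pd.DataFrame] = {}
    for metric in metrics:
        scores, sel = select_wsh_features(
            ps, samples, metric, alpha=alpha, seed=seed, min_reads=min_reads
        )
        if not sel:
            continue
        X = scores.loc[:, sel]
        wsh_parts[metric] = X
        reports[metric], _ = score_clock(metric, X, y, n_trees, seed)
    for metric, X in wsh_parts.items():
        if not mean_sel:
            break
        hybrid = build_hybrid([(mean_X, "mean_beta"), (X, metric)])
        reports[f"mean+{metric}"], _ = score_clock(f"mean+{metric}", hybrid, y, n_trees, seed)
    if len(wsh_parts) > 1 and mean_sel:
        parts = [(mean_X, "mean_beta")] + [(X, m) for m, X in wsh_parts.items()]
        name = "mean+" + "+".join(wsh_parts)
        reports[name], _ = score_clock(name, build_hybrid(parts), y, n_trees, seed)
    return reports
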