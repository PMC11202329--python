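"""Predictive models per grouper: high-cost classification and actual-cost regression.

High-cost outcome: an episode whose total cost lies strictly above the
80th/90th/95th percentile cut-off of the cost distribution (linear-
interpolation quantiles; ties at the cut-off count negative). The
classifier is a logistic regression with the grouper as the sole
categorical predictor — the saturated model, whose fitted probability for
each group is exactly the group's empirical high-cost rate. Separated
groups (empirical rate 0 or 1) keep the empirical rate and are flagged; an
add-½ smoothing option is available. Ranking performance is read off ROC
and precision-recall curves.

Actual cost: a lognormal regression — per-group mean of log cost with a
pooled residual log-SD; the expected euro cost per episode applies the
half-variance back-transform exp(μ_g + σ²/2) (the lognormal mean), with a
naive exp(μ_g) option. Observed and expected distributions are compared by
quantile tables and a Kolmogorov–Smirnov distance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import (
    average_precision_score,
    precision_recall_curve,
    roc_auc_score,
    roc_curve,
)

from casemix.errors import DataError
from casemix.evaluation import reduction_in_variance
from casemix.groupers import GrouperAssignment


@dataclass(frozen=True)
class ThresholdModelResult:
    """Fitted saturated-logistic high-cost model for one grouper and cut-off."""

    grouper_name: str
    percentile: float
    cutoff: float
    prevalence: float
    per_group_probability: pd.Series
    scores: pd.Series  # per-episode P(high cost) = its group's probability
    roc_points: pd.DataFrame  # columns fpr, tpr
    pr_points: pd.DataFrame  # columns recall, precision
    auroc: float
    auprc: float
    separated_groups: list = field(default_factory=list)


@dataclass(frozen=True)
class CostModelResult:
    """Fitted lognormal (or linear) actual-cost model for one grouper."""

    grouper_name: str
    model: str  # 'lognormal' or 'linear'
    per_group_location: pd.Series  # log-euros (lognormal) or euros (linear)
    residual_log_sd: float
    expected_cost: pd.Series  # per-episode expected euros
    rv_of_predictions: float


def percentile_cutoffs(costs, percentiles=(80.0, 90.0, 95.0)) -> dict[float, float]:
    """Cost cut-offs at the requested percentiles (linear interpolation)."""
    arr = np.asarray(costs, dtype=float)
    if arr.size == 0:
        raise DataError("percentile_cutoffs: empty cost vector")
    return {float(p): float(np.quantile(arr, p / 100.0)) for p in percentiles}


def high_cost_labels(costs, cutoff: float) -> np.ndarray:
    """Binary outcome: strictly above the cut-off counts as high cost."""
    return (np.asarray(costs, dtype=float) > cutoff).astype(int)


def roc_pr_curves(scores, labels) -> tuple[pd.DataFrame, pd.DataFrame, float, float]:
    """ROC and PR curves with their areas for a score vector.

    AUROC is the trapezoid area, equal to the probability of concordance
    with ties counted ½; AUPRC is the area under the step-interpolated PR
    curve (average precision). Requires both classes present.
    """
    y = np.asarray(labels, dtype=int)
    s = np.asarray(scores, dtype=float)
    if y.size == 0 or s.size != y.size:
        raise DataError("roc_pr_curves: scores and labels must be non-empty and aligned")
    if len(np.unique(y)) < 2:
        raise DataError("roc_pr_curves: both classes must be present")
    fpr, tpr, _ = roc_curve(y, s)
    precision, recall, _ = precision_recall_curve(y, s)
    roc_points = pd.DataFrame({"fpr": fpr, "tpr": tpr})
    # precision_recall_curve returns recall descending; store it ascending
    pr_points = pd.DataFrame({"recall": recall[::-1], "precision": precision[::-1]})
    return (
        roc_points,
        pr_points,
        float(roc_auc_score(y, s)),
        float(average_precision_score(y, s)),
    )


def fit_threshold_model(
    episodes: pd.DataFrame,
    assignment: GrouperAssignment,
    cutoff: float,
    percentile: float = float("nan"),
    smoothing: str | None = None,
) -> ThresholdModelResult:
    """Saturated logistic regression of the high-cost outcome on a grouper.

    With the grouper as the only (categorical) predictor, the MLE fitted
    probability in each group is the group's empirical positive rate; the
    model is fitted in that closed form. ``smoothing='add_half'`` replaces
    the rate by (k + ½) / (n + 1), which keeps separated groups off 0/1.
    """
    if smoothing not in (None, "add_half"):
        raise DataError(f"fit_threshold_model: unknown smoothing {smoothing!r}")
    y = high_cost_labels(episodes["total_cost"], cutoff)
    if len(np.unique(y)) < 2:
        raise DataError(
            f"fit_threshold_model: outcome is constant at cutoff {cutoff:.2f}"
        )
    labels = assignment.labels.set_axis(episodes.index)
    grouped = pd.Series(y, index=episodes.index).groupby(labels.values)
    k, n = grouped.sum(), grouped.size()
    if smoothing == "add_half":
        probs = (k + 0.5) / (n + 1.0)
    else:
        probs = k / n
    separated = probs.index[(k == 0) | (k == n)].tolist()
    scores = labels.map(probs).rename("score")
    roc_points, pr_points, auroc, auprc = roc_pr_curves(scores.to_numpy(), y)
    return ThresholdModelResult(
        grouper_name=assignment.grouper_name,
        percentile=float(percentile),
        cutoff=float(cutoff),
        prevalence=float(y.mean()),
        per_group_probability=probs.rename("probability"),
        scores=scores,
        roc_points=roc_points,
        pr_points=pr_points,
        auroc=auroc,
        auprc=auprc,
        separated_groups=separated,
    )


def fit_numeric_threshold_model(
    episodes: pd.DataFrame,
    assignment: GrouperAssignment,
    cutoff: float,
    percentile: float = float("nan"),
) -> ThresholdModelResult:
    """Logistic regression on a numeric index (QID/QIP) as a continuous predictor."""
    import statsmodels.api as sm

    y = high_cost_labels(episodes["total_cost"], cutoff)
    if len(np.unique(y)) < 2:
        raise DataError(
            f"fit_numeric_threshold_model: outcome is constant at cutoff {cutoff:.2f}"
        )
    x = assignment.labels.set_axis(episodes.index).astype(float)
    design = sm.add_constant(x.to_numpy())
    fit = sm.GLM(y, design, family=sm.families.Binomial()).fit()
    scores = pd.Series(fit.predict(design), index=episodes.index, name="score")
    roc_points, pr_points, auroc, auprc = roc_pr_curves(scores.to_numpy(), y)
    return ThresholdModelResult(
        grouper_name=assignment.grouper_name,
        percentile=float(percentile),
        cutoff=float(cutoff),
        prevalence=float(y.mean()),
        per_group_probability=pd.Series(
            {"const": float(fit.params[0]), "slope": float(fit.params[1])}
        ),
        scores=scores,
        roc_points=roc_points,
        pr_points=pr_points,
        auroc=auroc,
        auprc=auprc,
    )


def fit_lognormal_model(
    episodes: pd.DataFrame,
    assignment: GrouperAssignment,
    model: str = "lognormal",
    back_transform: str = "corrected",
) -> CostModelResult:
    """Regression of actual cost on a grouper.

    lognormal: per-group mean log cost μ_g, pooled residual log-SD σ with
    n − G degrees of freedom, expected cost exp(μ_g + σ²/2) (the lognormal
    mean; ``back_transform='naive'`` drops the correction). linear:
    per-group mean euro cost, expected cost = the group mean.
    ``rv_of_predictions`` is the RV of the grouping on raw euros.
    """
    if model not in ("lognormal", "linear"):
        raise DataError(f"fit_lognormal_model: model must be 'lognormal' or 'linear', got {model!r}")
    if back_transform not in ("corrected", "naive"):
        raise DataError(
            f"fit_lognormal_model: back_transform must be 'corrected' or 'naive', got {back_transform!r}"
        )
    if len(episodes) == 0:
        raise DataError("fit_lognormal_model: empty episode table")
    cost = episodes["total_cost"].to_numpy(dtype=float)
    if np.any(cost <= 0):
        raise DataError("fit_lognormal_model: non-positive costs cannot be log-transformed")
    labels = assignment.labels.set_axis(episodes.index)

    y = np.log(cost) if model == "lognormal" else cost
    ys = pd.Series(y, index=episodes.index)
    mu = ys.groupby(labels.values).mean()
    fitted = labels.map(mu)
    resid = ys - fitted
    dof = len(ys) - mu.size
    sigma = float(np.sqrt((resid**2).sum() / dof)) if dof > 0 else 0.0

    if model == "lognormal":
        correction = 0.5 * sigma**2 if back_transform == "corrected" else 0.0
        expected = np.exp(fitted + correction)
    else:
        expected = fitted
    return CostModelResult(
        grouper_name=assignment.grouper_name,
        model=model,
        per_group_location=mu.rename("location"),
        residual_log_sd=sigma if model == "lognormal" else float("nan"),
        expected_cost=expected.rename("expected_cost"),
        rv_of_predictions=reduction_in_variance(episodes, assignment, scale="raw")
        if len(episodes) >= 2 and episodes["total_cost"].nunique() > 1
        else 0.0,
    )


#: observed-vs-expected comparison grid: deciles plus the far right tail
OVE_QUANTILES = (0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9, 0.95, 0.99)


def observed_vs_expected(
    episodes: pd.DataFrame, result: CostModelResult
) -> tuple[pd.DataFrame, float]:
    """Quantile table of observed vs model-expected cost, plus a KS distance.

    Returns (table, ks): the table has one row per quantile in
    ``OVE_QUANTILES`` with observed and expected cost; ks is the two-sample
    Kolmogorov–Smirnov statistic between the observed and expected
    per-episode distributions (0 = the model reproduces the cost
    distribution exactly).
    """
    # micro-euro resolution: keeps log/exp round-trip noise from registering
    # as distributional distance when a model reproduces costs exactly
    observed = np.round(episodes["total_cost"].to_numpy(dtype=float), 6)
    expected = np.round(result.expected_cost.to_numpy(dtype=float), 6)
    table = pd.DataFrame(
        {
            "quantile": OVE_QUANTILES,
            "observed": np.quantile(observed, OVE_QUANTILES),
            "expected": np.quantile(expected, OVE_QUANTILES),
        }
    )
    ks = float(stats.ks_2samp(observed, expected).statistic)
    return table, ks


@dataclass(frozen=True)
class StratifiedResult:
    """Per-base-group analyses plus an episode-pooled summary."""

    inner_grouper: str
    per_base: pd.DataFrame  # one row per retained base group
    pooled: dict
    exclusion_report: dict


def stratified_run(
    episodes: pd.DataFrame,
    inner_assignment: GrouperAssignment,
    base_labels: pd.Series,
    min_n: int = 25,
) -> StratifiedResult:
    """Run the cost analyses within each base DRG group.

    Severity/complexity levels are only meaningful within a base group, so
    each analysis is repeated per base group (those with ≥ ``min_n``
    episodes) and pooled by treating (base, inner) pairs as the groups of a
    single combined analysis.
    """
    from casemix.groupers import filter_small_groups

    base = GrouperAssignment("base_group", pd.Series(base_labels).reset_index(drop=True))
    inner = inner_assignment.labels.set_axis(episodes.index)
    retained, report = filter_small_groups(episodes, base, min_n=min_n)
    if len(retained) == 0:
        raise DataError("stratified_run: no base group has enough episodes")

    base_kept = pd.Series(base_labels).set_axis(episodes.index).loc[retained.index]
    rows = []
    for label, sub in retained.groupby(base_kept.values):
        sub_inner = GrouperAssignment(inner_assignment.grouper_name, inner.loc[sub.index])
        cost = sub["total_cost"]
        rv = (
            reduction_in_variance(sub, sub_inner)
            if len(sub) >= 2 and cost.nunique() > 1
            else 0.0
        )
        rows.append(
            {
                "base_group": str(label),
                "n": len(sub),
                "n_inner_groups": sub_inner.labels.nunique(),
                "mean_cost": float(cost.mean()),
                "rv": float(rv),
            }
        )
    per_base = pd.DataFrame(rows).sort_values("base_group").reset_index(drop=True)

    pair = GrouperAssignment(
        f"base x {inner_assignment.grouper_name}",
        base_kept.astype(str) + "|" + inner.loc[retained.index].astype(str),
    )
    pooled = {
        "n": int(len(retained)),
        "n_base_groups": int(per_base.shape[0]),
        "rv": float(reduction_in_variance(retained, pair)),
        "rv_within_base_weighted": float(
            np.average(per_base["rv"], weights=per_base["n"])
        ),
    }
    return StratifiedResult(inner_assignment.grouper_name, per_base, pooled, report)
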