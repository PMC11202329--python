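"""Descriptive grouper comparison: efficiency curves, within-group CV, RV.

Efficiency: the share of total cost and of hospitalizations covered by an
increasing share of a grouper's groups, groups taken in descending order of
the measure of interest. A grouper whose curve hugs the diagonal covers
cost/episodes proportionally; a curve bowed toward the top-left means a few
groups concentrate most of the measure.

Homogeneity: the within-group coefficient of variation (sample SD over
mean, n-1 denominator throughout).

Reduction in variance (RV): the fraction of cost variance explained by the
grouping — one-way ANOVA R², computable on raw euros (default) or on log
cost.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from casemix.errors import DataError
from casemix.groupers import GrouperAssignment


@dataclass(frozen=True)
class EfficiencyCurve:
    """Cumulative coverage of cost and episodes by top groups.

    ``table`` has one row per group, in the sort order, with columns
    ``frac_groups``, ``frac_cost``, ``frac_episodes``, all in [0, 1] and
    non-decreasing; the last row is (1, 1, 1).
    """

    grouper_name: str
    sort_key: str  # 'cost' or 'episodes'
    table: pd.DataFrame


def _grouped_costs(episodes: pd.DataFrame, assignment: GrouperAssignment):
    labels = assignment.labels
    if len(labels) != len(episodes):
        raise DataError(
            f"assignment {assignment.grouper_name} ({len(labels)}) does not "
            f"cover the table ({len(episodes)})"
        )
    return episodes["total_cost"].groupby(labels.set_axis(episodes.index).values)


def group_cv(episodes: pd.DataFrame, assignment: GrouperAssignment) -> pd.DataFrame:
    """Per-group n, total/mean/sample-SD cost and coefficient of variation.

    Singleton groups get sd = cv = 0 with ``singleton`` flagged True; a
    positive-cost table cannot produce a zero mean, so cv is always defined.
    """
    if len(episodes) == 0:
        raise DataError("group_cv: empty episode table")
    g = _grouped_costs(episodes, assignment)
    out = g.agg(n="size", total_cost="sum", mean_cost="mean", sd_cost="std")
    out["sd_cost"] = out["sd_cost"].fillna(0.0)  # n=1 -> NaN under ddof=1
    out["cv"] = out["sd_cost"] / out["mean_cost"]
    out["singleton"] = out["n"] == 1
    out.index.name = "group_label"
    return out.reset_index()


def efficiency_curve(
    episodes: pd.DataFrame,
    assignment: GrouperAssignment,
    sort_key: str = "cost",
) -> EfficiencyCurve:
    """Cumulative (fraction of groups, of cost, of episodes) over top groups.

    Groups are sorted descending by their total of ``sort_key`` ('cost' or
    'episodes'); point k is the coverage achieved by the k largest groups.
    """
    if sort_key not in ("cost", "episodes"):
        raise DataError(f"efficiency_curve: sort_key must be 'cost' or 'episodes', got {sort_key!r}")
    if len(episodes) == 0:
        raise DataError("efficiency_curve: empty episode table")
    g = _grouped_costs(episodes, assignment)
    totals = g.agg(cost="sum", episodes="size")
    by = [sort_key] + [c for c in ("cost", "episodes") if c != sort_key]
    totals = totals.sort_values(by, ascending=False, kind="mergesort")
    n_groups = len(totals)
    table = pd.DataFrame(
        {
            "group_label": totals.index.astype(str),
            "frac_groups": np.arange(1, n_groups + 1) / n_groups,
            "frac_cost": totals["cost"].cumsum().values / totals["cost"].sum(),
            "frac_episodes": totals["episodes"].cumsum().values / totals["episodes"].sum(),
        }
    ).reset_index(drop=True)
    return EfficiencyCurve(assignment.grouper_name, sort_key, table)


def efficiency_summary(curve: EfficiencyCurve) -> float:
    """Scalar concentration index in [0, 1] for an efficiency curve.

    Area between the sorted-coordinate curve and the diagonal, normalized by
    the maximum achievable area for the same number of groups: 0 for a
    perfectly proportional (diagonal) grouper, → 1 when one group out of
    many carries everything.
    """
    key_col = "frac_cost" if curve.sort_key == "cost" else "frac_episodes"
    x = np.concatenate([[0.0], curve.table["frac_groups"].values])
    y = np.concatenate([[0.0], curve.table[key_col].values])
    n_groups = len(curve.table)
    max_area = 0.5 * (1.0 - 1.0 / n_groups)
    if max_area == 0:  # single group: curve and bound coincide
        return 0.0
    area = np.trapezoid(y, x) - 0.5
    return float(np.clip(area / max_area, 0.0, 1.0))


def reduction_in_variance(
    episodes: pd.DataFrame,
    assignment: GrouperAssignment,
    scale: str = "raw",
) -> float:
    """One-way ANOVA R² of cost on the grouping: 1 − SS_within / SS_total.

    ``scale='raw'`` decomposes euro variance; ``scale='log'`` decomposes
    log-euro variance (requires strictly positive costs, which the episode
    schema guarantees).
    """
    if scale not in ("raw", "log"):
        raise DataError(f"reduction_in_variance: scale must be 'raw' or 'log', got {scale!r}")
    if len(episodes) < 2:
        raise DataError("reduction_in_variance: need at least 2 episodes")
    y = episodes["total_cost"].to_numpy(dtype=float)
    if scale == "log":
        if np.any(y <= 0):
            raise DataError("reduction_in_variance: non-positive cost on log scale")
        y = np.log(y)
    ss_total = float(np.sum((y - y.mean()) ** 2))
    if ss_total == 0:
        raise DataError("reduction_in_variance: zero total variance, RV undefined")
    labels = assignment.labels.set_axis(episodes.index)
    group_means = pd.Series(y, index=episodes.index).groupby(labels.values).transform("mean")
    ss_within = float(np.sum((y - group_means.to_numpy()) ** 2))
    return float(np.clip(1.0 - ss_within / ss_total, 0.0, 1.0))
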