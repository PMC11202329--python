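"""Case-mix groupers: Queralt indices, complexity strata, DRG-severity, and filters.

The Queralt system summarizes a hospitalization as additive complexity
indices — QID = QIDP + QIDA + QIDC for diagnoses and QIP = QIPP + QIPS for
procedures — and cuts each index distribution into ordered complexity
strata (D_strata, P_strata). Their Cartesian combination (DP_strata) gives
an exhaustive diagnosis x procedure stratification. The DRG side is the
Cartesian combination of the base DRG group and the severity level.

Strata intervals are half-open [low, high); the lowest stratum is the least
complex. Quantile cut-points that coincide (heavily discrete indices) are
merged with a warning rather than producing empty strata.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from casemix.config import StrataConfig
from casemix.errors import DataError


@dataclass(frozen=True)
class GrouperAssignment:
    """A named per-episode group labelling for one case-mix tool.

    ``labels`` is aligned with the episode table it was built from; for the
    numeric groupers (QID, QIP) it holds index values rather than category
    labels.
    """

    grouper_name: str
    labels: pd.Series

    def __len__(self) -> int:
        return len(self.labels)

    @property
    def n_groups(self) -> int:
        return self.labels.nunique()


def _check_nonnegative(name: str, values) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if np.any(arr < 0):
        raise DataError(f"{name} contains negative index points")
    return arr


def compute_qid(qidp, qida, qidc):
    """Queralt diagnostic index: main diagnosis + comorbidities on admission
    + in-hospital complications, i.e. QIDP + QIDA + QIDC."""
    out = (
        _check_nonnegative("qidp", qidp)
        + _check_nonnegative("qida", qida)
        + _check_nonnegative("qidc", qidc)
    )
    return float(out) if out.ndim == 0 else out


def compute_qip(qipp, qips):
    """Queralt procedure index: main + secondary procedures, QIPP + QIPS."""
    out = _check_nonnegative("qipp", qipp) + _check_nonnegative("qips", qips)
    return float(out) if out.ndim == 0 else out


def make_strata(
    index_values,
    n_strata: int,
    method: str = "quantile",
    cutpoints=None,
) -> pd.Series:
    """Cut a complexity index into ordinal strata labelled 1..k.

    quantile method: interior cut-points at the (i/n)-quantiles of the
    observed distribution; duplicate cut-points (discrete indices) are
    merged, collapsing to fewer strata with a warning. fixed_cutpoints
    method: the supplied ascending thresholds define half-open intervals
    [c_i, c_{i+1}); values below the first cut-point form stratum 1.
    """
    values = np.asarray(index_values, dtype=float)
    if values.size == 0:
        raise DataError("make_strata: empty index vector")
    if n_strata < 1:
        raise DataError(f"make_strata: n_strata must be >= 1, got {n_strata}")

    if method == "quantile":
        qs = np.arange(1, n_strata) / n_strata
        cuts = np.quantile(values, qs) if n_strata > 1 else np.array([])
        unique_cuts = np.unique(cuts)
        if len(unique_cuts) < len(cuts):
            warnings.warn(
                f"make_strata: tied quantile cut-points merged; "
                f"{len(unique_cuts) + 1} strata instead of {n_strata}",
                UserWarning,
                stacklevel=2,
            )
        cuts = unique_cuts
    elif method == "fixed_cutpoints":
        if cutpoints is None:
            raise DataError("make_strata: fixed_cutpoints method requires cutpoints")
        cuts = np.asarray(cutpoints, dtype=float)
        if np.any(np.diff(cuts) <= 0):
            raise DataError("make_strata: cutpoints must be strictly ascending")
    else:
        raise DataError(f"make_strata: unknown method {method!r}")

    # half-open [low, high): a value equal to a cut-point belongs to the
    # stratum above it
    labels = np.searchsorted(cuts, values, side="right") + 1
    index = index_values.index if isinstance(index_values, pd.Series) else None
    return pd.Series(labels, index=index, name="stratum")


def combine_strata(d_labels, p_labels) -> pd.Series:
    """Cartesian DP combination: label 'D{d}|P{p}' per episode."""
    d = pd.Series(d_labels).reset_index(drop=True)
    p = pd.Series(p_labels).reset_index(drop=True)
    if len(d) != len(p):
        raise DataError(
            f"combine_strata: length mismatch ({len(d)} D labels vs {len(p)} P labels)"
        )
    index = d_labels.index if isinstance(d_labels, pd.Series) else None
    out = "D" + d.astype(str) + "|P" + p.astype(str)
    if index is not None:
        out.index = index
    return out.rename("dp_stratum")


def drg_severity(base_group, severity, severity_levels: int = 4) -> pd.Series | str:
    """DRG-severity grouper: the Cartesian pair (base DRG, severity level)."""
    scalar = np.isscalar(base_group) and np.isscalar(severity)
    base = pd.Series([base_group] if scalar else base_group)
    sev = pd.Series([severity] if scalar else severity)
    if len(base) != len(sev):
        raise DataError("drg_severity: base_group and severity lengths differ")
    bad = ~sev.isin(range(1, severity_levels + 1))
    if bad.any():
        raise DataError(
            f"drg_severity: severity out of range 1..{severity_levels}: "
            f"{sorted(sev[bad].unique().tolist())}"
        )
    out = base.astype(str) + "-" + sev.astype(str)
    if scalar:
        return out.iloc[0]
    if isinstance(base_group, pd.Series):
        out.index = base_group.index
    return out.rename("drg_severity")


def assign_groupers(
    episodes: pd.DataFrame, strata: StrataConfig | None = None
) -> dict[str, GrouperAssignment]:
    """Build every grouper the comparison knows about from an episode table."""
    strata = strata or StrataConfig()
    qid = pd.Series(
        compute_qid(episodes["qidp"], episodes["qida"], episodes["qidc"]),
        index=episodes.index,
        name="qid",
    )
    qip = pd.Series(
        compute_qip(episodes["qipp"], episodes["qips"]), index=episodes.index, name="qip"
    )
    d = make_strata(qid, strata.n_d_strata, strata.method, strata.d_cutpoints)
    p = make_strata(qip, strata.n_p_strata, strata.method, strata.p_cutpoints)
    severity_levels = int(episodes["severity"].max())
    return {
        "QID": GrouperAssignment("QID", qid),
        "QIP": GrouperAssignment("QIP", qip),
        "D_strata": GrouperAssignment("D_strata", d.rename("d_stratum")),
        "P_strata": GrouperAssignment("P_strata", p.rename("p_stratum")),
        "DP_strata": GrouperAssignment("DP_strata", combine_strata(d, p)),
        "DRG_Severity": GrouperAssignment(
            "DRG_Severity",
            drg_severity(episodes["base_group"], episodes["severity"], severity_levels),
        ),
    }


def filter_small_groups(
    episodes: pd.DataFrame,
    assignment: GrouperAssignment,
    min_n: int = 25,
) -> tuple[pd.DataFrame, dict]:
    """Drop groups with fewer than ``min_n`` episodes, plus unassignable rows.

    Episodes with a missing label are removed first and counted separately
    from the small-group exclusions. Returns the retained table (original
    row order) and an exclusion report; an empty result is allowed but
    warned about.
    """
    labels = assignment.labels
    if len(labels) != len(episodes):
        raise DataError(
            f"filter_small_groups: assignment ({len(labels)}) does not cover "
            f"the table ({len(episodes)})"
        )
    labels = labels.set_axis(episodes.index)
    assigned = labels.notna()
    n_unassigned = int((~assigned).sum())

    sizes = labels[assigned].value_counts()
    small = sizes[sizes < min_n]
    keep_mask = assigned & labels.isin(sizes[sizes >= min_n].index)
    retained = episodes.loc[keep_mask]

    if len(retained) == 0:
        warnings.warn(
            f"filter_small_groups: no episodes retained for {assignment.grouper_name}",
            UserWarning,
            stacklevel=2,
        )
    report = {
        "grouper_name": assignment.grouper_name,
        "min_n": int(min_n),
        "n_input": int(len(episodes)),
        "n_retained": int(len(retained)),
        "n_removed_small": int(small.sum()),
        "n_removed_unassigned": n_unassigned,
        "removed_groups": {str(k): int(v) for k, v in small.sort_index().items()},
    }
    return retained, report
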