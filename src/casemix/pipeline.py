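"""End-to-end grouper comparison: generate/load → group → filter → evaluate → predict.

``run`` executes the whole study analog for a :class:`RunConfig` and
returns a :class:`ComparisonReport`; if an output directory is configured
it also serializes the report (JSON + per-grouper CSV curve tables).
``render_report`` turns a report into a markdown summary and the standard
figure set (log-cost histogram, efficiency curves, CV distributions,
ROC/PR panels, observed-vs-expected quantiles).

Serialized numbers are never rounded — rounding happens only at render
time — and the JSON carries the config hash and seed, so a rerun with the
same config is byte-identical.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from casemix.config import RunConfig
from casemix.errors import DataError
from casemix.evaluation import (
    EfficiencyCurve,
    efficiency_curve,
    efficiency_summary,
    group_cv,
    reduction_in_variance,
)
from casemix.groupers import GrouperAssignment, assign_groupers, filter_small_groups
from casemix.prediction import (
    CostModelResult,
    ThresholdModelResult,
    fit_lognormal_model,
    fit_numeric_threshold_model,
    fit_threshold_model,
    observed_vs_expected,
    percentile_cutoffs,
)
from casemix.synthetic import generate_population, read_episodes, summarize_costs

NUMERIC_GROUPERS = {"QID", "QIP"}


def _package_version() -> str:
    import casemix

    return casemix.__version__


@dataclass
class GrouperResult:
    """Everything the comparison computes for one grouper."""

    grouper_name: str
    n_groups: int
    exclusion_report: dict
    efficiency_by_cost: EfficiencyCurve
    efficiency_by_episodes: EfficiencyCurve
    concentration_cost: float
    concentration_episodes: float
    cv_table: pd.DataFrame
    rv: float
    threshold_models: list[ThresholdModelResult]
    cost_model: CostModelResult
    ove_table: pd.DataFrame
    ks_statistic: float


@dataclass
class ComparisonReport:
    """Full output of one pipeline run, mirroring the study's result set."""

    config: RunConfig
    n_episodes: int
    demographics: pd.DataFrame
    cutoffs: dict[float, float]
    groupers: dict[str, GrouperResult]
    metadata: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        """JSON-serializable form; numbers at full precision."""
        out = {
            "metadata": self.metadata,
            "n_episodes": self.n_episodes,
            "cutoffs": {f"p{p:g}": c for p, c in self.cutoffs.items()},
            "demographics": self.demographics.to_dict(orient="records"),
            "groupers": {},
        }
        for name, g in self.groupers.items():
            out["groupers"][name] = {
                "n_groups": g.n_groups,
                "exclusions": g.exclusion_report,
                "concentration_cost": g.concentration_cost,
                "concentration_episodes": g.concentration_episodes,
                "rv": g.rv,
                "cv_median": float(g.cv_table["cv"].median()),
                "cv_iqr": [
                    float(g.cv_table["cv"].quantile(0.25)),
                    float(g.cv_table["cv"].quantile(0.75)),
                ],
                "threshold_models": [
                    {
                        "percentile": m.percentile,
                        "cutoff": m.cutoff,
                        "prevalence": m.prevalence,
                        "auroc": m.auroc,
                        "auprc": m.auprc,
                        "n_separated_groups": len(m.separated_groups),
                    }
                    for m in g.threshold_models
                ],
                "cost_model": {
                    "model": g.cost_model.model,
                    "residual_log_sd": g.cost_model.residual_log_sd,
                    "rv_of_predictions": g.cost_model.rv_of_predictions,
                    "ks_statistic": g.ks_statistic,
                },
            }
        return out


def _load_episodes(config: RunConfig) -> pd.DataFrame:
    if "file" in config.source:
        return read_episodes(config.source["file"])
    return generate_population(config.generator_config())


def _stage(name: str, grouper: str | None = None):
    where = f"stage '{name}'" + (f", grouper '{grouper}'" if grouper else "")
    return where


def run(config: RunConfig) -> ComparisonReport:
    """Execute the full comparison; deterministic given the config seed."""
    episodes = _load_episodes(config)
    if len(episodes) < 2:
        raise DataError("pipeline run: need at least 2 episodes")
    assignments = assign_groupers(episodes, config.strata)

    demographics = summarize_costs(episodes)
    cutoffs = percentile_cutoffs(episodes["total_cost"], config.percentiles)

    results: dict[str, GrouperResult] = {}
    for name in config.groupers:
        assignment = assignments[name]
        try:
            results[name] = _run_grouper(episodes, assignment, cutoffs, config)
        except DataError as err:
            raise DataError(f"{_stage('analysis', name)}: {err}") from err

    report = ComparisonReport(
        config=config,
        n_episodes=len(episodes),
        demographics=demographics,
        cutoffs=cutoffs,
        groupers=results,
        metadata={
            "config_hash": config.config_hash(),
            "seed": config.seed,
            "package_version": _package_version(),
            "config": config.analysis_dict(),
        },
    )
    if config.output_dir is not None:
        write_report(report, Path(config.output_dir))
    return report


def _run_grouper(
    episodes: pd.DataFrame,
    assignment: GrouperAssignment,
    cutoffs: dict[float, float],
    config: RunConfig,
) -> GrouperResult:
    numeric = assignment.grouper_name in NUMERIC_GROUPERS
    # the <25 filter applies to categorical groupers, as it does to DRG base
    # groups in the study design; numeric indices are not groups
    if numeric:
        retained, excl = episodes, {
            "grouper_name": assignment.grouper_name,
            "min_n": None,
            "n_input": int(len(episodes)),
            "n_retained": int(len(episodes)),
            "n_removed_small": 0,
            "n_removed_unassigned": 0,
            "removed_groups": {},
        }
        kept = assignment
    else:
        retained, excl = filter_small_groups(episodes, assignment, config.min_group_n)
        if len(retained) == 0:
            raise DataError("no group survives the minimum-size filter")
        kept = GrouperAssignment(
            assignment.grouper_name,
            assignment.labels.set_axis(episodes.index).loc[retained.index],
        )

    eff_cost = efficiency_curve(retained, kept, sort_key="cost")
    eff_epi = efficiency_curve(retained, kept, sort_key="episodes")
    cv_table = group_cv(retained, kept)
    rv = reduction_in_variance(retained, kept, scale=config.rv_scale)

    threshold_models = []
    for p, cutoff in cutoffs.items():
        if numeric or config.predictor == "numeric":
            model = fit_numeric_threshold_model(retained, kept, cutoff, percentile=p)
        else:
            model = fit_threshold_model(retained, kept, cutoff, percentile=p)
        threshold_models.append(model)

    cost_model = fit_lognormal_model(retained, kept, model=config.cost_model)
    ove_table, ks = observed_vs_expected(retained, cost_model)

    return GrouperResult(
        grouper_name=assignment.grouper_name,
        n_groups=kept.n_groups,
        exclusion_report=excl,
        efficiency_by_cost=eff_cost,
        efficiency_by_episodes=eff_epi,
        concentration_cost=efficiency_summary(eff_cost),
        concentration_episodes=efficiency_summary(eff_epi),
        cv_table=cv_table,
        rv=rv,
        threshold_models=threshold_models,
        cost_model=cost_model,
        ove_table=ove_table,
        ks_statistic=ks,
    )


def write_report(report: ComparisonReport, out_dir: Path) -> None:
    """Serialize a report: report.json plus per-grouper CSV curve tables."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    with open(out_dir / "report.json", "w") as fh:
        json.dump(report.to_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")
    report.demographics.to_csv(out_dir / "demographics.csv", index=False)
    for name, g in report.groupers.items():
        gdir = out_dir / name
        gdir.mkdir(exist_ok=True)
        g.efficiency_by_cost.table.to_csv(gdir / "efficiency_by_cost.csv", index=False)
        g.efficiency_by_episodes.table.to_csv(gdir / "efficiency_by_episodes.csv", index=False)
        g.cv_table.to_csv(gdir / "group_cv.csv", index=False)
        g.ove_table.to_csv(gdir / "observed_vs_expected.csv", index=False)
        for m in g.threshold_models:
            tag = f"p{m.percentile:g}"
            m.roc_points.to_csv(gdir / f"roc_{tag}.csv", index=False)
            m.pr_points.to_csv(gdir / f"pr_{tag}.csv", index=False)


def load_report_dict(run_dir: Path) -> dict:
    path = Path(run_dir) / "report.json"
    if not path.exists():
        raise DataError(f"no report.json under {run_dir}")
    with open(path) as fh:
        return json.load(fh)


def render_report(report: ComparisonReport, out_dir: Path, figures: bool = True) -> Path:
    """Write a human-readable markdown summary (and figures) for a report.

    Returns the path of the markdown file. Numbers are rounded here, and
    only here.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    lines = ["# Case-mix grouper comparison", ""]
    meta = report.metadata
    lines += [
        f"- episodes analysed: {report.n_episodes:,}",
        f"- seed: {meta.get('seed')} | config hash: {meta.get('config_hash')}",
        f"- high-cost cut-offs (EUR): "
        + ", ".join(f"p{p:g} = {c:,.0f}" for p, c in report.cutoffs.items()),
        "",
        "## Costs by demographics",
        "",
        report.demographics.round(1).to_markdown(index=False),
        "",
        "## Grouper comparison",
        "",
    ]
    rows = []
    for name, g in report.groupers.items():
        row = {
            "grouper": name,
            "groups": g.n_groups,
            "RV": round(g.rv, 3),
            "conc(cost)": round(g.concentration_cost, 3),
            "CV median": round(float(g.cv_table["cv"].median()), 3),
            "KS": round(g.ks_statistic, 3),
        }
        for m in g.threshold_models:
            row[f"AUROC p{m.percentile:g}"] = round(m.auroc, 3)
            row[f"AUPRC p{m.percentile:g}"] = round(m.auprc, 3)
        rows.append(row)
    lines += [pd.DataFrame(rows).to_markdown(index=False), ""]

    if figures:
        fig_dir = out_dir / "figures"
        _render_figures(report, fig_dir)
        lines += ["## Figures", ""]
        lines += [f"![{p.stem}](figures/{p.name})" for p in sorted(fig_dir.glob("*.png"))]
        lines.append("")

    md = out_dir / "summary.md"
    md.write_text("\n".join(lines))
    return md


def _render_figures(report: ComparisonReport, fig_dir: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig_dir.mkdir(parents=True, exist_ok=True)
    names = list(report.groupers)

    # efficiency curves, one axes per sort key
    for key, attr in (("cost", "efficiency_by_cost"), ("episodes", "efficiency_by_episodes")):
        fig, ax = plt.subplots(figsize=(5, 5))
        for name in names:
            t = getattr(report.groupers[name], attr).table
            ax.plot(
                np.r_[0, t["frac_groups"]],
                np.r_[0, t[f"frac_{key}"]],
                label=name,
            )
        ax.plot([0, 1], [0, 1], "k--", lw=0.8, label="proportional")
        ax.set_xlabel("fraction of groups")
        ax.set_ylabel(f"fraction of {key}")
        ax.set_title(f"Efficiency ({key})")
        ax.legend(fontsize=8)
        fig.tight_layout()
        fig.savefig(fig_dir / f"efficiency_{key}.png", dpi=120)
        plt.close(fig)

    # CV distribution per grouper
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.boxplot(
        [report.groupers[n].cv_table["cv"].to_numpy() for n in names],
        tick_labels=names,
        showfliers=False,
    )
    ax.axhline(1.0, color="grey", lw=0.8, ls=":")
    ax.set_ylabel("within-group CV of cost")
    fig.tight_layout()
    fig.savefig(fig_dir / "cv_distribution.png", dpi=120)
    plt.close(fig)

    # ROC / PR panels per percentile
    percentiles = [m.percentile for m in report.groupers[names[0]].threshold_models]
    for kind in ("roc", "pr"):
        fig, axes = plt.subplots(1, len(percentiles), figsize=(4 * len(percentiles), 4))
        axes = np.atleast_1d(axes)
        for ax, p in zip(axes, percentiles):
            for name in names:
                m = next(m for m in report.groupers[name].threshold_models if m.percentile == p)
                if kind == "roc":
                    ax.plot(m.roc_points["fpr"], m.roc_points["tpr"], label=f"{name} ({m.auroc:.3f})")
                    ax.plot([0, 1], [0, 1], "k--", lw=0.6)
                    ax.set_xlabel("FPR")
                    ax.set_ylabel("TPR")
                else:
                    ax.plot(m.pr_points["recall"], m.pr_points["precision"], label=f"{name} ({m.auprc:.3f})")
                    ax.axhline(m.prevalence, color="grey", lw=0.6, ls=":")
                    ax.set_xlabel("recall")
                    ax.set_ylabel("precision")
            ax.set_title(f"p{p:g}")
            ax.legend(fontsize=7)
        fig.tight_layout()
        fig.savefig(fig_dir / f"{kind}_curves.png", dpi=120)
        plt.close(fig)

    # observed vs expected quantiles
    fig, ax = plt.subplots(figsize=(6, 4))
    for name in names:
        t = report.groupers[name].ove_table
        ax.plot(t["observed"], t["expected"], "o-", ms=3, label=name)
    lims = ax.get_xlim()
    ax.plot(lims, lims, "k--", lw=0.6)
    ax.set_xscale("log")
    ax.set_yscale("log")
    ax.set_xlabel("observed cost quantile (EUR)")
    ax.set_ylabel("expected cost quantile (EUR)")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(fig_dir / "observed_vs_expected.png", dpi=120)
    plt.close(fig)
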