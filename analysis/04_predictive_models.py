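#!/usr/bin/env python
"""Fit the predictive models per grouper: high-cost classification and
lognormal actual-cost regression.

High-cost outcomes at the 80th/90th/95th cost percentiles are classified
by the saturated logistic model of each grouper (per-group empirical
rates); ranking quality is summarized by AUROC and AUPRC. The lognormal
regression's expected costs are compared to the observed distribution via
a KS distance. Writes results/model_performance.csv and
results/observed_vs_expected.csv and prints which grouper wins where.
"""

from pathlib import Path

import pandas as pd

from casemix.groupers import GrouperAssignment, assign_groupers, filter_small_groups
from casemix.prediction import (
    fit_lognormal_model,
    fit_threshold_model,
    observed_vs_expected,
    percentile_cutoffs,
)
from casemix.synthetic import read_episodes

ROOT = Path(__file__).resolve().parents[1]
GROUPERS = ("D_strata", "P_strata", "DP_strata", "DRG_Severity")


def main() -> None:
    episodes_path = ROOT / "scratch" / "episodes.csv"
    if not episodes_path.exists():
        raise SystemExit("scratch/episodes.csv not found — run analysis/01_simulate.py first")
    episodes = read_episodes(episodes_path)
    assignments = assign_groupers(episodes)
    cutoffs = percentile_cutoffs(episodes["total_cost"], (80, 90, 95))
    results = ROOT / "results"
    results.mkdir(exist_ok=True)

    perf_rows, ove_rows = [], []
    for name in GROUPERS:
        retained, _ = filter_small_groups(episodes, assignments[name], min_n=25)
        kept = GrouperAssignment(
            name, assignments[name].labels.set_axis(episodes.index).loc[retained.index]
        )
        for p, cut in cutoffs.items():
            m = fit_threshold_model(retained, kept, cut, percentile=p)
            perf_rows.append(
                {
                    "grouper": name,
                    "percentile": p,
                    "cutoff_eur": cut,
                    "prevalence": m.prevalence,
                    "auroc": m.auroc,
                    "auprc": m.auprc,
                }
            )
        cost_model = fit_lognormal_model(retained, kept)
        qtable, ks = observed_vs_expected(retained, cost_model)
        qtable.insert(0, "grouper", name)
        qtable["ks"] = ks
        ove_rows.append(qtable)

    perf = pd.DataFrame(perf_rows)
    perf.to_csv(results / "model_performance.csv", index=False)
    pd.concat(ove_rows).to_csv(results / "observed_vs_expected.csv", index=False)

    print(perf.round(3).to_string(index=False))
    for p in sorted({r["percentile"] for r in perf_rows}):
        sub = perf[perf.percentile == p]
        print(
            f"p{p:g}: best AUROC {sub.loc[sub.auroc.idxmax(), 'grouper']}, "
            f"best AUPRC {sub.loc[sub.auprc.idxmax(), 'grouper']}"
        )
    print("-> results/model_performance.csv, results/observed_vs_expected.csv")


if __name__ == "__main__":
    main()
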