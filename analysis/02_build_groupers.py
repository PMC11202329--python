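#!/usr/bin/env python
"""Build every case-mix grouper on the simulated population and apply the
25-episode eligibility filter.

Reads scratch/episodes.csv (run 01_simulate.py first); writes the per-
grouper group counts and exclusion report to results/, and prints how many
groups each tool yields — the Queralt DP grid should land near its ~600
group design target, the DRG-severity cross near base_groups x 4.
"""

import json
from pathlib import Path

import pandas as pd

from casemix.groupers import assign_groupers, filter_small_groups
from casemix.synthetic import read_episodes

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    episodes_path = ROOT / "scratch" / "episodes.csv"
    if not episodes_path.exists():
        raise SystemExit("scratch/episodes.csv not found — run analysis/01_simulate.py first")
    episodes = read_episodes(episodes_path)
    assignments = assign_groupers(episodes)

    rows, exclusions = [], {}
    for name in ("D_strata", "P_strata", "DP_strata", "DRG_Severity"):
        a = assignments[name]
        retained, report = filter_small_groups(episodes, a, min_n=25)
        exclusions[name] = report
        rows.append(
            {
                "grouper": name,
                "groups_observed": a.n_groups,
                "groups_retained": a.n_groups - len(report["removed_groups"]),
                "episodes_retained": report["n_retained"],
                "episodes_removed_small_groups": report["n_removed_small"],
            }
        )
        a.labels.set_axis(episodes["episode_id"]).rename("label").to_csv(
            ROOT / "scratch" / f"assignment_{name}.csv"
        )

    results = ROOT / "results"
    results.mkdir(exist_ok=True)
    counts = pd.DataFrame(rows)
    counts.to_csv(results / "grouper_group_counts.csv", index=False)
    with open(results / "grouper_exclusions.json", "w") as fh:
        json.dump(exclusions, fh, indent=2)

    print(counts.to_string(index=False))
    print("-> results/grouper_group_counts.csv, results/grouper_exclusions.json")


if __name__ == "__main__":
    main()
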