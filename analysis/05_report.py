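#!/usr/bin/env python
"""Run the full pipeline end to end and render the comparison report.

Equivalent to `casemix-eval run` on the default configuration: writes the
serialized report (JSON + curve CSVs) to results/report/ and the rendered
markdown summary with figures to results/report/summary.md.
"""

from pathlib import Path

from casemix import pipeline
from casemix.config import RunConfig

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    # the serialized run (curve CSVs per group, figures) is bulky -> scratch/
    out = ROOT / "scratch" / "report"
    report = pipeline.run(RunConfig(output_dir=str(out)))
    md = pipeline.render_report(report, out)
    for name, g in report.groupers.items():
        aucs = ", ".join(
            f"p{m.percentile:g} {m.auroc:.3f}/{m.auprc:.3f}" for m in g.threshold_models
        )
        print(f"{name}: {g.n_groups} groups, RV {g.rv:.3f}, AUROC/AUPRC {aucs}")
    print(f"-> {md}")


if __name__ == "__main__":
    main()
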