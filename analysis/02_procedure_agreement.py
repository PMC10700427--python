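#!/usr/bin/env python
"""Compare the three procedures' PSE and JND estimates per experiment.

Loads the cohorts simulated by 01_simulate_cohorts.py, screens outliers
(Sn, criterion 3), and computes the pairwise correlation table and
Bland-Altman agreement reports for both measures, writing
results/exp{N}/report.json, correlations.csv, agreement.csv and the
agreement/boxplot figures.
"""

from pathlib import Path

from psychocompare.cli import _load_bundle
from psychocompare.runner import make_report

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    for exp in (1, 2, 3):
        run_dir = RESULTS / f"exp{exp}"
        if not (run_dir / "trials.csv").exists():
            print(f"experiment {exp}: no simulated cohort found, run 01 first")
            continue
        bundle = _load_bundle(run_dir)
        report = make_report(bundle, run_dir, plots=True)
        print(f"\nexperiment {exp} ({bundle.config.units}):")
        for key, entry in report["correlations"].items():
            stat = "r" if entry["method"] == "pearson" else "r_s"
            print(f"  {key:28s} {stat} = {entry['r']:+.2f}  (p = {entry['p']:.3g})")
        spans = [v["agreement_span"] for k, v in report["agreement"].items() if k.startswith("pse")]
        print(f"  PSE agreement spans: {min(spans):.3g} - {max(spans):.3g} {bundle.config.units}")
        if report["excluded"]["ceiling"] or report["excluded"]["outliers"]:
            print(f"  excluded observers: {report['excluded']}")


if __name__ == "__main__":
    main()
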