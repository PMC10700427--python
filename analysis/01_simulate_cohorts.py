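#!/usr/bin/env python
"""Simulate full cohorts for the three discrimination experiments.

For each experiment (size, orientation, temporal order) this draws a
20-observer cohort inside the adaptive-grid parameter domain, runs every
observer through the three procedures in counterbalanced order, fits the
psychometric model to each procedure's trials, and writes the trial logs
and the estimates table under results/exp{1,2,3}/.
"""

import argparse
import time
from pathlib import Path

from psychocompare.runner import run_replication

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--n-observers", type=int, default=20)
    parser.add_argument("--seed", type=int, default=1)
    args = parser.parse_args()

    for exp in (1, 2, 3):
        t0 = time.time()
        out = RESULTS / f"exp{exp}"
        bundle = run_replication(
            exp, n_observers=args.n_observers, master_seed=args.seed, out_dir=out
        )
        per_proc = bundle.trials.groupby("procedure").size()
        print(
            f"experiment {exp}: {args.n_observers} observers, "
            f"{len(bundle.trials)} trials "
            f"(questplus {per_proc['questplus']}, cs {per_proc['cs']}, "
            f"staircase {per_proc['staircase']}) "
            f"in {time.time() - t0:.1f}s -> {out}"
        )


if __name__ == "__main__":
    main()
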