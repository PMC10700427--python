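"""Method of constant stimuli: fixed designs, seeded random administration.

Each experiment presents nine core stimulus values many times each, plus a
few extreme values inserted less often, in a fully randomized order:

* experiment 1 — diameters 1.3:0.1:1.9 dva, 24 repetitions each, plus the
  extremes 1.2 and 2.0 dva 8 times each (184 trials);
* experiment 2 — tilt differences -9:3:9 deg, 24 each, plus +-15 deg
  8 times each (184 trials);
* experiment 3 — signed SOAs +-{3,6,9,12,15,18} frames 12 times per sign
  (sign balanced: which gabor leads), plus 0 x12 and +-24, +-30 x6 each
  (180 trials).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .configs import get_experiment
from .psychometric import TrialRecord

__all__ = ["CSDesign", "build_design", "run_cs"]


@dataclass(frozen=True)
class CSDesign:
    experiment: int
    schedule: tuple[tuple[float, int], ...]

    @property
    def n_trials(self) -> int:
        return sum(count for _, count in self.schedule)

    def trial_multiset(self) -> np.ndarray:
        values = np.concatenate(
            [np.full(count, value, float) for value, count in self.schedule]
        )
        return values


def build_design(experiment: int) -> CSDesign:
    """The printed constant-stimuli schedule for experiment 1, 2, or 3."""
    cfg = get_experiment(experiment)
    return CSDesign(experiment=cfg.experiment, schedule=cfg.cs_schedule)


def run_cs(observer, design: CSDesign, seed: int, block: int = 1) -> list[TrialRecord]:
    """Administer the design in a seeded uniformly random order."""
    rng = np.random.default_rng(seed)
    order = rng.permutation(design.trial_multiset())
    records = []
    for i, x in enumerate(order, start=1):
        records.append(
            TrialRecord(
                trial_index=i,
                stimulus=float(x),
                response=observer.respond(float(x), block=block),
                procedure="cs",
                block=block,
            )
        )
    return records
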