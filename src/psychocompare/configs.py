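"""Experiment definitions for the three discrimination tasks.

Each experiment compares a test stimulus to a fixed reference along one
physical dimension:

* experiment 1 — disk-size discrimination in central vision; stimulus is the
  test-disk diameter in degrees of visual angle (dva), reference 1.6 dva.
* experiment 2 — gabor-orientation discrimination in peripheral vision;
  stimulus is the tilt-angle difference from the reference in degrees
  (reference difference 0).
* experiment 3 — temporal-order judgment; stimulus is the signed
  stimulus-onset asynchrony (SOA) in display frames (1 frame = 4.2 ms),
  reference 0 (simultaneity).

The dataclasses below carry, for each experiment, the stimulus domain and
trivariate (m, sd, lapse) grid used by the Bayesian adaptive procedure, the
constant-stimuli schedule, the staircase configuration, and the bounds used
for maximum-likelihood fitting. Configs can also be loaded from YAML/JSON
mappings with the same field names.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
import numpy as np

from .staircase import StaircaseConfig

__all__ = ["ExperimentConfig", "get_experiment", "EXPERIMENT_IDS", "config_hash"]

EXPERIMENT_IDS = (1, 2, 3)


def _grid(lo: float, hi: float, step: float, decimals: int = 6) -> np.ndarray:
    n = int(round((hi - lo) / step)) + 1
    return np.round(np.linspace(lo, hi, n), decimals)


@dataclass(frozen=True)
class ExperimentConfig:
    experiment: int
    units: str
    reference: float
    stimulus_domain: np.ndarray
    m_values: np.ndarray
    sd_values: np.ndarray
    lapse_values: np.ndarray
    cs_schedule: tuple[tuple[float, int], ...]
    staircase: StaircaseConfig

    @property
    def fit_bounds(self) -> list[tuple[float, float]]:
        """(m, sd, lapse) box for ML fitting, matching the adaptive grid."""
        return [
            (float(self.m_values.min()), float(self.m_values.max())),
            (float(self.sd_values.min()), float(self.sd_values.max())),
            (float(self.lapse_values.min()), float(self.lapse_values.max())),
        ]

    def to_jsonable(self) -> dict:
        return {
            "experiment": int(self.experiment),
            "units": self.units,
            "reference": float(self.reference),
            "stimulus_domain": self.stimulus_domain.tolist(),
            "m_values": self.m_values.tolist(),
            "sd_values": self.sd_values.tolist(),
            "lapse_values": self.lapse_values.tolist(),
            "cs_schedule": [[float(v), int(c)] for v, c in self.cs_schedule],
            "staircase": {
                "start_values": [float(v) for v in self.staircase.start_values],
                "step_schedule": [
                    [None if t is None else int(t), float(s)]
                    for t, s in self.staircase.step_schedule
                ],
                "domain_bounds": [float(v) for v in self.staircase.domain_bounds],
                "max_reversals": self.staircase.max_reversals,
                "max_boundary_hits": self.staircase.max_boundary_hits,
                "max_total_trials": self.staircase.max_total_trials,
                "reversals_for_threshold": self.staircase.reversals_for_threshold,
            },
        }


def config_hash(config: ExperimentConfig) -> str:
    """SHA-256 of the canonicalized config, for provenance headers."""
    payload = json.dumps(config.to_jsonable(), sort_keys=True, separators=(",", ":"))
    return hashlib.sha256(payload.encode()).hexdigest()


def _exp1() -> ExperimentConfig:
    # size task: diameters 1.2-2.0 dva; CS: 1.3:0.1:1.9 x24 plus extremes x8
    schedule = tuple((round(v, 2), 24) for v in np.arange(1.3, 1.95, 0.1)) + (
        (1.2, 8),
        (2.0, 8),
    )
    return ExperimentConfig(
        experiment=1,
        units="dva",
        reference=1.6,
        stimulus_domain=_grid(1.2, 2.0, 0.01),
        m_values=_grid(1.2, 2.0, 0.01),
        sd_values=_grid(0.02, 0.3, 0.01),
        lapse_values=_grid(0.0, 0.06, 0.01),
        cs_schedule=schedule,
        staircase=StaircaseConfig(
            start_values=(1.2, 1.6, 2.0),
            step_schedule=((2, 0.2), (None, 0.1)),
            domain_bounds=(1.2, 2.0),
        ),
    )


def _exp2() -> ExperimentConfig:
    # orientation task: tilt differences; CS: -9:3:9 x24 plus +-15 x8
    schedule = tuple((float(v), 24) for v in range(-9, 10, 3)) + (
        (-15.0, 8),
        (15.0, 8),
    )
    return ExperimentConfig(
        experiment=2,
        units="deg",
        reference=0.0,
        stimulus_domain=_grid(-24.0, 24.0, 2.0),
        m_values=_grid(-24.0, 24.0, 2.0),
        sd_values=_grid(1.0, 20.0, 0.1),
        lapse_values=_grid(0.0, 0.08, 0.01),
        cs_schedule=schedule,
        staircase=StaircaseConfig(
            # starts sit outside the +-24 bounds as designed; values are
            # presented as given and clamped from the first step onward
            start_values=(-28.0, 0.0, 28.0),
            step_schedule=((2, 4.0), (None, 2.0)),
            domain_bounds=(-24.0, 24.0),
        ),
    )


def _exp3() -> ExperimentConfig:
    # temporal-order task: signed SOAs in frames. CS: +-{3..18 by 3} x12 per
    # sign (24 per magnitude), plus 0 x12 and +-24, +-30 x6 each -> 180.
    magnitudes = [3, 6, 9, 12, 15, 18]
    schedule = tuple((float(s * v), 12) for v in magnitudes for s in (1, -1)) + (
        (0.0, 12),
        (24.0, 6),
        (-24.0, 6),
        (30.0, 6),
        (-30.0, 6),
    )
    return ExperimentConfig(
        experiment=3,
        units="frames",
        reference=0.0,
        stimulus_domain=_grid(-60.0, 60.0, 1.0),
        m_values=_grid(-40.0, 40.0, 1.0),
        sd_values=_grid(1.0, 50.0, 1.0),
        lapse_values=_grid(0.0, 0.08, 0.01),
        cs_schedule=schedule,
        staircase=StaircaseConfig(
            start_values=(-40.0, 0.0, 40.0),
            step_schedule=((2, 4.0), (3, 3.0), (None, 2.0)),
            domain_bounds=(-40.0, 40.0),
        ),
    )


_BUILDERS = {1: _exp1, 2: _exp2, 3: _exp3}


def get_experiment(experiment: int) -> ExperimentConfig:
    """Return the built-in configuration for experiment 1, 2, or 3."""
    try:
        return _BUILDERS[int(experiment)]()
    except (KeyError, ValueError):
        raise ValueError(f"unknown experiment id: {experiment!r}") from None


def from_mapping(data: dict) -> ExperimentConfig:
    """Build a configuration from a plain mapping (parsed YAML/JSON).

    The mapping uses the same field names as :meth:`ExperimentConfig.to_jsonable`,
    so a dumped config loads back unchanged.
    """
    sc = data["staircase"]
    config = ExperimentConfig(
        experiment=int(data["experiment"]),
        units=str(data["units"]),
        reference=float(data["reference"]),
        stimulus_domain=np.asarray(data["stimulus_domain"], float),
        m_values=np.asarray(data["m_values"], float),
        sd_values=np.asarray(data["sd_values"], float),
        lapse_values=np.asarray(data["lapse_values"], float),
        cs_schedule=tuple((float(v), int(c)) for v, c in data["cs_schedule"]),
        staircase=StaircaseConfig(
            start_values=tuple(float(v) for v in sc["start_values"]),
            step_schedule=tuple(
                (None if t is None else int(t), float(s))
                for t, s in sc["step_schedule"]
            ),
            domain_bounds=tuple(float(v) for v in sc["domain_bounds"]),
            max_reversals=int(sc.get("max_reversals", 15)),
            max_boundary_hits=int(sc.get("max_boundary_hits", 10)),
            max_total_trials=int(sc.get("max_total_trials", 150)),
            reversals_for_threshold=int(sc.get("reversals_for_threshold", 5)),
        ),
    )
    _validate(config)
    return config


def _validate(config: ExperimentConfig) -> None:
    """Cross-validate the domains at load time."""
    for name in ("stimulus_domain", "m_values", "sd_values", "lapse_values"):
        arr = getattr(config, name)
        if arr.size == 0 or np.any(np.diff(arr) <= 0):
            raise ValueError(f"{name} must be non-empty and strictly increasing")
    if config.lapse_values.min() < 0 or config.lapse_values.max() >= 0.5:
        raise ValueError("lapse grid must lie in [0, 0.5)")
    if any(count <= 0 for _, count in config.cs_schedule):
        raise ValueError("constant-stimuli repetition counts must be positive")


def load_experiment(path) -> ExperimentConfig:
    """Load a configuration from a YAML or JSON file."""
    import yaml

    with open(path) as fh:
        return from_mapping(yaml.safe_load(fh))
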