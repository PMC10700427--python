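"""Seeded simulated observers and cohorts.

A simulated observer replaces a human participant: it answers yes/no
discrimination trials by Bernoulli draws from the lapse-corrected
cumulative-Gaussian model, with true parameters drawn inside the
experiment's adaptive-grid domain. An optional per-block multiplicative
``drift`` on sd emulates the fast perceptual/procedural learning seen in
the peripheral-vision tasks (sensitivity improving, i.e. sd shrinking,
across the session's three procedure blocks); the default (1, 1, 1) is a
stationary observer.

Each observer carries its own response RNG stream, derived from the cohort
master seed and the observer index, so procedure-level stimulus randomness
(staircase interleaving, CS shuffling) never perturbs responses.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .configs import ExperimentConfig
from .psychometric import PsychometricParams, predict_p_yes

__all__ = [
    "SimulatedObserver",
    "CohortSpec",
    "sample_cohort",
    "PROCEDURE_ORDERS",
    "observer_seed",
]

#: the six counterbalanced orders in which the three procedures can be run
PROCEDURE_ORDERS: tuple[tuple[str, str, str], ...] = tuple(
    itertools.permutations(("questplus", "cs", "staircase"))
)


def observer_seed(master_seed: int, index: int) -> int:
    """Deterministic per-observer seed below 2**31."""
    return int(np.random.SeedSequence([master_seed, index]).generate_state(1)[0] % (2**31))


@dataclass
class SimulatedObserver:
    true_params: PsychometricParams
    drift: tuple[float, float, float] = (1.0, 1.0, 1.0)
    response_mapping: str = "yes-high"  # which response category means "yes"
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if any(d <= 0 for d in self.drift):
            raise ValueError("drift factors must be positive")
        self._rng = np.random.default_rng(self.rng_seed)

    def params_for_block(self, block: int) -> PsychometricParams:
        if block not in (1, 2, 3):
            raise ValueError(f"block must be 1, 2 or 3, got {block}")
        p = self.true_params
        return PsychometricParams(p.m, p.sd * self.drift[block - 1], p.lapse)

    def respond(self, x: float, block: int = 1) -> int:
        """Draw one binary response to stimulus ``x`` (1 = "yes")."""
        p = predict_p_yes(self.params_for_block(block), x)
        return int(self._rng.random() < p)

    def reset_rng(self) -> None:
        """Rewind the response stream (for reproducible re-runs)."""
        self._rng = np.random.default_rng(self.rng_seed)


@dataclass
class CohortSpec:
    """Sampling plan for a cohort of simulated observers.

    Default samplers: m uniform over the central 60% of the grid's mean
    domain, sd log-uniform over the central half (in log space) of the sd
    domain, lapse uniform over the full lapse domain. Keeping true
    parameters away from grid edges avoids the boundary pathologies that
    the human study handled by excluding participants.
    """

    config: ExperimentConfig
    n_observers: int = 20
    master_seed: int = 0
    drift: tuple[float, float, float] = (1.0, 1.0, 1.0)
    m_range: Optional[tuple[float, float]] = None
    sd_range: Optional[tuple[float, float]] = None
    lapse_range: Optional[tuple[float, float]] = None

    def resolved_ranges(self) -> dict:
        cfg = self.config
        m_lo, m_hi = float(cfg.m_values.min()), float(cfg.m_values.max())
        span = m_hi - m_lo
        m_range = self.m_range or (m_lo + 0.2 * span, m_hi - 0.2 * span)
        s_lo, s_hi = float(cfg.sd_values.min()), float(cfg.sd_values.max())
        log_lo, log_hi = np.log(s_lo), np.log(s_hi)
        sd_range = self.sd_range or (
            float(np.exp(log_lo + 0.25 * (log_hi - log_lo))),
            float(np.exp(log_lo + 0.75 * (log_hi - log_lo))),
        )
        lapse_range = self.lapse_range or (
            float(cfg.lapse_values.min()),
            float(cfg.lapse_values.max()),
        )
        for name, (lo, hi), (dlo, dhi) in (
            ("m", m_range, (m_lo, m_hi)),
            ("sd", sd_range, (s_lo, s_hi)),
            ("lapse", lapse_range, (float(cfg.lapse_values.min()), float(cfg.lapse_values.max()))),
        ):
            if lo < dlo or hi > dhi:
                raise ValueError(f"{name} sampling range ({lo}, {hi}) escapes the grid domain")
        return {"m": m_range, "sd": sd_range, "lapse": lapse_range}


def sample_cohort(spec: CohortSpec) -> list[SimulatedObserver]:
    """Draw the cohort's true parameters and per-observer RNG seeds.

    Fully deterministic under ``master_seed``. Procedure orders are assigned
    by the runner, cycling through the six permutations.
    """
    ranges = spec.resolved_ranges()
    rng = np.random.default_rng(np.random.SeedSequence([spec.master_seed, 791111]))
    observers = []
    for i in range(spec.n_observers):
        m = rng.uniform(*ranges["m"])
        sd = float(np.exp(rng.uniform(np.log(ranges["sd"][0]), np.log(ranges["sd"][1]))))
        lapse = rng.uniform(*ranges["lapse"])
        observers.append(
            SimulatedObserver(
                true_params=PsychometricParams(float(m), sd, float(lapse)),
                drift=spec.drift,
                rng_seed=observer_seed(spec.master_seed, i),
            )
        )
    return observers


def assigned_orders(n_observers: int) -> list[tuple[str, str, str]]:
    """Counterbalanced procedure orders, cycling the six permutations."""
    return [PROCEDURE_ORDERS[i % 6] for i in range(n_observers)]
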