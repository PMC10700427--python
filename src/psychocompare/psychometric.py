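"""Lapse-corrected cumulative-Gaussian psychometric model.

The model shared by every procedure in this package: the probability of a
"yes" response (test judged larger / more clockwise / first) to a stimulus
value ``x`` is

    P_yes(x) = lapse + (1 - 2*lapse) * 0.5 * (1 + erf((x - m) / (sd * sqrt(2))))

where ``m`` is the mean of the underlying normal distribution (the 50% point,
i.e. the PSE for this symmetric model), ``sd`` its standard deviation
(inversely related to sensitivity), and ``lapse`` a stimulus-independent
error rate that compresses both asymptotes to [lapse, 1 - lapse].

The module provides forward evaluation, closed-form inversion (quantiles),
PSE/JND extraction, the Bernoulli log-likelihood of a trial list, and
bounded maximum-likelihood fitting with a derivative-free simplex.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import ndtr, ndtri

__all__ = [
    "PsychometricParams",
    "TrialRecord",
    "FitResult",
    "InvalidParameterError",
    "UnreachableQuantileError",
    "predict_p_yes",
    "quantile",
    "compute_jnd",
    "log_likelihood",
    "fit_psychometric",
    "records_to_frame",
    "frame_to_records",
]

#: probabilities are clipped to this band inside the likelihood so that
#: lapse = 0 fits stay finite
_P_CLIP = 1e-9


class InvalidParameterError(ValueError):
    """Raised for parameter values outside the model's admissible set."""


class UnreachableQuantileError(ValueError):
    """Raised when a requested response probability lies outside (lapse, 1 - lapse)."""


@dataclass(frozen=True)
class PsychometricParams:
    """Parameter triplet (m, sd, lapse) of the psychometric function.

    ``m`` and ``sd`` are in stimulus units; ``lapse`` is a probability in
    [0, 0.5). ``sd`` may be negative only when a fit explicitly allows a
    negative slope; the canonical regime is ``sd > 0``.
    """

    m: float
    sd: float
    lapse: float = 0.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.lapse < 0.5):
            raise InvalidParameterError(
                f"lapse must lie in [0, 0.5), got {self.lapse}"
            )

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.m, self.sd, self.lapse)


@dataclass
class TrialRecord:
    """One presented stimulus and its binary response, with bookkeeping."""

    trial_index: int
    stimulus: float
    response: int  # 1 = "yes", 0 = "no"
    procedure: str = ""  # "questplus" | "cs" | "staircase"
    track_id: Optional[int] = None
    block: int = 1
    valid: bool = True


@dataclass
class FitResult:
    params: PsychometricParams
    pse: float
    jnd: float
    log_likelihood: float
    converged: bool
    n_trials: int
    degenerate: bool = False

    def to_dict(self) -> dict:
        return {
            "m": self.params.m,
            "sd": self.params.sd,
            "lapse": self.params.lapse,
            "pse": self.pse,
            "jnd": self.jnd,
            "loglik": self.log_likelihood,
            "converged": self.converged,
            "n_trials": self.n_trials,
        }


def predict_p_yes(params: PsychometricParams, x):
    """Evaluate the psychometric function at stimulus value(s) ``x``.

    Vectorized over ``x``. Monotonically increasing in ``x`` for ``sd > 0``,
    decreasing for ``sd < 0``; ``sd = 0`` is rejected.
    """
    if params.sd == 0:
        raise InvalidParameterError("sd must be non-zero")
    z = (np.asarray(x, dtype=float) - params.m) / params.sd
    p = params.lapse + (1.0 - 2.0 * params.lapse) * ndtr(z)
    return float(p) if np.isscalar(x) else p


def quantile(params: PsychometricParams, p: float) -> float:
    """Stimulus value at which the response probability equals ``p``.

    Closed-form inversion: x = m + sd * Phi^-1((p - lapse) / (1 - 2*lapse)).
    Only probabilities strictly inside (lapse, 1 - lapse) are reachable.
    """
    if params.sd == 0:
        raise InvalidParameterError("sd must be non-zero")
    if not (params.lapse < p < 1.0 - params.lapse):
        raise UnreachableQuantileError(
            f"p={p} outside the reachable band ({params.lapse}, {1 - params.lapse})"
        )
    core = (p - params.lapse) / (1.0 - 2.0 * params.lapse)
    return params.m + params.sd * float(ndtri(core))


def compute_jnd(params: PsychometricParams) -> float:
    """Just-noticeable difference, JND = (x_.75 - x_.25) / 2.

    Computed by exact inversion of the lapse-corrected function (not the
    lapse-free shortcut 0.6745*sd), so the value refers to response
    probabilities 0.75 and 0.25 as observed, lapses included. Negative for
    a negative-slope fit.
    """
    if params.lapse >= 0.25:
        raise UnreachableQuantileError(
            f"lapse={params.lapse} >= 0.25: the 25%/75% points are unreachable"
        )
    return 0.5 * (quantile(params, 0.75) - quantile(params, 0.25))


def _stimuli_responses(trials) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(trials, pd.DataFrame):
        return trials["stimulus"].to_numpy(float), trials["response"].to_numpy(int)
    trials = list(trials)
    if trials and isinstance(trials[0], TrialRecord):
        return (
            np.array([t.stimulus for t in trials], float),
            np.array([t.response for t in trials], int),
        )
    x, r = trials  # (stimuli, responses) pair
    return np.asarray(x, float), np.asarray(r, int)


def log_likelihood(params: PsychometricParams, trials) -> float:
    """Bernoulli log-likelihood (nats) of a trial list under ``params``.

    Predicted probabilities are clipped to [1e-9, 1 - 1e-9] so that fits
    with lapse = 0 never return -inf.
    """
    x, r = _stimuli_responses(trials)
    if x.size == 0:
        raise ValueError("empty trial list")
    p = np.clip(predict_p_yes(params, x), _P_CLIP, 1.0 - _P_CLIP)
    return float(np.sum(np.where(r == 1, np.log(p), np.log1p(-p))))


# deterministic multi-start fractions of the (m, sd, lapse) bound box
_START_FRACTIONS = (
    (0.50, 0.30, 0.25),
    (0.25, 0.50, 0.50),
    (0.75, 0.50, 0.50),
    (0.50, 0.70, 0.75),
    (0.35, 0.10, 0.10),
)


def fit_psychometric(
    trials,
    start: Optional[PsychometricParams] = None,
    bounds: Optional[Sequence[tuple[float, float]]] = None,
    allow_negative_slope: bool = False,
    xtol: float = 1e-6,
) -> FitResult:
    """Maximum-likelihood fit of the psychometric function.

    Runs a bounded Nelder-Mead simplex from five deterministic start points
    spread over the bound box (plus ``start`` if given); the best likelihood
    wins and ties go to the smallest |sd|. ``bounds`` is a 3-sequence of
    (lo, hi) for (m, sd, lapse); defaults are derived from the data range.
    By default the slope is constrained positive (sd lower bound > 0);
    ``allow_negative_slope`` widens the sd box to negative values so that
    reverse-ordered data can be fitted rather than rejected.

    All-identical responses cannot pin down the function; the fit then
    returns ``converged=False`` with a ``degenerate`` flag instead of
    raising.
    """
    x, r = _stimuli_responses(trials)
    if x.size == 0:
        raise ValueError("empty trial list")
    span = float(x.max() - x.min()) or 1.0
    if bounds is None:
        bounds = [
            (float(x.min()), float(x.max())),
            (1e-3 * span, 2.0 * span),
            (0.0, 0.06),
        ]
    bounds = [tuple(map(float, b)) for b in bounds]
    if allow_negative_slope:
        lo, hi = bounds[1]
        bounds[1] = (-hi, hi)

    # aggregate to per-value binomial counts: identical likelihood, and far
    # fewer curve evaluations when stimuli repeat (CS designs have 9 values)
    xu, inverse = np.unique(x, return_inverse=True)
    n_yes = np.bincount(inverse, weights=r).astype(float)
    n_tot = np.bincount(inverse).astype(float)
    n_no = n_tot - n_yes

    def neg_ll(theta: np.ndarray) -> float:
        m, sd, lapse = theta
        if sd == 0 or not (0.0 <= lapse < 0.5):
            return np.inf
        p = np.clip(
            lapse + (1.0 - 2.0 * lapse) * ndtr((xu - m) / sd),
            _P_CLIP,
            1.0 - _P_CLIP,
        )
        return -float(n_yes @ np.log(p) + n_no @ np.log1p(-p))

    degenerate = bool(np.all(r == r[0]))

    starts = [
        np.array([lo + f * (hi - lo) for (lo, hi), f in zip(bounds, fr)])
        for fr in _START_FRACTIONS
    ]
    if start is not None:
        starts.append(np.array(start.as_tuple(), float))

    best = None
    for s0 in starts:
        res = optimize.minimize(
            neg_ll,
            s0,
            method="Nelder-Mead",
            bounds=bounds,
            options={"xatol": xtol, "fatol": xtol, "maxiter": 2000},
        )
        key = (round(res.fun, 9), abs(res.x[1]))
        if best is None or key < best[0]:
            best = (key, res)
    res = best[1]
    m, sd, lapse = res.x
    params = PsychometricParams(float(m), float(sd), float(np.clip(lapse, 0.0, 0.499)))
    try:
        jnd = compute_jnd(params)
    except (InvalidParameterError, UnreachableQuantileError):
        jnd = math.nan
    return FitResult(
        params=params,
        pse=params.m,
        jnd=jnd,
        log_likelihood=-float(res.fun),
        converged=bool(res.success) and not degenerate,
        n_trials=int(x.size),
        degenerate=degenerate,
    )


_FRAME_COLUMNS = [
    "trial_index",
    "stimulus",
    "response",
    "procedure",
    "track_id",
    "block",
    "valid",
]


def records_to_frame(records: Iterable[TrialRecord]) -> pd.DataFrame:
    """Trial records as the shared tabular schema (one row per trial)."""
    rows = [
        (t.trial_index, t.stimulus, t.response, t.procedure, t.track_id, t.block, t.valid)
        for t in records
    ]
    return pd.DataFrame(rows, columns=_FRAME_COLUMNS)


def frame_to_records(frame: pd.DataFrame) -> list[TrialRecord]:
    out = []
    for row in frame.itertuples(index=False):
        track = None if pd.isna(row.track_id) else int(row.track_id)
        out.append(
            TrialRecord(
                trial_index=int(row.trial_index),
                stimulus=float(row.stimulus),
                response=int(row.response),
                procedure=str(row.procedure),
                track_id=track,
                block=int(row.block),
                valid=bool(row.valid),
            )
        )
    return out
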