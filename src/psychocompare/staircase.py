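"""Interleaved simple up-down staircase procedure.

Three independent tracks start far below, at, and far above the presumed
threshold and are randomly interleaved. Each track moves its stimulus one
step opposite to the response ("yes" = judged greater than the reference
moves the value down), with a step size that shrinks as reversals — changes
of response category within a track — accumulate. A track stops after a
fixed number of reversals or after repeatedly pinning a domain bound; the
whole procedure is capped at a global trial budget. The conventional 50%
threshold is the mean over tracks of the mean of each track's last five
reversal values; the per-trial records can additionally be fitted with the
full psychometric model.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .psychometric import TrialRecord, records_to_frame

__all__ = [
    "StaircaseConfig",
    "TrackState",
    "StaircaseState",
    "ConventionalThreshold",
    "step_track",
    "run_staircase",
    "conventional_threshold",
    "bin_for_fit",
]


@dataclass(frozen=True)
class StaircaseConfig:
    """Step schedule and termination rules for one interleaved staircase.

    ``step_schedule`` is a tuple of (reversal_threshold, step) pairs read in
    order: the current step is the first entry whose threshold exceeds the
    track's reversal count; a ``None`` threshold is the terminal catch-all.
    E.g. ``((2, 0.2), (None, 0.1))`` means step 0.2 until two reversals have
    occurred, then 0.1.
    """

    start_values: tuple[float, float, float]
    step_schedule: tuple[tuple[Optional[int], float], ...]
    domain_bounds: tuple[float, float]
    max_reversals: int = 15
    max_boundary_hits: int = 10
    max_total_trials: int = 150
    reversals_for_threshold: int = 5

    def step_for(self, n_reversals: int) -> float:
        for threshold, step in self.step_schedule:
            if threshold is None or n_reversals < threshold:
                return step
        raise ValueError("step schedule has no catch-all entry")


@dataclass
class TrackState:
    current_value: float
    last_response: Optional[int] = None
    reversal_values: list = field(default_factory=list)
    boundary_hits: int = 0
    terminated: bool = False
    n_trials: int = 0


@dataclass
class StaircaseState:
    config: StaircaseConfig
    tracks: list
    total_trial_count: int = 0

    @classmethod
    def fresh(cls, config: StaircaseConfig) -> "StaircaseState":
        return cls(config=config, tracks=[TrackState(v) for v in config.start_values])

    @property
    def active_tracks(self) -> list:
        return [i for i, t in enumerate(self.tracks) if not t.terminated]


def step_track(state: StaircaseState, track_id: int, response: int) -> StaircaseState:
    """Advance one track after a response to its current value.

    "yes" moves the value down by the current step, "no" up; a reversal is
    recorded (at the presented value) whenever the response category changes
    within the track. Values are clamped to the domain bounds; landing on a
    bound counts one boundary hit (hits at the minimum and maximum are
    pooled). Termination is checked after every step.
    """
    if not (0 <= track_id < len(state.tracks)):
        raise ValueError(f"unknown track_id: {track_id}")
    track = state.tracks[track_id]
    if track.terminated:
        raise ValueError(f"track {track_id} already terminated")
    cfg = state.config

    if track.last_response is not None and response != track.last_response:
        track.reversal_values.append(track.current_value)
    track.last_response = response
    track.n_trials += 1

    step = cfg.step_for(len(track.reversal_values))
    proposed = track.current_value - step if response == 1 else track.current_value + step
    lo, hi = cfg.domain_bounds
    new_value = min(max(proposed, lo), hi)
    if new_value == lo or new_value == hi:
        track.boundary_hits += 1
    track.current_value = new_value

    if (
        len(track.reversal_values) >= cfg.max_reversals
        or track.boundary_hits >= cfg.max_boundary_hits
    ):
        track.terminated = True
    return state


def run_staircase(
    observer,
    config: StaircaseConfig,
    seed: int,
    block: int = 1,
) -> list[TrialRecord]:
    """Run the full interleaved procedure against a simulated observer.

    The next track is drawn uniformly at random among non-terminated tracks
    from a dedicated interleaving RNG (``seed``), independent of the
    observer's response RNG. Stops when every track has terminated or the
    global trial cap is reached.
    """
    rng = np.random.default_rng(seed)
    state = StaircaseState.fresh(config)
    records: list[TrialRecord] = []
    while state.active_tracks and state.total_trial_count < config.max_total_trials:
        track_id = int(rng.choice(state.active_tracks))
        x = state.tracks[track_id].current_value
        response = observer.respond(x, block=block)
        state.total_trial_count += 1
        records.append(
            TrialRecord(
                trial_index=state.total_trial_count,
                stimulus=x,
                response=response,
                procedure="staircase",
                track_id=track_id,
                block=block,
            )
        )
        step_track(state, track_id, response)
    return records


@dataclass
class ConventionalThreshold:
    value: float
    per_track: dict
    warnings: list


def _reversals_by_track(records: Sequence[TrialRecord]) -> dict:
    """Brute scan for response-category changes within each track."""
    reversals: dict = {}
    last: dict = {}
    for rec in sorted(records, key=lambda r: r.trial_index):
        tid = rec.track_id
        if tid in last and rec.response != last[tid]:
            reversals.setdefault(tid, []).append(rec.stimulus)
        reversals.setdefault(tid, [])
        last[tid] = rec.response
    return reversals


def conventional_threshold(
    records: Sequence[TrialRecord],
    reversals_for_threshold: int = 5,
) -> ConventionalThreshold:
    """Mean over tracks of the mean of each track's last five reversal values.

    A track with fewer reversals than requested contributes the mean of all
    its reversals, with a warning recorded (such non-converged tracks exist
    whenever the global cap interrupts a slow track).
    """
    reversals = _reversals_by_track(records)
    per_track: dict = {}
    warnings: list = []
    for tid, values in sorted(reversals.items()):
        if len(values) == 0:
            warnings.append(f"track {tid}: no reversals, skipped")
            continue
        if len(values) < reversals_for_threshold:
            warnings.append(
                f"track {tid}: only {len(values)} reversals, using all of them"
            )
        per_track[tid] = float(np.mean(values[-reversals_for_threshold:]))
    if not per_track:
        raise ValueError("no track produced any reversal")
    return ConventionalThreshold(
        value=float(np.mean(list(per_track.values()))),
        per_track=per_track,
        warnings=warnings,
    )


def bin_for_fit(records: Sequence[TrialRecord], n_bins: int = 9) -> pd.DataFrame:
    """Quantile-based binning of staircase trials into a CS-like summary.

    Returns one row per bin with the mean stimulus, trial count, and yes
    count. Used for plotting and for summaries commensurate with the
    constant-stimuli design (9 stimulus values); psychometric fits consume
    the raw per-trial records, not the bins. If there are fewer distinct
    stimulus values than bins, bins are merged and the ``merged`` flag set.
    """
    frame = records_to_frame(records)
    if frame.empty:
        raise ValueError("no records to bin")
    x = frame["stimulus"].to_numpy(float)
    r = frame["response"].to_numpy(int)
    distinct = np.unique(x)
    merged = distinct.size < n_bins
    k = min(n_bins, distinct.size)
    # equal-count quantile bins: stable sort by stimulus (ties keep trial
    # order), then split the ranks into k near-equal contiguous chunks
    order = np.argsort(x, kind="stable")
    labels = np.empty(x.size, int)
    for b, chunk in enumerate(np.array_split(order, k)):
        labels[chunk] = b
    out = (
        frame.assign(_bin=labels)
        .groupby("_bin")
        .agg(
            stimulus_mean=("stimulus", "mean"),
            n=("stimulus", "size"),
            n_yes=("response", "sum"),
        )
        .reset_index(drop=True)
    )
    out.attrs["merged"] = bool(merged)
    return out
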