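"""One-up/one-down variable-step adaptive staircases and block layouts.

An inertial-nulling (IN) block interleaves four adaptive tracks — two per
visual-field-motion (VFM) direction, starting from +8 and -8 deg/s — each
contributing 18 trials for 72 in total.  A clockwise report moves the
signed inertial level down by the current step, a counterclockwise report
moves it up, so the track converges on the level at which the two reports
are equally likely (the PSE).  At every response reversal the step is
multiplied by ``shrink_factor`` and floored at ``min_step``.  Tracks may
cross zero.  The presentation order is a seeded uniformly random
interleaving of the four tracks' trial slots.

The step schedule itself (initial 2 deg/s, halve on reversal, floor
1 deg/s — see :class:`StepSchedule` for why the floor sits at the
threshold scale) is a configurable package default; so is the
control-block track structure (2 tracks x 18 trials = 36).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import StaircaseError
from .observer_models import (
    CONTROL_KINDS,
    TRIAL_COLUMNS,
    PsychometricObserver,
    respond,
)

__all__ = [
    "StepSchedule",
    "StaircaseState",
    "BlockDesign",
    "StudyDesign",
    "next_level",
    "run_block",
    "run_control_block",
]


@dataclass(frozen=True)
class StepSchedule:
    """Variable-step schedule for the 1-up/1-down rule."""

    initial_step: float = 2.0  # deg/s
    shrink_factor: float = 0.5  # applied at each response reversal
    #: The floor is set at the population threshold scale (~1 deg/s).  A much
    #: smaller floor parks every post-convergence trial inside a fraction of
    #: sigma around the PSE, where the response probability is ~50% whatever
    #: sigma is: the threshold becomes unidentifiable and resampling-based
    #: confidence intervals collapse.  A floor near sigma keeps trials around
    #: the 16%/84% response levels, the classical sweet spot for slope
    #: information in up-down procedures.
    min_step: float = 1.0  # deg/s

    def __post_init__(self) -> None:
        if not self.initial_step > self.min_step > 0:
            raise ValueError("need initial_step > min_step > 0")
        if not 0.0 < self.shrink_factor < 1.0:
            raise ValueError("shrink_factor must lie in (0, 1)")


@dataclass
class StaircaseState:
    """Bookkeeping for one adaptive track."""

    start_level: float  # deg/s, signed; the largest magnitude presented
    schedule: StepSchedule = field(default_factory=StepSchedule)
    trials_per_staircase: int = 18
    current_level: float = None  # type: ignore[assignment]
    current_step: float = None  # type: ignore[assignment]
    n_reversals: int = 0
    history: list = field(default_factory=list)  # [(level, response), ...]
    done: bool = False
    _last_response: str | None = None

    def __post_init__(self) -> None:
        if self.current_level is None:
            self.current_level = self.start_level
        if self.current_step is None:
            self.current_step = self.schedule.initial_step

    @property
    def trials_remaining(self) -> int:
        return self.trials_per_staircase - len(self.history)


def next_level(state: StaircaseState, response: str) -> StaircaseState:
    """Record ``response`` to the current level and advance the track.

    Mutates ``state`` in place and returns it.  A "CW" report lowers the
    signed level by the current step; "CCW" raises it.  On a reversal
    (response differs from the previous one) the step shrinks first, so
    the post-reversal move already uses the smaller step.
    """
    if state.done:
        raise StaircaseError("cannot step a finished staircase")
    if response not in ("CW", "CCW"):
        raise ValueError(f"response must be 'CW' or 'CCW', got {response!r}")
    level = state.current_level
    state.history.append((level, response))
    if state._last_response is not None and response != state._last_response:
        state.n_reversals += 1
        state.current_step = max(
            state.schedule.min_step, state.current_step * state.schedule.shrink_factor
        )
    state._last_response = response
    if response == "CW":
        state.current_level = level - state.current_step
    else:
        state.current_level = level + state.current_step
    if len(state.history) >= state.trials_per_staircase:
        state.done = True
    return state


@dataclass(frozen=True)
class BlockDesign:
    """Layout of one 72-trial inertial-nulling block."""

    vfm_duration: float  # s: 1, 4 or 8 in the study
    vfm_speed: float = 55.0  # deg/s star-field rotation
    n_staircases: int = 4  # 2 per VFM direction
    trials_per_staircase: int = 18
    start_levels: tuple = (8.0, -8.0)  # deg/s, one per track within each set
    step_schedule: StepSchedule = field(default_factory=StepSchedule)

    def __post_init__(self) -> None:
        if self.n_staircases != 2 * len(self.start_levels):
            raise ValueError("need one start level per track within each direction set")

    @property
    def n_trials(self) -> int:
        return self.n_staircases * self.trials_per_staircase


@dataclass(frozen=True)
class StudyDesign:
    """Whole-study block layout: controls, IN blocks and CE blocks."""

    vfm_durations: tuple = (1.0, 4.0, 8.0)
    control_kinds: tuple = CONTROL_KINDS
    control_trials: int = 36  # 2 tracks x 18
    trials_per_staircase: int = 18
    start_levels: tuple = (8.0, -8.0)
    step_schedule: StepSchedule = field(default_factory=StepSchedule)

    def in_block(self, duration: float) -> BlockDesign:
        return BlockDesign(
            vfm_duration=float(duration),
            trials_per_staircase=self.trials_per_staircase,
            start_levels=self.start_levels,
            step_schedule=self.step_schedule,
        )


def _interleave(rng, counts: list) -> np.ndarray:
    """Uniformly random presentation order over the tracks' trial slots."""
    slots = np.repeat(np.arange(len(counts)), counts)
    return rng.permutation(slots)


def _rows_to_frame(rows: list) -> pd.DataFrame:
    frame = pd.DataFrame(rows, columns=TRIAL_COLUMNS)
    frame["certainty"] = frame["certainty"].astype(float)
    return frame


def run_block(
    observer: PsychometricObserver, design: BlockDesign, seed: int
) -> pd.DataFrame:
    """Simulate one interleaved 72-trial IN block for one observer.

    Each of the four tracks pairs its VFM direction (at ``vfm_speed`` for
    ``vfm_duration`` seconds) with its current inertial level, queries the
    observer, and advances.  Returns a trial table with one row per
    presentation in presentation order.
    """
    condition_cw = (design.vfm_duration, "CW")
    _ = observer.vection_shift  # trigger a clear error early if absent
    for cond in (condition_cw, (design.vfm_duration, "CCW")):
        key = (float(cond[0]), cond[1])
        if key not in observer.vection_shift:
            raise ValueError(
                f"observer {observer.subject_id} has no vection shift for {key}"
            )

    rng = np.random.default_rng(seed)
    tracks = []
    for vfm_dir in ("CW", "CCW"):
        for start in design.start_levels:
            sign = "pos" if start >= 0 else "neg"
            tracks.append(
                (
                    f"{vfm_dir.lower()}vfm_{sign}{abs(start):g}",
                    vfm_dir,
                    StaircaseState(
                        start_level=start,
                        schedule=design.step_schedule,
                        trials_per_staircase=design.trials_per_staircase,
                    ),
                )
            )
    order = _interleave(rng, [design.trials_per_staircase] * len(tracks))
    block_type = f"IN-{design.vfm_duration:g}s"
    rows = []
    for track_idx in order:
        staircase_id, vfm_dir, state = tracks[track_idx]
        level = state.current_level
        answer = respond(observer, level, (design.vfm_duration, vfm_dir), rng)
        rows.append(
            {
                "subject_id": observer.subject_id,
                "group": observer.group,
                "block_type": block_type,
                "vfm_direction": vfm_dir,
                "inertial_peak_vel": level,
                "response": answer,
                "certainty": np.nan,
                "staircase_id": staircase_id,
                "trial_index": len(state.history),
                "rng_seed": seed,
            }
        )
        next_level(state, answer)
    return _rows_to_frame(rows)


def run_control_block(
    observer: PsychometricObserver,
    kind: str,
    seed: int,
    design: StudyDesign | None = None,
) -> pd.DataFrame:
    """Simulate one 36-trial visual-control block (darkness, static visual
    stimulus, or zero-coherence visual stimulus).

    Uses the same staircase machinery as the IN blocks, scaled to two
    interleaved tracks of 18 trials; responses come from the observer's
    control-condition psychometric function (mean = baseline bias).
    """
    if kind not in CONTROL_KINDS:
        raise ValueError(f"unknown control kind {kind!r}; expected one of {CONTROL_KINDS}")
    if design is None:
        design = StudyDesign()
    per_track = design.control_trials // len(design.start_levels)
    rng = np.random.default_rng(seed)
    tracks = []
    for start in design.start_levels:
        sign = "pos" if start >= 0 else "neg"
        tracks.append(
            (
                f"ctrl_{sign}{abs(start):g}",
                StaircaseState(
                    start_level=start,
                    schedule=design.step_schedule,
                    trials_per_staircase=per_track,
                ),
            )
        )
    order = _interleave(rng, [per_track] * len(tracks))
    rows = []
    for track_idx in order:
        staircase_id, state = tracks[track_idx]
        level = state.current_level
        answer = respond(observer, level, kind, rng)
        rows.append(
            {
                "subject_id": observer.subject_id,
                "group": observer.group,
                "block_type": f"control-{kind}",
                "vfm_direction": "none",
                "inertial_peak_vel": level,
                "response": answer,
                "certainty": np.nan,
                "staircase_id": staircase_id,
                "trial_index": len(state.history),
                "rng_seed": seed,
            }
        )
        next_level(state, answer)
    return _rows_to_frame(rows)
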