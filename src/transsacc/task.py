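"""Task design: geometry, timing, and interleaved 1-up-1-down staircases.

The displacement task asks a subject to saccade from a fixation cross at 6
or 8 deg on one side of the screen to a target at 6 or 8 deg on the other
side (stimulus amplitudes of 12, 14 or 16 deg).  The target is displaced in
sync with the saccade, either immediately (STEP) or after a 250-ms blank
(BLANK), and the subject reports the apparent jump direction.  Displacement
levels are driven by three independent, randomly interleaved one-up-one-down
staircases with a constant step size of 3 deg (STEP) or 1.5 deg (BLANK),
starting at +7/0/-7 deg (STEP) or +3.5/0/-3.5 deg (BLANK).

Coordinate conventions
----------------------
Screen coordinates are rightward-positive degrees and appear only in raw
trial records (fixation/target/landing positions).  Every analysis-facing
displacement is *forward-positive*: positive values are displacements in the
direction of the saccade, negative values against it.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError

CONDITIONS = ("STEP", "BLANK")
DIRECTIONS = ("leftward", "rightward")

#: Forward report: apparent jump in saccade direction.
FORWARD = "forward"
BACKWARD = "backward"
NONE = "none"

_CONDITION_DEFAULTS = {
    "STEP": dict(step_size=3.0, staircase_starts=(7.0, 0.0, -7.0), blank_duration_ms=0.0),
    "BLANK": dict(step_size=1.5, staircase_starts=(3.5, 0.0, -3.5), blank_duration_ms=250.0),
}


def direction_sign(direction: str) -> int:
    """Screen-coordinate sign of a saccade direction (+1 rightward)."""
    if direction == "rightward":
        return 1
    if direction == "leftward":
        return -1
    raise ConfigurationError(f"unknown saccade direction: {direction!r}")


@dataclass(frozen=True)
class TaskConfig:
    """Design constants for one block type (one condition, one direction)."""

    condition: str
    saccade_direction: str
    fixation_eccentricities: tuple[float, ...] = (6.0, 8.0)
    target_eccentricities: tuple[float, ...] = (6.0, 8.0)
    blank_duration_ms: float = 0.0
    foreperiod_range_ms: tuple[float, float] = (1600.0, 2400.0)
    response_window_ms: float = 5000.0
    trials_per_block: int = 24
    blocks_per_condition: int = 5
    step_size: float = 3.0
    staircase_starts: tuple[float, ...] = (7.0, 0.0, -7.0)

    def __post_init__(self) -> None:
        if self.condition not in CONDITIONS:
            raise ConfigurationError(f"condition must be one of {CONDITIONS}")
        if self.saccade_direction not in DIRECTIONS:
            raise ConfigurationError(f"direction must be one of {DIRECTIONS}")
        if self.trials_per_block != 24:
            raise ConfigurationError("trials_per_block is fixed at 24 by the design")
        if self.blocks_per_condition not in (5, 6):
            raise ConfigurationError("blocks_per_condition must be 5 or 6")
        if self.step_size <= 0:
            raise ConfigurationError("step_size must be positive")
        expected = _CONDITION_DEFAULTS[self.condition]
        if abs(self.step_size - expected["step_size"]) > 1e-9 or tuple(
            sorted(self.staircase_starts)
        ) != tuple(sorted(expected["staircase_starts"])):
            raise ConfigurationError(
                f"{self.condition} requires step {expected['step_size']} with "
                f"starts {expected['staircase_starts']}"
            )
        for f, t in itertools.product(self.fixation_eccentricities, self.target_eccentricities):
            if f + t not in (12.0, 14.0, 16.0):
                raise ConfigurationError(
                    "eccentricities must yield stimulus amplitudes in {12, 14, 16} deg"
                )

    @classmethod
    def for_condition(cls, condition: str, direction: str, **kwargs) -> "TaskConfig":
        """Build a config with the condition's canonical step/starts/blank."""
        defaults = _CONDITION_DEFAULTS.get(condition)
        if defaults is None:
            raise ConfigurationError(f"condition must be one of {CONDITIONS}")
        merged = {**defaults, **kwargs}
        return cls(condition=condition, saccade_direction=direction, **merged)


@dataclass
class StaircaseState:
    """One of the three interleaved staircases, in forward-positive degrees.

    ``history`` accumulates ``(level, report)`` pairs; void trials (report
    ``none``) are recorded but do not move the level.
    """

    staircase_id: int
    current_level: float
    step_size: float
    history: tuple[tuple[float, str], ...] = ()

    def __post_init__(self) -> None:
        if self.staircase_id not in (1, 2, 3):
            raise ConfigurationError("staircase_id must be 1, 2 or 3")
        if self.step_size <= 0:
            raise ConfigurationError("step_size must be positive")


def staircase_update(state: StaircaseState, report: str) -> StaircaseState:
    """Advance a 1-up-1-down staircase by one trial.

    A ``forward`` report (jump seen in saccade direction) lowers the next
    level by one step; a ``backward`` report raises it.  A ``none`` report
    (response window elapsed) leaves the level unchanged and marks the trial
    void in the history.
    """
    if report == NONE:
        return replace(state, history=state.history + ((state.current_level, NONE),))
    if report not in (FORWARD, BACKWARD):
        raise ConfigurationError(f"report must be forward/backward/none, got {report!r}")
    delta = -state.step_size if report == FORWARD else state.step_size
    return replace(
        state,
        current_level=state.current_level + delta,
        history=state.history + ((state.current_level, report),),
    )


def staircase_lattice(
    starts: Sequence[float], step_size: float, window: float = 10.0
) -> tuple[np.ndarray, float]:
    """Union of the staircases' reachable levels and its sampling resolution.

    Each staircase can only visit ``start + k * step_size``; interleaving
    staircases with offset starts therefore samples the displacement axis at
    a resolution finer than the step size.  Returns the sorted union of all
    reachable levels within ``[-window, window]`` and the minimal spacing
    between distinct union levels.
    """
    if step_size <= 0:
        raise ConfigurationError("step_size must be positive")
    if not len(starts):
        raise ConfigurationError("starts must be non-empty")
    if window <= 0:
        raise ConfigurationError("window must be positive")
    levels: set[float] = set()
    for start in starts:
        k_lo = int(np.ceil((-window - start) / step_size))
        k_hi = int(np.floor((window - start) / step_size))
        levels.update(start + k * step_size for k in range(k_lo, k_hi + 1))
    arr = np.array(sorted(levels), dtype=float)
    # collapse floating-point duplicates
    arr = arr[np.concatenate(([True], np.diff(arr) > 1e-9))]
    if len(arr) < 2:
        return arr, float(step_size)
    resolution = float(np.min(np.diff(arr)))
    return arr, resolution


def schedule_session(config: TaskConfig, rng_seed) -> pd.DataFrame:
    """Draw the trial skeletons for one session of one block type.

    Emits ``blocks_per_condition * 24`` rows.  Fixation and target
    eccentricity and the foreperiod are drawn uniformly per trial; staircase
    assignment is a seeded random interleave with near-equal counts per
    staircase (within +/-1).
    """
    rng = np.random.default_rng(rng_seed)
    n = config.blocks_per_condition * config.trials_per_block
    sign = direction_sign(config.saccade_direction)

    base, rem = divmod(n, 3)
    counts = np.array([base] * 3)
    counts[rng.permutation(3)[:rem]] += 1
    staircase_ids = np.repeat([1, 2, 3], counts)
    rng.shuffle(staircase_ids)

    fix_ecc = rng.choice(config.fixation_eccentricities, size=n)
    tgt_ecc = rng.choice(config.target_eccentricities, size=n)
    lo, hi = config.foreperiod_range_ms
    foreperiod = rng.uniform(lo, hi, size=n)

    return pd.DataFrame(
        {
            "trial_index": np.arange(n),
            "block": np.arange(n) // config.trials_per_block,
            "condition": config.condition,
            "direction": config.saccade_direction,
            "fixation_eccentricity": fix_ecc,
            "target_eccentricity": tgt_ecc,
            # fixation on the side opposite to saccade direction
            "fixation_position": -sign * fix_ecc,
            "target_position": sign * tgt_ecc,
            "stimulus_amplitude": sign * (fix_ecc + tgt_ecc),
            "foreperiod_ms": foreperiod,
            "staircase_id": staircase_ids,
        }
    )


#: Canonical column order for trial tables written to disk.
TRIAL_COLUMNS = [
    "subject",
    "trial_index",
    "block",
    "condition",
    "direction",
    "fixation_eccentricity",
    "target_eccentricity",
    "fixation_position",
    "target_position",
    "stimulus_amplitude",
    "foreperiod_ms",
    "staircase_id",
    "displacement",
    "report",
    "saccade_landing",
    "trigger_delay_ms",
    "motor_error",
]


def write_trials(trials: pd.DataFrame, path) -> None:
    """Write a trial table as CSV with missing values as empty fields."""
    cols = [c for c in TRIAL_COLUMNS if c in trials.columns]
    cols += [c for c in trials.columns if c not in cols]
    trials.to_csv(path, index=False, columns=cols)


def read_trials(path) -> pd.DataFrame:
    """Read a trial table written by :func:`write_trials`."""
    return pd.read_csv(path)
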