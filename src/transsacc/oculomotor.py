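"""Saccade detection and targeting-error metrics from eye-position traces.

Traces are low-pass filtered (zero-phase Butterworth, 60 Hz default),
velocity is computed by central differences, and saccade onset/offset are
located with a fixed 30-deg/s velocity criterion.  Start and end positions
are taken as the median gaze over fixation windows (50 ms default) before
onset and after offset.

Error conventions follow the two used in the field: ``targeting_error``
(landing eccentricity minus stimulus amplitude, undershoot negative) and
``hypometria_error`` (its sign flip, hypometric positive).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal

from .errors import DataError, NoSaccadeError
from .eyetrace import VELOCITY_THRESHOLD, EyeTrace
from .task import direction_sign


@dataclass(frozen=True)
class SaccadeEvent:
    """A detected saccade with positions in screen coordinates."""

    onset_ms: float
    offset_ms: float
    start_position: float
    end_position: float
    amplitude: float  # signed, end - start
    duration_ms: float
    peak_velocity: float
    multiple_intervals: bool = False

    def __post_init__(self) -> None:
        if self.offset_ms <= self.onset_ms:
            raise DataError("saccade offset must follow onset")


def filter_trace(
    position: np.ndarray, sampling_rate: float, cutoff_hz: float = 60.0
) -> np.ndarray:
    """Zero-phase second-order Butterworth low-pass filter."""
    position = np.asarray(position, dtype=float)
    nyq = sampling_rate / 2.0
    if not 0 < cutoff_hz < nyq:
        raise DataError(f"cutoff must lie in (0, {nyq}) Hz")
    b, a = signal.butter(2, cutoff_hz / nyq)
    padlen = 3 * (max(len(a), len(b)) - 1)
    if len(position) <= padlen:
        raise DataError("trace shorter than the filter span")
    return signal.filtfilt(b, a, position)


def velocity(position: np.ndarray, sampling_rate: float) -> np.ndarray:
    """Instantaneous velocity (deg/s) by central differences."""
    return np.gradient(np.asarray(position, dtype=float)) * sampling_rate


def detect_saccade(
    trace: EyeTrace | pd.DataFrame,
    sampling_rate: float | None = None,
    threshold: float = VELOCITY_THRESHOLD,
    cutoff_hz: float = 60.0,
    fixation_window_ms: float = 50.0,
) -> SaccadeEvent:
    """Detect the principal saccade in a trace.

    Onset is the first sample of the principal suprathreshold velocity
    interval, offset the first subsequent sample below threshold.  With
    several suprathreshold intervals (e.g. a corrective saccade) the one
    with the largest position change is returned and the event is flagged.
    """
    if isinstance(trace, EyeTrace):
        t = trace.time_ms
        x = trace.position_deg
        fs = trace.sampling_rate
    else:
        t = np.asarray(trace["time_ms"], dtype=float)
        x = np.asarray(trace["x_deg"], dtype=float)
        fs = sampling_rate if sampling_rate is not None else 1000.0 / np.median(np.diff(t))

    xf = filter_trace(x, fs, cutoff_hz)
    v = velocity(xf, fs)
    above = np.abs(v) > threshold
    if not above.any():
        raise NoSaccadeError("no sample exceeds the velocity criterion")

    # contiguous suprathreshold runs
    padded = np.r_[False, above, False]
    rises = np.flatnonzero(~padded[:-1] & padded[1:])
    falls = np.flatnonzero(padded[:-1] & ~padded[1:])
    runs = list(zip(rises, falls))  # [start, stop) sample indices

    def run_displacement(run):
        i0, i1 = run
        return abs(xf[min(i1, len(xf) - 1)] - xf[i0])

    principal = max(runs, key=run_displacement)
    flagged = len(runs) > 1
    i0, i1 = principal
    onset_ms = float(t[i0])
    # offset: first sample below threshold after the run, if within the trace
    i_off = min(i1, len(t) - 1)
    offset_ms = float(t[i_off])

    n_fix = max(1, int(round(fixation_window_ms / 1000.0 * fs)))
    pre = xf[max(0, i0 - n_fix) : i0]
    post = xf[i_off + 1 : i_off + 1 + n_fix]
    if len(pre) == 0 or len(post) == 0:
        raise DataError("insufficient fixation samples around the saccade")
    start_pos = float(np.median(pre))
    end_pos = float(np.median(post))
    return SaccadeEvent(
        onset_ms=onset_ms,
        offset_ms=offset_ms,
        start_position=start_pos,
        end_position=end_pos,
        amplitude=end_pos - start_pos,
        duration_ms=offset_ms - onset_ms,
        peak_velocity=float(np.max(np.abs(v[i0:i1]))),
        multiple_intervals=flagged,
    )


def per_trial_errors(trials: pd.DataFrame, landing_col: str = "saccade_landing") -> pd.DataFrame:
    """Per-trial gain and targeting errors from landing positions.

    Uses the trial table's ``fixation_position`` and ``stimulus_amplitude``
    (both screen coordinates).  Trials with a missing landing or with a
    saccade opposing the instructed direction are marked excluded.
    """
    out = trials.copy()
    landing = out[landing_col].astype(float)
    executed_signed = landing - out["fixation_position"]
    sign = out["direction"].map(direction_sign)
    executed = sign * executed_signed  # positive when in the instructed direction
    amp = out["stimulus_amplitude"].abs()
    out["executed_amplitude"] = executed
    out["gain"] = executed / amp
    out["targeting_error"] = executed - amp
    out["hypometria_error"] = -out["targeting_error"]
    out["excluded"] = landing.isna() | (executed <= 0)
    return out


def targeting_metrics(trials: pd.DataFrame, landing_col: str = "saccade_landing") -> pd.DataFrame:
    """Aggregate targeting metrics per condition x direction.

    Returns one row per cell with mean gain, mean (systematic) targeting
    error, its SD (variable error), mean hypometria error, and the counts
    of used and excluded trials.
    """
    per = per_trial_errors(trials, landing_col)
    rows = []
    for (condition, direction), grp in per.groupby(["condition", "direction"], sort=True):
        used = grp[~grp["excluded"]]
        rows.append(
            {
                "condition": condition,
                "direction": direction,
                "gain": used["gain"].mean(),
                "targeting_error": used["targeting_error"].mean(),
                "variable_error": used["targeting_error"].std(ddof=1),
                "hypometria_error": used["hypometria_error"].mean(),
                "n_used": len(used),
                "n_excluded": int(grp["excluded"].sum()),
            }
        )
    return pd.DataFrame(rows)


def trigger_check(
    onsets_ms: np.ndarray,
    offsets_ms: np.ndarray,
    trigger_times_ms: np.ndarray,
) -> dict:
    """Verify display triggers landed in the first half of each saccade.

    Returns the fraction of trials with the trigger before the saccade
    midpoint, the delay (trigger minus onset) mean and SD, and a per-trial
    violation flag.
    """
    onsets = np.asarray(onsets_ms, dtype=float)
    offsets = np.asarray(offsets_ms, dtype=float)
    triggers = np.asarray(trigger_times_ms, dtype=float)
    midpoints = (onsets + offsets) / 2.0
    delays = triggers - onsets
    ok = triggers < midpoints
    return {
        "fraction_first_half": float(np.mean(ok)),
        "delay_mean_ms": float(np.mean(delays)),
        "delay_sd_ms": float(np.std(delays, ddof=1)) if len(delays) > 1 else 0.0,
        "violations": ~ok,
    }
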