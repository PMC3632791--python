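"""Synthetic 500-Hz eye-position traces with a raised-cosine velocity pulse.

A saccade of screen displacement ``d`` over duration ``T`` follows

    v(t) = (2 d / T) * 0.5 * (1 - cos(2 pi t / T)),   t in [0, T]

so the velocity rises smoothly from zero to a peak of ``2 d / T`` and the
position integrates exactly to ``d``.  Duration scales with amplitude by the
main-sequence-like affine rule ``T = 2.2 |d| + 21`` ms, so a 14-deg saccade
lasts about 52 ms with a peak velocity near 540 deg/s.

Because the raised cosine starts at zero velocity, the 30-deg/s detection
criterion is crossed a few milliseconds after motion onset.  Traces
therefore carry two ground-truth timestamp pairs: the motion interval
(position change equals the executed amplitude) and the analytic 30-deg/s
crossing times (what a velocity-threshold detector should recover).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .observer import SaccadeSim

#: velocity criterion used throughout, deg/s
VELOCITY_THRESHOLD = 30.0

#: main-sequence constants: duration_ms = DUR_SLOPE * |amp| + DUR_INTERCEPT
DUR_SLOPE_MS_PER_DEG = 2.2
DUR_INTERCEPT_MS = 21.0

#: display frame duration at 110 Hz, ms
FRAME_MS = 1000.0 / 110.0


@dataclass(frozen=True)
class EyeTrace:
    """A single-trial gaze trace with generator ground truth."""

    time_ms: np.ndarray
    position_deg: np.ndarray
    sampling_rate: float
    motion_onset_ms: float
    motion_offset_ms: float
    threshold_onset_ms: float
    threshold_offset_ms: float
    displacement_deg: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time_ms": self.time_ms, "x_deg": self.position_deg})


def saccade_duration_ms(amplitude: float) -> float:
    """Main-sequence duration for an amplitude in degrees."""
    return DUR_SLOPE_MS_PER_DEG * abs(amplitude) + DUR_INTERCEPT_MS


def generate_eye_trace(
    saccade: SaccadeSim | float,
    start_position: float,
    sampling_rate: float = 500.0,
    noise_sd: float = 0.0,
    rng: np.random.Generator | None = None,
    pre_fixation_ms: float = 300.0,
    post_fixation_ms: float = 300.0,
) -> EyeTrace:
    """Generate a fixation-saccade-fixation gaze trace.

    ``saccade`` is either a :class:`SaccadeSim` (its landing position and
    the given ``start_position`` define the screen displacement) or a signed
    screen displacement in degrees.  Additive Gaussian position noise with
    SD ``noise_sd`` is applied to every sample.
    """
    if noise_sd < 0:
        raise ConfigurationError("noise_sd must be non-negative")
    if pre_fixation_ms < 200.0 or post_fixation_ms < 250.0:
        raise ConfigurationError("fixation padding must be >= 200 ms pre and >= 250 ms post")
    if isinstance(saccade, SaccadeSim):
        disp = saccade.landing_position - start_position
    else:
        disp = float(saccade)
    if disp == 0.0 or abs(disp) <= 0.0:
        raise ConfigurationError("saccade displacement must be non-zero")

    dur_ms = saccade_duration_ms(disp)
    dur_s = dur_ms / 1000.0
    peak_v = 2.0 * abs(disp) / dur_s
    if peak_v <= VELOCITY_THRESHOLD:
        raise ConfigurationError("amplitude too small for a suprathreshold saccade")

    dt_ms = 1000.0 / sampling_rate
    total_ms = pre_fixation_ms + dur_ms + post_fixation_ms
    n = int(np.floor(total_ms / dt_ms)) + 1
    t = np.arange(n) * dt_ms

    onset = pre_fixation_ms
    offset = pre_fixation_ms + dur_ms
    phase = np.clip((t - onset) / dur_ms, 0.0, 1.0)
    # integral of the raised-cosine velocity pulse
    pos = start_position + disp * (phase - np.sin(2.0 * np.pi * phase) / (2.0 * np.pi))

    if noise_sd > 0:
        if rng is None:
            rng = np.random.default_rng()
        pos = pos + rng.normal(0.0, noise_sd, size=n)

    # analytic 30 deg/s crossing: 0.5*(1 - cos(2 pi u)) = thr / peak_v
    frac = VELOCITY_THRESHOLD / peak_v
    u_cross = np.arccos(1.0 - 2.0 * frac) / (2.0 * np.pi)
    thr_onset = onset + u_cross * dur_ms
    thr_offset = onset + (1.0 - u_cross) * dur_ms

    return EyeTrace(
        time_ms=t,
        position_deg=pos,
        sampling_rate=sampling_rate,
        motion_onset_ms=onset,
        motion_offset_ms=offset,
        threshold_onset_ms=thr_onset,
        threshold_offset_ms=thr_offset,
        displacement_deg=disp,
    )


def trigger_time_ms(trace: EyeTrace) -> float:
    """Display-trigger time: one display frame after detected saccade onset.

    Mimics a gaze-contingent display running at 110 Hz that flips the target
    on the first frame after the eye tracker flags saccade onset.
    """
    return trace.threshold_onset_ms + FRAME_MS
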