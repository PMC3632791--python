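"""Generative observer model for trans-saccadic displacement judgments.

The observer is the minimal linear instantiation of corollary-discharge (CD)
monitoring.  On each trial with stimulus amplitude ``A`` (forward-positive
magnitude ``|A|``) the eye executes

    S = g * |A| + eps_m,          eps_m ~ N(0, sigma_m^2)

where ``g`` is the motor gain and ``eps_m`` the trial's motor error.  The
brain's internal estimate of the executed saccade is built from the CD of
the motor command plus whatever fraction ``lambda`` of the trial-to-trial
motor error the monitoring pathway captures:

    S_hat = g_cd * (g * |A| + lambda * eps_m) + eps_cd

The perceived displacement of the target is the physical displacement plus
the monitoring mismatch,

    D_hat = D + (S_hat - S)

and the binary report is forward iff ``w_cond * D_hat + eps_dec > 0`` (ties
broken forward), with decision noise ``eps_dec ~ N(0, sigma_dec,cond^2)``
and an optional lapse that replaces the report by a fair coin flip.

One knob per mechanism:

* ``cd_gain < 1`` (hypometric CD) underestimates executed amplitudes and
  yields a systematic backward-report bias, i.e. a forward-shifted point of
  subjective stationarity.
* ``cd_coupling = 0`` breaks trial-by-trial error monitoring: self-generated
  targeting errors are misattributed to external stimulus jumps, producing a
  positive correlation between hypometria and forward reports.
* ``decision_sd_step > decision_sd_blank`` encodes saccadic suppression of
  displacement: judgments are much noisier without the 250-ms blank.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping

import numpy as np
import pandas as pd

from . import task as task_mod
from .errors import ConfigurationError
from .task import BACKWARD, FORWARD, StaircaseState, TaskConfig, direction_sign, staircase_update


@dataclass(frozen=True)
class ObserverParams:
    """Generative parameters of a simulated subject.

    All degree-valued noises are standard deviations.  ``cd_coupling`` is
    the fraction of the trial's motor error captured by the CD estimate
    (1 = intact monitoring, 0 = none).  ``reliance_*`` down-weight the
    perceived displacement in the decision variable (1 = full reliance).
    """

    motor_gain: float = 0.92
    motor_sd: float = 1.0
    cd_gain: float = 1.0
    cd_noise: float = 0.3
    cd_coupling: float = 1.0
    decision_sd_step: float = 2.0
    decision_sd_blank: float = 0.5
    reliance_step: float = 1.0
    reliance_blank: float = 1.0
    lapse_rate: float = 0.02

    def __post_init__(self) -> None:
        if self.motor_gain <= 0 or self.cd_gain <= 0:
            raise ConfigurationError("motor_gain and cd_gain must be positive")
        for name in ("motor_sd", "cd_noise", "decision_sd_step", "decision_sd_blank"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be non-negative")
        for name in ("cd_coupling", "reliance_step", "reliance_blank", "lapse_rate"):
            if not 0 <= getattr(self, name) <= 1:
                raise ConfigurationError(f"{name} must lie in [0, 1]")

    def decision_sd(self, condition: str) -> float:
        return self.decision_sd_step if condition == "STEP" else self.decision_sd_blank

    def reliance(self, condition: str) -> float:
        return self.reliance_step if condition == "STEP" else self.reliance_blank


def control_preset(**overrides) -> ObserverParams:
    """Healthy observer: intact CD, full error monitoring, strong blanking
    benefit.  Illustrative defaults, not fitted to any subject."""
    return ObserverParams(**overrides)


def thalamic_preset(**overrides) -> ObserverParams:
    """Lesion-like observer: hypometric CD (gain 0.9), largely decoupled
    error monitoring and a noisier CD estimate.  Illustrative defaults."""
    params = dict(cd_gain=0.9, cd_coupling=0.0, cd_noise=0.6)
    params.update(overrides)
    return ObserverParams(**params)


@dataclass(frozen=True)
class SaccadeSim:
    """One simulated primary saccade (amplitudes are unsigned magnitudes)."""

    planned_amplitude: float
    executed_amplitude: float
    motor_error: float
    landing_position: float  # screen coordinates

    @property
    def targeting_error(self) -> float:
        """Executed minus stimulus amplitude is recovered downstream; here
        the error relative to the *planned* (gain-scaled) amplitude is just
        the motor noise draw."""
        return self.motor_error


def simulate_saccade(
    stimulus_amplitude: float,
    params: ObserverParams,
    rng: np.random.Generator,
    start_position: float = 0.0,
) -> SaccadeSim:
    """Execute one saccade toward a target at signed screen amplitude.

    The sign of ``stimulus_amplitude`` carries the saccade direction in
    screen coordinates; the executed amplitude is ``g * |A| + eps_m`` and
    the landing position is on the same side as the target.
    """
    mag = abs(stimulus_amplitude)
    if not 10.0 <= mag <= 20.0:
        raise ConfigurationError("stimulus amplitude magnitude must lie in [10, 20] deg")
    sign = 1.0 if stimulus_amplitude >= 0 else -1.0
    planned = params.motor_gain * mag
    eps_m = rng.normal(0.0, params.motor_sd) if params.motor_sd > 0 else 0.0
    executed = planned + eps_m
    return SaccadeSim(
        planned_amplitude=planned,
        executed_amplitude=executed,
        motor_error=eps_m,
        landing_position=start_position + sign * executed,
    )


def simulate_percept(
    displacement: float,
    saccade: SaccadeSim,
    params: ObserverParams,
    condition: str,
    rng: np.random.Generator,
) -> str:
    """Judge the apparent jump direction of the displaced target.

    ``displacement`` is forward-positive.  Returns ``"forward"`` or
    ``"backward"``.
    """
    eps_cd = rng.normal(0.0, params.cd_noise) if params.cd_noise > 0 else 0.0
    s_hat = (
        params.cd_gain * (saccade.planned_amplitude + params.cd_coupling * saccade.motor_error)
        + eps_cd
    )
    d_hat = displacement + (s_hat - saccade.executed_amplitude)
    sd = params.decision_sd(condition)
    eps_dec = rng.normal(0.0, sd) if sd > 0 else 0.0
    v = params.reliance(condition) * d_hat + eps_dec
    report = FORWARD if v >= 0 else BACKWARD
    if params.lapse_rate > 0 and rng.random() < params.lapse_rate:
        report = FORWARD if rng.random() < 0.5 else BACKWARD
    return report


def simulate_fixed_trials(
    params: ObserverParams,
    displacements,
    condition: str,
    rng_seed,
    stimulus_amplitude: float = 14.0,
) -> pd.DataFrame:
    """Simulate single trials at prescribed displacement levels.

    Bypasses the staircase: one saccade + judgment per entry of
    ``displacements`` (forward-positive degrees), at a fixed stimulus
    amplitude.  Returns displacement, report, motor error and the
    hypometria error (stimulus minus executed amplitude, hypometric
    positive) per trial — the inputs of the psychometric fit and of the
    error-attribution analysis.
    """
    rng = np.random.default_rng(rng_seed)
    rows = []
    for d in np.asarray(displacements, dtype=float):
        sacc = simulate_saccade(stimulus_amplitude, params, rng)
        report = simulate_percept(d, sacc, params, condition, rng)
        rows.append(
            {
                "displacement": d,
                "report": report,
                "motor_error": sacc.motor_error,
                "hypometria_error": abs(stimulus_amplitude) - sacc.executed_amplitude,
            }
        )
    return pd.DataFrame(rows)


#: mean and SD of the display-trigger delay after saccade onset, ms
TRIGGER_DELAY_MEAN_MS = 19.0
TRIGGER_DELAY_SD_MS = 4.0


def simulate_block_type(
    config: TaskConfig,
    params: ObserverParams,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Run the staircase procedure for one condition x direction."""
    skeleton = task_mod.schedule_session(config, rng)
    staircases = {
        i + 1: StaircaseState(i + 1, start, config.step_size)
        for i, start in enumerate(config.staircase_starts)
    }
    sign = direction_sign(config.saccade_direction)

    rows = []
    for rec in skeleton.itertuples(index=False):
        sc = staircases[rec.staircase_id]
        displacement = sc.current_level
        sacc = simulate_saccade(
            rec.stimulus_amplitude, params, rng, start_position=rec.fixation_position
        )
        report = simulate_percept(displacement, sacc, params, config.condition, rng)
        staircases[rec.staircase_id] = staircase_update(sc, report)
        trigger = float(np.clip(rng.normal(TRIGGER_DELAY_MEAN_MS, TRIGGER_DELAY_SD_MS), 8.0, 40.0))
        rows.append(
            {
                **rec._asdict(),
                "displacement": displacement,
                "report": report,
                "saccade_landing": sacc.landing_position,
                "trigger_delay_ms": trigger,
                "motor_error": sacc.motor_error,
            }
        )
    out = pd.DataFrame(rows)
    # final target position after displacement, screen coordinates
    out["target_position"] = out["target_position"] + sign * out["displacement"]
    return out


def simulate_session(
    params: ObserverParams | Mapping[str, ObserverParams],
    rng_seed,
    blocks_per_condition: int = 5,
    conditions=("STEP", "BLANK"),
    directions=("leftward", "rightward"),
    subject: str | None = None,
) -> pd.DataFrame:
    """Simulate a full session: every condition x direction block type.

    ``params`` may be a single :class:`ObserverParams` or a mapping from
    direction to parameters (lesion-like observers are often deficient for
    one saccade direction only).
    """
    rng = np.random.default_rng(rng_seed)
    if isinstance(params, ObserverParams):
        params = {d: params for d in directions}
    frames = []
    for condition in conditions:
        for direction in directions:
            config = TaskConfig.for_condition(
                condition, direction, blocks_per_condition=blocks_per_condition
            )
            frames.append(simulate_block_type(config, params[direction], rng))
    out = pd.concat(frames, ignore_index=True)
    if subject is not None:
        out.insert(0, "subject", subject)
    return out
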