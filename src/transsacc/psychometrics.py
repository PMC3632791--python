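"""Maximum-likelihood psychometric fitting and displacement thresholds.

The proportion of forward reports as a function of the (forward-positive)
displacement ``d`` is modelled as a cumulative Gaussian with a lapse floor:

    P(forward | d) = lapse/2 + (1 - lapse) * Phi((d - pss) / jnd)

``pss`` (point of subjective stationarity) is the displacement at which
forward and backward reports are equally likely and measures response bias;
``jnd`` is the SD of the Gaussian and measures precision.  Parameters are
estimated by maximizing the Bernoulli likelihood from several deterministic
starts.  The lapse rate is fixed at zero by default and can optionally be
estimated within [0, 0.05].

For condition comparisons the fitted function is folded into percent
correct, ``PC(|d|) = [F(|d|) + 1 - F(-|d|)] / 2`` (null displacements are
discarded), and the perceptual threshold is the absolute displacement at
which PC reaches 75%.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .errors import DataError, DegenerateDataError, NoThresholdError

JND_FLOOR = 1e-3
JND_CEIL = 50.0
MAX_LAPSE = 0.05


@dataclass(frozen=True)
class PsychometricFit:
    """A fitted cumulative-Gaussian psychometric function."""

    pss: float
    jnd: float
    lapse: float
    log_likelihood: float
    n_trials: int
    converged: bool
    at_bound: bool = False
    level_counts: pd.DataFrame | None = field(default=None, compare=False, repr=False)

    def predict(self, d) -> np.ndarray:
        """P(forward report) at displacement(s) ``d``."""
        d = np.asarray(d, dtype=float)
        return self.lapse / 2.0 + (1.0 - self.lapse) * stats.norm.cdf(
            (d - self.pss) / self.jnd
        )


def _nll(params, levels, responses, lapse, fit_lapse):
    pss, log_jnd = params[0], params[1]
    lam = params[2] if fit_lapse else lapse
    jnd = np.exp(log_jnd)
    p = lam / 2.0 + (1.0 - lam) * stats.norm.cdf((levels - pss) / jnd)
    p = np.clip(p, 1e-12, 1.0 - 1e-12)
    return -np.sum(responses * np.log(p) + (1 - responses) * np.log(1 - p))


def fit_cumulative_gaussian(
    levels,
    reports,
    lapse: float = 0.0,
    fit_lapse: bool = False,
    min_trials: int = 20,
) -> PsychometricFit:
    """Fit the psychometric function to per-trial forward/backward reports.

    ``levels`` are forward-positive displacements; ``reports`` are
    ``"forward"``/``"backward"`` strings or a boolean/0-1 array (1 =
    forward).  Trials with a ``"none"`` report must be removed upstream.
    """
    levels = np.asarray(levels, dtype=float)
    reports = np.asarray(reports)
    if reports.dtype.kind in "UOS":
        valid = np.isin(reports, ("forward", "backward"))
        if not valid.all():
            raise DataError("reports must be forward/backward only (drop void trials first)")
        responses = (reports == "forward").astype(float)
    else:
        responses = np.asarray(reports, dtype=float)
        if not np.isin(responses, (0.0, 1.0)).all():
            raise DataError("numeric reports must be 0/1")
    if len(levels) != len(responses):
        raise DataError("levels and reports must have equal length")
    if len(levels) < min_trials:
        raise DataError(f"need at least {min_trials} trials, got {len(levels)}")
    if len(np.unique(levels)) < 2:
        raise DegenerateDataError("need at least 2 distinct displacement levels")
    if responses.min() == responses.max():
        raise DegenerateDataError("all responses identical; psychometric fit is undefined")
    if not 0.0 <= lapse <= MAX_LAPSE:
        raise DataError(f"lapse must lie in [0, {MAX_LAPSE}]")

    spread = max(levels.max() - levels.min(), 1e-3)
    q25, q50, q75 = np.quantile(levels, [0.25, 0.5, 0.75])
    starts = [
        (q50, 0.25 * spread),
        (q25, 0.25 * spread),
        (q75, 0.25 * spread),
        (q50, 0.08 * spread),
        (q50, 0.6 * spread),
    ]
    bounds = [(levels.min() - spread, levels.max() + spread), (np.log(JND_FLOOR), np.log(JND_CEIL))]
    if fit_lapse:
        bounds.append((0.0, MAX_LAPSE))

    best = None
    any_converged = False
    for pss0, jnd0 in starts:
        x0 = [pss0, np.log(max(jnd0, JND_FLOOR))] + ([0.01] if fit_lapse else [])
        res = optimize.minimize(
            _nll,
            x0,
            args=(levels, responses, lapse, fit_lapse),
            method="L-BFGS-B",
            bounds=bounds,
            options={"ftol": 1e-12, "gtol": 1e-10},
        )
        if best is None or res.fun < best.fun:
            best = res
        any_converged = any_converged or bool(res.success)

    pss = float(best.x[0])
    jnd = float(np.exp(best.x[1]))
    lam = float(best.x[2]) if fit_lapse else lapse
    at_bound = jnd <= JND_FLOOR * (1 + 1e-6) or jnd >= JND_CEIL * (1 - 1e-6)

    counts = (
        pd.DataFrame({"level": levels, "forward": responses})
        .groupby("level")
        .agg(n=("forward", "size"), n_forward=("forward", "sum"))
        .reset_index()
    )
    return PsychometricFit(
        pss=pss,
        jnd=jnd,
        lapse=lam,
        log_likelihood=-float(best.fun),
        n_trials=len(levels),
        converged=any_converged,
        at_bound=at_bound,
        level_counts=counts,
    )


def percent_correct_curve(fit: PsychometricFit):
    """Folded percent-correct function ``PC(|d|)`` of the fitted curve.

    Averages correct-report probabilities at matched positive and negative
    displacement magnitudes; undefined at the null displacement, which the
    conversion discards.
    """

    def pc(abs_d):
        abs_d = np.asarray(abs_d, dtype=float)
        if np.any(abs_d <= 0):
            raise DataError("percent correct is defined for |d| > 0 only")
        return (fit.predict(abs_d) + 1.0 - fit.predict(-abs_d)) / 2.0

    return pc


def threshold_75(fit: PsychometricFit, criterion: float = 0.75, tol: float = 1e-4) -> float:
    """Absolute displacement at which folded percent correct reaches 75%.

    Found by bracketed root finding on the monotone PC curve.
    """
    pc = percent_correct_curve(fit)
    asymptote = 1.0 - fit.lapse / 2.0
    if asymptote <= criterion:
        raise NoThresholdError("percent-correct asymptote below the criterion")
    lo = 1e-8
    if pc(lo) >= criterion:
        return 0.0  # degenerate step-like function: threshold at the origin
    hi = max(fit.jnd, 1e-3)
    while pc(hi) < criterion:
        hi *= 2.0
        if hi > 1e6:
            raise NoThresholdError("criterion not attained at any finite displacement")
    root = optimize.brentq(lambda d: pc(d) - criterion, lo, hi, xtol=tol)
    return float(root)


def fit_condition_thresholds(
    trials: pd.DataFrame,
    lapse: float = 0.0,
    fit_lapse: bool = False,
    min_trials: int = 20,
) -> pd.DataFrame:
    """Fit every condition x direction cell of one subject's trial table.

    Void trials (report ``none``) are excluded before fitting.  Returns one
    row per cell with pss, jnd, lapse, threshold, n and convergence flag.
    """
    rows = []
    usable = trials[trials["report"].isin(["forward", "backward"])]
    for (condition, direction), grp in usable.groupby(["condition", "direction"], sort=True):
        fit = fit_cumulative_gaussian(
            grp["displacement"], grp["report"], lapse=lapse, fit_lapse=fit_lapse,
            min_trials=min_trials,
        )
        rows.append(
            {
                "condition": condition,
                "direction": direction,
                "pss": fit.pss,
                "jnd": fit.jnd,
                "lapse": fit.lapse,
                "threshold": threshold_75(fit),
                "n": fit.n_trials,
                "converged": fit.converged,
            }
        )
    return pd.DataFrame(rows)
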