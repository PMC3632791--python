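"""Individual-level deficit scores and classification against control norms.

Three per-subject measures capture distinct failure modes of corollary-
discharge monitoring:

* **Relative threshold** (BLANK / STEP, per saccade direction): healthy
  subjects improve markedly when the target blanks, so ratios sit well
  below 1; a missing blanking benefit drives the ratio toward or above 1.
* **Threshold asymmetry** (BLANK rightward minus BLANK leftward): lesions
  often spare one saccade direction, producing large signed asymmetries.
* **Error-attribution correlation**: BLANK trials are binned into eight
  equal-count bins by hypometria error; a positive correlation between bin
  mean error and proportion of forward reports means self-generated
  targeting errors are misread as stimulus jumps.

A subject is classified impaired on a measure when it falls beyond
mean + 1.96 SD (relative threshold, upper one-sided) or outside the
mean +/- 1.96 SD interval (asymmetry, two-sided) of the control sample.
Boundary equality does not count as impaired.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DataError
from .oculomotor import per_trial_errors

Z_CUTOFF = 1.96


@dataclass(frozen=True)
class ControlNorms:
    """Mean/SD/n of one measure over the control sample."""

    mean: float
    sd: float
    n: int

    def __post_init__(self) -> None:
        if self.sd <= 0:
            raise DataError("control SD must be positive")
        if self.n < 2:
            raise DataError("control norms need at least 2 subjects")


def relative_threshold(thr_blank: float, thr_step: float) -> float:
    """BLANK threshold relative to STEP; below 1 indicates a blanking benefit."""
    if thr_blank <= 0 or thr_step <= 0:
        raise DataError("thresholds must be positive")
    return thr_blank / thr_step


def classify(value: float, norms: ControlNorms, sided: str = "two_sided",
             z_cutoff: float = Z_CUTOFF) -> bool:
    """Flag a value as impaired relative to the control norms.

    ``two_sided`` flags values outside mean +/- z*SD; ``upper`` flags values
    strictly above mean + z*SD.  Values exactly on the boundary are not
    impaired.
    """
    if sided == "two_sided":
        return bool(abs(value - norms.mean) > z_cutoff * norms.sd)
    if sided == "upper":
        return bool(value - norms.mean > z_cutoff * norms.sd)
    raise DataError("sided must be 'two_sided' or 'upper'")


def error_bin_correlation(
    errors,
    forward,
    n_bins: int = 8,
) -> dict:
    """Correlate binned targeting error with the forward-report proportion.

    Trials are sorted by hypometria error and split into ``n_bins``
    contiguous bins of equal size (any remainder goes to the lowest-error
    bins); within each bin the mean error and the proportion of forward
    reports are computed and correlated (Pearson, two-sided,
    df = n_bins - 2).
    """
    errors = np.asarray(errors, dtype=float)
    forward = np.asarray(forward, dtype=float)
    if len(errors) != len(forward):
        raise DataError("errors and reports must have equal length")
    ok = np.isfinite(errors)
    errors, forward = errors[ok], forward[ok]
    n = len(errors)
    if n < n_bins:
        raise DataError(f"need at least {n_bins} trials, got {n}")

    order = np.argsort(errors, kind="stable")
    base, rem = divmod(n, n_bins)
    sizes = [base + 1] * rem + [base] * (n_bins - rem)
    bin_err, bin_prop = [], []
    start = 0
    for size in sizes:
        idx = order[start : start + size]
        bin_err.append(errors[idx].mean())
        bin_prop.append(forward[idx].mean())
        start += size
    bin_err = np.array(bin_err)
    bin_prop = np.array(bin_prop)

    if np.ptp(bin_prop) == 0 or np.ptp(bin_err) == 0:
        return {
            "r": np.nan,
            "p": 1.0,
            "n_bins": n_bins,
            "degenerate": True,
            "bin_errors": bin_err,
            "bin_proportions": bin_prop,
        }
    r, p = stats.pearsonr(bin_err, bin_prop)
    return {
        "r": float(r),
        "p": float(p),
        "n_bins": n_bins,
        "degenerate": False,
        "bin_errors": bin_err,
        "bin_proportions": bin_prop,
    }


def _subject_measures(fits: pd.DataFrame, trials: pd.DataFrame | None, n_bins: int) -> dict:
    """Derive the three deficit measures for one subject."""
    thr = {
        (row.condition, row.direction): row.threshold for row in fits.itertuples(index=False)
    }
    out: dict = {}
    for direction in ("leftward", "rightward"):
        blank = thr.get(("BLANK", direction))
        step = thr.get(("STEP", direction))
        out[f"thr_step_{direction}"] = step
        out[f"thr_blank_{direction}"] = blank
        out[f"relative_{direction}"] = (
            relative_threshold(blank, step) if blank is not None and step is not None else np.nan
        )
    bl, br = thr.get(("BLANK", "leftward")), thr.get(("BLANK", "rightward"))
    out["asymmetry"] = (br - bl) if bl is not None and br is not None else np.nan

    for direction in ("leftward", "rightward"):
        r = p = np.nan
        if trials is not None:
            sub = trials[
                (trials["condition"] == "BLANK")
                & (trials["direction"] == direction)
                & trials["report"].isin(["forward", "backward"])
            ]
            if len(sub) >= n_bins:
                per = per_trial_errors(sub)
                per = per[~per["excluded"]]
                if len(per) >= n_bins:
                    res = error_bin_correlation(
                        per["hypometria_error"], per["report"] == "forward", n_bins=n_bins
                    )
                    r, p = res["r"], res["p"]
        out[f"corr_r_{direction}"] = r
        out[f"corr_p_{direction}"] = p
    return out


def cohort_profiles(
    fits_by_subject: dict[str, pd.DataFrame],
    trials_by_subject: dict[str, pd.DataFrame] | None,
    control_ids,
    n_bins: int = 8,
    alpha: float = 0.05,
    z_cutoff: float = Z_CUTOFF,
) -> tuple[pd.DataFrame, dict[str, ControlNorms]]:
    """Score and classify every subject against control-derived norms.

    ``fits_by_subject`` maps subject id to a per-cell threshold table (as
    returned by :func:`transsacc.psychometrics.fit_condition_thresholds`);
    ``trials_by_subject`` optionally supplies trial tables for the
    error-attribution analysis.  Norms for the relative-threshold and
    asymmetry measures are computed over ``control_ids`` only.
    """
    control_ids = set(control_ids)
    missing = control_ids - set(fits_by_subject)
    if missing:
        raise DataError(f"control ids without fits: {sorted(missing)}")
    if len(control_ids) < 2:
        raise DataError("need at least 2 control subjects")

    rows = {}
    for subject, fits in fits_by_subject.items():
        trials = None if trials_by_subject is None else trials_by_subject.get(subject)
        rows[subject] = _subject_measures(fits, trials, n_bins)

    norms: dict[str, ControlNorms] = {}
    for measure in ("relative_leftward", "relative_rightward", "asymmetry"):
        vals = np.array([rows[s][measure] for s in control_ids], dtype=float)
        vals = vals[np.isfinite(vals)]
        if len(vals) < 2:
            raise DataError(f"not enough control values for {measure}")
        norms[measure] = ControlNorms(float(vals.mean()), float(vals.std(ddof=1)), len(vals))

    records = []
    for subject, m in rows.items():
        rec = {"subject": subject, "is_control": subject in control_ids, **m}
        for direction in ("leftward", "rightward"):
            val = m[f"relative_{direction}"]
            rec[f"impaired_relative_{direction}"] = (
                classify(val, norms[f"relative_{direction}"], "upper", z_cutoff)
                if np.isfinite(val)
                else None
            )
            p = m[f"corr_p_{direction}"]
            rec[f"impaired_attribution_{direction}"] = (
                bool(p < alpha) if np.isfinite(p) else None
            )
        rec["impaired_asymmetry"] = (
            classify(m["asymmetry"], norms["asymmetry"], "two_sided", z_cutoff)
            if np.isfinite(m["asymmetry"])
            else None
        )
        records.append(rec)
    return pd.DataFrame(records), norms
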