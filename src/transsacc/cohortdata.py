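"""Shipped cohort demographics and descriptive statistics.

The package ships the demographic and lesion characteristics of a
14-patient focal thalamic-stroke cohort (age in years, sex, years of
education, premorbid IQ estimate, time since lesion in months, lesion side,
lesion volume in cm^3) as a small delimited table used by the report stage.
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd


def load_patient_table() -> pd.DataFrame:
    """Load the shipped patient demographics/lesion table."""
    with resources.files("transsacc.data").joinpath("thalamic_cohort.csv").open() as fh:
        return pd.read_csv(fh)


def descriptive_stats(table: pd.DataFrame | None = None) -> dict:
    """Cohort descriptive statistics (means, sample SDs, side percentages).

    Percentages are on the 0-100 scale; SDs use the n-1 denominator.
    """
    t = load_patient_table() if table is None else table
    side = t["lesion_side"].astype(str)
    n = len(t)
    return {
        "n_patients": n,
        "mean_age_years": float(t["age"].mean()),
        "sd_age_years": float(t["age"].std(ddof=1)),
        "mean_tsl_months": float(t["tsl_months"].mean()),
        "mean_lesion_volume_cm3": float(t["lesion_volume_cm3"].mean()),
        "min_lesion_volume_cm3": float(t["lesion_volume_cm3"].min()),
        "max_lesion_volume_cm3": float(t["lesion_volume_cm3"].max()),
        "pct_unilateral_right": 100.0 * float(np.mean(side == "R")),
        "pct_unilateral_left": 100.0 * float(np.mean(side == "L")),
        "pct_bilateral": 100.0 * float(np.mean(side.str.startswith("B"))),
    }
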