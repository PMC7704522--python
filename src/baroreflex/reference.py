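"""Bundled reference dataset: per-subject summary statistics from a
nine-subject normocapnic-hypoxia crossover study of repeated
phenylephrine bolus testing.

Three tables ship with the package:

* ``reference_brs.csv`` — per-subject cardiovagal BRS (mean ± SEM in
  ms/mmHg) with the number of accepted boli per condition.
* ``reference_pressor.csv`` — per-subject pressor response ΔSBP
  (mean ± SEM in mmHg) with the number of analyzed boli.
* ``reference_respiratory.csv`` — per-subject respiratory rate, tidal
  volume, minute ventilation (mean ± SEM per condition), the hypoxic
  saturation drop ΔSpO2 (%), and the reported chemoreflex response.

These rows are the calibration source for the default synthetic cohort
and the ground truth against which the summary-statistic inference
layer is checked.  ``p_reported`` keeps the printed strings (including
censored values such as ``<0.001``); :func:`load_brs_table` adds parsed
``p_value`` and ``significant`` columns.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

# Cohort-level physiology used by the default synthetic cohort (values
# per condition, as reported for the study group).
GROUP_PHYSIOLOGY = {
    "normoxia": {
        "sbp_baseline": 133.0,
        "hr_baseline": 63.0,
        "spo2": 98.1,
        "etco2": 38.31,
    },
    "hypoxia": {
        "sbp_baseline": 135.0,
        "hr_baseline": 76.0,
        "spo2": 81.0,
        "etco2": 37.78,
    },
}


def _load(name: str) -> pd.DataFrame:
    with resources.files("baroreflex.data").joinpath(name).open("r") as fh:
        return pd.read_csv(fh, dtype={"subject": str})


def _parse_p(raw: str) -> float:
    """Printed p-values; '<x' is parsed as its upper bound x."""
    s = str(raw).strip()
    if s.startswith("<"):
        return float(s[1:])
    return float(s)


def _with_significance(df: pd.DataFrame) -> pd.DataFrame:
    df = df.copy()
    df["p_value"] = df["p_reported"].map(_parse_p)
    df["significant"] = df["p_value"] < 0.05
    return df


def load_brs_table() -> pd.DataFrame:
    """Per-subject cardiovagal BRS summaries (ms/mmHg)."""
    return _with_significance(_load("reference_brs.csv"))


def load_pressor_table() -> pd.DataFrame:
    """Per-subject phenylephrine pressor-response summaries (mmHg)."""
    return _with_significance(_load("reference_pressor.csv"))


def load_respiratory_table() -> pd.DataFrame:
    """Per-subject ventilation summaries and chemoreflex responses."""
    return _load("reference_respiratory.csv")
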