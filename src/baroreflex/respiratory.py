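"""Ventilation summaries and the hypoxic respiratory chemoreflex
response.

The chemoreflex response quantifies how strongly minute ventilation
rises per unit of arterial desaturation.  Note the scale: the value is
reported as 100 × ΔVe / ΔSpO2, i.e. the desaturation is treated as a
fraction rather than a percentage.  This convention is adopted because
it is the one under which the bundled reference table's chemoreflex
column is reproducible from its own ΔVe and ΔSpO2 cells; pass
``scaled=False`` for the plain (l/min)/% ratio.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .types import BaroreflexError, RespiratorySummary

CHEMOREFLEX_SCALE = 100.0


def chemoreflex_response(
    ve_norm: float, ve_hyp: float, delta_spo2: float, *, scaled: bool = True
) -> float:
    """Hypoxic ventilatory chemoreflex response.

    Parameters
    ----------
    ve_norm, ve_hyp
        Minute ventilation (l/min) in normoxia and hypoxia.
    delta_spo2
        Saturation drop in percentage points (normoxia − hypoxia); must
        be positive for a valid hypoxia exposure.
    scaled
        If True (default), return 100 × ΔVe/ΔSpO2 (the reference
        table's printed convention); otherwise the plain ratio.
    """
    if delta_spo2 <= 0:
        raise BaroreflexError(
            f"delta_spo2 must be positive for a hypoxia exposure, got {delta_spo2}"
        )
    ratio = (ve_hyp - ve_norm) / delta_spo2
    return (CHEMOREFLEX_SCALE if scaled else 1.0) * ratio


def cohort_chemoreflex_mean(responses) -> tuple[float, float]:
    """Arithmetic mean ± SEM of per-subject chemoreflex responses."""
    vals = np.asarray(responses, dtype=float)
    if vals.size == 0:
        raise BaroreflexError("need at least one chemoreflex response")
    mean = float(np.mean(vals))
    sem = float(np.std(vals, ddof=1) / math.sqrt(vals.size)) if vals.size > 1 else 0.0
    return mean, sem


def check_ventilation_consistency(row: RespiratorySummary, tol: float = 0.20) -> bool:
    """Device-derived minute ventilation should be ≈ rate × tidal volume.

    Returns True when both conditions agree within ``tol`` relative
    tolerance (device averages need not multiply exactly).
    """
    for rr, vt, ve in (
        (row.rr_normoxia, row.vt_normoxia, row.ve_normoxia),
        (row.rr_hypoxia, row.vt_hypoxia, row.ve_hypoxia),
    ):
        if ve <= 0 or abs(rr * vt - ve) > tol * ve:
            return False
    return True


def summarize_cohort(table: pd.DataFrame) -> pd.DataFrame:
    """Recompute chemoreflex responses from a respiratory summary table.

    Expects columns ``ve_normoxia``, ``ve_hypoxia``, ``delta_spo2``;
    returns a copy with a ``chemoreflex_response`` column on the
    100×ΔVe/ΔSpO2 scale.
    """
    out = table.copy()
    out["chemoreflex_response"] = [
        chemoreflex_response(vn, vh, ds)
        for vn, vh, ds in zip(out["ve_normoxia"], out["ve_hypoxia"], out["delta_spo2"])
    ]
    return out
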