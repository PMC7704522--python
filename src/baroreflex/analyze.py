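"""Rebuild study results from a persisted response table.

Lets the ``analyze`` stage run on a responses CSV produced earlier (or
by another tool emitting the same dialect) without re-extracting beats.
"""

from __future__ import annotations

import pandas as pd

from .model import StudyResults
from .types import BolusResponse, HYPOXIA, NORMOXIA


def _responses_from_frame(df: pd.DataFrame) -> list[BolusResponse]:
    out = []
    for r in df.itertuples():
        out.append(
            BolusResponse(
                bolus_index=int(r.bolus_index),
                sbp_baseline=float(r.sbp_baseline),
                sbp_peak=None if pd.isna(r.sbp_peak) else float(r.sbp_peak),
                delta_sbp=None if pd.isna(r.delta_sbp) else float(r.delta_sbp),
                brs_slope=None if pd.isna(r.brs_slope) else float(r.brs_slope),
                pearson_r=None if pd.isna(r.pearson_r) else float(r.pearson_r),
                n_beats_regression=int(r.n_beats),
                accepted=bool(r.accepted),
                reject_reason=None if pd.isna(r.reject_reason) else str(r.reject_reason),
            )
        )
    return out


def analyze_response_frame(
    df: pd.DataFrame,
    alpha: float = 0.05,
    *,
    equal_var: bool = False,
    holm: bool = False,
) -> StudyResults:
    """Individual + group inference from a response table.

    The frame must contain one row per bolus with ``subject`` and
    ``condition`` columns in the package's response dialect.
    """
    frames = []
    for subject in df["subject"].astype(str).unique():
        for cond in (NORMOXIA, HYPOXIA):
            sub = df[(df["subject"].astype(str) == subject) & (df["condition"] == cond)]
            frames.append((subject, cond, _responses_from_frame(sub)))
    return StudyResults._from_extraction(
        frames, alpha=alpha, equal_var=equal_var, holm=holm
    )
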