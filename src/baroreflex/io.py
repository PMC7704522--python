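"""CSV dialects and validated round-trip IO.

All artifacts are plain UTF-8 CSV with a mandatory header row and dot
decimals.  Every file written by the package starts with a ``#`` comment
line carrying the package version and, when available, the config hash
and seed, so any output table can be traced to the run that produced it.

Beat files:      beat_index,time_s,rri_ms,sbp_mmhg
Event files:     bolus_index,time_s,dose_ug,condition
Response files:  subject,condition,bolus_index,sbp_baseline,sbp_peak,
                 delta_sbp,brs_slope,pearson_r,n_beats,accepted,reject_reason
"""

from __future__ import annotations

import math
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .types import BeatSeries, BeatSeriesError, BolusEvent, BolusResponse

BEAT_COLUMNS = ["beat_index", "time_s", "rri_ms", "sbp_mmhg"]
EVENT_COLUMNS = ["bolus_index", "time_s", "dose_ug", "condition"]
RESPONSE_COLUMNS = [
    "subject", "condition", "bolus_index", "sbp_baseline", "sbp_peak",
    "delta_sbp", "brs_slope", "pearson_r", "n_beats", "accepted", "reject_reason",
]


def _meta_comment(config_hash: str | None = None, seed: int | None = None) -> str:
    parts = [f"baroreflex={__version__}"]
    if config_hash is not None:
        parts.append(f"config={config_hash}")
    if seed is not None:
        parts.append(f"seed={seed}")
    return "# " + " ".join(parts) + "\n"


def write_frame(
    df: pd.DataFrame,
    path: str | Path,
    *,
    config_hash: str | None = None,
    seed: int | None = None,
) -> None:
    """Write a DataFrame as CSV with the provenance comment header."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(_meta_comment(config_hash, seed))
        df.to_csv(fh, index=False)


def read_frame(path: str | Path) -> pd.DataFrame:
    # round_trip parsing: write->read must reproduce floats bit-exactly
    return pd.read_csv(path, comment="#", float_precision="round_trip")


def write_beats(
    beats: BeatSeries, path: str | Path, **meta
) -> None:
    df = pd.DataFrame(
        {
            "beat_index": np.arange(beats.n_beats),
            "time_s": beats.time_s,
            "rri_ms": beats.rri_ms,
            "sbp_mmhg": beats.sbp_mmhg,
        }
    )
    write_frame(df, path, **meta)


def read_beats(
    path: str | Path, subject_id: str = "?", condition: str = "?"
) -> BeatSeries:
    """Read and validate a beat series; errors carry beat indices."""
    df = read_frame(path)
    missing = [c for c in BEAT_COLUMNS if c not in df.columns]
    if missing:
        raise BeatSeriesError(f"{path}: missing columns {missing}")
    beats = BeatSeries(
        subject_id=subject_id,
        condition=condition,
        time_s=df["time_s"].to_numpy(float),
        rri_ms=df["rri_ms"].to_numpy(float),
        sbp_mmhg=df["sbp_mmhg"].to_numpy(float),
    )
    try:
        beats.validate()
    except BeatSeriesError as err:
        raise BeatSeriesError(f"{path}: {err}") from None
    return beats


def write_events(events: list[BolusEvent], path: str | Path, **meta) -> None:
    df = pd.DataFrame(
        {
            "bolus_index": [e.bolus_index for e in events],
            "time_s": [e.time_s for e in events],
            "dose_ug": [e.dose_ug for e in events],
            "condition": [e.condition for e in events],
        }
    )
    write_frame(df, path, **meta)


def read_events(path: str | Path) -> list[BolusEvent]:
    df = read_frame(path)
    return [
        BolusEvent(
            bolus_index=int(r.bolus_index),
            time_s=float(r.time_s),
            dose_ug=float(r.dose_ug) if not pd.isna(r.dose_ug) else math.nan,
            condition=None if pd.isna(r.condition) else str(r.condition),
        )
        for r in df.itertuples()
    ]


def responses_to_frame(
    responses: list[BolusResponse], subject: str, condition: str
) -> pd.DataFrame:
    rows = []
    for r in responses:
        rows.append(
            {
                "subject": subject,
                "condition": condition,
                "bolus_index": r.bolus_index,
                "sbp_baseline": r.sbp_baseline,
                "sbp_peak": r.sbp_peak,
                "delta_sbp": r.delta_sbp,
                "brs_slope": r.brs_slope,
                "pearson_r": r.pearson_r,
                "n_beats": r.n_beats_regression,
                "accepted": r.accepted,
                "reject_reason": r.reject_reason,
            }
        )
    return pd.DataFrame(rows, columns=RESPONSE_COLUMNS)


def comparisons_to_frame(comparisons) -> pd.DataFrame:
    rows = []
    for c in comparisons:
        rows.append(
            {
                "subject": c.subject_id,
                "metric": c.metric,
                "mean_normoxia": c.mean_normoxia,
                "sem_normoxia": c.sem_normoxia,
                "n_normoxia": c.n_normoxia,
                "mean_hypoxia": c.mean_hypoxia,
                "sem_hypoxia": c.sem_hypoxia,
                "n_hypoxia": c.n_hypoxia,
                "difference": c.difference,
                "t": c.t_statistic,
                "df": c.degrees_of_freedom,
                "p": c.p_value,
                "ci95_low": c.ci95_low,
                "ci95_high": c.ci95_high,
                "classification": c.classification,
            }
        )
    return pd.DataFrame(rows)


def group_to_frame(results) -> pd.DataFrame:
    rows = []
    for g in results:
        rows.append(
            {
                "metric": g.metric,
                "statistic": g.statistic,
                "group_mean_normoxia": g.group_mean_norm,
                "group_sem_normoxia": g.group_sem_norm,
                "group_mean_hypoxia": g.group_mean_hyp,
                "group_sem_hypoxia": g.group_sem_hyp,
                "mean_paired_difference": g.mean_paired_difference,
                "sem_paired_difference": g.sem_paired_difference,
                "paired_t": g.paired_t,
                "df": g.df,
                "p": g.p_value,
            }
        )
    return pd.DataFrame(rows)
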