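"""Synthetic beat-to-beat hemodynamics for repeated phenylephrine testing.

The forward model generates beats sequentially.  Beat ``i`` carries a
systolic pressure

    SBP_i = sbp_baseline + pressor(t_i) + e_i,    e_i ~ N(0, sbp_noise_sd²)

where ``pressor`` is a smooth unimodal transient per bolus (gamma-like
shape, peaking ``peak_time_s`` after injection).  The RR interval of the
*following* beat reflects the linear cardiovagal baroreflex:

    RRI_{i+1} = 60000/hr_baseline + g_j (SBP_i − sbp_baseline) + n_{i+1}

with ``n ~ N(0, rri_noise_sd²)`` and ``g_j`` the reflex gain during
bolus ``j``, drawn around ``brs_true`` (SD ``brs_bolus_sd``).  Beat
times advance by the RR interval, so tachycardia compresses and reflex
bradycardia stretches the sampling grid, as in a real recording.  RR
intervals saturate at the physiological range [300, 2000] ms.

Per-bolus pressor amplitudes are drawn around ``dsbp_true`` (SD
``dsbp_bolus_sd``, truncated below at 5 mmHg) so that repeated boli in
one subject scatter the way repeated Oxford-technique tests do.

Everything is deterministic given the seed; per-subject substreams are
keyed on the subject id so reordering a cohort never changes any
subject's data.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass, field, replace

import numpy as np

from .reference import GROUP_PHYSIOLOGY, load_brs_table, load_pressor_table, load_respiratory_table
from .types import (
    HYPOXIA,
    NORMOXIA,
    BaroreflexError,
    BeatSeries,
    BolusEvent,
    RespiratorySummary,
    ScheduleError,
)

# Shape of the pressor transient: rises to its maximum PEAK_TIME_S after
# injection and has decayed to <1% of the peak by ~180 s.
PEAK_TIME_S = 35.0
SHAPE_K = 2.0

# Lower truncation for per-bolus pressor amplitudes (mmHg).
MIN_AMPLITUDE = 5.0


@dataclass(frozen=True)
class ConditionParams:
    """True physiology of one subject under one condition.

    Units: pressures mmHg, heart rate beats/min, BRS ms/mmHg, noise SDs
    in the unit of the quantity they perturb, ventilation l/min, tidal
    volume l, respiratory rate breaths/min, SpO2 %, ETCO2 mmHg.
    """

    label: str
    sbp_baseline: float = 133.0
    hr_baseline: float = 63.0
    brs_true: float = 19.9
    dsbp_true: float = 22.0
    brs_bolus_sd: float = 5.0
    dsbp_bolus_sd: float = 5.0
    rri_noise_sd: float = 10.0
    sbp_noise_sd: float = 2.0
    spo2: float = 98.1
    ve: float = 11.9
    vt: float = 0.77
    rr_breaths: float = 16.0
    etco2: float = 38.3
    rsa_amplitude_ms: float = 0.0  # respiratory sinus arrhythmia, off by default

    def __post_init__(self) -> None:
        if self.brs_true < 0:
            raise ValueError("brs_true must be >= 0")
        if self.sbp_baseline <= 0 or self.hr_baseline <= 0:
            raise ValueError("sbp_baseline and hr_baseline must be positive")
        if not 0 < self.spo2 <= 100:
            raise ValueError("spo2 must be in (0, 100]")
        rri = 60000.0 / self.hr_baseline
        if not 300.0 <= rri <= 2000.0:
            raise ValueError(
                f"hr_baseline {self.hr_baseline} implies RRI {rri:.0f} ms "
                "outside 300-2000 ms"
            )
        for name in ("brs_bolus_sd", "dsbp_bolus_sd", "rri_noise_sd", "sbp_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass(frozen=True)
class BolusSchedule:
    """Timing of the repeated phenylephrine boli within one condition."""

    n_boli: int = 20
    interval_s: float = 240.0
    dose_ug: float = 50.0
    first_bolus_s: float = 120.0

    def __post_init__(self) -> None:
        if self.n_boli < 1:
            raise ValueError("n_boli must be >= 1")
        if self.interval_s <= 60:
            raise ValueError(
                "interval_s must exceed 60 s (peak window must not reach "
                "the next baseline window)"
            )
        if self.first_bolus_s <= 0:
            raise ValueError("first_bolus_s must be positive")

    def times(self) -> np.ndarray:
        return self.first_bolus_s + self.interval_s * np.arange(self.n_boli)

    def duration_needed_s(self) -> float:
        return float(self.times()[-1] + 60.0 + 60.0)


@dataclass(frozen=True)
class SubjectSpec:
    """Paired true physiology of one subject in both conditions."""

    subject_id: str
    normoxia: ConditionParams
    hypoxia: ConditionParams
    schedule: BolusSchedule = field(default_factory=BolusSchedule)
    first_condition: str = NORMOXIA


@dataclass
class SubjectRecording:
    """Simulated recording of one subject: both conditions plus truth."""

    subject_id: str
    condition_order: tuple[str, str]
    beats: dict[str, BeatSeries]
    events: dict[str, list[BolusEvent]]
    truth: dict[str, ConditionParams]
    respiratory: RespiratorySummary | None = None


def _transient(u: float, peak_time_s: float, shape_k: float) -> float:
    """Unimodal gamma-like pulse, 0 at u<=0, 1 at u=peak_time_s."""
    if u <= 0.0:
        return 0.0
    x = u / peak_time_s
    return (x ** shape_k) * math.exp(shape_k * (1.0 - x))


def _draw_amplitudes(
    rng: np.random.Generator, mean: float, sd: float, n: int
) -> np.ndarray:
    if sd == 0.0:
        return np.full(n, mean)
    amps = rng.normal(mean, sd, size=n)
    for _ in range(100):
        low = amps < MIN_AMPLITUDE
        if not low.any():
            break
        amps[low] = rng.normal(mean, sd, size=int(low.sum()))
    return np.clip(amps, MIN_AMPLITUDE, None)


def simulate_beats(
    params: ConditionParams,
    schedule: BolusSchedule,
    duration_s: float,
    seed: int | np.random.SeedSequence,
    *,
    peak_time_s: float = PEAK_TIME_S,
    shape_k: float = SHAPE_K,
    subject_id: str = "sim",
) -> tuple[BeatSeries, list[BolusEvent]]:
    """Simulate one subject-condition recording.

    ``duration_s`` must cover every bolus plus its 60 s peak-search
    window; otherwise a :class:`ScheduleError` names the first bolus
    that does not fit.
    """
    bolus_times = schedule.times()
    too_late = np.flatnonzero(bolus_times + 60.0 > duration_s)
    if too_late.size:
        k = int(too_late[0])
        raise ScheduleError(
            f"bolus {k} at t={bolus_times[k]:.0f} s needs its 60 s peak "
            f"window inside duration_s={duration_s:.0f} s"
        )

    rng = np.random.default_rng(seed)
    base_rri = 60000.0 / params.hr_baseline
    n_max = int(duration_s * params.hr_baseline / 60.0 * 1.5) + 20

    amps = _draw_amplitudes(rng, params.dsbp_true, params.dsbp_bolus_sd, schedule.n_boli)
    gains = rng.normal(params.brs_true, params.brs_bolus_sd, size=schedule.n_boli)
    gains = np.clip(gains, 0.0, None) if params.brs_bolus_sd else np.full(schedule.n_boli, params.brs_true)
    sbp_noise = rng.normal(0.0, 1.0, size=n_max) * params.sbp_noise_sd
    rri_noise = rng.normal(0.0, 1.0, size=n_max + 1) * params.rri_noise_sd

    bt = bolus_times.tolist()
    n_boli = schedule.n_boli
    rsa = params.rsa_amplitude_ms
    two_pi_f = 2.0 * math.pi * params.rr_breaths / 60.0

    times = np.empty(n_max)
    rris = np.empty(n_max)
    sbps = np.empty(n_max)

    t = 0.0
    nxt = min(max(base_rri + rri_noise[0], 300.0), 2000.0)
    b = -1  # most recent bolus index
    i = 0
    sbp_base = params.sbp_baseline
    exp = math.exp
    while t <= duration_s and i < n_max:
        while b + 1 < n_boli and bt[b + 1] <= t:
            b += 1
        if b >= 0:
            u = t - bt[b]
            if u > 0.0:
                x = u / peak_time_s
                press = amps[b] * (x ** shape_k) * exp(shape_k * (1.0 - x))
            else:
                press = 0.0
            gain = gains[b]
        else:
            press = 0.0
            gain = params.brs_true
        sbp = sbp_base + press + sbp_noise[i]
        times[i] = t
        rris[i] = nxt
        sbps[i] = sbp
        nxt = base_rri + gain * (sbp - sbp_base) + rri_noise[i + 1]
        if rsa:
            nxt += rsa * math.sin(two_pi_f * t)
        # reflex saturation: keep RR in the physiological band
        nxt = min(max(nxt, 300.0), 2000.0)
        t += nxt / 1000.0
        i += 1

    beats = BeatSeries(
        subject_id=subject_id,
        condition=params.label,
        time_s=times[:i].copy(),
        rri_ms=rris[:i].copy(),
        sbp_mmhg=sbps[:i].copy(),
    )
    events = [
        BolusEvent(bolus_index=k, time_s=float(bt[k]), dose_ug=schedule.dose_ug,
                   condition=params.label)
        for k in range(n_boli)
    ]
    return beats, events


def _subject_entropy(subject_id: str) -> int:
    digest = hashlib.sha256(subject_id.encode("utf-8")).digest()
    return int.from_bytes(digest[:4], "big")


def _simulate_respiratory(
    spec: SubjectSpec, rng: np.random.Generator
) -> RespiratorySummary:
    """Session-mean ventilation summary with small measurement jitter."""
    pn, ph = spec.normoxia, spec.hypoxia
    ve_n = pn.ve + rng.normal(0.0, 0.1)
    ve_h = ph.ve + rng.normal(0.0, 0.1)
    dspo2 = pn.spo2 - ph.spo2
    from .respiratory import chemoreflex_response

    # no desaturation (e.g. a null subject): the chemoreflex ratio is undefined
    chemo = chemoreflex_response(ve_n, ve_h, dspo2) if dspo2 > 0 else float("nan")
    return RespiratorySummary(
        subject_id=spec.subject_id,
        rr_normoxia=pn.rr_breaths + rng.normal(0.0, 0.1),
        rr_hypoxia=ph.rr_breaths + rng.normal(0.0, 0.1),
        vt_normoxia=pn.vt + rng.normal(0.0, 0.01),
        vt_hypoxia=ph.vt + rng.normal(0.0, 0.01),
        ve_normoxia=ve_n,
        ve_hypoxia=ve_h,
        delta_spo2=dspo2,
        chemoreflex_response=chemo,
    )


def simulate_cohort(
    cohort: list[SubjectSpec],
    seed: int,
    *,
    randomize_order: bool = False,
) -> list[SubjectRecording]:
    """Simulate every subject of a cohort with independent substreams.

    Each subject-condition stream is seeded from ``(seed, H(subject_id),
    condition)``, so adding, removing or reordering subjects leaves the
    other recordings bit-identical.
    """
    ids = [s.subject_id for s in cohort]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise BaroreflexError(f"duplicate subject ids: {', '.join(dupes)}")

    recordings = []
    for spec in cohort:
        ent = _subject_entropy(spec.subject_id)
        beats: dict[str, BeatSeries] = {}
        events: dict[str, list[BolusEvent]] = {}
        for ci, params in enumerate((spec.normoxia, spec.hypoxia)):
            ss = np.random.SeedSequence([int(seed), ent, ci])
            duration = spec.schedule.duration_needed_s()
            bs, ev = simulate_beats(
                params, spec.schedule, duration, ss, subject_id=spec.subject_id
            )
            beats[params.label] = bs
            events[params.label] = ev
        aux_rng = np.random.default_rng(np.random.SeedSequence([int(seed), ent, 2]))
        if randomize_order:
            first = NORMOXIA if aux_rng.random() < 0.5 else HYPOXIA
        else:
            first = spec.first_condition
        order = (first, HYPOXIA if first == NORMOXIA else NORMOXIA)
        recordings.append(
            SubjectRecording(
                subject_id=spec.subject_id,
                condition_order=order,
                beats=beats,
                events=events,
                truth={NORMOXIA: spec.normoxia, HYPOXIA: spec.hypoxia},
                respiratory=_simulate_respiratory(spec, aux_rng),
            )
        )
    return recordings


def _calibrated_dsbp_sd(table_sd: float, sbp_noise_sd: float, run: int = 3,
                        baseline_beats: int = 10) -> float:
    """Per-bolus amplitude SD that reproduces an observed ΔSBP SD.

    The measured ΔSBP adds window-averaging noise to the amplitude
    scatter: var = sd_amp² + σ²(1/run + 1/baseline_beats).  Invert and
    floor at 0.5 mmHg.
    """
    noise_var = sbp_noise_sd ** 2 * (1.0 / run + 1.0 / baseline_beats)
    return math.sqrt(max(table_sd ** 2 - noise_var, 0.25))


def default_cohort(
    schedule: BolusSchedule | None = None,
    *,
    rri_noise_sd: float = 10.0,
    sbp_noise_sd: float = 2.0,
) -> list[SubjectSpec]:
    """The nine-subject cohort calibrated to the bundled reference tables.

    Per-bolus SDs are set to SEM×√n from the per-subject BRS and ΔSBP
    summary rows; baseline SBP/HR, SpO2 and ETCO2 come from the group
    physiology; ventilation comes from the respiratory table.
    """
    schedule = schedule or BolusSchedule()
    brs = load_brs_table().set_index("subject")
    dsbp = load_pressor_table().set_index("subject")
    resp = load_respiratory_table().set_index("subject")

    cohort: list[SubjectSpec] = []
    for sid in brs.index:
        conds = {}
        for cond in (NORMOXIA, HYPOXIA):
            phys = GROUP_PHYSIOLOGY[cond]
            b_mean = float(brs.loc[sid, f"mean_{cond}"])
            b_sd = float(brs.loc[sid, f"sem_{cond}"]) * math.sqrt(
                float(brs.loc[sid, f"n_{cond}"])
            )
            d_mean = float(dsbp.loc[sid, f"mean_{cond}"])
            d_sd = float(dsbp.loc[sid, f"sem_{cond}"]) * math.sqrt(
                float(dsbp.loc[sid, f"n_{cond}"])
            )
            spo2 = phys["spo2"]
            if cond == HYPOXIA:
                # per-subject saturation drop from the respiratory table
                spo2 = GROUP_PHYSIOLOGY[NORMOXIA]["spo2"] - float(
                    resp.loc[sid, "delta_spo2"]
                )
            conds[cond] = ConditionParams(
                label=cond,
                sbp_baseline=phys["sbp_baseline"],
                hr_baseline=phys["hr_baseline"],
                brs_true=b_mean,
                dsbp_true=d_mean,
                brs_bolus_sd=b_sd,
                dsbp_bolus_sd=_calibrated_dsbp_sd(d_sd, sbp_noise_sd),
                rri_noise_sd=rri_noise_sd,
                sbp_noise_sd=sbp_noise_sd,
                spo2=spo2,
                ve=float(resp.loc[sid, f"ve_{cond}"]),
                vt=float(resp.loc[sid, f"vt_{cond}"]),
                rr_breaths=float(resp.loc[sid, f"rr_{cond}"]),
                etco2=phys["etco2"],
            )
        cohort.append(
            SubjectSpec(
                subject_id=str(sid),
                normoxia=conds[NORMOXIA],
                hypoxia=conds[HYPOXIA],
                schedule=schedule,
                first_condition=str(brs.loc[sid, "first_condition"]),
            )
        )
    return cohort


def with_schedule(cohort: list[SubjectSpec], schedule: BolusSchedule) -> list[SubjectSpec]:
    """Return a copy of the cohort with every subject on ``schedule``."""
    return [replace(s, schedule=schedule) for s in cohort]
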