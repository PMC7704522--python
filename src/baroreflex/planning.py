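"""How many bolus repetitions are needed to detect an individual
BRS change?

Two readings of "sensitivity versus repetitions" are provided:

* ``ttest_power`` — an individual responds when their per-subject Welch
  test reaches p < alpha; sensitivity is the detection rate among true
  responders (effect drawn from N(effect_mean, effect_sd²)).
* ``roc_mean_classifier`` — the observed mean condition difference is
  used as a score to discriminate responders from non-responders; the
  curve reports the sensitivity at the Youden-optimal ROC point and the
  AUC.

A closed-form noncentral-t power calculation cross-checks the
Monte-Carlo route.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_curve

from .types import BaroreflexError

METHOD_TTEST = "ttest_power"
METHOD_ROC = "roc_mean_classifier"


@dataclass(frozen=True)
class PlanSpec:
    """Design assumptions for the repetition-number simulation.

    ``effect_mean``/``effect_sd`` describe the distribution of true
    individual BRS differences between conditions (ms/mmHg);
    ``bolus_sd`` is the within-condition per-bolus SD.
    """

    effect_mean: float = 6.0
    effect_sd: float = 3.0
    bolus_sd: float = 6.5
    n_grid: tuple[int, ...] = (2, 4, 6, 8, 10, 12, 15, 20)
    n_sim: int = 2000
    alpha: float = 0.05
    target_sensitivity: float = 0.9
    seed: int = 0
    method: str = METHOD_TTEST

    def __post_init__(self) -> None:
        if self.effect_sd < 0:
            raise ValueError("effect_sd must be >= 0")
        if self.bolus_sd <= 0:
            raise BaroreflexError("bolus_sd must be positive")
        if any(n < 2 for n in self.n_grid):
            raise ValueError("n_grid entries must be >= 2")
        if not 0 < self.target_sensitivity < 1:
            raise ValueError("target_sensitivity must be in (0, 1)")
        if self.method not in (METHOD_TTEST, METHOD_ROC):
            raise ValueError(f"unknown method {self.method!r}")


@dataclass
class PlanResult:
    """Sensitivity-versus-repetitions curve."""

    spec: PlanSpec
    curve: pd.DataFrame  # columns: n, sensitivity, mc_se [, auc, threshold]
    minimal_n: int | None

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        tail = f"minimal_n={self.minimal_n}" if self.minimal_n else "target not met"
        return f"<PlanResult method={self.spec.method} {tail}>"


def _welch_p_rows(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Row-wise Welch p-values for two (n_sim, n) observation blocks."""
    n1, n2 = x.shape[1], y.shape[1]
    m1, m2 = x.mean(axis=1), y.mean(axis=1)
    v1 = x.var(axis=1, ddof=1) / n1
    v2 = y.var(axis=1, ddof=1) / n2
    se2 = v1 + v2
    se2 = np.where(se2 == 0.0, np.finfo(float).tiny, se2)
    t = (m1 - m2) / np.sqrt(se2)
    df = se2 ** 2 / (v1 ** 2 / (n1 - 1) + v2 ** 2 / (n2 - 1))
    return 2.0 * stats.t.sf(np.abs(t), df)


def sensitivity_curve(spec: PlanSpec) -> PlanResult:
    """Monte-Carlo sensitivity of the individual decision rule at each
    candidate repetition count.

    For every ``n`` in the grid, ``n_sim`` responders (true difference
    drawn from the effect distribution) and ``n_sim`` non-responders
    (true difference 0) are simulated with ``n`` boli per condition and
    per-bolus noise ``bolus_sd``.  Deterministic given ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    rows = []
    for n in spec.n_grid:
        true_d = rng.normal(spec.effect_mean, spec.effect_sd, size=spec.n_sim)
        resp_norm = rng.normal(0.0, spec.bolus_sd, size=(spec.n_sim, n))
        resp_hyp = true_d[:, None] + rng.normal(0.0, spec.bolus_sd, size=(spec.n_sim, n))
        null_norm = rng.normal(0.0, spec.bolus_sd, size=(spec.n_sim, n))
        null_hyp = rng.normal(0.0, spec.bolus_sd, size=(spec.n_sim, n))
        if spec.method == METHOD_TTEST:
            p = _welch_p_rows(resp_hyp, resp_norm)
            sens = float(np.mean(p < spec.alpha))
            rows.append(
                {
                    "n": n,
                    "sensitivity": sens,
                    "mc_se": math.sqrt(max(sens * (1 - sens), 1e-12) / spec.n_sim),
                }
            )
        else:
            scores = np.concatenate(
                [
                    (resp_hyp.mean(axis=1) - resp_norm.mean(axis=1)),
                    (null_hyp.mean(axis=1) - null_norm.mean(axis=1)),
                ]
            )
            labels = np.concatenate(
                [np.ones(spec.n_sim, dtype=int), np.zeros(spec.n_sim, dtype=int)]
            )
            fpr, tpr, thr = roc_curve(labels, scores)
            auc = float(np.trapezoid(tpr, fpr))
            j = int(np.argmax(tpr - fpr))  # Youden-optimal operating point
            sens = float(tpr[j])
            rows.append(
                {
                    "n": n,
                    "sensitivity": sens,
                    "mc_se": math.sqrt(max(sens * (1 - sens), 1e-12) / spec.n_sim),
                    "auc": auc,
                    "threshold": float(thr[j]),
                }
            )
    curve = pd.DataFrame(rows)
    meets = curve[curve["sensitivity"] >= spec.target_sensitivity]
    minimal_n = int(meets["n"].iloc[0]) if len(meets) else None
    return PlanResult(spec=spec, curve=curve, minimal_n=minimal_n)


def closed_form_power(
    delta: float, bolus_sd: float, n_per_arm: int, alpha: float = 0.05
) -> float:
    """Two-sample t-test power via the noncentral t distribution.

    Noncentrality is delta / (bolus_sd · √(2/n)); degrees of freedom
    2n − 2.  At delta = 0 this returns alpha exactly.
    """
    if n_per_arm < 2:
        raise ValueError("n_per_arm must be >= 2")
    if bolus_sd <= 0:
        raise BaroreflexError("bolus_sd must be positive")
    df = 2 * n_per_arm - 2
    ncp = delta / (bolus_sd * math.sqrt(2.0 / n_per_arm))
    tcrit = stats.t.ppf(1.0 - alpha / 2.0, df)
    return float(stats.nct.sf(tcrit, df, ncp) + stats.nct.cdf(-tcrit, df, ncp))


def derive_bolus_sd_from_table(sems, ns) -> float:
    """Median per-bolus SD implied by per-subject SEM and bolus counts.

    Each row contributes SD = SEM × √n; the median across rows is the
    default ``bolus_sd`` for :class:`PlanSpec`.
    """
    sems = np.asarray(sems, dtype=float)
    ns = np.asarray(ns, dtype=float)
    if sems.size == 0:
        raise BaroreflexError("need at least one row")
    if (ns <= 0).any():
        raise BaroreflexError("bolus counts must be positive")
    return float(np.median(sems * np.sqrt(ns)))


def default_plan_spec(**overrides) -> PlanSpec:
    """Plan spec with ``bolus_sd`` derived from the bundled BRS table."""
    from .reference import load_brs_table

    tab = load_brs_table()
    sems = np.concatenate([tab["sem_normoxia"], tab["sem_hypoxia"]])
    ns = np.concatenate([tab["n_normoxia"], tab["n_hypoxia"]])
    kwargs = {"bolus_sd": derive_bolus_sd_from_table(sems, ns)}
    kwargs.update(overrides)
    return PlanSpec(**kwargs)
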