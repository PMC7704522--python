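# Methods

This note records the model, the estimators, the synthetic-data design
and the numerical conventions, together with the reasoning behind the
choices that were genuinely open.

## Per-bolus estimators

**Baseline SBP** is the arithmetic mean of the 10 beats immediately
preceding the injection, regardless of elapsed time ("readings" in a
beat-indexed record are beats). **Peak SBP** is the maximal mean of 3
*consecutive* beats whose times fall in the window (t_bolus,
t_bolus + 60 s]; the window clock starts at injection start, which is
the only timestamp an automated injector log provides. Ties are broken
toward the earliest window; the peak time is the central beat of the
winning window. **ΔSBP = peak − baseline** exactly.

**BRS** is the ordinary least-squares slope of RRI(i+lag) on SBP(i)
over the *rise phase*, with lag = 1 by default: each systolic value is
paired with the RR interval ending at the next beat ("the following RR
interval"). The regression keeps an intercept; a zero-intercept fit of
raw RRI on raw SBP would force the line through the origin, which is
physiologically meaningless. lag is configurable in {0, 1, 2} because
pairing conventions differ between laboratories.

The rise phase needs an objective onset, which the Oxford tradition
leaves implicit. Here: from the first post-bolus beat whose SBP exceeds
baseline + 2 × SD(10 pre-bolus SBP values) up to and including the
central beat of the peak window, with a configurable minimum of 5
pairs. With noise-free data the threshold reduces to the baseline
itself and the slope is recovered exactly.

A slope is **accepted** iff Pearson r > 0.5, strict; r is computed on
exactly the regression pairs. Rejected boli are retained with
`accepted=False` and a reason, so the BRS and ΔSBP metrics can
legitimately count different numbers of boli (ΔSBP uses every bolus
with a valid baseline/peak pair).

Known small-sample behaviour, deliberate and tested: the max-of-windows
peak statistic is positively biased under beat noise (≈ +1–3 mmHg at
the default 2 mmHg SBP noise), identically in both conditions, so
condition *differences* are unaffected. The r > 0.5 filter truncates
the accepted-slope distribution; for subjects whose per-bolus slope SD
is large relative to the mean, the accepted-bolus mean is biased
upward by a fraction of one SEM.

## Individual (N-of-1) inference

Per subject and metric, the two conditions are compared with an
unpaired t test on the per-bolus values. Welch (unequal variances) is
the default — the safer choice when acceptance filtering can leave
different n and dispersion per condition — with the pooled test behind
a flag; the two coincide when SEMs and n match. `welch_t_from_summary`
is a pure function of (mean, SEM, n) per arm so that published summary
rows can be re-tested directly; on raw samples the two routes agree to
numerical precision by construction.

Differences are reported as hypoxia − normoxia with a 95% CI from the
Welch standard error and Welch–Satterthwaite df. Classification:
decreased / increased when p < α (default 0.05) with the corresponding
sign, else unchanged. No multiple-testing correction is applied by
default — each subject is their own trial and the per-subject error
rate is the quantity of interest — but a Holm option across the cohort
is available.

## Group inference

The cohort test is a paired t test on per-subject *medians* of the
per-bolus values (robust to occasional outlying boli); display tables
use per-subject means ± SEM. Both statistics are computed and labelled,
because the two summaries answer different questions and mixing them
silently is a classic reproducibility trap. The BRS-change versus
pressor-change relation is a Pearson correlation of the per-subject
mean differences.

## Synthetic cohort

The generator emulates the statistical structure the estimators assume,
not the physiology of a particular device:

* Beats are generated sequentially; beat times advance by the RR
  interval (the interval *ending* at a beat is stored with that beat),
  so reflex bradycardia stretches the sampling grid exactly as in a
  real record.
* SBP(t) = baseline + pressor(t) + white noise (default SD 2 mmHg).
  The pressor transient of each bolus is a gamma-like pulse
  (x^k e^{k(1−x)}, k = 2, x = t/35 s): peak 35 s after injection,
  < 1% of peak by ~180 s. Only the most recent bolus contributes
  (< 0.01 mmHg residual at the 240 s spacing). Per-bolus amplitudes
  are drawn around the condition's true ΔSBP, truncated at 5 mmHg.
* RRI(i+1) = 60000/HR + g_j · (SBP_i − baseline) + white noise
  (default SD 10 ms), where g_j is the reflex gain during bolus j,
  drawn around the condition's true BRS. RR intervals saturate at the
  physiological band [300, 2000] ms (reflex saturation); without the
  bound, high-gain subjects paired with large pressor amplitudes would
  occasionally produce intervals no validator should accept.
* Per-bolus gain and amplitude variability carry the repeat-test
  dispersion: beat-level RRI noise alone cannot produce per-bolus slope
  SDs of 3.5–13 ms/mmHg at physiological noise levels, so the
  between-bolus component is modelled explicitly. With all SDs at zero
  the estimators recover the true slope and amplitude exactly — a
  contract the tests enforce.
* Optional respiratory sinus arrhythmia (a sinusoid at the breathing
  rate added to RRI, off by default) lets users probe the claim that
  the pharmacological technique is relatively insensitive to
  ventilatory modulation.

The **default nine-subject cohort** is calibrated from the bundled
reference tables: per subject and condition, true BRS and ΔSBP equal
the tabulated means and the per-bolus SDs equal SEM × √n (for ΔSBP,
after subtracting the analytic window-averaging noise contribution,
σ²(1/3 + 1/10)). Baseline physiology is the group level: SBP 133/135
mmHg, HR 63/76 bpm, SpO2 98.1% versus 98.1 − ΔSpO2 (per-subject drop
from the respiratory table), ETCO2 ≈ 38 mmHg. The schedule is 20 boli,
one every 240 s, first at 120 s. These defaults *are* the study
conditions; they are not tuning knobs.

Per-subject random substreams are keyed on (seed, hash(subject_id),
condition), so editing or reordering a cohort never changes another
subject's data.

What the generator does **not** emulate — and what passing tests
therefore do not establish about real recordings: slow baseline drift
and the hypoxia onset ramp (conditions are stationary; all boli occur
after the ramp), autocorrelated or heavy-tailed beat noise, waveform-
level artefacts upstream of beat detection, dose–response
pharmacokinetics, and any coupling between the respiratory summaries
and the beat series beyond the optional sinusoid.

## Repetition planning

"How many boli?" is answered by simulating individuals: a responder's
true condition difference is drawn from Normal(6, 3²) ms/mmHg (the
individual-effect distribution the cohort suggests), a non-responder's
is 0, and each simulated individual gets n boli per condition with
per-bolus SD derived from the reference table (median SEM × √n ≈ 6.5
ms/mmHg). Two readings of "sensitivity" are reported side by side,
because the original ROC procedure is not fully specified and asserting
one interpretation would overreach:

* **ttest_power** — fraction of responders whose own Welch test reaches
  p < α; cross-validated against the closed-form noncentral-t power
  (df 2n − 2, noncentrality δ/(σ√(2/n))). At very small n the Welch
  route is measurably conservative relative to the equal-variance
  closed form (random Satterthwaite df < 2n − 2); from n ≈ 10 — the
  design-relevant range — the two agree within Monte-Carlo error, and
  that is where the cross-check grid sits.
* **roc_mean_classifier** — the observed mean difference scores
  responders against non-responders; the curve reports AUC and the
  sensitivity at the Youden-optimal threshold. As n grows the AUC
  approaches the separation implied by the effect distribution alone
  (Φ(6/3) ≈ 0.977), a limit the tests check at n = 200.

## Respiratory chemoreflex

The chemoreflex response is reported as 100 × ΔVe/ΔSpO2. The ×100
convention is adopted because recomputing the reference table's
chemoreflex column from its own ΔVe and ΔSpO2 cells requires it (the
plain ratio is available behind a flag); each cell reproduces within
0.25 of the printed value, the rounding envelope of two-decimal inputs.
Minute ventilation is checked against rate × tidal volume within ±20% —
device-derived session averages need not multiply exactly.

## Numerical conventions

* Peak-window ties → earliest window; even-count medians → midpoint of
  the central order statistics.
* Degenerate tests: both SEMs zero with equal means → t = 0, p = 1;
  unequal means → signed infinite t, p = 0. Zero-variance correlation
  → NaN flag rather than an exception.
* CSV round-trips are bit-exact (floats are written at shortest
  round-trip precision and parsed with round-trip parsing); every
  output table carries the package version, config hash and seed in a
  leading comment line.
* Validation bounds: RRI 300–2000 ms, SBP 50–300 mmHg, strictly
  increasing beat times; violations are reported with beat indices.
* Simulation sizes in the test suite (100 seeded cohort replicates for
  parameter recovery, 2500 null replicates for error calibration,
  4000 simulated individuals per planning grid point) are chosen so
  Monte-Carlo error is small against the tolerance being checked.

## Limitations

The N-of-1 layer treats boli as exchangeable replicates; slow
within-session trends would inflate the apparent per-bolus variance.
Carry-over between conditions is not modelled (the crossover design
randomizes order, and order effects are checked descriptively, not
adjusted for). The planner assumes normal per-bolus values and a normal
individual-effect distribution; both are conventions, adopted because
the inference layer is t-based. The bundled reference rows are printed
summaries rounded to one or two decimals, which bounds how exactly any
derived statistic can be reproduced (reconstructed t values agree to
~1%, except two tabulated t entries that are not reproducible from
their own row's cells under any t-test variant; the classification
counts are unaffected).
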