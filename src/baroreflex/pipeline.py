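"""End-to-end pipeline: simulate → extract → analyze → plan → report.

Every stage writes plain CSV artifacts stamped with the config hash and
seed; a run log records per-stage record counts and per-bolus rejection
reasons so that boli excluded from the BRS metric are auditable.
Identical config + seed produces byte-identical outputs.
"""

from __future__ import annotations

import logging
from pathlib import Path

import pandas as pd

from .config import PipelineConfig, config_hash, dump_config
from .io import (
    comparisons_to_frame,
    group_to_frame,
    write_beats,
    write_events,
    write_frame,
)
from .model import BaroreflexStudy, SubjectData
from .respiratory import cohort_chemoreflex_mean
from .simulate import simulate_cohort
from .types import HYPOXIA, METRICS, NORMOXIA

log = logging.getLogger("baroreflex")


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> dict:
    """Execute all stages; returns a dict of result objects.

    Writes, under ``outdir``: per-subject beat/event CSVs, the response
    table, the individual-comparison table, the group table, the
    respiratory summary, the plan curve, forest/correlation figures,
    the resolved config, and ``run.log``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    chash = config_hash(config)
    meta = {"config_hash": chash, "seed": config.seed}

    handler = logging.FileHandler(outdir / "run.log", mode="w", encoding="utf-8")
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    try:
        log.info("config hash %s seed %d", chash, config.seed)
        dump_config(config, outdir / "config.yaml")

        # -- simulate --------------------------------------------------
        specs = config.subject_specs()
        recordings = simulate_cohort(
            specs, config.seed, randomize_order=config.randomize_order
        )
        beat_dir = outdir / "recordings"
        for rec in recordings:
            for cond in (NORMOXIA, HYPOXIA):
                stem = f"{rec.subject_id}_{cond}"
                write_beats(rec.beats[cond], beat_dir / f"{stem}_beats.csv", **meta)
                write_events(rec.events[cond], beat_dir / f"{stem}_events.csv", **meta)
        log.info("simulate: %d subjects x 2 conditions", len(recordings))

        resp_rows = [
            {
                "subject": rec.subject_id,
                **{
                    k: getattr(rec.respiratory, k)
                    for k in (
                        "rr_normoxia", "rr_hypoxia", "vt_normoxia", "vt_hypoxia",
                        "ve_normoxia", "ve_hypoxia", "delta_spo2",
                        "chemoreflex_response",
                    )
                },
            }
            for rec in recordings
            if rec.respiratory is not None
        ]
        respiratory = pd.DataFrame(resp_rows)
        if len(respiratory):
            write_frame(respiratory, outdir / "respiratory.csv", **meta)
            mean, sem = cohort_chemoreflex_mean(respiratory["chemoreflex_response"])
            log.info("respiratory: chemoreflex mean %.2f +- %.2f", mean, sem)

        # -- extract + analyze ----------------------------------------
        study = BaroreflexStudy(
            [
                SubjectData(rec.subject_id, rec.beats, rec.events)
                for rec in recordings
            ],
            settings=config.extraction.to_settings(),
            alpha=config.stats.alpha,
            equal_var=config.stats.test_variant == "pooled",
            holm=config.stats.holm_correction,
        )
        results = study.fit()
        write_frame(results.responses, outdir / "responses.csv", **meta)
        n_rej = int((~results.responses["accepted"].astype(bool)).sum())
        log.info(
            "extract: %d boli, %d rejected for BRS", len(results.responses), n_rej
        )
        for _, row in results.responses[
            ~results.responses["accepted"].astype(bool)
        ].iterrows():
            log.info(
                "  rejected %s/%s bolus %d: %s",
                row["subject"], row["condition"], row["bolus_index"],
                row["reject_reason"],
            )
        write_frame(comparisons_to_frame(results.comparisons),
                    outdir / "individual.csv", **meta)
        write_frame(group_to_frame(results.group_results.values()),
                    outdir / "group.csv", **meta)
        log.info("analyze: %d comparisons", len(results.comparisons))

        # -- plan ------------------------------------------------------
        from .planning import sensitivity_curve

        plan = sensitivity_curve(config.plan.to_spec(config.seed))
        write_frame(plan.curve, outdir / "plan.csv", **meta)
        log.info("plan: minimal_n=%s (%s)", plan.minimal_n, plan.spec.method)

        # -- report ----------------------------------------------------
        _write_figures(results, plan, outdir)
        (outdir / "summary.txt").write_text(results.summary() + "\n", encoding="utf-8")
        for metric in METRICS:
            counts = results.classification_counts[metric]
            log.info("report: %s counts %s", metric, counts)
        return {
            "recordings": recordings,
            "results": results,
            "plan": plan,
            "respiratory": respiratory,
            "config_hash": chash,
        }
    finally:
        log.removeHandler(handler)
        handler.close()


def _write_figures(results, plan, outdir: Path) -> None:
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    for metric in METRICS:
        ax = results.plot_forest(metric)
        ax.figure.savefig(outdir / f"forest_{metric}.png", dpi=120,
                          bbox_inches="tight")
        plt.close(ax.figure)
        ax = results.plot_group(metric)
        ax.figure.savefig(outdir / f"group_{metric}.png", dpi=120,
                          bbox_inches="tight")
        plt.close(ax.figure)
    ax = results.plot_change_correlation()
    ax.figure.savefig(outdir / "change_correlation.png", dpi=120,
                      bbox_inches="tight")
    plt.close(ax.figure)

    fig, ax = plt.subplots(figsize=(5, 4))
    ax.errorbar(plan.curve["n"], plan.curve["sensitivity"],
                yerr=2 * plan.curve["mc_se"], fmt="-o")
    ax.axhline(plan.spec.target_sensitivity, color="k", ls="--", lw=0.8)
    ax.set_xlabel("boli per condition")
    ax.set_ylabel("sensitivity")
    ax.set_title(f"method: {plan.spec.method}")
    fig.savefig(outdir / "plan.png", dpi=120, bbox_inches="tight")
    plt.close(fig)
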