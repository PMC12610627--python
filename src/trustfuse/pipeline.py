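"""End-to-end orchestration: simulate -> score -> fuse -> validate -> report.

The central artifact is the modality score table: one row per
participant x scenario x event carrying the EEG, questionnaire, behavior
(and, after fusion, fused) trust scores on the common scale, plus the
planted latent value for diagnostics on synthetic cohorts.
"""
from __future__ import annotations

import json
import time
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from . import anfis, eeg, io, scoring, validation
from .errors import InvalidArgumentError
from .synthetic import CohortConfig, cohort_manifest, simulate_cohort
from .types import CohortDataset


def score_cohort(cohort: CohortDataset) -> pd.DataFrame:
    """Run the unimodal scoring pipelines over a cohort.

    Returns the aligned score table (columns participant, scenario,
    event_id, t_s, latent, eeg, questionnaire, behavior). Events skipped by
    the EEG pipeline are dropped from the table.
    """
    config: CohortConfig = cohort.config
    rows = []
    for pid, scen, sess in cohort.sessions():
        curve = eeg.compute_trust_curve(sess.recording, sess.timeline)
        eeg_by_event = {p.event_id: p.score for p in curve.points}
        q_scores = {r.event_id: scoring.score_questionnaire(r) for r in sess.responses}
        b_scores = {c.event_id: scoring.score_behavior(c, config.norms) for c in sess.codings}
        for k, ev in enumerate(sess.timeline.events):
            if ev.event_id not in eeg_by_event:
                continue
            rows.append(
                {
                    "participant": pid,
                    "scenario": scen,
                    "event_id": ev.event_id,
                    "t_s": ev.t_start_s,
                    "latent": float(sess.profile.trajectory[k]),
                    "eeg": eeg_by_event[ev.event_id],
                    "questionnaire": q_scores[ev.event_id],
                    "behavior": b_scores[ev.event_id],
                }
            )
    return pd.DataFrame(rows)


def fuse_scores(
    table: pd.DataFrame,
    *,
    epochs: int = 100,
    lr: float = 0.01,
    seed: int | None = None,
    run_loocv: bool = True,
) -> tuple[pd.DataFrame, anfis.AnfisModel, dict]:
    """Train the ANFIS on the full table and append the fused column.

    The fused scores come from the model trained on the whole cohort (the
    model that also produces the fusion surface); grouped LOOCV quantifies
    out-of-sample error separately.
    """
    x1 = table["eeg"].to_numpy(dtype=float)
    x2 = table["questionnaire"].to_numpy(dtype=float)
    y = table["behavior"].to_numpy(dtype=float)
    model, trace = anfis.anfis_fit_hybrid(x1, x2, y, epochs=epochs, lr=lr, seed=seed)
    out = table.copy()
    out["fused"] = anfis.anfis_forward(model, x1, x2)
    cv: dict = {}
    if run_loocv:
        cv = anfis.anfis_loocv(
            x1, x2, y, table["participant"].to_numpy(), epochs=epochs, lr=lr, seed=seed
        )
        cv = {"rmse": cv["rmse"], "r_squared": cv["r_squared"], "n_folds": len(cv["folds"])}
    fusion = {
        "training_rmse": trace.best_rmse,
        "best_epoch": trace.best_epoch,
        "loocv": cv,
    }
    return out, model, fusion


def recoverability(table: pd.DataFrame) -> dict[str, float]:
    """Spearman correlation of each modality with the planted latent trust.

    EEG scores are standardized within each session (Eq.-style z-scoring),
    which deliberately removes between-session level differences, so EEG
    recoverability is the mean within-session Spearman; the global-scale
    modalities (questionnaire, behavior, fused) are pooled across the cohort.
    """
    out: dict[str, float] = {}
    eeg_rhos = []
    for _, g in table.groupby(["participant", "scenario"], sort=True):
        if g["latent"].nunique() > 1 and g["eeg"].nunique() > 1:
            eeg_rhos.append(stats.spearmanr(g["latent"], g["eeg"]).statistic)
    out["eeg"] = float(np.mean(eeg_rhos))
    for col in ("questionnaire", "behavior", "fused"):
        if col in table.columns:
            out[col] = float(stats.spearmanr(table["latent"], table[col]).statistic)
    return out


def validate_scores(
    table: pd.DataFrame,
    *,
    thresholds: tuple[float, float] = validation.DEFAULT_THRESHOLDS,
    n_boot: int = 2000,
    seed: int = 0,
) -> dict:
    """Dispersion, correlation, classification-agreement battery on a fused table."""
    if "fused" not in table.columns:
        raise InvalidArgumentError("table must contain the fused column (run fuse_scores first)")
    disp = validation.dispersion_analysis(table)
    corr = validation.correlation_analysis(table)
    levels = pd.DataFrame(
        {c: validation.classify_trust(table[c].to_numpy(), thresholds) for c in
         ("eeg", "questionnaire", "fused", "behavior")}
    )
    agreement = validation.agreement_analysis(levels, n_boot=n_boot, seed=seed)
    # per-participant means: the pooled per-event unit of analysis is the
    # primary report; participant-level averages are emitted alongside
    per_participant = table.groupby("participant")[["eeg", "questionnaire", "fused", "behavior"]].mean()
    return {
        "dispersion": {
            "shapiro": {c: {"W": r.statistic, "p": r.p_value} for c, r in disp["shapiro"].items()},
            "variance": disp["variance"],
            "kruskal": {
                "H": disp["kruskal"].statistic,
                "p": disp["kruskal"].p_value,
                "epsilon_squared": disp["kruskal"].effect_size,
            },
            "dunn_bonferroni_p": {k: r.p_value for k, r in disp["dunn"].items()},
            "anova": {"F": disp["anova"].statistic, "p": disp["anova"].p_value},
        },
        "correlation_vs_behavior": corr,
        "classification": agreement.to_dict(),
        "per_participant_variance": {
            c: float(np.var(per_participant[c].to_numpy(), ddof=1)) for c in per_participant.columns
        },
    }


def run_pipeline(
    *,
    seed: int = 0,
    n_participants: int = 21,
    config: CohortConfig | None = None,
    epochs: int = 100,
    lr: float = 0.01,
    thresholds: tuple[float, float] = validation.DEFAULT_THRESHOLDS,
    n_boot: int = 2000,
    outdir: str | Path | None = None,
    run_loocv: bool = True,
) -> dict:
    """Full run: simulate -> score -> fuse -> validate; optionally write artifacts.

    Returns the report dict; with ``outdir`` set also writes the cohort
    manifest, score table CSV, ANFIS model JSON, fusion-surface CSV and the
    report JSON.
    """
    config = config or CohortConfig()
    stages: list[dict] = []

    def _stage(name, fn):
        t0 = time.perf_counter()
        result = fn()
        stages.append({"stage": name, "seconds": round(time.perf_counter() - t0, 3)})
        return result

    cohort = _stage("simulate", lambda: simulate_cohort(n_participants, config, seed))
    table = _stage("score", lambda: score_cohort(cohort))
    table, model, fusion = _stage(
        "fuse", lambda: fuse_scores(table, epochs=epochs, lr=lr, seed=seed, run_loocv=run_loocv)
    )
    report_stats = _stage(
        "validate", lambda: validate_scores(table, thresholds=thresholds, n_boot=n_boot, seed=seed)
    )
    report = {
        "seed": seed,
        "n_participants": n_participants,
        "n_rows": int(len(table)),
        "fusion": fusion,
        "recoverability_vs_latent": recoverability(table),
        **report_stats,
        "stages": stages,
    }
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        (outdir / "manifest.json").write_text(cohort_manifest(cohort))
        table.to_csv(outdir / "score_table.csv", index=False)
        io.write_model_json(model, outdir / "anfis_model.json", training_config=fusion)
        axis, surface = anfis.fusion_surface(model)
        io.write_surface_csv(axis, surface, outdir / "fusion_surface.csv")
        (outdir / "report.json").write_text(json.dumps(report, indent=1, sort_keys=True))
    return report
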