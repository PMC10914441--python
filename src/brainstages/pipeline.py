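"""End-to-end runs: preprocess -> fit -> diverge -> stage, plus recovery.

`analyse_table` executes the whole method on one subject table and returns
every intermediate product; `write_outputs` materializes the fixed-name
artefacts (models.json, divergence.csv/json, staging.csv/json, ks_report.csv,
outliers.csv, report.md, manifest.json) under a run directory.  Outputs
contain no timestamps, so a rerun on identical inputs and configuration is
byte-identical.  `recovery_run` replays the pipeline on synthetic cohorts
with known truth and scores onset error, ordering recovery (Kendall tau)
and detection rates.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as _sps

from . import __version__
from .cohort_table import (
    KSResult,
    StructureMetadata,
    StructureSeries,
    build_disease_training_set,
    combine_lr,
    flag_model_outliers,
    ks_normality,
    normalize_to_tiv,
    read_subject_table,
    validate_subject_table,
)
from .config import RunConfig
from .divergence import (
    DivergenceResult,
    analyse_structure,
    results_table,
    save_results_json,
)
from .staging import StagingScheme, build_staging, plot_timeline, rank_severity
from .synthetic_cohort import CohortSpec, TrajectoryTruth, generate_cohort
from .trajectory_fit import (
    TrajectoryModel,
    default_age_grid,
    fit_trajectory,
    save_models,
)

logger = logging.getLogger(__name__)


@dataclass
class PipelineResult:
    """Everything one staging run produces, in memory."""

    grid: np.ndarray
    models: list[TrajectoryModel]
    ks_results: list[KSResult]
    outlier_flags: pd.DataFrame          # structure, group, subject_id
    divergence: list[DivergenceResult]
    scheme: StagingScheme
    severity: list[DivergenceResult]
    config: RunConfig
    n_controls: int = 0
    n_cases: int = 0
    disease_training_n: int = 0


def _series_from(df: pd.DataFrame, structure: str, reference: tuple[float, float]):
    """StructureSeries for `structure` over df rows, using fixed reference stats."""
    ok = df[structure].notna().to_numpy()
    sub = df.loc[ok]
    norm = normalize_to_tiv(sub[structure].to_numpy(float), sub["tiv_mm3"].to_numpy(float))
    mean, sd = reference
    series = StructureSeries(
        structure_name=structure,
        ages=sub["age"].to_numpy(float),
        values=(norm - mean) / sd,
        groups=sub["group"].to_numpy(),
        reference_mean=mean,
        reference_sd=sd,
    )
    return series, sub["subject_id"].to_numpy()


def analyse_table(
    df: pd.DataFrame,
    metadata: StructureMetadata | None = None,
    config: RunConfig | None = None,
) -> PipelineResult:
    """Run the full staging analysis on a validated subject table.

    Steps: hemisphere summation; TIV normalization; z-scoring against the
    control reference; KS normality check per structure; healthy model fit
    on all controls; disease model fit on cases + controls younger than the
    youngest case; 2-SD model-outlier flagging; band non-overlap divergence
    detection on a common age grid; chronological staging and severity
    ranking.
    """
    config = config or RunConfig()
    validate_subject_table(df)
    combined = combine_lr(df, metadata)
    meta = metadata or StructureMetadata.infer(df.columns)
    structures = [s for s in meta.structures if s in combined.columns]

    controls = combined[combined["group"] == "control"]
    if len(controls) < 4:
        raise ValueError("need at least 4 controls to build the healthy chart")
    disease_df = build_disease_training_set(combined)
    n_cases = int((combined["group"] == "case").sum())
    logger.info(
        "disease training set: %d records (%d cases + %d controls younger than "
        "the youngest case)", len(disease_df), n_cases, len(disease_df) - n_cases,
    )

    # Detection grid: confined to ages where BOTH models have training data,
    # so band non-overlap is never judged on extrapolated bands.  The
    # severity distance at the reference age is a model-mean quantity and may
    # extrapolate up to extrapolation_window years past the disease data.
    h_min, h_max = float(controls["age"].min()), float(controls["age"].max())
    d_max = float(disease_df["age"].max())
    ext = config.extrapolation_window
    grid = default_age_grid(h_min, min(h_max, d_max), config.grid_step)
    if not (grid.min() <= config.reference_age <= min(h_max, d_max + ext)):
        raise ValueError(
            f"reference age {config.reference_age} outside the evaluable range "
            f"[{grid.min():g}, {min(h_max, d_max + ext):g}]; "
            "adjust extrapolation_window or data"
        )

    models: list[TrajectoryModel] = []
    ks_results: list[KSResult] = []
    outlier_rows: list[dict] = []
    div_results: list[DivergenceResult] = []

    for structure in structures:
        # z-score reference: quality-passing controls over the whole lifespan
        ref_norm = normalize_to_tiv(
            controls[structure].dropna().to_numpy(float),
            controls.loc[controls[structure].notna(), "tiv_mm3"].to_numpy(float),
        )
        reference = (float(np.mean(ref_norm)), float(np.std(ref_norm, ddof=1)))
        ks = ks_normality(ref_norm, alpha=config.alpha, structure_name=structure)
        ks_results.append(ks)
        if ks.tested and ks.reject:
            logger.warning("structure %s: normality rejected by KS (p=%.3g)",
                           structure, ks.pvalue)

        h_series, h_ids = _series_from(controls, structure, reference)
        d_series, d_ids = _series_from(disease_df, structure, reference)
        healthy = fit_trajectory(
            h_series.ages, h_series.values, structure, "control",
            alpha=config.alpha, include_intercept_gate=config.include_intercept_gate,
            design_note=f"all controls (n={h_series.ages.size})",
        )
        disease = fit_trajectory(
            d_series.ages, d_series.values, structure, "case",
            alpha=config.alpha, include_intercept_gate=config.include_intercept_gate,
            design_note=(f"cases + controls younger than the youngest case "
                         f"(n={d_series.ages.size})"),
        )
        for model in (healthy, disease):
            if model.degree == 0:
                logger.warning("structure %s (%s): no eligible polynomial, "
                               "constant fallback", structure, model.group)
        models.extend([healthy, disease])

        for model, series, ids in ((healthy, h_series, h_ids), (disease, d_series, d_ids)):
            flags = flag_model_outliers(series, model)
            for sid in ids[flags]:
                outlier_rows.append(
                    {"structure": structure, "group": model.group, "subject_id": sid}
                )
            if flags.any():
                logger.info("structure %s (%s): %d model outliers flagged (>2 SD)",
                            structure, model.group, int(flags.sum()))

        result = analyse_structure(
            healthy, disease, grid,
            level=config.level, band_mode=config.band_mode,
            rule=config.divergence_rule, ref_age=config.reference_age,
            extrapolation=ext,
        )
        if result.direction == "case_larger":
            logger.warning("structure %s: case-LARGER divergence at %.1f y "
                           "(reported, excluded from atrophy staging)",
                           structure, result.onset_age)
        div_results.append(result)

    strict_map = config.grouping not in ("default", "none", None)
    scheme = build_staging(div_results, config.grouping_map(), config.gap_threshold,
                           strict=strict_map)
    severity = rank_severity(div_results)
    return PipelineResult(
        grid=grid,
        models=models,
        ks_results=ks_results,
        outlier_flags=pd.DataFrame(outlier_rows,
                                   columns=["structure", "group", "subject_id"]),
        divergence=div_results,
        scheme=scheme,
        severity=severity,
        config=config,
        n_controls=len(controls),
        n_cases=n_cases,
        disease_training_n=len(disease_df),
    )


# ---------------------------------------------------------------------------
# output files
# ---------------------------------------------------------------------------

def _versions() -> dict[str, str]:
    import numpy, pandas, scipy, statsmodels
    return {
        "brainstages": __version__,
        "numpy": numpy.__version__,
        "scipy": scipy.__version__,
        "pandas": pandas.__version__,
        "statsmodels": statsmodels.__version__,
    }


def write_manifest(path: Path, config: RunConfig, extra: dict | None = None) -> None:
    manifest = {
        "config": config.to_dict(),
        "config_hash": config.hash(),
        "seed": config.seed,
        "versions": _versions(),
    }
    manifest.update(extra or {})
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True))


def write_outputs(result: PipelineResult, outdir: str | Path,
                  timeline_figure: bool = False) -> Path:
    """Write the fixed-name run artefacts; returns the run directory."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    save_models(result.models, outdir / "models.json")
    results_table(result.divergence).to_csv(outdir / "divergence.csv", index=False)
    save_results_json(result.divergence, outdir / "divergence.json")
    result.scheme.save(outdir / "staging.csv", outdir / "staging.json")
    pd.DataFrame(
        {
            "structure": [k.structure_name for k in result.ks_results],
            "ks_statistic": [k.statistic for k in result.ks_results],
            "ks_pvalue": [k.pvalue for k in result.ks_results],
            "normality_rejected": [k.reject for k in result.ks_results],
            "tested": [k.tested for k in result.ks_results],
        }
    ).to_csv(outdir / "ks_report.csv", index=False)
    result.outlier_flags.to_csv(outdir / "outliers.csv", index=False)
    (outdir / "report.md").write_text(render_report(result))
    write_manifest(
        outdir / "manifest.json", result.config,
        {"n_controls": result.n_controls, "n_cases": result.n_cases,
         "disease_training_n": result.disease_training_n},
    )
    if timeline_figure:
        plot_timeline(result.scheme, outdir / "timeline.png",
                      ref_age=result.config.reference_age)
    return outdir


def render_report(result: PipelineResult) -> str:
    """Human-readable run summary in Markdown."""
    c = result.config
    lines = [
        "# Lifespan divergence staging report",
        "",
        f"- controls: {result.n_controls}; cases: {result.n_cases}",
        f"- disease training set: {result.disease_training_n} records "
        "(cases + controls younger than the youngest case)",
        f"- age grid: {result.grid.min():g}-{result.grid.max():g} y, "
        f"step {c.grid_step} y; bands: {c.band_mode} at {c.level:.0%}; "
        f"divergence rule: {c.divergence_rule}; reference age: {c.reference_age:g} y",
        "",
        "## Per-structure summary",
        "",
        "| structure | healthy deg | disease deg | KS reject | diverged | onset (y) | distance@ref (z) |",
        "|---|---|---|---|---|---|---|",
    ]
    by_name: dict[str, dict[str, TrajectoryModel]] = {}
    for m in result.models:
        by_name.setdefault(m.structure_name, {})[m.group] = m
    ks_by = {k.structure_name: k for k in result.ks_results}
    for r in result.divergence:
        h = by_name[r.structure_name]["control"]
        d = by_name[r.structure_name]["case"]
        ks = ks_by.get(r.structure_name)
        onset = f"{r.onset_age:.1f}" if r.onset_age is not None else "-"
        lines.append(
            f"| {r.structure_name} | {h.degree} | {d.degree} | "
            f"{'yes' if ks and ks.tested and ks.reject else 'no'} | "
            f"{'yes' if r.diverged else 'no'} | {onset} | {r.distance_at_ref:.2f} |"
        )
    lines += ["", "## Staging scheme", ""]
    if result.scheme.entries:
        for stage, members in sorted(result.scheme.stage_members().items()):
            ages = [e.onset_age for e in result.scheme.entries if e.stage_index == stage]
            lines.append(f"- stage {stage} (onset {min(ages):.1f}-{max(ages):.1f} y): "
                         + ", ".join(members))
    else:
        lines.append("- no structure diverged")
    lines += ["", "## Severity ranking (|distance| at reference age)", ""]
    for i, r in enumerate(result.severity, 1):
        lines.append(f"{i}. {r.structure_name}: {abs(r.distance_at_ref):.2f} z")
    n_out = len(result.outlier_flags)
    lines += ["", f"Model-outlier flags (>2 residual SD, for review): {n_out}", ""]
    return "\n".join(lines)


def run_stage(
    input_table: str | Path | pd.DataFrame,
    outdir: str | Path,
    metadata: StructureMetadata | None = None,
    config: RunConfig | None = None,
    timeline_figure: bool = False,
) -> PipelineResult:
    """Read (or accept) a subject table, analyse it, write the run directory."""
    df = (input_table if isinstance(input_table, pd.DataFrame)
          else read_subject_table(input_table))
    result = analyse_table(df, metadata=metadata, config=config)
    write_outputs(result, outdir, timeline_figure=timeline_figure)
    return result


# ---------------------------------------------------------------------------
# simulation + parameter recovery
# ---------------------------------------------------------------------------

def simulate_to_dir(
    specs: Sequence[CohortSpec],
    truths: Sequence[TrajectoryTruth],
    seed: int,
    outdir: str | Path,
) -> tuple[Path, Path]:
    """Generate a synthetic cohort and write subjects.csv + truth.csv + manifest."""
    from .synthetic_cohort import save_truth_table

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    subjects, _ = generate_cohort(specs, truths, seed)
    subjects_path = outdir / "subjects.csv"
    truth_path = outdir / "truth.csv"
    subjects.to_csv(subjects_path, index=False)
    save_truth_table(truths, truth_path)
    cfg = RunConfig(seed=seed)
    write_manifest(outdir / "manifest.json", cfg,
                   {"n_subjects": len(subjects),
                    "n_clamped": subjects.attrs.get("n_clamped", 0)})
    return subjects_path, truth_path


@dataclass
class RecoveryMetrics:
    """Aggregated parameter-recovery scores across replicates."""

    per_structure: pd.DataFrame       # seed, structure, true/estimated onset, error
    per_seed: pd.DataFrame            # seed, kendall_tau, n_detected, median_abs_error
    median_abs_onset_error: float
    mean_kendall_tau: float
    frac_seeds_tau_ge: float          # fraction of seeds with tau >= tau_threshold
    detection_rate: float
    tau_threshold: float = 0.8


def recovery_run(
    specs: Sequence[CohortSpec],
    truths: Sequence[TrajectoryTruth],
    seeds: Sequence[int],
    config: RunConfig | None = None,
    tau_threshold: float = 0.8,
) -> RecoveryMetrics:
    """Replay generate -> analyse over seeds and score onset/order recovery.

    Onset errors and the Kendall tau between recovered and true onset order
    are computed over the structures detected as diverging in each
    replicate (an undetected structure contributes to the detection rate
    only).
    """
    config = config or RunConfig()
    true_onsets = {t.structure_name: t.onset_age for t in truths
                   if t.onset_age is not None and t.deviation_rate > 0}
    if not true_onsets:
        raise ValueError("recovery needs at least one truly diverging structure")
    rows, seed_rows = [], []
    for seed in seeds:
        subjects, _ = generate_cohort(specs, truths, seed)
        result = analyse_table(subjects, config=config)
        est = {r.structure_name: r.onset_age for r in result.divergence
               if r.diverged and r.direction == "case_smaller"}
        unknown = set(est) - {t.structure_name for t in truths}
        if unknown:
            raise ValueError(f"estimated structures not in truth table: {sorted(unknown)}")
        errs = []
        t_ord, e_ord = [], []
        for name, true_onset in true_onsets.items():
            est_onset = est.get(name)
            detected = est_onset is not None
            err = (est_onset - true_onset) if detected else np.nan
            rows.append({"seed": seed, "structure": name, "true_onset": true_onset,
                         "estimated_onset": est_onset, "onset_error": err,
                         "detected": detected})
            if detected:
                errs.append(abs(err))
                t_ord.append(true_onset)
                e_ord.append(est_onset)
        tau = (_sps.kendalltau(t_ord, e_ord).statistic if len(t_ord) >= 2 else np.nan)
        seed_rows.append({"seed": seed, "kendall_tau": tau,
                          "n_detected": len(t_ord),
                          "median_abs_error": float(np.median(errs)) if errs else np.nan})
    per_structure = pd.DataFrame(rows)
    per_seed = pd.DataFrame(seed_rows)
    detected_errs = per_structure.loc[per_structure["detected"], "onset_error"].abs()
    taus = per_seed["kendall_tau"].dropna()
    return RecoveryMetrics(
        per_structure=per_structure,
        per_seed=per_seed,
        median_abs_onset_error=float(detected_errs.median()) if len(detected_errs) else np.nan,
        mean_kendall_tau=float(taus.mean()) if len(taus) else np.nan,
        frac_seeds_tau_ge=float((taus >= tau_threshold).mean()) if len(taus) else 0.0,
        detection_rate=float(per_structure["detected"].mean()),
        tau_threshold=tau_threshold,
    )


def write_recovery(metrics: RecoveryMetrics, outdir: str | Path,
                   config: RunConfig | None = None) -> Path:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    metrics.per_structure.to_csv(outdir / "recovery_per_structure.csv", index=False)
    metrics.per_seed.to_csv(outdir / "recovery_per_seed.csv", index=False)
    summary = {
        "median_abs_onset_error_years": metrics.median_abs_onset_error,
        "mean_kendall_tau": metrics.mean_kendall_tau,
        "frac_seeds_tau_ge_threshold": metrics.frac_seeds_tau_ge,
        "tau_threshold": metrics.tau_threshold,
        "detection_rate": metrics.detection_rate,
    }
    (outdir / "recovery_summary.json").write_text(
        json.dumps(summary, indent=2, sort_keys=True))
    if config is not None:
        write_manifest(outdir / "manifest.json", config)
    return outdir
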