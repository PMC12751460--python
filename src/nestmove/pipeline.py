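"""End-to-end study pipeline: trajectories -> study table -> contrasts.

Stages, in order, per the movement-analysis protocol:

1. step lengths per individual, with per-individual outlier masking
   (mean + 2 SD);
2. one pause/move threshold per species from the kernel density of the
   pooled valid steps;
3. bout segmentation, traveled distance (also standardized by body length),
   pause proportion and moving speed per individual;
4. equal-area zone occupancy and inner-bout metrics;
5. optional discrete-ML fits of the four duration families to the pooled
   pause and move bouts of each species, compared by AIC weight;
6. nesting-type contrasts (LMM with colony nested in species) for every
   response, plus within-species body-size/distance correlations.

Any stage failure aborts with the stage and the offending individual or
species named; a run log records thresholds, removal counts and fit
diagnostics.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import bout_models, kinematics, spatial, stats
from .io import ArenaGeometry, Trajectory, load_config, read_metadata, read_trajectory
from .synthetic import CohortSpec, default_cohort_spec, generate_cohort

__all__ = ["StudyConfig", "PipelineResult", "build_study_table", "run_pipeline"]

#: response column -> transform used in its nesting-type contrast
RESPONSES: dict[str, str | None] = {
    "distance_bodylengths": None,
    "pause_proportion": "logit",
    "moving_speed_mm_s": None,
    "prop_outer": "logit",
    "mean_bout_duration_s": None,
    "mean_bout_path_mm": None,
    "mean_bout_chord_mm": None,
    "mean_bout_straightness": None,
}


@dataclass(frozen=True)
class StudyConfig:
    """What to analyse and which optional stages to run.

    Either ``cohort`` (synthetic) or ``trajectory_dir`` + ``metadata_csv``
    (real tracking exports, one ``frame,x,y`` CSV named
    ``<individual_id>.csv`` per individual) must be supplied.
    """

    cohort: CohortSpec | None = None
    trajectory_dir: str | None = None
    metadata_csv: str | None = None
    mm_per_px: float = 1.0
    source_fps: float = 5.0
    analysis_fps: float = 5.0
    arena_diameter_mm: float = 140.0
    remove_outliers: bool = True
    distance_on_clean_steps: bool = True
    fit_models: bool = True
    min_bouts_for_fit: int = 50
    families: Sequence[str] = bout_models.FAMILIES

    @classmethod
    def from_yaml(cls, path) -> "StudyConfig":
        cfg = load_config(path)
        if "cohort" in cfg:
            c = dict(cfg.pop("cohort"))
            if c.pop("default", False):
                cohort = default_cohort_spec(**c)
            else:
                raise ValueError("only the default synthetic cohort is YAML-configurable; build CohortSpec in code for custom archetypes")
            return cls(cohort=cohort, **cfg)
        return cls(**cfg)


@dataclass(frozen=True)
class PipelineResult:
    study_table: pd.DataFrame
    thresholds: dict[str, kinematics.ThresholdResult]
    fits: pd.DataFrame | None
    contrasts: pd.DataFrame
    correlations: pd.Series
    report: str
    log: list[str] = field(default_factory=list)


def _load_trajectories(config: StudyConfig, seed: int | None) -> list[Trajectory]:
    if config.cohort is not None:
        spec = config.cohort if seed is None else replace(config.cohort, seed=seed)
        trajectories, _ = generate_cohort(spec)
        return trajectories
    if not (config.trajectory_dir and config.metadata_csv):
        raise ValueError("config must provide either a cohort spec or trajectory_dir + metadata_csv")
    meta = read_metadata(config.metadata_csv)
    arena = ArenaGeometry(radius_mm=config.arena_diameter_mm / 2.0)
    out = []
    for _, row in meta.iterrows():
        path = Path(config.trajectory_dir) / f"{row['individual_id']}.csv"
        traj = read_trajectory(
            path,
            metadata=row.to_dict(),
            calibration=config.mm_per_px,
            arena=arena,
            frame_interval_s=1.0 / config.source_fps,
        )
        if config.source_fps != config.analysis_fps:
            from .io import downsample

            traj = downsample(traj, config.analysis_fps)
        out.append(traj)
    return out


def build_study_table(
    trajectories: Sequence[Trajectory],
    remove_outliers: bool = True,
    distance_on_clean_steps: bool = True,
):
    """Per-individual responses plus per-species thresholds and pooled bouts.

    Returns ``(table, thresholds, pooled_durations, log)`` where
    ``pooled_durations[(species, state)]`` collects bout durations across all
    individuals of a species, as used for the duration-model fits.
    """
    log: list[str] = []
    by_species: dict[str, list[Trajectory]] = {}
    for t in trajectories:
        by_species.setdefault(t.species, []).append(t)

    series_by_id: dict[str, kinematics.StepSeries] = {}
    raw_by_id: dict[str, kinematics.StepSeries] = {}
    thresholds: dict[str, kinematics.ThresholdResult] = {}
    for sp, trajs in by_species.items():
        pooled = []
        for t in trajs:
            try:
                raw = kinematics.compute_steps(t)
            except ValueError as exc:
                raise RuntimeError(f"stage compute_steps failed for {t.individual_id}: {exc}") from exc
            clean = kinematics.remove_outlier_steps(raw) if remove_outliers else raw
            n_removed = int((~clean.valid_mask).sum())
            if n_removed:
                log.append(f"{t.individual_id}: masked {n_removed} outlier steps")
            series_by_id[t.individual_id] = clean
            raw_by_id[t.individual_id] = raw
            pooled.append(clean.valid_steps)
        try:
            thr = kinematics.estimate_threshold(np.concatenate(pooled), species=sp)
        except (ValueError, kinematics.UnimodalStepsError) as exc:
            raise RuntimeError(f"stage estimate_threshold failed for species {sp}: {exc}") from exc
        thresholds[sp] = thr
        log.append(
            f"{sp}: threshold {thr.threshold_mm:.3f} mm "
            f"(pause mode {thr.pause_mode_mm:.3f}, move mode {thr.move_mode_mm:.3f})"
        )

    rows = []
    pooled_durations: dict[tuple[str, str], list[np.ndarray]] = {}
    for t in trajectories:
        clean = series_by_id[t.individual_id]
        thr = thresholds[t.species]
        bouts = kinematics.segment_bouts(clean, thr.threshold_mm)
        for state in (kinematics.PAUSE, kinematics.MOVE):
            pooled_durations.setdefault((t.species, state), []).append(bouts.durations_for(state))
        dist_series = clean if distance_on_clean_steps else raw_by_id[t.individual_id]
        total_mm = kinematics.total_distance(dist_series)
        zones = spatial.inner_bouts(t, step_valid_mask=clean.valid_mask)
        rows.append(
            {
                "individual_id": t.individual_id,
                "species": t.species,
                "colony": t.colony,
                "nesting_type": t.nesting_type,
                "body_length_mm": t.body_length_mm,
                "total_distance_mm": total_mm,
                "distance_bodylengths": total_mm / t.body_length_mm,
                "pause_proportion": kinematics.pause_proportion(bouts),
                "moving_speed_mm_s": kinematics.moving_speed(clean, thr.threshold_mm),
                "prop_outer": zones.prop_outer,
                "entered_inner": zones.entered_inner,
                "n_inner_bouts": len(zones.bouts),
                "mean_bout_duration_s": zones.mean_duration_s,
                "mean_bout_path_mm": zones.mean_path_mm,
                "mean_bout_chord_mm": zones.mean_chord_mm,
                "mean_bout_straightness": zones.mean_straightness,
            }
        )
    table = pd.DataFrame(rows)
    if table["individual_id"].duplicated().any():
        raise RuntimeError("stage build_study_table: duplicated individual ids")
    pooled = {k: np.concatenate(v) for k, v in pooled_durations.items()}
    return table, thresholds, pooled, log


def _fit_species_models(pooled, families, min_bouts, log):
    rows = []
    for (sp, state), durations in sorted(pooled.items()):
        if durations.size < min_bouts:
            log.append(f"{sp}/{state}: only {durations.size} bouts, skipping fits")
            continue
        fits = [bout_models.fit(durations, fam, min_n=min_bouts) for fam in families]
        fits = bout_models.compare_models(fits)
        for f in fits:
            rows.append(
                {
                    "species": sp,
                    "behaviour": state,
                    "family": f.model.family,
                    **{f"param_{k}": v for k, v in f.model.params.items()},
                    "x_min": f.model.x_min,
                    "x_max": f.model.x_max,
                    "n_bouts": f.n,
                    "log_likelihood": f.log_likelihood,
                    "aic": f.aic,
                    "aic_weight": f.aic_weight,
                    "ks_D": f.ks_D,
                    "flagged": f.flagged,
                }
            )
            if f.flagged:
                log.append(f"{sp}/{state}/{f.model.family}: flagged fit ({f.message})")
    return pd.DataFrame(rows)


def _report(table, thresholds, fits, contrasts, correlations) -> str:
    lines = ["# nestmove pipeline report", ""]
    by_type = table.groupby("nesting_type")["distance_bodylengths"].mean()
    lines.append(f"Individuals analysed: {len(table)} across {table['species'].nunique()} species.")
    for typ, val in by_type.items():
        lines.append(f"Mean standardized distance, {typ}: {val:.1f} body lengths")
    lines.append("")
    lines.append("Per-species pause/move thresholds (mm): " + ", ".join(
        f"{sp}={t.threshold_mm:.3f}" for sp, t in sorted(thresholds.items())
    ))
    if fits is not None and len(fits):
        best = fits.loc[fits.groupby(["species", "behaviour"])["aic_weight"].idxmax()]
        lines.append("")
        lines.append("Best-supported duration model per species x behaviour:")
        for _, r in best.iterrows():
            lines.append(
                f"  {r['species']}/{r['behaviour']}: {r['family']} "
                f"(w={r['aic_weight']:.3f}, D={r['ks_D']:.3f}, n={int(r['n_bouts'])})"
            )
    lines.append("")
    lines.append("Nesting-type contrasts (forager - one_piece):")
    for _, r in contrasts.iterrows():
        if r["degenerate"]:
            lines.append(f"  {r['response']}: degenerate design, not testable")
        else:
            lines.append(
                f"  {r['response']}: estimate={r['estimate']:.3g}, chi2={r['chi_sq']:.2f}, "
                f"p={r['p_value']:.3g}, variance% (species/colony/residual)="
                f"{r['var_species_pct']:.1f}/{r['var_colony_pct']:.1f}/{r['var_residual_pct']:.1f}"
            )
    lines.append("")
    lines.append("Within-species body-size vs distance correlations: " + ", ".join(
        f"{sp}: r={v:.3f}" if np.isfinite(v) else f"{sp}: r=NA" for sp, v in correlations.items()
    ))
    return "\n".join(lines)


def run_pipeline(config: StudyConfig, seed: int | None = None) -> PipelineResult:
    """Run the full analysis; deterministic for a given config and seed."""
    trajectories = _load_trajectories(config, seed)
    table, thresholds, pooled, log = build_study_table(
        trajectories,
        remove_outliers=config.remove_outliers,
        distance_on_clean_steps=config.distance_on_clean_steps,
    )

    fits = None
    if config.fit_models:
        fits = _fit_species_models(pooled, config.families, config.min_bouts_for_fit, log)

    contrast_rows = []
    for response, transform in RESPONSES.items():
        res = stats.fit_contrast(table, response, transform=transform)
        contrast_rows.append(
            {
                "response": response,
                "transform": transform or "none",
                "estimate": res.estimate,
                "se": res.se,
                "chi_sq": res.chi_sq,
                "df": res.df,
                "p_value": res.p_value,
                "var_species_pct": res.var_species_pct,
                "var_colony_pct": res.var_colony_pct,
                "var_residual_pct": res.var_residual_pct,
                "n": res.n,
                "singular": res.singular,
                "degenerate": res.degenerate,
            }
        )
        if res.degenerate:
            log.append(f"contrast {response}: degenerate design ({res.message})")
        elif res.singular:
            log.append(f"contrast {response}: singular fit ({res.message})")
    contrasts = pd.DataFrame(contrast_rows)
    correlations = stats.within_species_correlation(table)
    report = _report(table, thresholds, fits, contrasts, correlations)
    return PipelineResult(
        study_table=table,
        thresholds=thresholds,
        fits=fits,
        contrasts=contrasts,
        correlations=correlations,
        report=report,
        log=log,
    )
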