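"""End-to-end study pipeline: filtering, regularization, HMM, summaries.

``run_study_pipeline`` executes the full analysis sequence —

    truncate -> speed filter -> terrestrial filter -> segment ->
    regularize (CTCRW) -> HMM fit/selection -> Viterbi decode -> summaries

— and returns a :class:`StudyReport` that accounts for every input fix
(counts at each stage are conserved: input = removed + retained), the
model-selection table, decoded time budget, stationary-probability curve,
and tag-performance tables.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import core, hmm, preprocess, regularize, tag_performance

logger = logging.getLogger("beartrack")

__all__ = ["DEFAULT_CONFIG", "StageCount", "StudyReport", "run_study_pipeline", "write_report"]

DEFAULT_CONFIG: dict = {
    "truncate_days": 3.0,
    "vmax_kmh": 40.0,
    "speed_mode": "rms",  # or "pairwise" for sensitivity checks
    "max_foray": 50,
    "gap_hours": 24.0,
    "min_segment_len": 100,
    "landmask_path": None,
    "interval_hours": 4.0,
    "error_sd_by_class": dict(regularize.DEFAULT_ARGOS_SD_KM),
    "gps_sd_km": regularize.DEFAULT_GPS_SD_KM,
    "ctcrw_max_iter": 500,
    "ctcrw_tol": 1e-8,
    "fallback_linear": True,
    "temp_max_gap_h": 6.0,
    "n_states": 2,
    "models": ("intercept_only", "temp", "temp2"),
    "n_restarts": 50,
    "zero_step_policy": "half_min_positive",
    "stationary_temp_grid": None,  # default: observed range
}


@dataclass
class StageCount:
    stage: str
    n_in: int
    n_removed: int
    n_out: int


@dataclass
class StudyReport:
    """Everything the pipeline measured, plus full stage accounting."""

    n_input: int
    stages: list  # list[StageCount]
    n_segments: int
    n_grid_points: int
    ctcrw_fallbacks: list
    hmm_skipped: bool
    model_table: pd.DataFrame | None
    best_model: str | None
    fits: dict = field(default_factory=dict)
    time_budget: np.ndarray | None = None
    decoded: pd.DataFrame | None = None
    stationary: pd.DataFrame | None = None
    duration_summary: pd.DataFrame | None = None
    error_classes: pd.DataFrame | None = None
    gps_errors: dict | None = None

    def counts_conserved(self) -> bool:
        """input = removed + retained at every stage (no silent drops)."""
        return all(s.n_in == s.n_removed + s.n_out for s in self.stages)


def _merge_config(config: dict | None) -> dict:
    cfg = dict(DEFAULT_CONFIG)
    if config:
        unknown = set(config) - set(DEFAULT_CONFIG) - {"seed"}
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        cfg.update(config)
    return cfg


def run_study_pipeline(
    fixes: pd.DataFrame,
    deployments: pd.DataFrame,
    temperature: pd.DataFrame,
    config: dict | None = None,
    seed: int = 0,
) -> StudyReport:
    """Run the full analysis and return a :class:`StudyReport`.

    If no segment survives filtering, the HMM stage is marked skipped and
    the report still carries the stage accounting and tag-performance
    summaries.
    """
    cfg = _merge_config(config)
    n_input = len(fixes)
    stages: list[StageCount] = []

    # tag-performance summaries use the full (pre-filtering) record
    dur_rows = []
    for _, dep in deployments.iterrows():
        tag_fx = fixes[fixes["tag_id"] == dep["tag_id"]]
        dur_rows.append(
            {"design": dep["design"], "tag_id": dep["tag_id"],
             "duration_days": tag_performance.functional_duration(dep, tag_fx)}
        )
    duration_summary = tag_performance.summarize_durations(pd.DataFrame(dur_rows)) if dur_rows else None
    error_classes = tag_performance.error_class_table(fixes, deployments) if n_input else None
    gps_errors = tag_performance.gps_error_summary(fixes) if n_input else None

    land_polygon = None
    if cfg["landmask_path"]:
        from shapely import from_wkt

        land_polygon = from_wkt(Path(cfg["landmask_path"]).read_text())

    # 1. post-capture truncation, per deployment
    parts = []
    for _, dep in deployments.iterrows():
        tag_fx = fixes[fixes["tag_id"] == dep["tag_id"]]
        parts.append(preprocess.truncate_post_capture(tag_fx, dep, cfg["truncate_days"]))
    current = pd.concat(parts, ignore_index=True) if parts else fixes.iloc[0:0]
    stages.append(StageCount("truncate_post_capture", n_input, n_input - len(current), len(current)))

    # 2. speed filter, per tag
    n_in = len(current)
    parts = []
    for _, g in current.groupby("tag_id", sort=False):
        retained, _removed = preprocess.speed_filter(g, cfg["vmax_kmh"], cfg["speed_mode"])
        parts.append(retained)
    current = pd.concat(parts, ignore_index=True) if parts else current.iloc[0:0]
    stages.append(StageCount("speed_filter", n_in, n_in - len(current), len(current)))

    # 3. terrestrial/foray selection
    n_in = len(current)
    current = preprocess.terrestrial_filter(current, cfg["max_foray"], land_polygon)
    stages.append(StageCount("terrestrial_filter", n_in, n_in - len(current), len(current)))

    # 4. gap segmentation, dropping short segments
    n_in = len(current)
    segments, n_short = preprocess.segment_tracks(current, cfg["gap_hours"], cfg["min_segment_len"])
    n_kept = sum(len(s) for s in segments)
    stages.append(StageCount("segment_tracks", n_in, n_short, n_kept))

    # 5. regularization to the analysis grid
    tracks = []
    fallbacks = []
    for seg in segments:
        try:
            fit = regularize.fit_ctcrw(
                seg, cfg["error_sd_by_class"], cfg["gps_sd_km"],
                max_iter=cfg["ctcrw_max_iter"], tol=cfg["ctcrw_tol"],
            )
            track = regularize.regularize_segment(seg, fit, cfg["interval_hours"])
        except (regularize.CtcrwConvergenceError, ValueError) as exc:
            if not cfg["fallback_linear"]:
                raise
            logger.warning("CTCRW failed for %s:%d (%s); linear fallback", seg.tag_id, seg.segment_index, exc)
            fallbacks.append(f"{seg.tag_id}:{seg.segment_index}")
            track = regularize.regularize_linear(seg, cfg["interval_hours"])
        track.data = core.attach_temperature(track.data, temperature, cfg["temp_max_gap_h"]) \
            if not temperature.empty else track.data.assign(temp_c=np.nan, temp_missing=True)
        tracks.append(track)
    n_grid = sum(len(t) for t in tracks)

    report = StudyReport(
        n_input=n_input,
        stages=stages,
        n_segments=len(segments),
        n_grid_points=n_grid,
        ctcrw_fallbacks=fallbacks,
        hmm_skipped=False,
        model_table=None,
        best_model=None,
        duration_summary=duration_summary,
        error_classes=error_classes,
        gps_errors=gps_errors,
    )

    usable = [t for t in tracks if len(t) >= 3]
    if not usable:
        report.hmm_skipped = True
        return report

    series = hmm.build_step_series(usable)
    if len(series) < 10:
        report.hmm_skipped = True
        return report

    # 6-7. HMM fitting, selection, decoding
    have_temp = bool(np.isfinite(series.data["temp_c"].to_numpy(dtype=float)).all())
    fits = {}
    for label in cfg["models"]:
        if hmm._N_COVARIATES[label] > 0 and not have_temp:
            logger.warning("skipping model %s: temperature covariate incomplete", label)
            continue
        fits[label] = hmm.fit_hmm(series, label, n_restarts=cfg["n_restarts"], seed=seed,
                                  n_states=cfg["n_states"])
    if not fits:
        report.hmm_skipped = True
        return report
    report.fits = fits
    report.model_table = hmm.model_selection(list(fits.values()))
    report.best_model = str(report.model_table["model"].iloc[0])
    best = fits[report.best_model]

    decoding = hmm.viterbi_decode(series, best)
    report.time_budget = hmm.time_budget(decoding)
    report.decoded = pd.DataFrame(
        {
            "segment_id": decoding.segment_id,
            "state": decoding.states,
            "p_state1": decoding.posterior[:, 0],
            "p_state2": decoding.posterior[:, 1],
        }
    )
    if best.params.n_covariates > 0:
        grid = cfg["stationary_temp_grid"]
        if grid is None:
            temp = series.data["temp_c"].to_numpy(dtype=float)
            grid = np.linspace(np.nanmin(temp), np.nanmax(temp), 41)
        report.stationary = hmm.stationary_probs(best, grid)
    return report


def write_report(report: StudyReport, out_dir) -> None:
    """Emit the report as a key/value text file plus delimited tables."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    lines = [f"n_input: {report.n_input}"]
    for s in report.stages:
        lines.append(f"stage {s.stage}: in={s.n_in} removed={s.n_removed} retained={s.n_out}")
    lines.append(f"counts_conserved: {report.counts_conserved()}")
    lines.append(f"n_segments: {report.n_segments}")
    lines.append(f"n_grid_points: {report.n_grid_points}")
    lines.append(f"ctcrw_fallbacks: {','.join(report.ctcrw_fallbacks) or 'none'}")
    lines.append(f"hmm_skipped: {report.hmm_skipped}")
    if report.best_model is not None:
        lines.append(f"best_model: {report.best_model}")
    if report.time_budget is not None:
        lines.append(
            "time_budget: " + ", ".join(f"state{i + 1}={p:.3f}" for i, p in enumerate(report.time_budget))
        )
    if report.gps_errors is not None:
        lines.append(f"gps_error_m: {report.gps_errors}")
    (out / "report.txt").write_text("\n".join(lines) + "\n")
    if report.model_table is not None:
        report.model_table.to_csv(out / "model_selection.csv", index=False)
    if report.decoded is not None:
        report.decoded.to_csv(out / "decoded_states.csv", index=False)
    if report.stationary is not None:
        report.stationary.to_csv(out / "stationary_probs.csv", index=False)
    if report.duration_summary is not None:
        report.duration_summary.to_csv(out / "duration_summary.csv", index=False)
    if report.error_classes is not None:
        report.error_classes.to_csv(out / "error_classes.csv", index=False)
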