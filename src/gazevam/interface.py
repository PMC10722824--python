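"""Run configuration, gaze-file I/O and the end-to-end pipeline driver.

``run_analysis`` is the in-memory pipeline (simulate/load -> screen ->
aggregate -> features -> cross-validated VAMs -> voting diagnosis ->
metrics); ``run_pipeline`` wraps it with on-disk artifacts: a resolved
config snapshot, per-subject and per-fold CSV reports and a JSON summary.
All outputs are fully determined by the config and its seeds.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import diagnose, fixtures, preprocess, vam
from .features import extract_features, movement_scale
from .fixtures import GazeRecording, GazeSimConfig, Stimulus, StimulusConfig

logger = logging.getLogger("gazevam")

__all__ = ["RunConfig", "read_gaze_tsv", "read_fixations_tsv", "run_analysis", "run_pipeline"]


@dataclass
class RunConfig:
    """Resolved parameters of one pipeline run; defaults follow the study protocol."""

    stimulus_dir: str | None = None  # None -> generate fixtures
    gaze_tsv: str | None = None
    fixations_tsv: str | None = None
    out_dir: str = "gazevam_out"
    aggregation_threshold: float = preprocess.DEFAULT_MOTION_THRESHOLD  # 0.33
    aggregation_rule: str = "running_mean"
    loss_threshold: float = preprocess.DEFAULT_LOSS_THRESHOLD  # 0.20
    sigma_frac: float = 0.02  # fixation-map smoothing, fraction of frame width
    masks_mode: str = "ground_truth"
    algorithm: str = "rf"
    feature_mode: str = "all"
    fixed_features: list[int] | None = None
    relief_k: int = 60
    ga_n_features: int = 15
    n_folds: int = 5
    similarity_metric: str = "pearson"
    hyperparams: dict = field(default_factory=dict)
    sampling: dict = field(default_factory=dict)
    sweep_thresholds: list[float] = field(
        default_factory=lambda: list(diagnose.DEFAULT_SWEEP_THRESHOLDS)
    )
    stimulus: dict = field(default_factory=dict)  # StimulusConfig overrides
    gaze_sim: dict = field(default_factory=dict)  # GazeSimConfig overrides
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)


# ---------------------------------------------------------------------------
# gaze I/O


def read_gaze_tsv(
    path: str | Path,
    column_map: dict[str, str] | None = None,
    sample_rate_hz: float = 250.0,
) -> list[GazeRecording]:
    """Read a gaze-sample TSV into per-subject recordings.

    Expects (possibly renamed via ``column_map``) columns
    subject_id, group, t_ms, x, y, valid. Rows out of time order are sorted
    with a warning; negative coordinates on valid samples are an error that
    lists the offending line numbers.
    """
    df = pd.read_csv(path, sep="\t")
    if column_map:
        df = df.rename(columns=column_map)
    required = {"subject_id", "t_ms", "x", "y", "valid"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    if "group" not in df.columns:
        df["group"] = "unknown"
    bad = df.index[(df["valid"] == 1) & ((df["x"] < 0) | (df["y"] < 0))]
    if len(bad):
        lines = [int(i) + 2 for i in bad[:20]]  # header + 1-based
        raise ValueError(f"{path}: negative coordinates on valid samples at lines {lines}")
    recordings = []
    for sid, sub in df.groupby("subject_id", sort=True):
        if not sub["t_ms"].is_monotonic_increasing:
            warnings.warn(f"{path}: samples for {sid} out of order; sorting by t_ms")
            sub = sub.sort_values("t_ms", kind="stable")
        recordings.append(
            GazeRecording(
                subject_id=str(sid),
                group=str(sub["group"].iloc[0]),
                samples=sub[["t_ms", "x", "y", "valid"]].to_numpy(float),
                fixations=np.empty((0, 4)),
                sample_rate_hz=sample_rate_hz,
            )
        )
    return recordings


def read_fixations_tsv(path: str | Path, recordings: list[GazeRecording]) -> None:
    """Attach fixations from a companion TSV to matching recordings in place."""
    df = pd.read_csv(path, sep="\t")
    by_id = {rec.subject_id: rec for rec in recordings}
    for sid, sub in df.groupby("subject_id", sort=True):
        if str(sid) in by_id:
            by_id[str(sid)].fixations = sub[
                ["t_start_ms", "t_end_ms", "x", "y"]
            ].to_numpy(float)


# ---------------------------------------------------------------------------
# pipeline


def _build_maps(
    recordings: list[GazeRecording],
    groups: list[preprocess.FrameGroup],
    shape: tuple[int, int],
    sigma_px: float,
    fps: float,
):
    """Cohort maps (impulses summed across subjects before smoothing) and
    per-subject maps for every frame group."""
    cohorts = sorted({r.group for r in recordings if r.group in ("TD", "ASD")})
    cohort_maps: dict[str, dict[int, preprocess.FixationMap]] = {c: {} for c in cohorts}
    subject_maps: dict[str, dict[int, preprocess.FixationMap]] = {
        r.subject_id: {} for r in recordings
    }
    for fg in groups:
        for c in cohorts:
            fix = [r.fixations for r in recordings if r.group == c]
            cohort_maps[c][fg.index] = preprocess.build_fixation_map(
                fix, fg, shape, sigma_px, fps, subject_scope=f"cohort:{c}"
            )
        for r in recordings:
            subject_maps[r.subject_id][fg.index] = preprocess.build_fixation_map(
                r.fixations, fg, shape, sigma_px, fps, subject_scope=r.subject_id
            )
    return cohort_maps, subject_maps


def run_analysis(
    stimulus: Stimulus,
    recordings: list[GazeRecording],
    aggregation_threshold: float = preprocess.DEFAULT_MOTION_THRESHOLD,
    aggregation_rule: str = "running_mean",
    loss_threshold: float = preprocess.DEFAULT_LOSS_THRESHOLD,
    sigma_frac: float = 0.02,
    masks_mode: str = "ground_truth",
    algorithm: str = "rf",
    feature_mode: str = "all",
    fixed_features: tuple[int, ...] | None = None,
    relief_k: int = 60,
    ga_n_features: int = 15,
    n_folds: int = 5,
    similarity_metric: str = "pearson",
    hyperparams: dict | None = None,
    sampling: dict | None = None,
    seed: int = 0,
) -> tuple[diagnose.EvalReport, dict]:
    """Execute the full analysis in memory and return (report, extras).

    extras carries the intermediate artifacts a caller may want to persist:
    frame groups, per-fold models, diagnosis results and loss fractions.
    """
    retained, excluded, loss = preprocess.screen_subjects(recordings, loss_threshold)
    cohort_sizes = {c: sum(r.group == c for r in retained) for c in ("TD", "ASD")}
    if min(cohort_sizes.values()) == 0:
        raise ValueError(f"a cohort was fully excluded: retained {cohort_sizes}")
    logger.info("screening: retained %d, excluded %d", len(retained), len(excluded))

    groups = preprocess.aggregate_frames(
        stimulus, threshold=aggregation_threshold, rule=aggregation_rule
    )
    logger.info("aggregated %d frames into %d groups", stimulus.n_frames, len(groups))

    scale = movement_scale(stimulus)
    stacks = {
        fg.index: extract_features(
            fg, stimulus, masks_mode=masks_mode, movement_scale_value=scale
        )
        for fg in groups
    }
    shape = stimulus.frame_shape
    sigma_px = sigma_frac * shape[1]
    cohort_maps, subject_maps = _build_maps(
        retained, groups, shape, sigma_px, stimulus.fps
    )

    fold_results = vam.cross_validate(
        stacks,
        cohort_maps,
        algorithm=algorithm,
        feature_mode=feature_mode,
        n_folds=n_folds,
        seed=seed,
        hyperparams=hyperparams,
        fixed_features=fixed_features,
        relief_k=relief_k,
        ga_n_features=ga_n_features,
        sampling=sampling,
    )
    results = diagnose.diagnose_cohort(fold_results, subject_maps, similarity_metric)
    truth = {r.subject_id: r.group for r in retained}
    report = diagnose.evaluate(results, truth)
    extras = {
        "n_groups": len(groups),
        "frame_groups": groups,
        "fold_results": fold_results,
        "diagnosis": results,
        "loss_fractions": loss,
        "excluded": [r.subject_id for r in excluded],
        "truth": truth,
    }
    return report, extras


def run_pipeline(config: RunConfig) -> Path:
    """Run the pipeline per config and write reports; returns the output dir."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config_resolved.yaml")

    if config.stimulus_dir:
        stimulus = fixtures.read_stimulus(config.stimulus_dir)
    else:
        stimulus = fixtures.generate_stimulus(
            StimulusConfig(**config.stimulus), seed=config.seed
        )
    if config.gaze_tsv:
        if not Path(config.gaze_tsv).exists():
            raise FileNotFoundError(f"gaze stage: gaze file not found: {config.gaze_tsv}")
        recordings = read_gaze_tsv(config.gaze_tsv)
        if config.fixations_tsv:
            read_fixations_tsv(config.fixations_tsv, recordings)
    else:
        recordings = fixtures.simulate_gaze(
            stimulus, GazeSimConfig(**config.gaze_sim), seed=config.seed + 1
        )

    report, extras = run_analysis(
        stimulus,
        recordings,
        aggregation_threshold=config.aggregation_threshold,
        aggregation_rule=config.aggregation_rule,
        loss_threshold=config.loss_threshold,
        sigma_frac=config.sigma_frac,
        masks_mode=config.masks_mode,
        algorithm=config.algorithm,
        feature_mode=config.feature_mode,
        fixed_features=tuple(config.fixed_features) if config.fixed_features else None,
        relief_k=config.relief_k,
        ga_n_features=config.ga_n_features,
        n_folds=config.n_folds,
        similarity_metric=config.similarity_metric,
        hyperparams=config.hyperparams,
        sampling=config.sampling,
        seed=config.seed,
    )

    subjects = pd.DataFrame(
        [
            {
                "subject_id": r.subject_id,
                "fold": r.fold_id,
                "true_group": extras["truth"][r.subject_id],
                "predicted": r.predicted,
                "score": r.score,
                "n_votes_asd": r.votes.count("ASD"),
                "n_votes_td": r.votes.count("TD"),
                "n_abstain": r.votes.count("abstain"),
                "flagged": r.flagged,
            }
            for r in extras["diagnosis"]
        ]
    )
    subjects.to_csv(out / "subjects.csv", index=False)
    report.per_fold.to_csv(out / "folds.csv", index=False)
    summary = {
        "mean_metrics": report.mean,
        "n_frame_groups": extras["n_groups"],
        "n_retained": len(extras["loss_fractions"]) - len(extras["excluded"]),
        "excluded_subjects": extras["excluded"],
        "seed": config.seed,
    }
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True)
    for fr in extras["fold_results"]:
        for cohort, model in fr.models.items():
            model.save(out / "models" / f"fold{fr.fold_id}_{cohort.lower()}")
    return out
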