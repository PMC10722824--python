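"""Subject screening, inter-frame motion, frame aggregation and fixation maps.

Single video frames rarely accumulate enough fixations to learn from, so
consecutive frames whose inter-frame motion stays below a threshold
(default 0.33) are aggregated into frame groups; fixation maps are then
built per group, for one subject or for a whole cohort.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter

from .fixtures import GazeRecording, Stimulus

__all__ = [
    "FrameGroup",
    "FixationMap",
    "screen_subjects",
    "compute_motion",
    "aggregate_frames",
    "build_fixation_map",
]

DEFAULT_LOSS_THRESHOLD = 0.20
DEFAULT_MOTION_THRESHOLD = 0.33


@dataclass
class FrameGroup:
    """A maximal run of consecutive frames aggregated under the motion threshold."""

    index: int
    frame_ids: range
    representative_frame: np.ndarray  # mean image of members, (H, W, 3)
    mean_motion: float  # mean consecutive-pair motion inside the group

    @property
    def n_frames(self) -> int:
        return len(self.frame_ids)


@dataclass
class FixationMap:
    group_index: int
    subject_scope: str  # subject id or "cohort:<TD|ASD>"
    density: np.ndarray  # (H, W), nonnegative, max-normalized to 1
    n_fixations: int


def screen_subjects(
    recordings: list[GazeRecording], loss_threshold: float = DEFAULT_LOSS_THRESHOLD
) -> tuple[list[GazeRecording], list[GazeRecording], dict[str, float]]:
    """Partition subjects by the data-loss exclusion criterion.

    A subject is excluded iff the fraction of invalid samples is strictly
    greater than ``loss_threshold`` (default 20%). Returns
    (retained, excluded, per-subject loss fractions).
    """
    if not recordings:
        raise ValueError("no recordings to screen")
    retained, excluded, fractions = [], [], {}
    for rec in recordings:
        frac = rec.loss_fraction  # raises on zero samples
        fractions[rec.subject_id] = frac
        (excluded if frac > loss_threshold else retained).append(rec)
    return retained, excluded, fractions


def compute_motion(frame_a: np.ndarray, frame_b: np.ndarray) -> float:
    """Mean absolute grayscale difference between two frames, in [0, 1].

    Grayscale is the channel mean; intensities are assumed in [0, 1]. The
    metric is symmetric and zero iff the frames are identical.
    """
    if frame_a.shape != frame_b.shape:
        raise ValueError(f"frame shapes differ: {frame_a.shape} vs {frame_b.shape}")
    a = frame_a.astype(np.float64)
    b = frame_b.astype(np.float64)
    if a.ndim == 3:
        a = a.mean(axis=2)
        b = b.mean(axis=2)
    return float(np.abs(a - b).mean())


def consecutive_motions(frames: np.ndarray) -> np.ndarray:
    """Motion between each consecutive frame pair; length n_frames - 1."""
    return np.array(
        [compute_motion(frames[i], frames[i + 1]) for i in range(len(frames) - 1)]
    )


def group_boundaries(
    motions: np.ndarray, threshold: float, rule: str = "running_mean"
) -> list[tuple[int, int]]:
    """Greedy left-to-right grouping of ``len(motions) + 1`` frames.

    rule="running_mean": frame j joins the current group iff the mean of the
    consecutive-pair motions inside the group, including the pair (j-1, j),
    stays strictly below the threshold.
    rule="pairwise": frame j joins iff motion(j-1, j) < threshold.
    Returns (start, stop) half-open frame-index ranges.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    if rule not in ("running_mean", "pairwise"):
        raise ValueError(f"unknown aggregation rule: {rule!r}")
    n_frames = len(motions) + 1
    bounds = []
    start = 0
    acc: list[float] = []
    for j in range(1, n_frames):
        m = motions[j - 1]
        if rule == "pairwise":
            join = m < threshold
        else:
            join = (sum(acc) + m) / (len(acc) + 1) < threshold
        if join:
            acc.append(m)
        else:
            bounds.append((start, j))
            start = j
            acc = []
    bounds.append((start, n_frames))
    return bounds


def aggregate_frames(
    stimulus: Stimulus,
    threshold: float = DEFAULT_MOTION_THRESHOLD,
    rule: str = "running_mean",
) -> list[FrameGroup]:
    """Aggregate consecutive frames whose average motion stays below threshold.

    Every frame is assigned to exactly one group; groups are contiguous and
    chronological. The representative frame is the mean image of members.
    """
    if stimulus.n_frames == 0:
        raise ValueError("stimulus has no frames")
    motions = consecutive_motions(stimulus.frames)
    groups = []
    for gi, (start, stop) in enumerate(group_boundaries(motions, threshold, rule)):
        internal = motions[start : stop - 1]
        groups.append(
            FrameGroup(
                index=gi,
                frame_ids=range(start, stop),
                representative_frame=stimulus.frames[start:stop].mean(axis=0),
                mean_motion=float(internal.mean()) if len(internal) else 0.0,
            )
        )
    return groups


def _group_time_span_ms(group: FrameGroup, fps: float) -> tuple[float, float]:
    return group.frame_ids.start / fps * 1000.0, group.frame_ids.stop / fps * 1000.0


def build_fixation_map(
    fixations: np.ndarray | list[np.ndarray],
    frame_group: FrameGroup,
    shape: tuple[int, int],
    sigma_px: float,
    fps: float,
    subject_scope: str = "subject",
    assign: str = "midpoint",
) -> FixationMap:
    """Smoothed map of fixation centroids falling on a frame group.

    A fixation contributes to the group whose time span contains its
    temporal midpoint (``assign="midpoint"``, the default), so each
    fixation counts toward exactly one frame group; ``assign="overlap"``
    instead credits every group the fixation's [t_start, t_end) interval
    touches. Exclusive assignment matters under cross-validation over
    frame groups: a fixation spanning a fold boundary would otherwise
    enter both a training map and a held-out map and leak cohort identity
    into the diagnosis. For cohort scope pass a list of per-subject
    fixation arrays, whose impulse maps are summed before smoothing. The
    result is smoothed with an isotropic Gaussian and normalized to max 1
    (all-zero iff no fixation contributes). Centroids outside the frame
    are clamped with a warning.
    """
    if assign not in ("midpoint", "overlap"):
        raise ValueError(f"unknown assignment rule: {assign!r}")
    h, w = shape
    t0, t1 = _group_time_span_ms(frame_group, fps)
    if isinstance(fixations, np.ndarray):
        fixations = [fixations]
    impulses = np.zeros((h, w), dtype=np.float64)
    n_fix = 0
    n_clamped = 0
    for fix in fixations:
        if len(fix) == 0:
            continue
        if assign == "midpoint":
            mid = (fix[:, 0] + fix[:, 1]) / 2.0
            selected = (mid >= t0) & (mid < t1)
        else:
            selected = (fix[:, 0] < t1) & (fix[:, 1] > t0)
        for _, _, x, y in fix[selected]:
            xi, yi = int(round(x)), int(round(y))
            if not (0 <= xi < w and 0 <= yi < h):
                n_clamped += 1
                xi = min(max(xi, 0), w - 1)
                yi = min(max(yi, 0), h - 1)
            impulses[yi, xi] += 1.0
            n_fix += 1
    if n_clamped:
        warnings.warn(f"{n_clamped} fixation centroid(s) outside frame bounds; clamped")
    if n_fix == 0:
        return FixationMap(frame_group.index, subject_scope, impulses, 0)
    density = gaussian_filter(impulses, sigma=sigma_px) if sigma_px > 0 else impulses
    density = density / density.max()
    return FixationMap(frame_group.index, subject_scope, density, n_fix)
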