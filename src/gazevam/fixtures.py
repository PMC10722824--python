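"""Synthetic split-screen stimuli and simulated group-specific gaze recordings.

Clinical eye-tracking recordings for the GeoPref-style preferential-looking
paradigm are not publicly deposited, so every downstream stage of the
pipeline is exercised against synthetic data generated here: a split-screen
video with a social-proxy scene on the left half and an animated geometric
pattern on the right half, plus per-subject gaze sample streams drawn from
group-specific mixtures over attractor maps (screen center, scene centers,
face, either half, uniform).

The generator is fully seeded: identical seeds produce bit-identical frames
and recordings.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np

__all__ = [
    "Stimulus",
    "StimulusConfig",
    "GazeSimConfig",
    "GazeRecording",
    "ATTRACTOR_NAMES",
    "generate_stimulus",
    "simulate_gaze",
    "write_stimulus",
    "read_stimulus",
    "write_gaze_tsv",
    "write_fixations_tsv",
]

MASK_NAMES = ("face", "people", "skin", "social_half", "geometric_half")
ATTRACTOR_NAMES = (
    "center_screen",
    "center_scene",
    "face",
    "social_half",
    "geometric_half",
    "uniform",
)


@dataclass
class Stimulus:
    """An ordered RGB frame sequence with per-frame ground-truth masks.

    frames : (T, H, W, 3) float array, intensities in [0, 1].
    masks  : name -> (T, H, W) boolean array; social/geometric halves are
             disjoint and each confined to one lateral half.
    """

    frames: np.ndarray
    fps: float
    masks: dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.frames.shape[1], self.frames.shape[2]

    @property
    def duration_s(self) -> float:
        return self.n_frames / self.fps


@dataclass(frozen=True)
class StimulusConfig:
    width: int = 320
    height: int = 180
    fps: float = 30.0
    duration_s: float = 10.0
    #: scales all temporal change; 0 -> perfectly static scene
    motion: float = 1.0

    def validate(self) -> None:
        if self.width <= 0 or self.height <= 0:
            raise ValueError("frame dimensions must be positive")
        if self.width % 2 != 0:
            raise ValueError("width must be even (two lateral halves)")
        if self.fps <= 0:
            raise ValueError("fps must be positive")
        if self.duration_s <= 0:
            raise ValueError("duration_s must be positive")
        if self.motion < 0:
            raise ValueError("motion must be nonnegative")


@dataclass(frozen=True)
class GazeSimConfig:
    """Mixture weights and noise model for the simulated cohorts.

    Default weights give the TD group a strong face/social preference and
    the ASD group a geometric-half preference, emulating the preferential-
    looking contrast the paradigm probes. Sampling rate defaults to 250 Hz.
    """

    n_td: int = 20
    n_asd: int = 20
    weights_td: dict[str, float] = field(
        default_factory=lambda: {
            "face": 0.6,
            "center_screen": 0.15,
            "social_half": 0.15,
            "uniform": 0.1,
        }
    )
    weights_asd: dict[str, float] = field(
        default_factory=lambda: {
            "face": 0.1,
            "geometric_half": 0.55,
            "center_scene": 0.25,
            "uniform": 0.1,
        }
    )
    noise_sigma_px: float = 5.0
    sample_rate_hz: float = 250.0
    loss_rate: float = 0.05
    #: dwell-time range of one gaze event (attractor + target held fixed)
    dwell_ms_range: tuple[float, float] = (150.0, 400.0)
    #: dispersion-based fixation derivation (stand-in for the vendor I-VT filter)
    fixation_radius_px: float = 25.0
    fixation_min_dur_ms: float = 100.0

    def validate(self) -> None:
        if not 0 <= self.loss_rate < 1:
            raise ValueError("loss_rate must be in [0, 1)")
        for w in (self.weights_td, self.weights_asd):
            unknown = set(w) - set(ATTRACTOR_NAMES)
            if unknown:
                raise ValueError(f"unknown attractor name(s): {sorted(unknown)}")
            if not w or sum(w.values()) <= 0:
                raise ValueError("mixture weights must have positive sum")
            if any(v < 0 for v in w.values()):
                raise ValueError("mixture weights must be nonnegative")


@dataclass
class GazeRecording:
    """One subject's timestamped gaze samples and derived fixations.

    samples   : (n, 4) array of (t_ms, x_px, y_px, valid_flag), sorted by t_ms.
    fixations : (m, 4) array of (t_start_ms, t_end_ms, x_px, y_px).
    """

    subject_id: str
    group: str  # "TD" | "ASD" | "unknown"
    samples: np.ndarray
    fixations: np.ndarray
    sample_rate_hz: float

    @property
    def loss_fraction(self) -> float:
        if len(self.samples) == 0:
            raise ValueError(f"recording {self.subject_id} has zero samples")
        return float(1.0 - self.samples[:, 3].mean())


# ---------------------------------------------------------------------------
# stimulus rendering


def _disk(h: int, w: int, cy: float, cx: float, r: float) -> np.ndarray:
    yy, xx = np.mgrid[0:h, 0:w]
    return (yy - cy) ** 2 + (xx - cx) ** 2 <= r**2


def _ellipse(h: int, w: int, cy: float, cx: float, ry: float, rx: float) -> np.ndarray:
    yy, xx = np.mgrid[0:h, 0:w]
    return ((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2 <= 1.0


def generate_stimulus(cfg: StimulusConfig = StimulusConfig(), seed: int = 0) -> Stimulus:
    """Render the split-screen stimulus and its ground-truth masks.

    Left half: a skin-toned person proxy (body ellipse + head disk with a
    darker face patch) drifting sinusoidally on a muted background. Right
    half: a high-contrast animated color plaid whose phase advances at a
    randomly modulated speed, so inter-frame motion varies over time and the
    frame-aggregation stage produces a nontrivial grouping. ``cfg.motion``
    scales every temporal change; 0 yields identical frames throughout.
    """
    cfg.validate()
    rng = np.random.default_rng(seed)
    h, w = cfg.height, cfg.width
    n = int(round(cfg.fps * cfg.duration_s))
    half = w // 2

    yy, xx = np.mgrid[0:h, 0:w]
    frames = np.empty((n, h, w, 3), dtype=np.float32)
    masks = {name: np.zeros((n, h, w), dtype=bool) for name in MASK_NAMES}
    masks["social_half"][:, :, :half] = True
    masks["geometric_half"][:, :, half:] = True

    # Temporal dynamics: a global luminance sequence alternates between
    # strong flicker runs (bright/dark every frame) and calmer zig-zag
    # runs, so consecutive-frame motion spans the whole sweep range and
    # frame aggregation yields varied group sizes; the plaid phase and the
    # person proxy add slower structured motion on top.
    phase0 = rng.uniform(0, 2 * np.pi, size=4)
    lum_seq = np.empty(n)
    i = 0
    state_fast = bool(rng.random() < 0.5)
    cur = rng.uniform(0.4, 0.7)
    direction = 1.0
    while i < n:
        if state_fast:
            run = int(rng.integers(6, 15))
            for t in range(i, min(i + run, n)):
                lum_seq[t] = 1.0 if (t - i) % 2 == 0 else 0.12
            cur = rng.uniform(0.4, 0.7)
        else:
            run = int(rng.integers(3, 8))
            step = rng.uniform(0.28, 0.36)
            for t in range(i, min(i + run, n)):
                cur += direction * step
                if cur > 0.9:
                    cur, direction = 0.9 - (cur - 0.9), -1.0
                elif cur < 0.2:
                    cur, direction = 0.2 + (0.2 - cur), 1.0
                lum_seq[t] = cur
        i += run
        state_fast = not state_fast
    person_phase = rng.uniform(0, 2 * np.pi, size=2)

    fx, fy = 4.0 / w, 6.0 / h  # plaid spatial frequencies
    phase = phase0[:3].copy()
    for t in range(n):
        frame = np.empty((h, w, 3), dtype=np.float32)
        # --- social half: light background + person proxy
        frame[:, :, 0] = 0.60
        frame[:, :, 1] = 0.65
        frame[:, :, 2] = 0.70
        drift = cfg.motion * t / cfg.fps
        pcx = half * 0.5 + half * 0.18 * np.sin(0.8 * drift + person_phase[0])
        pcy = h * 0.55 + h * 0.10 * np.sin(1.3 * drift + person_phase[1])
        head_r = h * 0.07
        body = _ellipse(h, w, pcy + h * 0.18, pcx, h * 0.16, h * 0.09)
        head = _disk(h, w, pcy, pcx, head_r)
        skin = (0.91, 0.72, 0.56)
        for c in range(3):
            frame[:, :, c][body] = skin[c] * 0.9
            frame[:, :, c][head] = skin[c]
        # face patch: eyes + mouth as darker dots inside the head
        eyes = _disk(h, w, pcy - head_r * 0.25, pcx - head_r * 0.4, head_r * 0.16) | _disk(
            h, w, pcy - head_r * 0.25, pcx + head_r * 0.4, head_r * 0.16
        )
        mouth = _ellipse(h, w, pcy + head_r * 0.45, pcx, head_r * 0.14, head_r * 0.4)
        for c in range(3):
            frame[:, :, c][eyes | mouth] = 0.15

        # --- geometric half: animated high-contrast plaid
        if t > 0:
            phase = phase + cfg.motion * np.array([0.20, 0.13, 0.26])
        gx = xx[:, half:]
        gy = yy[:, half:]
        plaid_a = 0.5 + 0.5 * np.sin(2 * np.pi * fx * gx + phase[0]) * np.sin(
            2 * np.pi * fy * gy + phase[1]
        )
        plaid_b = 0.5 + 0.5 * np.sin(2 * np.pi * (fx * gx + fy * gy) + phase[2])
        frame[:, half:, 0] = plaid_a
        frame[:, half:, 1] = plaid_b
        frame[:, half:, 2] = 1.0 - plaid_a

        # global luminance (scene lighting), shared by both halves; with
        # motion 0 the sequence is frozen at its first value
        lum = lum_seq[t] if cfg.motion > 0 else lum_seq[0]
        frames[t] = np.clip(frame * lum, 0.0, 1.0)
        masks["face"][t] = head
        masks["people"][t] = body | head
        masks["skin"][t] = (body | head) & ~(eyes | mouth)

    return Stimulus(frames=frames, fps=cfg.fps, masks=masks)


# ---------------------------------------------------------------------------
# gaze simulation


def _attractor_map(stimulus: Stimulus, name: str, frame_idx: int) -> np.ndarray:
    """Nonnegative sampling map for one attractor on one frame."""
    h, w = stimulus.frame_shape
    if name == "uniform":
        return np.ones((h, w))
    if name in ("center_screen", "center_scene"):
        from .features import center_maps

        cs, cc = center_maps((h, w))
        return cs if name == "center_screen" else cc
    if name in stimulus.masks:
        return stimulus.masks[name][frame_idx].astype(float)
    raise ValueError(f"unknown attractor name: {name}")


def _sample_from_map(density: np.ndarray, rng: np.random.Generator, size: int) -> np.ndarray:
    """Inverse-CDF sampling over the flattened map; returns (size, 2) of (y, x)."""
    flat = density.ravel().astype(np.float64)
    total = flat.sum()
    if total <= 0:
        raise ValueError("attractor map has zero mass")
    cdf = np.cumsum(flat / total)
    idx = np.searchsorted(cdf, rng.random(size), side="right")
    idx = np.minimum(idx, flat.size - 1)
    y, x = np.unravel_index(idx, density.shape)
    return np.stack([y, x], axis=1)


def _derive_fixations(
    samples: np.ndarray,
    radius_px: float,
    min_dur_ms: float,
    max_gap_ms: float = 75.0,
) -> np.ndarray:
    """Dispersion-based fixation detection over valid samples.

    A run grows while every valid sample stays within ``radius_px`` of the
    running centroid; short dropout gaps (up to ``max_gap_ms``) inside a run
    are tolerated, longer ones break it; runs shorter than ``min_dur_ms``
    are discarded. This emulates (but is not) the vendor velocity-threshold
    filter with its gap fill-in.
    """
    fixations = []
    run: list[tuple[float, float, float]] = []
    sx = sy = 0.0  # running centroid sums

    def _flush() -> None:
        nonlocal sx, sy
        if len(run) >= 2:
            arr = np.asarray(run)
            dur = arr[-1, 0] - arr[0, 0]
            if dur >= min_dur_ms:
                fixations.append(
                    (arr[0, 0], arr[-1, 0], arr[:, 1].mean(), arr[:, 2].mean())
                )
        run.clear()
        sx = sy = 0.0

    for t, x, y, valid in samples:
        if not valid:
            if run and t - run[-1][0] > max_gap_ms:
                _flush()
            continue
        if run:
            if t - run[-1][0] > max_gap_ms:
                _flush()
        if run:
            cx, cy = sx / len(run), sy / len(run)
            if (x - cx) ** 2 + (y - cy) ** 2 > radius_px**2:
                _flush()
        run.append((t, x, y))
        sx += x
        sy += y
    _flush()
    return np.asarray(fixations, dtype=float).reshape(-1, 4)


def simulate_gaze(
    stimulus: Stimulus, cfg: GazeSimConfig = GazeSimConfig(), seed: int = 0
) -> list[GazeRecording]:
    """Simulate gaze recordings for both cohorts watching ``stimulus``.

    Gaze is generated as a sequence of dwell events: per event an attractor
    is chosen from the subject's group mixture, a target point is drawn by
    inverse-CDF sampling proportional to that attractor's map on the
    current frame, and for the event's dwell time every sample scatters
    around the target with Gaussian jitter, clamped to the frame. Samples
    are marked invalid with probability ``loss_rate``. Fixations are then
    derived with a dispersion criterion.
    """
    cfg.validate()
    rng = np.random.default_rng(seed)
    h, w = stimulus.frame_shape
    n_samples = int(round(stimulus.duration_s * cfg.sample_rate_hz))
    t_ms = np.arange(n_samples) * 1000.0 / cfg.sample_rate_hz
    frame_idx = np.minimum(
        (t_ms / 1000.0 * stimulus.fps).astype(int), stimulus.n_frames - 1
    )

    static = {"uniform", "center_screen", "center_scene", "social_half", "geometric_half"}
    map_cache: dict[tuple[str, int], np.ndarray] = {}
    centroid_cache: dict[str, np.ndarray] = {}

    def draw_target(name: str, frame: int) -> np.ndarray:
        key = (name, 0 if name in static else frame)
        if key not in map_cache:
            map_cache[key] = _attractor_map(stimulus, name, key[1])
        return _sample_from_map(map_cache[key], rng, 1)[0]

    def centroids(name: str) -> np.ndarray:
        # per-frame (y, x) centroid of a moving mask attractor
        if name not in centroid_cache:
            m = stimulus.masks[name]
            ys = np.array([np.argwhere(fr).mean(axis=0) for fr in m])
            centroid_cache[name] = ys
        return centroid_cache[name]

    recordings = []
    groups = [("TD", cfg.n_td, cfg.weights_td), ("ASD", cfg.n_asd, cfg.weights_asd)]
    for group, n_subj, weights in groups:
        names = sorted(weights)
        probs = np.array([weights[k] for k in names], dtype=float)
        probs = probs / probs.sum()
        for name in names:  # fail fast on unknown attractors
            _attractor_map(stimulus, name, 0)
        for s in range(n_subj):
            pts = np.empty((n_samples, 2))
            i = 0
            while i < n_samples:
                aname = names[rng.choice(len(names), p=probs)]
                dwell = rng.uniform(*cfg.dwell_ms_range)
                n_dwell = max(1, int(round(dwell * cfg.sample_rate_hz / 1000.0)))
                stop = min(i + n_dwell, n_samples)
                f0 = int(frame_idx[i])
                target = draw_target(aname, f0)
                if aname in static:
                    pts[i:stop] = target
                else:
                    # the target rides the moving mask (smooth pursuit)
                    c = centroids(aname)
                    pts[i:stop] = target + c[frame_idx[i:stop]] - c[f0]
                i = stop
            xy = pts[:, ::-1].astype(float)  # (x, y)
            if cfg.noise_sigma_px > 0:
                xy = xy + rng.normal(0, cfg.noise_sigma_px, size=xy.shape)
            xy[:, 0] = np.clip(xy[:, 0], 0, w - 1)
            xy[:, 1] = np.clip(xy[:, 1], 0, h - 1)
            valid = (rng.random(n_samples) >= cfg.loss_rate).astype(float)
            samples = np.column_stack([t_ms, xy, valid])
            fixations = _derive_fixations(
                samples, cfg.fixation_radius_px, cfg.fixation_min_dur_ms
            )
            recordings.append(
                GazeRecording(
                    subject_id=f"{group.lower()}_{s:03d}",
                    group=group,
                    samples=samples,
                    fixations=fixations,
                    sample_rate_hz=cfg.sample_rate_hz,
                )
            )
    return recordings


# ---------------------------------------------------------------------------
# on-disk formats


def write_stimulus(stimulus: Stimulus, outdir: str | Path) -> Path:
    """Write frames (and masks) as zero-padded PNGs plus a JSON metadata file."""
    outdir = Path(outdir)
    (outdir / "frames").mkdir(parents=True, exist_ok=True)
    for name in stimulus.masks:
        (outdir / "masks" / name).mkdir(parents=True, exist_ok=True)
    meta = {
        "fps": stimulus.fps,
        "duration_s": stimulus.duration_s,
        "n_frames": stimulus.n_frames,
        "height": stimulus.frame_shape[0],
        "width": stimulus.frame_shape[1],
        "frames": [],
        "masks": {name: [] for name in stimulus.masks},
    }
    for t in range(stimulus.n_frames):
        fname = f"frame_{t:05d}.png"
        iio.imwrite(
            outdir / "frames" / fname,
            (stimulus.frames[t] * 255).round().astype(np.uint8),
        )
        meta["frames"].append(f"frames/{fname}")
        for name, m in stimulus.masks.items():
            mname = f"masks/{name}/{fname}"
            iio.imwrite(outdir / mname, m[t].astype(np.uint8) * 255)
            meta["masks"][name].append(mname)
    with open(outdir / "stimulus.json", "w") as fh:
        json.dump(meta, fh, indent=1, sort_keys=True)
    return outdir


def read_stimulus(indir: str | Path) -> Stimulus:
    indir = Path(indir)
    with open(indir / "stimulus.json") as fh:
        meta = json.load(fh)
    frames = np.stack(
        [iio.imread(indir / f).astype(np.float32) / 255.0 for f in meta["frames"]]
    )
    masks = {
        name: np.stack([iio.imread(indir / f) > 127 for f in files])
        for name, files in meta["masks"].items()
    }
    return Stimulus(frames=frames, fps=meta["fps"], masks=masks)


def write_gaze_tsv(recordings: list[GazeRecording], path: str | Path) -> Path:
    """TSV with header ``subject_id group t_ms x y valid``."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("subject_id\tgroup\tt_ms\tx\ty\tvalid\n")
        for rec in recordings:
            for t, x, y, v in rec.samples:
                fh.write(
                    f"{rec.subject_id}\t{rec.group}\t{t:.4f}\t{x:.4f}\t{y:.4f}\t{int(v)}\n"
                )
    return path


def write_fixations_tsv(recordings: list[GazeRecording], path: str | Path) -> Path:
    """Companion TSV ``subject_id t_start_ms t_end_ms x y``."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("subject_id\tt_start_ms\tt_end_ms\tx\ty\n")
        for rec in recordings:
            for t0, t1, x, y in rec.fixations:
                fh.write(f"{rec.subject_id}\t{t0:.4f}\t{t1:.4f}\t{x:.4f}\t{y:.4f}\n")
    return path
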