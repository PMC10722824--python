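"""Per-pixel feature extraction: the 28-channel stack used by the attention models.

Channels (1-based, order is fixed and bit-stable):

  1-13  steerable-pyramid subbands (3 scales x 4 orientations + lowpass
        residual), each rectified and divided by its spatial mean so every
        subband has mean exactly 1, varying only between pixels
  14    Itti-style color conspicuity          (in [0, 1])
  15    Itti-style intensity conspicuity
  16    Itti-style orientation conspicuity
  17    presence of skin
  18-20 raw R, G, B intensities
  21    horizon-line band
  22    presence of face
  23    presence of people
  24    center-screen Gaussian (frame-independent)
  25    movement (within-group temporal difference, stimulus-global scale)
  26    social-scene half indicator (soft)
  27    geometric-scene half indicator (soft)
  28    center-scene Gaussian, one peak per lateral half (frame-independent)

Face/people/skin/social/geometric channels come either from ground-truth
fixtures masks (``masks_mode="ground_truth"``) or from classical detectors
(``masks_mode="detector"``: a YCbCr skin rule and skin-blob box heuristics).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter
from skimage.measure import label, regionprops

from .fixtures import Stimulus
from .preprocess import FrameGroup

__all__ = ["FeatureStack", "FEATURE_NAMES", "extract_features", "center_maps"]

FEATURE_NAMES: tuple[str, ...] = tuple(
    [f"steerable_pyramid_{i}" for i in range(1, 14)]
    + [
        "itti_color",
        "itti_intensity",
        "itti_orientation",
        "skin",
        "color_red",
        "color_green",
        "color_blue",
        "horizon_line",
        "face",
        "people",
        "center_screen",
        "movement",
        "social_scene",
        "geometric_scene",
        "center_scene",
    ]
)

N_FEATURES = 28

_PYRAMID_SIGMAS = (1.0, 2.0, 4.0)
_ORIENTATIONS = (0.0, 45.0, 90.0, 135.0)
_RESIDUAL_SIGMA = 8.0


@dataclass
class FeatureStack:
    group_index: int
    stack: np.ndarray  # (H, W, 28) float32
    feature_names: tuple[str, ...] = FEATURE_NAMES


def _mean_normalize(channel: np.ndarray) -> np.ndarray:
    """Divide by the spatial mean so the channel averages exactly 1.

    A channel with zero mean (e.g. band-pass response of a uniform frame)
    carries no spatial information; it is replaced by the constant 1 map,
    which has the required mean and is equally uninformative.
    """
    m = channel.mean()
    if m <= 0:
        return np.ones_like(channel)
    return channel / m


def _max_normalize(channel: np.ndarray) -> np.ndarray:
    # floor guards against amplifying numerical dust on contrast-free frames
    m = channel.max()
    if m < 1e-9:
        return np.zeros_like(channel)
    return channel / m


def _steerable_g2(gray: np.ndarray, sigma: float, theta_deg: float) -> np.ndarray:
    """Oriented second-derivative-of-Gaussian response (steerable basis).

    The mean is removed first: the discrete derivative kernels carry a
    small DC bias, so a constant image would otherwise produce a nonzero
    response.
    """
    gray = gray - gray.mean()
    gxx = gaussian_filter(gray, sigma, order=(0, 2))
    gyy = gaussian_filter(gray, sigma, order=(2, 0))
    gxy = gaussian_filter(gray, sigma, order=(1, 1))
    th = np.deg2rad(theta_deg)
    return np.cos(th) ** 2 * gxx + np.sin(th) ** 2 * gyy + 2 * np.sin(th) * np.cos(th) * gxy


def steerable_pyramid_channels(gray: np.ndarray) -> list[np.ndarray]:
    """13 rectified, mean-normalized subbands: 3 scales x 4 orientations + residual."""
    channels = []
    for sigma in _PYRAMID_SIGMAS:
        for theta in _ORIENTATIONS:
            channels.append(_mean_normalize(np.abs(_steerable_g2(gray, sigma, theta))))
    channels.append(_mean_normalize(gaussian_filter(gray, _RESIDUAL_SIGMA)))
    return channels


def _center_surround(img: np.ndarray) -> np.ndarray:
    """Sum of |difference-of-Gaussian| maps across two scale pairs."""
    out = np.zeros_like(img)
    for c, s in ((1.0, 4.0), (2.0, 8.0)):
        out += np.abs(gaussian_filter(img, c) - gaussian_filter(img, s))
    return out


def itti_channels(frame: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Simplified Itti-Koch conspicuity maps: color, intensity, orientation.

    Color uses red-green and blue-yellow opponency, intensity the channel
    mean, orientation the energy of the oriented band-pass responses; each
    map is center-surround filtered and max-normalized to [0, 1]. A uniform
    frame yields all-zero maps (no contrast, no conspicuity).
    """
    r, g, b = frame[:, :, 0], frame[:, :, 1], frame[:, :, 2]
    intensity = frame.mean(axis=2)
    rg = r - g
    by = b - (r + g) / 2.0
    color = _max_normalize(_center_surround(rg) + _center_surround(by))
    inten = _max_normalize(_center_surround(intensity))
    orient = np.zeros_like(intensity)
    for sigma in (1.0, 2.0):
        for theta in _ORIENTATIONS:
            orient += np.abs(_steerable_g2(intensity, sigma, theta))
    return color, inten, _max_normalize(orient)


def detect_skin(frame: np.ndarray) -> np.ndarray:
    """Classical YCbCr box rule for skin pixels (binary map)."""
    r, g, b = (frame[:, :, i] * 255.0 for i in range(3))
    cb = 128 - 0.168736 * r - 0.331264 * g + 0.5 * b
    cr = 128 + 0.5 * r - 0.418688 * g - 0.081312 * b
    return (cb >= 77) & (cb <= 127) & (cr >= 133) & (cr <= 173)


def _blob_box_map(mask: np.ndarray, sigma: float, expand: float = 1.0) -> np.ndarray:
    """Gaussian-blurred union of bounding boxes of the mask's blobs."""
    out = np.zeros(mask.shape, dtype=float)
    h, w = mask.shape
    for region in regionprops(label(mask)):
        if region.area < 9:
            continue
        y0, x0, y1, x1 = region.bbox
        cy, cx = (y0 + y1) / 2, (x0 + x1) / 2
        hy, hx = (y1 - y0) / 2 * expand, (x1 - x0) / 2 * expand
        out[
            max(int(cy - hy), 0) : min(int(cy + hy) + 1, h),
            max(int(cx - hx), 0) : min(int(cx + hx) + 1, w),
        ] = 1.0
    return _max_normalize(gaussian_filter(out, sigma)) if out.any() else out


def center_maps(shape: tuple[int, int]) -> tuple[np.ndarray, np.ndarray]:
    """Frame-independent center-bias maps.

    center_screen: isotropic Gaussian falloff from the frame center, peak 1.
    center_scene:  pixelwise max of two Gaussians, one per lateral half
                   (the split-screen layout gives each scene its own center).
    """
    h, w = shape
    if w % 2 != 0:
        raise ValueError("width must be even")
    yy, xx = np.mgrid[0:h, 0:w].astype(float)
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    sigma_screen = 0.5 * h
    center_screen = np.exp(-((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * sigma_screen**2))
    sigma_scene = 0.35 * h
    left = np.exp(
        -((yy - cy) ** 2 + (xx - (w / 2 - 1) / 2.0) ** 2) / (2 * sigma_scene**2)
    )
    right = np.exp(
        -((yy - cy) ** 2 + (xx - (w / 2 + (w / 2 - 1) / 2.0)) ** 2)
        / (2 * sigma_scene**2)
    )
    # renormalize so the discretized peak is exactly 1
    center_scene = np.maximum(left, right)
    return center_screen / center_screen.max(), center_scene / center_scene.max()


def _horizon_line(shape: tuple[int, int], row_frac: float = 0.5) -> np.ndarray:
    h, w = shape
    yy = np.arange(h, dtype=float)[:, None]
    band = np.exp(-((yy - row_frac * (h - 1)) ** 2) / (2 * (0.08 * h) ** 2))
    return np.broadcast_to(band, (h, w)).copy()


def _group_mask(stimulus: Stimulus, group: FrameGroup, name: str) -> np.ndarray:
    """Mean of the per-frame masks over the group's members (soft in [0,1])."""
    return stimulus.masks[name][group.frame_ids.start : group.frame_ids.stop].mean(axis=0)


def _soft(mask: np.ndarray, sigma: float) -> np.ndarray:
    out = gaussian_filter(mask.astype(float), sigma)
    return _max_normalize(out)


def movement_scale(stimulus: Stimulus) -> float:
    """Stimulus-global rescaling constant for the movement channel.

    The maximum per-pixel absolute temporal difference across all
    consecutive frame pairs; one constant per stimulus keeps movement
    comparable across frame groups.
    """
    if stimulus.n_frames < 2:
        return 1.0
    gray = stimulus.frames.mean(axis=3)
    peak = float(np.abs(np.diff(gray, axis=0)).max())
    return peak if peak > 0 else 1.0


def _movement_channel(stimulus: Stimulus, group: FrameGroup, scale: float) -> np.ndarray:
    gray = stimulus.frames[group.frame_ids.start : group.frame_ids.stop].mean(axis=3)
    if gray.shape[0] < 2:
        return np.zeros(gray.shape[1:])
    move = np.abs(np.diff(gray, axis=0)).mean(axis=0) / scale
    return np.clip(move, 0.0, 1.0)


def extract_features(
    frame_group: FrameGroup,
    stimulus: Stimulus,
    masks_mode: str = "ground_truth",
    movement_scale_value: float | None = None,
    mask_sigma_frac: float = 0.02,
) -> FeatureStack:
    """Compute the full 28-channel stack for a frame group's representative frame."""
    if masks_mode not in ("ground_truth", "detector"):
        raise ValueError(f"masks_mode must be 'ground_truth' or 'detector', got {masks_mode!r}")
    frame = frame_group.representative_frame
    h, w = frame.shape[:2]
    sigma = mask_sigma_frac * w
    gray = frame.mean(axis=2)

    if masks_mode == "ground_truth":
        required = {"face", "people", "skin", "social_half", "geometric_half"}
        missing = required - set(stimulus.masks)
        if missing:
            raise ValueError(f"ground_truth mode requires masks: {sorted(missing)}")
        skin = _soft(_group_mask(stimulus, frame_group, "skin"), sigma)
        face = _soft(_group_mask(stimulus, frame_group, "face"), sigma)
        people = _soft(_group_mask(stimulus, frame_group, "people"), sigma)
        social = _soft(_group_mask(stimulus, frame_group, "social_half"), sigma)
        geometric = _soft(_group_mask(stimulus, frame_group, "geometric_half"), sigma)
        # keep the two scene channels supported on their own (disjoint) halves
        social[:, w // 2 :] = 0.0
        geometric[:, : w // 2] = 0.0
    else:
        skin_bin = detect_skin(frame)
        skin = _soft(skin_bin, sigma)
        face = _blob_box_map(skin_bin, sigma)
        people = _blob_box_map(skin_bin, sigma, expand=2.5)
        half = np.zeros((h, w))
        half[:, : w // 2] = 1.0
        social = _soft(half, sigma)
        geometric = _soft(1.0 - half, sigma)

    color, inten, orient = itti_channels(frame)
    center_screen, center_scene = center_maps((h, w))
    scale = movement_scale_value if movement_scale_value is not None else movement_scale(stimulus)

    channels = steerable_pyramid_channels(gray)
    channels += [
        color,
        inten,
        orient,
        skin,
        frame[:, :, 0],
        frame[:, :, 1],
        frame[:, :, 2],
        _horizon_line((h, w)),
        face,
        people,
        center_screen,
        _movement_channel(stimulus, frame_group, scale),
        social,
        geometric,
        center_scene,
    ]
    stack = np.stack(channels, axis=2).astype(np.float32)
    assert stack.shape == (h, w, N_FEATURES)
    return FeatureStack(group_index=frame_group.index, stack=stack)
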