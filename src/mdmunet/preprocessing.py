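"""CT preprocessing and training-time augmentation.

The training pipeline is: resample every case to a common voxel spacing,
linearly remap the CT intensity window to [0, 1], crop to the nonzero
foreground bounding box, then repeatedly draw class-balanced patches and
augment them. Validation and test cases get only the first three steps.

Augmentation applies, to every training patch, a rotation about the
depth (Z) axis with angle drawn uniformly from [0, pi/30] rad and a uniform
scaling with one factor drawn from [1 - max_scale_frac, 1 + max_scale_frac],
and — with probability ``shift_prob`` — adds a single scalar intensity offset
drawn uniformly from [-shift_range, +shift_range] to the image. Labels are
always resampled with nearest-neighbor interpolation, so the label alphabet
is preserved.

Axis convention: arrays are (D, H, W); the rotation axis is D; coordinates
are 0-based voxel indices.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace as dc_replace

import numpy as np
from scipy import ndimage

from .data import LabeledCase

__all__ = [
    "PreprocessConfig",
    "MSDPT_PRESET",
    "NIHP_PRESET",
    "resample_to_spacing",
    "remap_intensity",
    "foreground_crop",
    "preprocess_case",
    "sample_patch",
    "sample_balanced_patches",
    "augment",
]


@dataclass(frozen=True)
class PreprocessConfig:
    target_spacing: tuple[float, float, float] = (1.2, 1.2, 2.0)
    intensity_window: tuple[float, float] = (-145.0, 275.0)
    patch_size: tuple[int, int, int] = (96, 96, 96)
    pos_neg_ratio: float = 1.0
    shift_prob: float = 0.5
    shift_range: float = 0.1
    max_rotation_rad: float = math.pi / 30
    max_scale_frac: float = 0.10
    crop_margin: int = 0

    def __post_init__(self):
        lo, hi = self.intensity_window
        if not lo < hi:
            raise ValueError(f"intensity_window must be increasing, got {self.intensity_window}")
        if any(s <= 0 for s in self.target_spacing):
            raise ValueError("target_spacing must be positive")
        if any(p % 16 for p in self.patch_size):
            raise ValueError(
                f"patch_size {self.patch_size} must be divisible by 16 (network contract)"
            )
        if self.pos_neg_ratio <= 0:
            raise ValueError("pos_neg_ratio must be positive")
        if not 0.0 <= self.shift_prob <= 1.0:
            raise ValueError("shift_prob must lie in [0, 1]")


MSDPT_PRESET = PreprocessConfig(target_spacing=(1.2, 1.2, 2.0))
NIHP_PRESET = PreprocessConfig(target_spacing=(0.93, 0.93, 1.0))


def resample_to_spacing(case: LabeledCase, target_spacing) -> LabeledCase:
    """Trilinear image / nearest-neighbor label resampling to a new voxel grid.

    New extents are round(old_extent * old_spacing / new_spacing).
    """
    target_spacing = tuple(float(s) for s in target_spacing)
    if any(s <= 0 for s in target_spacing):
        raise ValueError("target spacing must be positive")
    old_shape = np.array(case.shape, dtype=float)
    new_shape = np.round(old_shape * np.array(case.spacing) / np.array(target_spacing))
    if np.any(new_shape < 1):
        raise ValueError(
            f"resampling {case.shape} from {case.spacing} to {target_spacing} "
            "would produce a zero-extent volume"
        )
    if np.array_equal(new_shape, old_shape):
        return LabeledCase(case.image.copy(), case.labels.copy(), target_spacing)
    zoom = new_shape / old_shape
    image = ndimage.zoom(case.image.astype(np.float32), zoom, order=1, mode="nearest")
    labels = ndimage.zoom(case.labels, zoom, order=0, mode="nearest")
    assert image.shape == tuple(int(s) for s in new_shape)
    return LabeledCase(image, labels, target_spacing)


def remap_intensity(image, window) -> np.ndarray:
    """Linear map of ``window`` onto [0, 1], clamped."""
    lo, hi = (float(w) for w in window)
    if not lo < hi:
        raise ValueError(f"invalid intensity window {window}")
    out = (np.asarray(image, dtype=np.float32) - lo) / (hi - lo)
    return np.clip(out, 0.0, 1.0)


def foreground_crop(case: LabeledCase, margin: int = 0) -> LabeledCase:
    """Crop image and labels to the bounding box of voxels with intensity > 0."""
    fg = case.image > 0
    if not fg.any():
        raise ValueError("cannot foreground-crop a volume with no positive intensities")
    slices = []
    for axis in range(3):
        proj = fg.any(axis=tuple(a for a in range(3) if a != axis))
        idx = np.flatnonzero(proj)
        lo = max(0, idx[0] - margin)
        hi = min(case.shape[axis], idx[-1] + 1 + margin)
        slices.append(slice(lo, hi))
    slices = tuple(slices)
    return LabeledCase(case.image[slices].copy(), case.labels[slices].copy(), case.spacing)


def preprocess_case(case: LabeledCase, cfg: PreprocessConfig) -> LabeledCase:
    """The deterministic validation/test path: resample, remap, crop."""
    case = resample_to_spacing(case, cfg.target_spacing)
    case = LabeledCase(remap_intensity(case.image, cfg.intensity_window), case.labels,
                       case.spacing)
    return foreground_crop(case, cfg.crop_margin)


def _pad_to_patch(case: LabeledCase, patch_size) -> LabeledCase:
    pads = []
    for s, p in zip(case.shape, patch_size):
        short = max(0, p - s)
        pads.append((short // 2, short - short // 2))
    if not any(lo or hi for lo, hi in pads):
        return case
    return LabeledCase(
        np.pad(case.image, pads),
        np.pad(case.labels, pads),
        case.spacing,
    )


def sample_patch(
    case: LabeledCase,
    cfg: PreprocessConfig,
    rng: np.random.Generator,
    positive: bool | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw one patch; ``positive`` centers it on a foreground-label voxel.

    ``positive=None`` draws the class with probability ratio/(1+ratio), the
    per-draw form of the balanced sampling used when patches are requested
    one at a time during training.
    """
    patch = tuple(int(p) for p in cfg.patch_size)
    case = _pad_to_patch(case, patch)
    shape = np.array(case.shape)
    if positive is None:
        positive = bool(rng.uniform() < cfg.pos_neg_ratio / (1.0 + cfg.pos_neg_ratio))
    pool = np.argwhere(case.labels > 0 if positive else case.labels == 0)
    if len(pool) == 0:
        pool = np.argwhere(case.labels >= 0)
    center = pool[rng.integers(len(pool))]
    half_lo = np.array([p // 2 for p in patch])
    start = np.clip(center - half_lo, 0, shape - patch)
    sl = tuple(slice(int(s), int(s + p)) for s, p in zip(start, patch))
    return case.image[sl].copy(), case.labels[sl].copy()


def sample_balanced_patches(
    case: LabeledCase,
    n: int,
    cfg: PreprocessConfig,
    rng: np.random.Generator | int,
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Draw ``n`` patches with a fixed positive:negative center ratio.

    A positive patch is centered on a foreground-label voxel, a negative one
    on a background voxel; centers are clamped so patches stay inside the
    (zero-padded if necessary) volume. Deterministic for a given seed.
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    patch = tuple(int(p) for p in cfg.patch_size)
    case = _pad_to_patch(case, patch)
    shape = np.array(case.shape)

    fg = np.argwhere(case.labels > 0)
    bg = np.argwhere(case.labels == 0)
    n_pos = int(round(n * cfg.pos_neg_ratio / (1.0 + cfg.pos_neg_ratio)))
    if fg.size == 0:
        warnings.warn("case has no foreground labels; sampling negatives only", stacklevel=2)
        n_pos = 0

    half_lo = np.array([p // 2 for p in patch])
    out = []
    for i in range(n):
        pool = fg if (i < n_pos and fg.size) else bg
        if len(pool) == 0:
            pool = np.argwhere(case.labels >= 0)
        center = pool[rng.integers(len(pool))]
        start = np.clip(center - half_lo, 0, shape - patch)
        sl = tuple(slice(int(s), int(s + p)) for s, p in zip(start, patch))
        out.append((case.image[sl].copy(), case.labels[sl].copy()))
    return out


def _affine_matrices(angle: float, scale: float, shape) -> tuple[np.ndarray, np.ndarray]:
    """Output->input coordinate map for a rotation about the D axis plus uniform scaling."""
    c, s = math.cos(angle), math.sin(angle)
    # forward rotation in the (H, W) plane; inverse = transpose / scale
    fwd = np.array([[1.0, 0.0, 0.0], [0.0, c, -s], [0.0, s, c]]) * scale
    inv = np.linalg.inv(fwd)
    center = (np.asarray(shape, dtype=float) - 1.0) / 2.0
    offset = center - inv @ center
    return inv, offset


def augment(
    image: np.ndarray,
    labels: np.ndarray,
    cfg: PreprocessConfig,
    rng: np.random.Generator | int,
) -> tuple[np.ndarray, np.ndarray]:
    """Mandatory rotation+scaling, optional global intensity shift (image only)."""
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    angle = float(rng.uniform(0.0, cfg.max_rotation_rad))
    scale = float(rng.uniform(1.0 - cfg.max_scale_frac, 1.0 + cfg.max_scale_frac))
    matrix, offset = _affine_matrices(angle, scale, image.shape)
    image_out = ndimage.affine_transform(
        image.astype(np.float32), matrix, offset=offset, order=1, mode="nearest"
    )
    labels_out = ndimage.affine_transform(labels, matrix, offset=offset, order=0, mode="nearest")
    if rng.uniform() < cfg.shift_prob:
        image_out = image_out + float(rng.uniform(-cfg.shift_range, cfg.shift_range))
    return image_out, labels_out
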