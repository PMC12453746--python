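"""Synthetic pancreas/tumor phantoms for download-free end-to-end testing.

A phantom emulates the statistical structure the segmentation task targets:
a small elongated organ (rotated ellipsoid) of low contrast against the
background, with one or more small spherical lesions of even lower contrast
embedded strictly inside it, Gaussian boundary blurring and additive noise.
It does not attempt anatomical realism — no surrounding organs, no CT
texture, no acquisition artifacts — so results on phantoms demonstrate that
the pipeline is wired correctly and can learn low-contrast shapes, not
clinical performance.

Intensities are on the [0, 1] scale of the preprocessed CT pipeline. The
default contrasts are organ-vs-background 0.3 and tumor-vs-organ 0.1, small
enough to make segmentation nontrivial at desk scale while remaining
learnable.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
from scipy import ndimage

from .data import LabeledCase, write_case

__all__ = ["PhantomSpec", "generate_phantom", "generate_dataset"]

_SEED_MOD = 2**31 - 1


@dataclass(frozen=True)
class PhantomSpec:
    shape: tuple[int, int, int] = (96, 96, 96)
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    # ellipsoid semi-axes in voxels; None scales the 96^3 default
    # (13, 30, 15) — a small organ elongated in-plane — with the volume shape
    organ_axes: tuple[float, float, float] | None = None
    organ_center: tuple[float, float, float] | None = None  # None -> volume center
    organ_angle: float = 0.0  # rotation about the D axis, radians
    organ_intensity: float = 0.55
    background_intensity: float = 0.25
    tumor_count_range: tuple[int, int] = (1, 3)
    tumor_radius_range: tuple[float, float] = (3.0, 6.0)
    tumor_intensity: float = 0.65
    noise_sigma: float = 0.05
    smoothing_sigma: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.organ_axes is None:
            base = (13.0 / 96.0, 30.0 / 96.0, 15.0 / 96.0)
            object.__setattr__(
                self, "organ_axes", tuple(f * s for f, s in zip(base, self.shape))
            )
        for v in (self.organ_intensity, self.background_intensity, self.tumor_intensity):
            if not 0.0 <= v <= 1.0:
                raise ValueError("intensities must lie in [0, 1]")
        if self.noise_sigma < 0 or self.smoothing_sigma < 0:
            raise ValueError("noise_sigma and smoothing_sigma must be nonnegative")
        lo, hi = self.tumor_count_range
        if lo < 0 or hi < lo:
            raise ValueError(f"invalid tumor_count_range {self.tumor_count_range}")
        center = self.center
        for c, a, s in zip(center, self.organ_axes, self.shape):
            if a <= 0:
                raise ValueError("organ semi-axes must be positive")
            if c - a < 0 or c + a > s - 1:
                raise ValueError(
                    f"organ (center {center}, semi-axes {self.organ_axes}) does not fit "
                    f"inside volume shape {self.shape}"
                )

    @property
    def center(self) -> tuple[float, float, float]:
        if self.organ_center is not None:
            return self.organ_center
        return tuple((s - 1) / 2.0 for s in self.shape)


def _organ_mask(spec: PhantomSpec) -> np.ndarray:
    d, h, w = np.meshgrid(*(np.arange(s, dtype=float) for s in spec.shape), indexing="ij")
    cd, ch, cw = spec.center
    # rotate the (H, W) plane by -angle into the ellipsoid's own frame
    c, s = math.cos(spec.organ_angle), math.sin(spec.organ_angle)
    hr = c * (h - ch) + s * (w - cw)
    wr = -s * (h - ch) + c * (w - cw)
    ad, ah, aw = spec.organ_axes
    return ((d - cd) / ad) ** 2 + (hr / ah) ** 2 + (wr / aw) ** 2 <= 1.0


def generate_phantom(spec: PhantomSpec) -> LabeledCase:
    """Deterministic phantom: labels 0/1/2 = background/organ/tumor."""
    rng = np.random.default_rng(spec.seed)
    organ = _organ_mask(spec)
    labels = organ.astype(np.int64)

    # sample tumor centers deep enough inside the organ that the whole
    # sphere stays within the organ mask
    depth = ndimage.distance_transform_edt(organ)
    n_tumors = int(rng.integers(spec.tumor_count_range[0], spec.tumor_count_range[1] + 1))
    for _ in range(n_tumors):
        radius = float(rng.uniform(*spec.tumor_radius_range))
        candidates = np.argwhere(depth > radius + 1.0)
        if len(candidates) == 0:
            continue
        cd, ch, cw = candidates[rng.integers(len(candidates))]
        d, h, w = np.ogrid[: spec.shape[0], : spec.shape[1], : spec.shape[2]]
        sphere = (d - cd) ** 2 + (h - ch) ** 2 + (w - cw) ** 2 <= radius**2
        labels[sphere] = 2

    image = np.full(spec.shape, spec.background_intensity, dtype=np.float32)
    image[labels == 1] = spec.organ_intensity
    image[labels == 2] = spec.tumor_intensity
    if spec.smoothing_sigma > 0:
        image = ndimage.gaussian_filter(image, spec.smoothing_sigma)
    if spec.noise_sigma > 0:
        image = image + rng.normal(0.0, spec.noise_sigma, size=spec.shape).astype(np.float32)
    image = np.clip(image, 0.0, 1.0).astype(np.float32)
    return LabeledCase(image=image, labels=labels, spacing=spec.spacing)


def _jitter(spec: PhantomSpec, rng: np.random.Generator, seed: int) -> PhantomSpec:
    axes = tuple(a * rng.uniform(0.8, 1.2) for a in spec.organ_axes)
    angle = float(rng.uniform(-math.pi / 4, math.pi / 4))
    center = tuple(
        min(max(c + rng.uniform(-0.05, 0.05) * s, a + 1), s - a - 2)
        for c, s, a in zip(spec.center, spec.shape, axes)
    )
    return replace(spec, organ_axes=axes, organ_angle=angle, organ_center=center, seed=seed)


def generate_dataset(n: int, spec: PhantomSpec, out_dir) -> Path:
    """Write ``n`` jittered phantoms as NIfTI pairs plus a JSON manifest.

    Fully determined by ``spec.seed``; returns the manifest path.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    master = np.random.default_rng(spec.seed)
    cases = []
    for i in range(n):
        case_seed = int(master.integers(_SEED_MOD))
        case_spec = _jitter(spec, np.random.default_rng(case_seed), case_seed)
        case = generate_phantom(case_spec)
        image_path = out_dir / f"case_{i:03d}_image.nii.gz"
        label_path = out_dir / f"case_{i:03d}_label.nii.gz"
        write_case(case, image_path, label_path)
        cases.append({"image": image_path.name, "label": label_path.name, "seed": case_seed})
    manifest = out_dir / "manifest.json"
    with open(manifest, "w") as fh:
        json.dump({"cases": cases}, fh, indent=2)
    return manifest
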