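"""The labeled-case container and NIfTI round-trip helpers.

A :class:`LabeledCase` bundles what every pipeline stage consumes: an
intensity volume, an integer label map of identical extents and the voxel
spacing in millimetres along (depth, height, width). Label values are
0 = background, 1 = organ (pancreas), 2 = lesion (tumor).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np


@dataclass
class LabeledCase:
    image: np.ndarray  # rank-3 float volume (D, H, W), normalized units
    labels: np.ndarray  # rank-3 integer volume, values in {0..num_classes-1}
    spacing: tuple[float, float, float]  # mm per voxel along (D, H, W)

    def __post_init__(self):
        self.image = np.asarray(self.image)
        self.labels = np.asarray(self.labels)
        if self.image.ndim != 3 or self.labels.ndim != 3:
            raise ValueError("image and labels must be rank-3 volumes")
        if self.image.shape != self.labels.shape:
            raise ValueError(
                f"image {self.image.shape} and labels {self.labels.shape} extents differ"
            )
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be three positive reals, got {self.spacing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.image.shape


def _affine_from_spacing(spacing) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = spacing
    return aff


def write_nifti(volume: np.ndarray, spacing, path) -> Path:
    """Write a volume with a diagonal affine carrying the voxel spacing."""
    path = Path(path)
    dtype = np.uint8 if np.issubdtype(volume.dtype, np.integer) else np.float32
    img = nib.Nifti1Image(np.asarray(volume, dtype=dtype), _affine_from_spacing(spacing))
    img.header.set_zooms(tuple(float(s) for s in spacing))
    nib.save(img, path)
    return path


def read_nifti(path) -> tuple[np.ndarray, tuple[float, float, float]]:
    """Read a volume and its voxel spacing (the first three header zooms)."""
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return data, spacing


def write_case(case: LabeledCase, image_path, label_path) -> tuple[Path, Path]:
    return (
        write_nifti(case.image.astype(np.float32), case.spacing, image_path),
        write_nifti(case.labels.astype(np.uint8), case.spacing, label_path),
    )


def read_case(image_path, label_path) -> LabeledCase:
    image, spacing = read_nifti(image_path)
    labels, lbl_spacing = read_nifti(label_path)
    if not np.allclose(spacing, lbl_spacing, rtol=1e-5):
        raise ValueError(f"image spacing {spacing} differs from label spacing {lbl_spacing}")
    return LabeledCase(image=image.astype(np.float32), labels=labels.astype(np.int64),
                       spacing=spacing)


def load_manifest(path) -> list[dict]:
    """A dataset manifest is a JSON object {"cases": [{"image", "label", ...}]}."""
    path = Path(path)
    with open(path) as fh:
        payload = json.load(fh)
    cases = payload["cases"] if isinstance(payload, dict) else payload
    out = []
    for entry in cases:
        entry = dict(entry)
        for key in ("image", "label"):
            if key not in entry:
                raise ValueError(f"manifest entry missing {key!r}: {entry}")
            p = Path(entry[key])
            entry[key] = str(p if p.is_absolute() else path.parent / p)
        out.append(entry)
    return out
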