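"""NIfTI read/write helpers (volumes, masks, habitat maps, composites)."""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np


def _affine(spacing_mm) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = spacing_mm
    return aff


def save_volume(path, data: np.ndarray, spacing_mm=(1.0, 1.0, 2.5)) -> None:
    """Write a 3D (or 4D composite) array as NIfTI with a diagonal affine."""
    data = np.asarray(data)
    if data.dtype == bool:
        data = data.astype(np.uint8)
    nib.save(nib.Nifti1Image(data, _affine(spacing_mm)), str(path))


def load_volume(path) -> tuple[np.ndarray, tuple[float, float, float]]:
    img = nib.load(str(path))
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return np.asarray(img.dataobj), spacing


def save_mask(path, mask: np.ndarray, spacing_mm=(1.0, 1.0, 2.5)) -> None:
    save_volume(path, np.asarray(mask, dtype=np.uint8), spacing_mm)


def load_mask(path) -> np.ndarray:
    data, _ = load_volume(path)
    return data.astype(bool)


def save_labels(path, labels: np.ndarray, spacing_mm=(1.0, 1.0, 2.5)) -> None:
    save_volume(path, np.asarray(labels, dtype=np.int16), spacing_mm)


def load_labels(path) -> np.ndarray:
    data, _ = load_volume(path)
    return data.astype(np.int32)


def ensure_dir(path) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
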