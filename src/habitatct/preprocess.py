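"""From raw HU volume + lung mask to the 4-channel composite image.

The composite stacks four co-registered channels, all scaled to [0, 1]:

1. lung-window normalized intensity (clip-and-rescale, default
   center -600 / width 1500 HU),
2. mediastinal-window normalized intensity (default center 40 / width
   400 HU),
3. local entropy of the lung-window channel,
4. local entropy of the mediastinal-window channel.

Windowing is the contrast-enhancing step: a monotone clip-and-rescale of
HU into [0, 1].  The entropy channels capture local texture: per axial
slice, the Shannon entropy (bits) of the 32-bin intensity histogram in a
disk neighborhood, rescaled by log2(n_bins).  Entropy runs in 2D because
2.5 mm slices are much thicker than the in-plane spacing, so 3D
neighborhoods would mix anatomy across slices.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.filters.rank import entropy as _rank_entropy
from skimage.morphology import ball, disk

__all__ = [
    "WindowSpec",
    "LUNG_WINDOW",
    "MEDIASTINUM_WINDOW",
    "CHANNEL_NAMES",
    "apply_window",
    "local_entropy",
    "fuse_channels",
    "make_composite",
    "smooth_mask",
    "split_lungs",
]


@dataclass(frozen=True)
class WindowSpec:
    center: float
    width: float

    def __post_init__(self) -> None:
        if not self.width > 0:
            raise ValueError("window width must be > 0")


LUNG_WINDOW = WindowSpec(center=-600.0, width=1500.0)
MEDIASTINUM_WINDOW = WindowSpec(center=40.0, width=400.0)

CHANNEL_NAMES = ("lung", "mediastinum", "lung_entropy", "mediastinum_entropy")

DEFAULT_ENTROPY_RADIUS = 4
DEFAULT_ENTROPY_BINS = 32


def apply_window(volume: np.ndarray, window: WindowSpec) -> np.ndarray:
    """Clip-and-rescale HU into [0, 1]: ``clip((HU - (c - w/2)) / w, 0, 1)``."""
    volume = np.asarray(volume, dtype=float)
    if not np.isfinite(volume).all():
        raise ValueError("volume contains non-finite HU values")
    lo = window.center - window.width / 2.0
    return np.clip((volume - lo) / window.width, 0.0, 1.0)


def local_entropy(
    image: np.ndarray,
    radius: int = DEFAULT_ENTROPY_RADIUS,
    n_bins: int = DEFAULT_ENTROPY_BINS,
    footprint: np.ndarray | None = None,
    mask: np.ndarray | None = None,
) -> np.ndarray:
    """Slice-wise local Shannon entropy (bits) of the binned intensity histogram.

    ``image`` must already be normalized to [0, 1]; values are quantized
    into ``n_bins`` equal bins and the entropy of the histogram inside a
    disk of ``radius`` (or an explicit 2D ``footprint``) is computed per
    axial slice (last axis).  Range: [0, log2(n_bins)].

    When ``mask`` is given, voxels outside it are excluded from every
    neighborhood histogram, so entropy near the lung boundary reflects
    lung texture only and is not inflated by the sharp lung/soft-tissue
    edge.
    """
    image = np.asarray(image, dtype=float)
    if image.min() < 0 or image.max() > 1:
        raise ValueError("image must be normalized to [0, 1] before entropy filtering")
    if radius < 1:
        raise ValueError("radius must be >= 1")
    if footprint is None:
        footprint = disk(radius)
    squeeze = False
    if image.ndim == 2:
        image = image[..., None]
        if mask is not None:
            mask = np.asarray(mask, dtype=bool)[..., None]
        squeeze = True
    elif mask is not None:
        mask = np.asarray(mask, dtype=bool)
    if any(f > s for f, s in zip(footprint.shape, image.shape[:2])):
        raise ValueError("entropy neighborhood larger than the slice")
    binned = np.minimum((image * n_bins).astype(np.uint8), n_bins - 1)
    out = np.empty(image.shape, dtype=float)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # rank filters warn on low bit-depth
        for z in range(image.shape[2]):
            m = None if mask is None else mask[:, :, z].astype(np.uint8)
            out[:, :, z] = _rank_entropy(binned[:, :, z], footprint, mask=m)
    return out[..., 0] if squeeze else out


def fuse_channels(
    lung_img: np.ndarray,
    med_img: np.ndarray,
    lung_ent: np.ndarray,
    med_ent: np.ndarray,
    n_bins: int = DEFAULT_ENTROPY_BINS,
) -> np.ndarray:
    """Stack the four channels into a composite ``(x, y, z, 4)`` array.

    Entropy channels are rescaled to [0, 1] by dividing by log2(n_bins).
    Channels remain distinct (stacking, not blending) because superpixel
    statistics are later computed separately per channel; order follows
    :data:`CHANNEL_NAMES`.
    """
    arrs = [np.asarray(a, dtype=float) for a in (lung_img, med_img, lung_ent, med_ent)]
    if len({a.shape for a in arrs}) != 1:
        raise ValueError("all four channels must share a shape")
    scale = np.log2(n_bins)
    composite = np.stack(
        [arrs[0], arrs[1], np.clip(arrs[2] / scale, 0, 1), np.clip(arrs[3] / scale, 0, 1)],
        axis=-1,
    )
    return composite


def make_composite(
    volume: np.ndarray,
    mask: np.ndarray | None = None,
    lung_window: WindowSpec = LUNG_WINDOW,
    mediastinum_window: WindowSpec = MEDIASTINUM_WINDOW,
    entropy_radius: int = DEFAULT_ENTROPY_RADIUS,
    entropy_bins: int = DEFAULT_ENTROPY_BINS,
) -> np.ndarray:
    """Window, entropy-filter, and fuse a HU volume into the 4-channel composite.

    Pass the lung ``mask`` so the entropy channels measure intra-lung
    texture only (recommended for any downstream habitat analysis).
    """
    lung_img = apply_window(volume, lung_window)
    med_img = apply_window(volume, mediastinum_window)
    lung_ent = local_entropy(lung_img, entropy_radius, entropy_bins, mask=mask)
    med_ent = local_entropy(med_img, entropy_radius, entropy_bins, mask=mask)
    return fuse_channels(lung_img, med_img, lung_ent, med_ent, entropy_bins)


def smooth_mask(mask: np.ndarray, radius: int = 1) -> np.ndarray:
    """Morphological closing (dilate then erode with the same ball element)."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        return mask.copy()
    return ndimage.binary_closing(mask, structure=ball(radius))


def split_lungs(mask: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Split a lung mask into (left, right) by connected components.

    "Left" is the component with the smaller centroid along axis 0 (the
    image-left side; phantoms carry no patient orientation metadata).
    Components beyond the two largest are dropped with a warning; a single
    fused component falls back to a midline split at the x-centroid.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask")
    labels, n = ndimage.label(mask)
    if n >= 2:
        sizes = ndimage.sum_labels(mask, labels, index=np.arange(1, n + 1))
        order = np.argsort(sizes)[::-1] + 1
        if n > 2:
            warnings.warn(
                f"mask has {n} connected components; keeping the 2 largest "
                f"({int(sizes.max())} and {int(np.sort(sizes)[-2])} voxels)",
                stacklevel=2,
            )
        a = labels == order[0]
        b = labels == order[1]
        ca = ndimage.center_of_mass(a)[0]
        cb = ndimage.center_of_mass(b)[0]
        left, right = (a, b) if ca <= cb else (b, a)
        return left, right
    warnings.warn("single fused lung component; splitting at the x-centroid midline", stacklevel=2)
    cx = ndimage.center_of_mass(mask)[0]
    xs = np.arange(mask.shape[0])[:, None, None]
    left = mask & (xs < cx)
    right = mask & ~(xs < cx)
    if not left.any() or not right.any():
        raise ValueError("midline split produced an empty side")
    return left, right
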