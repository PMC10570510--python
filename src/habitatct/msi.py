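"""Multiregional spatial interaction (MSI) features of a habitat map.

The canonical bank for K=5 habitats (SR1..SR5) has 88 named values:

- MSI1-4    : co-occurrence (GLCM) second-order statistics — contrast,
              correlation, homogeneity, energy — computed on the habitat
              labels themselves;
- MSI5-9    : absolute subregion volumes (voxel counts), SR1..SR5;
- MSI10-14  : absolute subregion-to-border interactions (exposed faces of
              each subregion on the lung-mask boundary);
- MSI15-24  : absolute pairwise subregion interactions (face-adjacent
              voxel pairs), the 10 unordered pairs in order
              (1,2)..(1,5), (2,3)..(2,5), (3,4), (3,5), (4,5);
- MSI25-29  : subregion volume percentages (sum to 1);
- MSI30-34  : normalized border interactions (share of boundary faces);
- MSI35-44  : normalized pairwise interactions (share of all adjacent
              in-mask voxel pairs);
- MSI45-88  : the left/right symmetric-difference counterparts of
              MSI1-44, elementwise |MSI_L - MSI_W| * |MSI_R - MSI_W|.

"Interaction" is face adjacency (6-connectivity in 3D).  The GLCM uses
the four in-plane unit offsets at distance 1 (0, 45, 90, 135 degrees),
symmetrized and normalized, because slice spacing is much larger than the
in-plane spacing.  A whole-lung classical-radiomics comparator (the same
first-order bank on all four composite channels plus GLCM statistics on
the 32-level-quantized lung-window channel) is provided for benchmarking;
it is deliberately blind to the spatial arrangement the MSI bank captures.
"""

from __future__ import annotations

import json

import numpy as np
import pandas as pd

from .habitat import STAT_NAMES, stat_bank
from .preprocess import CHANNEL_NAMES

__all__ = [
    "N_HABITATS",
    "HABITAT_PAIRS",
    "glcm_stats",
    "region_volumes",
    "interaction_counts",
    "msi_whole",
    "symmetric_difference",
    "full_msi",
    "msi_feature_names",
    "feature_dictionary",
    "whole_lung_radiomics",
    "radiomics_feature_names",
]

N_HABITATS = 5


def habitat_pairs(K: int = N_HABITATS) -> list[tuple[int, int]]:
    """Unordered habitat pairs in canonical bank order: (1,2)..(1,K), (2,3).."""
    return [(i, j) for i in range(1, K + 1) for j in range(i + 1, K + 1)]


#: the canonical 10 pairs for K=5
HABITAT_PAIRS = habitat_pairs(N_HABITATS)

#: in-plane GLCM offsets at distance 1 (axes 0/1 are in-plane)
GLCM_OFFSETS = ((1, 0, 0), (0, 1, 0), (1, 1, 0), (1, -1, 0))

#: face-adjacency offsets (6-connectivity; one per axis, symmetric pairs implied)
FACE_OFFSETS = ((1, 0, 0), (0, 1, 0), (0, 0, 1))


def _shifted_views(arr: np.ndarray, off: tuple[int, int, int]):
    """Aligned (a, b) views such that b is a's neighbor at offset ``off``."""
    sl_a, sl_b = [], []
    for o in off:
        if o >= 0:
            sl_a.append(slice(None, arr.shape[len(sl_a)] - o if o else None))
            sl_b.append(slice(o, None))
        else:
            sl_a.append(slice(-o, None))
            sl_b.append(slice(None, o))
    return arr[tuple(sl_a)], arr[tuple(sl_b)]


def glcm_stats(
    labels: np.ndarray,
    mask: np.ndarray | None = None,
    offsets: tuple = GLCM_OFFSETS,
) -> tuple[float, float, float, float]:
    """(contrast, correlation, homogeneity, energy) of the label co-occurrence matrix.

    Pairs are counted over ``offsets``, symmetrized, and restricted to
    voxels with label > 0 inside ``mask``.  Standard Haralick formulas on
    the normalized matrix; a constant map has contrast 0, homogeneity 1,
    energy 1, and correlation defined as 0 (zero-variance policy).
    """
    labels = np.asarray(labels)
    valid = labels > 0 if mask is None else (np.asarray(mask, dtype=bool) & (labels > 0))
    if not valid.any():
        raise ValueError("empty mask")
    levels = int(labels[valid].max())
    counts = np.zeros((levels + 1, levels + 1), dtype=np.int64)
    lab = np.where(valid, labels, 0)
    for off in offsets:
        a, b = _shifted_views(lab, off)
        ok = (a > 0) & (b > 0)
        np.add.at(counts, (a[ok], b[ok]), 1)
    counts = counts + counts.T  # symmetrize
    total = counts.sum()
    if total == 0:  # single isolated voxel: no co-occurrences
        return 0.0, 0.0, 1.0, 1.0
    p = counts / total
    i = np.arange(levels + 1, dtype=float)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    contrast = float((p * (ii - jj) ** 2).sum())
    homogeneity = float((p / (1.0 + (ii - jj) ** 2)).sum())
    energy = float((p * p).sum())
    mu_i = float((p * ii).sum())
    mu_j = float((p * jj).sum())
    var_i = float((p * (ii - mu_i) ** 2).sum())
    var_j = float((p * (jj - mu_j) ** 2).sum())
    if var_i <= 0 or var_j <= 0:
        correlation = 0.0
    else:
        correlation = float((p * (ii - mu_i) * (jj - mu_j)).sum() / np.sqrt(var_i * var_j))
    return contrast, correlation, homogeneity, energy


def region_volumes(labels: np.ndarray, K: int = N_HABITATS) -> tuple[np.ndarray, np.ndarray]:
    """Absolute voxel counts and fractional volumes of SR1..SRK."""
    labels = np.asarray(labels)
    if labels.max() > K:
        raise ValueError(f"labels exceed K={K}")
    counts = np.bincount(labels.ravel(), minlength=K + 1)[1:].astype(float)
    total = counts.sum()
    pct = counts / total if total > 0 else np.zeros(K)
    return counts, pct


def interaction_counts(
    labels: np.ndarray, mask: np.ndarray, K: int = N_HABITATS
) -> dict[str, np.ndarray]:
    """Face-adjacency interaction counts (6-connectivity, 3D).

    - ``pair_abs[p]``: adjacent in-mask voxel pairs with one voxel in SRi
      and the other in SRj, for each unordered pair p=(i, j);
    - ``border_abs[c]``: faces of SRc voxels exposed to non-mask voxels
      (including the grid boundary);
    - normalized variants divide by the total adjacency events of the
      family (all in-mask adjacent pairs; all mask-boundary faces).
    """
    labels = np.asarray(labels)
    mask = np.asarray(mask, dtype=bool)
    if labels.shape != mask.shape:
        raise ValueError("shape mismatch")
    if labels.max() > K:
        raise ValueError(f"labels exceed K={K}")
    pair_mat = np.zeros((K + 1, K + 1), dtype=np.int64)
    border = np.zeros(K + 1, dtype=np.int64)
    for off in FACE_OFFSETS:
        la, lb = _shifted_views(labels, off)
        ma, mb = _shifted_views(mask, off)
        both = ma & mb
        np.add.at(pair_mat, (la[both], lb[both]), 1)
        # exposed faces in both directions along this axis
        border += np.bincount(la[ma & ~mb], minlength=K + 1)
        border += np.bincount(lb[mb & ~ma], minlength=K + 1)
    # grid-boundary faces also count as border exposure
    for axis in range(3):
        for sl in (0, -1):
            face = np.take(labels, sl, axis=axis)
            fmask = np.take(mask, sl, axis=axis)
            border += np.bincount(face[fmask], minlength=K + 1)
    pair_mat = pair_mat + pair_mat.T
    total_pairs = pair_mat.sum() // 2
    pair_abs = np.array([pair_mat[i, j] for i, j in habitat_pairs(K)], dtype=float)
    border_abs = border[1:].astype(float)
    total_border = border_abs.sum()
    return {
        "pair_abs": pair_abs,
        "border_abs": border_abs,
        "pair_norm": pair_abs / total_pairs if total_pairs > 0 else np.zeros_like(pair_abs),
        "border_norm": border_abs / total_border if total_border > 0 else np.zeros_like(border_abs),
        "total_pairs": float(total_pairs),
        "total_border": float(total_border),
    }


def msi_whole(labels: np.ndarray, mask: np.ndarray, K: int = N_HABITATS) -> np.ndarray:
    """The 44-value MSI block on one mask: GLCM(4) + volumes + interactions."""
    contrast, correlation, homogeneity, energy = glcm_stats(labels, mask)
    vol_abs, vol_pct = region_volumes(np.where(mask, labels, 0), K)
    inter = interaction_counts(np.where(mask, labels, 0), mask, K)
    return np.concatenate(
        [
            [contrast, correlation, homogeneity, energy],
            vol_abs,
            inter["border_abs"],
            inter["pair_abs"],
            vol_pct,
            inter["border_norm"],
            inter["pair_norm"],
        ]
    )


def symmetric_difference(
    msi_left: np.ndarray, msi_right: np.ndarray, msi_whole_: np.ndarray
) -> np.ndarray:
    """Elementwise left/right asymmetry: ``|L - W| * |R - W|``."""
    l, r, w = (np.asarray(a, dtype=float) for a in (msi_left, msi_right, msi_whole_))
    if not (l.shape == r.shape == w.shape):
        raise ValueError("blocks must have equal length")
    return np.abs(l - w) * np.abs(r - w)


def msi_feature_names(K: int = N_HABITATS) -> list[str]:
    n_pairs = K * (K - 1) // 2
    n_block = 4 + K + K + n_pairs + K + K + n_pairs  # 44 for K=5
    return [f"MSI{i}" for i in range(1, 2 * n_block + 1)]


def full_msi(
    labels: np.ndarray,
    left_mask: np.ndarray,
    right_mask: np.ndarray,
    K: int = N_HABITATS,
) -> pd.Series:
    """The full 88-feature MSI vector (MSI1..MSI88) of one habitat map.

    MSI1-44 are computed on the whole mask; MSI45-88 apply the symmetric
    difference to blocks computed on the left, right, and whole masks
    (three distinct computations — the whole-mask block is not the sum of
    the sides).
    """
    left_mask = np.asarray(left_mask, dtype=bool)
    right_mask = np.asarray(right_mask, dtype=bool)
    if (left_mask & right_mask).any():
        raise ValueError("left and right masks overlap")
    whole = left_mask | right_mask
    w = msi_whole(labels, whole, K)
    l = msi_whole(labels, left_mask, K)
    r = msi_whole(labels, right_mask, K)
    vec = np.concatenate([w, symmetric_difference(l, r, w)])
    return pd.Series(vec, index=msi_feature_names(K))


_BLOCK_DESCRIPTIONS = [
    (range(1, 5), "second-order co-occurrence statistic ({}) of the habitat map",
     ["contrast", "correlation", "homogeneity", "energy"]),
    (range(5, 10), "absolute volume (voxels) of SR{}", None),
    (range(10, 15), "absolute interaction between SR{} and the lung border", None),
    (range(15, 25), "absolute interaction between SR{0} and SR{1}", "pairs"),
    (range(25, 30), "fractional volume of SR{}", None),
    (range(30, 35), "normalized interaction between SR{} and the lung border", None),
    (range(35, 45), "normalized interaction between SR{0} and SR{1}", "pairs"),
]


def feature_dictionary() -> dict[str, str]:
    """Machine-readable mapping MSI name -> plain-language definition."""
    d: dict[str, str] = {}
    for rng_, template, extra in _BLOCK_DESCRIPTIONS:
        for pos, i in enumerate(rng_):
            if extra == "pairs":
                a, b = HABITAT_PAIRS[pos]
                d[f"MSI{i}"] = template.format(a, b)
            elif isinstance(extra, list):
                d[f"MSI{i}"] = template.format(extra[pos])
            else:
                d[f"MSI{i}"] = template.format(pos + 1)
    for i in range(1, 45):
        d[f"MSI{i + 44}"] = (
            "left/right symmetric difference |L-W|*|R-W| of: " + d[f"MSI{i}"]
        )
    return d


def write_feature_dictionary(path) -> None:
    with open(path, "w") as fh:
        json.dump(feature_dictionary(), fh, indent=1)


# --------------------------------------------------------------------------
# whole-lung classical radiomics comparator


def radiomics_feature_names() -> list[str]:
    names = [f"RAD_{ch}_{st}" for ch in CHANNEL_NAMES for st in STAT_NAMES]
    names += [f"RAD_glcm_{s}" for s in ("contrast", "correlation", "homogeneity", "energy")]
    return names


def whole_lung_radiomics(
    composite: np.ndarray, mask: np.ndarray, n_levels: int = 32
) -> pd.Series:
    """First-order statistics per channel + GLCM on the quantized lung channel.

    44 values: the 10-statistic bank on each of the 4 composite channels
    over all mask voxels, plus contrast/correlation/homogeneity/energy of
    the co-occurrence matrix of the ``n_levels``-quantized lung-window
    channel.  Pooling over the whole lung discards spatial arrangement,
    which is exactly the limitation the habitat/MSI bank addresses.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask")
    if composite.shape[:3] != mask.shape:
        raise ValueError("composite and mask are not co-registered")
    vals = composite[mask]  # (n, 4)
    stats = np.concatenate([stat_bank(vals[:, c]) for c in range(vals.shape[1])])
    lung = composite[..., 0]
    quant = np.zeros(mask.shape, dtype=np.int32)
    quant[mask] = np.minimum((lung[mask] * n_levels).astype(np.int32), n_levels - 1) + 1
    glcm = glcm_stats(quant, mask)
    return pd.Series(np.concatenate([stats, glcm]), index=radiomics_feature_names())
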