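import itertools

import numpy as np
import pandas as pd
import pytest

from habitatct.msi import (
    HABITAT_PAIRS,
    feature_dictionary,
    full_msi,
    glcm_stats,
    interaction_counts,
    msi_feature_names,
    msi_whole,
    radiomics_feature_names,
    region_volumes,
    symmetric_difference,
    whole_lung_radiomics,
)

# ---------------------------------------------------------------------------
# independent oracles (pure-python enumeration over voxel pairs)


def brute_interactions(labels, mask, K):
    """Enumerate all 6-connected voxel pairs and boundary faces directly."""
    nx, ny, nz = labels.shape
    pair = {p: 0 for p in itertools.combinations(range(1, K + 1), 2)}
    border = dict.fromkeys(range(1, K + 1), 0)
    total_pairs = 0
    for x in range(nx):
        for y in range(ny):
            for z in range(nz):
                if not mask[x, y, z]:
                    continue
                here = labels[x, y, z]
                for dx, dy, dz in ((1, 0, 0), (0, 1, 0), (0, 0, 1),
                                   (-1, 0, 0), (0, -1, 0), (0, 0, -1)):
                    u, v, w = x + dx, y + dy, z + dz
                    inside = 0 <= u < nx and 0 <= v < ny and 0 <= w < nz
                    if inside and mask[u, v, w]:
                        if dx + dy + dz > 0:  # count each in-mask pair once
                            total_pairs += 1
                            other = labels[u, v, w]
                            if here != other:
                                key = (min(here, other), max(here, other))
                                if key in pair:
                                    pair[key] += 1
                    else:
                        border[here] += 1  # exposed face (grid edge included)
    return pair, border, total_pairs


def brute_glcm(labels, mask, offsets):
    counts = {}
    nx, ny, nz = labels.shape
    for dx, dy, dz in offsets:
        for x in range(nx):
            for y in range(ny):
                for z in range(nz):
                    u, v, w = x + dx, y + dy, z + dz
                    if not (0 <= u < nx and 0 <= v < ny and 0 <= w < nz):
                        continue
                    a, b = labels[x, y, z], labels[u, v, w]
                    if a > 0 and b > 0 and mask[x, y, z] and mask[u, v, w]:
                        counts[(a, b)] = counts.get((a, b), 0) + 1
                        counts[(b, a)] = counts.get((b, a), 0) + 1
    total = sum(counts.values())
    levels = max(k for pair in counts for k in pair)
    p = np.zeros((levels + 1, levels + 1))
    for (a, b), c in counts.items():
        p[a, b] = c / total
    i = np.arange(levels + 1, dtype=float)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    contrast = (p * (ii - jj) ** 2).sum()
    homog = (p / (1 + (ii - jj) ** 2)).sum()
    energy = (p * p).sum()
    mu_i, mu_j = (p * ii).sum(), (p * jj).sum()
    vi = (p * (ii - mu_i) ** 2).sum()
    vj = (p * (jj - mu_j) ** 2).sum()
    corr = 0.0 if vi <= 0 or vj <= 0 else (p * (ii - mu_i) * (jj - mu_j)).sum() / np.sqrt(vi * vj)
    return contrast, corr, homog, energy


class TestGLCM:
    def test_single_label_map(self):
        labels = np.ones((4, 4, 1), dtype=np.int32)
        contrast, corr, homog, energy = glcm_stats(labels)
        assert contrast == 0 and homog == 1 and energy == 1 and corr == 0

    def test_alternating_strip(self):
        # [1,2,1,2] along one axis: every co-occurring pair is (1,2)/(2,1)
        labels = np.array([1, 2, 1, 2], dtype=np.int32).reshape(4, 1, 1)
        contrast, corr, homog, energy = glcm_stats(labels)
        assert contrast == pytest.approx(1.0)
        assert energy == pytest.approx(0.5)
        assert homog == pytest.approx(0.5)
        assert corr == pytest.approx(-1.0)

    def test_checkerboard_exceeds_constant(self):
        cb = (np.indices((6, 6, 1)).sum(axis=0) % 2 + 1).astype(np.int32)
        const = np.ones((6, 6, 1), dtype=np.int32)
        assert glcm_stats(cb)[0] > glcm_stats(const)[0]

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            glcm_stats(np.zeros((3, 3, 1), dtype=np.int32))


class TestRegionVolumes:
    def test_direct_counts_and_percentages(self):
        labels = np.zeros((10, 10, 1), dtype=np.int32)
        labels[:3, :, 0] = 1  # 30 voxels SR1
        labels[3:, :7, 0] = 4  # 49 voxels SR4
        labels[3:, 7:, 0] = 4  # 21 voxels SR4 -> 70 total
        absolute, pct = region_volumes(labels, 5)
        assert absolute.tolist() == [30, 0, 0, 70, 0]
        assert pct.tolist() == [0.3, 0, 0, 0.7, 0]
        assert pct.sum() == pytest.approx(1.0)

    def test_labels_exceeding_k_rejected(self):
        with pytest.raises(ValueError):
            region_volumes(np.full((2, 2, 1), 7, dtype=np.int32), 5)


class TestInteractionCounts:
    def test_small_grid_enumeration(self):
        labels = np.array([[1, 1, 2], [1, 2, 2]], dtype=np.int32).reshape(2, 3, 1)
        mask = np.ones_like(labels, dtype=bool)
        out = interaction_counts(labels, mask, 5)
        assert out["pair_abs"][HABITAT_PAIRS.index((1, 2))] == 3
        assert out["total_pairs"] == 7

    def test_single_region_cube_border_is_surface_faces(self):
        labels = np.zeros((5, 5, 5), dtype=np.int32)
        labels[1:4, 1:4, 1:4] = 1
        mask = labels > 0
        out = interaction_counts(labels, mask, 5)
        assert np.all(out["pair_abs"] == 0)
        assert out["border_abs"][0] == 6 * 9  # 3x3 faces on 6 sides
        assert out["border_norm"][0] == pytest.approx(1.0)

    def test_normalized_pairwise_bounded_by_one(self):
        rng = np.random.default_rng(0)
        labels = rng.integers(1, 6, (6, 6, 3)).astype(np.int32)
        mask = np.ones_like(labels, dtype=bool)
        out = interaction_counts(labels, mask, 5)
        assert 0 <= out["pair_norm"].sum() <= 1


class TestOracleEquivalence:
    @pytest.mark.parametrize("seed", range(8))
    def test_interactions_match_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        shape = tuple(rng.integers(3, 7, 3))
        labels = rng.integers(0, 6, shape).astype(np.int32)
        mask = labels > 0
        if not mask.any():
            return
        out = interaction_counts(labels, mask, 5)
        pair, border, total = brute_interactions(labels, mask, 5)
        for idx, key in enumerate(HABITAT_PAIRS):
            assert out["pair_abs"][idx] == pair[key]
        for c in range(1, 6):
            assert out["border_abs"][c - 1] == border[c]
        assert out["total_pairs"] == total

    @pytest.mark.parametrize("seed", range(4))
    def test_glcm_matches_brute_force(self, seed):
        rng = np.random.default_rng(100 + seed)
        shape = tuple(rng.integers(3, 7, 3))
        labels = rng.integers(1, 5, shape).astype(np.int32)
        mask = np.ones(shape, dtype=bool)
        got = glcm_stats(labels, mask)
        offsets = ((1, 0, 0), (0, 1, 0), (1, 1, 0), (1, -1, 0))
        expected = brute_glcm(labels, mask, offsets)
        assert np.allclose(got, expected, atol=1e-12)


class TestMSIVector:
    def test_whole_block_has_44_values(self):
        labels = np.random.default_rng(0).integers(1, 6, (8, 8, 2)).astype(np.int32)
        mask = np.ones_like(labels, dtype=bool)
        assert msi_whole(labels, mask).shape == (44,)

    def test_all_sr1_map_nonzeros(self):
        labels = np.zeros((6, 6, 2), dtype=np.int32)
        labels[1:5, 1:5, :] = 1
        mask = labels > 0
        vec = msi_whole(labels, mask)
        names = msi_feature_names()[:44]
        nonzero = {names[i] for i in np.nonzero(vec)[0]}
        # volumes/border of SR1 plus the trivial single-label GLCM values
        assert nonzero == {"MSI3", "MSI4", "MSI5", "MSI10", "MSI25", "MSI30"}

    def test_symmetric_difference_examples(self):
        assert symmetric_difference([2.0], [6.0], [4.0])[0] == pytest.approx(4.0)
        assert symmetric_difference([4.0], [9.0], [4.0])[0] == 0.0
        a, b, w = np.array([1.0, 2]), np.array([3.0, 5]), np.array([2.0, 2])
        assert np.array_equal(
            symmetric_difference(a, b, w), symmetric_difference(b, a, w)
        )

    def test_symmetric_difference_length_mismatch(self):
        with pytest.raises(ValueError):
            symmetric_difference([1.0], [1.0, 2.0], [1.0])

    def test_full_msi_length_and_names(self):
        rng = np.random.default_rng(1)
        labels = np.zeros((10, 6, 2), dtype=np.int32)
        labels[1:5, 1:5, :] = rng.integers(1, 6, (4, 4, 2))
        labels[6:9, 1:5, :] = rng.integers(1, 6, (3, 4, 2))
        left = np.zeros_like(labels, dtype=bool)
        right = np.zeros_like(labels, dtype=bool)
        left[:5] = labels[:5] > 0
        right[5:] = labels[5:] > 0
        vec = full_msi(labels, left, right)
        assert len(vec) == 88
        assert list(vec.index) == [f"MSI{i}" for i in range(1, 89)]
        assert (vec[44:] >= 0).all()

    def test_overlapping_sides_rejected(self):
        labels = np.ones((4, 4, 1), dtype=np.int32)
        m = labels > 0
        with pytest.raises(ValueError):
            full_msi(labels, m, m)

    def test_mirrored_map_has_zero_percentage_asymmetry(self):
        rng = np.random.default_rng(2)
        half = rng.integers(1, 6, (5, 6, 2)).astype(np.int32)
        labels = np.concatenate([half, half[::-1]], axis=0)
        left = np.zeros_like(labels, dtype=bool)
        right = np.zeros_like(labels, dtype=bool)
        left[:5] = True
        right[5:] = True
        vec = full_msi(labels, left, right)
        # percentage-volume asymmetry features MSI69-73 vanish exactly
        for i in range(69, 74):
            assert vec[f"MSI{i}"] == pytest.approx(0.0, abs=1e-15)

    def test_translation_invariance(self):
        rng = np.random.default_rng(3)
        labels = np.zeros((12, 12, 3), dtype=np.int32)
        labels[2:6, 2:6, :] = rng.integers(1, 6, (4, 4, 3))
        labels[7:10, 2:6, :] = rng.integers(1, 6, (3, 4, 3))
        left = np.zeros_like(labels, bool)
        right = np.zeros_like(labels, bool)
        left[:6] = labels[:6] > 0
        right[6:] = labels[6:] > 0
        v1 = full_msi(labels, left, right)
        shifted = np.roll(labels, (0, 3, 0), axis=(0, 1, 2))
        v2 = full_msi(shifted, np.roll(left, 3, 1), np.roll(right, 3, 1))
        assert np.allclose(v1.to_numpy(), v2.to_numpy())

    def test_feature_dictionary_covers_all_names(self):
        d = feature_dictionary()
        assert set(d) == set(msi_feature_names())


class TestWholeLungRadiomics:
    def test_constant_lung_has_zero_dispersion(self):
        comp = np.full((8, 8, 2, 4), 0.5)
        mask = np.zeros((8, 8, 2), dtype=bool)
        mask[2:6, 2:6, :] = True
        vec = whole_lung_radiomics(comp, mask)
        for ch in ("lung", "mediastinum"):
            assert vec[f"RAD_{ch}_sd"] == 0
            assert vec[f"RAD_{ch}_iqr"] == 0

    def test_vector_length(self):
        comp = np.random.default_rng(0).random((8, 8, 2, 4))
        mask = np.ones((8, 8, 2), dtype=bool)
        vec = whole_lung_radiomics(comp, mask)
        assert len(vec) == 44
        assert list(vec.index) == radiomics_feature_names()

    def test_blind_to_spatial_arrangement(self):
        # identical voxel multisets arranged unilaterally vs bilaterally
        rng = np.random.default_rng(1)
        vals = rng.random(64)
        a = np.zeros((8, 8, 1, 4))
        b = np.zeros((8, 8, 1, 4))
        a[..., 0, :] = vals.reshape(8, 8)[..., None]
        b[..., 0, :] = vals.reshape(8, 8)[::-1][..., None]  # rearranged
        mask = np.ones((8, 8, 1), dtype=bool)
        va = whole_lung_radiomics(a, mask)
        vb = whole_lung_radiomics(b, mask)
        first_order = [n for n in va.index if not n.startswith("RAD_glcm")]
        assert np.allclose(va[first_order], vb[first_order])

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            whole_lung_radiomics(np.zeros((4, 4, 1, 4)), np.zeros((4, 4, 1), bool))
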