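"""Feature panel: exact accounting, filter bank, and enumeration oracles."""

import itertools

import numpy as np
import pytest

from habitatomics.images import ImageVolume
from habitatomics.radiomics import (
    FeaturePanelConfig,
    apply_transforms,
    channel_names,
    discretize,
    extract_region_features,
    region_feature_names,
)
from habitatomics.radiomics.firstorder import first_order_features
from habitatomics.radiomics.shape import shape_features
from habitatomics.radiomics.texture import (
    DIRECTIONS_13,
    glcm_matrices,
    glrlm_matrices,
    glszm_matrix,
)

CFG = FeaturePanelConfig()


class TestAccounting:
    def test_per_region_count_is_1223(self):
        assert CFG.n_per_region == 1223
        names = region_feature_names(CFG)
        assert len(names) == 1223
        assert len(set(names)) == 1223

    def test_family_arithmetic(self):
        # 18+24+16+16+14+5 = 93 intensity features per channel, 13 channels
        assert len(CFG.intensity_feature_names()) == 93
        assert len(CFG.channels) == 13
        assert 14 + 93 * 13 == 1223

    def test_patient_row_is_9784(self, full_panel_row):
        assert len(full_panel_row) == 9784
        assert full_panel_row.index.is_unique
        assert not np.isnan(full_panel_row.to_numpy()).any()

    def test_shr_tr_ratio(self, full_panel_row):
        pre_tr = [n for n in full_panel_row.index if n.startswith("pre|TR|")]
        pre_shr = [n for n in full_panel_row.index if n.startswith("pre|habitat")]
        assert len(pre_tr) == 1223
        assert len(pre_shr) == 3669


class TestTransforms:
    def test_channel_count_is_13(self, phantom):
        pv = phantom[0]
        channels = apply_transforms(pv)
        assert len(channels) == 13
        assert set(channels) == set(channel_names())
        for arr in channels.values():
            assert arr.shape == pv.voxels.shape

    def test_constant_volume_flat_subbands(self):
        vol = ImageVolume(np.full((16, 16, 16), 50.0))
        channels = apply_transforms(vol)
        for name, arr in channels.items():
            if name.startswith("wavelet-") and "H" in name:
                assert np.abs(arr).max() < 1e-8
        # LLL of a constant is a scaled constant
        lll = channels["wavelet-LLL"]
        assert np.allclose(lll, lll.flat[0])

    def test_log_scale_selection_on_gaussian_blob(self):
        zz, yy, xx = np.indices((32, 32, 32), dtype=float)
        r2 = (zz - 16) ** 2 + (yy - 16) ** 2 + (xx - 16) ** 2
        blob_sigma = 3.0
        vol = ImageVolume(100 * np.exp(-r2 / (2 * blob_sigma**2)))
        channels = apply_transforms(vol)
        # γ-normalized |LoG| response at the blob centre: in 3D the centre
        # response scales as (σ_b²+σ²)^(-5/2), so σ^2.5 normalization peaks
        # exactly at the blob scale
        responses = {
            s: s**2.5 * abs(channels[f"log-sigma-{s:g}mm"][16, 16, 16])
            for s in (2.0, 3.0, 4.0, 5.0)
        }
        assert max(responses, key=responses.get) == 3.0

    def test_volume_below_filter_support_rejected(self):
        vol = ImageVolume(np.zeros((8, 8, 8)))  # coif3 support is 18 samples
        with pytest.raises(ValueError):
            apply_transforms(vol, wavelet="coif3")


class TestFirstOrderOracle:
    def test_brute_force_equivalence(self):
        rng = np.random.default_rng(3)
        vals = rng.normal(100, 25, 500)
        disc = discretize(vals, 25.0)
        f = first_order_features(vals, 1.0, disc)
        assert abs(f["Mean"] - vals.mean()) < 1e-9
        assert abs(f["Variance"] - vals.var()) < 1e-9
        assert abs(f["Energy"] - np.sum(vals**2)) < 1e-6
        assert abs(f["RootMeanSquared"] - np.sqrt(np.mean(vals**2))) < 1e-9
        m2 = vals.var()
        assert abs(f["Skewness"] - np.mean((vals - vals.mean()) ** 3) / m2**1.5) < 1e-9
        p = np.bincount(disc)[1:]
        p = p[p > 0] / len(vals)
        assert abs(f["Uniformity"] - (p**2).sum()) < 1e-12
        assert abs(f["Entropy"] + (p * np.log2(p)).sum()) < 1e-12


class TestShape:
    def test_sphere_sphericity(self):
        zz, yy, xx = np.indices((40, 40, 40))
        ball = (zz - 20) ** 2 + (yy - 20) ** 2 + (xx - 20) ** 2 <= 15**2
        f = shape_features(ball, (1.0, 1.0, 1.0))
        assert abs(f["Sphericity"] - 1.0) < 0.05
        analytic = 4 / 3 * np.pi * 15**3
        assert abs(f["MeshVolume"] - analytic) / analytic < 0.05
        assert abs(f["Maximum3DDiameter"] - 30) < 2.5

    def test_anisotropic_spacing_scales_volume(self):
        box = np.zeros((12, 12, 12), bool)
        box[2:10, 2:10, 2:10] = True
        f1 = shape_features(box, (1, 1, 1))
        f2 = shape_features(box, (2, 1, 1))
        assert abs(f2["VoxelVolume"] / f1["VoxelVolume"] - 2.0) < 1e-9


def brute_glcm_counts(levels, region, offset, ng):
    """Enumerate co-occurring voxel pairs directly (symmetric)."""
    m = np.zeros((ng, ng))
    nz, ny, nx = levels.shape
    for z, y, x in itertools.product(range(nz), range(ny), range(nx)):
        if not region[z, y, x]:
            continue
        z2, y2, x2 = z + offset[0], y + offset[1], x + offset[2]
        if 0 <= z2 < nz and 0 <= y2 < ny and 0 <= x2 < nx and region[z2, y2, x2]:
            i, j = levels[z, y, x] - 1, levels[z2, y2, x2] - 1
            m[i, j] += 1
            m[j, i] += 1
    return m


def brute_run_lengths(levels, region, offset, ng, lmax):
    """Walk every lattice line explicitly and count maximal runs."""
    m = np.zeros((ng, lmax))
    nz, ny, nx = levels.shape

    def inside(p):
        return (
            0 <= p[0] < nz and 0 <= p[1] < ny and 0 <= p[2] < nx and region[tuple(p)]
        )

    for start in itertools.product(range(nz), range(ny), range(nx)):
        if not inside(start):
            continue
        prev = (start[0] - offset[0], start[1] - offset[1], start[2] - offset[2])
        if inside(prev) and levels[prev] == levels[start]:
            continue  # not the beginning of a run
        length = 1
        cur = start
        while True:
            nxt = (cur[0] + offset[0], cur[1] + offset[1], cur[2] + offset[2])
            if inside(nxt) and levels[nxt] == levels[start]:
                length += 1
                cur = nxt
            else:
                break
        m[levels[start] - 1, length - 1] += 1
    return m


class TestTextureOracles:
    def test_glcm_matrix_matches_enumeration(self):
        rng = np.random.default_rng(0)
        levels = rng.integers(1, 5, size=(5, 5, 5))
        region = rng.random((5, 5, 5)) > 0.25
        levels = np.where(region, levels, 0)
        mats = glcm_matrices(levels, region, ng=4)
        for mat, d in zip(mats, DIRECTIONS_13):
            assert np.array_equal(mat, brute_glcm_counts(levels, region, d, 4))

    def test_glcm_contrast_on_toy_grid(self):
        # classic 4×4 two-level checkerboard slab, single slice
        grid = np.array([[1, 2, 1, 2], [2, 1, 2, 1], [1, 2, 1, 2], [2, 1, 2, 1]])
        levels = grid[None, :, :]
        region = np.ones_like(levels, bool)
        mats = glcm_matrices(levels, region, ng=2)
        # in-plane horizontal direction (0,0,1): all 24 symmetric pairs differ
        horiz = mats[0]
        p = horiz / horiz.sum()
        contrast = sum(
            (i - j) ** 2 * p[i - 1, j - 1] for i in (1, 2) for j in (1, 2)
        )
        assert contrast == 1.0  # every horizontally adjacent pair differs by 1

    def test_glrlm_matches_line_walker(self):
        rng = np.random.default_rng(1)
        for trial in range(5):
            levels = rng.integers(1, 4, size=(6, 6, 6))
            region = rng.random((6, 6, 6)) > 0.2
            levels = np.where(region, levels, 0)
            mats = glrlm_matrices(levels, region, ng=3)
            for mat, d in zip(mats, DIRECTIONS_13):
                brute = brute_run_lengths(levels, region, d, 3, 6)
                assert np.array_equal(mat, brute[:, : mat.shape[1]])
                assert brute[:, mat.shape[1]:].sum() == 0

    def test_glszm_zone_counting(self):
        levels = np.zeros((4, 4, 4), dtype=int)
        levels[0, 0, :2] = 1  # one zone of size 2
        levels[2, 2, 2] = 1  # one zone of size 1
        levels[3, :, :] = 2  # one zone of size 16
        region = levels > 0
        m = glszm_matrix(levels, region, ng=2)
        assert m[0, 0] == 1 and m[0, 1] == 1  # level 1: sizes 1 and 2
        assert m[1, 15] == 1  # level 2: size 16


class TestInvariances:
    def _random_region(self, seed, shape=(10, 10, 10)):
        rng = np.random.default_rng(seed)
        vol = rng.normal(150, 40, shape)
        zz, yy, xx = np.indices(shape)
        c = (np.array(shape) - 1) / 2
        region = (zz - c[0]) ** 2 + (yy - c[1]) ** 2 + (xx - c[2]) ** 2 <= 16
        return vol, region

    def test_translation_invariance(self):
        cfg = FeaturePanelConfig(use_transforms=False, include_shape=False)
        vol, region = self._random_region(0, (12, 12, 12))
        base, _ = extract_region_features({"original": vol}, region, (1, 1, 1), cfg)
        shifted_vol = np.roll(vol, (2, 1, 2), axis=(0, 1, 2))
        shifted_region = np.roll(region, (2, 1, 2), axis=(0, 1, 2))
        moved, _ = extract_region_features(
            {"original": shifted_vol}, shifted_region, (1, 1, 1), cfg
        )
        np.testing.assert_allclose(base, moved, rtol=1e-12, atol=1e-12)

    def test_rotation_robustness_90deg(self):
        # 90° in-plane rotation permutes the 13 directions among ± pairs:
        # direction-averaged GLCM features are exactly preserved
        cfg = FeaturePanelConfig(
            families=("glcm",), use_transforms=False, include_shape=False
        )
        vol, region = self._random_region(1)
        base, _ = extract_region_features({"original": vol}, region, (1, 1, 1), cfg)
        rot_vol = np.rot90(vol, axes=(1, 2))
        rot_region = np.rot90(region, axes=(1, 2))
        rot, _ = extract_region_features(
            {"original": np.ascontiguousarray(rot_vol)},
            np.ascontiguousarray(rot_region),
            (1, 1, 1),
            cfg,
        )
        np.testing.assert_allclose(base, rot, rtol=0, atol=1e-9)


class TestDegenerateRegions:
    def test_tiny_region_flagged_not_dropped(self):
        cfg = FeaturePanelConfig(use_transforms=False, include_shape=False)
        vol = np.random.default_rng(0).normal(size=(10, 10, 10))
        region = np.zeros((10, 10, 10), bool)
        region[5, 5, :4] = True  # 4 voxels < 8
        vec, flagged = extract_region_features({"original": vol}, region, (1, 1, 1), cfg)
        assert flagged
        assert np.isnan(vec).all()
        assert len(vec) == cfg.n_per_region

    def test_single_grey_level_defined_values(self):
        cfg = FeaturePanelConfig(use_transforms=False, include_shape=False)
        vol = np.full((10, 10, 10), 42.0)
        region = np.zeros((10, 10, 10), bool)
        region[3:7, 3:7, 3:7] = True
        vec, flagged = extract_region_features({"original": vol}, region, (1, 1, 1), cfg)
        assert not flagged
        assert np.all(np.isfinite(vec))

    def test_discretize_bin_width(self):
        vals = np.array([0.0, 24.9, 25.0, 49.9, 100.0])
        np.testing.assert_array_equal(discretize(vals, 25.0), [1, 1, 2, 2, 5])
        with pytest.raises(ValueError):
            discretize(vals, 0.0)
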