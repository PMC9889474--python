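"""Radiomics feature catalogue against brute-force and analytic oracles."""
import math

import numpy as np
import pytest

from deltarad.features import (
    GLCM_NAMES,
    OFFSETS_13,
    discretize,
    extract_all,
    first_order_features,
    glcm_features,
    glrlm_features,
    shape_features,
)
from deltarad.grid import BinaryMask, VoxelGrid, make_rings

from _oracles import ALL_OFFSETS_13, glcm_brute, glrlm_features_brute
from conftest import digital_sphere


def _region(values, mask=None, spacing=1.0):
    values = np.asarray(values, dtype=float)
    if mask is None:
        mask = np.ones(values.shape, dtype=bool)
    g = VoxelGrid(values, np.full(3, spacing))
    m = BinaryMask(mask, np.full(3, spacing))
    return g, m


class TestDiscretize:
    def test_constant_region_single_level(self):
        g, m = _region(np.full((4, 4, 4), 3.0))
        d = discretize(g, m, 32)
        assert set(np.unique(d.levels[d.mask])) == {1}

    def test_full_range_one_per_bin(self):
        g, m = _region(np.arange(32, dtype=float).reshape(2, 4, 4))
        d = discretize(g, m, 32)
        counts = np.bincount(d.levels[d.mask], minlength=33)[1:]
        assert np.all(counts == 1)

    @pytest.mark.parametrize("seed", range(5))
    def test_histogram_conserves_voxels(self, seed):
        rng = np.random.default_rng(seed)
        vals = rng.normal(size=(6, 6, 6))
        mask = rng.random((6, 6, 6)) < 0.7
        mask[3, 3, 3] = True
        g, m = _region(vals, mask)
        d = discretize(g, m, 16)
        assert (d.levels > 0).sum() == mask.sum()
        assert d.levels.max() <= 16

    def test_empty_mask_rejected(self):
        g, m = _region(np.zeros((3, 3, 3)), np.zeros((3, 3, 3), bool))
        with pytest.raises(ValueError):
            discretize(g, m)


class TestFirstOrder:
    def test_constant_region(self):
        g, m = _region(np.full((4, 4, 4), 5.0))
        f = first_order_features(g, m)
        assert f["variance"] == 0 and f["entropy"] == 0 and f["uniformity"] == 1
        assert np.isnan(f["skewness"]) and np.isnan(f["kurtosis"])

    def test_small_example(self):
        vals = np.array([1.0, 2.0, 3.0, 4.0]).reshape(4, 1, 1)
        g, m = _region(vals)
        f = first_order_features(g, m)
        assert f["mean"] == 2.5 and f["range"] == 3.0 and f["minimum"] == 1.0

    def test_moments_of_standard_normal(self):
        rng = np.random.default_rng(0)
        vals = rng.normal(size=10_000).reshape(10, 10, 100)
        g, m = _region(vals)
        f = first_order_features(g, m)
        assert abs(f["skewness"]) < 0.08
        assert abs(f["kurtosis"]) < 0.15

    @pytest.mark.parametrize("shift", [-17.5, 42.0])
    def test_intensity_shift_equivariance(self, shift):
        rng = np.random.default_rng(3)
        vals = rng.normal(size=(6, 6, 6))
        mask = rng.random((6, 6, 6)) < 0.8
        g0, m = _region(vals, mask)
        g1, _ = _region(vals + shift, mask)
        f0, f1 = first_order_features(g0, m), first_order_features(g1, m)
        for k in ("mean", "median", "minimum", "maximum", "p10", "p90"):
            assert f1[k] == pytest.approx(f0[k] + shift, abs=1e-9)
        for k in ("variance", "entropy", "uniformity", "range", "iqr", "mad"):
            assert f1[k] == pytest.approx(f0[k], abs=1e-9)


class TestShape:
    def test_sphere_oracle(self, sphere10):
        f = shape_features(sphere10)
        assert 0.95 <= f["sphericity"] <= 1.02
        assert f["max_diameter_mm"] == pytest.approx(20.0, abs=2.0)
        assert f["voxel_volume_mm3"] == pytest.approx(4 / 3 * math.pi * 1000, rel=0.05)

    def test_ellipsoid_axes_and_elongation(self):
        n = 64
        c = n // 2
        x, y, z = np.meshgrid(*[np.arange(n)] * 3, indexing="ij")
        ell = ((x - c) / 20) ** 2 + ((y - c) / 10) ** 2 + ((z - c) / 10) ** 2 <= 1
        m = BinaryMask(ell, np.ones(3))
        f = shape_features(m)
        assert f["major_axis_mm"] / f["minor_axis_mm"] == pytest.approx(2.0, rel=0.05)
        assert f["elongation"] == pytest.approx(0.5, rel=0.05)
        assert f["flatness"] == pytest.approx(0.5, rel=0.05)

    def test_planar_mask_mesh_missing(self):
        m = BinaryMask(np.zeros((6, 6, 6), bool), np.ones(3))
        m.values[2, :, :] = True
        f = shape_features(m)
        assert np.isnan(f["sphericity"])
        assert f["voxel_volume_mm3"] == 36.0


def _checkerboard_disc():
    vals = (np.indices((4, 4, 1)).sum(axis=0) % 2).astype(float)
    g, m = _region(vals)
    return discretize(g, m, 2)


class TestGLCM:
    def test_checkerboard_single_offset_oracle(self):
        d = _checkerboard_disc()
        ref = glcm_brute(d.levels, (1, 0, 0))
        assert ref["contrast"] == 1.0
        assert ref["energy"] == 0.5
        assert ref["homogeneity"] == 0.5

    def test_constant_region(self):
        g, m = _region(np.full((4, 4, 4), 2.0))
        f = glcm_features(discretize(g, m))
        assert f["contrast"] == 0.0 and f["energy"] == 1.0
        assert np.isnan(f["correlation"])  # single occupied level

    def test_gray_flip_symmetry(self):
        rng = np.random.default_rng(5)
        g, m = _region(rng.integers(0, 8, (5, 5, 5)).astype(float))
        d = discretize(g, m, 8)
        flipped = d.levels.copy()
        flipped[d.mask] = 9 - flipped[d.mask]
        d2 = type(d)(levels=flipped, mask=d.mask, n_levels=8, edges=d.edges)
        f, f2 = glcm_features(d), glcm_features(d2)
        for k in ("contrast", "energy", "homogeneity", "entropy", "dissimilarity"):
            assert f[k] == pytest.approx(f2[k], abs=1e-12)

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        vals = rng.integers(0, 5, (6, 6, 6)).astype(float)
        mask = rng.random((6, 6, 6)) < 0.8
        mask[0, 0, 0] = True
        g, m = _region(vals, mask)
        d = discretize(g, m, 5)
        mine = glcm_features(d)
        per_off = {k: [] for k in GLCM_NAMES}
        for off in ALL_OFFSETS_13:
            ref = glcm_brute(d.levels, off)
            if ref is None:
                continue
            for k in GLCM_NAMES:
                if ref.get(k) is not None:
                    per_off[k].append(ref[k])
        for k in GLCM_NAMES:
            if per_off[k]:
                assert mine[k] == pytest.approx(np.mean(per_off[k]), abs=1e-10), k


class TestGLRLM:
    def test_constant_cube_runs(self):
        g, m = _region(np.full((4, 4, 4), 1.0))
        d = discretize(g, m)
        from deltarad.features import _run_length_matrix

        R = _run_length_matrix(d.levels, (1, 0, 0), 4)
        assert R[0, 3] == 16 and R.sum() == 16  # 16 runs of length 4

    def test_checkerboard_axis_runs_all_length_one(self):
        # along the axes a checkerboard alternates every step
        from deltarad.features import _run_length_matrix

        d = _checkerboard_disc()
        for off in ((1, 0, 0), (0, 1, 0)):
            R = _run_length_matrix(d.levels, off, 4)
            assert R[:, 1:].sum() == 0 and R[:, 0].sum() == 16

    def test_all_distinct_levels_all_short_runs(self):
        # no two voxels share a level -> every run has length 1 in every direction
        g, m = _region(np.arange(27, dtype=float).reshape(3, 3, 3))
        f = glrlm_features(discretize(g, m, 27))
        assert f["sre"] == pytest.approx(1.0)
        assert f["run_percentage"] == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_brute_force(self, seed):
        rng = np.random.default_rng(100 + seed)
        vals = rng.integers(0, 4, (6, 6, 6)).astype(float)
        mask = rng.random((6, 6, 6)) < 0.75
        mask[2, 2, 2] = True
        g, m = _region(vals, mask)
        d = discretize(g, m, 4)
        mine = glrlm_features(d)
        ref = glrlm_features_brute(d.levels, int(d.mask.sum()))
        for k, v in ref.items():
            assert mine[k] == pytest.approx(v, abs=1e-10), k

    def test_run_length_conservation(self):
        rng = np.random.default_rng(7)
        vals = rng.integers(0, 4, (7, 7, 7)).astype(float)
        mask = rng.random((7, 7, 7)) < 0.7
        mask[3, 3, 3] = True
        g, m = _region(vals, mask)
        d = discretize(g, m, 4)
        from deltarad.features import _run_length_matrix

        for off in OFFSETS_13:
            R = _run_length_matrix(d.levels, off, max(d.levels.shape))
            lengths = np.arange(1, R.shape[1] + 1)
            assert (R * lengths).sum() == d.mask.sum()


@pytest.fixture(scope="module")
def rings(sphere10, full_lung):
    return make_rings(sphere10, full_lung)


class TestExtractAll:
    def test_arity_fixed(self, noise_grid, rings):
        fv = extract_all(noise_grid, rings, "F0")
        # 3 regions x (16 first-order + 6 glcm + 6 glrlm) + 12 shape
        assert len(fv) == 3 * 28 + 12
        assert all(k.startswith("F0__") for k in fv)

    def test_deterministic(self, noise_grid, rings):
        a = extract_all(noise_grid, rings, "F0")
        b = extract_all(noise_grid, rings, "F0")
        assert a == b

    def test_translation_invariance(self, noise_grid, rings):
        shift = 3
        g2 = VoxelGrid(np.roll(noise_grid.values, shift, axis=0), noise_grid.spacing_mm)
        shifted = {
            name: BinaryMask(np.roll(m.values, shift, axis=0), m.spacing_mm)
            for name, m in rings
        }
        rs2 = type(rings)(**shifted)
        a = extract_all(noise_grid, rings, "F0")
        b = extract_all(g2, rs2, "F0")
        for k in a:
            if np.isnan(a[k]):
                assert np.isnan(b[k])
            else:
                # mesh features accumulate floats in a different order
                assert a[k] == pytest.approx(b[k], rel=1e-5), k
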