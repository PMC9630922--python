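import numpy as np
import pandas as pd
import pytest

from cordmaskvar import agreement
from cordmaskvar.agreement import (adjacent_region, adjacent_sc_ratio, build_tables,
                                   cv_adjacent, dsc, gm_wm_contrast, logit,
                                   slice_inclusion)
from cordmaskvar.errors import UndefinedMetricError
from cordmaskvar.phantom import PhantomSpec, generate_phantom, simulate_misregistration

from conftest import random_mask_pair


def brute_force_dice(a, b):
    """Independent voxel-counting oracle: literal 2|A∩B|/(|A|+|B|)."""
    inter = sizes = 0
    for idx in np.ndindex(a.shape):
        inter += bool(a[idx]) and bool(b[idx])
        sizes += bool(a[idx]) + bool(b[idx])
    return 2.0 * inter / sizes


class TestDsc:
    def test_identical_masks_give_one(self):
        m = np.zeros((5, 5, 2), dtype=bool)
        m[1:4, 1:4, :] = True
        assert dsc(m, m) == 1.0

    def test_disjoint_masks_give_zero(self):
        a = np.zeros((5, 5, 1), dtype=bool)
        b = np.zeros((5, 5, 1), dtype=bool)
        a[0, 0, 0] = True
        b[4, 4, 0] = True
        assert dsc(a, b) == 0.0

    def test_counted_toy_example(self):
        # |REF| = 4, |RM| = 3, |REF∩RM| = 2 → 2·2/(4+3) = 4/7
        a = np.zeros((4, 4, 1), dtype=bool)
        b = np.zeros((4, 4, 1), dtype=bool)
        a[0, 0:4, 0] = True
        b[0, 2:4, 0] = True
        b[1, 0, 0] = True
        assert dsc(a, b) == pytest.approx(4 / 7)

    def test_matches_brute_force_on_random_pairs(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            a, b = random_mask_pair(rng, shape=(16, 16, 4))
            if not (a.any() or b.any()):
                continue
            assert dsc(a, b) == brute_force_dice(a, b)
            assert dsc(a, b) == dsc(b, a)

    def test_volume_dsc_is_count_weighted_slice_combination(self):
        rng = np.random.default_rng(3)
        a, b = random_mask_pair(rng, shape=(10, 10, 5))
        num = sum(2 * (a[:, :, s] & b[:, :, s]).sum() for s in range(5))
        den = sum(a[:, :, s].sum() + b[:, :, s].sum() for s in range(5))
        assert dsc(a, b) == pytest.approx(num / den)

    def test_both_empty_raises(self):
        z = np.zeros((3, 3, 1), dtype=bool)
        with pytest.raises(UndefinedMetricError):
            dsc(z, z)


class TestLogit:
    @pytest.mark.parametrize("p,expected", [(0.5, 0.0), (0.75, np.log(3.0))])
    def test_closed_form_values(self, p, expected):
        assert logit(p) == pytest.approx(expected, abs=1e-12)

    def test_boundaries_are_finite_and_clamped(self):
        assert logit(1.0) == pytest.approx(np.log((1 - 1e-6) / 1e-6))
        assert np.isfinite(logit(0.0))
        assert logit(0.0) == pytest.approx(-logit(1.0))


class TestSliceInclusion:
    def test_trims_one_from_each_end(self):
        idx = slice_inclusion(25, n_trim=1)
        assert len(idx) == 23 and idx[0] == 1 and idx[-1] == 23

    def test_zero_trim_keeps_all(self):
        assert len(slice_inclusion(25, n_trim=0)) == 25

    def test_over_trimming_is_an_error(self):
        with pytest.raises(ValueError):
            slice_inclusion(25, n_trim=13)


class TestAdjacentRegion:
    def test_single_voxel_two_dilations_gives_chebyshev_ball(self):
        m = np.zeros((11, 11, 1), dtype=bool)
        m[5, 5, 0] = True
        adj = adjacent_region(m, n_dilate=2)
        # enumeration oracle: voxels with Chebyshev distance 1..2 of center
        expected = {(r, c) for r in range(11) for c in range(11)
                    if 0 < max(abs(r - 5), abs(c - 5)) <= 2}
        assert set(zip(*np.nonzero(adj[:, :, 0]))) == expected
        assert adj.sum() == 24

    def test_corner_voxel_clips_at_border(self):
        m = np.zeros((6, 6, 1), dtype=bool)
        m[0, 0, 0] = True
        adj = adjacent_region(m, n_dilate=1)
        assert set(zip(*np.nonzero(adj[:, :, 0]))) == {(0, 1), (1, 0), (1, 1)}

    def test_disjoint_from_mask_and_within_distance(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            m, _ = random_mask_pair(rng, shape=(9, 9, 2), p=0.2)
            for n_dilate in (1, 2):
                adj = adjacent_region(m, n_dilate=n_dilate)
                assert not (adj & m).any()
                for s in range(m.shape[2]):
                    pts = np.argwhere(m[:, :, s])
                    for r, c in np.argwhere(adj[:, :, s]):
                        cheb = np.max(np.abs(pts - [r, c]), axis=1).min()
                        assert 1 <= cheb <= n_dilate


class TestIntensityMetrics:
    @staticmethod
    def _slice_setup(adjacent_values, cord_value=100.0):
        img = np.zeros((9, 9, 1))
        ref = np.zeros((9, 9, 1), dtype=bool)
        ref[4, 4, 0] = True
        img[4, 4, 0] = cord_value
        adj = adjacent_region(ref, n_dilate=1)
        coords = np.argwhere(adj[:, :, 0])
        img[:, :, 0][tuple(coords.T)] = np.resize(adjacent_values, len(coords))
        return img, ref

    def test_cv_zero_for_constant_adjacent(self):
        img, ref = self._slice_setup([100.0])
        assert cv_adjacent(img, ref, 0, n_dilate=1) == 0.0

    def test_cv_hand_computed_two_values(self):
        # 1-column grid: the center voxel has exactly 2 in-plane neighbours;
        # adjacent {90, 110} → mean 100, sample sd √200
        img = np.zeros((9, 1, 1))
        ref = np.zeros((9, 1, 1), dtype=bool)
        ref[4, 0, 0] = True
        img[3, 0, 0], img[5, 0, 0] = 90.0, 110.0
        assert cv_adjacent(img, ref, 0, n_dilate=1) == pytest.approx(np.sqrt(200) / 100)

    def test_cv_scale_invariant(self):
        rng = np.random.default_rng(0)
        img, ref = self._slice_setup(rng.uniform(50, 150, 8))
        assert cv_adjacent(3.7 * img, ref, 0, n_dilate=1) == pytest.approx(
            cv_adjacent(img, ref, 0, n_dilate=1))

    def test_adjacent_sc_direct_ratio(self):
        img, ref = self._slice_setup([200.0], cord_value=100.0)
        assert adjacent_sc_ratio(img, ref, 0, n_dilate=1) == pytest.approx(2.0)
        img, ref = self._slice_setup([100.0], cord_value=100.0)
        assert adjacent_sc_ratio(img, ref, 0, n_dilate=1) == pytest.approx(1.0)

    def test_contrast_breakdown_slices_give_ratio_below_one(self):
        # CSF dipping below cord signal on the lowest slices
        n = 10
        csf = np.where(np.arange(n) >= 5, 80.0, 200.0)
        spec = PhantomSpec(grid_shape=(32, 32, n), cord_center=(16.0, 16.0),
                           cord_radii=(4.0, 6.0), csf_mean=csf, wm_mean=100.0,
                           gm_mean=100.0, noise_sd=0.0, seed=0)
        vol = generate_phantom(spec)
        for s in range(n):
            ratio = adjacent_sc_ratio(vol.image, vol.cord_mask, s)
            assert (ratio < 1.0) == (s >= 5)
            expected = csf[s] / 100.0
            assert ratio == pytest.approx(expected)


class TestGmWmContrast:
    def test_equal_means_give_unity(self, small_spec):
        from dataclasses import replace
        vol = generate_phantom(replace(small_spec, gm_mean=100.0, wm_mean=100.0))
        assert gm_wm_contrast(vol.image, vol.gm_mask, vol.wm_mask) == pytest.approx(1.0)

    def test_constructed_ratio(self, noiseless_phantom):
        vol = noiseless_phantom
        c = gm_wm_contrast(vol.image, vol.gm_mask, vol.wm_mask)
        assert c == pytest.approx(1.2)
        assert np.log(c) == pytest.approx(np.log(1.2))

    def test_misregistration_reduces_contrast(self, noiseless_phantom):
        vol = noiseless_phantom
        aligned = gm_wm_contrast(vol.image, vol.gm_mask, vol.wm_mask)
        shifted = simulate_misregistration(vol, (2.0, 0.0))
        assert gm_wm_contrast(shifted.image, vol.gm_mask, vol.wm_mask) < aligned


class TestBuildTables:
    def test_counts_and_identity_rater(self, demo_study):
        study_dir, config, manifest = demo_study
        slice_table, cell_table = build_tables(study_dir)
        n_slices = config.grid_shape[2] - 2
        assert len(slice_table) == config.n_datasets * len(config.rater_models) * n_slices
        # one cell per rater×dataset plus the reference row
        assert len(cell_table) == config.n_datasets * (len(config.rater_models) + 1)
        ref_rows = cell_table[cell_table["rater"] == "REF"]
        assert np.allclose(ref_rows["mean_logit_dsc"], agreement.logit(1.0))
        assert np.allclose(cell_table["log_gm_wm"], np.log(cell_table["gm_wm_ratio"]))

    def test_csv_round_trip(self, demo_study, tmp_path):
        study_dir, _, _ = demo_study
        slice_table, _ = build_tables(study_dir)
        path = tmp_path / "slices.csv"
        slice_table.to_csv(path, index=False)
        back = pd.read_csv(path)
        pd.testing.assert_frame_equal(back, slice_table, check_dtype=False)

    def test_missing_file_error_names_the_file(self, tmp_path):
        with pytest.raises(FileNotFoundError, match="manifest"):
            build_tables(tmp_path)
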