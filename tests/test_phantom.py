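"""Synthetic phantom generator: geometry, coil bias, pairs, datasets."""

import numpy as np
import pytest

from ganstrip.metrics import dice
from ganstrip.phantom import (
    GE,
    SE,
    LABELS,
    CoilProfile,
    PhantomSpec,
    default_profile,
    default_spec,
    load_dataset,
    make_brain_phantom,
    make_coil_bias,
    make_dataset,
    make_pair,
    save_dataset,
)


class TestBrainPhantom:
    def test_no_shell_mask_equals_support(self):
        spec = default_spec(GE, grid_shape=(32, 32, 16), seed=1,
                            shell_thickness=0)
        lv = make_brain_phantom(spec)
        np.testing.assert_array_equal(lv.brain_mask, lv.intensity > 0)

    def test_deterministic_given_seed(self):
        spec = default_spec(SE, grid_shape=(24, 24, 16), seed=7)
        a = make_brain_phantom(spec)
        b = make_brain_phantom(spec)
        np.testing.assert_array_equal(a.intensity, b.intensity)
        np.testing.assert_array_equal(a.labels, b.labels)

    def test_mask_volume_matches_analytic_ellipsoid(self):
        spec = default_spec(GE, grid_shape=(64, 64, 64), seed=0,
                            brain_axes=(10.0, 8.0, 6.0))
        lv = make_brain_phantom(spec)
        analytic = 4.0 / 3.0 * np.pi * 10 * 8 * 6
        count = int(lv.brain_mask.sum())
        assert abs(count - analytic) / analytic < 0.15

    def test_compartments_present_and_disjoint(self):
        spec = default_spec(SE, grid_shape=(32, 32, 16), seed=3)
        lv = make_brain_phantom(spec)
        present = set(np.unique(lv.labels))
        assert {LABELS["WM"], LABELS["GM"], LABELS["CSF"], LABELS["shell"],
                LABELS["external_phantom"]} <= present
        # external phantom disjoint from brain mask
        assert not np.any((lv.labels == LABELS["external_phantom"])
                          & lv.brain_mask)

    def test_oversized_geometry_rejected(self):
        with pytest.raises(ValueError, match="exceeds the grid"):
            PhantomSpec(grid_shape=(16, 16, 16), brain_axes=(12, 12, 12))

    def test_external_phantom_is_se_only(self):
        with pytest.raises(ValueError, match="SE-only"):
            PhantomSpec(modality=GE, external_phantom=True)


class TestCoilBias:
    def test_unity_at_coil_center(self):
        prof = CoilProfile(coil_center=(4.5, 4.5, 4.5), coil_radius=5.0,
                           floor=0.2)
        bias = make_coil_bias(prof, (9, 9, 9))
        assert bias[4, 4, 4] == pytest.approx(1.0)

    def test_closed_form_at_one_radius(self):
        # d = a = 10 -> floor + (1-floor)/2^1.5
        prof = CoilProfile(coil_center=(0.5, 0.5, 0.5), coil_radius=10.0,
                           floor=0.2)
        bias = make_coil_bias(prof, (1, 1, 21))
        assert bias[0, 0, 10] == pytest.approx(0.2 + 0.8 / 2 ** 1.5,
                                               abs=1e-6)

    def test_floor_asymptote(self):
        prof = CoilProfile(coil_center=(0.5, 0.5, 0.5), coil_radius=2.0,
                           floor=0.3)
        bias = make_coil_bias(prof, (1, 1, 500))
        assert bias[0, 0, 499] == pytest.approx(0.3, abs=1e-4)
        assert bias.min() >= 0.3 - 1e-6 and bias.max() <= 1.0 + 1e-6

    def test_plane_mean_monotone_away_from_coil(self):
        prof = default_profile((16, 16, 16), (0.3, 0.3, 0.5))
        bias = make_coil_bias(prof, (16, 16, 16), (0.3, 0.3, 0.5))
        plane_means = bias.mean(axis=(0, 1))  # coil sits above +z
        assert np.all(np.diff(plane_means) >= -1e-9)  # increasing toward coil

    def test_invalid_profile_rejected(self):
        with pytest.raises(ValueError):
            CoilProfile(coil_center=(0, 0, 0), coil_radius=5.0, floor=0.0)
        with pytest.raises(ValueError):
            CoilProfile(coil_center=(0, 0, 0), coil_radius=-1.0, floor=0.5)


class TestMakePair:
    def test_noiseless_source_is_intensity_times_bias(self):
        spec = default_spec(GE, grid_shape=(24, 24, 16), seed=2,
                            noise_sigma=0.0)
        prof = default_profile((24, 24, 16), spec.voxel_size)
        pair = make_pair(spec, prof)
        lv = make_brain_phantom(spec)
        bias = make_coil_bias(prof, spec.grid_shape, spec.voxel_size)
        np.testing.assert_allclose(pair.source, lv.intensity * bias,
                                   rtol=1e-5, atol=1e-7)

    def test_identity_bias_source_restricted_equals_target(self):
        spec = default_spec(GE, grid_shape=(24, 24, 16), seed=2,
                            noise_sigma=0.0)
        prof = CoilProfile(coil_center=(12, 12, 40), coil_radius=5.0,
                           floor=1.0)  # uniform coil
        pair = make_pair(spec, prof)
        np.testing.assert_allclose(pair.source * pair.brain_mask,
                                   pair.target, rtol=1e-5, atol=1e-7)

    def test_target_zero_outside_mask(self):
        pair = make_pair(default_spec(SE, grid_shape=(24, 24, 16), seed=5))
        assert np.all(pair.target[pair.brain_mask == 0] == 0)

    def test_target_support_matches_mask(self):
        pair = make_pair(default_spec(GE, grid_shape=(24, 24, 16), seed=6))
        assert dice(pair.target, pair.brain_mask.astype(float)) == 1.0

    def test_noise_sd_matches_sigma_where_unclipped(self):
        spec = default_spec(GE, grid_shape=(32, 32, 16), seed=9,
                            noise_sigma=0.05)
        prof = default_profile((32, 32, 16), spec.voxel_size)
        pair = make_pair(spec, prof)
        lv = make_brain_phantom(spec)
        bias = make_coil_bias(prof, spec.grid_shape, spec.voxel_size)
        clean = lv.intensity * bias
        head = clean > 5 * spec.noise_sigma  # clipping never binds here
        resid = (pair.source - clean)[head]
        assert resid.size > 300
        assert abs(resid.std() - 0.05) / 0.05 < 0.10

    def test_deterministic(self):
        spec = default_spec(SE, grid_shape=(24, 24, 16), seed=4)
        a, b = make_pair(spec), make_pair(spec)
        np.testing.assert_array_equal(a.source, b.source)
        np.testing.assert_array_equal(a.target, b.target)

    def test_se_shell_brighter_than_ge(self):
        ge = make_brain_phantom(default_spec(GE, grid_shape=(32, 32, 16),
                                             seed=1))
        se = make_brain_phantom(default_spec(SE, grid_shape=(32, 32, 16),
                                             seed=1))
        ge_shell = ge.intensity[ge.labels == LABELS["shell"]].mean()
        se_shell = se.intensity[se.labels == LABELS["shell"]].mean()
        assert se_shell > ge_shell


class TestDataset:
    def test_split_arithmetic_all_ge(self):
        ds = make_dataset(10, 0, test_fraction=0.1, seed=0,
                          grid_shape=(16, 16, 16))
        assert ds.composition["train"][GE] == 9
        assert ds.composition["test"][GE] == 1
        assert ds.composition["train"][SE] == 0

    def test_deterministic_split(self):
        a = make_dataset(6, 2, test_fraction=0.25, seed=3,
                         grid_shape=(16, 16, 16))
        b = make_dataset(6, 2, test_fraction=0.25, seed=3,
                         grid_shape=(16, 16, 16))
        assert a.split == b.split
        np.testing.assert_array_equal(a.pairs[0].source, b.pairs[0].source)

    def test_expected_test_count(self):
        # round(n * fraction) pairs go to test for every seed
        for seed in range(5):
            ds = make_dataset(12, 0, test_fraction=0.25, seed=seed,
                              grid_shape=(16, 16, 16))
            assert len(ds.test_pairs) == 3
            assert len(ds.train_pairs) == 9

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            make_dataset(1, 0, 0.5, 0, grid_shape=(16, 16, 16))
        with pytest.raises(ValueError):
            make_dataset(4, 0, 1.5, 0, grid_shape=(16, 16, 16))

    def test_save_load_round_trip(self, tmp_path):
        ds = make_dataset(2, 1, test_fraction=0.34, seed=8,
                          grid_shape=(16, 16, 16))
        save_dataset(ds, tmp_path / "data")
        back = load_dataset(tmp_path / "data")
        assert back.split == ds.split
        assert [p.modality for p in back.pairs] == \
            [p.modality for p in ds.pairs]
        np.testing.assert_allclose(back.pairs[0].source, ds.pairs[0].source,
                                   rtol=1e-6)
        np.testing.assert_array_equal(back.pairs[2].brain_mask,
                                      ds.pairs[2].brain_mask)
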