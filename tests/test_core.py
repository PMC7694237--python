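import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from dummyrun import (
    BinaryMask,
    DoseGrid,
    FractionationScheme,
    GridGeometry,
    convert_to_eqd2,
    extract_isodose_mask,
    mask_volume_cc,
    read_volume,
    resample_nearest,
    write_volume,
)

from .conftest import make_geometry, sphere_mask, uniform_dose


class TestGeometry:
    def test_validation(self):
        with pytest.raises(ValueError):
            GridGeometry((0, 4, 4), (1, 1, 1))
        with pytest.raises(ValueError):
            GridGeometry((4, 4, 4), (1, -1, 1))

    def test_exact_compatibility_is_field_equality(self):
        a = GridGeometry((4, 4, 4), (1, 1, 1))
        assert a == GridGeometry((4, 4, 4), (1, 1, 1))
        assert a != GridGeometry((4, 4, 4), (1, 1, 1.0000001))
        assert a.approx_equal(GridGeometry((4, 4, 4), (1, 1, 1 + 1e-9)))

    def test_shape_mismatch_rejected(self):
        g = make_geometry(4)
        with pytest.raises(ValueError):
            DoseGrid(g, np.zeros((4, 4, 5)))
        with pytest.raises(ValueError):
            BinaryMask(g, np.zeros((3, 4, 4), bool))

    def test_dose_rejects_nan_and_negative(self):
        g = make_geometry(2)
        with pytest.raises(ValueError):
            DoseGrid(g, np.full(g.shape, np.nan))
        with pytest.raises(ValueError):
            DoseGrid(g, np.full(g.shape, -1.0))


class TestMaskVolume:
    @pytest.mark.parametrize(
        "n_true, spacing, expected_cc",
        [
            (0, 1.0, 0.0),  # empty mask
            (1000, 2.0, 8.0),  # 1000 voxels x 8 mm^3
            (1000, 1.0, 1.0),  # full 10^3 grid at 1 mm
        ],
    )
    def test_volume_examples(self, n_true, spacing, expected_cc):
        g = GridGeometry((10, 10, 10), (spacing,) * 3)
        vals = np.zeros(g.shape, bool)
        vals.ravel()[:n_true] = True
        assert mask_volume_cc(BinaryMask(g, vals)) == pytest.approx(expected_cc)

    def test_additive_over_disjoint_masks(self):
        g = make_geometry(12, spacing=2.5)
        a = sphere_mask(g, (4, 4, 4), 2)
        b = sphere_mask(g, (9, 9, 9), 2)
        assert not (a.values & b.values).any()
        union = BinaryMask(g, a.values | b.values)
        assert mask_volume_cc(union) == pytest.approx(
            mask_volume_cc(a) + mask_volume_cc(b)
        )


class TestIsodoseExtraction:
    def test_uniform_prescription_gives_full_grid(self):
        g = make_geometry(6)
        mask = extract_isodose_mask(uniform_dose(g, 50.0), FractionationScheme(50, 25))
        assert mask.values.all()

    def test_zero_dose_gives_empty_mask(self):
        g = make_geometry(6)
        mask = extract_isodose_mask(uniform_dose(g, 0.0), FractionationScheme(50, 25))
        assert not mask.values.any()

    def test_threshold_is_inclusive_at_90_percent(self):
        g = GridGeometry((3, 1, 1), (1, 1, 1))
        dose = DoseGrid(g, np.array([44.9, 45.0, 45.1]).reshape(3, 1, 1))
        mask = extract_isodose_mask(dose, FractionationScheme(50, 25), 0.9)
        assert mask.values.ravel().tolist() == [False, True, True]

    def test_level_fraction_bounds(self):
        g = make_geometry(4)
        with pytest.raises(ValueError):
            extract_isodose_mask(uniform_dose(g, 1.0), FractionationScheme(50, 25), 0.0)
        with pytest.raises(ValueError):
            FractionationScheme(-50, 25)

    @settings(max_examples=25, derandomize=True, deadline=None)
    @given(st.integers(0, 10_000))
    def test_monotone_in_level(self, seed):
        g = make_geometry(8)
        rng = np.random.default_rng(seed)
        dose = DoseGrid(g, 60.0 * rng.random(g.shape))
        scheme = FractionationScheme(50, 25)
        lo = extract_isodose_mask(dose, scheme, 0.5)
        hi = extract_isodose_mask(dose, scheme, 0.9)
        # lowering the level never removes voxels
        assert np.all(lo.values | ~hi.values)


class TestEqd2:
    def test_identity_at_2gy_per_fraction(self):
        g = make_geometry(4)
        for total, n in [(50.0, 25), (30.0, 15), (2.0, 1)]:
            dose = uniform_dose(g, total)
            out = convert_to_eqd2(dose, FractionationScheme(total, n), alpha_beta=3.0)
            np.testing.assert_allclose(out.values, dose.values, rtol=1e-12)

    def test_hypofractionated_formula_value(self):
        # 40.05 Gy in 15 fractions (2.67 Gy/fx), alpha/beta 3: 40.05 * 5.67 / 5
        g = make_geometry(2)
        out = convert_to_eqd2(
            uniform_dose(g, 40.05), FractionationScheme(40.05, 15), alpha_beta=3.0
        )
        assert out.values[0, 0, 0] == pytest.approx(45.4167, abs=1e-4)

    def test_zero_dose_maps_to_zero(self):
        g = make_geometry(2)
        out = convert_to_eqd2(uniform_dose(g, 0.0), FractionationScheme(40.05, 15))
        assert np.all(out.values == 0)

    def test_strictly_increasing_in_dose(self):
        g = GridGeometry((64, 1, 1), (1, 1, 1))
        d = np.linspace(0.1, 60, 64).reshape(64, 1, 1)
        out = convert_to_eqd2(DoseGrid(g, d), FractionationScheme(50, 25)).values.ravel()
        assert np.all(np.diff(out) > 0)

    def test_commutes_with_masking(self):
        g = make_geometry(10)
        rng = np.random.default_rng(7)
        dose = DoseGrid(g, 55 * rng.random(g.shape))
        scheme = FractionationScheme(43.2, 16)
        mask = sphere_mask(g, (5, 5, 5), 3)
        full = convert_to_eqd2(dose, scheme).values[mask.values]
        restricted = convert_to_eqd2(
            DoseGrid(g, dose.values * mask.values), scheme
        ).values[mask.values]
        np.testing.assert_allclose(full, restricted, rtol=1e-12)


class TestNiftiRoundTrip:
    def test_mask_round_trip_identity(self, tmp_path):
        g = GridGeometry((8, 8, 8), (2, 2, 3), (1.5, -2.0, 10.0))
        rng = np.random.default_rng(0)
        mask = BinaryMask(g, rng.random(g.shape) > 0.5)
        back = read_volume(write_volume(mask, tmp_path / "m.nii.gz"))
        assert isinstance(back, BinaryMask)
        assert np.array_equal(back.values, mask.values)
        assert back.geometry.approx_equal(g)

    def test_dose_round_trip_preserves_spacing(self, tmp_path):
        g = GridGeometry((5, 6, 7), (2, 2, 3))
        dose = DoseGrid(g, np.float32(np.random.default_rng(1).random((5, 6, 7)) * 50))
        back = read_volume(write_volume(dose, tmp_path / "d.nii.gz"))
        assert isinstance(back, DoseGrid)
        np.testing.assert_array_equal(back.values, dose.values)
        assert back.geometry.approx_equal(g)

    def test_4d_input_rejected(self, tmp_path):
        import nibabel as nib

        img = nib.Nifti1Image(np.zeros((4, 4, 4, 2), np.float32), np.eye(4))
        nib.save(img, str(tmp_path / "vol4d.nii.gz"))
        with pytest.raises(ValueError, match="3D"):
            read_volume(tmp_path / "vol4d.nii.gz")

    def test_nan_input_rejected(self, tmp_path):
        import nibabel as nib

        data = np.zeros((4, 4, 4), np.float32)
        data[0, 0, 0] = np.nan
        nib.save(nib.Nifti1Image(data, np.eye(4)), str(tmp_path / "nan.nii.gz"))
        with pytest.raises(ValueError, match="NaN"):
            read_volume(tmp_path / "nan.nii.gz")


class TestResample:
    def test_identity_on_same_geometry(self):
        g = make_geometry(6)
        mask = sphere_mask(g, (3, 3, 3), 2)
        out = resample_nearest(mask, g)
        assert np.array_equal(out.values, mask.values)

    def test_downsampling_halves_shape(self):
        g = GridGeometry((8, 8, 8), (1, 1, 1))
        coarse = GridGeometry((4, 4, 4), (2, 2, 2))
        dose = uniform_dose(g, 10.0)
        out = resample_nearest(dose, coarse)
        assert out.geometry == coarse
        assert np.all(out.values == 10.0)
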