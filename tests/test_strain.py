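"""Strain algebra: conversions, accumulation, gradients, box statistics."""

import numpy as np
import pytest
from hypothesis import given, strategies as st_

import stretchlab as sl


class TestEngineeringStrain:
    @pytest.mark.parametrize(
        "l0, l, expected",
        [
            (2.0, 8.0, 3.0),       # 2 mm -> 8 mm grip travel = 300%
            (2.0, 5.0, 1.5),       # 2 mm + 8 x 375 um = 5 mm = 150%
            (7.3, 7.3, 0.0),
        ],
    )
    def test_length_ratio(self, l0, l, expected):
        assert sl.engineering_strain(l0, l) == pytest.approx(expected)

    def test_nonpositive_original_length_rejected(self):
        with pytest.raises(ValueError):
            sl.engineering_strain(0.0, 1.0)
        with pytest.raises(ValueError):
            sl.engineering_strain(-2.0, 1.0)


class TestTrueStrainConversion:
    @pytest.mark.parametrize(
        "eng, true",
        [(0.0, 0.0), (3.0, np.log(4.0)), (-0.19, np.log(0.81))],
    )
    def test_known_values(self, eng, true):
        assert sl.eng_to_true(eng) == pytest.approx(true, rel=1e-12)
        assert sl.true_to_eng(true) == pytest.approx(eng, rel=1e-12)

    @given(st_.floats(min_value=-0.99, max_value=10.0))
    def test_round_trip(self, x):
        assert sl.true_to_eng(sl.eng_to_true(x)) == pytest.approx(x, abs=1e-12)

    def test_annihilation_rejected(self):
        with pytest.raises(ValueError):
            sl.eng_to_true(-1.0)
        with pytest.raises(ValueError):
            sl.eng_to_true(np.array([0.1, -1.2]))


class TestAccumulate:
    def test_two_ten_percent_steps(self):
        assert sl.accumulate([0.1, 0.1]) == pytest.approx(0.21, abs=1e-12)

    def test_empty_is_identity(self):
        assert sl.accumulate([]) == 0.0

    def test_zero_steps(self):
        assert sl.accumulate([0.0] * 7) == pytest.approx(0.0, abs=1e-15)

    def test_grip_schedule_telescopes_to_150_percent(self):
        lengths = 2000.0 + 375.0 * np.arange(9)
        steps = np.diff(lengths) / lengths[:-1]
        assert sl.accumulate(steps) == pytest.approx(1.5, abs=1e-12)

    @given(
        st_.lists(st_.floats(min_value=-0.5, max_value=0.5), min_size=1,
                  max_size=50)
    )
    def test_matches_product_oracle(self, steps):
        oracle = np.prod([1.0 + s for s in steps]) - 1.0
        assert sl.accumulate(steps) == pytest.approx(oracle, abs=1e-12)

    @given(st_.integers(min_value=1, max_value=20))
    def test_substep_path_consistency(self, k):
        # uniform stretch split into k equal sub-steps composes to the
        # single-step strain of the total length change
        total = 0.8
        sub = (1.0 + total) ** (1.0 / k) - 1.0
        assert sl.accumulate([sub] * k) == pytest.approx(total, abs=1e-9)

    def test_step_at_or_below_minus_one_rejected(self):
        with pytest.raises(ValueError):
            sl.accumulate([0.2, -1.0])

    def test_pixelwise_propagates_invalid(self):
        a = np.array([[0.1, np.nan], [0.1, 0.1]])
        b = np.array([[0.1, 0.1], [np.nan, 0.1]])
        out = sl.accumulate([a, b])
        assert out[0, 0] == pytest.approx(0.21)
        assert np.isnan(out[0, 1]) and np.isnan(out[1, 0])


class TestStrainRate:
    def test_zero_strain(self):
        assert sl.strain_rate(0.0, 30.0) == 0.0

    def test_order_of_magnitude_of_slow_stretch(self):
        # cumulative 0.73 over 60 min -> ~1.2e-2 per min
        assert sl.strain_rate(0.73, 60.0) == pytest.approx(0.01217, abs=5e-5)

    def test_stepped_protocol_rate(self):
        assert sl.strain_rate(1.5, 16.0) == pytest.approx(0.09375)

    def test_nonpositive_elapsed_rejected(self):
        with pytest.raises(ValueError):
            sl.strain_rate(0.5, 0.0)


class TestStrainFromDisplacement:
    def test_rigid_translation_has_zero_strain(self):
        d = sl.DisplacementField(np.full((12, 12), 3.7), np.full((12, 12), -1.2))
        f = sl.strain_from_displacement(d)
        for comp in ("xx", "yy", "xy"):
            assert np.nanmax(np.abs(f.component(comp))) < 1e-12

    def test_uniaxial_gradient(self, affine_displacement):
        f = sl.strain_from_displacement(
            affine_displacement((16, 16), ux=(0.0, 0.1, 0.0)))
        assert np.nanmax(np.abs(f.eps_xx - 0.1)) < 1e-12
        assert np.nanmax(np.abs(f.eps_yy)) < 1e-12
        assert np.nanmax(np.abs(f.eps_xy)) < 1e-12

    def test_simple_shear(self, affine_displacement):
        f = sl.strain_from_displacement(
            affine_displacement((16, 16), ux=(0.0, 0.0, 0.2)))
        assert np.nanmax(np.abs(f.eps_xy - 0.1)) < 1e-12
        assert np.nanmax(np.abs(f.eps_xx)) < 1e-12

    @given(st_.tuples(*[st_.floats(-0.5, 0.5) for _ in range(6)]))
    def test_affine_fields_recovered_exactly(self, affine_displacement, coeffs):
        a, b, c, d, e, g = coeffs
        f = sl.strain_from_displacement(
            affine_displacement((10, 14), ux=(a, b, c), vy=(d, e, g)))
        assert np.nanmax(np.abs(f.eps_xx - b)) < 1e-9
        assert np.nanmax(np.abs(f.eps_yy - g)) < 1e-9
        assert np.nanmax(np.abs(f.eps_xy - 0.5 * (c + e))) < 1e-9

    def test_border_policy_invalid(self, affine_displacement):
        f = sl.strain_from_displacement(
            affine_displacement((8, 8), ux=(0, 0.1, 0)), boundary="invalid")
        assert not f.valid[0].any() and not f.valid[:, 0].any()
        assert f.valid[1:-1, 1:-1].all()

    def test_all_invalid_input_gives_all_invalid_output(self):
        d = sl.DisplacementField(np.zeros((6, 6)), np.zeros((6, 6)),
                                 valid=np.zeros((6, 6), bool))
        f = sl.strain_from_displacement(d)
        assert not f.valid.any()

    def test_window_larger_than_image_rejected(self):
        d = sl.DisplacementField.zeros((5, 5))
        with pytest.raises(ValueError):
            sl.strain_from_displacement(d, window=7)

    def test_even_window_rejected(self):
        with pytest.raises(ValueError):
            sl.strain_from_displacement(sl.DisplacementField.zeros((8, 8)),
                                        window=4)


class TestAccumulateFields:
    def test_composes_like_scalars_and_intersects_validity(self):
        xx = np.full((6, 6), 0.1)
        step = sl.StrainField(xx, -0.02 * np.ones_like(xx), np.zeros_like(xx))
        bad = np.ones((6, 6), bool)
        bad[2, 3] = False
        step2 = sl.StrainField(xx, -0.02 * np.ones_like(xx),
                               np.zeros_like(xx), valid=bad)
        cum = sl.accumulate_fields([step, step2])
        assert cum.kind == "cum_eng"
        assert cum.eps_xx[0, 0] == pytest.approx(0.21)
        assert not cum.valid[2, 3]
        assert np.isnan(cum.eps_xx[2, 3])


class TestBoxStats:
    def test_400x400_field_yields_400_boxes(self):
        stats = sl.box_stats(np.zeros((400, 400)), box=20)
        assert stats.n_boxes == 400

    def test_constant_field(self):
        stats = sl.box_stats(np.full((40, 40), 3.14), box=20)
        assert np.allclose(stats.means, 3.14)
        assert np.allclose(stats.sds, 0.0)
        assert stats.global_sd == 0.0

    def test_half_and_half_field(self):
        field = np.zeros((40, 40))
        field[:, 20:] = 1.0
        stats = sl.box_stats(field, box=20)
        assert sorted(stats.means.ravel()) == [0.0, 0.0, 1.0, 1.0]
        assert stats.global_mean == pytest.approx(0.5)

    def test_mean_of_box_means_equals_global_mean_for_exact_tiling(self, rng):
        field = rng.normal(size=(60, 80))
        stats = sl.box_stats(field, box=20)
        assert stats.global_mean == pytest.approx(field.mean(), abs=1e-12)

    def test_partial_tiles_dropped_with_warning(self, caplog):
        import logging

        with caplog.at_level(logging.WARNING, logger="stretchlab.strain"):
            stats = sl.box_stats(np.zeros((45, 45)), box=20)
        assert stats.n_boxes == 4
        assert any("partial" in r.message for r in caplog.records)

    def test_oversized_box_rejected(self):
        with pytest.raises(ValueError):
            sl.box_stats(np.zeros((30, 30)), box=40)


class TestStrainSeries:
    def test_scalar_series_rates(self):
        s = sl.StrainSeries(steps=[0.1] * 4, times=[0.0, 2.0, 4.0, 6.0, 8.0])
        assert s.cumulative() == pytest.approx(1.1 ** 4 - 1)
        rates = s.rates()
        assert rates[0] == pytest.approx(0.1 / 2.0)
        assert rates[-1] == pytest.approx((1.1 ** 4 - 1) / 8.0)
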