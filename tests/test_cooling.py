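import numpy as np
import pandas as pd
import pytest

import greencool as gc
from greencool.cooling import large_green_patches

from _bruteforce import brute_heat_mitigation


def _stations(day_temps):
    """Long station table from {date: [per-station temps]}."""
    rows = [(pd.Timestamp(d), s, t)
            for d, temps in day_temps.items() for s, t in enumerate(temps)]
    return pd.DataFrame(rows, columns=["date", "station_id", "temp_21h_c"])


class TestHargreaves:
    def test_zero_diurnal_range(self):
        assert gc.hargreaves_et0(20, 20, 20, 12) == 0.0

    def test_worked_example(self):
        # 0.0023 * 12 * (22.2 + 17.8) * sqrt(30 - 15)
        assert gc.hargreaves_et0(15, 22.2, 30, 12) == pytest.approx(4.2758, abs=1e-3)

    def test_vanishing_temperature_factor(self):
        assert gc.hargreaves_et0(-20, -17.8, -10, 12) == 0.0

    def test_inverted_day_rejected(self):
        with pytest.raises(ValueError):
            gc.hargreaves_et0(25, 22, 20, 12)


class TestReferenceDay:
    def test_single_day_mirror(self):
        st = _stations({"2018-07-27": [20.60, 28.08]})
        day, t_ref, uhi = gc.select_reference_day(st)
        assert day == pd.Timestamp("2018-07-27")
        assert t_ref == pytest.approx(20.60)
        assert uhi == pytest.approx(7.48)

    def test_admissibility_beats_spread(self):
        # day B has the bigger spread but an inadmissible T_ref
        st = _stations({"2018-07-01": [21.0, 26.0], "2018-07-02": [19.0, 28.0]})
        day, t_ref, uhi = gc.select_reference_day(st)
        assert day == pd.Timestamp("2018-07-01")
        assert (t_ref, uhi) == (pytest.approx(21.0), pytest.approx(5.0))

    def test_identical_stations_zero_uhi(self):
        st = _stations({"2018-07-01": [22.0, 22.0, 22.0]})
        _, _, uhi = gc.select_reference_day(st)
        assert uhi == 0.0

    def test_no_admissible_day(self):
        st = _stations({"2018-07-01": [15.0, 25.0]})
        with pytest.raises(ValueError, match="no day"):
            gc.select_reference_day(st)

    def test_single_station_rejected(self):
        st = _stations({"2018-07-01": [21.0]})
        with pytest.raises(ValueError, match="two stations"):
            gc.select_reference_day(st)


class TestCoolingCapacity:
    def test_convex_combination_bounds(self):
        assert gc.cooling_capacity(1, 1, 1) == pytest.approx(1.0)
        assert gc.cooling_capacity(0, 0, 0) == 0.0

    def test_worked_example(self):
        assert gc.cooling_capacity(0.875, 0.20, 0.5) == pytest.approx(0.665)

    def test_invalid_weights(self):
        with pytest.raises(ValueError):
            gc.cooling_capacity(0.5, 0.5, 0.5, weights=(0.5, 0.5, 0.5))

    def test_eti_clipping(self):
        assert gc.evapotranspiration_index(1.2, 10.0, 5.0) == 1.0
        assert gc.evapotranspiration_index(0.5, 4.0, 8.0) == pytest.approx(0.25)


PARAMS = gc.ClimateParams(t_ref=20.6, uhi_max=7.48, d_cool=30.0,
                          green_area_min_ha=0.04, r_mix=60.0)


class TestHeatMitigation:
    def test_no_green_identity(self):
        cc = np.random.default_rng(0).uniform(0, 1, (8, 8))
        hm = gc.heat_mitigation(cc, np.zeros((8, 8), dtype=bool), 10.0, PARAMS)
        np.testing.assert_array_equal(hm, cc)

    def test_uniform_large_patch_fixed_point(self):
        cc = np.full((10, 10), 0.9)
        green = np.ones((10, 10), dtype=bool)
        hm = gc.heat_mitigation(cc, green, 10.0, PARAMS)
        np.testing.assert_allclose(hm, 0.9)

    def test_small_patches_have_no_park_effect(self):
        cc = np.zeros((9, 9))
        green = np.zeros((9, 9), dtype=bool)
        green[4, 4] = True  # 0.01 ha < threshold
        cc[4, 4] = 1.0
        params = gc.ClimateParams(t_ref=20, uhi_max=5, d_cool=30.0,
                                  green_area_min_ha=0.04)
        hm = gc.heat_mitigation(cc, green, 10.0, params)
        np.testing.assert_array_equal(hm, cc)

    def test_beyond_cooling_distance_unaffected(self):
        cc = np.zeros((1, 30))
        cc[0, :2] = 0.9
        green = np.zeros((1, 30), dtype=bool)
        green[0, :2] = True
        params = gc.ClimateParams(t_ref=20, uhi_max=5, d_cool=30.0,
                                  green_area_min_ha=0.001)
        hm = gc.heat_mitigation(cc, green, 10.0, params)
        assert hm[0, 3] > 0          # within 30 m of the patch
        assert hm[0, 10] == 0.0      # far beyond d_cool

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_all_pairs_brute_force(self, seed):
        """Convolution-based park effect equals the explicit double loop."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(8, 21))
        cc = rng.uniform(0, 1, (n, n))
        green = rng.random((n, n)) < 0.3
        params = gc.ClimateParams(t_ref=20, uhi_max=5, d_cool=35.0,
                                  green_area_min_ha=0.03)
        hm = gc.heat_mitigation(cc, green, 10.0, params)
        ref = brute_heat_mitigation(cc.tolist(), green.tolist(), 10.0,
                                    params.d_cool, params.green_area_min_ha)
        np.testing.assert_allclose(hm, np.array(ref), atol=1e-9)

    def test_large_green_patch_threshold(self):
        green = np.zeros((10, 10), dtype=bool)
        green[:2, :10] = True  # 20 cells = 0.2 ha at 10 m
        big = large_green_patches(green, 10.0, 0.2)
        assert big.sum() == 20
        assert large_green_patches(green, 10.0, 0.21).sum() == 0


class TestTemperatureMap:
    def test_full_mitigation_gives_reference_temperature(self):
        field = gc.temperature_map(np.ones((12, 12)), PARAMS)
        np.testing.assert_allclose(field.t_air, PARAMS.t_ref)

    def test_zero_mitigation_gives_maximum_uhi(self):
        params = gc.ClimateParams(t_ref=20.60, uhi_max=7.48)
        field = gc.temperature_map(np.zeros((12, 12)), params)
        np.testing.assert_allclose(field.t_air, 28.08)

    def test_blending_preserves_uniform_fields(self):
        field = gc.temperature_map(np.full((15, 15), 0.37), PARAMS)
        np.testing.assert_allclose(field.t_air, field.t_air[0, 0])

    def test_bounds_hold_for_random_fields(self):
        hm = np.random.default_rng(3).uniform(0, 1, (20, 20))
        field = gc.temperature_map(hm, PARAMS)
        assert (field.t_air >= PARAMS.t_ref - 1e-9).all()
        assert (field.t_air <= PARAMS.t_ref + PARAMS.uhi_max + 1e-9).all()


class TestSimulate:
    def test_uniform_water_grid_is_spatially_uniform(self):
        bp = gc.CityBlueprint(side_m=200, class_mix={"water": 1.0})
        lulc = gc.make_lulc(bp)
        tree, bld = gc.make_masks(lulc, bp)
        covers = gc.CoverFractions(gc.cover_fractions(tree, 10),
                                   gc.cover_fractions(bld, 10))
        ref = gc.refine_lulc(lulc, covers)
        bio = gc.build_biophysical_table(ref)
        field = gc.simulate(ref, bio, 4.0, PARAMS)
        np.testing.assert_allclose(field.t_air, field.t_air[0, 0])

    def test_missing_code_rejected(self, small_inputs):
        bio = small_inputs.biophys.iloc[:3]
        with pytest.raises(ValueError, match="missing"):
            gc.simulate(small_inputs.refined, bio, 4.0, small_inputs.params)

    def test_greening_never_warms_any_pixel(self, small_inputs):
        """Raising tree cover increases shade only, so air temperature is
        pixel-wise non-increasing."""
        ref = small_inputs.refined
        cands = gc.find_candidates(ref)
        base = gc.simulate(ref, small_inputs.biophys, small_inputs.et0,
                           small_inputs.params)
        for p in (0.25, 1.0):
            px = cands.pixels[: round(p * cands.total_count)]
            scen = gc.apply_scenario(ref, px)
            field = gc.simulate(scen, small_inputs.biophys, small_inputs.et0,
                                small_inputs.params)
            assert (field.t_air <= base.t_air + 1e-9).all()
            assert field.t_mean <= base.t_mean

    def test_temperature_bounds_invariant(self, small_inputs):
        field = gc.simulate(small_inputs.refined, small_inputs.biophys,
                            small_inputs.et0, small_inputs.params)
        p = small_inputs.params
        assert (field.t_air >= p.t_ref - 1e-9).all()
        assert (field.t_air <= p.t_ref + p.uhi_max + 1e-9).all()
        assert 0 <= field.hm.min() and field.hm.max() <= 1
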