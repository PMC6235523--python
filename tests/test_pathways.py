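"""Unit and property tests for the 21 pathway estimators."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ncskit.core import C_TO_CO2, GWPSet, SGWP_TIDAL
from ncskit.grids import LAND_COVER_CODES, LandscapeGrid
from ncskit.pathways import (
    BiocharParams,
    FireRegimeParams,
    NutrientParams,
    ReforestationConfig,
    RotationParams,
    avoided_forest_conversion,
    avoided_grassland_conversion,
    biochar_mitigation,
    calibrate_response_exponent,
    fire_management_benefit,
    grassland_per_ha_emissions,
    nutrient_cascade,
    nutrient_management,
    reforestation_eligible_area,
    reforestation_mitigation,
    root_biomass_from_climate,
    rotation_extension_gain,
    scalar_pathway,
    seagrass_avoided_loss,
    seagrass_restoration,
    tidal_wetland_restoration,
)


def _make_grid(land_cover, tree_cover=None, masks=None, cell_area=100.0):
    land_cover = np.asarray(land_cover)
    shape = land_cover.shape
    if tree_cover is None:
        tree_cover = np.zeros(shape)
    base_masks = {
        name: np.zeros(shape, dtype=bool)
        for name in ("urban", "impervious", "major_road", "histosol")
    }
    if masks:
        base_masks.update(masks)
    return LandscapeGrid(
        cell_area=cell_area,
        land_cover=land_cover,
        tree_cover=np.asarray(tree_cover, dtype=float),
        soil_c_1m=np.full(shape, 100.0),
        mat=np.full(shape, 10.0),
        map_mm=np.full(shape, 800.0),
        conifer_frac=np.zeros(shape),
        masks=base_masks,
    )


class TestReforestationEligibility:
    def test_all_urban_grid_is_fully_excluded(self):
        grid = _make_grid(np.full((5, 5), LAND_COVER_CODES["urban"]))
        assert reforestation_eligible_area(grid) == 0.0

    def test_matches_brute_force_cell_enumeration(self, toy_landscape):
        cfg = ReforestationConfig()
        fast = reforestation_eligible_area(toy_landscape, cfg)
        eligible_codes = {LAND_COVER_CODES[c] for c in cfg.native_forest_classes}
        count = 0
        nrows, ncols = toy_landscape.shape
        for i in range(nrows):
            for j in range(ncols):
                if toy_landscape.land_cover[i, j] not in eligible_codes:
                    continue
                if toy_landscape.tree_cover[i, j] >= cfg.tree_cover_threshold:
                    continue
                if any(
                    toy_landscape.masks[m][i, j] for m in cfg.exclusion_masks
                ):
                    continue
                count += 1
        assert fast == pytest.approx(count * toy_landscape.cell_area / 1e6)

    def test_adding_histosol_mask_removes_cells(self):
        lc = np.full((10, 10), LAND_COVER_CODES["forest"])
        tc = np.zeros((10, 10))
        tc[0, :3] = 80.0  # 3 cells above threshold -> 97 eligible
        grid = _make_grid(lc, tc)
        base = reforestation_eligible_area(grid)
        assert base == pytest.approx(97 * 100.0 / 1e6)
        histosol = np.zeros((10, 10), dtype=bool)
        histosol[5, :5] = True  # 5 eligible cells removed
        grid2 = _make_grid(lc, tc, masks={"histosol": histosol})
        assert reforestation_eligible_area(grid2) == pytest.approx(92 * 100.0 / 1e6)

    def test_missing_mask_layer_error_names_layer(self):
        grid = _make_grid(np.full((3, 3), LAND_COVER_CODES["forest"]))
        del grid.masks["histosol"]
        with pytest.raises(ValueError, match="histosol"):
            reforestation_eligible_area(grid)

    def test_released_cropland_capped(self):
        lc = np.full((10, 10), LAND_COVER_CODES["cropland"])
        grid = _make_grid(lc)
        assert reforestation_eligible_area(grid) == 0.0  # cropland retained
        cfg = ReforestationConfig(retain_cropland=False, released_cropland_mha=0.0005)
        assert reforestation_eligible_area(grid, cfg) == pytest.approx(0.0005)


class TestReforestationMitigation:
    def test_no_conifer_is_plain_area_times_rate(self):
        est = reforestation_mitigation(10.0, 5.0, conifer_frac=0.0, albedo_discount=0.5)
        assert est.mean == pytest.approx(50.0)

    def test_albedo_discount_hand_value(self):
        est = reforestation_mitigation(10.0, 10.0, conifer_frac=0.5, albedo_discount=0.2)
        assert est.mean == pytest.approx(90.0)

    def test_discount_strictly_reduces_the_undiscounted_product(self):
        undiscounted = reforestation_mitigation(51.6, 307.0 / 51.6).mean
        discounted = reforestation_mitigation(
            51.6, 307.0 / 51.6, conifer_frac=0.4, albedo_discount=0.15
        ).mean
        assert undiscounted == pytest.approx(307.0)
        assert discounted < undiscounted

    def test_discount_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            reforestation_mitigation(1.0, 1.0, albedo_discount=1.5)


def _fire_oracle(p: FireRegimeParams) -> float:
    """Independent event-by-event cohort enumeration."""
    benefits = []
    cohort_years: list[int] = []
    cohort_areas: list[float] = []
    for year in range(1, p.horizon + 1):
        protected_area = sum(
            a
            for ty, a in zip(cohort_years, cohort_areas)
            if year - ty < p.protection_years
        )
        newly = min(p.treat_frac_per_yr * p.treatable_area, p.treatable_area - protected_area)
        cohort_years.append(year)
        cohort_areas.append(newly)
        avoided = 0.0
        for ty, a in zip(cohort_years, cohort_areas):
            if 0 <= year - ty < p.protection_years:
                avoided += p.wildfire_annual_prob * a * p.wildfire_emission
        benefits.append(avoided - newly * p.rx_emission)
    return sum(benefits) / p.horizon


class TestFireManagement:
    def test_no_wildfire_means_pure_treatment_cost(self):
        p = FireRegimeParams(
            treatable_area=10.0, treat_frac_per_yr=0.05, wildfire_annual_prob=0.0,
            rx_emission=4.0,
        )
        benefit = fire_management_benefit(p)
        assert benefit == pytest.approx(-0.05 * 10.0 * 4.0)
        assert benefit < 0

    def test_full_protection_limit(self):
        p = FireRegimeParams(
            treatable_area=10.0,
            treat_frac_per_yr=1.0,
            protection_years=30,
            horizon=20,
            rx_emission=0.0,
            wildfire_annual_prob=1.0,
            wildfire_emission=2.0,
        )
        # everything treated in year 1 and protected for the whole horizon
        assert fire_management_benefit(p) == pytest.approx(10.0 * 2.0)

    def test_default_regime_average_annual_benefit(self):
        assert fire_management_benefit(FireRegimeParams()) == pytest.approx(18.0)

    @given(
        treat_frac=st.floats(min_value=0.0, max_value=1.0),
        protection=st.integers(min_value=1, max_value=30),
        horizon=st.integers(min_value=1, max_value=30),
        prob=st.floats(min_value=0.0, max_value=1.0),
        rx=st.floats(min_value=0.0, max_value=50.0),
        wf=st.floats(min_value=0.0, max_value=200.0),
    )
    def test_agrees_with_cohort_enumeration_oracle(
        self, treat_frac, protection, horizon, prob, rx, wf
    ):
        p = FireRegimeParams(
            treatable_area=20.0,
            treat_frac_per_yr=treat_frac,
            protection_years=protection,
            horizon=horizon,
            rx_emission=rx,
            wildfire_annual_prob=prob,
            wildfire_emission=wf,
        )
        assert fire_management_benefit(p) == pytest.approx(_fire_oracle(p), abs=1e-9)

    def test_stochastic_mode_matches_expectation(self):
        p = FireRegimeParams()
        rng = np.random.default_rng(42)
        draws = [fire_management_benefit(p, rng=rng, n_units=400) for _ in range(60)]
        assert np.mean(draws) == pytest.approx(18.0, rel=0.05)

    def test_invalid_horizon_rejected(self):
        with pytest.raises(ValueError):
            FireRegimeParams(horizon=0)


class TestAvoidedConversion:
    def test_forest_all_clearing_regenerates(self):
        assert avoided_forest_conversion(0.5, 0.0, 200.0).mean == 0.0

    def test_forest_hand_value(self):
        assert avoided_forest_conversion(0.5, 0.4, 200.0).mean == pytest.approx(40.0)

    def test_forest_soil_pool_always_excluded(self):
        est = avoided_forest_conversion(1.3, 0.7, 150.0, conifer_frac=0.3,
                                        albedo_discount=0.1)
        assert est.by_pool["soil"] == 0.0
        assert est.by_pool["biomass"] == pytest.approx(est.mean)

    def test_grassland_soil_term_from_spec_stock(self):
        soil_term, _ = grassland_per_ha_emissions(soil_stock=121.9, root_c=0.0)
        assert soil_term == pytest.approx(125.1, abs=0.1)

    def test_grassland_default_soil_share(self):
        soil_term, total = grassland_per_ha_emissions()
        assert soil_term == pytest.approx(125.0, abs=1e-9)
        assert soil_term / total == pytest.approx(0.81, abs=0.005)

    def test_grassland_zero_area(self):
        assert avoided_grassland_conversion(0.0).mean == 0.0

    def test_grassland_pool_decomposition_matches_shares(self):
        est = avoided_grassland_conversion(0.6934)
        assert est.by_pool["soil"] / est.mean == pytest.approx(0.81, abs=0.005)


class TestRootBiomass:
    def test_intercept_only(self):
        coeffs = {"c0": 5.0, "c_mat": 0.0, "c_map": 0.0}
        assert root_biomass_from_climate(25.0, 100.0, coeffs) == 5.0

    def test_linear_hand_value(self):
        coeffs = {"c0": 1.0, "c_mat": 0.1, "c_map": 0.001}
        assert root_biomass_from_climate(10.0, 500.0, coeffs) == pytest.approx(2.5)

    def test_negative_prediction_clamped(self):
        coeffs = {"c0": -10.0, "c_mat": 0.0, "c_map": 0.0}
        assert root_biomass_from_climate(0.0, 0.0, coeffs) == 0.0

    def test_missing_coefficient_rejected(self):
        with pytest.raises(ValueError, match="c_map"):
            root_biomass_from_climate(0.0, 0.0, {"c0": 1.0, "c_mat": 0.1})


class TestNutrientManagement:
    def test_zero_reduction_zero_mitigation(self):
        p = NutrientParams(rate_reduction=0.0)
        assert nutrient_management(p).mean == 0.0

    def test_default_cascade_reproduces_22_33_29(self):
        c = nutrient_cascade(NutrientParams())
        assert round(100 * c.n_reduction) == 22
        assert round(100 * c.field_reduction) == 33
        assert round(100 * c.combined_reduction) == 29
        assert c.field_reduction == pytest.approx(0.33, abs=1e-9)

    def test_combined_is_emission_weighted_mean_at_7_to_4(self):
        # one-unknown oracle: w*0.33 + (1-w)*0.22 = 0.29 -> w = 7/11
        w = (0.29 - 0.22) / (0.33 - 0.22)
        assert w == pytest.approx(7.0 / 11.0)
        c = nutrient_cascade(NutrientParams())
        assert c.combined_reduction == pytest.approx(
            w * c.field_reduction + (1 - w) * c.upstream_reduction
        )

    def test_linear_response_gives_smaller_field_cut(self):
        c = nutrient_cascade(NutrientParams(response="linear"))
        assert c.field_reduction == pytest.approx(0.22)
        assert c.field_reduction < 0.33

    def test_default_mitigation_total(self):
        assert nutrient_management().mean == pytest.approx(52.0)

    def test_calibration_is_exact_root(self):
        k = calibrate_response_exponent(0.22, 0.33)
        assert 1.0 - (1.0 - 0.22) ** k == pytest.approx(0.33, abs=1e-9)


class TestBiochar:
    def test_zero_permanence(self):
        assert biochar_mitigation(BiocharParams(permanence=0.0)).mean == 0.0

    def test_hand_chain_product(self):
        est = biochar_mitigation(
            BiocharParams(residue_mass=100.0, char_yield=0.3, char_c_frac=0.7,
                          permanence=0.796)
        )
        assert est.mean == pytest.approx(100 * 0.3 * 0.7 * 0.796 * C_TO_CO2, abs=1e-9)
        assert est.mean == pytest.approx(61.3, abs=0.05)

    def test_no_ch4_or_n2o_terms(self):
        est = biochar_mitigation()
        assert est.by_gas.ch4 == 0.0 and est.by_gas.n2o == 0.0


class TestBlueCarbon:
    def test_tidal_zero_freshened(self):
        assert tidal_wetland_restoration(1.7, freshened_frac=0.0).mean == 0.0

    def test_tidal_default_reproduces_largest_wetland_pathway(self):
        assert tidal_wetland_restoration(1.7).mean == pytest.approx(12.0)

    def test_tidal_linear_in_gwp_factor(self):
        base = tidal_wetland_restoration(1.7, gwp=SGWP_TIDAL).mean
        doubled = tidal_wetland_restoration(
            1.7, gwp=GWPSet(2 * SGWP_TIDAL.ch4_factor, SGWP_TIDAL.n2o_factor)
        ).mean
        assert doubled == pytest.approx(2 * base)

    def test_tidal_pool_is_avoided_gas(self):
        est = tidal_wetland_restoration(1.7)
        assert est.by_pool["avoided_ch4_n2o"] == pytest.approx(est.mean)

    def test_seagrass_loss_zero_release(self):
        assert seagrass_avoided_loss(1.0, release_frac=0.0).mean == 0.0

    def test_seagrass_loss_hand_value(self):
        est = seagrass_avoided_loss(1.0, 0.015, 100.0, 0.5)
        assert est.mean == pytest.approx(2.75, abs=0.001)

    def test_seagrass_loss_linear_in_loss_rate(self):
        full = seagrass_avoided_loss(1.0, 0.015, 100.0, 0.5).mean
        half = seagrass_avoided_loss(1.0, 0.0075, 100.0, 0.5).mean
        assert half == pytest.approx(full / 2)

    def test_seagrass_restoration_zero_frac_override(self):
        assert seagrass_restoration(1.0, 1.0, restorable_frac=0.0).mean == 0.0

    def test_seagrass_restoration_ci_brackets_midpoint_mean(self):
        est = seagrass_restoration(1.35, 0.74)
        lo, hi = est.ci
        assert lo < est.mean < hi
        assert lo == pytest.approx(est.mean * 0.29 / 0.405)
        assert hi == pytest.approx(est.mean * 0.52 / 0.405)

    def test_seagrass_restoration_hand_value(self):
        est = seagrass_restoration(1.0, 1.0, restorable_frac=0.29)
        assert est.mean == pytest.approx(0.29 * C_TO_CO2, abs=1e-9)
        assert est.mean == pytest.approx(1.063, abs=0.001)


def _toy_curve():
    # logistic-like stand carbon, tabulated at 5-year steps
    ages = np.arange(5, 105, 5)
    stocks = 150.0 / (1.0 + np.exp(-(ages - 35) / 12.0))
    return tuple(zip(ages.tolist(), stocks.tolist()))


class TestRotationExtension:
    def test_zero_gain_when_econ_equals_biological(self):
        curve = _toy_curve()
        ages = np.array([a for a, _ in curve])
        mai = np.array([c for _, c in curve]) / ages
        t_bio = float(ages[np.argmax(mai)])
        p = RotationParams(growth_curve=curve, econ_rotation=t_bio, area=1.0)
        assert rotation_extension_gain(p).mean == pytest.approx(0.0, abs=1e-12)

    def test_biological_rotation_matches_exhaustive_argmax(self):
        curve = _toy_curve()
        best_age, best_mai = max(
            ((a, c / a) for a, c in curve), key=lambda t: t[1]
        )
        p = RotationParams(growth_curve=curve, econ_rotation=25.0, area=2.0)
        est = rotation_extension_gain(p)
        c_econ = dict(curve)[25.0]
        expected = 2.0 * (best_mai - c_econ / 25.0) * C_TO_CO2
        assert est.mean == pytest.approx(expected)

    def test_earlier_econ_harvest_never_decreases_gain(self):
        curve = _toy_curve()
        gains = [
            rotation_extension_gain(
                RotationParams(growth_curve=curve, econ_rotation=t, area=1.0)
            ).mean
            for t in (45.0, 35.0, 25.0, 15.0)
        ]
        assert all(b >= a - 1e-12 for a, b in zip(gains, gains[1:]))
        assert all(g >= 0.0 for g in gains)

    def test_econ_rotation_outside_curve_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            rotation_extension_gain(
                RotationParams(growth_curve=_toy_curve(), econ_rotation=200.0, area=1.0)
            )


class TestScalarPathways:
    @pytest.mark.parametrize(
        "pid, extent, rate, expected",
        [
            ("grassland_restoration", 2.1, 0.0, 0.0),
            ("peatland_restoration", 1.0, 8.2, 8.2),
            ("windbreaks", 0.88, 5.0 / 0.88, 5.0),
        ],
    )
    def test_examples(self, pid, extent, rate, expected):
        assert scalar_pathway(pid, extent, rate).mean == pytest.approx(expected)

    def test_unknown_id_error_lists_valid_ids(self):
        with pytest.raises(ValueError, match="reforestation"):
            scalar_pathway("no_such_pathway", 1.0, 1.0)

    @given(
        k=st.floats(min_value=0.0, max_value=50.0),
        extent=st.floats(min_value=0.0, max_value=100.0),
        rate=st.floats(min_value=-20.0, max_value=20.0),
    )
    @settings(max_examples=30)
    def test_every_estimator_is_degree_one_in_extent(self, k, extent, rate):
        pairs = [
            scalar_pathway("cover_crops", extent, abs(rate)).mean,
            reforestation_mitigation(extent, abs(rate), 0.3, 0.1).mean,
            avoided_forest_conversion(extent, 0.4, abs(rate)).mean,
            avoided_grassland_conversion(extent).mean,
            seagrass_avoided_loss(extent, 0.015, abs(rate), 0.5).mean,
            tidal_wetland_restoration(extent).mean,
        ]
        scaled = [
            scalar_pathway("cover_crops", k * extent, abs(rate)).mean,
            reforestation_mitigation(k * extent, abs(rate), 0.3, 0.1).mean,
            avoided_forest_conversion(k * extent, 0.4, abs(rate)).mean,
            avoided_grassland_conversion(k * extent).mean,
            seagrass_avoided_loss(k * extent, 0.015, abs(rate), 0.5).mean,
            tidal_wetland_restoration(k * extent).mean,
        ]
        for base, big in zip(pairs, scaled):
            assert big == pytest.approx(k * base, rel=1e-9, abs=1e-9)
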