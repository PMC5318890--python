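"""Synthetic survey generator: design, determinism, marginals, responses."""

import numpy as np
import pandas as pd
import pytest

from lakehealth.errors import ConfigurationError, ValidationError
from lakehealth.synthetic import (Component, GroupResponse, LakeDesign,
                                  ResponseSpec, VariableSpec, apply_censoring,
                                  generate_abiotic, generate_plankton,
                                  generate_stations, linear, ramp, saturating,
                                  taihu_design, taihu_lods,
                                  taihu_response_spec, taihu_variable_specs)


class TestDesign:
    def test_survey_design_row_count(self, abiotic_396):
        assert len(abiotic_396) == 396
        assert abiotic_396["site_id"].nunique() == 33
        assert sorted(abiotic_396["month"].unique()) == list(range(1, 13))

    def test_default_design_station_counts(self):
        d = taihu_design()
        assert d.n_stations == 33
        assert d.months == 12
        assert dict(d.sub_regions)["CZ"] == 6

    def test_minimal_design_single_row(self):
        d = LakeDesign(sub_regions=(("A", 1),), months=1)
        table = generate_abiotic(d, [VariableSpec("WTEMP", 15, 5, 0, 30)], seed=0)
        assert len(table) == 1

    @pytest.mark.parametrize("kwargs", [
        {"sub_regions": (("A", 0),), "months": 12},
        {"sub_regions": (("A", 2),), "months": 0},
        {"sub_regions": (), "months": 12},
    ])
    def test_invalid_design_rejected(self, kwargs):
        with pytest.raises(ConfigurationError):
            LakeDesign(**kwargs)

    def test_spec_validation(self):
        with pytest.raises(ConfigurationError):
            VariableSpec("x", mean=5, sd=1, min=6, max=10)
        with pytest.raises(ConfigurationError):
            VariableSpec("x", mean=5, sd=0, min=0, max=10)
        with pytest.raises(ConfigurationError):
            VariableSpec("x", mean=5, sd=1, min=0, max=10, seasonal_amplitude=3)


class TestAbiotic:
    def test_same_seed_byte_identical(self):
        d = taihu_design()
        a = generate_abiotic(d, taihu_variable_specs(), seed=3)
        b = generate_abiotic(d, taihu_variable_specs(), seed=3)
        assert a.to_csv(index=False) == b.to_csv(index=False)

    def test_different_seed_differs(self):
        d = taihu_design()
        a = generate_abiotic(d, taihu_variable_specs(), seed=3)
        b = generate_abiotic(d, taihu_variable_specs(), seed=4)
        assert not a.equals(b)

    def test_values_within_spec_range(self, abiotic_396):
        for spec in taihu_variable_specs():
            col = abiotic_396[spec.name]
            assert col.min() >= spec.min - 1e-12
            assert col.max() <= spec.max + 1e-12

    def test_marginal_fidelity_uncensored_variables(self, abiotic_396):
        """Sample means of variables without detection limits sit within
        3 standard errors of their target means at the fixed seed."""
        for spec in taihu_variable_specs():
            if spec.lod is not None:
                continue
            se = spec.sd / np.sqrt(len(abiotic_396))
            assert abs(abiotic_396[spec.name].mean() - spec.mean) < 3 * se, spec.name

    def test_wtemp_annual_cycle(self, abiotic_396):
        monthly = abiotic_396.groupby("month")["WTEMP"].mean()
        assert monthly[8] > monthly[2] + 15  # summer far above winter
        assert monthly.idxmax() in (7, 8, 9)

    def test_seasonal_driver_induces_do_wtemp_anticorrelation(self, abiotic_396):
        r = np.corrcoef(abiotic_396["WTEMP"], abiotic_396["DO"])[0, 1]
        assert r < -0.6


class TestStations:
    def test_station_coordinates_distinct_and_deterministic(self):
        a = generate_stations(taihu_design(), seed=5)
        b = generate_stations(taihu_design(), seed=5)
        pd.testing.assert_frame_equal(a, b)
        assert a[["x", "y"]].drop_duplicates().shape[0] == 33


class TestCensoring:
    def test_zero_lod_flags_nothing(self, abiotic_396):
        cen = apply_censoring(abiotic_396, {"WTEMP": 0.0})
        assert cen.table["WTEMP_below_lod"].sum() == 0

    def test_value_equal_to_lod_is_a_detect(self):
        table = pd.DataFrame({"site_id": ["a", "b"], "month": [1, 1],
                              "X": [0.03, 0.0299]})
        cen = apply_censoring(table, {"X": 0.03})
        assert list(cen.table["X_below_lod"]) == [False, True]

    def test_heavy_nitrite_censoring_fraction(self, censored_396):
        """The nitrite spec is tuned so roughly 366/396 records fall below
        its 0.03 mg/L detection limit."""
        n_flagged = censored_396.fractions["NO2-N"] * 396
        assert abs(n_flagged - 366) < 25

    def test_truth_retained_for_flagged_records(self, censored_396):
        t = censored_396.table
        for var, lod in taihu_lods().items():
            flags = t[f"{var}_below_lod"]
            assert t.loc[flags, var].isna().all()
            truth_vals = censored_396.truth.loc[flags, var]
            assert (truth_vals < lod).all()

    def test_unknown_variable_lod_rejected(self, abiotic_396):
        with pytest.raises(ConfigurationError):
            apply_censoring(abiotic_396, {"nope": 0.1})


class TestPlankton:
    def _constant_table(self, n=5, wtemp=20.0):
        return pd.DataFrame({
            "site_id": [f"S{i}" for i in range(n)], "month": 1,
            "WTEMP": wtemp, "PO4-P": 0.02, "pH": 8.42, "TSS": 61.36})

    def test_zero_noise_constant_drivers_identical_biomass(self):
        resp = taihu_response_spec(noise_sd=0.0)
        pl = generate_plankton(self._constant_table(), resp, seed=0)
        for _, grp in pl.groupby("group"):
            assert grp["wet_biomass_mg_per_L"].nunique() == 1

    def test_temperature_ramp_raises_biomass(self):
        """A ramp component with threshold at 16 degC gives strictly larger
        biomass at 25 degC than at 10 degC; the expected log gap equals the
        configured component evaluated at both temperatures."""
        resp = ResponseSpec(
            groups={"algae": GroupResponse(
                intercept=1.0,
                components=(Component("WTEMP", ramp(16.0, 26.0, 2.6)),))},
            noise_sd=0.0)
        table = self._constant_table(n=2)
        table["WTEMP"] = [10.0, 25.0]
        pl = generate_plankton(table, resp, seed=0)
        b10, b25 = pl["wet_biomass_mg_per_L"].to_numpy()
        assert b25 > b10
        expected_gap = ramp(16.0, 26.0, 2.6)(np.array([25.0]))[0]
        assert np.isclose(np.log(b25) - np.log(b10), expected_gap)

    def test_log_biomass_equals_response_truth_without_noise(self, abiotic_396):
        resp = taihu_response_spec(noise_sd=0.0)
        pl = generate_plankton(abiotic_396, resp, seed=0)
        algae = pl[pl["group"] == "algae"]
        expected = resp.groups["algae"].evaluate(abiotic_396)
        assert np.allclose(np.log(algae["wet_biomass_mg_per_L"]), expected)

    def test_default_truth_spans_published_phytoplankton_range(self, plankton_396):
        phyt = plankton_396.loc[plankton_396["group"] == "algae",
                                "wet_biomass_mg_per_L"]
        assert phyt.min() < 3.0       # reaches down toward the 0.67 mg/L floor
        assert phyt.max() > 100.0     # reaches the bloom scale (224 mg/L)
        assert (phyt > 0).all()

    def test_all_five_groups_present(self, plankton_396):
        assert set(plankton_396["group"]) == {
            "algae", "protozoa", "rotifera", "cladocera", "copepoda"}

    def test_missing_driver_column_rejected(self):
        table = self._constant_table().drop(columns=["TSS"])
        with pytest.raises(ConfigurationError):
            generate_plankton(table, taihu_response_spec(), seed=0)

    def test_incomplete_abiotic_rejected(self):
        table = self._constant_table()
        table.loc[0, "WTEMP"] = np.nan
        with pytest.raises(ValidationError):
            generate_plankton(table, taihu_response_spec(), seed=0)

    def test_component_shapes(self):
        r = ramp(16, 26, 2.0)
        assert r(np.array([10.0]))[0] == 0.0
        assert r(np.array([30.0]))[0] == 2.0
        assert 0 < r(np.array([21.0]))[0] < 2.0
        s = saturating(0.0, 1.0, 3.0)
        assert s(np.array([-1.0]))[0] == 0.0
        assert s(np.array([100.0]))[0] == pytest.approx(3.0)
        assert linear(2.0, 1.0)(np.array([3.0]))[0] == 4.0
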