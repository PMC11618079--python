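"""Heat-balance physics: geometry, coefficients, oracle equivalence, invariants."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.optimize import brentq

from partmig import thermo
from partmig.thermo import (
    STEFAN_BOLTZMANN,
    ThermoParams,
    blackbird_params,
    geometry_from_mass,
    heat_transfer_coefficients,
    required_heat_loss,
    simulate_thermo_series,
    thermo_power,
)


def prolate_area_exact(a: float, b: float) -> float:
    """Closed-form prolate spheroid surface area (independent oracle)."""
    if a == b:
        return 4.0 * np.pi * a * a
    e = np.sqrt(1.0 - (b / a) ** 2)
    return 2.0 * np.pi * b * b * (1.0 + (a / (b * e)) * np.arcsin(e))


def bisection_heat_loss(tb: float, ta: float, params: ThermoParams) -> float:
    """Independent route to the same balance: solve for the outer-surface
    temperature where conduction out of the body equals surface loss, then
    convert the conductive flow to the required power."""
    geom = geometry_from_mass(
        params.body_mass_kg, params.body_density_kg_m3, params.elongation, params.plumage_depth_m
    )
    if tb <= ta:
        return 0.0
    h_conv, h_rad = heat_transfer_coefficients(geom, params, 0.5 * (tb + ta))
    r_cond = params.flesh_thickness_m / (
        params.flesh_conductivity_W_mK * geom.area_skin_m2
    ) + params.plumage_depth_m / (params.plumage_conductivity_W_mK * geom.area_mean_m2)

    def imbalance(ts: float) -> float:
        conduction = (tb - ts) / r_cond
        surface = (h_conv + h_rad) * geom.area_outer_m2 * (ts - ta)
        return conduction - surface

    ts = brentq(imbalance, ta, tb, xtol=1e-12)
    return (tb - ts) / r_cond


class TestGeometry:
    def test_volume_is_mass_over_density(self):
        geom = geometry_from_mass(0.090, 1000.0)
        assert geom.volume_m3 == pytest.approx(9.0e-5)

    def test_sphere_limit_area(self):
        geom = geometry_from_mass(0.090, 1000.0, elongation=1.0, plumage_depth_m=0.006)
        r = (3 * geom.volume_m3 / (4 * np.pi)) ** (1 / 3)
        assert geom.area_skin_m2 == pytest.approx(4 * np.pi * r * r, rel=0.002)

    def test_areas_match_closed_form_oracle(self):
        geom = geometry_from_mass(1.0, 1000.0, elongation=2.0, plumage_depth_m=0.006)
        assert geom.area_skin_m2 == pytest.approx(
            prolate_area_exact(geom.semi_major_m, geom.semi_minor_m), rel=0.02
        )
        assert geom.area_outer_m2 == pytest.approx(
            prolate_area_exact(geom.semi_major_m + 0.006, geom.semi_minor_m + 0.006), rel=0.02
        )


class TestCoefficients:
    def test_zero_wind_hits_free_convection_floor(self):
        p = blackbird_params(wind_speed_m_s=0.0)
        geom = geometry_from_mass(p.body_mass_kg, plumage_depth_m=p.plumage_depth_m)
        h_conv, _ = heat_transfer_coefficients(geom, p, 10.0)
        expected = thermo.NU_FREE_CONVECTION * p.air_conductivity_W_mK / geom.char_length_m
        assert h_conv == pytest.approx(expected)

    def test_zero_emissivity_kills_radiation(self):
        p = blackbird_params()
        p.emissivity = 1e-12
        geom = geometry_from_mass(p.body_mass_kg)
        _, h_rad = heat_transfer_coefficients(geom, p, 0.0)
        assert h_rad == pytest.approx(0.0, abs=1e-9)

    def test_radiative_coefficient_direct_evaluation(self):
        p = blackbird_params()
        geom = geometry_from_mass(p.body_mass_kg)
        _, h_rad = heat_transfer_coefficients(geom, p, 0.0)
        assert h_rad == pytest.approx(4 * 0.95 * STEFAN_BOLTZMANN * 273.15**3, rel=1e-9)
        assert h_rad == pytest.approx(4.39, abs=0.02)


class TestHeatBalance:
    def test_zero_gradient_zero_loss(self):
        p = blackbird_params()
        assert required_heat_loss(39.5, 39.5, p) == 0.0

    def test_inverted_gradient_clamped_to_zero(self):
        assert required_heat_loss(38.0, 42.0, blackbird_params()) == 0.0

    def test_doubling_gradient_at_fixed_film_doubles_loss(self):
        p = blackbird_params()
        q1 = required_heat_loss(40.0, 38.0, p)  # film 39
        q2 = required_heat_loss(41.0, 37.0, p)  # film 39, double gradient
        assert q2 == pytest.approx(2 * q1, rel=1e-12)

    def test_bisection_oracle_equivalence_on_grid(self):
        """Closed form equals the surface-temperature bisection to < 1e-6 W."""
        rng = np.random.default_rng(12345)
        for _ in range(100):
            p = blackbird_params(
                wind_speed_m_s=float(rng.uniform(0, 8)),
                plumage_depth_m=float(rng.uniform(0.002, 0.015)),
            )
            tb = float(rng.uniform(37, 43))
            ta = float(rng.uniform(-25, tb - 0.5))
            closed = float(required_heat_loss(tb, ta, p))
            assert abs(closed - bisection_heat_loss(tb, ta, p)) < 1e-6

    def test_monotone_in_gradient_wind_and_plumage(self):
        p = blackbird_params()
        q = [float(required_heat_loss(39.5, ta, p)) for ta in (10.0, 0.0, -10.0)]
        assert q[0] < q[1] < q[2]
        winds = [
            float(required_heat_loss(39.5, 0.0, blackbird_params(wind_speed_m_s=w)))
            for w in (0.5, 2.0, 6.0)
        ]
        assert winds[0] < winds[1] < winds[2]
        plumes = [
            float(required_heat_loss(39.5, 0.0, blackbird_params(plumage_depth_m=d)))
            for d in (0.003, 0.006, 0.012)
        ]
        assert plumes[0] > plumes[1] > plumes[2]

    @settings(derandomize=True, max_examples=60, deadline=None)
    @given(
        tb=st.floats(35.0, 44.0),
        ta=st.floats(-30.0, 50.0),
        wind=st.floats(0.0, 10.0),
    )
    def test_loss_nonnegative_and_zero_above_tb(self, tb, ta, wind):
        q = float(required_heat_loss(tb, ta, blackbird_params(wind_speed_m_s=wind)))
        assert q >= 0.0
        if ta >= tb:
            assert q == 0.0

    def test_nonfinite_temperature_rejected(self):
        with pytest.raises(ValueError):
            required_heat_loss(np.nan, 0.0, blackbird_params())


class TestThermoPower:
    def test_thermoneutral_floor(self):
        p = blackbird_params()
        total, above = thermo_power(39.5, 38.0, p)  # tiny gradient
        assert float(total) == pytest.approx(p.basal_power_W)
        assert float(above) == 0.0

    def test_above_basal_offset(self):
        p = blackbird_params()
        # find a T_a where the load is twice basal, then check the split
        q_target = 2 * p.basal_power_W
        from scipy.optimize import brentq as _brentq

        ta = _brentq(lambda t: float(required_heat_loss(39.5, t, p)) - q_target, -60, 39)
        total, above = thermo_power(39.5, ta, p)
        assert float(above) == pytest.approx(p.basal_power_W, rel=1e-9)

    def test_monotone_cold_response(self):
        p = blackbird_params()
        tas = np.linspace(39.0, -30.0, 80)
        totals = np.array([float(thermo_power(39.5, t, p)[0]) for t in tas])
        assert np.all(np.diff(totals) >= 0)  # colder -> never cheaper


class TestSeriesSimulation:
    def _series(self, n, tb=39.5, ta=0.0):
        ts = pd.date_range("2016-12-01", periods=n, freq="30min")
        return (
            pd.DataFrame({"timestamp": ts, "T_b_C": tb}),
            pd.DataFrame({"timestamp": ts, "T_a_C": ta}),
        )

    def test_one_watt_day_is_86_4_kJ(self):
        p = blackbird_params()
        p.basal_power_W = 1.0
        tb, ta = self._series(48)
        ta["T_a_C"] = tb["T_b_C"]  # zero load -> runs at basal 1 W
        ledger = simulate_thermo_series(tb, ta, p)
        assert ledger["cum_kJ"].iloc[-1] == pytest.approx(86.4)

    def test_energy_accounting_closes(self):
        p = blackbird_params()
        tb, ta = self._series(200, ta=-5.0)
        ledger = simulate_thermo_series(tb, ta, p)
        total = (ledger["total_W"] * 1800 / 1000).sum()
        assert ledger["cum_kJ"].iloc[-1] == pytest.approx(total, abs=1e-6)
        assert (np.diff(ledger["cum_kJ"]) >= 0).all()

    def test_colder_series_costs_strictly_more(self):
        p = blackbird_params()
        tb, ta = self._series(300, ta=2.0)
        _, ta_cold = self._series(300, ta=2.0 - 5.7)
        warm = simulate_thermo_series(tb, ta, p)
        cold = simulate_thermo_series(tb, ta_cold, p)
        assert cold["cum_kJ"].iloc[-1] > warm["cum_kJ"].iloc[-1]
        assert (cold["cum_kJ"] >= warm["cum_kJ"]).all()

    def test_grid_mismatch_names_timestamps(self):
        p = blackbird_params()
        tb, ta = self._series(48)
        ta = ta.iloc[: len(ta) // 4]  # large gap, beyond the ffill limit
        with pytest.raises(ValueError, match="does not cover"):
            simulate_thermo_series(tb, ta, p)
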