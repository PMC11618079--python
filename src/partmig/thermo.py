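"""One-node biophysical model of endotherm thermoregulation.

The bird is a prolate ellipsoid at core temperature T_b wrapped in a flesh
shell and a plumage layer, losing heat to air at T_a through a series path:
conduction through flesh, conduction through plumage, then convection and
thermal radiation from the outer surface.  The metabolic power required to
hold T_b is the heat flow through that path; below the thermoneutral load
the total is floored at basal power.  This is a transparent simplification
of full endotherm microclimate models (no evaporative or respiratory loss,
no posture or microclimate adjustment, boundary-layer film temperature
fixed at the midpoint of T_b and T_a).

Units: SI throughout; temperatures in °C, power in W, energy in kJ.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

STEFAN_BOLTZMANN = 5.670e-8  # W m^-2 K^-4
#: Nusselt floor for free convection around a compact body
NU_FREE_CONVECTION = 2.0


@dataclass
class ThermoParams:
    """Morphology and environment of the heat balance (blackbird defaults).

    The default parameter set describes a ~90 g thrush: flesh shell of a
    few millimetres under a ~6 mm feather layer whose conductivity is close
    to still air, light wind, and a passerine basal metabolic power of
    about 1 W.
    """

    body_mass_kg: float = 0.090
    body_density_kg_m3: float = 1000.0
    elongation: float = 2.0  # prolate long:short axis ratio
    plumage_depth_m: float = 0.006
    plumage_conductivity_W_mK: float = 0.027
    flesh_thickness_m: float = 0.005
    flesh_conductivity_W_mK: float = 0.5
    wind_speed_m_s: float = 1.0
    air_conductivity_W_mK: float = 0.0257
    air_kinematic_viscosity_m2_s: float = 1.35e-5
    emissivity: float = 0.95
    basal_power_W: float = 1.0

    def validate(self) -> None:
        positives = {
            k: v
            for k, v in self.__dict__.items()
            if k not in ("wind_speed_m_s",) and isinstance(v, float)
        }
        for name, value in positives.items():
            if name == "emissivity":
                continue
            if value <= 0:
                raise ValueError(f"{name} must be strictly positive (got {value})")
        if not 0.0 < self.emissivity <= 1.0:
            raise ValueError("emissivity must lie in (0, 1]")
        if self.wind_speed_m_s < 0:
            raise ValueError("wind speed must be non-negative")


def blackbird_params(body_mass_kg: float = 0.090, **overrides) -> ThermoParams:
    """Blackbird preset with an allometric basal power for the given mass.

    Basal power follows the passerine night-phase allometry
    ``BMR[W] ~ 6.25 * M[kg]^0.724``.
    """
    p = ThermoParams(body_mass_kg=body_mass_kg, **overrides)
    if "basal_power_W" not in overrides:
        p.basal_power_W = 6.25 * body_mass_kg**0.724
    return p


@dataclass
class Geometry:
    volume_m3: float
    semi_major_m: float
    semi_minor_m: float
    area_skin_m2: float
    area_outer_m2: float
    area_mean_m2: float
    char_length_m: float


def _prolate_area(a: float, b: float, p: float = 1.6075) -> float:
    """Thomsen's approximation of a prolate spheroid's surface area."""
    term = ((a * b) ** p + (a * b) ** p + (b * b) ** p) / 3.0
    return 4.0 * np.pi * term ** (1.0 / p)


def geometry_from_mass(
    mass_kg: float,
    density_kg_m3: float = 1000.0,
    elongation: float = 2.0,
    plumage_depth_m: float = 0.006,
) -> Geometry:
    """Prolate-ellipsoid body geometry from mass.

    The characteristic dimension for convection is the diameter of the
    sphere with the feathered body's volume.
    """
    volume = mass_kg / density_kg_m3
    b = (3.0 * volume / (4.0 * np.pi * elongation)) ** (1.0 / 3.0)
    a = elongation * b
    area_skin = _prolate_area(a, b)
    a_out, b_out = a + plumage_depth_m, b + plumage_depth_m
    area_outer = _prolate_area(a_out, b_out)
    outer_volume = 4.0 / 3.0 * np.pi * a_out * b_out**2
    char = (6.0 * outer_volume / np.pi) ** (1.0 / 3.0)
    return Geometry(
        volume_m3=volume,
        semi_major_m=a,
        semi_minor_m=b,
        area_skin_m2=area_skin,
        area_outer_m2=area_outer,
        area_mean_m2=0.5 * (area_skin + area_outer),
        char_length_m=char,
    )


def heat_transfer_coefficients(
    geometry: Geometry, params: ThermoParams, T_film_C: float | np.ndarray
) -> tuple[float | np.ndarray, float | np.ndarray]:
    """Convective and radiative surface coefficients (W m^-2 K^-1).

    Forced convection uses Nu = 0.37 Re^0.6 with a free-convection floor of
    Nu = 2; the radiative coefficient is the linearized
    ``4 e sigma T_film^3``.
    """
    D = geometry.char_length_m
    Re = params.wind_speed_m_s * D / params.air_kinematic_viscosity_m2_s
    Nu = np.maximum(0.37 * np.asarray(Re) ** 0.6, NU_FREE_CONVECTION)
    h_conv = Nu * params.air_conductivity_W_mK / D
    h_rad = 4.0 * params.emissivity * STEFAN_BOLTZMANN * (np.asarray(T_film_C) + 273.15) ** 3
    return h_conv, h_rad


def thermal_resistance(params: ThermoParams, T_film_C: float | np.ndarray) -> np.ndarray:
    """Series core-to-air resistance (K/W) at the given film temperature."""
    geom = geometry_from_mass(
        params.body_mass_kg,
        params.body_density_kg_m3,
        params.elongation,
        params.plumage_depth_m,
    )
    h_conv, h_rad = heat_transfer_coefficients(geom, params, T_film_C)
    r_flesh = params.flesh_thickness_m / (params.flesh_conductivity_W_mK * geom.area_skin_m2)
    r_plume = params.plumage_depth_m / (params.plumage_conductivity_W_mK * geom.area_mean_m2)
    r_surface = 1.0 / ((h_conv + h_rad) * geom.area_outer_m2)
    return np.asarray(r_flesh + r_plume + r_surface)


def required_heat_loss(
    T_b_C: float | np.ndarray, T_a_C: float | np.ndarray, params: ThermoParams
) -> np.ndarray:
    """Heat flow (W) needed to hold T_b against T_a; 0 when T_a >= T_b."""
    tb = np.asarray(T_b_C, dtype=float)
    ta = np.asarray(T_a_C, dtype=float)
    if not (np.all(np.isfinite(tb)) and np.all(np.isfinite(ta))):
        raise ValueError("non-finite temperatures passed to the heat balance")
    params.validate()
    film = 0.5 * (tb + ta)
    R = thermal_resistance(params, film)
    q = (tb - ta) / R
    return np.maximum(q, 0.0)


def thermo_power(
    T_b_C: float | np.ndarray, T_a_C: float | np.ndarray, params: ThermoParams
) -> tuple[np.ndarray, np.ndarray]:
    """Total metabolic power (floored at basal) and above-basal component."""
    q = required_heat_loss(T_b_C, T_a_C, params)
    total = np.maximum(q, params.basal_power_W)
    above = np.maximum(q - params.basal_power_W, 0.0)
    return total, above


def simulate_thermo_series(
    tb_series: pd.DataFrame,
    ta_series: pd.DataFrame,
    params: ThermoParams,
    bird_id: str = "",
    scenario: str = "",
    interval_s: float = 1800.0,
    max_ffill: int = 4,
) -> pd.DataFrame:
    """Per-interval thermoregulatory ledger for one bird under one scenario.

    ``tb_series`` (timestamp, T_b_C) and ``ta_series`` (timestamp, T_a_C)
    must share the 30-min grid; T_a gaps at T_b timestamps are forward
    filled up to ``max_ffill`` steps, remaining gaps raise.  Returns
    columns: bird_id, scenario, timestamp, T_b_C, T_a_C, Q_req_W, total_W,
    above_basal_W, cum_kJ.
    """
    tb = tb_series.sort_values("timestamp").reset_index(drop=True)
    ta = ta_series.set_index("timestamp")["T_a_C"]
    aligned = ta.reindex(pd.DatetimeIndex(tb["timestamp"]))
    if aligned.isna().any():
        aligned = aligned.ffill(limit=max_ffill)
    if aligned.isna().any():
        missing = aligned.index[aligned.isna()][:5].tolist()
        raise ValueError(f"ambient series does not cover T_b timestamps, e.g. {missing}")

    q = required_heat_loss(tb["T_b_C"].to_numpy(), aligned.to_numpy(), params)
    total = np.maximum(q, params.basal_power_W)
    above = np.maximum(q - params.basal_power_W, 0.0)
    energy_kj = total * interval_s / 1000.0
    return pd.DataFrame(
        {
            "bird_id": bird_id,
            "scenario": scenario,
            "timestamp": tb["timestamp"],
            "T_b_C": tb["T_b_C"],
            "T_a_C": aligned.to_numpy(),
            "Q_req_W": q,
            "total_W": total,
            "above_basal_W": above,
            "cum_kJ": np.cumsum(energy_kj),
        }
    )
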