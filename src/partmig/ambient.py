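"""Ambient temperature handling: interpolation, per-bird experienced series,
and the resident-offset / wintering-quantile scenario grid.

A migrant's experienced air temperature is modelled as a convex combination
of the breeding-site and wintering-site series.  The journey is divided by
its number of flight nights: after the k-th of n fall flight nights the
wintering weight steps to k/n (night-end convention), so the experienced
temperature converges linearly on the wintering series with each migratory
night, and symmetrically back in spring.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .events import MigrationEvents

RESIDENT_OFFSETS = (0.0, 1.0, 2.0)
WINTERING_QUANTILES = ("mean", "q25", "q75")


def to_halfhour(hourly: pd.DataFrame) -> pd.DataFrame:
    """Linearly interpolate an hourly series onto the 30-min grid.

    Midpoints are the arithmetic means of their neighbours; endpoints are
    preserved.  Duplicate timestamps are rejected.
    """
    ts = pd.DatetimeIndex(hourly["timestamp"])
    if ts.has_duplicates:
        dups = ts[ts.duplicated()].unique()
        raise ValueError(f"duplicate timestamps in hourly series: {list(dups[:5])}")
    if not ts.is_monotonic_increasing:
        hourly = hourly.sort_values("timestamp")
        ts = pd.DatetimeIndex(hourly["timestamp"])
    s = pd.Series(hourly["T_a_C"].to_numpy(), index=ts)
    grid = pd.date_range(ts[0], ts[-1], freq="30min")
    out = s.reindex(s.index.union(grid)).interpolate(method="time").reindex(grid)
    return pd.DataFrame({"timestamp": grid, "T_a_C": out.to_numpy()})


def site_series(ambient: pd.DataFrame, site: str) -> pd.DataFrame:
    sub = ambient.loc[ambient["site"] == site, ["timestamp", "T_a_C"]]
    if sub.empty:
        raise ValueError(f"ambient frame has no site '{site}'")
    return sub.reset_index(drop=True)


def _wintering_weight(grid: pd.DatetimeIndex, events: MigrationEvents) -> np.ndarray:
    """Breeding(0)->wintering(1) weight on the grid, stepping at night end.

    Night intervals (small hours) belong to the previous calendar date, so
    the weight advances on the morning after each flight night.
    """
    from .solar import night_date

    eff = pd.DatetimeIndex(night_date(grid))
    w = np.zeros(len(grid))
    n = len(events.fall_flight_nights)
    if n == 0:
        raise ValueError(f"{events.bird_id}: migrant with zero fall flight nights")
    for k, d in enumerate(events.fall_flight_nights, start=1):
        w[eff > pd.Timestamp(d)] = k / n
    m = len(events.spring_flight_nights)
    for k, d in enumerate(events.spring_flight_nights, start=1):
        w[eff > pd.Timestamp(d)] = 1.0 - k / m
    return w


def experienced_temperature(
    events: MigrationEvents | None,
    breeding: pd.DataFrame,
    wintering: pd.DataFrame,
) -> pd.DataFrame:
    """Per-bird experienced T_a series on the breeding series' grid.

    Residents (``events`` empty or None) experience the breeding series
    unchanged.  For migrants the series is
    ``(1 - w) * breeding + w * wintering`` with the per-night convergence
    weight ``w``.
    """
    grid = pd.DatetimeIndex(breeding["timestamp"])
    tb = breeding["T_a_C"].to_numpy()
    if events is None or events.is_empty:
        return pd.DataFrame({"timestamp": grid, "T_a_C": tb})
    tw = (
        wintering.set_index("timestamp")["T_a_C"].reindex(grid).interpolate(method="time")
    ).to_numpy()
    w = _wintering_weight(grid, events)
    return pd.DataFrame({"timestamp": grid, "T_a_C": (1.0 - w) * tb + w * tw})


@dataclass(frozen=True)
class ScenarioSpec:
    """One cell of the sensitivity grid."""

    resident_offset_C: float
    wintering_quantile: str  # mean | q25 | q75

    @property
    def label(self) -> str:
        return f"res+{self.resident_offset_C:g}C/win_{self.wintering_quantile}"


def scenario_grid(
    offsets: tuple[float, ...] = RESIDENT_OFFSETS,
    quantiles: tuple[str, ...] = WINTERING_QUANTILES,
) -> list[ScenarioSpec]:
    return [ScenarioSpec(o, q) for o in offsets for q in quantiles]


def migrant_absence_window(
    events: dict[str, MigrationEvents]
) -> tuple[pd.Timestamp, pd.Timestamp]:
    """[earliest fall departure, latest spring arrival] across migrants."""
    departures = [ev.fall_departure for ev in events.values() if ev.fall_departure]
    arrivals = [ev.spring_arrival for ev in events.values() if ev.spring_arrival]
    if not departures or not arrivals:
        raise ValueError("no migrant events to derive the absence window from")
    return pd.Timestamp(min(departures)), pd.Timestamp(max(arrivals))


def resident_scenario_series(
    breeding: pd.DataFrame,
    offset_C: float,
    absence: tuple[pd.Timestamp, pd.Timestamp],
) -> pd.DataFrame:
    """Breeding series with the micro-climate offset inside the absence window."""
    out = breeding.copy()
    ts = pd.DatetimeIndex(out["timestamp"])
    inside = (ts >= absence[0]) & (ts <= absence[1])
    out["T_a_C"] = out["T_a_C"].to_numpy() + np.where(inside, offset_C, 0.0)
    return out


def build_scenarios(
    ambient_halfhour: pd.DataFrame,
    events: dict[str, MigrationEvents],
    offsets: tuple[float, ...] = RESIDENT_OFFSETS,
    quantiles: tuple[str, ...] = WINTERING_QUANTILES,
) -> list[tuple[ScenarioSpec, pd.DataFrame, dict[str, pd.DataFrame]]]:
    """All (spec, resident series, per-migrant series) combinations.

    ``ambient_halfhour`` must hold the four reference sites on the 30-min
    grid.  Returns, per scenario, the resident T_a series (shared by all
    residents) and a per-migrant dict of experienced T_a series.
    """
    breeding = site_series(ambient_halfhour, "breeding")
    absence = migrant_absence_window(events)
    out = []
    for spec in scenario_grid(offsets, quantiles):
        wintering = site_series(ambient_halfhour, f"wintering_{spec.wintering_quantile}")
        res_series = resident_scenario_series(breeding, spec.resident_offset_C, absence)
        mig_series = {
            bird: experienced_temperature(ev, breeding, wintering)
            for bird, ev in events.items()
            if not ev.is_empty
        }
        out.append((spec, res_series, mig_series))
    return out
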