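"""Approximate day/night split from a seasonal daylength sinusoid.

Civil dusk/dawn are approximated by the astronomical sunrise/sunset of a
standard solar-declination formula at the configured latitude, with solar
noon pinned to 12:00 in series time.  This avoids an ephemeris dependency
and is accurate to well under half an hour at mid latitudes, which is ample
for splitting a 30-min series into day and night.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["daylength_hours", "is_night", "night_date"]


def daylength_hours(day_of_year: np.ndarray, latitude_deg: float) -> np.ndarray:
    """Hours of daylight for each day of year at ``latitude_deg``."""
    doy = np.asarray(day_of_year, dtype=float)
    decl = np.deg2rad(-23.44) * np.cos(2.0 * np.pi * (doy + 10.0) / 365.25)
    lat = np.deg2rad(latitude_deg)
    cos_h = -np.tan(lat) * np.tan(decl)
    cos_h = np.clip(cos_h, -1.0, 1.0)
    return 2.0 * np.rad2deg(np.arccos(cos_h)) / 15.0


def is_night(timestamps: pd.DatetimeIndex | pd.Series, latitude_deg: float) -> np.ndarray:
    """Boolean night mask: before sunrise or at/after sunset."""
    ts = pd.DatetimeIndex(timestamps)
    doy = ts.dayofyear.to_numpy()
    hours = ts.hour.to_numpy() + ts.minute.to_numpy() / 60.0
    half = daylength_hours(doy, latitude_deg) / 2.0
    sunrise = 12.0 - half
    sunset = 12.0 + half
    return (hours < sunrise) | (hours >= sunset)


def night_date(timestamps: pd.DatetimeIndex | pd.Series) -> np.ndarray:
    """Date of the dusk that opened the night a timestamp belongs to.

    Evening hours (>= 12:00) keep their calendar date; small hours are
    assigned to the previous day, so one night carries one label.
    """
    ts = pd.DatetimeIndex(timestamps)
    dates = ts.normalize()
    before_noon = ts.hour < 12
    return np.where(before_noon, dates - pd.Timedelta(days=1), dates).astype("datetime64[ns]")
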