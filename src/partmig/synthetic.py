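"""Synthetic bio-logger populations with known ground truth.

Generates migrant and resident birds carrying implanted heart-rate /
body-temperature loggers over one non-breeding season, together with the
ambient-temperature series of the breeding and wintering grounds and the
true migration events.  Every effect the analysis pipeline is meant to
detect is injected here with a configurable magnitude (see
:mod:`partmig.config`), so recovery can be verified against ground truth.

The statistical skeleton per bird is:

    f_H(t) = [mu_phase + b_i + e(t)] * (1 - ramp(t)) + flight(t) + recovery(t)
    T_b(t) =  mu_phase + c_i + u(t) - winter_decline(t) + flight_Tb(t)

with phase means for day and night, normal individual intercepts b_i/c_i,
stationary AR(1) residuals e/u, a multiplicative nocturnal pre-departure
ramp for migrants, additive flight-night elevations, an additive
post-arrival recovery dip, and a resident-only core-winter decline of T_b.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date, timedelta

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from .config import QiModel, SimConfig
from .events import MigrationEvents
from .solar import is_night, night_date

SITES = ("breeding", "wintering_mean", "wintering_q25", "wintering_q75")


@dataclass
class TrueState:
    """Ground truth for a simulated population."""

    events: dict[str, MigrationEvents]
    #: per-interval latent truth: bird_id, timestamp, true_fH_bpm, true_Tb_C,
    #: is_night, is_flight, site_weight (0 = breeding, 1 = wintering)
    latent: pd.DataFrame | None = None


def _ar1(rng: np.random.Generator, n: int, phi: float, sd: float) -> np.ndarray:
    """Stationary AR(1) series with marginal standard deviation ``sd``."""
    if sd == 0.0 or n == 0:
        return np.zeros(n)
    innov_sd = sd * np.sqrt(max(1.0 - phi**2, 1e-12))
    e = rng.normal(0.0, innov_sd, size=n)
    e[0] = rng.normal(0.0, sd)
    return lfilter([1.0], [1.0, -phi], e)


# ---------------------------------------------------------------------------
# population structure


def generate_population(config: SimConfig) -> tuple[pd.DataFrame, TrueState]:
    """Draw bird metadata and true migration phenology.

    Returns a metadata frame (bird_id, sex, strategy, body_mass_kg,
    transmitter_mass_g, logger_id) and a :class:`TrueState` holding each
    migrant's true departure, flight, stopover and arrival structure.
    Deterministic given ``config.seed``.
    """
    config.validate()
    rng = np.random.default_rng([config.seed, 11])

    n = config.n_residents + config.n_migrants
    strategies = ["resident"] * config.n_residents + ["migrant"] * config.n_migrants
    sexes = np.where(rng.random(n) < config.female_fraction, "F", "M")
    masses = np.clip(
        rng.normal(config.body_mass_mean_kg, config.body_mass_sd_kg, n),
        0.06,
        0.13,
    )
    lo, hi = config.transmitter_mass_range_g
    # heavier birds carry the heavier tags
    rank = pd.Series(masses).rank(method="first").to_numpy()
    tags = lo + (hi - lo) * (rank - 1) / max(n - 1, 1)

    meta = pd.DataFrame(
        {
            "bird_id": [f"B{i:03d}" for i in range(n)],
            "sex": sexes,
            "strategy": strategies,
            "body_mass_kg": np.round(masses, 4),
            "transmitter_mass_g": np.round(tags, 2),
            "logger_id": [f"L{i:03d}" for i in range(n)],
        }
    )

    events: dict[str, MigrationEvents] = {}
    for bird_id, strategy in zip(meta["bird_id"], meta["strategy"]):
        if strategy == "resident":
            events[bird_id] = MigrationEvents(bird_id)
            continue
        events[bird_id] = _draw_migrant_events(bird_id, config, rng)
    return meta, TrueState(events=events)


def _draw_journey(
    rng: np.random.Generator,
    window: tuple[date, date],
    config: SimConfig,
    latest_end: date,
) -> list[date]:
    """Flight-night dates of one journey, kept within ``latest_end``."""
    ph = config.phenology
    w0, w1 = window
    dep = w0 + timedelta(days=int(rng.integers(0, (w1 - w0).days + 1)))
    n_nights = int(
        np.clip(ph.nights_min + rng.poisson(ph.nights_mean - ph.nights_min),
                ph.nights_min, ph.nights_max)
    )
    gaps = 1 + rng.poisson(ph.stopover_mean_nights, size=max(n_nights - 1, 0))
    if n_nights > 1 and dep + timedelta(days=int(gaps.sum())) > latest_end:
        gaps = np.ones_like(gaps)  # compress stopovers if the journey overruns
    nights = [dep]
    for g in gaps:
        nights.append(nights[-1] + timedelta(days=int(g)))
    kept = [d for d in nights if d <= latest_end]
    # a journey lying wholly beyond the recorded season is kept as-is: its
    # nights simply have no measurements on the grid
    return kept or nights


def _draw_migrant_events(bird_id: str, config: SimConfig, rng: np.random.Generator) -> MigrationEvents:
    # the core winter starts after the last fall event (and its recovery
    # window), so journeys must complete before it
    winter_start, _ = config.winter_window_dates()
    fall_nights = _draw_journey(
        rng,
        config.fall_window_dates(),
        config,
        winter_start - timedelta(days=config.recovery.duration_days + 2),
    )
    spring_nights = _draw_journey(
        rng, config.spring_window_dates(), config, config.season_end - timedelta(days=16)
    )

    def stopovers(nights: list[date]) -> list[date]:
        out = []
        for a, b in zip(nights[:-1], nights[1:]):
            d = a + timedelta(days=1)
            while d < b:
                out.append(d)
                d += timedelta(days=1)
        return out

    ev = MigrationEvents(
        bird_id,
        fall_departure=fall_nights[0],
        fall_flight_nights=fall_nights,
        fall_stopover_nights=stopovers(fall_nights),
        winter_arrival=fall_nights[-1] + timedelta(days=1),
        spring_departure=spring_nights[0],
        spring_flight_nights=spring_nights,
        spring_stopover_nights=stopovers(spring_nights),
        spring_arrival=spring_nights[-1] + timedelta(days=1),
    )
    ev.validate()
    return ev


# ---------------------------------------------------------------------------
# ambient temperature


def generate_ambient_series(config: SimConfig) -> pd.DataFrame:
    """Hourly air-temperature series for the four reference sites.

    ``breeding`` follows the configured seasonal + diel cycle with AR(1)
    noise; ``wintering_mean`` adds the configured winter offset (with its
    own noise); the quantile series bracket the mean by the configured
    spread, so q25 <= mean <= q75 pointwise by construction.
    """
    config.validate()
    rng = np.random.default_rng([config.seed, 22])
    p = config.ambient

    idx = pd.date_range(
        pd.Timestamp(config.season_start),
        pd.Timestamp(config.season_end) + pd.Timedelta(days=1),
        freq="1h",
    )
    doy = idx.dayofyear.to_numpy().astype(float)
    hour = idx.hour.to_numpy().astype(float)
    seasonal = p.annual_mean_C + p.seasonal_amplitude_C * np.cos(
        2.0 * np.pi * (doy - 196.0) / 365.25
    )
    diel = p.diel_amplitude_C * np.cos(2.0 * np.pi * (hour - 14.0) / 24.0)

    breeding = seasonal + diel + _ar1(rng, len(idx), p.ar1_phi, p.noise_sd_C)
    wintering = (
        seasonal + diel + config.winter_offset_C + _ar1(rng, len(idx), p.ar1_phi, p.noise_sd_C)
    )

    frames = []
    series = {
        "breeding": breeding,
        "wintering_mean": wintering,
        "wintering_q25": wintering - p.quantile_spread_C,
        "wintering_q75": wintering + p.quantile_spread_C,
    }
    for site, values in series.items():
        frames.append(pd.DataFrame({"site": site, "timestamp": idx, "T_a_C": values}))
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# bio-logger series


def _ramp_fraction(night_dates: np.ndarray, departure: date, config: SimConfig) -> np.ndarray:
    """Fractional nocturnal f_H reduction; 0 outside the ramp window."""
    ramp_days = config.predeparture.start_days_before
    dep = np.datetime64(departure)
    days_before = (dep - night_dates.astype("datetime64[D]")).astype("timedelta64[D]").astype(float)
    frac = config.predeparture.max_fraction * (1.0 - days_before / ramp_days)
    frac[(days_before <= 0) | (days_before > ramp_days)] = 0.0
    return np.clip(frac, 0.0, 1.0)


def _flight_mask(
    timestamps: pd.DatetimeIndex,
    night: np.ndarray,
    nights_of: np.ndarray,
    flight_nights: list[date],
    fraction: float,
) -> np.ndarray:
    """Per-interval flight flags: the first ``fraction`` of each flight night."""
    mask = np.zeros(len(timestamps), dtype=bool)
    flight_set = {np.datetime64(d) for d in flight_nights}
    nd = nights_of.astype("datetime64[D]")
    for d in flight_set:
        sel = np.flatnonzero(night & (nd == d))
        if sel.size == 0:
            continue
        k = int(np.ceil(fraction * sel.size))
        mask[sel[:k]] = True
    return mask


def generate_biologger_series(
    metadata: pd.DataFrame,
    truth: TrueState,
    ambient: pd.DataFrame,
    config: SimConfig,
) -> pd.DataFrame:
    """Clean (uncorrupted) 30-min logger records for every bird.

    Fills ``truth.latent`` with the per-interval ground truth (including
    flight flags and the breeding-to-wintering site weight) and returns the
    record frame: bird_id, logger_id, timestamp, f_H_bpm, T_b_C, is_night.
    """
    config.validate()
    _check_ambient_coverage(ambient, config)
    rng = np.random.default_rng([config.seed, 33])

    ts = pd.date_range(
        pd.Timestamp(config.season_start),
        pd.Timestamp(config.season_end) + pd.Timedelta(days=1),
        freq=f"{config.cadence_min}min",
        inclusive="left",
    )
    night = is_night(ts, config.latitude_deg)
    nights_of = night_date(ts)
    # effective date for site-weight steps: night intervals keep their dusk
    # date, day intervals their calendar date (weight advances at night end)
    eff_date = np.where(night, nights_of, ts.normalize()).astype("datetime64[D]")

    win_start, win_end = config.winter_window_dates()
    dates_d = ts.normalize().to_numpy().astype("datetime64[D]")
    in_winter = (dates_d >= np.datetime64(win_start)) & (dates_d <= np.datetime64(win_end))

    rec_frames = []
    latent_frames = []
    for row in metadata.itertuples(index=False):
        ev = truth.events[row.bird_id]
        n = len(ts)

        fh_mu = np.where(night, config.fH.nocturnal_mean_bpm, config.fH.diurnal_mean_bpm)
        fh = fh_mu + rng.normal(0.0, config.fH.individual_sd_bpm) + _ar1(
            rng, n, config.fH.ar1_phi, config.fH.noise_sd_bpm
        )
        tb_mu = np.where(night, config.Tb.nocturnal_mean_C, config.Tb.diurnal_mean_C)
        tb = tb_mu + rng.normal(0.0, config.Tb.individual_sd_C) + _ar1(
            rng, n, config.Tb.ar1_phi, config.Tb.noise_sd_C
        )

        is_flight = np.zeros(n, dtype=bool)
        weight = np.zeros(n)
        if row.strategy == "resident":
            tb = tb - np.where(in_winter, config.Tb.resident_winter_decline_C, 0.0)
        else:
            ramp = np.where(night, _ramp_fraction(nights_of, ev.fall_departure, config), 0.0)
            fh = fh * (1.0 - ramp)
            is_flight = _flight_mask(
                ts, night, nights_of, ev.flight_nights, config.flight.night_flight_fraction
            )
            fh = fh + np.where(is_flight, config.flight.delta_fH_bpm, 0.0)
            tb = tb + np.where(is_flight, config.flight.delta_Tb_C, 0.0)

            rec_start = np.datetime64(ev.winter_arrival)
            rec_end = rec_start + np.timedelta64(config.recovery.duration_days, "D")
            nd = nights_of.astype("datetime64[D]")
            in_recovery = night & (nd >= rec_start) & (nd < rec_end)
            fh = fh + np.where(in_recovery, config.recovery.delta_fH_bpm, 0.0)

            weight = _site_weight(eff_date, ev)

        rec_frames.append(
            pd.DataFrame(
                {
                    "bird_id": row.bird_id,
                    "logger_id": row.logger_id,
                    "timestamp": ts,
                    "f_H_bpm": fh,
                    "T_b_C": tb,
                    "is_night": night,
                }
            )
        )
        latent_frames.append(
            pd.DataFrame(
                {
                    "bird_id": row.bird_id,
                    "timestamp": ts,
                    "true_fH_bpm": fh,
                    "true_Tb_C": tb,
                    "is_night": night,
                    "is_flight": is_flight,
                    "site_weight": weight,
                }
            )
        )

    truth.latent = pd.concat(latent_frames, ignore_index=True)
    return pd.concat(rec_frames, ignore_index=True)


def _site_weight(eff_date: np.ndarray, ev: MigrationEvents) -> np.ndarray:
    """Breeding(0) to wintering(1) weight, stepping at the end of each flight night."""
    w = np.zeros(len(eff_date))
    n_fall = len(ev.fall_flight_nights)
    for k, d in enumerate(ev.fall_flight_nights, start=1):
        w[eff_date > np.datetime64(d)] = k / n_fall
    m = len(ev.spring_flight_nights)
    for k, d in enumerate(ev.spring_flight_nights, start=1):
        w[eff_date > np.datetime64(d)] = 1.0 - k / m
    return w


def _check_ambient_coverage(ambient: pd.DataFrame, config: SimConfig) -> None:
    for site in ("breeding", "wintering_mean"):
        sub = ambient.loc[ambient["site"] == site, "timestamp"]
        if sub.empty:
            raise ValueError(f"ambient series missing site '{site}'")
        if sub.min() > pd.Timestamp(config.season_start) or sub.max() < pd.Timestamp(
            config.season_end
        ):
            raise ValueError(
                f"ambient series for '{site}' does not cover the season: "
                f"have [{sub.min()}, {sub.max()}], "
                f"need [{config.season_start}, {config.season_end}]"
            )


# ---------------------------------------------------------------------------
# measurement corruption


def corrupt_with_qi(
    clean: pd.DataFrame, qi_model: QiModel, seed: int
) -> pd.DataFrame:
    """Apply the quality-index measurement model to clean records.

    Each record draws an ordinal QI class and is corrupted with that class's
    probability by multiplying the heart rate by a kernel factor (missed or
    double-counted beats).  Every ``truth_every_n``-th record per logger
    keeps the true bpm (raw-ECG verification subsample).  Body temperature
    is never corrupted (factory-calibrated sensor).
    """
    for p in qi_model.corruption_probs:
        if not 0.0 <= p <= 1.0:
            raise ValueError("corruption probabilities must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    out = clean.sort_values(["bird_id", "timestamp"], kind="stable").reset_index(drop=True)
    n = len(out)

    qi = rng.choice(len(qi_model.class_probs), size=n, p=np.asarray(qi_model.class_probs))
    p_corrupt = np.asarray(qi_model.corruption_probs)[qi]
    corrupted = rng.random(n) < p_corrupt
    factors = rng.choice(np.asarray(qi_model.kernel_factors), size=n)

    true_fh = out["f_H_bpm"].to_numpy().copy()
    fh = np.where(corrupted, true_fh * factors, true_fh)

    # raw-ECG truth subsample: every truth_every_n-th record per logger
    pos = out.groupby("bird_id", sort=False).cumcount().to_numpy()
    has_truth = pos % qi_model.truth_every_n == 0

    out["f_H_bpm"] = fh
    out["qi_class"] = qi.astype(int)
    out["has_ecg_truth"] = has_truth
    out["true_fH_bpm"] = np.where(has_truth, true_fh, np.nan)
    return out
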