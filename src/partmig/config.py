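"""Configuration objects for the synthetic population generator.

All magnitudes that the downstream analyses are expected to recover live
here, exposed as plain dataclass fields: the pre-departure nocturnal
heart-rate ramp, the flight-night elevations of heart rate and body
temperature, the post-arrival recovery dip, the resident winter decline in
body temperature, the wintering-ground ambient-temperature offset, and the
quality-index corruption model.  Nothing downstream reads these values —
they are the ground truth the pipeline is tested against.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from datetime import date


@dataclass
class AmbientParams:
    """Breeding-site air temperature model (°C).

    A seasonal cosine (coldest in mid January) plus a diel cosine (warmest
    mid afternoon) plus stationary AR(1) noise.
    """

    annual_mean_C: float = 9.0
    seasonal_amplitude_C: float = 9.0
    diel_amplitude_C: float = 4.0
    ar1_phi: float = 0.9
    noise_sd_C: float = 1.5
    #: half-distance between the 25th/75th wintering quantile series and the
    #: wintering mean series
    quantile_spread_C: float = 2.0


@dataclass
class HeartRateParams:
    """Baseline heart-rate model (beats per minute)."""

    nocturnal_mean_bpm: float = 374.0
    diurnal_mean_bpm: float = 470.0
    individual_sd_bpm: float = 15.0
    ar1_phi: float = 0.6
    noise_sd_bpm: float = 12.0


@dataclass
class BodyTempParams:
    """Baseline core body-temperature model (°C)."""

    nocturnal_mean_C: float = 39.6
    diurnal_mean_C: float = 41.3
    #: seasonal nocturnal decline of residents during the core winter,
    #: relative to migrants wintering in milder climate
    resident_winter_decline_C: float = 0.18
    individual_sd_C: float = 0.25
    ar1_phi: float = 0.5
    noise_sd_C: float = 0.15


@dataclass
class PredepartureRamp:
    """Nocturnal heart-rate reduction building up before fall departure."""

    start_days_before: float = 28.0
    max_fraction: float = 0.195


@dataclass
class FlightEffects:
    """Elevations during active migratory flight intervals."""

    delta_fH_bpm: float = 199.0
    delta_Tb_C: float = 1.23
    #: fraction of the night actually spent flying on a migration night
    night_flight_fraction: float = 0.7


@dataclass
class Recovery:
    """Post-arrival nocturnal heart-rate dip at the wintering site."""

    delta_fH_bpm: float = -36.0
    duration_days: int = 8


@dataclass
class MigrationPhenology:
    """Departure windows and journey structure.

    Windows are (month, day) pairs; the fall window falls in the season's
    first calendar year, the spring window in the second.
    """

    fall_window: tuple[tuple[int, int], tuple[int, int]] = ((10, 5), (11, 10))
    spring_window: tuple[tuple[int, int], tuple[int, int]] = ((3, 1), (3, 20))
    nights_min: int = 1
    nights_mean: float = 4.0
    nights_max: int = 9
    #: mean stopover nights between consecutive flight nights (Poisson)
    stopover_mean_nights: float = 1.5


@dataclass
class QiModel:
    """Quality-index corruption model for heart-rate measurements.

    Each record draws an ordinal QI class; records of class *i* are corrupted
    with probability ``corruption_probs[i]`` by multiplying the true bpm by a
    factor drawn from ``kernel_factors`` (missed vs double-counted beats).
    Raw-ECG ground truth is retained every ``truth_every_n`` records.
    """

    class_probs: tuple[float, ...] = (0.4, 0.3, 0.2, 0.1)
    corruption_probs: tuple[float, ...] = (0.02, 0.08, 0.20, 0.50)
    kernel_factors: tuple[float, float] = (0.5, 2.0)
    truth_every_n: int = 120  # 60 h at 30-min cadence


@dataclass
class SimConfig:
    n_residents: int = 10
    n_migrants: int = 10
    season_start: date = date(2016, 9, 1)
    season_end: date = date(2017, 4, 30)
    cadence_min: int = 30
    latitude_deg: float = 47.78
    #: wintering sites warmer than the breeding site by this much (°C)
    winter_offset_C: float = 5.7
    #: calendar core-winter window (month, day), inclusive
    winter_window: tuple[tuple[int, int], tuple[int, int]] = ((12, 3), (1, 17))
    female_fraction: float = 0.5
    body_mass_mean_kg: float = 0.090
    body_mass_sd_kg: float = 0.006
    transmitter_mass_range_g: tuple[float, float] = (1.8, 2.6)
    ambient: AmbientParams = field(default_factory=AmbientParams)
    fH: HeartRateParams = field(default_factory=HeartRateParams)
    Tb: BodyTempParams = field(default_factory=BodyTempParams)
    predeparture: PredepartureRamp = field(default_factory=PredepartureRamp)
    flight: FlightEffects = field(default_factory=FlightEffects)
    recovery: Recovery = field(default_factory=Recovery)
    phenology: MigrationPhenology = field(default_factory=MigrationPhenology)
    qi: QiModel = field(default_factory=QiModel)
    seed: int = 0

    # -- validation -------------------------------------------------------

    def validate(self) -> None:
        if self.n_residents < 0 or self.n_migrants < 0:
            raise ValueError("bird counts must be non-negative")
        if self.n_residents + self.n_migrants == 0:
            raise ValueError("population must contain at least one bird")
        if not 0.0 < self.predeparture.max_fraction < 1.0:
            raise ValueError("pre-departure max fractional reduction must lie in (0, 1)")
        if (24 * 60) % self.cadence_min != 0:
            raise ValueError("cadence must divide 24 h")
        if self.season_end <= self.season_start:
            raise ValueError("season_end must come after season_start")
        fall_end = self._mk_date(self.phenology.fall_window[1], spring=False)
        spring_start = self._mk_date(self.phenology.spring_window[0], spring=True)
        if not fall_end < spring_start:
            raise ValueError(
                "fall migration window must precede the spring window "
                f"(fall ends {fall_end}, spring starts {spring_start})"
            )
        ph = self.phenology
        if not ph.nights_min <= ph.nights_mean <= ph.nights_max:
            raise ValueError("nights per journey: need min <= mean <= max")
        for p in self.qi.corruption_probs:
            if not 0.0 <= p <= 1.0:
                raise ValueError("QI corruption probabilities must lie in [0, 1]")
        if len(self.qi.class_probs) != len(self.qi.corruption_probs):
            raise ValueError("QI class_probs and corruption_probs must align")

    def _mk_date(self, month_day: tuple[int, int], spring: bool) -> date:
        month, day = month_day
        year = self.season_start.year + 1 if spring else self.season_start.year
        return date(year, month, day)

    def fall_window_dates(self) -> tuple[date, date]:
        return (
            self._mk_date(self.phenology.fall_window[0], spring=False),
            self._mk_date(self.phenology.fall_window[1], spring=False),
        )

    def spring_window_dates(self) -> tuple[date, date]:
        return (
            self._mk_date(self.phenology.spring_window[0], spring=True),
            self._mk_date(self.phenology.spring_window[1], spring=True),
        )

    def winter_window_dates(self) -> tuple[date, date]:
        (m0, d0), (m1, d1) = self.winter_window
        start_year = self.season_start.year if m0 >= 7 else self.season_end.year
        end_year = self.season_start.year if m1 >= 7 else self.season_end.year
        return date(start_year, m0, d0), date(end_year, m1, d1)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["season_start"] = self.season_start.isoformat()
        d["season_end"] = self.season_end.isoformat()
        return d
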