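"""Migration event containers shared by the generator and the classifier."""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date

import pandas as pd


@dataclass
class MigrationEvents:
    """Departure/arrival dates and per-night flight structure for one bird.

    Dates are calendar dates; a flight night is labelled by the date at dusk.
    Arrival dates are the morning after the last flight night of the journey.
    Residents carry an empty event set.
    """

    bird_id: str
    fall_departure: date | None = None
    fall_flight_nights: list[date] = field(default_factory=list)
    fall_stopover_nights: list[date] = field(default_factory=list)
    winter_arrival: date | None = None
    spring_departure: date | None = None
    spring_flight_nights: list[date] = field(default_factory=list)
    spring_stopover_nights: list[date] = field(default_factory=list)
    spring_arrival: date | None = None

    @property
    def flight_nights(self) -> list[date]:
        return sorted(self.fall_flight_nights + self.spring_flight_nights)

    @property
    def is_empty(self) -> bool:
        return not self.flight_nights

    def validate(self) -> None:
        for nights in (self.fall_flight_nights, self.spring_flight_nights):
            if nights != sorted(nights):
                raise ValueError(f"{self.bird_id}: flight nights out of order")
        seq = [d for d in (self.fall_departure, self.winter_arrival,
                           self.spring_departure, self.spring_arrival) if d is not None]
        if seq != sorted(seq):
            raise ValueError(f"{self.bird_id}: event dates out of chronological order")


def events_to_frame(events: dict[str, MigrationEvents]) -> pd.DataFrame:
    """Long-format night table plus per-bird anchor dates, one row per night."""
    rows = []
    for ev in events.values():
        for d in ev.fall_flight_nights:
            rows.append((ev.bird_id, pd.Timestamp(d), "fall", "flight"))
        for d in ev.fall_stopover_nights:
            rows.append((ev.bird_id, pd.Timestamp(d), "fall", "stopover"))
        for d in ev.spring_flight_nights:
            rows.append((ev.bird_id, pd.Timestamp(d), "spring", "flight"))
        for d in ev.spring_stopover_nights:
            rows.append((ev.bird_id, pd.Timestamp(d), "spring", "stopover"))
    return pd.DataFrame(rows, columns=["bird_id", "night_date", "season", "kind"])


def anchors_to_frame(events: dict[str, MigrationEvents]) -> pd.DataFrame:
    rows = []
    for ev in events.values():
        rows.append(
            {
                "bird_id": ev.bird_id,
                "fall_departure": ev.fall_departure,
                "winter_arrival": ev.winter_arrival,
                "spring_departure": ev.spring_departure,
                "spring_arrival": ev.spring_arrival,
            }
        )
    return pd.DataFrame(rows)
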