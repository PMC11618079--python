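"""Season labels, event-centred stages, resident-migrant pairing, thinning.

Comparisons between strategies are made two ways: on fixed calendar seasons
(fall / core winter / post-migration spring) and on eight stages centred on
each migrant's own departure and arrival events.  For the event-centred
comparison every resident measurement is paired to exactly one simultaneous
same-sex migrant measurement, so residents inherit the migrant's stage and
day-offset without pseudoreplication.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .events import MigrationEvents
from .solar import night_date

STAGES = (
    "fall_premigration",
    "fall_migration",
    "fall_stopover",
    "winter_arrival",
    "spring_premigration",
    "spring_migration",
    "spring_stopover",
    "spring_arrival",
)


@dataclass
class SeasonDefinition:
    """Calendar season windows, (month, day) inclusive."""

    fall: tuple[tuple[int, int], tuple[int, int]] = ((9, 1), (9, 7))
    winter: tuple[tuple[int, int], tuple[int, int]] = ((12, 3), (1, 17))
    spring: tuple[tuple[int, int], tuple[int, int]] = ((4, 2), (4, 10))

    def day_counts(self) -> dict[str, int]:
        """Inclusive day counts of each window (winter spans the year end)."""
        counts = {}
        for name, ((m0, d0), (m1, d1)) in (
            ("fall", self.fall),
            ("winter", self.winter),
            ("spring", self.spring),
        ):
            y0 = 2016
            y1 = y0 + (1 if (m1, d1) < (m0, d0) else 0)
            counts[name] = (pd.Timestamp(y1, m1, d1) - pd.Timestamp(y0, m0, d0)).days + 1
        return counts

    def span_days(self) -> dict[str, int]:
        """End-minus-start day spans (the spring window is quoted this way)."""
        return {k: v - 1 for k, v in self.day_counts().items()}


@dataclass
class StageWindows:
    """Event-centred stage windows in days relative to each anchor."""

    fall_premigration_days: int = 35
    spring_premigration_days: int = 21
    arrival_days: int = 14


def _in_window(month_day: pd.DataFrame, window) -> np.ndarray:
    (m0, d0), (m1, d1) = window
    md = month_day["month"] * 100 + month_day["day"]
    lo, hi = m0 * 100 + d0, m1 * 100 + d1
    if lo <= hi:
        return ((md >= lo) & (md <= hi)).to_numpy()
    return ((md >= lo) | (md <= hi)).to_numpy()  # wraps the year end


def label_calendar_seasons(
    records: pd.DataFrame, definition: SeasonDefinition | None = None
) -> pd.DataFrame:
    """Add a ``season`` column: fall / winter / spring / none."""
    defn = definition or SeasonDefinition()
    ts = pd.DatetimeIndex(records["timestamp"])
    md = pd.DataFrame({"month": ts.month, "day": ts.day})
    season = np.full(len(records), "none", dtype=object)
    season[_in_window(md, defn.fall)] = "fall"
    season[_in_window(md, defn.winter)] = "winter"
    season[_in_window(md, defn.spring)] = "spring"
    out = records.copy()
    out["season"] = season
    return out


def label_migration_stages(
    records: pd.DataFrame,
    events: dict[str, MigrationEvents],
    windows: StageWindows | None = None,
) -> pd.DataFrame:
    """Label migrant records with event-centred stage and signed day-offset.

    The offset counts nights (date at dusk) from the anchor: departure day
    is offset 0 for migration stages, arrival day offset 0 for arrival
    stages.  Records outside all stage windows keep ``stage = None``.
    Migrants lacking an anchor event have that stage skipped with a warning.
    """
    win = windows or StageWindows()
    out = records.copy()
    out["stage"] = None
    out["day_offset"] = np.nan
    nd = pd.DatetimeIndex(night_date(out["timestamp"]))

    for bird_id, ev in events.items():
        sel = (out["bird_id"] == bird_id).to_numpy()
        if not sel.any() or ev.is_empty:
            continue
        bird_nd = nd[sel]
        stage = np.full(sel.sum(), None, dtype=object)
        offset = np.full(sel.sum(), np.nan)

        def apply(mask: np.ndarray, name: str, off: np.ndarray) -> None:
            stage[mask] = name
            offset[mask] = off[mask]

        missing = []
        for name, anchor, lo, hi in (
            ("fall_premigration", ev.fall_departure, -win.fall_premigration_days, -1),
            ("winter_arrival", ev.winter_arrival, 0, win.arrival_days - 1),
            ("spring_premigration", ev.spring_departure, -win.spring_premigration_days, -1),
            ("spring_arrival", ev.spring_arrival, 0, win.arrival_days - 1),
        ):
            if anchor is None:
                missing.append(name)
                continue
            off = (bird_nd - pd.Timestamp(anchor)).days.to_numpy()
            apply((off >= lo) & (off <= hi), name, off)
        if missing:
            import warnings

            warnings.warn(f"{bird_id}: missing anchor for stages {missing}")

        # migration / stopover nights override premigration windows
        for name, nights, anchor in (
            ("fall_migration", ev.fall_flight_nights, ev.fall_departure),
            ("fall_stopover", ev.fall_stopover_nights, ev.fall_departure),
            ("spring_migration", ev.spring_flight_nights, ev.spring_departure),
            ("spring_stopover", ev.spring_stopover_nights, ev.spring_departure),
        ):
            if not nights or anchor is None:
                continue
            night_set = pd.DatetimeIndex([pd.Timestamp(d) for d in nights])
            mask = bird_nd.isin(night_set)
            off = (bird_nd - pd.Timestamp(anchor)).days.to_numpy()
            apply(np.asarray(mask), name, off)

        out.loc[sel, "stage"] = stage
        out.loc[sel, "day_offset"] = offset
    return out


def pair_residents_to_migrants(
    migrant_records: pd.DataFrame,
    resident_records: pd.DataFrame,
    metadata: pd.DataFrame,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Pair each migrant measurement with at most one same-sex, same-time resident.

    Within every (timestamp, sex) cell, residents are distributed among the
    migrants by a seeded random one-to-one matching, so across the dataset
    every resident measurement is referenced at most once and residents are
    spread as evenly as the counts allow.  Returns the paired frame (migrant
    columns plus ``resident_*`` columns) and a report with unpaired counts.
    """
    rng = np.random.default_rng(seed)
    sex = metadata.set_index("bird_id")["sex"]

    mig = migrant_records.copy()
    res = resident_records.copy()
    if res.empty:
        report = {
            "n_migrant_measurements": len(mig),
            "n_resident_measurements": 0,
            "n_pairs": 0,
            "n_unpaired_migrant": len(mig),
        }
        return mig.iloc[0:0].assign(resident_bird_id=pd.Series(dtype=object)), report
    mig["sex"] = mig["bird_id"].map(sex)
    res["sex"] = res["bird_id"].map(sex)

    # seeded shuffle, then rank within each (timestamp, sex) cell
    mig = mig.sample(frac=1.0, random_state=rng.integers(2**31)).reset_index(drop=True)
    res = res.sample(frac=1.0, random_state=rng.integers(2**31)).reset_index(drop=True)
    mig["_rank"] = mig.groupby(["timestamp", "sex"]).cumcount()
    res["_rank"] = res.groupby(["timestamp", "sex"]).cumcount()

    res_cols = {c: f"resident_{c}" for c in res.columns if c not in ("timestamp", "sex", "_rank")}
    paired = mig.merge(
        res.rename(columns=res_cols), on=["timestamp", "sex", "_rank"], how="left"
    )
    matched = paired["resident_bird_id"].notna()
    report = {
        "n_migrant_measurements": len(mig),
        "n_resident_measurements": len(res),
        "n_pairs": int(matched.sum()),
        "n_unpaired_migrant": int((~matched).sum()),
    }
    out = (
        paired.loc[matched]
        .drop(columns=["_rank"])
        .sort_values(["bird_id", "timestamp"], kind="stable")
        .reset_index(drop=True)
    )
    # hard guarantee: no resident measurement referenced twice
    dup = out.duplicated(subset=["resident_bird_id", "timestamp"]).sum()
    assert dup == 0, "pairing produced duplicated resident references"
    return out, report


def paired_to_long(paired: pd.DataFrame, value_col: str = "f_H_bpm") -> pd.DataFrame:
    """Stack a paired frame into long format for the event-centred models.

    Each pair contributes a migrant row and a resident row sharing the
    migrant's stage and day-offset (that is how residents acquire an
    event-centred time axis).
    """
    base_cols = ["timestamp", "stage", "day_offset", "sex"]
    mig = paired[base_cols + ["bird_id", value_col]].copy()
    mig["strategy"] = "migrant"
    res = paired[base_cols + ["resident_bird_id", f"resident_{value_col}"]].rename(
        columns={"resident_bird_id": "bird_id", f"resident_{value_col}": value_col}
    )
    res["strategy"] = "resident"
    return pd.concat([mig, res], ignore_index=True)


def thin_autocorrelation(
    records: pd.DataFrame, fraction: float = 0.30, seed: int = 0
) -> pd.DataFrame:
    """Randomly discard ``fraction`` of each bird's measurements.

    Exactly ``round(fraction * n)`` records are removed per bird, uniformly
    at random, deterministically for a given seed.
    """
    if not 0.0 <= fraction < 1.0:
        raise ValueError("fraction must lie in [0, 1)")
    if fraction == 0.0:
        return records.copy()
    rng = np.random.default_rng(seed)
    keep_parts = []
    for _, grp in records.groupby("bird_id", sort=True):
        n_drop = int(round(fraction * len(grp)))
        drop_idx = rng.choice(len(grp), size=n_drop, replace=False)
        mask = np.ones(len(grp), dtype=bool)
        mask[drop_idx] = False
        keep_parts.append(grp.iloc[mask])
    return pd.concat(keep_parts).sort_index()
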