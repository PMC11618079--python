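"""Flight/stationary classification of nocturnal logger measurements.

A gradient-boosted tree ensemble is trained on measurements with known
flight status (telemetry-anchored in the field, generator truth in
simulation) using heart rate, body temperature, the logger identity and
per-individual standardized features.  Nightly measurement labels are then
aggregated to night-level calls, from which departures, arrivals and
stopovers are derived.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date, timedelta

import numpy as np
import pandas as pd
from sklearn.ensemble import GradientBoostingClassifier
from sklearn.metrics import roc_auc_score

from .events import MigrationEvents
from .solar import night_date

FEATURE_COLUMNS = [
    "f_H_bpm",
    "T_b_C",
    "logger_code",
    "fH_scaled",
    "Tb_scaled",
    "fH_diff_mean",
    "Tb_diff_mean",
    "Tb_prop_increase",
]

#: fraction of a night's intervals that must be flight-labelled for a
#: flight night call
DEFAULT_NIGHT_FRACTION = 0.25

#: fall/spring journeys are split at this (month, day) boundary
SEASON_SPLIT = (2, 1)


def build_features(
    records: pd.DataFrame,
    baseline_days: int = 30,
) -> pd.DataFrame:
    """Per-measurement feature rows for the flight classifier.

    Individual scaling statistics (mean/sd of f_H and T_b) are computed on
    each bird's first ``baseline_days`` days — the pre-migratory window —
    so flight nights cannot leak into the standardization.  The first
    interval per bird has no previous value and is dropped
    (``Tb_prop_increase`` undefined).
    """
    out = records.sort_values(["bird_id", "timestamp"], kind="stable").copy()
    counts = out.groupby("bird_id")["timestamp"].transform("size")
    if (counts <= 1).any():
        import warnings

        dropped = out.loc[counts <= 1, "bird_id"].unique().tolist()
        warnings.warn(f"birds with a single measurement yield no feature rows: {dropped}")
    out = out.loc[counts > 1]
    if out.empty:
        return out.assign(**{c: [] for c in FEATURE_COLUMNS if c not in out})

    start = out.groupby("bird_id")["timestamp"].transform("min")
    in_base = out["timestamp"] < start + pd.Timedelta(days=baseline_days)
    base = out.loc[in_base].groupby("bird_id").agg(
        fH_mean=("f_H_bpm", "mean"),
        fH_sd=("f_H_bpm", "std"),
        Tb_mean=("T_b_C", "mean"),
        Tb_sd=("T_b_C", "std"),
    )
    out = out.merge(base, left_on="bird_id", right_index=True, how="left")
    out["fH_scaled"] = (out["f_H_bpm"] - out["fH_mean"]) / out["fH_sd"]
    out["Tb_scaled"] = (out["T_b_C"] - out["Tb_mean"]) / out["Tb_sd"]
    out["fH_diff_mean"] = out["f_H_bpm"] - out["fH_mean"]
    out["Tb_diff_mean"] = out["T_b_C"] - out["Tb_mean"]

    prev = out.groupby("bird_id")["T_b_C"].shift(1)
    out["Tb_prop_increase"] = out["T_b_C"] / prev - 1.0
    out = out.loc[prev.notna()]

    out["logger_code"] = out["logger_id"].astype("category").cat.codes
    return out.drop(columns=["fH_mean", "fH_sd", "Tb_mean", "Tb_sd"]).reset_index(drop=True)


@dataclass
class BoostedTreeParams:
    """Hyperparameters of the boosted classifier (R-gbm style defaults)."""

    n_trees: int = 500
    max_depth: int = 3
    learning_rate: float = 0.05
    subsample: float = 1.0


@dataclass
class TrainedClassifier:
    model: GradientBoostingClassifier
    feature_columns: list[str]
    training_auc: float


def train_migration_model(
    features: pd.DataFrame,
    labels: np.ndarray | pd.Series,
    hyperparams: BoostedTreeParams | None = None,
    seed: int = 0,
) -> TrainedClassifier:
    """Fit the boosted flight/stationary classifier on labelled rows."""
    hp = hyperparams or BoostedTreeParams()
    y = np.asarray(labels).astype(int)
    if len(np.unique(y)) < 2:
        raise ValueError("training labels contain a single class")
    X = features[FEATURE_COLUMNS].to_numpy()
    model = GradientBoostingClassifier(
        n_estimators=hp.n_trees,
        max_depth=hp.max_depth,
        learning_rate=hp.learning_rate,
        subsample=hp.subsample,
        random_state=seed,
    )
    model.fit(X, y)
    auc = float(roc_auc_score(y, model.predict_proba(X)[:, 1]))
    return TrainedClassifier(model=model, feature_columns=list(FEATURE_COLUMNS), training_auc=auc)


def classify_measurements(
    clf: TrainedClassifier,
    features: pd.DataFrame,
    threshold: float = 0.5,
    nocturnal_only: bool = True,
) -> pd.DataFrame:
    """Attach flight probability and label to (nocturnal) feature rows."""
    missing = [c for c in clf.feature_columns if c not in features.columns]
    if missing:
        raise ValueError(f"feature schema mismatch, missing columns: {missing}")
    out = features.copy()
    if nocturnal_only:
        out = out.loc[out["is_night"]].copy()
    proba = clf.model.predict_proba(out[clf.feature_columns].to_numpy())[:, 1]
    out["flight_prob"] = proba
    out["flight_label"] = proba >= threshold
    return out


def aggregate_nights(
    labelled: pd.DataFrame,
    night_fraction: float = DEFAULT_NIGHT_FRACTION,
) -> pd.DataFrame:
    """Night-level calls: flight if the flight-labelled fraction reaches the cutoff.

    Returns one row per (bird_id, night_date) with the interval count,
    flight fraction and the call.
    """
    sub = labelled.loc[labelled["is_night"]].copy()
    sub["night_date"] = night_date(sub["timestamp"])
    calls = (
        sub.groupby(["bird_id", "night_date"])["flight_label"]
        .agg(n_intervals="size", flight_fraction="mean")
        .reset_index()
    )
    calls["call"] = np.where(calls["flight_fraction"] >= night_fraction, "flight", "stationary")
    return calls


def derive_migration_events(
    night_calls: pd.DataFrame,
    season_split: tuple[int, int] = SEASON_SPLIT,
) -> dict[str, MigrationEvents]:
    """Departure/arrival/stopover events from night-level calls.

    The first fall flight night is the fall departure; the winter arrival is
    the morning after the last fall flight night; stationary nights strictly
    between are stopovers.  Spring is symmetric.  Flight nights are assigned
    to fall or spring by the calendar split (default 1 February).
    """
    events: dict[str, MigrationEvents] = {}
    for bird_id, grp in night_calls.groupby("bird_id"):
        flights = pd.DatetimeIndex(grp.loc[grp["call"] == "flight", "night_date"]).sort_values()
        if flights.empty:
            events[bird_id] = MigrationEvents(bird_id)
            continue
        split_year = flights[0].year + (1 if flights[0].month >= 7 else 0)
        split = pd.Timestamp(date(split_year, *season_split))
        fall = [t.date() for t in flights[flights < split]]
        spring = [t.date() for t in flights[flights >= split]]

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
            fall_departure=fall[0] if fall else None,
            fall_flight_nights=fall,
            fall_stopover_nights=stopovers(fall),
            winter_arrival=fall[-1] + timedelta(days=1) if fall else None,
            spring_departure=spring[0] if spring else None,
            spring_flight_nights=spring,
            spring_stopover_nights=stopovers(spring),
            spring_arrival=spring[-1] + timedelta(days=1) if spring else None,
        )
        try:
            ev.validate()
        except ValueError as exc:  # pragma: no cover - consistency warning path
            import warnings

            warnings.warn(f"inconsistent event sequence for {bird_id}: {exc}")
        events[bird_id] = ev
    return events


def evaluate_classifier(
    labelled: pd.DataFrame,
    truth_flight: pd.Series | np.ndarray,
    night_calls: pd.DataFrame | None = None,
    truth_night_calls: pd.DataFrame | None = None,
) -> dict[str, float]:
    """Measurement-level AUC and (optionally) night-level percent agreement."""
    out = {
        "auc": float(roc_auc_score(np.asarray(truth_flight).astype(int), labelled["flight_prob"]))
    }
    if night_calls is not None and truth_night_calls is not None:
        merged = night_calls.merge(
            truth_night_calls, on=["bird_id", "night_date"], suffixes=("", "_true")
        )
        out["night_agreement_pct"] = float(100.0 * (merged["call"] == merged["call_true"]).mean())
    return out


def true_night_calls(latent: pd.DataFrame, night_fraction: float = DEFAULT_NIGHT_FRACTION) -> pd.DataFrame:
    """Ground-truth night calls from the generator's latent flight flags."""
    sub = latent.loc[latent["is_night"]].copy()
    sub["night_date"] = night_date(sub["timestamp"])
    calls = (
        sub.groupby(["bird_id", "night_date"])["is_flight"]
        .agg(n_intervals="size", flight_fraction="mean")
        .reset_index()
    )
    calls["call"] = np.where(calls["flight_fraction"] >= night_fraction, "flight", "stationary")
    return calls
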