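"""Quality control of logger heart-rate measurements.

The logger's internal quality index (QI) is a per-device signal-to-noise
class that is not comparable between devices, so error rates are calibrated
per (logger, QI class) against the raw-ECG verification subsample saved
every 60 h.  Filtering then keeps only measurements whose class has a known
error rate below the threshold and whose value lies within plausibility
bounds.  Body-temperature values come from a factory-calibrated sensor and
are retained independently of the heart-rate filter.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: heart rates outside this bpm range are considered implausible in the field
DEFAULT_FH_BOUNDS = (60.0, 800.0)
#: a logger value differing from the ECG-derived truth by more than this
#: relative fraction counts as an error
DEFAULT_MISMATCH_TOLERANCE = 0.10
#: minimum truth subsamples per (logger, class) before a rate is defined
DEFAULT_MIN_TRUTH_SAMPLES = 5
#: classes with a calibrated error rate at or above this are discarded
DEFAULT_MAX_ERROR = 0.15


def estimate_qi_error_rates(
    records: pd.DataFrame,
    mismatch_tolerance: float = DEFAULT_MISMATCH_TOLERANCE,
    min_truth_samples: int = DEFAULT_MIN_TRUTH_SAMPLES,
) -> pd.DataFrame:
    """Per-(logger, QI class) error-rate table from truth subsamples.

    A truth subsample counts as an error when
    ``|f_H - true_fH| / true_fH > mismatch_tolerance``.  Classes with fewer
    than ``min_truth_samples`` subsamples get ``error_rate = NaN``
    (undefined, not zero).

    Returns columns: logger_id, qi_class, n_truth_samples, error_rate.
    """
    truth = records.loc[records["has_ecg_truth"] & records["true_fH_bpm"].notna()].copy()
    all_pairs = records[["logger_id", "qi_class"]].drop_duplicates()

    if truth.empty:
        table = all_pairs.copy()
        table["n_truth_samples"] = 0
        table["error_rate"] = np.nan
        return table.reset_index(drop=True)

    rel = (truth["f_H_bpm"] - truth["true_fH_bpm"]).abs() / truth["true_fH_bpm"]
    truth["is_error"] = rel > mismatch_tolerance
    grouped = (
        truth.groupby(["logger_id", "qi_class"], observed=True)["is_error"]
        .agg(n_truth_samples="size", error_rate="mean")
        .reset_index()
    )
    table = all_pairs.merge(grouped, on=["logger_id", "qi_class"], how="left")
    table["n_truth_samples"] = table["n_truth_samples"].fillna(0).astype(int)
    table.loc[table["n_truth_samples"] < min_truth_samples, "error_rate"] = np.nan
    return table.sort_values(["logger_id", "qi_class"]).reset_index(drop=True)


@dataclass
class FilterReport:
    n_input: int = 0
    n_kept_fh: int = 0
    n_dropped_rate: int = 0
    n_dropped_bounds: int = 0
    #: loggers with no QI class passing the error threshold
    excluded_loggers: list[str] = field(default_factory=list)


def filter_by_quality(
    records: pd.DataFrame,
    table: pd.DataFrame,
    max_error: float = DEFAULT_MAX_ERROR,
    fh_bounds: tuple[float, float] = DEFAULT_FH_BOUNDS,
) -> tuple[pd.DataFrame, pd.DataFrame, FilterReport]:
    """Keep records whose QI class passes calibration and whose f_H is plausible.

    Returns ``(kept_fh, kept_tb, report)``: the heart-rate-valid records,
    the body-temperature records (retained independently of the f_H filter),
    and an exclusion report listing loggers without a single passing class.
    Input frames are never mutated; filtering is idempotent.
    """
    report = FilterReport(n_input=len(records))
    if records.empty:
        return records.copy(), records.copy(), report

    merged = records.merge(
        table[["logger_id", "qi_class", "error_rate"]],
        on=["logger_id", "qi_class"],
        how="left",
    )
    rate_ok = merged["error_rate"].notna() & (merged["error_rate"] < max_error)
    lo, hi = fh_bounds
    bounds_ok = merged["f_H_bpm"].between(lo, hi)

    kept_fh = records.loc[(rate_ok & bounds_ok).to_numpy()].copy()
    kept_tb = records.copy()  # T_b sensor is pre-calibrated; retain all

    report.n_kept_fh = len(kept_fh)
    report.n_dropped_rate = int((~rate_ok).sum())
    report.n_dropped_bounds = int((rate_ok & ~bounds_ok).sum())

    passing = table.loc[table["error_rate"] < max_error, "logger_id"].unique()
    report.excluded_loggers = sorted(set(records["logger_id"]) - set(passing))
    return kept_fh, kept_tb, report
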