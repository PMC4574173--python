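"""Step I of the CO2 method: from raw gas log to CH4:CO2 ratios.

The stage matches 15-s gas samples to AMS visits, subtracts the barn
background estimated from daily instrument-disconnection windows, drops
samples whose corrected CO2 falls below a threshold (default 400 ppm,
guarding against diluted samples when the cow's muzzle is away from the
inlet), and aggregates per-sample ratios up the visit / day / period
hierarchy.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal

import numpy as np
import pandas as pd

from .config import ConfigurationError

__all__ = [
    "BarnBackground",
    "match_visits",
    "estimate_barn_background",
    "correct_background",
    "filter_low_co2",
    "compute_ratios",
    "process_gas_log",
]

Level = Literal["sample", "visit", "day", "period"]


class DataConsistencyError(ValueError):
    """Raised for inconsistent inputs (e.g. overlapping visit intervals)."""


class EstimationError(ValueError):
    """Raised when an estimate cannot be formed (e.g. no background samples)."""


@dataclass(frozen=True)
class BarnBackground:
    """Average barn-air concentrations used as the correction pair."""

    ch4_ppm: float
    co2_ppm: float
    n_samples: int
    per_day: pd.DataFrame | None = None   # date, ch4_ppm, co2_ppm, n (diagnostics)

    def __post_init__(self) -> None:
        if self.n_samples <= 0:
            raise EstimationError("background estimated from zero samples")


def match_visits(gas: pd.DataFrame, visits: pd.DataFrame) -> pd.DataFrame:
    """Assign each gas sample to the AMS visit containing its timestamp.

    Intervals are half-open ``[entry, exit)``: a sample at the entry time
    belongs to the visit, one at the exit time does not (avoids double
    assignment at back-to-back visits).  Samples outside all visits get a
    missing ``visit_id``/``cow_id``.  Overlapping visits are impossible at
    a single sampling point and raise :class:`DataConsistencyError`.
    """
    gas = gas.sort_values("timestamp", ignore_index=True)
    out = gas.copy()
    out["visit_id"] = pd.Series(pd.NA, index=out.index, dtype="object")
    out["cow_id"] = pd.Series(pd.NA, index=out.index, dtype="object")
    if visits.empty:
        return out
    v = visits.sort_values("entry_time", ignore_index=True)
    overlap = v["entry_time"].iloc[1:].to_numpy() < v["exit_time"].iloc[:-1].to_numpy()
    if overlap.any():
        i = int(np.argmax(overlap))
        raise DataConsistencyError(
            f"visits {v['visit_id'].iloc[i]} and {v['visit_id'].iloc[i + 1]} overlap in time"
        )
    # position of each sample among the sorted entry times
    idx = np.searchsorted(v["entry_time"].to_numpy(), out["timestamp"].to_numpy(), side="right") - 1
    valid = idx >= 0
    inside = np.zeros(len(out), dtype=bool)
    inside[valid] = out["timestamp"].to_numpy()[valid] < v["exit_time"].to_numpy()[idx[valid]]
    out.loc[inside, "visit_id"] = v["visit_id"].to_numpy()[idx[inside]]
    out.loc[inside, "cow_id"] = v["cow_id"].to_numpy()[idx[inside]]
    return out


def estimate_barn_background(
    gas: pd.DataFrame,
    disconnected_windows: pd.DataFrame | Iterable[tuple],
) -> BarnBackground:
    """Grand mean of the samples inside the daily disconnection windows.

    The instrument is disconnected ~10 min per measurement day to sample
    barn air; the mean over all those samples is used as a single
    correction pair for the whole period.  Per-day means are returned for
    diagnostics (and for the optional per-day correction mode).
    """
    if isinstance(disconnected_windows, pd.DataFrame):
        wins = list(zip(disconnected_windows["start"], disconnected_windows["end"]))
    else:
        wins = list(disconnected_windows)
    if not wins:
        raise EstimationError("no disconnection windows supplied")
    ts = gas["timestamp"]
    mask = np.zeros(len(gas), dtype=bool)
    for a, b in wins:
        mask |= ((ts >= pd.Timestamp(a)) & (ts < pd.Timestamp(b))).to_numpy()
    sub = gas.loc[mask]
    if sub.empty:
        raise EstimationError("no gas samples fall inside the disconnection windows")
    per_day = (
        sub.assign(date=sub["timestamp"].dt.date)
        .groupby("date", as_index=False)
        .agg(ch4_ppm=("ch4_ppm", "mean"), co2_ppm=("co2_ppm", "mean"), n=("ch4_ppm", "size"))
    )
    return BarnBackground(
        ch4_ppm=float(sub["ch4_ppm"].mean()),
        co2_ppm=float(sub["co2_ppm"].mean()),
        n_samples=int(len(sub)),
        per_day=per_day,
    )


def correct_background(
    gas: pd.DataFrame,
    background: BarnBackground,
    mode: Literal["period", "day"] = "period",
) -> pd.DataFrame:
    """Subtract the barn background from the raw concentrations.

    Adds ``corrected_ch4_ppm`` / ``corrected_co2_ppm``; raw columns are
    preserved and negative corrected values are retained (they are only
    ever removed by the CO2 filter).  ``mode='day'`` subtracts that day's
    window mean instead of the single period pair.
    """
    out = gas.copy()
    if mode == "period":
        out["corrected_ch4_ppm"] = out["ch4_ppm"] - background.ch4_ppm
        out["corrected_co2_ppm"] = out["co2_ppm"] - background.co2_ppm
        return out
    if background.per_day is None or background.per_day.empty:
        raise EstimationError("per-day correction requested but no per-day means available")
    per_day = background.per_day.set_index("date")
    dates = out["timestamp"].dt.date
    bg_ch4 = dates.map(per_day["ch4_ppm"]).fillna(background.ch4_ppm)
    bg_co2 = dates.map(per_day["co2_ppm"]).fillna(background.co2_ppm)
    out["corrected_ch4_ppm"] = out["ch4_ppm"] - bg_ch4
    out["corrected_co2_ppm"] = out["co2_ppm"] - bg_co2
    return out


def filter_low_co2(gas: pd.DataFrame, threshold_ppm: float = 400.0) -> pd.DataFrame:
    """Drop samples whose corrected CO2 is strictly below the threshold.

    "Below" is strict: a sample exactly at the threshold is kept.
    """
    if threshold_ppm <= 0:
        raise ConfigurationError("threshold_ppm must be > 0")
    if "corrected_co2_ppm" not in gas.columns:
        raise DataConsistencyError("corrected concentrations missing; run correct_background first")
    return gas.loc[gas["corrected_co2_ppm"] >= threshold_ppm].reset_index(drop=True)


def _mean_or_nan(x: pd.Series) -> float:
    return float(x.mean()) if len(x) else float("nan")


def compute_ratios(
    gas: pd.DataFrame,
    level: Level = "day",
    aggregation: Literal["mean-of-ratios", "ratio-of-means"] = "mean-of-ratios",
) -> pd.DataFrame:
    """CH4:CO2 ratios at the requested aggregation level.

    Per-sample ratio = corrected CH4 / corrected CO2.  ``mean-of-ratios``
    (default) then averages sample ratios within a visit, visit ratios
    within a cow-day, and day ratios within the cow's period.
    ``ratio-of-means`` instead divides summed corrected CH4 by summed
    corrected CO2 at each level.  Each output row carries ``n``, the
    number of units averaged (samples for the visit level, visits for the
    day level, days for the period level).

    Input must be visit-matched, background-corrected and filtered; only
    samples with an assigned visit contribute.
    """
    need = {"visit_id", "cow_id", "corrected_ch4_ppm", "corrected_co2_ppm"}
    missing = need - set(gas.columns)
    if missing:
        raise DataConsistencyError(f"missing columns: {sorted(missing)}")
    g = gas.dropna(subset=["visit_id"]).copy()
    g["date"] = g["timestamp"].dt.date
    g["ratio"] = g["corrected_ch4_ppm"] / g["corrected_co2_ppm"]
    if level == "sample":
        return g[["cow_id", "date", "visit_id", "timestamp", "ratio"]].assign(n=1)

    if aggregation == "mean-of-ratios":
        visit = g.groupby(["cow_id", "date", "visit_id"], as_index=False).agg(
            ratio=("ratio", "mean"),
            n=("ratio", "size"),
            first_ts=("timestamp", "min"),
        )
    else:
        visit = g.groupby(["cow_id", "date", "visit_id"], as_index=False).agg(
            ch4=("corrected_ch4_ppm", "sum"),
            co2=("corrected_co2_ppm", "sum"),
            n=("ratio", "size"),
            first_ts=("timestamp", "min"),
        )
        visit["ratio"] = visit["ch4"] / visit["co2"]
        visit = visit.drop(columns=["ch4", "co2"])
    visit["hour_of_day"] = visit["first_ts"].dt.hour
    visit = visit.drop(columns=["first_ts"])
    if level == "visit":
        return visit

    day = visit.groupby(["cow_id", "date"], as_index=False).agg(
        ratio=("ratio", "mean"), n=("ratio", "size")
    )
    if level == "day":
        return day

    period = day.groupby("cow_id", as_index=False).agg(
        ratio=("ratio", "mean"), n=("ratio", "size")
    )
    return period


def process_gas_log(
    gas: pd.DataFrame,
    visits: pd.DataFrame,
    background_windows: pd.DataFrame,
    threshold_ppm: float = 400.0,
    background_mode: Literal["period", "day"] = "period",
    aggregation: Literal["mean-of-ratios", "ratio-of-means"] = "mean-of-ratios",
) -> dict:
    """Run Step I end to end; returns every intermediate of interest.

    Keys: ``background``, ``matched``, ``corrected``, ``filtered``,
    ``ratios`` (dict level -> table) and ``counts`` (row bookkeeping).
    """
    background = estimate_barn_background(gas, background_windows)
    matched = match_visits(gas, visits)
    corrected = correct_background(matched, background, background_mode)
    filtered = filter_low_co2(corrected, threshold_ppm)
    ratios = {
        lvl: compute_ratios(filtered, lvl, aggregation)
        for lvl in ("sample", "visit", "day", "period")
    }
    counts = {
        "read": int(len(gas)),
        "kept": int(len(filtered)),
        "filtered": int(len(gas) - len(filtered)),
        "matched": int(matched["visit_id"].notna().sum()),
    }
    return {
        "background": background,
        "matched": matched,
        "corrected": corrected,
        "filtered": filtered,
        "ratios": ratios,
        "counts": counts,
    }
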