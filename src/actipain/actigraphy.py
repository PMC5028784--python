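"""Actigraphy phenotypes from 1-minute accelerometer epochs.

Accelerometers differ in sensitivity, so every device's counts are first
referenced to that device's calibration maximum and expressed as a
percentage.  Three phenotypes are then derived from the last seven complete
(midnight-to-midnight, fully worn) days of wear:

1. **Time spent active** — the trace is cut into successive five-minute
   windows; windows with mean activity below 2.5 % of the device maximum are
   "inactive" (sleeping or resting), the rest "active".  Active windows are
   summed over each 24 h day and averaged over the seven days.
2. **Intensity of activity** — the median 1-minute activity (as % of device
   maximum) over epochs falling in active windows, pooled across the week.
3. **Endurance** — minutes spent at 0, 1-24, 25-49, 50-74 and >= 75 % of the
   participant's own maximum recorded 1-minute activity for the week.

All functions operate on :class:`EpochSeries`; :func:`summarize` runs the
full chain and returns an :class:`ActivitySummary`.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "EpochSeries",
    "ActivityConfig",
    "ActivitySummary",
    "normalize_counts",
    "select_complete_days",
    "window_means",
    "classify_windows",
    "time_active",
    "median_intensity",
    "endurance_profile",
    "summarize",
    "read_trace_csv",
    "write_trace_csv",
    "read_device_maxima",
]

MINUTES_PER_DAY = 1440


@dataclass
class EpochSeries:
    """One participant's 1-minute accelerometer record.

    ``counts`` holds raw counts/min unless ``normalized`` is True, in which
    case values are percentages of ``device_max``.
    """

    participant_id: str
    device_id: str
    timestamps: pd.DatetimeIndex
    counts: np.ndarray
    worn: np.ndarray
    device_max: float
    normalized: bool = False

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        self.worn = np.asarray(self.worn, dtype=bool)
        if not (len(self.timestamps) == len(self.counts) == len(self.worn)):
            raise ValueError("timestamps, counts and worn must have equal length")
        if len(self.timestamps) > 1:
            # 1-minute grid, strictly increasing; gaps are only allowed at
            # midnight boundaries (a trimmed series may skip incomplete days)
            deltas = np.diff(self.timestamps.asi8)
            minute = 60_000_000_000
            if np.any(deltas <= 0) or np.any(deltas % minute):
                raise ValueError("timestamps must be strictly increasing on a 1-minute grid")
            gap_starts = self.timestamps[1:][deltas > minute]
            if len(gap_starts) and not (
                (gap_starts.hour == 0) & (gap_starts.minute == 0)
            ).all():
                raise ValueError("within-day gaps are not allowed in an epoch series")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")

    def __len__(self) -> int:
        return len(self.counts)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "timestamp": self.timestamps,
                "count": self.counts,
                "worn": self.worn.astype(int),
            }
        )


@dataclass(frozen=True)
class ActivityConfig:
    """Tunable parameters of the phenotype extraction."""

    window_minutes: int = 5
    inactive_threshold_pct: float = 2.5
    analysis_days: int = 7
    endurance_edges: tuple[float, float, float, float] = (0.0, 25.0, 50.0, 75.0)
    #: "pooled": median over all active-window epochs of the week;
    #: "daily": median of the seven daily medians.
    intensity_method: str = "pooled"

    def __post_init__(self) -> None:
        if MINUTES_PER_DAY % self.window_minutes:
            raise ValueError("window_minutes must divide 1440")
        if not 0 < self.inactive_threshold_pct < 100:
            raise ValueError("inactive_threshold_pct must be in (0, 100)")
        if self.intensity_method not in ("pooled", "daily"):
            raise ValueError("intensity_method must be 'pooled' or 'daily'")


@dataclass
class ActivitySummary:
    """Derived activity phenotype for one participant."""

    participant_id: str
    minutes_active_per_day: float
    median_active_intensity: float  # % of device max; NaN if never active
    intensity_defined: bool
    endurance_minutes: tuple[float, float, float, float, float]
    individual_max: float  # % of device max
    days_used: list  # calendar dates analysed

    def to_dict(self) -> dict:
        d = {
            "participant_id": self.participant_id,
            "minutes_active_per_day": self.minutes_active_per_day,
            "median_active_intensity": self.median_active_intensity,
            "intensity_defined": self.intensity_defined,
            "individual_max": self.individual_max,
            "days_used": [str(x) for x in self.days_used],
        }
        labels = ("zero", "1_24", "25_49", "50_74", "75_plus")
        for lab, v in zip(labels, self.endurance_minutes):
            d[f"endurance_{lab}"] = v
        return d


def normalize_counts(series: EpochSeries) -> EpochSeries:
    """Express counts as % of the device calibration maximum.

    Counts above the device maximum (calibration drift) are clamped to
    100 % with a warning.
    """
    if series.normalized:
        return series
    if series.device_max <= 0:
        raise ValueError(f"device_max must be positive, got {series.device_max}")
    pct = 100.0 * series.counts / series.device_max
    n_over = int(np.sum(pct > 100.0))
    if n_over:
        logger.warning(
            "participant %s: %d epochs exceed device max %s; clamped to 100%%",
            series.participant_id,
            n_over,
            series.device_max,
        )
        pct = np.minimum(pct, 100.0)
    return replace(series, counts=pct, normalized=True)


def complete_day_dates(series: EpochSeries) -> list:
    """Calendar dates (midnight-to-midnight) with all 1440 epochs present and worn."""
    df = pd.DataFrame({"worn": series.worn}, index=series.timestamps)
    by_day = df.groupby(series.timestamps.date)["worn"]
    agg = by_day.agg(["size", "sum"])
    ok = agg[(agg["size"] == MINUTES_PER_DAY) & (agg["sum"] == MINUTES_PER_DAY)]
    return sorted(ok.index)


def select_complete_days(series: EpochSeries, n_days: int | None = 7) -> EpochSeries:
    """Keep the last ``n_days`` complete days (all 1440 epochs present, worn).

    Raises if fewer complete days exist — such participants are excluded as
    inconsistent wearers.
    """
    if n_days is None:
        n_days = 7
    if n_days < 1:
        raise ValueError("n_days must be >= 1")
    dates = complete_day_dates(series)
    if len(dates) < n_days:
        raise ValueError(
            f"participant {series.participant_id}: only {len(dates)} complete "
            f"day(s) of wear, {n_days} required"
        )
    keep = set(dates[-n_days:])
    mask = np.array([d in keep for d in series.timestamps.date])
    return replace(
        series,
        timestamps=series.timestamps[mask],
        counts=series.counts[mask],
        worn=series.worn[mask],
    )


def _check_complete(series: EpochSeries, window_minutes: int) -> None:
    if len(series) % MINUTES_PER_DAY:
        raise ValueError("series must consist of complete 1440-epoch days")
    if not series.normalized:
        raise ValueError("series must be normalized to % of device max first")


def window_means(series: EpochSeries, window_minutes: int = 5) -> np.ndarray:
    """Means of successive non-overlapping windows aligned to midnight."""
    _check_complete(series, window_minutes)
    return series.counts.reshape(-1, window_minutes).mean(axis=1)


def classify_windows(means: np.ndarray, threshold_pct: float = 2.5) -> np.ndarray:
    """True for active windows.  Inactive iff mean < threshold (strict:
    a window at exactly the threshold counts as active)."""
    return np.asarray(means) >= threshold_pct


def time_active(active: np.ndarray, n_days: int, window_minutes: int = 5) -> float:
    """Mean daily active minutes: active windows summed per day, averaged."""
    active = np.asarray(active, dtype=bool)
    per_day = active.reshape(n_days, -1).sum(axis=1) * window_minutes
    return float(per_day.mean())


def median_intensity(
    series: EpochSeries,
    active: np.ndarray,
    window_minutes: int = 5,
    method: str = "pooled",
) -> tuple[float, bool]:
    """Median 1-minute activity over epochs in active windows.

    Returns ``(value, defined)``; undefined (NaN, False) when the
    participant has no active window at all.
    """
    _check_complete(series, window_minutes)
    epoch_active = np.repeat(np.asarray(active, dtype=bool), window_minutes)
    vals = series.counts[epoch_active]
    if vals.size == 0:
        return float("nan"), False
    if method == "pooled":
        return float(np.median(vals)), True
    # "daily": median of the daily medians over days with any active epoch
    day_idx = np.repeat(np.arange(len(series) // MINUTES_PER_DAY), MINUTES_PER_DAY)
    daily = [
        float(np.median(series.counts[(day_idx == d) & epoch_active]))
        for d in np.unique(day_idx[epoch_active])
    ]
    return float(np.median(daily)), True


def endurance_profile(
    series: EpochSeries, config: ActivityConfig | None = None
) -> tuple[float, float, float, float, float]:
    """Minutes at (0, 1-24, 25-49, 50-74, >=75) % of the individual maximum.

    The individual maximum is the largest normalized 1-minute epoch over the
    analysed week.  Zero counts form their own category; the bins always
    partition the full analysed time.
    """
    config = config or ActivityConfig()
    _check_complete(series, config.window_minutes)
    x = series.counts
    imax = float(x.max())
    if imax == 0.0:
        warnings.warn(
            f"participant {series.participant_id}: individual max is 0; "
            "all time assigned to the zero bin",
            stacklevel=2,
        )
        return (float(len(x)), 0.0, 0.0, 0.0, 0.0)
    pct = 100.0 * x / imax
    zero = x == 0.0
    e1, e2, e3 = config.endurance_edges[1:]
    bins = (
        float(zero.sum()),
        float(np.sum(~zero & (pct < e1))),
        float(np.sum((pct >= e1) & (pct < e2))),
        float(np.sum((pct >= e2) & (pct < e3))),
        float(np.sum(pct >= e3)),
    )
    assert sum(bins) == len(x)
    return bins


def summarize(series: EpochSeries, config: ActivityConfig | None = None) -> ActivitySummary:
    """Full phenotype chain: normalize, trim to the last complete days,
    window, classify, and derive all three phenotypes."""
    config = config or ActivityConfig()
    norm = normalize_counts(series)
    week = select_complete_days(norm, config.analysis_days)
    means = window_means(week, config.window_minutes)
    active = classify_windows(means, config.inactive_threshold_pct)
    minutes = time_active(active, config.analysis_days, config.window_minutes)
    med, defined = median_intensity(
        week, active, config.window_minutes, config.intensity_method
    )
    endurance = endurance_profile(week, config)
    return ActivitySummary(
        participant_id=series.participant_id,
        minutes_active_per_day=minutes,
        median_active_intensity=med,
        intensity_defined=defined,
        endurance_minutes=endurance,
        individual_max=float(week.counts.max()),
        days_used=sorted(set(week.timestamps.date)),
    )


# ---------------------------------------------------------------------------
# file I/O: one CSV per participant + a JSON sidecar of device maxima


def write_trace_csv(series: EpochSeries, path: str | Path) -> None:
    df = series.to_frame()
    df["timestamp"] = df["timestamp"].dt.strftime("%Y-%m-%dT%H:%M")
    df["count"] = df["count"].round().astype(int)
    df.to_csv(path, index=False)


def read_trace_csv(
    path: str | Path,
    device_max: float,
    participant_id: str | None = None,
    device_id: str = "",
) -> EpochSeries:
    df = pd.read_csv(path)
    pid = participant_id if participant_id is not None else Path(path).stem
    return EpochSeries(
        participant_id=pid,
        device_id=device_id,
        timestamps=pd.DatetimeIndex(pd.to_datetime(df["timestamp"])),
        counts=df["count"].to_numpy(dtype=float),
        worn=df["worn"].to_numpy(dtype=bool),
        device_max=device_max,
    )


def read_device_maxima(path: str | Path) -> dict[str, float]:
    with open(path) as fh:
        return {str(k): float(v) for k, v in json.load(fh).items()}
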