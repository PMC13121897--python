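"""Daily tracks and the three movement metrics.

A daily track runs from 16:00 of day D to 14:00 of day D+1 (the window that
brackets the main resting periods of the study population), giving 12
expected 2-h fix slots at 16, 18, ..., 12, 14 h.  Fixes falling in the
(14:00, 16:00) gap belong to no track.  Only tracks with more than 90%
completeness (at most one missing slot) enter the analysis.

Metrics per track:

* daily distance — sum of Euclidean step lengths between consecutive fixes;
* net displacement — straight-line distance first fix -> last fix;
* straightness index — net / daily, in [0, 1]; undefined when daily = 0.

Missing intermediate fixes are bridged (no interpolation): one missing slot
turns two 2-h steps into one 4-h step.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date, timedelta

import numpy as np
import pandas as pd

N_SLOTS = 12
TRACK_START_HOUR = 16
SLOT_TOL_MIN = 30.0


@dataclass
class DailyTrack:
    individual_id: str
    track_date: date  # date of the 16:00 boundary
    timestamps: pd.DatetimeIndex
    x: np.ndarray  # km
    y: np.ndarray
    slots: np.ndarray  # slot index 0..11 per fix

    @property
    def n_observed(self) -> int:
        return len(self.slots)

    @property
    def completeness(self) -> float:
        return self.n_observed / N_SLOTS

    @property
    def track_id(self) -> str:
        return f"{self.individual_id}_{self.track_date.isoformat()}"

    @property
    def midpoint(self) -> tuple[float, float]:
        return float(np.mean(self.x)), float(np.mean(self.y))


def segment_days(fixes: pd.DataFrame, slot_tol_min: float = SLOT_TOL_MIN) -> list[DailyTrack]:
    """Assign fixes to 16:00->14:00 daily tracks.

    Parameters
    ----------
    fixes : DataFrame with columns individual_id, timestamp, x_km, y_km.

    A fix belongs to the slot whose nominal time (16:00 + 2h*k) is within
    ``slot_tol_min`` minutes; anything else (including the 14:00-16:00 gap)
    is discarded.  Duplicate timestamps within an individual are an error.
    """
    fixes = fixes.copy()
    fixes["timestamp"] = pd.to_datetime(fixes["timestamp"])
    tracks: list[DailyTrack] = []
    for ind, grp in fixes.groupby("individual_id", sort=True):
        grp = grp.sort_values("timestamp")
        if grp["timestamp"].duplicated().any():
            dup = grp.loc[grp["timestamp"].duplicated(), "timestamp"].iloc[0]
            raise ValueError(f"duplicate timestamp {dup} for individual {ind!r}")
        ts = grp["timestamp"]
        # minutes since the most recent 16:00 boundary
        shifted = ts - pd.Timedelta(hours=TRACK_START_HOUR)
        track_dates = shifted.dt.normalize()
        delta_min = (ts - (track_dates + pd.Timedelta(hours=TRACK_START_HOUR))).dt.total_seconds() / 60.0
        slot = np.round(delta_min / 120.0).astype(int)
        ok = (np.abs(delta_min - 120.0 * slot) <= slot_tol_min) & (slot >= 0) & (slot < N_SLOTS)
        sub = grp[ok.to_numpy()]
        if sub.empty:
            continue
        tdates = track_dates[ok.to_numpy()]
        slots_ok = slot[ok.to_numpy()]
        for tdate, idx in sub.groupby(tdates.to_numpy()).groups.items():
            rows = sub.loc[idx]
            srows = slots_ok.loc[idx].to_numpy()
            if len(np.unique(srows)) < len(srows):
                raise ValueError(f"multiple fixes in one slot for individual {ind!r} on {tdate}")
            order = np.argsort(srows)
            tracks.append(
                DailyTrack(
                    individual_id=str(ind),
                    track_date=pd.Timestamp(tdate).date(),
                    timestamps=pd.DatetimeIndex(rows["timestamp"].to_numpy()[order]),
                    x=rows["x_km"].to_numpy()[order].astype(float),
                    y=rows["y_km"].to_numpy()[order].astype(float),
                    slots=srows[order],
                )
            )
    return tracks


def filter_complete(tracks: list[DailyTrack], min_observed: int = N_SLOTS - 1) -> tuple[list[DailyTrack], dict]:
    """Keep tracks with >90% completeness (>= 11 of 12 slots).

    Returns the surviving tracks and a bookkeeping dict with retained/dropped
    counts, so no record disappears silently.
    """
    kept = [t for t in tracks if t.n_observed >= min_observed]
    report = {"n_input": len(tracks), "n_retained": len(kept), "n_dropped": len(tracks) - len(kept)}
    return kept, report


def daily_distance(track: DailyTrack) -> float:
    """Sum of Euclidean step lengths over consecutive observed fixes (km)."""
    if track.n_observed < 2:
        return float("nan")
    return float(np.hypot(np.diff(track.x), np.diff(track.y)).sum())


def net_displacement(track: DailyTrack) -> float:
    """Euclidean distance from the first to the last observed fix (km)."""
    if track.n_observed < 2:
        return float("nan")
    return float(np.hypot(track.x[-1] - track.x[0], track.y[-1] - track.y[0]))


def straightness(track: DailyTrack) -> float:
    """Net displacement / daily distance; NaN when daily distance is 0
    (the 0/0 ratio is undefined and such days are excluded from modeling)."""
    dd = daily_distance(track)
    if not np.isfinite(dd):
        return float("nan")
    if dd == 0.0:
        return float("nan")
    return net_displacement(track) / dd


def track_metrics(tracks: list[DailyTrack]) -> pd.DataFrame:
    """Per-track metric table (one row per daily track)."""
    rows = []
    for t in tracks:
        mx, my = t.midpoint
        rows.append(
            {
                "track_id": t.track_id,
                "individual_id": t.individual_id,
                "track_date": t.track_date,
                "n_observed": t.n_observed,
                "completeness": t.completeness,
                "daily_distance_km": daily_distance(t),
                "net_displacement_km": net_displacement(t),
                "straightness": straightness(t),
                "mid_x_km": mx,
                "mid_y_km": my,
            }
        )
    return pd.DataFrame(rows)


def summarize_metrics(metrics: pd.DataFrame, columns: tuple[str, ...] = ("daily_distance_km", "net_displacement_km", "straightness")) -> pd.DataFrame:
    """Eight summary statistics per metric: mean, median, SD, min, max, Q1,
    Q3, IQR.  Quantiles use linear interpolation (numpy default); NaNs
    (undefined straightness) are excluded.
    """
    if metrics.empty:
        raise ValueError("cannot summarize an empty metric table")
    rows = {}
    for col in columns:
        v = metrics[col].dropna().to_numpy(dtype=float)
        if v.size == 0:
            raise ValueError(f"no finite values for metric {col!r}")
        q1, q3 = np.quantile(v, [0.25, 0.75])
        rows[col] = {
            "mean": v.mean(),
            "median": float(np.median(v)),
            "sd": v.std(ddof=1) if v.size > 1 else 0.0,
            "min": v.min(),
            "max": v.max(),
            "q1": q1,
            "q3": q3,
            "iqr": q3 - q1,
        }
    return pd.DataFrame(rows).T


def expected_slot_times(track_date: date) -> pd.DatetimeIndex:
    """The 12 nominal fix times of a daily track (16:00 ... next-day 14:00)."""
    start = pd.Timestamp(track_date) + pd.Timedelta(hours=TRACK_START_HOUR)
    return pd.DatetimeIndex([start + timedelta(hours=2 * k) for k in range(N_SLOTS)])
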