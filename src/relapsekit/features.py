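"""Daily features and data-quality ratios from raw event streams.

The synthetic generator normally simulates daily aggregates directly;
this module is the convergent path for raw-event inputs (GPS fixes,
accelerometer samples, screen-state transitions, survey completions).
The derivations for sleep duration, time at home, and screen duration
are reconstructions: fixed, testable rules chosen for this package, not
published definitions (see docs/methods.md).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import DBSCAN

from .streams import FEATURE_CHANNEL

DAY_SECONDS = 86_400
#: surveys the app prompts per day (two prompts of two instruments)
EXPECTED_SURVEYS_PER_DAY = 4


@dataclass(frozen=True)
class QualityRatio:
    participant_id: str
    channel: str  # active | passive
    ratio: float


def active_quality(surveys_completed: int, surveys_expected: int) -> float:
    """Completed / expected surveys, clamped to [0, 1]."""
    if surveys_expected <= 0:
        raise ZeroDivisionError("surveys_expected must be > 0")
    if surveys_completed < 0:
        raise ValueError("surveys_completed must be >= 0")
    return float(min(surveys_completed / surveys_expected, 1.0))


def passive_quality(hours_with_any_data: int, hours_expected: int) -> float:
    """Hours with any passive data / expected hours, clamped to [0, 1]."""
    if hours_expected <= 0:
        raise ZeroDivisionError("hours_expected must be > 0")
    if hours_with_any_data < 0:
        raise ValueError("hours_with_any_data must be >= 0")
    return float(min(hours_with_any_data / hours_expected, 1.0))


def _to_meters(lat: np.ndarray, lon: np.ndarray, lat0: float, lon0: float):
    """Local equirectangular projection (adequate at neighborhood scale)."""
    r = 6_371_000.0
    x = np.radians(lon - lon0) * r * np.cos(np.radians(lat0))
    y = np.radians(lat - lat0) * r
    return np.column_stack([x, y])


def home_anchor(events: pd.DataFrame, radius_m: float = 100.0, min_points: int = 5):
    """Densest nighttime (00:00-06:00) GPS cluster centroid as (lat, lon).

    DBSCAN with ``radius_m`` / ``min_points``; falls back to the median
    position of all fixes when no cluster exists. Returns None when no
    GPS data at all.
    """
    gps = events[events["stream"] == "gps"]
    if not len(gps):
        return None
    hours = (gps["timestamp"] % DAY_SECONDS) // 3600
    night = gps[(hours >= 0) & (hours < 6)]
    pts = night if len(night) >= min_points else gps
    lat0, lon0 = float(pts["lat"].median()), float(pts["lon"].median())
    if len(pts) >= min_points:
        xy = _to_meters(pts["lat"].to_numpy(), pts["lon"].to_numpy(), lat0, lon0)
        labels = DBSCAN(eps=radius_m, min_samples=min_points).fit_predict(xy)
        good = labels >= 0
        if good.any():
            counts = pd.Series(labels[good]).value_counts()
            top = counts.index[0]
            sel = labels == top
            return float(pts["lat"].to_numpy()[sel].mean()), float(
                pts["lon"].to_numpy()[sel].mean()
            )
    return lat0, lon0


def _screen_sessions(screen: pd.DataFrame):
    """On-to-off intervals from screen_state transitions (seconds)."""
    sessions = []
    on_t = None
    for _, row in screen.sort_values("timestamp").iterrows():
        state = str(row["state"]).lower()
        if state == "on" and on_t is None:
            on_t = float(row["timestamp"])
        elif state == "off" and on_t is not None:
            sessions.append((on_t, float(row["timestamp"])))
            on_t = None
    return sessions


def derive_daily(
    events: pd.DataFrame,
    day: int,
    anchor: tuple[float, float] | None = None,
    sleep_threshold: float | None = None,
) -> tuple[float, float, float]:
    """(sleep_duration, home_time, screen_duration) in hours for one day.

    Day boundaries are local midnights, ``day`` counting from the epoch
    of the ``timestamp`` column (seconds / 86400). Sessions straddling
    midnight are clipped to the day. Streams absent for the day yield
    NaN (absence, not zero).
    """
    t0, t1 = day * DAY_SECONDS, (day + 1) * DAY_SECONDS
    events = events.sort_values("timestamp", kind="stable")

    # screen duration: summed on->off session overlap with the day
    screen = events[events["stream"] == "screen_state"]
    screen_today = screen[(screen["timestamp"] >= t0) & (screen["timestamp"] < t1)]
    if len(screen_today) == 0:
        screen_h = np.nan
    else:
        total = 0.0
        for a, b in _screen_sessions(screen):
            total += max(0.0, min(b, t1) - max(a, t0))
        screen_h = total / 3600

    # home time: hours whose modal GPS position is within 100 m of the anchor
    gps = events[events["stream"] == "gps"]
    gps_today = gps[(gps["timestamp"] >= t0) & (gps["timestamp"] < t1)]
    if len(gps_today) == 0:
        home_h = np.nan
    else:
        if anchor is None:
            anchor = home_anchor(events)
        alat, alon = anchor
        hrs = ((gps_today["timestamp"] - t0) // 3600).astype(int)
        home_h = 0.0
        for _, sub in gps_today.groupby(hrs):
            mlat, mlon = float(sub["lat"].median()), float(sub["lon"].median())
            d = np.linalg.norm(_to_meters(np.array([mlat]), np.array([mlon]), alat, alon))
            if d <= 100.0:
                home_h += 1.0

    # sleep: longest 21:00-11:00 run of low-activity, screen-off 10-min bins
    acc = events[events["stream"] == "accelerometer"]
    n0, n1 = t0 - 3 * 3600, t0 + 11 * 3600  # 21:00 previous day .. 11:00
    acc_night = acc[(acc["timestamp"] >= n0) & (acc["timestamp"] < n1)]
    if len(acc_night) == 0:
        sleep_h = np.nan
    else:
        if sleep_threshold is None:
            allbins = (acc["timestamp"] // 600).astype(int)
            bin_var = acc.groupby(allbins)["magnitude"].var().dropna()
            sleep_threshold = float(bin_var.quantile(0.2)) if len(bin_var) else 0.0
        screen_on_bins = set()
        for a, b in _screen_sessions(screen):
            lo, hi = int(a // 600), int(b // 600)
            screen_on_bins.update(range(lo, hi + 1))
        nbins = 14 * 6
        quiet = np.zeros(nbins, dtype=bool)
        bins = ((acc_night["timestamp"] - n0) // 600).astype(int)
        for b, sub in acc_night.groupby(bins):
            v = float(sub["magnitude"].var()) if len(sub) > 1 else 0.0
            absolute = int((n0 + b * 600) // 600)
            quiet[b] = v <= sleep_threshold and absolute not in screen_on_bins
        best = cur = 0
        for q in quiet:
            cur = cur + 1 if q else 0
            best = max(best, cur)
        sleep_h = best * 10 / 60

    return (
        float(np.clip(sleep_h, 0, 24)) if not np.isnan(sleep_h) else np.nan,
        float(np.clip(home_h, 0, 24)) if not np.isnan(home_h) else np.nan,
        float(np.clip(screen_h, 0, 24)) if not np.isnan(screen_h) else np.nan,
    )


def events_to_features(events: pd.DataFrame, enrollment_days: int) -> pd.DataFrame:
    """Convert one participant's raw events to the daily long-form schema.

    Emits the same (id, day, channel, feature, value) layout the
    synthetic generator writes, so both data paths converge.
    """
    pid = str(events["id"].iloc[0]) if len(events) else ""
    anchor = home_anchor(events)
    rows = []
    surveys = events[events["stream"] == "survey"]
    passive = events[events["stream"].isin(["gps", "accelerometer", "screen_state"])]
    for day in range(enrollment_days):
        t0, t1 = day * DAY_SECONDS, (day + 1) * DAY_SECONDS
        sleep_h, home_h, screen_h = derive_daily(events, day, anchor=anchor)
        for feat, val in (
            ("sleep_duration", sleep_h),
            ("home_time", home_h),
            ("screen_duration", screen_h),
        ):
            rows.append({"id": pid, "day": day, "feature": feat, "value": val})
        sv = surveys[(surveys["timestamp"] >= t0) & (surveys["timestamp"] < t1)]
        for inst, sub in sv.groupby("instrument"):
            rows.append(
                {"id": pid, "day": day, "feature": str(inst),
                 "value": float(sub["score"].mean())}
            )
        rows.append(
            {"id": pid, "day": day, "feature": "active_quality",
             "value": active_quality(len(sv), EXPECTED_SURVEYS_PER_DAY)}
        )
        pv = passive[(passive["timestamp"] >= t0) & (passive["timestamp"] < t1)]
        hours_with = pv.groupby((pv["timestamp"] - t0) // 3600).size().shape[0]
        rows.append(
            {"id": pid, "day": day, "feature": "passive_quality",
             "value": passive_quality(hours_with, 24)}
        )
    out = pd.DataFrame(rows, columns=["id", "day", "feature", "value"])
    out["channel"] = out["feature"].map(FEATURE_CHANNEL).fillna("active")
    return out[["id", "day", "channel", "feature", "value"]]
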