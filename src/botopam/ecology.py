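"""Ecological summaries of detection records.

Daily acoustic presence is the daily duration with acoustic occurrences
(5 s per positive segment) divided by the total daily recording duration —
a proportion, so sites with different duty cycles (continuous, 1 min on /
9 min off, 10 on / 110 off) are comparable.  Dolphin-boat co-occurrence
counts calendar minutes containing at least one click-positive and at least
one boat-positive segment.  The day/night comparison tests, per month,
whether the distribution of per-day detection rates (positive segments
scaled by the period duration in minutes) differs between day (dawn-dusk)
and night, with a two-sided Wilcoxon rank-sum test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from datetime import date, datetime, time, timedelta

import numpy as np
import pandas as pd
from scipy import stats

SEGMENT_SECONDS = 5.0


def _parse_times(records: pd.DataFrame) -> pd.Series:
    return pd.to_datetime(records["start_time_iso"])


def daily_presence(
    records: pd.DataFrame,
    schedule: pd.DataFrame,
    classes: tuple[str, ...] = ("click", "boat", "rain"),
) -> pd.DataFrame:
    """Daily presence proportion per site, date and class.

    ``schedule`` rows (``source_id/site``, ``date``, ``recorded_minutes``)
    define the denominator; occurrence duration is 5 s per positive segment
    (segments are non-overlapping by construction, so no merging is needed).
    A date with detections but no scheduled recording is a consistency error.
    Days with ``recorded_minutes == 0`` yield a NaN proportion and are
    flagged in the ``defined`` column.
    """
    sched = schedule.rename(columns={"source_id": "site"}).copy()
    sched["date"] = pd.to_datetime(sched["date"]).dt.date

    recs = records.copy()
    recs["date"] = _parse_times(recs).dt.date

    scheduled = set(zip(sched["site"], sched["date"]))
    for site, day in set(zip(recs["site"], recs["date"])):
        if (site, day) not in scheduled:
            raise ValueError(
                f"detections on {site} {day} but no scheduled recording that day"
            )

    rows = []
    for srow in sched.itertuples(index=False):
        day_recs = recs[(recs["site"] == srow.site) & (recs["date"] == srow.date)]
        for cls in classes:
            n_pos = int(day_recs[f"flag_{cls}"].sum()) if len(day_recs) else 0
            positive_min = n_pos * SEGMENT_SECONDS / 60.0
            recorded = float(srow.recorded_minutes)
            rows.append(
                {
                    "site": srow.site,
                    "date": srow.date,
                    "class": cls,
                    "recorded_min": recorded,
                    "positive_min": positive_min,
                    "proportion": positive_min / recorded if recorded > 0 else np.nan,
                    "defined": recorded > 0,
                }
            )
    return pd.DataFrame(rows)


def positive_minutes_per_hour(
    records: pd.DataFrame, cls: str = "click"
) -> pd.DataFrame:
    """Count distinct positive calendar minutes per (site, date, hour).

    A 5-s segment is attributed to the minute containing its start time;
    under a 1-on/9-off duty cycle with saturated detections this caps at
    6 positive minutes per hour.
    """
    recs = records[records[f"flag_{cls}"]].copy()
    t = _parse_times(recs)
    recs["date"] = t.dt.date
    recs["hour"] = t.dt.hour
    recs["minute"] = t.dt.minute
    grouped = (
        recs.groupby(["site", "date", "hour"])["minute"].nunique().reset_index()
    )
    return grouped.rename(columns={"minute": "positive_minutes"})


def cooccurrence_minutes(records: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """Minutes containing both a click-positive and a boat-positive segment.

    A calendar minute co-occurs when at least one click-positive segment and
    at least one boat-positive segment start within it.  Returns the per
    (site, date, hour) table plus a summary with the mean and SD of per-hour
    co-occurrence minutes and the percentage of recorded time (minutes with
    any segment) that co-occurs.
    """
    recs = records.copy()
    t = _parse_times(recs)
    recs["date"] = t.dt.date
    recs["hour"] = t.dt.hour
    recs["minute_key"] = t.dt.floor("min")

    per_minute = recs.groupby(["site", "date", "hour", "minute_key"]).agg(
        any_click=("flag_click", "any"), any_boat=("flag_boat", "any")
    )
    per_minute["cooccur"] = per_minute["any_click"] & per_minute["any_boat"]

    hourly = (
        per_minute.groupby(["site", "date", "hour"])
        .agg(cooccur_min=("cooccur", "sum"), recorded_min=("cooccur", "size"))
        .reset_index()
    )
    hourly["cooccur_min"] = hourly["cooccur_min"].astype(int)

    total_minutes = int(len(per_minute))
    total_cooccur = int(per_minute["cooccur"].sum())
    summary = {
        "mean_cooccur_min_per_hour": float(hourly["cooccur_min"].mean())
        if len(hourly)
        else 0.0,
        "sd_cooccur_min_per_hour": float(hourly["cooccur_min"].std(ddof=1))
        if len(hourly) > 1
        else 0.0,
        "pct_recorded_time": 100.0 * total_cooccur / total_minutes
        if total_minutes
        else 0.0,
        "total_cooccur_min": total_cooccur,
        "total_recorded_min": total_minutes,
    }
    return hourly, summary


@dataclass
class DayNightTestResult:
    """Monthly Wilcoxon rank-sum comparison of day vs night detection rates."""

    month: str
    n_days: int
    day_rates: np.ndarray
    night_rates: np.ndarray
    statistic: float
    p_value: float
    significant: bool
    alpha: float = 0.05


def solar_day_window(
    day: date, latitude_deg: float, longitude_deg: float
) -> tuple[datetime, datetime]:
    """Approximate sunrise/sunset (UTC) from the standard solar-elevation
    sunrise equation; adequate for tropical sites where errors are minutes."""
    n = day.toordinal() - date(2000, 1, 1).toordinal() + 1
    # mean solar noon, solar mean anomaly, ecliptic longitude (degrees)
    j_star = n - longitude_deg / 360.0
    m = (357.5291 + 0.98560028 * j_star) % 360.0
    c = 1.9148 * math.sin(math.radians(m)) + 0.02 * math.sin(math.radians(2 * m))
    lam = (m + c + 180.0 + 102.9372) % 360.0
    j_transit = j_star + 0.0053 * math.sin(math.radians(m)) - 0.0069 * math.sin(
        math.radians(2 * lam)
    )
    decl = math.degrees(
        math.asin(math.sin(math.radians(lam)) * math.sin(math.radians(23.44)))
    )
    cos_h = (
        math.sin(math.radians(-0.83))
        - math.sin(math.radians(latitude_deg)) * math.sin(math.radians(decl))
    ) / (math.cos(math.radians(latitude_deg)) * math.cos(math.radians(decl)))
    cos_h = min(1.0, max(-1.0, cos_h))
    h = math.degrees(math.acos(cos_h)) / 360.0
    base = datetime(2000, 1, 1, 12, 0, 0)
    sunrise = base + timedelta(days=j_transit - h - 1)
    sunset = base + timedelta(days=j_transit + h - 1)
    return (
        datetime.combine(day, sunrise.time()),
        datetime.combine(day, sunset.time()),
    )


def day_night_test(
    records: pd.DataFrame,
    dawn_dusk: dict,
    month: str,
    cls: str = "click",
    alpha: float = 0.05,
) -> DayNightTestResult | None:
    """Two-sided rank-sum test of day vs night activity for one month.

    ``dawn_dusk`` maps each date to ``(dawn, dusk)`` datetimes.  For each
    day, the day rate is the count of positive segments with start time in
    [dawn, dusk) divided by the day-period duration in minutes; the night
    rate covers the remainder of the calendar day.  Requires at least two
    days; months with no night (or day) period are skipped (returns None).
    The test is exact for small tie-free samples and uses the tie-corrected
    normal approximation otherwise.
    """
    recs = records.copy()
    t = _parse_times(recs)
    recs["date"] = t.dt.date
    recs["_t"] = t
    month_mask = recs["_t"].dt.strftime("%Y-%m") == month
    recs = recs[month_mask]

    day_rates, night_rates = [], []
    for day, (dawn, dusk) in sorted(dawn_dusk.items()):
        if pd.Timestamp(day).strftime("%Y-%m") != month:
            continue
        day_min = (dusk - dawn).total_seconds() / 60.0
        night_min = 24 * 60.0 - day_min
        if day_min <= 0 or night_min <= 0:
            return None
        day_recs = recs[recs["date"] == day]
        if len(day_recs) == 0:
            continue
        in_day = (day_recs["_t"] >= dawn) & (day_recs["_t"] < dusk)
        n_day = int((day_recs[f"flag_{cls}"] & in_day).sum())
        n_night = int((day_recs[f"flag_{cls}"] & ~in_day).sum())
        day_rates.append(n_day / day_min)
        night_rates.append(n_night / night_min)

    if len(day_rates) < 2:
        return None
    day_rates = np.asarray(day_rates)
    night_rates = np.asarray(night_rates)
    if np.all(day_rates == night_rates):
        # all paired values tie; the rank-sum statistic is at its null mean
        stat, p = 0.0, 1.0
    else:
        res = stats.mannwhitneyu(
            day_rates, night_rates, alternative="two-sided", method="auto"
        )
        stat, p = float(res.statistic), float(res.pvalue)
    return DayNightTestResult(
        month=month,
        n_days=len(day_rates),
        day_rates=day_rates,
        night_rates=night_rates,
        statistic=stat,
        p_value=p,
        significant=p < alpha,
        alpha=alpha,
    )
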