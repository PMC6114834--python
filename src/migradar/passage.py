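"""Target passage rate (TPR) through the 1-km standard front.

TPR is the study's activity index: targets per hour crossing a 1-km-wide
vertical standard front (±500 m along the VSR scan plane), analogous to
the migration traffic rate used elsewhere in radar ornithology.  For the
one-hour dawn and dusk periods TPR equals the target count; for day and
night it is the mean hourly rate (count / effective hours).

The unit of observation downstream is the *period instance*: one site x
solar date x biological period.
"""

from __future__ import annotations

import datetime as dt
import logging
from typing import Sequence

import numpy as np
import pandas as pd

from .solar import SolarDay, assign_period
from .tracks import ExclusionMask

logger = logging.getLogger(__name__)

#: Local civil time of the study region in season (US Eastern, UTC-4).
LOCAL_UTC_OFFSET_HOURS = -4


def _overlap_hours(start, end, mask_df) -> float:
    """Total hours of [start, end) covered by mask intervals (pre-merged)."""
    if not len(mask_df):
        return 0.0
    start64 = pd.Timestamp(start).tz_convert("UTC").to_datetime64()
    end64 = pd.Timestamp(end).tz_convert("UTC").to_datetime64()
    lo = np.maximum(mask_df["start"].values, start64)
    hi = np.minimum(mask_df["end"].values, end64)
    sec = np.clip((hi - lo) / np.timedelta64(1, "s"), 0, None).sum()
    return float(sec) / 3600.0


def period_tpr(
    records: pd.DataFrame,
    calendar: Sequence[SolarDay],
    mask: ExclusionMask | None = None,
) -> pd.DataFrame:
    """Per-period-instance passage rates for one site's filtered VSR table.

    Returns a tidy frame with one row per period instance: site_id,
    night_id (solar date of the instance; for night, the date of its
    dusk), period, target_count, effective_hours, tpr.  Instances whose
    effective observation time is fully excluded are omitted (logged).
    Records are assumed to be standard-front and track-length filtered
    and from a single site.
    """
    if mask is None:
        mask = ExclusionMask.empty()
    site_ids = records["site_id"].unique()
    if len(site_ids) > 1:
        raise ValueError("period_tpr expects records from a single site")
    site_id = site_ids[0] if len(site_ids) else None
    site_mask = mask.for_site(site_id) if site_id is not None else mask.entries

    counts = {}
    if len(records):
        assigned = assign_period(records["timestamp"], calendar)
        grouped = assigned.groupby(["night_id", "period"], observed=True).size()
        counts = grouped.to_dict()

    rows = []
    for day in calendar:
        for period, (lo, hi) in day.period_bounds.items():
            full_hours = (hi - lo).total_seconds() / 3600.0
            eff = full_hours - _overlap_hours(lo, hi, site_mask)
            count = int(counts.get((day.date, period), 0))
            if eff <= 1e-9:
                logger.info(
                    "period %s %s at %s fully excluded; omitted", day.date, period, site_id
                )
                continue
            rows.append(
                {
                    "site_id": site_id,
                    "night_id": day.date,
                    "period": period,
                    "target_count": count,
                    "effective_hours": eff,
                    "tpr": count / eff,
                }
            )
    return pd.DataFrame(rows, columns=[
        "site_id", "night_id", "period", "target_count", "effective_hours", "tpr"
    ])


def hourly_counts(
    records: pd.DataFrame,
    mask: ExclusionMask | None = None,
    tz_offset_hours: int = LOCAL_UTC_OFFSET_HOURS,
    span: tuple[dt.datetime, dt.datetime] | None = None,
) -> pd.DataFrame:
    """Per-local-clock-hour target counts for one site's filtered VSR table.

    Zero-count hours inside the span are emitted as explicit rows, not
    missing.  Hours intersecting an exclusion interval are flagged
    ``excluded`` so paired analyses can drop them.  ``span`` (UTC)
    defaults to the records' range, floored/ceiled to whole local hours.
    """
    if mask is None:
        mask = ExclusionMask.empty()
    site_ids = records["site_id"].unique()
    if len(site_ids) > 1:
        raise ValueError("hourly_counts expects records from a single site")
    site_id = site_ids[0] if len(site_ids) else None
    tz = dt.timezone(dt.timedelta(hours=tz_offset_hours))

    ts = pd.to_datetime(records["timestamp"], utc=True)
    local = ts.dt.tz_convert(tz)
    if span is None:
        if not len(records):
            return pd.DataFrame(columns=["site_id", "hour_start", "target_count", "excluded"])
        lo = local.min().floor("h")
        hi = local.max().ceil("h")
    else:
        lo = pd.Timestamp(span[0]).tz_convert(tz).floor("h")
        hi = pd.Timestamp(span[1]).tz_convert(tz).ceil("h")
    hours = pd.date_range(lo, hi, freq="h", inclusive="left")
    counts = local.dt.floor("h").value_counts()
    site_mask = mask.for_site(site_id) if site_id is not None else mask.entries

    out = pd.DataFrame({
        "site_id": site_id,
        "hour_start": hours,
        "target_count": [int(counts.get(h, 0)) for h in hours],
    })
    excl = np.zeros(len(out), dtype=bool)
    for row in site_mask.itertuples(index=False):
        h0 = hours.tz_convert("UTC")
        excl |= (h0 < row.end) & ((h0 + pd.Timedelta(hours=1)) > row.start)
    out["excluded"] = excl
    return out


def daily_counts(
    records: pd.DataFrame, tz_offset_hours: int = LOCAL_UTC_OFFSET_HOURS
) -> pd.DataFrame:
    """Total targets per local civil day (midnight-to-midnight time series)."""
    tz = dt.timezone(dt.timedelta(hours=tz_offset_hours))
    local_date = pd.to_datetime(records["timestamp"], utc=True).dt.tz_convert(tz).dt.date
    out = (
        records.assign(date=local_date)
        .groupby(["site_id", "date"], observed=True)
        .size()
        .rename("target_count")
        .reset_index()
    )
    return out


def pooled_mean_tpr(observations: pd.DataFrame, period: str | None = None) -> tuple[float, float]:
    """Mean ± SE of per-instance TPR pooled over both radar units.

    ``observations`` holds PeriodObservation rows from both sites of a
    trial; ``period`` restricts to one biological period.  SE is the
    sample standard deviation over instances divided by sqrt(n); with a
    single instance the SE is NaN (flagged by the caller).
    """
    obs = observations if period is None else observations[observations["period"] == period]
    vals = obs["tpr"].to_numpy(dtype=float)
    if len(vals) == 0:
        raise ValueError("no observations to pool")
    mean = float(vals.mean())
    se = float(vals.std(ddof=1) / np.sqrt(len(vals))) if len(vals) > 1 else float("nan")
    return mean, se


def percent_difference(
    shoreline_obs: pd.DataFrame, inland_obs: pd.DataFrame, period: str | None = None
) -> tuple[float, float, int]:
    """Mean ± SE of the per-instance proportional shoreline excess.

    For each period instance present at both sites, computes
    (shoreline TPR - inland TPR) / inland TPR, then the mean and SE over
    instances.  Reported as a proportion of inland TPR (x100 to display
    as percent).  Instances with inland TPR of zero are dropped (logged)
    rather than producing infinities.  Returns (mean, se, n_instances).
    """
    s = shoreline_obs if period is None else shoreline_obs[shoreline_obs["period"] == period]
    i = inland_obs if period is None else inland_obs[inland_obs["period"] == period]
    merged = s.merge(i, on=["night_id", "period"], suffixes=("_shore", "_inland"))
    zero = merged["tpr_inland"] == 0
    if zero.any():
        logger.warning("dropped %d instances with inland TPR 0", int(zero.sum()))
        merged = merged[~zero]
    if not len(merged):
        raise ValueError("no pairable instances with nonzero inland TPR")
    diff = (merged["tpr_shore"] - merged["tpr_inland"]) / merged["tpr_inland"]
    vals = diff.to_numpy(dtype=float)
    mean = float(vals.mean())
    se = float(vals.std(ddof=1) / np.sqrt(len(vals))) if len(vals) > 1 else float("nan")
    return mean, se, len(vals)


def paired_hour_correlation(hourly_a: pd.DataFrame, hourly_b: pd.DataFrame) -> tuple[float, int]:
    """Pearson r of hourly counts over hours where both units operated.

    Hours flagged excluded at either unit are dropped.  Returns (r, n
    paired hours).  Requires at least 3 shared hours and nonzero variance
    in both series.
    """
    merged = hourly_a.merge(hourly_b, on="hour_start", suffixes=("_a", "_b"))
    merged = merged[~merged["excluded_a"] & ~merged["excluded_b"]]
    n = len(merged)
    if n < 3:
        raise ValueError(f"only {n} shared non-excluded hours; need >= 3")
    a = merged["target_count_a"].to_numpy(dtype=float)
    b = merged["target_count_b"].to_numpy(dtype=float)
    if a.std() == 0 or b.std() == 0:
        raise ValueError("zero variance in an hourly series; correlation undefined")
    r = float(np.corrcoef(a, b)[0, 1])
    return r, n
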