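"""Track-table I/O, site configuration, and record-level filters.

A *target* is one radar-tracked flying animal (bird or bat).  Track tables
hold one row per target and come from two antennas on each radar unit:

* VSR (vertical scanning radar): timestamp, signed offset along the scan
  plane, altitude, track length — the counting antenna.
* HSR (horizontal surveillance radar): timestamp, position, compass
  heading, speed — the direction antenna.

Tables are pandas DataFrames with the column schemas below (CSV with an
ISO-8601 UTC timestamp column; XLSX accepted with the same columns).
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

#: Columns common to both antennas.
BASE_COLUMNS = ["target_id", "site_id", "antenna", "timestamp", "n_observations"]
#: VSR-specific columns (altitude optional).
VSR_COLUMNS = BASE_COLUMNS + ["vsr_offset_m", "altitude_m"]
#: HSR-specific columns (speed optional).
HSR_COLUMNS = BASE_COLUMNS + ["longitude_deg", "latitude_deg", "heading_deg", "speed_mps"]

_REQUIRED = {
    "VSR": BASE_COLUMNS + ["vsr_offset_m"],
    "HSR": BASE_COLUMNS + ["longitude_deg", "latitude_deg", "heading_deg"],
}

#: Half-width of the standard front used to standardise VSR counts (m).
STANDARD_FRONT_HALF_WIDTH_M = 500.0
#: Minimum radar returns for a track to be considered a real target.
MIN_TRACK_OBSERVATIONS = 5


class SchemaError(ValueError):
    """A track table is missing required columns for its antenna."""


class RowError(ValueError):
    """A track-table row could not be parsed (carries the line number)."""


@dataclass(frozen=True)
class SiteConfig:
    """Geometry and role of one radar deployment.

    ``overwater_longitude_deg`` is the longitude of the (north-south)
    shoreline within the radar's sample volume; HSR targets strictly west
    of it are classified as flying over open water.  Inland sites have no
    such threshold.
    """

    site_id: str
    trial: str  # one of RC, A, B, C, D
    role: str  # "shoreline" or "inland"
    latitude_deg: float
    longitude_deg: float
    date_start: dt.date
    date_end: dt.date
    vsr_azimuth_deg: float = 300.0
    overwater_longitude_deg: float | None = None
    radar_name: str = ""

    def __post_init__(self):
        if self.role not in ("shoreline", "inland"):
            raise ValueError(f"unknown site role {self.role!r}")
        if self.role == "shoreline" and self.overwater_longitude_deg is None:
            raise ValueError(
                f"shoreline site {self.site_id} needs overwater_longitude_deg"
            )
        if self.date_end < self.date_start:
            raise ValueError(f"empty date range for site {self.site_id}")


def load_site_registry(path: str | Path) -> dict[str, SiteConfig]:
    """Read a YAML site/trial registry into SiteConfig objects keyed by id."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    registry = {}
    for entry in raw["sites"]:
        entry = dict(entry)
        entry["date_start"] = pd.Timestamp(entry["date_start"]).date()
        entry["date_end"] = pd.Timestamp(entry["date_end"]).date()
        cfg = SiteConfig(**entry)
        registry[cfg.site_id] = cfg
    return registry


def save_site_registry(registry: dict[str, SiteConfig], path: str | Path) -> None:
    rows = []
    for cfg in registry.values():
        d = dataclasses.asdict(cfg)
        d["date_start"] = cfg.date_start.isoformat()
        d["date_end"] = cfg.date_end.isoformat()
        if d["overwater_longitude_deg"] is None:
            del d["overwater_longitude_deg"]
        rows.append(d)
    with open(path, "w") as fh:
        yaml.safe_dump({"sites": rows}, fh, sort_keys=False)


@dataclass(frozen=True)
class ExclusionMask:
    """Intervals removed from analysis (rain, non-biological contamination).

    ``entries`` is a DataFrame with columns site_id, start, end, reason;
    overlapping entries for a site are merged (with a warning) on creation.
    """

    entries: pd.DataFrame

    @classmethod
    def empty(cls) -> "ExclusionMask":
        return cls(pd.DataFrame(columns=["site_id", "start", "end", "reason"]))

    @classmethod
    def from_csv(cls, path: str | Path) -> "ExclusionMask":
        df = pd.read_csv(path)
        df["start"] = pd.to_datetime(df["start"], utc=True)
        df["end"] = pd.to_datetime(df["end"], utc=True)
        return cls(df)

    def __post_init__(self):
        df = self.entries
        if len(df) and (df["start"] >= df["end"]).any():
            raise ValueError("exclusion mask entry with start >= end")
        merged = _merge_overlaps(df)
        if len(merged) < len(df):
            logger.warning(
                "merged %d overlapping exclusion entries", len(df) - len(merged)
            )
        object.__setattr__(self, "entries", merged)

    def for_site(self, site_id: str) -> pd.DataFrame:
        return self.entries[self.entries["site_id"] == site_id]


def _merge_overlaps(df: pd.DataFrame) -> pd.DataFrame:
    if not len(df):
        return df.reset_index(drop=True)
    out = []
    for site, grp in df.sort_values(["site_id", "start"]).groupby("site_id"):
        cur = None
        for row in grp.itertuples(index=False):
            if cur is None or row.start > cur["end"]:
                if cur is not None:
                    out.append(cur)
                cur = {"site_id": site, "start": row.start, "end": row.end,
                       "reason": row.reason}
            else:
                cur["end"] = max(cur["end"], row.end)
                if row.reason not in cur["reason"]:
                    cur["reason"] = f"{cur['reason']};{row.reason}"
        out.append(cur)
    return pd.DataFrame(out, columns=["site_id", "start", "end", "reason"])


# ---------------------------------------------------------------------------
# I/O

def read_track_table(
    path: str | Path, antenna: str, on_bad_rows: str = "raise"
) -> pd.DataFrame:
    """Read a per-target track table for one antenna type.

    Parameters
    ----------
    path : CSV (UTF-8, header row) or XLSX file.
    antenna : "VSR" or "HSR"; the matching column schema is enforced.
    on_bad_rows : "raise" (default) or "skip".  Unparseable timestamps
        fail fast by default because silently dropped rows would bias
        passage rates; "skip" drops them and logs line numbers.
    """
    antenna = antenna.upper()
    if antenna not in _REQUIRED:
        raise ValueError(f"unknown antenna {antenna!r}")
    path = Path(path)
    if path.suffix.lower() in (".xlsx", ".xls"):
        df = pd.read_excel(path)
    else:
        df = pd.read_csv(path)
    missing = [c for c in _REQUIRED[antenna] if c not in df.columns]
    if missing:
        raise SchemaError(f"{path.name}: missing required columns {missing}")

    ts = pd.to_datetime(df["timestamp"], utc=True, errors="coerce", format="ISO8601")
    bad = ts.isna() & df["timestamp"].notna()
    if bad.any():
        lines = (df.index[bad] + 2).tolist()  # +1 header, +1 one-based
        if on_bad_rows == "raise":
            raise RowError(f"{path.name}: unparseable timestamp at line(s) {lines[:10]}")
        logger.warning("%s: skipped %d rows with bad timestamps (lines %s)",
                       path.name, bad.sum(), lines[:10])
        df = df[~bad].reset_index(drop=True)
        ts = ts[~bad].reset_index(drop=True)
    df = df.copy()
    df["timestamp"] = ts
    df["antenna"] = df["antenna"].astype(str).str.upper()
    if (df["antenna"] != antenna).any():
        raise SchemaError(f"{path.name}: antenna column disagrees with declared {antenna}")
    df["n_observations"] = df["n_observations"].astype(int)
    if (df["n_observations"] < 1).any():
        raise RowError(f"{path.name}: n_observations must be >= 1")
    if antenna == "HSR":
        # wrap headings into [0, 360): tracking software convention is
        # 0 = north, ascending clockwise
        df["heading_deg"] = np.mod(df["heading_deg"].astype(float), 360.0)
    cols = VSR_COLUMNS if antenna == "VSR" else HSR_COLUMNS
    for c in cols:
        if c not in df.columns:
            df[c] = np.nan
    return df[cols]


def write_track_table(df: pd.DataFrame, path: str | Path) -> None:
    """Write a track table as CSV with ISO-8601 UTC timestamps."""
    out = df.copy()
    out["timestamp"] = pd.to_datetime(out["timestamp"], utc=True).dt.strftime(
        "%Y-%m-%dT%H:%M:%S.%f%z"
    )
    out.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Record-level filters (all idempotent and order-commutative)

def filter_min_track_length(
    records: pd.DataFrame, min_obs: int = MIN_TRACK_OBSERVATIONS
) -> pd.DataFrame:
    """Drop tracks with fewer than ``min_obs`` sequential radar returns."""
    keep = records["n_observations"] >= min_obs
    n_removed = int((~keep).sum())
    if n_removed:
        logger.info("track-length filter removed %d of %d records", n_removed, len(records))
    return records[keep].reset_index(drop=True)


def filter_standard_front(
    records: pd.DataFrame, half_width_m: float = STANDARD_FRONT_HALF_WIDTH_M
) -> pd.DataFrame:
    """Keep VSR targets within the 1-km standard front (|offset| <= half width).

    The boundary is closed: an offset of exactly ±500 m is retained.
    """
    if (records["antenna"] != "VSR").any():
        raise TypeError("standard-front filter applies to VSR records only")
    keep = records["vsr_offset_m"].abs() <= half_width_m
    n_removed = int((~keep).sum())
    if n_removed:
        logger.info("standard-front filter removed %d of %d records", n_removed, len(records))
    return records[keep].reset_index(drop=True)


def classify_overwater(records: pd.DataFrame, site: SiteConfig) -> pd.DataFrame:
    """Subset of HSR targets tracked over open water.

    A target is over water when its longitude is strictly west of (less
    than) the site's shoreline longitude threshold.  Only meaningful for
    shoreline sites.
    """
    if site.role != "shoreline" or site.overwater_longitude_deg is None:
        raise ValueError(
            f"site {site.site_id} is not a shoreline site with an over-water threshold"
        )
    if (records["antenna"] != "HSR").any():
        raise TypeError("over-water classification applies to HSR records only")
    keep = records["longitude_deg"] < site.overwater_longitude_deg
    return records[keep].reset_index(drop=True)


def apply_exclusions(
    records: pd.DataFrame, mask: ExclusionMask
) -> pd.DataFrame:
    """Drop records falling inside masked (rain/contamination) intervals.

    Mask intervals are half-open ``[start, end)`` and site-specific.  The
    reduction of effective observation time is handled separately when
    passage rates are computed (see ``passage.period_tpr``).
    """
    if not len(mask.entries) or not len(records):
        return records.reset_index(drop=True)
    drop = np.zeros(len(records), dtype=bool)
    ts = pd.to_datetime(records["timestamp"], utc=True)
    for row in mask.entries.itertuples(index=False):
        drop |= (
            (records["site_id"] == row.site_id).values
            & (ts >= row.start).values
            & (ts < row.end).values
        )
    n_removed = int(drop.sum())
    if n_removed:
        logger.info("exclusion mask removed %d of %d records", n_removed, len(records))
    return records[~drop].reset_index(drop=True)
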