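"""Synthetic seasons of VSR/HSR radar track tables with known ground truth.

The generator emulates the statistical structure the analysis assumes,
for a paired shoreline + inland radar deployment on an eastern lakeshore
during spring migration:

* sporadic nocturnal migration pulses — a mean-one log-normal nightly
  multiplier on a base intensity, with a per-night pulse probability,
  giving the spiky day-to-day pattern typical of migration seasons;
* per-period hourly-rate factors (night is the peak; dawn, day and dusk
  are fractions of it) and per-period shoreline intensity multipliers
  (the quantities the slope regression estimates);
* compass headings from von Mises mixtures per (location, period), with
  the dawn distributions rotated clockwise relative to night — most
  strongly for targets over open water;
* the radars' detection geometry: a +-500 m standard front inside a
  +-1400 m VSR plane, a 3.7 km HSR detection disk with a configurable
  over-water fraction west of the shoreline longitude threshold, a
  configurable fraction of sub-5-observation tracks, and HSR
  double-counting.

Counts for targets that survive the record-level filters are drawn
directly as Poisson with the configured intensity, so the ground truth
refers to post-filter rates; filter-fodder records (outside the front,
short tracks, duplicates) are layered on top.  Everything is seeded and
byte-reproducible.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .solar import solar_calendar
from .tracks import ExclusionMask, SiteConfig, save_site_registry, write_track_table

PERIOD_ORDER = ("dawn", "day", "dusk", "night")
KM_PER_DEG_LAT = 110.574
KM_PER_DEG_LON_EQ = 111.320


def _default_shoreline_site() -> SiteConfig:
    return SiteConfig(
        site_id="S2", trial="A", role="shoreline",
        latitude_deg=44.434, longitude_deg=-86.227,
        date_start=dt.date(2014, 4, 23), date_end=dt.date(2014, 5, 8),
        overwater_longitude_deg=-86.249, radar_name="Batman",
    )


def _default_inland_site() -> SiteConfig:
    return SiteConfig(
        site_id="S3", trial="A", role="inland",
        latitude_deg=44.422, longitude_deg=-85.932,
        date_start=dt.date(2014, 4, 23), date_end=dt.date(2014, 5, 8),
        radar_name="Robin",
    )


def _default_heading_mixtures() -> dict:
    # (location, period) -> list of (mu compass deg, kappa, weight).
    # Night flight is to the north/northwest with a secondary lobe; at
    # dawn the means rotate clockwise, most strongly over water
    # (343 -> 35 deg), as over-water migrants reorient toward land.
    two_lobe = lambda mu: [((mu - 20) % 360, 1.5, 0.5), ((mu + 20) % 360, 1.5, 0.5)]
    return {
        ("inland", "night"): two_lobe(349.0),
        ("inland", "dawn"): [(0.0, 1.6, 1.0)],
        ("inland", "dusk"): two_lobe(341.0),
        ("inland", "day"): [(15.0, 0.5, 1.0)],
        ("shoreline", "night"): two_lobe(342.0),
        ("shoreline", "dawn"): [(5.0, 1.6, 1.0)],
        ("shoreline", "dusk"): two_lobe(340.0),
        ("shoreline", "day"): [(10.0, 0.5, 1.0)],
        ("over_water", "night"): [(343.0, 1.0, 1.0)],
        ("over_water", "dawn"): [(35.0, 1.6, 1.0)],
        ("over_water", "dusk"): [(340.0, 1.0, 1.0)],
        ("over_water", "day"): [(20.0, 0.5, 1.0)],
    }


@dataclass
class ScenarioConfig:
    """Knobs of one simulated paired-deployment season.

    ``night_base_rate`` is the inland nighttime post-filter passage rate
    (targets/h through the 1-km front); 517/h puts the pooled
    shoreline+inland night mean near the observed 545/h.  Period factors
    are the ratios of the observed per-period hourly means to the night
    mean (dawn 112, day 38, dusk 35 vs 545 targets/h).  Shoreline
    multipliers default to the estimated per-period shoreline:inland
    activity ratios (dawn 2.32 ... night 1.11).
    """

    shoreline_site: SiteConfig = field(default_factory=_default_shoreline_site)
    inland_site: SiteConfig = field(default_factory=_default_inland_site)
    night_base_rate: float = 517.0
    pulse_probability: float = 0.5
    pulse_sigma: float = 0.8          # log-normal sd of pulse-night magnitude
    quiet_factor: float = 0.15        # intensity multiplier on non-pulse nights
    period_rate_factors: dict = field(default_factory=lambda: {
        "dawn": 0.206, "day": 0.070, "dusk": 0.064, "night": 1.0,
    })
    shoreline_multipliers: dict = field(default_factory=lambda: {
        "dawn": 2.32, "day": 1.35, "dusk": 1.37, "night": 1.11,
    })
    heading_mixtures: dict = field(default_factory=_default_heading_mixtures)
    overwater_fraction: dict = field(default_factory=lambda: {
        "dawn": 0.30, "day": 0.20, "dusk": 0.35, "night": 0.40,
    })
    hsr_rate_factor: float = 3.0      # HSR targets per front-qualified VSR target
    hsr_radius_km: float = 3.7
    vsr_halfwidth_m: float = 1400.0
    front_halfwidth_m: float = 500.0
    short_track_fraction: float = 0.2  # fraction of detections with < 5 returns
    double_count_rate: float = 0.08    # HSR duplicate-record rate
    with_vsr: bool = True              # generate VSR tables
    with_hsr: bool = True              # generate HSR tables
    seed: int = 0

    def __post_init__(self):
        for period, mix in self.heading_mixtures.items():
            w = sum(c[2] for c in mix)
            if abs(w - 1.0) > 1e-9:
                raise ValueError(f"mixture weights for {period} sum to {w}, not 1")
        if any(m <= 0 for m in self.shoreline_multipliers.values()):
            raise ValueError("shoreline multipliers must be positive")
        if self.hsr_radius_km <= 0 or self.vsr_halfwidth_m <= 0:
            raise ValueError("detection geometry must be positive")
        if self.inland_site.role != "inland" or self.shoreline_site.role != "shoreline":
            raise ValueError("scenario needs one shoreline and one inland site")


@dataclass
class GroundTruth:
    """What the generator actually used — the recovery-testing contract."""

    shoreline_multipliers: dict
    period_rate_factors: dict
    night_base_rate: float
    nightly_multipliers: dict          # ISO date -> realized multiplier
    heading_means: dict                # "location/period" -> circular mean of mixture
    heading_mixtures: dict
    seed: int

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, default=str)


def mixture_circular_mean(mix) -> float:
    """Circular mean direction (compass deg) of a von Mises mixture."""
    from scipy.special import i0, i1
    e = n = 0.0
    for mu, kappa, w in mix:
        a = i1(kappa) / i0(kappa)
        e += w * a * math.sin(math.radians(mu))
        n += w * a * math.cos(math.radians(mu))
    mean = math.degrees(math.atan2(e, n)) % 360.0
    return 0.0 if mean >= 360.0 else mean


def _sample_mixture(rng, mix, size):
    comps = rng.choice(len(mix), size=size, p=[c[2] for c in mix])
    out = np.empty(size)
    for k, (mu, kappa, _w) in enumerate(mix):
        m = comps == k
        if m.any():
            out[m] = (mu + np.degrees(rng.vonmises(0.0, kappa, size=int(m.sum())))) % 360.0
    return out


def _uniform_times(rng, lo, hi, size):
    # integer milliseconds so timestamps survive CSV round-trips exactly
    span_ms = int((hi - lo).total_seconds() * 1000)
    offsets = np.sort(rng.integers(0, span_ms, size=size))
    return pd.to_datetime(lo) + pd.to_timedelta(offsets, unit="ms")


def _track_lengths(rng, size, short_frac):
    short = rng.random(size) < short_frac
    n_obs = 5 + rng.poisson(8.0, size=size)
    n_obs[short] = rng.integers(1, 5, size=int(short.sum()))
    return n_obs


def simulate_season(config: ScenarioConfig):
    """Generate one paired season.

    Returns ``(vsr, hsr, truth)`` where ``vsr`` and ``hsr`` map site_id
    to track-table DataFrames and ``truth`` is the :class:`GroundTruth`
    side-car.  Identical config + seed give byte-identical tables.
    """
    rng = np.random.default_rng(config.seed)
    sites = [config.shoreline_site, config.inland_site]
    start, end = config.shoreline_site.date_start, config.shoreline_site.date_end

    # mean-one sporadic nightly process shared by both sites
    p, q = config.pulse_probability, config.quiet_factor
    mean_raw = p + (1 - p) * q
    dates = pd.date_range(start, end).date
    pulses = rng.random(len(dates)) < p
    mags = np.exp(rng.normal(0.0, config.pulse_sigma, len(dates))
                  - config.pulse_sigma**2 / 2.0)
    nightly = np.where(pulses, mags, q) / mean_raw
    nightly_map = {d: float(m) for d, m in zip(dates, nightly)}

    vsr_tables, hsr_tables = {}, {}
    for site in sites:
        cal = solar_calendar(start, end, site.latitude_deg, site.longitude_deg)
        vsr_rows, hsr_rows = [], []
        vid = hid = 0
        for day in cal:
            m_night = nightly_map[day.date]
            for period in PERIOD_ORDER:
                lo, hi = day.period_bounds[period]
                hours = (hi - lo).total_seconds() / 3600.0
                rate = (config.night_base_rate * m_night
                        * config.period_rate_factors[period])
                if site.role == "shoreline":
                    rate *= config.shoreline_multipliers[period]
                if config.with_vsr:
                    vid = _gen_vsr(rng, vsr_rows, site, config, lo, hi, hours,
                                   rate, vid)
                if config.with_hsr:
                    hid = _gen_hsr(rng, hsr_rows, site, config, lo, hi, hours,
                                   rate, period, hid)
        vsr_tables[site.site_id] = _vsr_frame(vsr_rows, site)
        hsr_tables[site.site_id] = _hsr_frame(hsr_rows, site, rng, config)

    truth = GroundTruth(
        shoreline_multipliers=dict(config.shoreline_multipliers),
        period_rate_factors=dict(config.period_rate_factors),
        night_base_rate=config.night_base_rate,
        nightly_multipliers={d.isoformat(): m for d, m in nightly_map.items()},
        heading_means={f"{loc}/{per}": mixture_circular_mean(mix)
                       for (loc, per), mix in config.heading_mixtures.items()},
        heading_mixtures={f"{loc}/{per}": mix
                          for (loc, per), mix in config.heading_mixtures.items()},
        seed=config.seed,
    )
    return vsr_tables, hsr_tables, truth


def _gen_vsr(rng, rows, site, cfg, lo, hi, hours, rate, counter):
    # front-qualified targets (inside +-500 m, >= 5 returns): Poisson at
    # the configured post-filter rate
    n_front = rng.poisson(rate * hours)
    # filter fodder: same areal density outside the front, plus short tracks
    outside_w = cfg.vsr_halfwidth_m - cfg.front_halfwidth_m
    n_out = rng.poisson(rate * hours * outside_w / cfg.front_halfwidth_m)
    f = cfg.short_track_fraction
    n_short = rng.poisson(rate * hours * (cfg.vsr_halfwidth_m / cfg.front_halfwidth_m)
                          * f / max(1.0 - f, 1e-9))
    n_tot = n_front + n_out + n_short
    if n_tot == 0:
        return counter
    offsets = np.concatenate([
        rng.uniform(-cfg.front_halfwidth_m, cfg.front_halfwidth_m, n_front),
        rng.uniform(cfg.front_halfwidth_m, cfg.vsr_halfwidth_m, n_out)
        * rng.choice([-1.0, 1.0], n_out),
        rng.uniform(-cfg.vsr_halfwidth_m, cfg.vsr_halfwidth_m, n_short),
    ])
    n_obs = np.concatenate([
        5 + rng.poisson(8.0, n_front + n_out),
        rng.integers(1, 5, n_short),
    ])
    times = _uniform_times(rng, lo, hi, n_tot)
    alt = np.round(100.0 + rng.lognormal(math.log(250.0), 0.6, n_tot), 1)
    rows.append({
        "target_id": np.char.add(f"{site.site_id}-V",
                                 np.arange(counter, counter + n_tot).astype(str)),
        "timestamp": times,
        "n_observations": n_obs.astype(int),
        "vsr_offset_m": np.round(offsets, 1),
        "altitude_m": alt,
    })
    return counter + n_tot


def _gen_hsr(rng, rows, site, cfg, lo, hi, hours, rate, period, counter):
    f = cfg.short_track_fraction
    n_tot = rng.poisson(rate * hours * cfg.hsr_rate_factor / max(1.0 - f, 1e-9))
    if n_tot == 0:
        return counter
    over = np.zeros(n_tot, dtype=bool)
    if site.role == "shoreline":
        over = rng.random(n_tot) < cfg.overwater_fraction[period]
    lon, lat = _disk_positions(rng, site, cfg, over)
    loc_label = "inland" if site.role == "inland" else "shoreline"
    headings = np.empty(n_tot)
    if over.any():
        headings[over] = _sample_mixture(
            rng, cfg.heading_mixtures[("over_water", period)], int(over.sum()))
    if (~over).any():
        headings[~over] = _sample_mixture(
            rng, cfg.heading_mixtures[(loc_label, period)], int((~over).sum()))
    n_obs = _track_lengths(rng, n_tot, f)
    times = _uniform_times(rng, lo, hi, n_tot)
    speed = np.clip(rng.normal(12.0, 3.0, n_tot), 1.0, None)
    rows.append({
        "target_id": np.char.add(f"{site.site_id}-H",
                                 np.arange(counter, counter + n_tot).astype(str)),
        "timestamp": times,
        "n_observations": n_obs.astype(int),
        "longitude_deg": np.round(lon, 6),
        "latitude_deg": np.round(lat, 6),
        "heading_deg": np.round(headings, 1),
        "speed_mps": np.round(speed, 1),
    })
    return counter + n_tot


def _disk_positions(rng, site, cfg, over_water):
    n = over_water.size
    km_lon = KM_PER_DEG_LON_EQ * math.cos(math.radians(site.latitude_deg))
    lon = np.empty(n)
    lat = np.empty(n)
    todo = np.ones(n, dtype=bool)
    thr = site.overwater_longitude_deg
    while todo.any():
        k = int(todo.sum())
        r = cfg.hsr_radius_km * np.sqrt(rng.random(k))
        th = rng.uniform(0, 2 * math.pi, k)
        cand_lon = site.longitude_deg + r * np.sin(th) / km_lon
        cand_lat = site.latitude_deg + r * np.cos(th) / KM_PER_DEG_LAT
        idx = np.flatnonzero(todo)
        if thr is None:
            ok = np.ones(k, dtype=bool)
        else:
            west = cand_lon < thr
            ok = np.where(over_water[idx], west, ~west)
        lon[idx[ok]] = cand_lon[ok]
        lat[idx[ok]] = cand_lat[ok]
        todo[idx[ok]] = False
    return lon, lat


def _concat_chunks(rows, columns):
    if not rows:
        return pd.DataFrame({c: [] for c in columns})
    return pd.DataFrame({
        c: np.concatenate([np.asarray(chunk[c]) for chunk in rows])
        if c != "timestamp"
        else pd.DatetimeIndex(np.concatenate([chunk[c].values for chunk in rows]),
                              tz="UTC")
        for c in columns
    })


def _vsr_frame(rows, site):
    df = _concat_chunks(rows, ["target_id", "timestamp", "n_observations",
                               "vsr_offset_m", "altitude_m"])
    df.insert(1, "site_id", site.site_id)
    df.insert(2, "antenna", "VSR")
    return df[["target_id", "site_id", "antenna", "timestamp", "n_observations",
               "vsr_offset_m", "altitude_m"]]


def _hsr_frame(rows, site, rng, cfg):
    df = _concat_chunks(rows, ["target_id", "timestamp", "n_observations",
                               "longitude_deg", "latitude_deg",
                               "heading_deg", "speed_mps"])
    df.insert(1, "site_id", site.site_id)
    df.insert(2, "antenna", "HSR")
    df = df[["target_id", "site_id", "antenna", "timestamp", "n_observations",
             "longitude_deg", "latitude_deg", "heading_deg", "speed_mps"]]
    # double-counting: one animal yielding several track records
    if cfg.double_count_rate > 0 and len(df):
        dup = rng.random(len(df)) < cfg.double_count_rate
        if dup.any():
            extra = df[dup].copy()
            k = len(extra)
            extra["target_id"] = [f"{t}-dup" for t in extra["target_id"]]
            extra["longitude_deg"] = np.round(
                extra["longitude_deg"] + rng.normal(0, 0.001, k), 6)
            extra["latitude_deg"] = np.round(
                extra["latitude_deg"] + rng.normal(0, 0.001, k), 6)
            extra["heading_deg"] = np.round(
                np.mod(extra["heading_deg"] + rng.normal(0, 5.0, k), 360.0), 1)
            extra["timestamp"] = extra["timestamp"] + pd.to_timedelta(
                rng.integers(5, 60, k), unit="s")
            df = pd.concat([df, extra], ignore_index=True)
            df = df.sort_values("timestamp", kind="mergesort").reset_index(drop=True)
    return df


def write_scenario(config: ScenarioConfig, outdir: str | Path):
    """Simulate and write track CSVs, site YAML and the truth JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    vsr, hsr, truth = simulate_season(config)
    for site_id, df in vsr.items():
        write_track_table(df, outdir / f"vsr_{site_id}.csv")
    for site_id, df in hsr.items():
        write_track_table(df, outdir / f"hsr_{site_id}.csv")
    save_site_registry(
        {s.site_id: s for s in (config.shoreline_site, config.inland_site)},
        outdir / "sites.yaml",
    )
    truth.to_json(outdir / "ground_truth.json")
    return vsr, hsr, truth


# ---------------------------------------------------------------------------
# small deterministic fixtures for unit tests

def make_fixture(name: str, seed: int = 0):
    """Tiny (<= 1000-row) seeded datasets with hand-verifiable structure.

    * ``dawn_turn`` — over-water HSR headings: night ~ vM(343, 1.0),
      dawn ~ vM(35, 1.6); the night-to-dawn shift is ~ +52 deg.
    * ``front_edges`` — VSR offsets exactly at +-499/500/501 m.
    * ``rain_mask`` — three nights of VSR data with the middle night
      fully masked.
    """
    rng = np.random.default_rng(seed)
    site = _default_shoreline_site()
    if name == "dawn_turn":
        cal = solar_calendar(dt.date(2014, 4, 24), dt.date(2014, 4, 24),
                             site.latitude_deg, site.longitude_deg)
        day = cal[0]
        rows = []
        for period, mu, kappa, n in (("night", 343.0, 1.0, 500),
                                     ("dawn", 35.0, 1.6, 500)):
            lo, hi = day.period_bounds[period]
            times = _uniform_times(rng, lo, hi, n)
            h = (mu + np.degrees(rng.vonmises(0.0, kappa, n))) % 360.0
            lon = rng.uniform(site.overwater_longitude_deg - 0.02,
                              site.overwater_longitude_deg - 0.001, n)
            lat = site.latitude_deg + rng.uniform(-0.02, 0.02, n)
            for i in range(n):
                rows.append((f"F{len(rows)}", site.site_id, "HSR", times[i], 9,
                             round(lon[i], 6), round(lat[i], 6),
                             round(h[i], 1), 12.0))
        hsr = pd.DataFrame(rows, columns=["target_id", "site_id", "antenna",
                                          "timestamp", "n_observations",
                                          "longitude_deg", "latitude_deg",
                                          "heading_deg", "speed_mps"])
        return {"hsr": hsr, "site": site, "calendar": cal}
    if name == "front_edges":
        ts = pd.Timestamp("2014-04-24T18:00:00Z")
        rows = []
        for i, off in enumerate([-501.0, -500.0, -499.0, 499.0, 500.0, 501.0]):
            rows.append((f"E{i}", site.site_id, "VSR", ts, 7, off, 300.0))
        vsr = pd.DataFrame(rows, columns=["target_id", "site_id", "antenna",
                                          "timestamp", "n_observations",
                                          "vsr_offset_m", "altitude_m"])
        return {"vsr": vsr, "site": site}
    if name == "rain_mask":
        cal = solar_calendar(dt.date(2014, 4, 24), dt.date(2014, 4, 26),
                             site.latitude_deg, site.longitude_deg)
        rows = []
        for day in cal:
            lo, hi = day.period_bounds["night"]
            times = _uniform_times(rng, lo, hi, 60)
            for t in times:
                rows.append((f"R{len(rows)}", site.site_id, "VSR", t, 8,
                             float(rng.uniform(-450, 450)), 250.0))
        vsr = pd.DataFrame(rows, columns=["target_id", "site_id", "antenna",
                                          "timestamp", "n_observations",
                                          "vsr_offset_m", "altitude_m"])
        lo, hi = cal[1].period_bounds["night"]
        mask = ExclusionMask(pd.DataFrame(
            [{"site_id": site.site_id, "start": pd.Timestamp(lo),
              "end": pd.Timestamp(hi), "reason": "rain"}]))
        return {"vsr": vsr, "mask": mask, "site": site, "calendar": cal}
    raise KeyError(f"unknown fixture {name!r}")
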