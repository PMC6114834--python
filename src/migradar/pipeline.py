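"""End-to-end orchestration: ingest -> filter -> segment -> TPR ->
slope tests -> direction analysis -> tidy reports.

All functions work on in-memory track tables plus a site registry; the
CLI is a thin file-handling layer on top.  Reports are tidy DataFrames
(written as CSV) plus JSON summaries, and every inferential step is
seeded.  Trial D — after the end of the migration season — is excluded
from inferential outputs by default but kept in descriptive time series.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import passage
from .circular import circ_mean_mrl, rose_bins, subsample_equal, watson_williams
from .regression import LeastRectangles
from .solar import solar_calendar
from .tracks import (
    ExclusionMask,
    SiteConfig,
    classify_overwater,
    filter_min_track_length,
    filter_standard_front,
    apply_exclusions,
)

logger = logging.getLogger(__name__)

INFERENTIAL_TRIALS = ("A", "B", "C")


@dataclass
class RunConfig:
    """Analysis switches for one pipeline run."""

    sites: dict[str, SiteConfig]
    mask: ExclusionMask = field(default_factory=ExclusionMask.empty)
    family: str = "poisson"
    bootstrap: int = 2000
    seed: int = 0
    subsample_n: int = 20000
    front_halfwidth_m: float = 500.0
    min_track_obs: int = 5
    include_trial_d: bool = False
    tz_offset_hours: int = passage.LOCAL_UTC_OFFSET_HOURS


def prepare_vsr(records: pd.DataFrame, config: RunConfig) -> pd.DataFrame:
    """Record-level filters for a VSR table: track length, standard
    front, exclusion mask.  Counts after each filter are logged."""
    logger.info("VSR ingest: %d records", len(records))
    records = filter_min_track_length(records, config.min_track_obs)
    records = filter_standard_front(records, config.front_halfwidth_m)
    records = apply_exclusions(records, config.mask)
    logger.info("VSR after filters: %d records", len(records))
    return records


def prepare_hsr(records: pd.DataFrame, config: RunConfig) -> pd.DataFrame:
    records = filter_min_track_length(records, config.min_track_obs)
    return apply_exclusions(records, config.mask)


def site_period_observations(
    records: pd.DataFrame, site: SiteConfig, config: RunConfig
) -> pd.DataFrame:
    """Per-period-instance TPR for one site over its deployment dates."""
    cal = solar_calendar(site.date_start, site.date_end,
                        site.latitude_deg, site.longitude_deg)
    obs = passage.period_tpr(records, cal, config.mask)
    obs["trial"] = site.trial
    obs["role"] = site.role
    return obs


def run_radar_comparison(
    vsr_by_site: dict[str, pd.DataFrame],
    site_a: SiteConfig,
    site_b: SiteConfig,
    config: RunConfig,
) -> dict:
    """Side-by-side radar comparison: unit b hourly TPR on unit a.

    The two units sampled the same traffic; similar detection means a
    regression line near y = x.  Returns Pearson r over paired hours,
    the bootstrap least-rectangles fit, the identity-line test, and the
    fitted envelope for plotting.
    """
    hourly = {}
    for site in (site_a, site_b):
        rec = prepare_vsr(vsr_by_site[site.site_id], config)
        hourly[site.site_id] = passage.hourly_counts(
            rec, config.mask, config.tz_offset_hours)
    merged = hourly[site_a.site_id].merge(
        hourly[site_b.site_id], on="hour_start", suffixes=("_a", "_b"))
    merged = merged[~merged["excluded_a"] & ~merged["excluded_b"]]
    if not len(merged):
        raise ValueError("no overlapping operating hours between the two units")
    r, n_hours = passage.paired_hour_correlation(
        hourly[site_a.site_id], hourly[site_b.site_id])
    model = LeastRectangles(
        merged["target_count_b"].to_numpy(float),
        merged["target_count_a"].to_numpy(float),
        family=config.family,
    )
    res = model.fit(bootstrap=config.bootstrap, seed=config.seed)
    test = res.identity_line_test() if config.bootstrap >= 100 else None
    return {
        "paired_hours": n_hours,
        "pearson_r": r,
        "results": res,
        "identity_test": test,
        "paired_table": merged,
    }


def _paired_observations(
    vsr_by_site: dict[str, pd.DataFrame], config: RunConfig, trials
) -> pd.DataFrame:
    """Shoreline/inland TPR pairs per (trial, night_id, period)."""
    frames = []
    for site in config.sites.values():
        if site.trial not in trials or site.site_id not in vsr_by_site:
            continue
        rec = prepare_vsr(vsr_by_site[site.site_id], config)
        frames.append(site_period_observations(rec, site, config))
    if not frames:
        raise ValueError("no usable sites/trials")
    obs = pd.concat(frames, ignore_index=True)
    shore = obs[obs["role"] == "shoreline"]
    inland = obs[obs["role"] == "inland"]
    paired = shore.merge(
        inland, on=["trial", "night_id", "period"], suffixes=("_shore", "_inland"))
    if not len(paired):
        raise ValueError("no shoreline-inland pairs; check site registry")
    return paired


def run_trial_comparison(
    vsr_by_site: dict[str, pd.DataFrame], config: RunConfig
) -> dict:
    """Shoreline-vs-inland slope tests and descriptive summaries.

    Fits the least-rectangles line of shoreline TPR (y) on inland TPR
    (x) per biological period and for all periods combined, each with a
    bootstrap confidence region and identity-line test, plus pooled
    means and percent differences per trial and period.
    """
    trials = INFERENTIAL_TRIALS + (("D",) if config.include_trial_d else ())
    paired = _paired_observations(vsr_by_site, config, trials)

    fits = {}
    rows = []
    subsets = {"all": paired}
    subsets.update({p: paired[paired["period"] == p]
                    for p in ("dawn", "day", "dusk", "night")})
    for name, sub in subsets.items():
        if len(sub) < 3:
            logger.warning("period %s has %d pairs; skipped", name, len(sub))
            continue
        model = LeastRectangles(
            sub["tpr_shore"].to_numpy(float),
            sub["tpr_inland"].to_numpy(float),
            family=config.family,
        )
        res = model.fit(bootstrap=config.bootstrap, seed=config.seed)
        fits[name] = res
        row = {"period": name, "n_pairs": len(sub),
               "slope": res.slope, "intercept": res.intercept}
        if config.bootstrap:
            ci = res.conf_int()
            row.update(slope_lo=ci.loc["slope", "lower"], slope_hi=ci.loc["slope", "upper"],
                       intercept_lo=ci.loc["intercept", "lower"],
                       intercept_hi=ci.loc["intercept", "upper"])
            if config.bootstrap >= 100:
                row["identity_excluded"] = res.identity_line_test().significant
        rows.append(row)
    slope_table = pd.DataFrame(rows)

    summary_rows = []
    for (trial, period), sub in paired.groupby(["trial", "period"], observed=True):
        both = pd.concat([
            sub[["night_id", "period", "tpr_shore"]].rename(columns={"tpr_shore": "tpr"}),
            sub[["night_id", "period", "tpr_inland"]].rename(columns={"tpr_inland": "tpr"}),
        ])
        mean, se = passage.pooled_mean_tpr(both)
        shore = sub.rename(columns={"tpr_shore": "tpr"})[["night_id", "period", "tpr"]]
        inl = sub.rename(columns={"tpr_inland": "tpr"})[["night_id", "period", "tpr"]]
        try:
            pdiff, pdiff_se, n_inst = passage.percent_difference(shore, inl)
        except ValueError:
            pdiff = pdiff_se = float("nan")
            n_inst = 0
        summary_rows.append({
            "trial": trial, "period": period, "n_instances": len(sub),
            "pooled_mean_tpr": mean, "pooled_se": se,
            "percent_difference": pdiff, "percent_difference_se": pdiff_se,
        })
    return {
        "fits": fits,
        "slope_table": slope_table,
        "summary_table": pd.DataFrame(summary_rows),
        "paired_observations": paired,
    }


def run_direction_analysis(
    hsr_by_site: dict[str, pd.DataFrame], config: RunConfig
) -> dict:
    """Night-vs-dawn flight-direction analysis (Watson-Williams).

    Groups HSR targets by location (inland, shoreline, over_water — the
    last a subset of shoreline targets west of the site's shoreline
    longitude) and trial, draws seeded equal-size subsamples per
    (location, trial, period), and tests for a change in mean direction
    from night to dawn.  Positive differences are clockwise.
    """
    trials = INFERENTIAL_TRIALS + (("D",) if config.include_trial_d else ())
    groups: dict[tuple, np.ndarray] = {}
    for site in config.sites.values():
        if site.trial not in trials or site.site_id not in hsr_by_site:
            continue
        rec = prepare_hsr(hsr_by_site[site.site_id], config)
        # one day past the deployment end: the final night runs into the
        # next civil day, and double-counted records can trail it slightly
        cal = solar_calendar(site.date_start,
                             site.date_end + pd.Timedelta(days=1).to_pytimedelta(),
                             site.latitude_deg, site.longitude_deg)
        from .solar import assign_period
        assigned = assign_period(rec["timestamp"], cal)
        rec = rec.assign(period=assigned["period"].values)
        for period in ("night", "dawn"):
            sub = rec[rec["period"] == period]
            loc = "inland" if site.role == "inland" else "shoreline"
            key = (loc, site.trial, period)
            groups.setdefault(key, []).append(sub["heading_deg"].to_numpy(float))
            if site.role == "shoreline":
                over = classify_overwater(sub, site)
                key = ("over_water", site.trial, period)
                groups.setdefault(key, []).append(over["heading_deg"].to_numpy(float))
    groups = {k: np.concatenate(v) for k, v in groups.items()}

    # pooled all-trial groups
    for loc in ("inland", "shoreline", "over_water"):
        for period in ("night", "dawn"):
            parts = [groups[(loc, t, period)] for t in trials
                     if (loc, t, period) in groups]
            if parts:
                groups[(loc, "all", period)] = np.concatenate(parts)

    flat = {f"{loc}/{trial}/{period}": h for (loc, trial, period), h in groups.items()}
    samples = subsample_equal(flat, n=config.subsample_n, seed=config.seed)

    rows = []
    roses = {}
    for loc in ("inland", "shoreline", "over_water"):
        for trial in ("all",) + tuple(trials):
            k_night, k_dawn = f"{loc}/{trial}/night", f"{loc}/{trial}/dawn"
            if k_night not in samples or k_dawn not in samples:
                continue
            ww = watson_williams(samples[k_night], samples[k_dawn])
            s_night = circ_mean_mrl(samples[k_night])
            s_dawn = circ_mean_mrl(samples[k_dawn])
            rows.append({
                "location": loc, "trial": trial,
                "df1": ww.df1, "df2": ww.df2, "F": ww.F, "p": ww.p,
                "difference_deg": ww.difference_deg,
                "mean_night_deg": s_night.mean_direction_deg,
                "mean_dawn_deg": s_dawn.mean_direction_deg,
                "mrl_night": s_night.mrl, "mrl_dawn": s_dawn.mrl,
                "n_per_sample": config.subsample_n, "seed": config.seed,
            })
            roses[k_night] = rose_bins(samples[k_night])
            roses[k_dawn] = rose_bins(samples[k_dawn])
    return {"ww_table": pd.DataFrame(rows), "rose_bins": roses, "samples": samples}


def write_reports(outdir: str | Path, *, trial_report=None, radar_report=None,
                  direction_report=None, config: RunConfig | None = None) -> None:
    """Write tidy CSV reports plus a JSON run summary."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    summary: dict = {}
    if config is not None:
        summary["config"] = {
            "family": config.family, "bootstrap": config.bootstrap,
            "seed": config.seed, "subsample_n": config.subsample_n,
            "include_trial_d": config.include_trial_d,
        }
    if trial_report is not None:
        trial_report["slope_table"].to_csv(outdir / "slopes.csv", index=False)
        trial_report["summary_table"].to_csv(outdir / "tpr_summary.csv", index=False)
        trial_report["paired_observations"].to_csv(
            outdir / "period_observations.csv", index=False)
        for name, res in trial_report["fits"].items():
            if res.B:
                res.fitted_envelope().to_csv(
                    outdir / f"envelope_{name}.csv", index=False)
        summary["trial_comparison"] = trial_report["slope_table"].to_dict("records")
    if radar_report is not None:
        res = radar_report["results"]
        summary["radar_comparison"] = {
            "paired_hours": radar_report["paired_hours"],
            "pearson_r": radar_report["pearson_r"],
            "slope": res.slope, "intercept": res.intercept,
        }
        if res.B:
            ci = res.conf_int()
            summary["radar_comparison"].update(
                slope_ci=[ci.loc["slope", "lower"], ci.loc["slope", "upper"]])
        if radar_report["identity_test"] is not None:
            summary["radar_comparison"]["identity_excluded"] = bool(
                radar_report["identity_test"].significant)
        radar_report["paired_table"].to_csv(outdir / "radar_paired_hours.csv", index=False)
    if direction_report is not None:
        direction_report["ww_table"].to_csv(outdir / "watson_williams.csv", index=False)
        for key, bins in direction_report["rose_bins"].items():
            safe = key.replace("/", "_")
            bins.to_csv(outdir / f"rose_{safe}.csv", index=False)
        summary["directions"] = direction_report["ww_table"].to_dict("records")
    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, default=float)
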