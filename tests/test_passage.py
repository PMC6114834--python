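"""Passage-rate computation: period TPR, pooled means, percent
differences, paired-hour correlation."""

import datetime as dt

import numpy as np
import pandas as pd
import pytest

from migradar.passage import (
    daily_counts,
    hourly_counts,
    paired_hour_correlation,
    percent_difference,
    period_tpr,
    pooled_mean_tpr,
)
from migradar.solar import solar_calendar
from migradar.tracks import ExclusionMask

LAT, LON = 44.43, -86.2


@pytest.fixture(scope="module")
def calendar():
    return solar_calendar(dt.date(2014, 4, 24), dt.date(2014, 4, 24), LAT, LON)


def _records(times, site="S2"):
    return pd.DataFrame({
        "target_id": [f"T{i}" for i in range(len(times))],
        "site_id": site,
        "antenna": "VSR",
        "timestamp": pd.to_datetime(times, utc=True),
        "n_observations": 8,
        "vsr_offset_m": 0.0,
        "altitude_m": 200.0,
    })


def _uniform_in(lo, hi, n, rng):
    span = (hi - lo).total_seconds()
    return [lo + dt.timedelta(seconds=float(s)) for s in np.sort(rng.uniform(0, span, n))]


class TestPeriodTPR:
    def test_dawn_tpr_equals_target_count(self, calendar):
        rng = np.random.default_rng(0)
        lo, hi = calendar[0].period_bounds["dawn"]
        obs = period_tpr(_records(_uniform_in(lo, hi, 50, rng)), calendar)
        dawn = obs[obs["period"] == "dawn"].iloc[0]
        assert dawn["target_count"] == 50
        assert dawn["effective_hours"] == pytest.approx(1.0)
        assert dawn["tpr"] == pytest.approx(50.0)

    def test_night_tpr_is_mean_hourly_rate(self, calendar):
        rng = np.random.default_rng(1)
        lo, hi = calendar[0].period_bounds["night"]
        obs = period_tpr(_records(_uniform_in(lo, hi, 100, rng)), calendar)
        night = obs[obs["period"] == "night"].iloc[0]
        hours = (hi - lo).total_seconds() / 3600.0
        assert night["tpr"] == pytest.approx(100.0 / hours)

    def test_exclusion_reduces_effective_hours(self, calendar):
        """A partially masked night divides the surviving count by the
        surviving hours, e.g. 80 targets over (night - 2 h)."""
        rng = np.random.default_rng(2)
        lo, hi = calendar[0].period_bounds["night"]
        mask = ExclusionMask(pd.DataFrame([{
            "site_id": "S2", "start": pd.Timestamp(lo),
            "end": pd.Timestamp(lo) + pd.Timedelta(hours=2), "reason": "rain",
        }]))
        keep_lo = lo + dt.timedelta(hours=2)
        records = _records(_uniform_in(keep_lo, hi, 80, rng))
        obs = period_tpr(records, calendar, mask)
        night = obs[obs["period"] == "night"].iloc[0]
        expected_hours = (hi - lo).total_seconds() / 3600.0 - 2.0
        assert night["effective_hours"] == pytest.approx(expected_hours)
        assert night["tpr"] == pytest.approx(80.0 / expected_hours)

    def test_fully_excluded_period_omitted(self, calendar):
        lo, hi = calendar[0].period_bounds["dusk"]
        mask = ExclusionMask(pd.DataFrame([{
            "site_id": "S2", "start": pd.Timestamp(lo),
            "end": pd.Timestamp(hi), "reason": "rain",
        }]))
        obs = period_tpr(_records([]), calendar, mask)
        assert "dusk" not in set(obs["period"])

    def test_counts_conserved_across_segmentation(self, calendar):
        rng = np.random.default_rng(3)
        lo = calendar[0].period_bounds["dawn"][0]
        hi = calendar[0].period_bounds["night"][1]
        records = _records(_uniform_in(lo, hi, 500, rng))
        obs = period_tpr(records, calendar)
        assert obs["target_count"].sum() == 500

    def test_order_invariance(self, calendar):
        rng = np.random.default_rng(4)
        lo, hi = calendar[0].period_bounds["night"]
        records = _records(_uniform_in(lo, hi, 60, rng))
        shuffled = records.sample(frac=1, random_state=0).reset_index(drop=True)
        a = period_tpr(records, calendar)
        b = period_tpr(shuffled, calendar)
        pd.testing.assert_frame_equal(a, b)


class TestHourlyCounts:
    def test_counts_and_zero_hours(self):
        times = (["2014-04-24T03:10:00Z"] * 10) + ["2014-04-24T05:30:00Z"]
        out = hourly_counts(_records(times))
        assert list(out["target_count"]) == [10, 0, 1]

    def test_matches_bruteforce_binning(self):
        rng = np.random.default_rng(5)
        t0 = pd.Timestamp("2014-04-24T01:00:00Z")
        times = [t0 + pd.Timedelta(seconds=float(s))
                 for s in rng.uniform(0, 6 * 3600, 400)]
        out = hourly_counts(_records(times))
        for row in out.itertuples():
            lo = row.hour_start.tz_convert("UTC")
            hi = lo + pd.Timedelta(hours=1)
            assert row.target_count == sum(1 for t in times if lo <= t < hi)


def test_pooled_mean_and_se():
    obs = pd.DataFrame({"period": "night", "tpr": [10.0, 20.0]})
    mean, se = pooled_mean_tpr(obs)
    assert mean == 15.0
    assert se == pytest.approx(np.std([10, 20], ddof=1) / np.sqrt(2))
    equal = pd.DataFrame({"period": "night", "tpr": [7.0] * 5})
    assert pooled_mean_tpr(equal)[1] == 0.0


class TestPercentDifference:
    def _obs(self, tprs, period="dawn"):
        return pd.DataFrame({
            "night_id": [dt.date(2014, 4, 24) + dt.timedelta(days=i)
                         for i in range(len(tprs))],
            "period": period,
            "tpr": tprs,
        })

    def test_formula_case(self):
        mean, se, n = percent_difference(self._obs([150.0]), self._obs([100.0]))
        assert mean == pytest.approx(0.5)
        assert n == 1

    def test_equal_rates_give_zero(self):
        mean, _, _ = percent_difference(self._obs([42.0, 13.0]), self._obs([42.0, 13.0]))
        assert mean == 0.0

    def test_zero_inland_instance_dropped(self):
        mean, _, n = percent_difference(self._obs([150.0, 80.0]), self._obs([100.0, 0.0]))
        assert n == 1
        assert mean == pytest.approx(0.5)

    def test_recovers_true_multiplier(self):
        rng = np.random.default_rng(6)
        lam = rng.uniform(50, 400, 40)
        inland = rng.poisson(lam).astype(float)
        shore = rng.poisson(1.5 * lam).astype(float)
        keep = inland > 0
        mean, se, _ = percent_difference(
            self._obs(list(shore[keep])), self._obs(list(inland[keep])))
        assert abs(mean - 0.5) < 3 * se + 0.02


class TestPairedHourCorrelation:
    def _hourly(self, counts, excluded=False):
        t0 = pd.Timestamp("2014-04-24T00:00:00-04:00")
        return pd.DataFrame({
            "site_id": "X",
            "hour_start": [t0 + pd.Timedelta(hours=i) for i in range(len(counts))],
            "target_count": counts,
            "excluded": excluded,
        })

    def test_identical_series_r_is_one(self):
        h = self._hourly([3, 9, 1, 14, 6])
        r, n = paired_hour_correlation(h, h)
        assert r == pytest.approx(1.0)
        assert n == 5

    def test_independent_series_r_near_zero(self):
        rng = np.random.default_rng(7)
        a = self._hourly(list(rng.poisson(20, 2000)))
        b = self._hourly(list(rng.poisson(20, 2000)))
        r, _ = paired_hour_correlation(a, b)
        assert abs(r) < 0.08

    def test_excluded_hours_dropped(self):
        a = self._hourly([3, 9, 1, 14, 6])
        b = self._hourly([3, 9, 1, 14, 6])
        a.loc[0, "excluded"] = True
        _, n = paired_hour_correlation(a, b)
        assert n == 4

    def test_matches_covariance_formula(self):
        rng = np.random.default_rng(8)
        x = rng.poisson(30, 50).astype(float)
        y = rng.poisson(30, 50).astype(float) + 0.5 * x
        r, _ = paired_hour_correlation(self._hourly(list(x)), self._hourly(list(y)))
        num = ((x - x.mean()) * (y - y.mean())).sum()
        den = np.sqrt(((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum())
        assert r == pytest.approx(num / den, abs=1e-12)

    def test_zero_variance_refused(self):
        with pytest.raises(ValueError, match="variance"):
            paired_hour_correlation(self._hourly([5, 5, 5, 5]),
                                    self._hourly([1, 2, 3, 4]))


def test_daily_counts_midnight_to_midnight():
    # 23:30 local on day 1 and 00:30 local on day 2 land on different days
    times = ["2014-04-25T03:30:00Z", "2014-04-25T04:30:00Z"]  # UTC-4 local
    out = daily_counts(_records(times))
    assert len(out) == 2
    assert set(out["target_count"]) == {1}
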