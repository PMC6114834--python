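"""Circular statistics: compass means, MRL, Watson-Williams, shifts,
rose binning."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.special import i0, i1

from migradar.circular import (
    circ_mean_mrl,
    kappa_ml,
    night_dawn_shift,
    rose_bins,
    subsample_equal,
    watson_williams,
    wrap_signed,
)


class TestMeanAndMRL:
    def test_symmetric_pair_about_north(self):
        s = circ_mean_mrl([350.0, 10.0])
        assert s.mean_direction_deg == pytest.approx(0.0, abs=1e-10)
        assert s.mrl == pytest.approx(np.cos(np.radians(10.0)), abs=1e-12)

    def test_antipodal_pair_has_undefined_mean(self):
        s = circ_mean_mrl([0.0, 180.0])
        assert s.mrl == pytest.approx(0.0, abs=1e-12)
        assert not s.mean_defined

    def test_single_heading_is_its_own_mean(self):
        s = circ_mean_mrl([123.4])
        assert s.mean_direction_deg == pytest.approx(123.4)
        assert s.mrl == pytest.approx(1.0)

    def test_von_mises_sample_matches_moments(self):
        """Mean direction ~ mu and MRL ~ A(kappa) = I1/I0 for large
        von Mises samples."""
        rng = np.random.default_rng(0)
        kappa = 1.6
        h = (343.0 + np.degrees(rng.vonmises(0.0, kappa, 10000))) % 360.0
        s = circ_mean_mrl(h)
        assert abs(wrap_signed(s.mean_direction_deg - 343.0)) < 2.0
        assert s.mrl == pytest.approx(i1(kappa) / i0(kappa), abs=0.02)

    def test_matches_vector_sum_oracle(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            h = rng.uniform(0, 360, 37)
            s = circ_mean_mrl(h)
            e = np.sin(np.radians(h)).mean()
            n = np.cos(np.radians(h)).mean()
            assert s.mrl == pytest.approx(np.hypot(e, n), abs=1e-12)
            assert s.mean_direction_deg == pytest.approx(
                np.degrees(np.arctan2(e, n)) % 360.0, abs=1e-10)

    @settings(deadline=None, max_examples=30)
    @given(shift=st.floats(0.0, 360.0), seed=st.integers(0, 10_000))
    def test_rotational_equivariance(self, shift, seed):
        rng = np.random.default_rng(seed)
        h = rng.uniform(0, 360, 25)
        base = circ_mean_mrl(h)
        rotated = circ_mean_mrl((h + shift) % 360.0)
        assert rotated.mrl == pytest.approx(base.mrl, abs=1e-9)
        if base.mean_defined:
            assert abs(wrap_signed(
                rotated.mean_direction_deg - base.mean_direction_deg - shift
            )) < 1e-6


class TestShift:
    def test_reported_dawn_turn_example(self):
        night = circ_mean_mrl([343.0])
        dawn = circ_mean_mrl([35.0])
        assert night_dawn_shift(night, dawn) == pytest.approx(52.0)

    def test_counterclockwise_is_negative(self):
        assert night_dawn_shift(circ_mean_mrl([10.0]), circ_mean_mrl([350.0])) \
            == pytest.approx(-20.0)

    def test_matches_minimal_angle_oracle(self):
        rng = np.random.default_rng(2)
        for _ in range(200):
            a, b = rng.uniform(0, 360, 2)
            got = night_dawn_shift(circ_mean_mrl([a]), circ_mean_mrl([b]))
            candidates = [b - a + k * 360 for k in (-2, -1, 0, 1, 2)]
            best = min(candidates, key=abs)
            if abs(best) == 180.0:
                best = 180.0
            assert got == pytest.approx(best, abs=1e-9)

    def test_undefined_mean_refused(self):
        with pytest.raises(ValueError):
            night_dawn_shift(circ_mean_mrl([0.0, 180.0]), circ_mean_mrl([35.0]))


class TestWatsonWilliams:
    def test_identical_samples_give_zero_F(self):
        rng = np.random.default_rng(3)
        a = rng.uniform(0, 90, 100)
        ww = watson_williams(a, a.copy())
        assert ww.F == pytest.approx(0.0, abs=1e-9)
        assert ww.difference_deg == pytest.approx(0.0, abs=1e-9)
        assert ww.p > 0.99

    def test_matches_stepwise_formula_oracle(self):
        """Hand computation of R1, R2, R, kappa, K and F for two small
        samples, spreadsheet style."""
        a = np.array([10.0, 350.0, 55.0, 315.0, 340.0, 28.0, 3.0, 290.0])
        b = np.array([40.0, 95.0, 12.0, 47.0, 81.0, 8.0, 70.0, 44.0, 349.0, 58.0])
        ww = watson_williams(a, b)

        def res(h):
            r = np.radians(h)
            return np.sin(r).sum(), np.cos(r).sum()
        e1, c1 = res(a)
        e2, c2 = res(b)
        r1 = np.hypot(e1, c1)
        r2 = np.hypot(e2, c2)
        r = np.hypot(e1 + e2, c1 + c2)
        n = len(a) + len(b)
        rbar = (r1 + r2) / n
        kappa = -0.4 + 1.39 * rbar + 0.43 / (1 - rbar)  # rbar in [0.53, 0.85)
        K = 1 + 3 / (8 * kappa)
        F = K * (n - 2) * (r1 + r2 - r) / (n - r1 - r2)
        assert 0.53 <= rbar < 0.85
        assert ww.F == pytest.approx(F, abs=1e-8)
        assert ww.df1 == 1
        assert ww.df2 == n - 2
        mean_a = np.degrees(np.arctan2(e1, c1)) % 360
        mean_b = np.degrees(np.arctan2(e2, c2)) % 360
        assert ww.difference_deg == pytest.approx(
            wrap_signed(mean_b - mean_a), abs=1e-9)

    def test_clear_shift_detected_with_positive_sign(self):
        rng = np.random.default_rng(4)
        night = (343.0 + np.degrees(rng.vonmises(0, 1.0, 2000))) % 360
        dawn = (35.0 + np.degrees(rng.vonmises(0, 1.6, 2000))) % 360
        ww = watson_williams(night, dawn)
        assert ww.p < 1e-6
        assert ww.difference_deg == pytest.approx(52.0, abs=5.0)

    def test_uniform_sample_refused(self):
        h = np.arange(0, 360, 1.0)  # perfectly balanced, MRL ~ 0
        with pytest.raises(ValueError, match="concentration|refused"):
            watson_williams(h, h + 0.5)

    def test_kappa_inverse_consistent_with_A(self):
        # A(kappa_ml(r)) ~ r across the three approximation branches
        for r in (0.2, 0.45, 0.6, 0.8, 0.9, 0.97):
            k = kappa_ml(r)
            assert i1(k) / i0(k) == pytest.approx(r, abs=0.012)


class TestSubsample:
    def _groups(self):
        rng = np.random.default_rng(5)
        return {"big": rng.uniform(0, 360, 500), "exact": rng.uniform(0, 360, 100)}

    def test_exact_size_group_returned_whole(self):
        g = self._groups()
        out = subsample_equal(g, n=100, seed=0)
        np.testing.assert_array_equal(out["exact"], g["exact"])
        assert len(out["big"]) == 100

    def test_seed_contract(self):
        g = self._groups()
        a = subsample_equal(g, n=50, seed=7)
        b = subsample_equal(g, n=50, seed=7)
        c = subsample_equal(g, n=50, seed=8)
        np.testing.assert_array_equal(a["big"], b["big"])
        assert not np.array_equal(a["big"], c["big"])

    def test_undersized_group_named_in_error(self):
        with pytest.raises(ValueError, match="exact"):
            subsample_equal(self._groups(), n=200, seed=0)

    def test_subsample_preserves_distribution(self):
        rng = np.random.default_rng(6)
        parent = (20.0 + np.degrees(rng.vonmises(0, 2.0, 30000))) % 360
        sub = subsample_equal({"g": parent}, n=5000, seed=1)["g"]
        assert abs(wrap_signed(circ_mean_mrl(sub).mean_direction_deg
                               - circ_mean_mrl(parent).mean_direction_deg)) < 2.0


class TestRoseBins:
    def test_zero_heading_in_first_wedge(self):
        out = rose_bins([0.0], width_deg=5.0)
        assert out["count"].iloc[0] == 1
        assert out["count"].sum() == 1

    def test_counts_conserved(self):
        rng = np.random.default_rng(7)
        h = rng.uniform(0, 360, 7777)
        out = rose_bins(h)
        assert out["count"].sum() == 7777
        assert len(out) == 72

    def test_uniform_draws_spread_evenly(self):
        rng = np.random.default_rng(8)
        h = rng.uniform(0, 360, 72000)
        out = rose_bins(h, width_deg=5.0)
        assert out["count"].min() > 800
        assert out["count"].max() < 1200

    def test_non_divisor_width_rejected(self):
        with pytest.raises(ValueError, match="divide"):
            rose_bins([10.0], width_deg=7.0)
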