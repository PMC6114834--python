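"""Circular statistics for compass headings.

All directions are compass degrees: 0 = north, ascending clockwise, in
[0, 360).  The compass-to-vector convention is fixed project-wide as
u = (sin theta, cos theta) so that compass means round-trip exactly —
mixing this with the mathematical (cos, sin) convention is the classic
silent bug in heading analyses.

Provides the circular mean and mean resultant length (MRL), seeded
equal-size subsampling, the two-sample Watson-Williams test for a
difference in mean direction, the signed night-to-dawn shift (positive =
clockwise), and rose-diagram wedge binning.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

#: MRL below this is treated as "no preferred direction"; the circular
#: mean is then undefined.
MRL_UNDEFINED = 1e-12


@dataclass(frozen=True)
class CircularSummary:
    """Circular mean direction (compass degrees; NaN if undefined), mean
    resultant length in [0, 1], and sample size."""

    mean_direction_deg: float
    mrl: float
    n: int

    @property
    def mean_defined(self) -> bool:
        return not np.isnan(self.mean_direction_deg)


@dataclass(frozen=True)
class WWResult:
    """Watson-Williams comparison of two heading samples.

    ``difference_deg`` is the wrapped signed change from sample a to
    sample b in (-180, 180]; positive = clockwise.  ``correction_K`` is
    the concentration correction 1 + 3/(8 kappa_hat).
    """

    F: float
    df1: int
    df2: int
    p: float
    difference_deg: float
    correction_K: float
    kappa_hat: float
    mean_a_deg: float
    mean_b_deg: float


def _resultant(headings_deg: np.ndarray) -> tuple[float, float]:
    """(east-component sum, north-component sum) of unit heading vectors."""
    rad = np.radians(headings_deg)
    return float(np.sin(rad).sum()), float(np.cos(rad).sum())


def circ_mean_mrl(headings_deg) -> CircularSummary:
    """Circular mean and mean resultant length of compass headings."""
    h = np.asarray(headings_deg, dtype=float)
    if h.size == 0:
        raise ValueError("need at least one heading")
    e, n = _resultant(h)
    r = np.hypot(e, n) / h.size
    if r < MRL_UNDEFINED:
        logger.info("mean resultant length ~ 0; circular mean undefined")
        return CircularSummary(float("nan"), float(r), int(h.size))
    mean = np.degrees(np.arctan2(e, n)) % 360.0
    if mean >= 360.0:  # float wrap of a tiny negative angle
        mean = 0.0
    return CircularSummary(float(mean), float(r), int(h.size))


def wrap_signed(angle_deg: float) -> float:
    """Wrap an angle to (-180, 180]."""
    a = (-angle_deg) % 360.0
    return -a if a < 180.0 else 360.0 - a


def night_dawn_shift(night: CircularSummary, dawn: CircularSummary) -> float:
    """Signed change in mean direction from night to dawn.

    Positive values are clockwise (e.g. 343 deg -> 35 deg gives +52), the
    direction of a turn from north-northwest toward land on an eastern
    shoreline at first light.
    """
    if not (night.mean_defined and dawn.mean_defined):
        raise ValueError("cannot compute shift with an undefined circular mean")
    return wrap_signed(dawn.mean_direction_deg - night.mean_direction_deg)


def kappa_ml(rbar: float) -> float:
    """ML von Mises concentration from a mean resultant length.

    Standard three-branch rational approximation to the inverse of
    A(kappa) = I1(kappa)/I0(kappa).
    """
    if not 0.0 <= rbar <= 1.0:
        raise ValueError("mean resultant length must be in [0, 1]")
    if rbar < 0.53:
        return 2.0 * rbar + rbar**3 + 5.0 * rbar**5 / 6.0
    if rbar < 0.85:
        return -0.4 + 1.39 * rbar + 0.43 / (1.0 - rbar)
    denom = rbar**3 - 4.0 * rbar**2 + 3.0 * rbar
    return 1.0 / denom if denom > 0 else float("inf")


def watson_williams(sample_a, sample_b) -> WWResult:
    """Two-sample Watson-Williams test for equal mean direction.

    Classical high-concentration F approximation: with per-sample
    resultant lengths R1, R2 and pooled resultant R (all unnormalised),
    F = K * (N - 2) * (R1 + R2 - R) / (N - R1 - R2), where
    K = 1 + 3 / (8 kappa_hat) corrects for finite concentration and
    kappa_hat is the ML concentration of the weighted mean of the
    within-sample MRLs.  The test assumes comparable concentrations in
    the two samples; a large discrepancy is logged, not enforced, because
    with the study's sample sizes the magnitude of the direction shift
    carries the biological signal and p-values saturate.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    n1, n2 = a.size, b.size
    if n1 < 2 or n2 < 2:
        raise ValueError("each sample needs at least 2 headings")
    e1, c1 = _resultant(a)
    e2, c2 = _resultant(b)
    r1 = float(np.hypot(e1, c1))
    r2 = float(np.hypot(e2, c2))
    if r1 / n1 < MRL_UNDEFINED or r2 / n2 < MRL_UNDEFINED:
        raise ValueError("a sample has no directional concentration; test refused")
    big_n = n1 + n2
    r = float(np.hypot(e1 + e2, c1 + c2))
    rbar_w = (r1 + r2) / big_n
    if abs(r1 / n1 - r2 / n2) > 0.2:
        logger.warning(
            "Watson-Williams concentration check: per-sample MRLs %.3f vs %.3f differ; "
            "F approximation may be off", r1 / n1, r2 / n2,
        )
    kappa = kappa_ml(rbar_w)
    K = 1.0 + 3.0 / (8.0 * kappa)
    df1, df2 = 1, big_n - 2
    denom = big_n - r1 - r2
    F = K * df2 * (r1 + r2 - r) / denom if denom > 0 else float("inf")
    F = max(F, 0.0)
    p = float(stats.f.sf(F, df1, df2))
    mean_a = np.degrees(np.arctan2(e1, c1)) % 360.0
    mean_b = np.degrees(np.arctan2(e2, c2)) % 360.0
    return WWResult(
        F=float(F), df1=df1, df2=df2, p=p,
        difference_deg=wrap_signed(mean_b - mean_a),
        correction_K=float(K), kappa_hat=float(kappa),
        mean_a_deg=float(mean_a), mean_b_deg=float(mean_b),
    )


def subsample_equal(
    groups: dict[str, np.ndarray], n: int = 20000, seed: int | None = None
) -> dict[str, np.ndarray]:
    """Seeded equal-size random subsamples (without replacement) per group.

    Equal sizes let groups of very different sizes be compared on the
    same footing.  A group smaller than ``n`` raises, naming the group.
    """
    rng = np.random.default_rng(seed)
    out = {}
    for name in groups:
        h = np.asarray(groups[name])
        if h.size < n:
            raise ValueError(f"group {name!r} has {h.size} targets; need >= {n}")
        out[name] = h if h.size == n else rng.choice(h, size=n, replace=False)
    return out


def rose_bins(headings_deg, width_deg: float = 5.0) -> pd.DataFrame:
    """Wedge counts for a rose diagram.

    Wedges are half-open [k*w, (k+1)*w) compass-degree intervals; the
    width must divide 360 so that the wedges tile the circle and the
    counts conserve the sample size.
    """
    if 360.0 % width_deg != 0:
        raise ValueError(f"wedge width {width_deg} does not divide 360")
    h = np.mod(np.asarray(headings_deg, dtype=float), 360.0)
    n_bins = int(round(360.0 / width_deg))
    idx = np.floor(h / width_deg).astype(int)
    idx = np.clip(idx, 0, n_bins - 1)
    counts = np.bincount(idx, minlength=n_bins)
    return pd.DataFrame({
        "wedge_start_deg": np.arange(n_bins) * width_deg,
        "count": counts,
    })
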