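"""Least-rectangles (errors-in-both-variables) slope regression.

The shoreline-vs-inland comparison regresses one passage-rate series on
another when neither is a "predictor": both are noisy measurements of the
same underlying migration intensity.  Least-rectangles regression treats
the axes symmetrically.  Two families are provided:

``gaussian``
    The classical geometric-mean (reduced major axis) line:
    slope = sign(r) * s_y / s_x, intercept = ybar - slope * xbar.

``poisson``
    A latent-intensity errors-in-variables likelihood suited to counts
    and rates: each point i carries a latent intensity mu_i with
    x_i ~ Poisson(mu_i) and y_i ~ Poisson(a + b * mu_i).  The mu_i are
    profiled out in closed form (per-point quadratic) and (a, b) are
    maximised by quasi-Newton ascent with an analytic envelope-theorem
    gradient, started from the gaussian fit.  The model is symmetric
    under axis exchange: swapping x and y maps (a, b) -> (-a/b, 1/b).

``sqrt_gaussian``
    Sensitivity alternative: the gaussian family on variance-stabilised
    sqrt counts, with the slope reported on the original scale as the
    squared sqrt-scale slope.

Uncertainty comes from a seeded non-parametric bootstrap over (x, y)
pairs with percentile confidence intervals, and the identity-line test
asks whether the joint 95% bootstrap region of (slope, intercept)
excludes the 1:1 line (slope 1, intercept 0).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

logger = logging.getLogger(__name__)

FAMILIES = ("gaussian", "poisson", "sqrt_gaussian")


class DegenerateFitError(ValueError):
    """x or y has zero variance; no line is identifiable."""


class ConvergenceError(RuntimeError):
    """The poisson-family optimizer failed; carries diagnostics."""


# ---------------------------------------------------------------------------
# point estimators

def _gaussian_lr(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    sx = x.std(ddof=1)
    sy = y.std(ddof=1)
    if sx == 0 or sy == 0:
        raise DegenerateFitError("zero variance in x or y")
    cov = np.cov(x, y, ddof=1)[0, 1]
    sign = 1.0 if cov >= 0 else -1.0
    slope = sign * sy / sx
    intercept = y.mean() - slope * x.mean()
    return float(slope), float(intercept)


def _profile_loglik_and_grad(
    a: float, b: float, x: np.ndarray, y: np.ndarray
) -> tuple[float, float, float]:
    """Poisson EIV log-likelihood with latent mu_i profiled out.

    For fixed (a, b) the optimal mu_i solves a per-point quadratic
    (1+b) b mu^2 + ((1+b) a - b (x+y)) mu - x a = 0; both roots plus the
    rate-nonnegativity boundary are screened and the best feasible one
    taken.  Returns (loglik, dL/da, dL/db) by the envelope theorem.
    """
    A = (1.0 + b) * b
    B = (1.0 + b) * a - b * (x + y)
    C = -x * a
    with np.errstate(invalid="ignore", divide="ignore"):
        disc = np.sqrt(np.maximum(B * B - 4.0 * A * C, 0.0))
        if abs(A) < 1e-12:
            r1 = np.where(np.abs(B) > 1e-30, -C / np.where(B == 0, 1.0, B), 0.0)
            r2 = r1
        else:
            q = -0.5 * (B + np.sign(B + (B == 0)) * disc)
            r1 = q / A
            r2 = np.where(np.abs(q) > 1e-300, C / np.where(q == 0, 1.0, q), 0.0)
    # candidate latent means: both quadratic roots, zero, and the
    # rate-zero boundary (relevant when y = 0 and a < 0)
    boundary = np.full_like(x, max(0.0, -a / b) if b > 0 else 0.0)
    cands = np.stack([
        np.clip(r1, 0.0, None),
        np.clip(r2, 0.0, None),
        np.zeros_like(x),
        boundary,
    ])

    def obj(mu):
        rate = a + b * mu
        with np.errstate(invalid="ignore", divide="ignore"):
            t1 = np.where(x > 0, x * np.log(np.where(mu > 0, mu, np.nan)), 0.0)
            t2 = np.where(y > 0, y * np.log(np.where(rate > 0, rate, np.nan)), 0.0)
        out = -mu + t1 - rate + t2
        bad = (mu < 0) | (rate < -1e-12) | ((x > 0) & (mu <= 0)) | ((y > 0) & (rate <= 0))
        return np.where(bad | np.isnan(out), -np.inf, out)

    vals = obj(cands)
    best = np.argmax(vals, axis=0)
    mu_star = cands[best, np.arange(x.size)]
    ll = vals[best, np.arange(x.size)]
    if not np.isfinite(ll).all():
        return -np.inf, 0.0, 0.0
    rate = a + b * mu_star
    # envelope theorem at interior optima; at the rate-zero boundary
    # (y = 0, a < 0, mu* = -a/b) the contribution is a/b exactly, with
    # its own derivatives 1/b and -a/b^2
    on_boundary = (best == 3) & (y == 0) & (a < 0) & (b > 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        resid = np.where(rate > 0, y / np.where(rate > 0, rate, 1.0) - 1.0, -1.0)
    ga = np.where(on_boundary, 1.0 / b, resid)
    gb = np.where(on_boundary, -a / b**2, mu_star * resid)
    return float(ll.sum()), float(ga.sum()), float(gb.sum())


def _poisson_lr(
    x: np.ndarray, y: np.ndarray, start: tuple[float, float] | None = None,
    gtol: float = 1e-11,
) -> tuple[float, float]:
    if start is None:
        start = _gaussian_lr(x, y)
    a0, b0 = start
    b0 = max(b0, 1e-3)

    def neg(theta):
        a, logb = theta
        b = np.exp(logb)
        ll, ga, gb = _profile_loglik_and_grad(a, b, x, y)
        if not np.isfinite(ll):
            return 1e12, np.array([0.0, 0.0])
        return -ll, -np.array([ga, gb * b])

    theta0 = np.array([a0, np.log(b0)])
    res = optimize.minimize(
        neg, theta0, jac=True, method="L-BFGS-B",
        options={"maxiter": 500, "ftol": 1e-15, "gtol": gtol},
    )
    # Zero-count points make the profiled likelihood kinked at a = 0
    # (their contribution switches to the rate-zero boundary), which can
    # defeat the quasi-Newton line search.  If the returned point is not
    # an interior optimum (non-negligible gradient), polish with a
    # derivative-free simplex from the better candidate.
    f_res, g_res = neg(res.x)
    needs_polish = (not np.isfinite(f_res)) or res.status != 0 \
        or float(np.max(np.abs(g_res))) > 1e-2
    if needs_polish:
        f0 = neg(theta0)[0]
        start = res.x if (np.isfinite(f_res) and f_res <= f0) else theta0
        nm = optimize.minimize(
            lambda t: neg(t)[0], start, method="Nelder-Mead",
            options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 4000},
        )
        if not np.isfinite(nm.fun):
            raise ConvergenceError(
                f"poisson least-rectangles fit did not converge: {res.message}"
                f" (nll {f_res:.6g})"
            )
        if nm.fun <= f_res or not np.isfinite(f_res):
            res = nm
    a, logb = res.x
    return float(a), float(np.exp(logb))


def fit_least_rectangles(
    x: np.ndarray, y: np.ndarray, family: str = "gaussian"
) -> tuple[float, float]:
    """Point estimate (slope, intercept) of the least-rectangles line."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D arrays of equal length")
    if len(x) < 3:
        raise ValueError("need at least 3 points")
    if family == "gaussian":
        return _gaussian_lr(x, y)
    if family == "sqrt_gaussian":
        if (x < 0).any() or (y < 0).any():
            raise ValueError("sqrt_gaussian family requires non-negative values")
        s, _ = _gaussian_lr(np.sqrt(x), np.sqrt(y))
        slope = float(np.sign(s) * s * s)
        return slope, float(y.mean() - slope * x.mean())
    if family == "poisson":
        if (x < 0).any() or (y < 0).any():
            raise ValueError("poisson family requires non-negative values")
        a, b = _poisson_lr(x, y)
        return b, a
    raise ValueError(f"unknown family {family!r}; choose from {FAMILIES}")


# ---------------------------------------------------------------------------
# model / results

@dataclass
class IdentityTestResult:
    """Joint bootstrap test of the 1:1 reference line.

    ``significant`` is True when (slope, intercept) = (1, 0) lies outside
    the Mahalanobis 95% region of the bootstrap draws — the operational
    form of "the 95% confidence region does not include the line y = x".
    ``joint_pvalue_proxy`` is the fraction of draws at least as far from
    the draw centre as the reference point.
    """

    significant: bool
    joint_pvalue_proxy: float
    mahalanobis_ref: float
    mahalanobis_threshold: float
    slope_ci_excludes_1: bool
    intercept_ci_excludes_0: bool
    envelope: pd.DataFrame | None = None


class LeastRectanglesResults:
    """Fit results: estimates, bootstrap draws, CIs, identity-line test."""

    def __init__(self, model, slope, intercept, draws, seed, n_degenerate=0):
        self.model = model
        self.slope = slope
        self.intercept = intercept
        self.params = pd.Series({"slope": slope, "intercept": intercept})
        self.bootstrap_draws_ = draws  # (B, 2) array of (slope, intercept)
        self.seed = seed
        self.B = 0 if draws is None else len(draws)
        self.n_degenerate_resamples = n_degenerate
        self.nobs = model.nobs
        self.family = model.family

    def conf_int(self, alpha: float = 0.05) -> pd.DataFrame:
        """Percentile bootstrap CIs for slope and intercept."""
        if self.bootstrap_draws_ is None or self.B == 0:
            raise ValueError("no bootstrap draws; refit with bootstrap > 0")
        lo, hi = 100 * alpha / 2, 100 * (1 - alpha / 2)
        s = np.percentile(self.bootstrap_draws_[:, 0], [lo, hi])
        i = np.percentile(self.bootstrap_draws_[:, 1], [lo, hi])
        return pd.DataFrame([s, i], index=["slope", "intercept"], columns=["lower", "upper"])

    def predict(self, x) -> np.ndarray:
        return self.intercept + self.slope * np.asarray(x, dtype=float)

    def fitted_envelope(self, x_grid=None, alpha: float = 0.05, n_grid: int = 50) -> pd.DataFrame:
        """Pointwise fitted-value percentile band over the observed x-range."""
        if self.bootstrap_draws_ is None or self.B == 0:
            raise ValueError("no bootstrap draws; refit with bootstrap > 0")
        if x_grid is None:
            x_grid = np.linspace(self.model.x.min(), self.model.x.max(), n_grid)
        x_grid = np.asarray(x_grid, dtype=float)
        fitted = self.bootstrap_draws_[:, 1][:, None] + np.outer(
            self.bootstrap_draws_[:, 0], x_grid
        )
        lo, hi = np.percentile(fitted, [100 * alpha / 2, 100 * (1 - alpha / 2)], axis=0)
        return pd.DataFrame({"x": x_grid, "fit": self.predict(x_grid), "lower": lo, "upper": hi})

    def identity_line_test(self, alpha: float = 0.05, min_draws: int = 100) -> IdentityTestResult:
        """Does the joint bootstrap region exclude the line y = x?"""
        if self.bootstrap_draws_ is None or self.B < min_draws:
            raise ValueError(
                f"identity-line test needs >= {min_draws} bootstrap draws (have {self.B})"
            )
        draws = self.bootstrap_draws_
        centre = draws.mean(axis=0)
        cov = np.cov(draws.T)
        cov += np.eye(2) * 1e-12 * max(np.trace(cov), 1e-300)
        cinv = np.linalg.inv(cov)
        dev = draws - centre
        d2 = np.einsum("ij,jk,ik->i", dev, cinv, dev)
        ref = np.array([1.0, 0.0]) - centre
        d2_ref = float(ref @ cinv @ ref)
        threshold = float(np.quantile(d2, 1 - alpha))
        ci = self.conf_int(alpha)
        return IdentityTestResult(
            significant=d2_ref > threshold,
            joint_pvalue_proxy=float(np.mean(d2 >= d2_ref)),
            mahalanobis_ref=np.sqrt(d2_ref),
            mahalanobis_threshold=np.sqrt(threshold),
            slope_ci_excludes_1=not (ci.loc["slope", "lower"] <= 1.0 <= ci.loc["slope", "upper"]),
            intercept_ci_excludes_0=not (
                ci.loc["intercept", "lower"] <= 0.0 <= ci.loc["intercept", "upper"]
            ),
            envelope=self.fitted_envelope(),
        )

    def summary(self) -> str:
        lines = [
            "Least Rectangles Regression Results",
            "=" * 46,
            f"family:            {self.family}",
            f"n points:          {self.nobs}",
            f"bootstrap draws:   {self.B} (seed {self.seed})",
            "-" * 46,
            f"slope:             {self.slope:.4f}",
            f"intercept:         {self.intercept:.4f}",
        ]
        if self.B:
            ci = self.conf_int()
            lines += [
                f"slope 95% CI:      ({ci.loc['slope', 'lower']:.4f}, "
                f"{ci.loc['slope', 'upper']:.4f})",
                f"intercept 95% CI:  ({ci.loc['intercept', 'lower']:.4f}, "
                f"{ci.loc['intercept', 'upper']:.4f})",
            ]
            if self.B >= 100:
                t = self.identity_line_test()
                verdict = "excluded" if t.significant else "included"
                lines.append(f"y = x line:        {verdict} from joint 95% region "
                             f"(p-proxy {t.joint_pvalue_proxy:.3f})")
        lines.append("=" * 46)
        return "\n".join(lines)


class LeastRectangles:
    """Symmetric errors-in-both-variables line model for paired rates.

    Parameters
    ----------
    y, x : 1-D arrays of paired measurements (e.g. shoreline and inland
        TPR per period instance).  Which series is y is arbitrary by
        design; the estimator is symmetric under exchange.
    family : "gaussian", "poisson" (default for count-like rates) or
        "sqrt_gaussian".
    """

    def __init__(self, y, x, family: str = "poisson"):
        self.y = np.asarray(y, dtype=float)
        self.x = np.asarray(x, dtype=float)
        if self.x.shape != self.y.shape or self.x.ndim != 1:
            raise ValueError("x and y must be 1-D arrays of equal length")
        if len(self.x) < 3:
            raise ValueError("need at least 3 points")
        if family not in FAMILIES:
            raise ValueError(f"unknown family {family!r}; choose from {FAMILIES}")
        if family in ("poisson", "sqrt_gaussian") and ((self.x < 0).any() or (self.y < 0).any()):
            raise ValueError(f"{family} family requires non-negative values")
        self.family = family
        self.nobs = len(self.x)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, y: str, x: str, family: str = "poisson"):
        return cls(df[y].to_numpy(), df[x].to_numpy(), family=family)

    def _fit_point(self, x, y, start=None):
        if self.family == "poisson":
            a, b = _poisson_lr(x, y, start=None if start is None else (start[1], start[0]))
            return b, a
        return fit_least_rectangles(x, y, family=self.family)

    def fit(self, bootstrap: int = 2000, seed: int | None = None) -> LeastRectanglesResults:
        """Fit the line; with ``bootstrap`` > 0, add seeded percentile CIs.

        The bootstrap resamples (x, y) *pairs* with replacement and
        refits each resample; degenerate resamples (zero variance on an
        axis) are redrawn and counted.  Fewer than 10 points is allowed
        but flagged with a warning.
        """
        if self.nobs < 10 and bootstrap:
            logger.warning("bootstrap on only %d points; CIs will be unstable", self.nobs)
        slope, intercept = self._fit_point(self.x, self.y)
        draws = None
        n_degen = 0
        if bootstrap:
            rng = np.random.default_rng(seed)
            draws = np.empty((bootstrap, 2))
            n = self.nobs
            for b_i in range(bootstrap):
                for _attempt in range(100):
                    idx = rng.integers(0, n, size=n)
                    xb, yb = self.x[idx], self.y[idx]
                    if xb.std() == 0 or yb.std() == 0:
                        n_degen += 1
                        continue
                    try:
                        draws[b_i] = self._fit_point(xb, yb, start=(slope, intercept))
                    except (DegenerateFitError, ConvergenceError):
                        n_degen += 1
                        continue
                    break
                else:
                    raise DegenerateFitError(
                        "could not draw a non-degenerate bootstrap resample"
                    )
            if n_degen:
                logger.info("redrew %d degenerate bootstrap resamples", n_degen)
        return LeastRectanglesResults(self, slope, intercept, draws, seed, n_degen)
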