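"""Heteroskedastic normal spline regression of preferences on spider fear.

The model for a per-participant response y (a summarized preference or an
incoherency index) given the SPQ score s is

    y ~ Normal(mu(s), sigma^2(s)),
    mu(s)          = B(s) . beta,
    log sigma^2(s) = B(s) . gamma,

where B(s) is the natural-cubic-spline design with, by default, a single
internal knot at the empirical median of SPQ and boundary knots at the
observed extremes.  Both coefficient vectors are estimated jointly by
maximum likelihood (quasi-Newton on the analytic gradient, deterministic
initialization from ordinary least squares).  With one internal knot the
basis has three columns (intercept, linear, one curvature term), i.e. six
free parameters in total.

A natural cubic spline is linear beyond its boundary knots (zero second
derivative at and outside them), so predictions outside the observed SPQ
range extrapolate linearly.

Display bands assume normality of the response around the fitted mean:
the quartile band is mu -+ z_{0.75} sigma and the decile band is
mu -+ z_{0.9} sigma.

The response lives on [0, 1] but the likelihood is an unbounded normal;
no truncation correction is applied (a deliberate modeling caveat -- see
the package docs).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = ["NcsBasis", "SplineFitResult", "ncs_basis", "fit_hetero_spline",
           "predict_bands"]

Z_QUARTILE = float(stats.norm.ppf(0.75))  # ~0.6745
Z_DECILE = float(stats.norm.ppf(0.90))    # ~1.2816


@dataclass(frozen=True)
class NcsBasis:
    """Natural cubic spline basis with fixed knots.

    ``design`` evaluates the (n, 2 + n_internal) matrix with columns
    [1, x, N_1(x), ...]; each curvature column N_k is built from
    truncated cubic powers combined so that every spanned function has
    zero second derivative at and beyond the boundary knots.
    """

    internal_knots: tuple[float, ...]
    boundary_knots: tuple[float, float]

    def __post_init__(self) -> None:
        lo, hi = self.boundary_knots
        if not lo < hi:
            raise ValueError("boundary knots must satisfy low < high")
        for k in self.internal_knots:
            if not lo < k < hi:
                raise ValueError(
                    f"internal knot {k} outside the open boundary range ({lo}, {hi})")
        if len(set(self.internal_knots)) != len(self.internal_knots):
            raise ValueError("internal knots must be distinct")

    @property
    def dim(self) -> int:
        return 2 + len(self.internal_knots)

    @property
    def all_knots(self) -> np.ndarray:
        return np.sort(np.r_[self.boundary_knots, self.internal_knots])

    def design(self, x: Sequence[float] | np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        knots = self.all_knots
        k_last = knots[-1]

        def d(k: float) -> np.ndarray:
            num = np.maximum(x - k, 0.0) ** 3 - np.maximum(x - k_last, 0.0) ** 3
            return num / (k_last - k)

        cols = [np.ones_like(x), x]
        d_pen = d(knots[-2])
        for k in knots[:-2]:
            cols.append(d(k) - d_pen)
        return np.column_stack(cols)


def ncs_basis(x: Sequence[float] | np.ndarray,
              internal_knots: Sequence[float] | None = None,
              boundary_knots: tuple[float, float] | None = None,
              ) -> tuple[np.ndarray, NcsBasis]:
    """Design matrix of the natural cubic spline at the points ``x``.

    Defaults follow the analysis convention: one internal knot at the
    empirical median of ``x`` and boundary knots at the observed extremes.
    Returns ``(matrix, basis)``.
    """
    x = np.asarray(x, dtype=float)
    if boundary_knots is None:
        boundary_knots = (float(x.min()), float(x.max()))
    if internal_knots is None:
        internal_knots = (float(np.median(x)),)
    basis = NcsBasis(internal_knots=tuple(float(k) for k in internal_knots),
                     boundary_knots=boundary_knots)
    return basis.design(x), basis


@dataclass
class SplineFitResult:
    """Maximum-likelihood fit of the location-scale spline model."""

    beta: np.ndarray
    gamma: np.ndarray
    basis: NcsBasis
    loglik: float
    loglik_init: float
    converged: bool
    n: int
    n_iter: int
    homoskedastic: bool = False

    def mu(self, s: Sequence[float] | np.ndarray) -> np.ndarray:
        """Fitted conditional mean at SPQ values ``s``."""
        return self.basis.design(s) @ self.beta

    def log_var(self, s: Sequence[float] | np.ndarray) -> np.ndarray:
        B = self.basis.design(s)
        if self.homoskedastic:
            return np.full(B.shape[0], self.gamma[0])
        return B @ self.gamma

    def sigma(self, s: Sequence[float] | np.ndarray) -> np.ndarray:
        """Fitted conditional SD at SPQ values ``s`` (always positive)."""
        return np.exp(0.5 * self.log_var(s))


def _neg_loglik_and_grad(theta: np.ndarray, B: np.ndarray, y: np.ndarray,
                         p: int, q: int) -> tuple[float, np.ndarray]:
    beta, gamma = theta[:p], theta[p:]
    mu = B @ beta
    # clip the log-variance to keep line-search probes finite
    g = np.clip(B[:, :q] @ gamma, -60.0, 60.0)
    r = y - mu
    inv_v = np.exp(-g)
    nll = 0.5 * np.sum(np.log(2 * np.pi) + g + r * r * inv_v)
    grad_beta = -(B.T @ (r * inv_v))
    grad_gamma = -0.5 * (B[:, :q].T @ (r * r * inv_v - 1.0))
    return float(nll), np.r_[grad_beta, grad_gamma]


def fit_hetero_spline(spq: Sequence[float] | np.ndarray,
                      y: Sequence[float] | np.ndarray,
                      internal_knots: Sequence[float] | None = None,
                      homoskedastic: bool = False,
                      max_iter: int = 500) -> SplineFitResult:
    """Jointly fit the spline mean and log-variance by maximum likelihood.

    Initialization is deterministic: beta from ordinary least squares on
    the mean basis, the gamma intercept from the log OLS residual
    variance (ML denominator) and remaining gamma entries zero; the
    optimizer can therefore only improve on the homoskedastic
    least-squares log-likelihood.  With ``homoskedastic=True`` the
    log-variance is restricted to a constant, which reduces the mean fit
    to ordinary least squares.
    """
    s = np.asarray(spq, dtype=float)
    y = np.asarray(y, dtype=float)
    if s.shape != y.shape or s.ndim != 1:
        raise ValueError("spq and y must be one-dimensional arrays of equal length")
    if len(s) < 10:
        raise ValueError(f"need >= 10 observations, got {len(s)}")
    if np.unique(s).size < 3:
        raise ValueError("rank-deficient spline basis: need >= 3 distinct SPQ values")

    B_raw, basis = ncs_basis(s, internal_knots=internal_knots)
    if np.linalg.matrix_rank(B_raw) < B_raw.shape[1]:
        raise ValueError(
            f"rank-deficient spline basis: need >= {B_raw.shape[1]} distinct "
            "SPQ values")
    p = B_raw.shape[1]
    q = 1 if homoskedastic else p
    # precondition: the curvature columns span hundreds of cubic units,
    # which ruins quasi-Newton conditioning; fit in column-scaled units
    scale = np.maximum(np.abs(B_raw).max(axis=0), 1.0)
    B = B_raw / scale

    beta0, *_ = np.linalg.lstsq(B, y, rcond=None)
    resid = y - B @ beta0
    var0 = max(float(np.mean(resid**2)), 1e-10)
    theta0 = np.r_[beta0, np.log(var0), np.zeros(q - 1)]
    nll0, _ = _neg_loglik_and_grad(theta0, B, y, p, q)

    res = optimize.minimize(
        _neg_loglik_and_grad, theta0, args=(B, y, p, q), jac=True,
        method="L-BFGS-B",
        options={"maxiter": max_iter, "ftol": 1e-14, "gtol": 1e-8},
    )
    nll, grad = _neg_loglik_and_grad(res.x, B, y, p, q)
    if nll > nll0:  # optimizer must never end below its start
        res.x, nll = theta0, nll0
    converged = bool(res.success) and np.max(np.abs(grad)) < 1e-4 * max(1.0, nll)
    return SplineFitResult(
        beta=res.x[:p] / scale, gamma=res.x[p:] / scale[:q], basis=basis,
        loglik=-nll, loglik_init=-nll0, converged=converged,
        n=len(y), n_iter=int(res.nit), homoskedastic=homoskedastic,
    )


def predict_bands(fit: SplineFitResult,
                  grid: Sequence[float] | np.ndarray) -> pd.DataFrame:
    """Normal-quantile display bands of the fitted model on an SPQ grid.

    Columns: ``spq, mean, q1, q3, d1, d9, extrapolated``; the quartile
    band is mean -+ 0.6745 sigma and the decile band mean -+ 1.2816
    sigma.  Grid points outside the boundary knots use the spline's
    linear extrapolation and are flagged.
    """
    grid = np.asarray(grid, dtype=float)
    mu = fit.mu(grid)
    sd = fit.sigma(grid)
    lo, hi = fit.basis.boundary_knots
    return pd.DataFrame({
        "spq": grid,
        "mean": mu,
        "q1": mu - Z_QUARTILE * sd,
        "q3": mu + Z_QUARTILE * sd,
        "d1": mu - Z_DECILE * sd,
        "d9": mu + Z_DECILE * sd,
        "extrapolated": (grid < lo) | (grid > hi),
    })
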