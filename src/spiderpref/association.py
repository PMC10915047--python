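"""Association analysis: Spearman correlation matrix and power utility.

The correlation matrix relates the spider-fear score (SPQ) and the six
summarized preference variables (three features x two instructions)
pairwise through Spearman's rank correlation with average-rank tie
handling; two-sided p-values use the t approximation on n - 2 degrees of
freedom.  No multiple-testing correction is applied: the matrix reports
raw p-values.

``correlation_power`` verifies sample-size statements of the form "if the
true correlation is rho, the test of zero correlation rejects with power
1 - beta at level alpha" by Monte-Carlo simulation of bivariate-normal
samples, cross-checked against the Fisher-z closed form.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["CorrelationMatrix", "spearman_matrix", "PowerEstimate", "correlation_power",
           "fisher_z_power"]


@dataclass
class CorrelationMatrix:
    """Pairwise Spearman coefficients and two-sided p-values."""

    variables: list[str]
    rho: pd.DataFrame
    p: pd.DataFrame
    n: int

    def to_long(self) -> pd.DataFrame:
        """Long format (var1, var2, rho, p, n) over the upper triangle."""
        rows = []
        for i, a in enumerate(self.variables):
            for b in self.variables[i + 1:]:
                rows.append({"var1": a, "var2": b,
                             "rho": self.rho.loc[a, b], "p": self.p.loc[a, b],
                             "n": self.n})
        return pd.DataFrame(rows)


def spearman_matrix(table: pd.DataFrame) -> CorrelationMatrix:
    """Spearman correlation matrix of every column pair of ``table``.

    Rows with any missing value are dropped (listwise completion);
    at least 4 complete rows are required.  A constant column has no
    defined rank correlation: its off-diagonal entries are reported as
    NaN with a warning.
    """
    data = table.dropna()
    n = len(data)
    if n < 4:
        raise ValueError(f"need >= 4 complete rows, got {n}")
    variables = list(data.columns)
    values = data.to_numpy(dtype=float)

    constant = [v for v, col in zip(variables, values.T) if np.ptp(col) == 0]
    if constant:
        warnings.warn(f"constant column(s) {constant}: correlations undefined, "
                      "reported as NaN", stacklevel=2)

    with np.errstate(invalid="ignore"):
        rho, p = stats.spearmanr(values, axis=0)
    if np.ndim(rho) == 0:  # scipy collapses the two-column case to a scalar
        rho = np.array([[1.0, rho], [rho, 1.0]])
        p = np.array([[1.0, p], [p, 1.0]])
    np.fill_diagonal(rho, 1.0)
    np.fill_diagonal(p, 1.0)

    rho_df = pd.DataFrame(rho, index=variables, columns=variables)
    p_df = pd.DataFrame(p, index=variables, columns=variables)
    return CorrelationMatrix(variables=variables, rho=rho_df, p=p_df, n=n)


@dataclass
class PowerEstimate:
    """Monte-Carlo power with standard error and the analytic cross-check."""

    power: float
    se: float
    analytic: float
    reps: int
    n: int
    rho_true: float
    alpha: float


def fisher_z_power(rho_true: float, n: int, alpha: float = 0.05) -> float:
    """Closed-form power of the two-sided correlation test (Fisher z).

    The sample Fisher transform atanh(r) is approximately normal with
    mean atanh(rho) and SD 1/sqrt(n - 3).
    """
    z_crit = stats.norm.ppf(1 - alpha / 2)
    shift = np.arctanh(rho_true) * np.sqrt(n - 3)
    return float(stats.norm.cdf(shift - z_crit) + stats.norm.cdf(-shift - z_crit))


def correlation_power(rho_true: float, n: int, alpha: float = 0.05,
                      reps: int = 20_000, seed: int = 0,
                      method: str = "pearson") -> PowerEstimate:
    """Monte-Carlo power of the two-sided test of zero correlation.

    Simulates ``reps`` bivariate-normal samples of size ``n`` with true
    correlation ``rho_true`` and counts rejections of H0: rho = 0 at
    level ``alpha``.  ``method`` selects the test statistic: ``pearson``
    (the conventional reading of a sample-size statement) or
    ``spearman``.
    """
    if not -1.0 < rho_true < 1.0:
        raise ValueError("rho_true must lie strictly inside (-1, 1)")
    if n < 4:
        raise ValueError("n must be >= 4")
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    x = rng.standard_normal((reps, n))
    e = rng.standard_normal((reps, n))
    y = rho_true * x + np.sqrt(1 - rho_true**2) * e

    if method == "pearson":
        xc = x - x.mean(axis=1, keepdims=True)
        yc = y - y.mean(axis=1, keepdims=True)
        r = (xc * yc).sum(axis=1) / np.sqrt((xc**2).sum(axis=1) * (yc**2).sum(axis=1))
    elif method == "spearman":
        rx = stats.rankdata(x, axis=1)
        ry = stats.rankdata(y, axis=1)
        rxc = rx - rx.mean(axis=1, keepdims=True)
        ryc = ry - ry.mean(axis=1, keepdims=True)
        r = (rxc * ryc).sum(axis=1) / np.sqrt(
            (rxc**2).sum(axis=1) * (ryc**2).sum(axis=1))
    else:
        raise ValueError(f"unknown method {method!r}")

    # two-sided p from the t approximation on n - 2 df
    with np.errstate(divide="ignore"):
        t = r * np.sqrt((n - 2) / (1 - r**2))
    pvals = 2 * stats.t.sf(np.abs(t), df=n - 2)
    power = float(np.mean(pvals < alpha))
    se = float(np.sqrt(power * (1 - power) / reps))
    return PowerEstimate(power=power, se=se,
                         analytic=fisher_z_power(rho_true, n, alpha),
                         reps=reps, n=n, rho_true=rho_true, alpha=alpha)
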