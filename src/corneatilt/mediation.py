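"""Pearson correlation and simple mediation analysis.

A simple mediation model proposes that an antecedent variable X influences
an outcome Y through a single intervening variable M.  Ordinary least
squares gives the paths

* ``a``  — slope of M on X,
* ``b``  — slope of Y on M adjusting for X,
* ``c``  — total slope of Y on X,
* ``c'`` — direct slope of Y on X adjusting for M,

with the exact in-sample identity ``c = c' + a*b``.  The indirect
(mediated) effect is ``a*b``; its inference uses a seeded percentile
bootstrap over jointly resampled rows, the practice of modern mediation
macros, with the Sobel z statistic reported as a diagnostic only.  Percent
direct and percent mediated are ``100*c'/c`` and ``100*a*b/c``; by the OLS
identity they sum to 100 whenever ``c != 0``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "MediationResult",
    "StandardizedPaths",
    "pearson",
    "simple_mediation",
    "mediation_from_correlations",
    "normality_check",
]


def pearson(x, y) -> tuple[float, float]:
    """Product-moment correlation with its two-sided p-value.

    The p-value comes from the t transform with n - 2 degrees of freedom.
    Requires equal lengths of at least 3 and non-zero variances.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("inputs must be equal-length 1D vectors")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance input")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


@dataclass
class MediationResult:
    """Paths and inference for one simple-mediation case."""

    case: str
    a: float
    b: float
    c: float
    c_prime: float
    indirect: float
    percent_direct: float | None
    percent_mediated: float | None
    ci_level: float
    ci_lower: float
    ci_upper: float
    p_a: float
    p_b: float
    p_c: float
    p_c_prime: float
    sobel_z: float
    sobel_p: float
    n_boot: int
    seed: int
    n: int

    @property
    def indirect_significant(self) -> bool:
        """The mediated effect exists iff its bootstrap CI excludes zero."""
        return not (self.ci_lower <= 0.0 <= self.ci_upper)

    def to_json_dict(self) -> dict:
        return {
            "case": self.case,
            "n": self.n,
            "a": self.a,
            "b": self.b,
            "c": self.c,
            "c_prime": self.c_prime,
            "indirect": self.indirect,
            "percent_direct": self.percent_direct,
            "percent_mediated": self.percent_mediated,
            "ci_level": self.ci_level,
            "ci": [self.ci_lower, self.ci_upper],
            "indirect_significant": self.indirect_significant,
            "p_values": {
                "a": self.p_a,
                "b": self.p_b,
                "c": self.p_c,
                "c_prime": self.p_c_prime,
            },
            "sobel": {"z": self.sobel_z, "p": self.sobel_p},
            "n_boot": self.n_boot,
            "seed": self.seed,
        }

    def report(self) -> str:
        pd_s = "undefined" if self.percent_direct is None else f"{self.percent_direct:.1f}%"
        pm_s = "undefined" if self.percent_mediated is None else f"{self.percent_mediated:.1f}%"
        sig = "significant" if self.indirect_significant else "not significant"
        return (
            f"Mediation case: {self.case} (n={self.n})\n"
            f"  a = {self.a:.4f} (p={self.p_a:.3g}), b = {self.b:.4f} (p={self.p_b:.3g})\n"
            f"  total c = {self.c:.4f} (p={self.p_c:.3g}), "
            f"direct c' = {self.c_prime:.4f} (p={self.p_c_prime:.3g})\n"
            f"  indirect a*b = {self.indirect:.4f}, "
            f"{100 * self.ci_level:.0f}% bootstrap CI "
            f"[{self.ci_lower:.4f}, {self.ci_upper:.4f}] ({sig})\n"
            f"  percent direct = {pd_s}, percent mediated = {pm_s}\n"
        )


def simple_mediation(
    x,
    m,
    y,
    n_boot: int = 5000,
    ci_level: float = 0.95,
    seed: int = 0,
    standardize: bool = False,
    case: str = "X -> M -> Y",
) -> MediationResult:
    """Simple mediation of X on Y through M with bootstrap inference.

    All regressions include intercepts; variables are used on their raw
    scales unless ``standardize`` is set.  The percentile bootstrap
    resamples rows jointly ``n_boot`` times with a seeded generator, so
    results are reproducible.  When the total effect c is zero the percent
    shares are reported as None rather than propagating NaN.
    """
    x = np.asarray(x, dtype=float)
    m = np.asarray(m, dtype=float)
    y = np.asarray(y, dtype=float)
    if not (x.shape == m.shape == y.shape) or x.ndim != 1:
        raise ValueError("X, M, Y must be equal-length 1D vectors")
    n = x.size
    if n < 5:
        raise ValueError("need at least 5 observations")
    r_xm = np.corrcoef(x, m)[0, 1]
    if abs(r_xm) > 1.0 - 1e-12:
        raise ValueError("X and M are collinear; mediation paths are undefined")
    if standardize:
        x = (x - x.mean()) / x.std(ddof=1)
        m = (m - m.mean()) / m.std(ddof=1)
        y = (y - y.mean()) / y.std(ddof=1)

    # point estimates and path p-values via OLS t-tests
    fit_a = sm.OLS(m, sm.add_constant(x)).fit()
    fit_c = sm.OLS(y, sm.add_constant(x)).fit()
    fit_bc = sm.OLS(y, sm.add_constant(np.column_stack([x, m]))).fit()
    a = float(fit_a.params[1])
    c = float(fit_c.params[1])
    c_prime = float(fit_bc.params[1])
    b = float(fit_bc.params[2])
    indirect = a * b
    se_a = float(fit_a.bse[1])
    se_b = float(fit_bc.bse[2])
    sobel_se = math.sqrt(b**2 * se_a**2 + a**2 * se_b**2)
    sobel_z = indirect / sobel_se if sobel_se > 0 else float("nan")
    sobel_p = 2.0 * stats.norm.sf(abs(sobel_z)) if np.isfinite(sobel_z) else float("nan")

    # percentile bootstrap of a*b over jointly resampled rows
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n, size=(n_boot, n))
    boot = _bootstrap_indirect(x, m, y, idx)
    alpha = 1.0 - ci_level
    lo, hi = np.quantile(boot, [alpha / 2.0, 1.0 - alpha / 2.0])

    if c == 0.0:
        pct_direct = pct_mediated = None
    else:
        pct_direct = 100.0 * c_prime / c
        pct_mediated = 100.0 * indirect / c
    return MediationResult(
        case=case,
        a=a,
        b=b,
        c=c,
        c_prime=c_prime,
        indirect=indirect,
        percent_direct=pct_direct,
        percent_mediated=pct_mediated,
        ci_level=ci_level,
        ci_lower=float(lo),
        ci_upper=float(hi),
        p_a=float(fit_a.pvalues[1]),
        p_b=float(fit_bc.pvalues[2]),
        p_c=float(fit_c.pvalues[1]),
        p_c_prime=float(fit_bc.pvalues[1]),
        sobel_z=float(sobel_z),
        sobel_p=float(sobel_p),
        n_boot=n_boot,
        seed=seed,
        n=n,
    )


def _bootstrap_indirect(x, m, y, idx) -> np.ndarray:
    """Vectorised a*b over bootstrap index matrix idx (n_boot, n)."""
    xb, mb, yb = x[idx], m[idx], y[idx]
    n = x.size

    def cov(u, v):
        um = u.mean(axis=1, keepdims=True)
        vm = v.mean(axis=1, keepdims=True)
        return ((u - um) * (v - vm)).sum(axis=1) / (n - 1)

    sxx, sxm, smm = cov(xb, xb), cov(xb, mb), cov(mb, mb)
    sxy, smy = cov(xb, yb), cov(mb, yb)
    det = sxx * smm - sxm * sxm
    with np.errstate(divide="ignore", invalid="ignore"):
        a = sxm / sxx
        b = (sxx * smy - sxm * sxy) / det
        ab = a * b
    return ab[np.isfinite(ab)]


@dataclass(frozen=True)
class StandardizedPaths:
    """Mediation paths computed directly from a correlation matrix."""

    a: float
    b: float
    c: float
    c_prime: float
    indirect: float
    percent_direct: float | None
    percent_mediated: float | None


def mediation_from_correlations(
    r_xm: float, r_xy: float, r_my: float
) -> StandardizedPaths:
    """Standardised mediation paths from pairwise correlations.

    For standardised variables the paths have the closed forms::

        a  = r_xm
        b  = (r_my - r_xy * r_xm) / (1 - r_xm^2)
        c' = (r_xy - r_my * r_xm) / (1 - r_xm^2)
        c  = r_xy

    and the identity ``c = c' + a*b`` holds algebraically.  The implied
    3x3 correlation matrix must be positive semi-definite and |r_xm| < 1.
    """
    for r in (r_xm, r_xy, r_my):
        if abs(r) > 1.0:
            raise ValueError("correlation magnitudes must not exceed 1")
    if abs(abs(r_xm) - 1.0) < 1e-15:
        raise ValueError("|r_xm| = 1: X and M are collinear")
    corr = np.array([[1.0, r_xm, r_xy], [r_xm, 1.0, r_my], [r_xy, r_my, 1.0]])
    if np.linalg.eigvalsh(corr).min() < -1e-10:
        raise ValueError("implied correlation matrix is not positive semi-definite")
    denom = 1.0 - r_xm**2
    a = r_xm
    b = (r_my - r_xy * r_xm) / denom
    c_prime = (r_xy - r_my * r_xm) / denom
    c = r_xy
    indirect = a * b
    if c == 0.0:
        pct_direct = pct_mediated = None
    else:
        pct_direct = 100.0 * c_prime / c
        pct_mediated = 100.0 * indirect / c
    return StandardizedPaths(a, b, c, c_prime, indirect, pct_direct, pct_mediated)


def normality_check(values) -> tuple[float, float]:
    """Shapiro-Wilk normality test (statistic, p).

    Delegates to the standard routine; valid for 3 <= n <= 5000 and
    rejects constant input.
    """
    v = np.asarray(values, dtype=float)
    if v.ndim != 1 or not 3 <= v.size <= 5000:
        raise ValueError("Shapiro-Wilk requires a 1D sample with 3 <= n <= 5000")
    if np.ptp(v) == 0:
        raise ValueError("zero-variance sample")
    res = stats.shapiro(v)
    return float(res.statistic), float(res.pvalue)
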