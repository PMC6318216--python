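"""Residual diagnostics and the zero-intercept test behind the RTO choice.

Forcing the regression through the origin is only safe when the data admit a
zero intercept: a nonzero true intercept makes the no-intercept slope badly
biased.  ``intercept_zero_test`` fits the unconstrained two-parameter line
W = α + βV + ε and tests H0: α = 0 with a t statistic on n − 2 degrees of
freedom.  Shapiro–Wilk and normal Q–Q points cover the normality checks that
gate the least-squares fit; confidence intervals use the t(n − 2) critical
value for every method.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.stats as st
import statsmodels.api as sm

from .model import BcefResults


@dataclass(frozen=True)
class NormalityReport:
    w_stat: float
    p_value: float
    n: int
    target: str = "sample"


@dataclass(frozen=True)
class InterceptTest:
    alpha_hat: float
    beta_hat: float
    se_alpha: float
    t_stat: float
    p_value: float
    df: int


def shapiro_wilk(x, target: str = "sample") -> NormalityReport:
    """Shapiro–Wilk normality test (scipy backend)."""
    x = np.asarray(x, dtype=float)
    if x.size < 3 or x.size > 5000:
        raise ValueError(f"Shapiro–Wilk needs 3 <= n <= 5000, got n={x.size}")
    stat, p = st.shapiro(x)
    return NormalityReport(w_stat=float(stat), p_value=float(p), n=int(x.size), target=target)


def qq_points(x) -> np.ndarray:
    """Normal Q–Q data points, no rendering.

    Returns an (n, 2) array pairing the theoretical standard-normal quantile
    at plotting position (i − 0.5)/n with the i-th order statistic.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    if n < 2:
        raise ValueError("Q–Q points need n >= 2")
    probs = (np.arange(1, n + 1) - 0.5) / n
    return np.column_stack([st.norm.ppf(probs), np.sort(x)])


def intercept_zero_test(W, V) -> InterceptTest:
    """Test H0: α = 0 in the ordinary regression W = α + βV + ε."""
    W = np.asarray(W, dtype=float)
    V = np.asarray(V, dtype=float)
    n = W.size
    if n < 3:
        raise ValueError("intercept test needs n >= 3")
    if np.ptp(V) == 0:
        raise ValueError("volume is constant; the intercept is not identifiable")
    res = sm.OLS(W, sm.add_constant(V)).fit()
    degenerate = res.ssr <= 1e-20 * float(np.sum(W**2))
    if degenerate or not np.isfinite(res.bse[0]) or res.bse[0] == 0:
        raise ValueError("zero residual variance; the t statistic is undefined")
    t = float(res.params[0] / res.bse[0])
    df = n - 2
    p = float(2.0 * st.t.sf(abs(t), df))
    return InterceptTest(
        alpha_hat=float(res.params[0]),
        beta_hat=float(res.params[1]),
        se_alpha=float(res.bse[0]),
        t_stat=t,
        p_value=p,
        df=df,
    )


def confidence_interval(fit: BcefResults, level: float = 0.95) -> tuple[float, float]:
    """BCEF confidence interval, half-width t(level, n − 2) × SE.

    The n − 2 degrees of freedom are used for every method, including the
    one-parameter RTO where n − 1 would be the orthodox choice; the slightly
    wider interval is deliberate and documented.
    """
    if fit.nobs < 3:
        raise ValueError("confidence interval needs n >= 3 (df = n - 2 >= 1)")
    if fit.se == 0:
        return (fit.estimate, fit.estimate)
    tcrit = st.t.ppf(0.5 + level / 2.0, fit.nobs - 2)
    half = tcrit * fit.se
    return (fit.estimate - half, fit.estimate + half)


def ci_significant(fit: BcefResults, level: float = 0.95) -> bool:
    """True when the CI excludes zero (the BCEF is distinguishable from 0)."""
    lo, hi = confidence_interval(fit, level=level)
    return lo > 0 or hi < 0
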