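"""Biomass conversion and expansion factor (BCEF) estimators.

A BCEF is the slope of the no-intercept regression

    Ŵ = BCEF · V

of tree-component dry biomass W (Mg) on stem volume V (m³).  In inventory
practice the slope is usually taken as a ratio of observed biomass to
volume; here that convention sits side by side with the least-squares slope
of the regression through the origin (RTO), so the two can be compared on
equal terms.

Four fitting methods are exposed through :class:`BcefModel`:

``ratio_mean_of_ratios``
    mean of the per-tree ratios Wᵢ/Vᵢ;
``ratio_ratio_of_means``
    ΣW/ΣV, the classical ratio-of-totals estimator;
``ls_rto``
    the least-squares RTO slope Σ WᵢVᵢ / Σ Vᵢ²;
``glm_rto``
    a no-intercept generalized linear model (default Gamma family with
    identity link) for positive, right-skewed biomass whose RTO residuals
    fail a normality check.

Each of the first three is a one-parameter *linear smoother*: fitted values
are Ŵ = H W for a hat matrix H whose diagonal has a closed form, which is
what makes the leave-one-out prediction error (PRESS) computable without
refitting (see :mod:`bcef.metrics`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd
import scipy.stats as st
import statsmodels.api as sm

RATIO_VARIANTS = ("mean_of_ratios", "ratio_of_means")
METHODS = ("ratio_mean_of_ratios", "ratio_ratio_of_means", "ls_rto", "glm_rto")


def _as_arrays(W, V) -> tuple[np.ndarray, np.ndarray]:
    W = np.asarray(W, dtype=float)
    V = np.asarray(V, dtype=float)
    if W.ndim != 1 or V.ndim != 1 or W.shape != V.shape:
        raise ValueError("W and V must be one-dimensional arrays of equal length")
    if not (np.isfinite(W).all() and np.isfinite(V).all()):
        raise ValueError("W and V must be finite")
    return W, V


def hat_diagonal(V, method: str) -> np.ndarray:
    """Leverages H_ii of the three linear BCEF smoothers.

    ls_rto: H_ii = Vᵢ²/ΣV²;  mean_of_ratios: H_ii = 1/n;
    ratio_of_means: H_ii = Vᵢ/ΣV.  Each sums to 1 (one fitted parameter).
    """
    V = np.asarray(V, dtype=float)
    n = V.size
    if method == "ls_rto":
        return V**2 / np.sum(V**2)
    if method == "ratio_mean_of_ratios":
        return np.full(n, 1.0 / n)
    if method == "ratio_ratio_of_means":
        return V / np.sum(V)
    raise ValueError(f"no hat-diagonal closed form for method {method!r}")


@dataclass
class BcefResults:
    """A fitted BCEF and the pieces downstream scoring needs.

    ``estimate`` is the BCEF in Mg m⁻³ (the slope through the origin),
    ``se`` its standard error on the same scale.  ``resid`` are
    eᵢ = Wᵢ − BCEF·Vᵢ (Mg) and ``hat_diag`` the leverages of the fit's
    linear-smoother form.
    """

    method: str
    estimate: float
    se: float
    nobs: int
    W: np.ndarray = field(repr=False)
    V: np.ndarray = field(repr=False)
    component: str | None = None
    species: str | None = None
    gate: dict[str, Any] | None = None

    @property
    def se_pct(self) -> float:
        return 100.0 * self.se / self.estimate if self.estimate != 0 else np.inf

    @property
    def fittedvalues(self) -> np.ndarray:
        return self.estimate * self.V

    @property
    def resid(self) -> np.ndarray:
        return self.W - self.fittedvalues

    @property
    def hat_diag(self) -> np.ndarray:
        if self.method == "glm_rto":
            # IRLS-weighted projection; for Gamma the working weights are 1/μ².
            mu = self.fittedvalues
            w = 1.0 / mu**2
            return w * self.V**2 / np.sum(w * self.V**2)
        return hat_diagonal(self.V, self.method)

    def predict(self, V) -> np.ndarray:
        return self.estimate * np.asarray(V, dtype=float)

    def conf_int(self, level: float = 0.95) -> tuple[float, float]:
        """Two-sided CI, half-width t(level, n−2) × SE."""
        from .diagnostics import confidence_interval

        return confidence_interval(self, level=level)

    def metrics(self, k: int = 10, seed: int | None = 0, cost: str = "rmspe"):
        from .metrics import score_fit

        return score_fit(self, k=k, seed=seed, cost=cost)

    def summary(self) -> str:
        lo, hi = self.conf_int()
        lines = [
            "BCEF fit",
            "=" * 44,
            f"method:        {self.method}",
            f"species:       {self.species or '-'}",
            f"component:     {self.component or '-'}",
            f"n:             {self.nobs}",
            f"BCEF [Mg/m3]:  {self.estimate:.4f}",
            f"SE [Mg/m3]:    {self.se:.4f}  ({self.se_pct:.1f}%)",
            f"95% CI:        ({lo:.4f}, {hi:.4f})",
        ]
        if self.gate:
            lines.append(f"normality gate: {self.gate}")
        return "\n".join(lines)


class BcefModel:
    """No-intercept biomass-on-volume model, statsmodels-style.

    Parameters
    ----------
    W : array-like
        Component dry biomass per tree, Mg.
    V : array-like
        Stem volume per tree, m³.
    """

    def __init__(self, W, V, component: str | None = None, species: str | None = None):
        self.W, self.V = _as_arrays(W, V)
        self.component = component
        self.species = species
        self.nobs = self.W.size

    @classmethod
    def from_dataset(cls, dataset, component: str, species: str | None = None) -> "BcefModel":
        W, V = dataset.component_arrays(component, species=species)
        return cls(W, V, component=component, species=species)

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        biomass_col: str = "W_Mg",
        volume_col: str = "V_m3",
        component: str | None = None,
        species: str | None = None,
    ) -> "BcefModel":
        sub = df
        if species is not None and "species" in df.columns:
            sub = sub[sub["species"] == species]
        if component is not None and "component" in df.columns:
            sub = sub[sub["component"] == component]
        return cls(
            sub[biomass_col].to_numpy(dtype=float),
            sub[volume_col].to_numpy(dtype=float),
            component=component,
            species=species,
        )

    # -- fitting -----------------------------------------------------------

    def fit(self, method: str = "ls_rto", **kwargs) -> BcefResults:
        if method == "ls_rto":
            return self._fit_ls()
        if method in ("ratio_mean_of_ratios", "ratio_ratio_of_means"):
            return self._fit_ratio(method.removeprefix("ratio_"))
        if method == "glm_rto":
            return self._fit_glm(**kwargs)
        if method == "auto":
            return self.fit_auto(**kwargs)
        raise ValueError(f"unknown method {method!r}; expected one of {METHODS + ('auto',)}")

    def _result(self, method: str, estimate: float, se: float, gate=None) -> BcefResults:
        return BcefResults(
            method=method,
            estimate=float(estimate),
            se=float(se),
            nobs=self.nobs,
            W=self.W,
            V=self.V,
            component=self.component,
            species=self.species,
            gate=gate,
        )

    def _fit_ls(self) -> BcefResults:
        if self.nobs < 2:
            raise ValueError("least-squares RTO needs n >= 2")
        ssv = float(np.sum(self.V**2))
        if ssv == 0:
            raise ValueError("all volumes are zero; slope undefined")
        b = float(np.sum(self.W * self.V) / ssv)
        resid = self.W - b * self.V
        # one mean parameter -> n-1 residual degrees of freedom
        sigma2 = float(np.sum(resid**2) / (self.nobs - 1))
        se = float(np.sqrt(sigma2 / ssv))
        return self._result("ls_rto", b, se)

    def _fit_ratio(self, variant: str = "mean_of_ratios") -> BcefResults:
        if variant not in RATIO_VARIANTS:
            raise ValueError(f"unknown ratio variant {variant!r}")
        if self.nobs < 2:
            raise ValueError("ratio estimator needs n >= 2 for a standard error")
        if np.any(self.V <= 0):
            raise ValueError("ratio estimators require all volumes > 0")
        if variant == "mean_of_ratios":
            r = self.W / self.V
            est = float(np.mean(r))
            se = float(np.std(r, ddof=1) / np.sqrt(self.nobs))
        else:
            est = float(np.sum(self.W) / np.sum(self.V))
            vbar = float(np.mean(self.V))
            s2 = float(np.sum((self.W - est * self.V) ** 2) / (self.nobs - 1))
            se = float(np.sqrt(s2 / (self.nobs * vbar**2)))
        return self._result(f"ratio_{variant}", est, se)

    def _fit_glm(
        self,
        family: str = "gamma",
        link: str = "identity",
        max_iter: int = 200,
    ) -> BcefResults:
        if self.nobs < 3:
            raise ValueError("GLM fit needs n >= 3")
        if family == "gamma" and np.any(self.W <= 0):
            raise ValueError("Gamma GLM requires strictly positive biomass")
        links = {"identity": sm.families.links.Identity(), "log": sm.families.links.Log()}
        fams = {
            "gamma": sm.families.Gamma,
            "inverse_gaussian": sm.families.InverseGaussian,
            "gaussian": sm.families.Gaussian,
        }
        if family not in fams or link not in links:
            raise ValueError(f"unsupported GLM family/link {family}/{link}")
        import warnings

        from statsmodels.tools.sm_exceptions import DomainWarning

        with warnings.catch_warnings():
            # identity link on Gamma is a deliberate choice (keeps the
            # proportional interpretation); statsmodels warns about it
            warnings.simplefilter("ignore", DomainWarning)
            glm = sm.GLM(self.W, self.V[:, None], family=fams[family](link=links[link]))
        res = glm.fit(maxiter=max_iter)
        if not getattr(res, "converged", True):
            raise RuntimeError(
                f"GLM ({family}/{link}) did not converge in {max_iter} iterations; "
                f"fit history: {getattr(res, 'fit_history', None)}"
            )
        return self._result("glm_rto", res.params[0], res.bse[0])

    def fit_auto(
        self,
        alpha_level: float = 0.05,
        gate_on: str = "rto",
        **glm_kwargs,
    ) -> BcefResults:
        """Normality-gated fit: least squares, or a GLM when residuals are skewed.

        The RTO is fitted first and its residuals tested with Shapiro–Wilk
        (``gate_on="ols"`` instead tests the residuals of the two-parameter
        ordinary regression).  When the test rejects at ``alpha_level`` and a
        Gamma GLM is admissible (all W > 0), the GLM refit is returned.
        """
        if self.nobs < 3:
            raise ValueError("the normality gate needs n >= 3")
        ls = self._fit_ls()
        if np.allclose(ls.resid, 0.0, atol=1e-12):
            # exact proportionality: nothing to diagnose, no dispersion to model
            ls.gate = {"test": "shapiro_wilk", "decision": "ls_rto (exact fit)"}
            return ls
        if gate_on == "ols":
            X = sm.add_constant(self.V)
            resid = sm.OLS(self.W, X).fit().resid
        else:
            resid = ls.resid
        sw_stat, sw_p = st.shapiro(resid)
        gate = {
            "test": "shapiro_wilk",
            "on": f"{gate_on}_residuals",
            "w": float(sw_stat),
            "p": float(sw_p),
            "alpha": alpha_level,
        }
        if sw_p < alpha_level and np.all(self.W > 0):
            gate["decision"] = "glm_rto"
            out = self._fit_glm(**glm_kwargs)
            out.gate = gate
            return out
        gate["decision"] = "ls_rto" if sw_p >= alpha_level else "ls_rto (GLM inadmissible: W <= 0)"
        ls.gate = gate
        return ls


# -- functional wrappers (thin veneers over BcefModel) ------------------------


def ratio_bcef(W, V, variant: str = "mean_of_ratios") -> BcefResults:
    """Ratio-based BCEF: mean of per-tree ratios, or ratio of totals."""
    return BcefModel(W, V).fit(f"ratio_{variant}")


def ls_rto_bcef(W, V) -> BcefResults:
    """Least-squares slope of the regression through the origin."""
    return BcefModel(W, V).fit("ls_rto")


def glm_rto_bcef(W, V, family: str = "gamma", link: str = "identity", max_iter: int = 200) -> BcefResults:
    """No-intercept GLM slope (default Gamma family, identity link)."""
    return BcefModel(W, V).fit("glm_rto", family=family, link=link, max_iter=max_iter)


def fit_bcef_auto(W, V, alpha_level: float = 0.05, **kwargs) -> BcefResults:
    """Shapiro–Wilk-gated choice between the LS RTO fit and the GLM."""
    return BcefModel(W, V).fit_auto(alpha_level=alpha_level, **kwargs)
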