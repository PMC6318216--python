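"""Predictive accuracy and ability scores for BCEF fits.

Accuracy is scored in-sample: Akaike information criterion (model
misspecification), SE% of the slope (parameter uncertainty), coefficient of
variation of the residuals and Furnival's index (residual variability).
Ability is scored out-of-sample: the mean quadratic error of prediction

    MEP = (1/n) Σ eᵢ² / (1 − Hᵢᵢ)²

which for a linear smoother equals the mean of squared leave-one-out
prediction errors (PRESS/n) without any refitting, and the model prediction
error MPE, the root-mean-square held-out error from K-fold cross-validation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import BcefModel, BcefResults, hat_diagonal

__all__ = [
    "FitMetrics",
    "aic_gaussian",
    "cvr",
    "furnival_index",
    "mep",
    "hat_diagonal",
    "kfold_mpe",
    "score_fit",
]


def aic_gaussian(residuals, k_params: int) -> float:
    """AIC under the full Gaussian likelihood, σ̂² = RSS/n.

    AIC = n·ln(2π σ̂²) + n + 2k.  ``k_params`` counts the mean parameters
    plus one variance parameter, so a one-slope BCEF fit has k = 2.  A
    perfect fit (RSS = 0) has no finite AIC under this convention.
    """
    e = np.asarray(residuals, dtype=float)
    n = e.size
    if n <= k_params:
        raise ValueError(f"AIC needs n > k_params ({n} <= {k_params})")
    rss = float(np.sum(e**2))
    if rss <= 0:
        raise ValueError("RSS = 0: AIC undefined for a perfect fit")
    sigma2 = rss / n
    return n * np.log(2.0 * np.pi * sigma2) + n + 2 * k_params


def cvr(residuals, W, dof: int = 1) -> float:
    """Coefficient of variation of the residuals, % of mean observed biomass.

    100 · sqrt(RSS/(n − dof)) / mean(W).
    """
    e = np.asarray(residuals, dtype=float)
    W = np.asarray(W, dtype=float)
    n = e.size
    if n <= dof:
        raise ValueError("cvr needs n > dof")
    wbar = float(np.mean(W))
    if wbar <= 0:
        raise ValueError("cvr needs mean observed biomass > 0")
    return 100.0 * float(np.sqrt(np.sum(e**2) / (n - dof))) / wbar


def furnival_index(residuals, W, transform: str = "identity", dof: int = 1) -> float:
    """Furnival's index of fit.

    RMSE on the (possibly transformed) response scale divided by the
    geometric mean of the transform derivative f′(W); for the identity
    transform this is just the residual RMSE, in Mg.  Supplying
    ``transform="log"`` scores a log-scale fit back on the original scale.
    """
    e = np.asarray(residuals, dtype=float)
    W = np.asarray(W, dtype=float)
    n = e.size
    if n <= dof:
        raise ValueError("Furnival index needs n > dof")
    rmse = float(np.sqrt(np.sum(e**2) / (n - dof)))
    if transform == "identity":
        return rmse
    if transform == "log":
        if np.any(W <= 0):
            raise ValueError("log transform needs all W > 0")
        geo_mean_deriv = float(np.exp(np.mean(np.log(1.0 / W))))
        return rmse / geo_mean_deriv
    raise ValueError(f"unknown transform {transform!r}")


def mep(residuals, hat_diag) -> float:
    """Mean quadratic error of prediction: (1/n) Σ eᵢ²/(1 − Hᵢᵢ)².

    Equals PRESS/n — the mean squared leave-one-out prediction error — for
    any linear smoother, since e₍ᵢ₎ = eᵢ/(1 − Hᵢᵢ).
    """
    e = np.asarray(residuals, dtype=float)
    h = np.asarray(hat_diag, dtype=float)
    if e.shape != h.shape:
        raise ValueError("residuals and hat diagonal must have equal length")
    if np.any(h >= 1):
        raise ValueError("degenerate leverage: some H_ii >= 1")
    return float(np.mean(e**2 / (1.0 - h) ** 2))


def _make_folds(n: int, k: int, rng: np.random.Generator) -> list[np.ndarray]:
    idx = rng.permutation(n)
    return [fold for fold in np.array_split(idx, k)]


def kfold_mpe(
    W,
    V,
    method: str = "ls_rto",
    k: int = 10,
    seed: int | None = 0,
    cost: str = "rmspe",
    **fit_kwargs,
) -> float:
    """K-fold cross-validated model prediction error (Mg).

    Indices are shuffled with ``seed`` and split into K near-equal folds;
    each fold is predicted from a fit on its complement, and the held-out
    errors are pooled.  ``cost="rmspe"`` (default) returns the root mean
    squared prediction error, ``cost="mae"`` the mean absolute error.
    When n < K the split degrades gracefully to leave-one-out.
    """
    W = np.asarray(W, dtype=float)
    V = np.asarray(V, dtype=float)
    n = W.size
    if n < 2:
        raise ValueError("cross-validation needs n >= 2")
    if n < k:
        k = n  # leave-one-out fallback
    rng = np.random.default_rng(seed)
    preds = np.empty(n)
    for fold in _make_folds(n, k, rng):
        mask = np.ones(n, dtype=bool)
        mask[fold] = False
        fit = BcefModel(W[mask], V[mask]).fit(method, **fit_kwargs)
        preds[fold] = fit.predict(V[fold])
    err = W - preds
    if cost == "rmspe":
        return float(np.sqrt(np.mean(err**2)))
    if cost == "mae":
        return float(np.mean(np.abs(err)))
    raise ValueError(f"unknown cost {cost!r}")


@dataclass(frozen=True)
class FitMetrics:
    """Score card of one BCEF fit, in the column order of the report tables."""

    aic: float
    se_pct: float
    cvr_pct: float
    fi: float
    mep: float
    mpe: float
    n: int
    k_params: int = 2

    def to_row(self) -> dict:
        return {
            "aic": self.aic,
            "se_pct": self.se_pct,
            "cvr_pct": self.cvr_pct,
            "fi": self.fi,
            "mep": self.mep,
            "mpe": self.mpe,
        }


def score_fit(fit: BcefResults, k: int = 10, seed: int | None = 0, cost: str = "rmspe") -> FitMetrics:
    """All six metrics for a fitted BCEF.

    AIC uses the Gaussian likelihood evaluated at the fit's own slope with
    k = 2 (slope + variance) for every method, so ratio and LS fits carry
    the same penalty; a zero-residual fit reports AIC = −inf rather than
    failing, so noiseless data can still be scored end to end.
    """
    e = fit.resid
    rss = float(np.sum(e**2))
    aic = -np.inf if rss == 0 else aic_gaussian(e, k_params=2)
    mpe = kfold_mpe(fit.W, fit.V, method=fit.method, k=k, seed=seed, cost=cost)
    return FitMetrics(
        aic=aic,
        se_pct=fit.se_pct,
        cvr_pct=cvr(e, fit.W, dof=1),
        fi=furnival_index(e, fit.W, dof=1),
        mep=mep(e, fit.hat_diag),
        mpe=mpe,
        n=fit.nobs,
    )
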