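"""Impulse-response resistance of annual biomass to a standardized drought.

The field-data stage: each species' annual flowering-stalk biomass series
and the growing-season precipitation series are linearly detrended and
standardized to N(0, 1).  The standardized biomass is then modelled as an
autoregression of order 0, 1 or 2 with standardized precipitation as an
exogenous driver,

    y_t = φ₁ y_{t−1} + ... + φ_p y_{t−p} + β x_t + ε_t,

fitted by ordinary least squares without an intercept (both series have
mean zero).  The best order is chosen by BIC, and drought resistance is the
lag-0 response of the impulse response function to a −2σ precipitation
shock — for any order this equals β·(−2).  Recovery, elasticity and return
time summarize the rest of the IRF trajectory.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from c4drought.errors import (
    CollinearityError,
    DegenerateSeriesError,
    InsufficientDataError,
)

RSS_FLOOR = 1e-12  # per-observation floor guarding BIC against log(0) on exact fits


@dataclass(frozen=True)
class StandardizedSeries:
    """A detrended, standardized series with the metadata to invert the transform."""

    values: np.ndarray
    removed_trend: tuple[float, float]  # (intercept, slope) in original units
    original_mean: float  # mean of detrended residuals (≈0 by construction of OLS)
    original_sd: float  # sd (ddof=1) of detrended residuals

    def inverse(self, t: np.ndarray | None = None) -> np.ndarray:
        """Map standardized values back to original units."""
        if t is None:
            t = np.arange(len(self.values))
        intercept, slope = self.removed_trend
        return self.values * self.original_sd + self.original_mean + intercept + slope * t


@dataclass(frozen=True)
class ARXFit:
    """A fitted ARX(p) model on standardized series."""

    p: int
    phi: tuple[float, ...]
    beta: float
    sigma2: float
    bic: float
    n_effective: int


@dataclass(frozen=True)
class IRFResult:
    """Impulse-response trajectory after a one-time precipitation shock at lag 0."""

    shock: float
    horizon: int
    responses: tuple[float, ...]
    resistance: float = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "resistance", self.responses[0])


def detrend_standardize(values, t=None) -> StandardizedSeries:
    """Remove an OLS linear trend, then center and scale residuals to N(0, 1).

    ``t`` defaults to the observation index 0..n−1.  Raises
    InsufficientDataError below 5 points and DegenerateSeriesError when the
    detrended residuals have (numerically) zero variance.
    """
    y = np.asarray(values, dtype=float)
    if y.ndim != 1 or len(y) < 5:
        raise InsufficientDataError("need at least 5 observations to detrend")
    if t is None:
        t = np.arange(len(y), dtype=float)
    else:
        t = np.asarray(t, dtype=float)
    X = np.column_stack([np.ones_like(t), t])
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    sd = float(np.std(resid, ddof=1))
    if sd < 1e-12 * max(1.0, float(np.abs(y).max())):
        raise DegenerateSeriesError("zero residual variance after detrending")
    mean = float(resid.mean())
    z = (resid - mean) / sd
    return StandardizedSeries(
        values=z,
        removed_trend=(float(coef[0]), float(coef[1])),
        original_mean=mean,
        original_sd=sd,
    )


def _as_values(series) -> np.ndarray:
    if isinstance(series, StandardizedSeries):
        return series.values
    return np.asarray(series, dtype=float)


def fit_arx(y, x, p: int) -> ARXFit:
    """OLS fit of y_t = Σ φ_i y_{t−i} + β x_t (no intercept) for p ∈ {0, 1, 2}.

    sigma2 is RSS divided by the effective sample size n − p, and BIC uses
    the Gaussian profile likelihood, counting k = p + 1 parameters
    (the φ's and β, not σ²): BIC = n_eff·ln(RSS/n_eff) + k·ln(n_eff).
    """
    yv, xv = _as_values(y), _as_values(x)
    if len(yv) != len(xv):
        raise ValueError("y and x must have equal length")
    if p not in (0, 1, 2):
        raise ValueError("AR order p must be 0, 1 or 2")
    n = len(yv)
    n_eff = n - p
    if n_eff < p + 2:
        raise InsufficientDataError(f"need at least {2 * p + 2} observations for AR({p})")
    cols = [yv[p - i - 1 : n - i - 1] for i in range(p)]  # lags 1..p
    cols.append(xv[p:])
    X = np.column_stack(cols)
    target = yv[p:]
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise CollinearityError("singular regressor matrix in ARX fit")
    coef, *_ = np.linalg.lstsq(X, target, rcond=None)
    resid = target - X @ coef
    rss = float(resid @ resid)
    sigma2 = rss / n_eff
    k = p + 1
    bic = n_eff * np.log(max(sigma2, RSS_FLOOR)) + k * np.log(n_eff)
    return ARXFit(
        p=p,
        phi=tuple(float(c) for c in coef[:p]),
        beta=float(coef[p]),
        sigma2=sigma2,
        bic=float(bic),
        n_effective=n_eff,
    )


def select_order(y, x, orders=(0, 1, 2)) -> ARXFit:
    """Fit every candidate order and return the minimum-BIC fit.

    Ties break toward lower order, so candidates are scanned ascending.
    """
    best: ARXFit | None = None
    for p in sorted(orders):
        fit = fit_arx(y, x, p)
        if best is None or fit.bic < best.bic:
            best = fit
    assert best is not None
    return best


def impulse_response(fit: ARXFit, shock: float = -2.0, horizon: int = 3) -> IRFResult:
    """Trajectory after a one-time exogenous shock at lag 0.

    responses[0] = β·shock (the resistance); later lags propagate only
    through the AR terms: responses[k] = Σ_{i≤min(k,p)} φ_i·responses[k−i].
    """
    if horizon < 0:
        raise ValueError("horizon must be >= 0")
    resp = [fit.beta * shock]
    for k in range(1, horizon + 1):
        resp.append(sum(fit.phi[i] * resp[k - 1 - i] for i in range(min(k, fit.p))))
    return IRFResult(shock=shock, horizon=horizon, responses=tuple(resp))


def resilience_summary(irf: IRFResult, tolerance: float = 0.05) -> dict:
    """Resistance / recovery / elasticity / return-time summary of an IRF.

    resistance is the lag-0 decline; recovery the state at the final
    horizon; elasticity the mean per-step change (slope of the recovery
    trajectory); return_time the first lag whose response is within
    ``tolerance`` of zero, or horizon + 1 if the system never returns
    within the horizon.
    """
    if irf.horizon < 1:
        raise ValueError("summary requires horizon >= 1")
    r = np.asarray(irf.responses)
    elasticity = float(np.mean(np.diff(r)))
    inside = np.nonzero(np.abs(r) < tolerance)[0]
    return_time = int(inside[0]) if len(inside) else irf.horizon + 1
    return {
        "resistance": float(r[0]),
        "recovery": float(r[-1]),
        "elasticity": elasticity,
        "return_time": return_time,
    }


def analyze_panel(
    panel,
    shock: float = -2.0,
    horizon: int = 3,
    orders=(0, 1, 2),
) -> dict:
    """Full field-stage analysis of one species' (year, precip_mm, biomass) panel.

    Detrends and standardizes both series, selects the ARX order by BIC and
    returns the chosen fit, the per-order BIC table, the IRF and the
    resilience summary as a JSON-ready dict.
    """
    t = np.asarray(panel["year"], dtype=float)
    t = t - t[0]
    y = detrend_standardize(panel["biomass"], t)
    x = detrend_standardize(panel["precip_mm"], t)
    fits = {p: fit_arx(y, x, p) for p in sorted(orders)}
    best = min(fits.values(), key=lambda f: (f.bic, f.p))
    irf = impulse_response(best, shock=shock, horizon=horizon)
    summary = resilience_summary(irf)
    return {
        "order": best.p,
        "phi": list(best.phi),
        "beta": best.beta,
        "sigma2": best.sigma2,
        "bic_table": {str(p): f.bic for p, f in fits.items()},
        "shock": shock,
        "irf": list(irf.responses),
        **summary,
    }
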