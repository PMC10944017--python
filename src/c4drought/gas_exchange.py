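"""Leaf physiology: RWC, growth rate, A–Ci fits and the limitation partition.

The chamber-experiment stage.  An A–Ci (demand) curve from a CO₂ ramp is
fitted with the asymptotic monomolecular model

    A(Ci) = a − (a − b)·exp(−c·Ci),

where ``a`` is the CO₂-saturated assimilation rate, ``b`` the rate at
Ci = 0 (typically negative: dark/photo-respiration) and ``c`` the curvature.
Evaluating the fitted curve at the Ci equivalent of 40 Pa atmospheric CO₂
— i.e. with no stomatal drawdown of CO₂ — gives A_40, the rate a drought
leaf could achieve if its stomata imposed no supply limitation.  Comparing
A_40 with the leaf's observed rate and the species-mean control rate splits
the drought-induced loss of photosynthesis into a stomatal (CO₂ supply) and
a metabolic (biochemical demand) component:

    RSL = 100·(A_40 − A_obs,drought) / A_obs,control
    RML = 100·(A_obs,control − A_40) / A_obs,control

which sum to the total relative loss 100·(A_obs,control − A_obs,drought) /
A_obs,control.  RML can be negative when A_40 exceeds the control mean.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from c4drought.errors import (
    DegenerateCurveError,
    InvalidHeightError,
    InvalidReferenceError,
    InvalidWeightsError,
)

STANDARD_PRESSURE_KPA = 101.325
RWC_QC_THRESHOLD = 0.30  # records below 30% RWC are flagged (negative g_sw territory)


@dataclass(frozen=True)
class LeafWeights:
    """Fresh / hydrated / dry weight triplet in grams."""

    fresh: float
    hydrated: float
    dry: float

    def __post_init__(self) -> None:
        if self.dry <= 0:
            raise InvalidWeightsError("dry weight must be > 0")
        if self.hydrated <= self.dry:
            raise InvalidWeightsError("hydrated weight must exceed dry weight")


@dataclass(frozen=True)
class MonomolecularParams:
    """Fitted (a, b, c) of A = a − (a−b)·exp(−c·Ci), with fit diagnostics."""

    a: float
    b: float
    c: float
    rss: float
    converged: bool

    def __post_init__(self) -> None:
        if self.c <= 0:
            raise ValueError("rate constant c must be > 0")
        if self.a < self.b:
            raise ValueError("asymptote a must be >= b")


@dataclass(frozen=True)
class LimitationResult:
    """RSL/RML partition for one drought leaf against its species' control mean."""

    a40_drought: float
    aobs_drought: float
    aobs_control_mean: float
    rsl: float
    rml: float


def relative_water_content(w: LeafWeights) -> float:
    """RWC = (fresh − dry) / (hydrated − dry).

    Not clamped to [0, 1]: fresh > hydrated happens with real leaves and is
    surfaced to QC rather than silently altered.
    """
    return (w.fresh - w.dry) / (w.hydrated - w.dry)


def mean_relative_growth_rate(heights) -> float:
    """Mean of successive height ratios H_{t+1}/H_t over consecutive weeks.

    NaN entries break the chain: a pair is used only when both weeks are
    observed consecutively (no interpolation).  Any non-positive observed
    height is an error.
    """
    h = np.asarray(heights, dtype=float)
    observed = h[~np.isnan(h)]
    if np.any(observed <= 0):
        raise InvalidHeightError("heights must be positive")
    ratios = [
        h[i + 1] / h[i]
        for i in range(len(h) - 1)
        if not (np.isnan(h[i]) or np.isnan(h[i + 1]))
    ]
    if not ratios:
        raise InvalidHeightError("need at least one consecutive pair of heights")
    return float(np.mean(ratios))


def predict_A(p: MonomolecularParams, ci) -> np.ndarray | float:
    """Evaluate the fitted monomolecular curve at intercellular CO₂ ``ci``."""
    ci = np.asarray(ci, dtype=float)
    out = p.a - (p.a - p.b) * np.exp(-p.c * ci)
    return float(out) if out.ndim == 0 else out


def _initial_guess(ci: np.ndarray, A: np.ndarray) -> tuple[float, float, float]:
    a0 = float(A.max())
    b0 = float(A.min())
    spread = a0 - b0
    # log-linear regression of ln((a0 + eps − A)/(a0 + eps − b0)) on Ci over
    # interior points gives slope −c
    a_top = a0 + 0.05 * spread
    r = (a_top - A) / (a_top - b0)
    keep = r > 1e-9
    if keep.sum() >= 3:
        slope = np.polyfit(ci[keep], np.log(r[keep]), 1)[0]
        c0 = max(-float(slope), 1e-6)
    else:
        c0 = 3.0 / max(float(ci.max()), 1.0)
    return a0, b0, c0


def fit_monomolecular(ci, A) -> MonomolecularParams:
    """Nonlinear least squares of A = a − (a−b)·exp(−c·Ci), c constrained > 0.

    Initialization: a₀ = max(A), b₀ = min(A), c₀ from a log-linear
    regression of the scaled deficit on Ci.  Non-convergence yields a
    result flagged ``converged=False`` rather than an exception; a flat
    curve raises DegenerateCurveError.
    """
    ci = np.asarray(ci, dtype=float)
    A = np.asarray(A, dtype=float)
    if len(ci) != len(A) or len(ci) < 10:
        raise ValueError("need >= 10 paired (Ci, A) observations")
    if np.any(ci < 0):
        raise ValueError("Ci must be non-negative")
    if ci.max() < 5 * max(ci.min(), 1e-9):
        raise ValueError("Ci range must span at least a factor of 5")
    if np.ptp(A) < 1e-9 * max(1.0, float(np.abs(A).max())):
        raise DegenerateCurveError("flat A-Ci curve cannot be fitted")

    def resid(theta):
        a, b, log_c = theta
        return a - (a - b) * np.exp(-np.exp(log_c) * ci) - A

    a0, b0, c0 = _initial_guess(ci, A)
    sol = least_squares(resid, x0=[a0, b0, np.log(c0)], method="lm", max_nfev=5000)
    a, b, c = float(sol.x[0]), float(sol.x[1]), float(np.exp(sol.x[2]))
    rss = float(sol.fun @ sol.fun)
    converged = bool(sol.success) and a >= b
    if a < b:  # pathological fit: report honestly with swapped-safe params
        a, b = b, a
    return MonomolecularParams(a=a, b=b, c=c, rss=rss, converged=converged)


def a40_unlimited(p: MonomolecularParams, pressure_kpa: float = STANDARD_PRESSURE_KPA) -> float:
    """Assimilation at 40 Pa CO₂ with no stomatal limitation.

    40 Pa is converted to a mole fraction at chamber pressure
    (40 / (pressure·1000) × 10⁶ µmol mol⁻¹ ≈ 394.77 at 101.325 kPa) and the
    fitted curve is evaluated there: Ci equal to atmospheric CO₂ means no
    stomatal drawdown.
    """
    if pressure_kpa <= 0:
        raise ValueError("pressure must be > 0")
    ci_equiv = 40.0 / (pressure_kpa * 1000.0) * 1e6
    return float(predict_A(p, ci_equiv))


def limitation_partition(
    fit: MonomolecularParams,
    aobs_drought: float,
    aobs_control_mean: float,
    pressure_kpa: float = STANDARD_PRESSURE_KPA,
) -> LimitationResult:
    """Split the drought loss of assimilation into stomatal and metabolic parts.

    RSL + RML always equals the total relative loss
    100·(A_obs,control − A_obs,drought)/A_obs,control; RML may be negative.
    """
    if aobs_control_mean <= 0:
        raise InvalidReferenceError("species-mean control assimilation must be > 0")
    a40 = a40_unlimited(fit, pressure_kpa)
    rsl = 100.0 * (a40 - aobs_drought) / aobs_control_mean
    rml = 100.0 * (aobs_control_mean - a40) / aobs_control_mean
    return LimitationResult(
        a40_drought=a40,
        aobs_drought=float(aobs_drought),
        aobs_control_mean=float(aobs_control_mean),
        rsl=rsl,
        rml=rml,
    )


def normalize_curve(A, reference_A: float) -> np.ndarray:
    """Express assimilation as a percentage of a reference rate (Ci untouched)."""
    if reference_A == 0:
        raise InvalidReferenceError("reference assimilation must be nonzero")
    if reference_A < 0:
        warnings.warn("negative reference flips the sign of normalized rates", stacklevel=2)
    return np.asarray(A, dtype=float) / reference_A * 100.0


def partition_table(
    fits,
    survey,
    response_name: str = "A",
    pressure_kpa: float = STANDARD_PRESSURE_KPA,
    control_average: str = "week",
) -> pd.DataFrame:
    """RSL/RML partition for every fitted drought curve against the survey table.

    ``fits`` is an iterable of dicts with keys species, treatment, week,
    replicate and params (a :class:`MonomolecularParams`).  ``survey`` is a
    long-format experiment table (replicate, species, treatment, week,
    response_name, value) of steady-state assimilation measurements.  Each
    drought curve is paired with the survey week via
    :func:`match_survey_week`; A_obs,drought is that leaf's measured survey
    rate (falling back to the drought-cell mean when the replicate was not
    surveyed), and A_obs,control is the species mean of control rates — in
    the matched week (``control_average="week"``) or across all weeks
    (``"all"``).
    """
    if control_average not in ("week", "all"):
        raise ValueError("control_average must be 'week' or 'all'")
    sv = survey[survey["response_name"] == response_name]
    if sv.empty:
        raise InvalidReferenceError(f"no survey rows with response {response_name!r}")
    rows = []
    for rec in fits:
        if rec["treatment"] != "drought":
            continue
        sp = rec["species"]
        sp_rows = sv[sv["species"] == sp]
        wk = match_survey_week(int(rec["week"]), sorted(sp_rows["week"].unique()))
        drought_cell = sp_rows[(sp_rows["treatment"] == "drought") & (sp_rows["week"] == wk)]
        leaf = drought_cell[drought_cell["replicate"] == rec["replicate"]]
        aobs_drought = float(leaf["value"].iloc[0]) if len(leaf) else float(
            drought_cell["value"].mean()
        )
        control = sp_rows[sp_rows["treatment"] == "control"]
        if control_average == "week":
            control = control[control["week"] == wk]
        aobs_control = float(control["value"].mean())
        res = limitation_partition(rec["params"], aobs_drought, aobs_control, pressure_kpa)
        rows.append(
            {
                "replicate": rec["replicate"],
                "species": sp,
                "week": rec["week"],
                "survey_week": wk,
                "A40": res.a40_drought,
                "Aobs_drought": res.aobs_drought,
                "Aobs_control_mean": res.aobs_control_mean,
                "RSL_pct": res.rsl,
                "RML_pct": res.rml,
            }
        )
    return pd.DataFrame(rows)


def match_survey_week(curve_week: int, survey_weeks) -> int:
    """Pair an A–Ci curve week with the nearest survey week not after week+1.

    Curve weeks (2, 4) and steady-state survey weeks (1, 3, 5, 7) do not
    coincide; the closest survey week no later than curve_week + 1 is used
    (2 → 3, 4 → 5).
    """
    candidates = [w for w in survey_weeks if w <= curve_week + 1]
    if not candidates:
        raise ValueError(f"no survey week at or before {curve_week + 1}")
    return max(candidates)
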