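"""Synthetic-data generators with known ground truth.

Every input the pipeline consumes can be generated here: an annual panel of
growing-season precipitation and flowering-stalk biomass with AR structure
and a known precipitation coefficient ``beta``; monomolecular A–Ci ramp
curves with additive Gaussian noise; and balanced (or unbalanced) factorial
treatment × week experiment tables with known cell means.  All generators
are deterministic given their ``seed``.

Default parameter choices emulate the study conditions the pipeline was
built for: a 10 → 1500 µmol mol⁻¹ CO₂ ramp at 200 µmol mol⁻¹ min⁻¹ sampled
at 1 Hz, standardized precipitation mapped to a plausible mm range
(mean 600, sd 150), and two grass species with 13 and 10 replicates per
watering treatment.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from c4drought.errors import StationarityError

PRECIP_MEAN_MM = 600.0
PRECIP_SD_MM = 150.0

DEFAULT_SPECIES_REPS = {"Andropogon gerardii": 13, "Schizachyrium scoparium": 10}


def _check_stationary(phi: tuple[float, ...]) -> None:
    """Raise unless all roots of 1 - phi1 z - phi2 z^2 lie outside the unit circle."""
    if not phi:
        return
    # np.roots wants descending powers: -phi_p ... -phi_1 1
    coeffs = [-p for p in reversed(phi)] + [1.0]
    roots = np.roots(coeffs)
    if np.any(np.abs(roots) <= 1.0 + 1e-12):
        raise StationarityError(f"AR coefficients {phi} imply a non-stationary process")


@dataclass(frozen=True)
class TimeSeriesTruth:
    """Generative truth for one species' annual precipitation–biomass panel.

    ``beta`` is the coefficient linking standardized precipitation to
    standardized biomass; ``phi`` are AR coefficients (up to order 2);
    ``trend_slope`` adds a deterministic linear trend in original units
    that the detrending stage must remove.
    """

    n_years: int = 38
    beta: float = 0.6
    phi: tuple[float, ...] = ()
    trend_slope: float = 0.0
    noise_sd: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_years < 10:
            raise ValueError("n_years must be >= 10")
        if len(self.phi) > 2:
            raise ValueError("AR order at most 2")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        _check_stationary(tuple(self.phi))


@dataclass(frozen=True)
class ACiTruth:
    """Generative truth for one monomolecular A–Ci ramp curve.

    The response is A = a − (a − b)·exp(−c·Ci) plus i.i.d. Gaussian noise,
    sampled along a linear CO₂ ramp with both endpoints included.
    """

    a: float = 30.0
    b: float = -2.0
    c: float = 0.01
    noise_sd: float = 0.5
    ramp_start: float = 10.0
    ramp_end: float = 1500.0
    ramp_rate: float = 200.0  # µmol mol⁻¹ min⁻¹
    sample_hz: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.a > self.b:
            raise ValueError("asymptote a must exceed intercept b")
        if self.c <= 0:
            raise ValueError("curvature c must be > 0")
        if self.ramp_end <= self.ramp_start:
            raise ValueError("ramp_end must exceed ramp_start")
        if self.ramp_rate <= 0 or self.sample_hz <= 0:
            raise ValueError("ramp_rate and sample_hz must be > 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass(frozen=True)
class FactorialTruth:
    """Generative truth for a species × treatment × week factorial experiment.

    ``cell_means`` maps (species, treatment, week) to the cell mean; every
    combination of the stated levels must be present.  ``n_reps`` may be a
    single integer or a per-species mapping (the study design was
    unbalanced: 13 vs 10 replicates per treatment).
    """

    species: tuple[str, ...] = tuple(DEFAULT_SPECIES_REPS)
    treatments: tuple[str, ...] = ("control", "drought")
    weeks: tuple[int, ...] = (4, 7)
    cell_means: dict = field(default_factory=dict)
    n_reps: int | dict = field(default_factory=lambda: dict(DEFAULT_SPECIES_REPS))
    residual_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.residual_sd < 0:
            raise ValueError("residual_sd must be >= 0")
        for sp in self.species:
            if self.reps_for(sp) < 2:
                raise ValueError("n_reps must be >= 2 for every species")
        if self.cell_means:
            for sp in self.species:
                for tr in self.treatments:
                    for wk in self.weeks:
                        if (sp, tr, wk) not in self.cell_means:
                            raise ValueError(f"missing cell mean for {(sp, tr, wk)}")

    def reps_for(self, species: str) -> int:
        if isinstance(self.n_reps, dict):
            return int(self.n_reps[species])
        return int(self.n_reps)

    def mean_for(self, species: str, treatment: str, week: int) -> float:
        if not self.cell_means:
            return 0.0
        return float(self.cell_means[(species, treatment, week)])


def gen_timeseries(truth: TimeSeriesTruth) -> pd.DataFrame:
    """Simulate an annual (year, precip_mm, biomass) panel.

    Standardized precipitation x_t is i.i.d. N(0, 1); the stationary biomass
    core follows z_t = Σ φ_i z_{t−i} + β x_t + ε_t with ε ~ N(0, noise_sd²);
    a deterministic trend ``trend_slope * t`` is added on top, and
    precipitation is affinely mapped to a plausible mm range so the
    detrend/standardize stage has real work to undo.
    """
    rng = np.random.default_rng(truth.seed)
    n = truth.n_years
    x = rng.standard_normal(n)
    eps = rng.standard_normal(n) * truth.noise_sd
    p = len(truth.phi)
    z = np.zeros(n)
    for t in range(n):
        ar = sum(truth.phi[i] * z[t - 1 - i] for i in range(min(p, t)))
        z[t] = ar + truth.beta * x[t] + eps[t]
    years = np.arange(n)
    biomass = truth.trend_slope * years + z
    precip_mm = PRECIP_MEAN_MM + PRECIP_SD_MM * x
    return pd.DataFrame({"year": 1983 + years, "precip_mm": precip_mm, "biomass": biomass})


def gen_aci_curve(truth: ACiTruth) -> pd.DataFrame:
    """Simulate one dynamic-assimilation ramp as (t_s, Ci_umol_mol, A_umol_m2_s).

    The Ci grid is a uniform ramp from ramp_start to ramp_end inclusive,
    sampled at ``sample_hz``; the default study ramp (10 → 1500 at
    200 µmol mol⁻¹ min⁻¹, 1 Hz) yields 448 samples over 7.45 minutes.
    """
    rng = np.random.default_rng(truth.seed)
    duration_s = (truth.ramp_end - truth.ramp_start) / truth.ramp_rate * 60.0
    n = int(round(duration_s * truth.sample_hz)) + 1
    t_s = np.arange(n) / truth.sample_hz
    ci = np.linspace(truth.ramp_start, truth.ramp_end, n)
    a_clean = truth.a - (truth.a - truth.b) * np.exp(-truth.c * ci)
    a = a_clean + rng.standard_normal(n) * truth.noise_sd
    df = pd.DataFrame({"t_s": t_s, "Ci_umol_mol": ci, "A_umol_m2_s": a})
    df.attrs["truth"] = truth
    return df


def gen_factorial(truth: FactorialTruth, response_name: str = "response") -> pd.DataFrame:
    """Simulate a long-format experiment table.

    Columns: replicate, species, treatment, week, response_name, value.
    Each observation is its cell mean plus N(0, residual_sd²) noise; the
    design is balanced within species per ``n_reps``.
    """
    rng = np.random.default_rng(truth.seed)
    rows = []
    for sp in truth.species:
        reps = truth.reps_for(sp)
        for tr in truth.treatments:
            for wk in truth.weeks:
                mu = truth.mean_for(sp, tr, wk)
                vals = mu + rng.standard_normal(reps) * truth.residual_sd
                for r, v in enumerate(vals, start=1):
                    rows.append((r, sp, tr, wk, response_name, v))
    return pd.DataFrame(
        rows, columns=["replicate", "species", "treatment", "week", "response_name", "value"]
    )
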