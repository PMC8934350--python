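"""Closed-form risk formulas for the one-dimensional carcinogenesis model.

The model describes a tissue microstate as a single coordinate x₁ along the
first principal axis of gene-expression space.  Starting near the origin
(the normal-cloud center), the microstate must travel a minimal walk length
R = x̄₁ − Rₙ − Rₜ to reach the tumor basin.  Two transport mechanisms are
considered:

* a Brownian component of per-generation scale D, whose escape probability
  over t generations is Erfc(√2·R/(D√t)), giving the log-linear predictor
  ln(D√t/R) − 2(R/(D√t))² for ln(risk/N_sc);
* rare Lévy jumps with a Pareto tail of exponent ν, occurring at rate μ per
  generation, whose escape probability is ∝ μ·t·(D/R)^(ν−1), giving the
  predictor ln(D·t/R) at ν = 2.

Time is measured in stem-cell generations: t = t₀ + m_sc·age with
t₀ = log₂(N_sc) the number of doublings needed to build the tissue and
m_sc the per-year stem-cell turnover rate.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.special import log_ndtr

__all__ = [
    "ModelParams",
    "RiskPrediction",
    "DEFAULT_AGE",
    "DEFAULT_NU",
    "DEFAULT_A_REF",
    "ERS_NORMAL_BAND",
    "t0_generations",
    "total_generations",
    "minimal_walk_length",
    "brownian_density_param",
    "log_erfc",
    "log_erfc_asymptotic",
    "brownian_escape_log_probability",
    "brownian_predictor",
    "levy_tail_probability",
    "levy_predictor",
    "levy_risk",
    "ers_score",
    "ers_band",
]

DEFAULT_AGE = 80.0  # years; the registry risks are cumulative to age 80
DEFAULT_NU = 2.0  # Pareto exponent; expression tails show 1.6-2.0
DEFAULT_A_REF = 2e-14  # per-generation reference rate of the extra risk score
ERS_NORMAL_BAND = (1.0, 6.0)

_LN2 = math.log(2.0)
_SQRT2 = math.sqrt(2.0)


@dataclass
class ModelParams:
    """Parameters of the one-dimensional risk model for a single tissue.

    d_scale
        Fluctuation scale D: the per-generation step amplitude along PC1,
        estimated as max|v₁ᵢ| of the principal direction (dimensionless).
    r_walk
        Minimal walk length R = x̄₁ − Rₙ − Rₜ (PC1 units).
    n_sc
        Number of tissue stem cells.
    m_sc
        Stem-cell turnover rate (1/year).
    age
        Exposure age in years (default 80).
    nu
        Pareto exponent ν of the jump-size tail (default 2).
    mu
        Effective large-jump rate μ′ per generation; unknown a priori and
        therefore optional — required only by :func:`levy_risk`.
    a_ref
        Reference per-generation rate in the extra-risk-score rescaling.
    """

    d_scale: float
    r_walk: float
    n_sc: float
    m_sc: float
    age: float = DEFAULT_AGE
    nu: float = DEFAULT_NU
    mu: float | None = None
    a_ref: float = DEFAULT_A_REF

    def __post_init__(self) -> None:
        if self.d_scale <= 0:
            raise ValueError("d_scale must be > 0")
        if self.r_walk <= 0:
            raise ValueError("r_walk must be > 0")
        if self.n_sc < 1:
            raise ValueError("n_sc must be >= 1")
        if self.m_sc < 0:
            raise ValueError("m_sc must be >= 0")
        if self.nu <= 1:
            raise ValueError("nu must be > 1")
        if self.a_ref <= 0:
            raise ValueError("a_ref must be > 0")
        # Eq for the jump tail assumes R sits deep in the Pareto tail
        if self.r_walk / self.d_scale <= 10:
            warnings.warn(
                f"r_walk/d_scale = {self.r_walk / self.d_scale:.2f} <= 10; the "
                "tail approximation for the jump escape probability is dubious",
                stacklevel=2,
            )

    @property
    def t_total(self) -> float:
        return total_generations(self.n_sc, self.m_sc, self.age)


@dataclass(frozen=True)
class RiskPrediction:
    """One (predictor, response) pair of the model regression for a tissue.

    ``response`` is ln(risk/N_sc); ``predictor`` is the model's right-hand
    side: ln(D√t/R) − 2(R/(D√t))² for ``model='brownian'`` or ln(D·t/R) for
    ``model='levy'``.
    """

    tissue: str
    predictor: float
    response: float
    model: str

    def __post_init__(self) -> None:
        if self.model not in ("brownian", "levy"):
            raise ValueError(f"model must be 'brownian' or 'levy', got {self.model!r}")
        if self.response >= 0:
            raise ValueError(
                f"{self.tissue}: response ln(risk/N_sc) must be negative (risk < N_sc)"
            )


def t0_generations(n_sc: float) -> float:
    """Development time t₀ = log₂(N_sc), the doublings forming the tissue.

    Returned continuous (not rounded): 2×10⁸ stem cells give 27.575.
    """
    if np.any(np.asarray(n_sc) < 1):
        raise ValueError("n_sc must be >= 1")
    return np.log2(n_sc)


def total_generations(n_sc: float, m_sc: float, age: float = DEFAULT_AGE) -> float:
    """Total exposure t = t₀ + m_sc·age, in stem-cell generations."""
    if np.any(np.asarray(age) < 0):
        raise ValueError("age must be >= 0")
    return t0_generations(n_sc) + np.asarray(m_sc) * age


def minimal_walk_length(xbar1: float, rn: float, rt: float) -> float:
    """Minimal PC1 distance R = x̄₁ − Rₙ − Rₜ between the cloud edges."""
    if min(xbar1, rn, rt) < 0 or xbar1 <= 0:
        raise ValueError("xbar1 must be positive and radii non-negative")
    r = xbar1 - rn - rt
    if r <= 0:
        raise ValueError(
            f"clouds overlap: xbar1 - rn - rt = {r:.4f} <= 0 (no walk length)"
        )
    return r


def brownian_density_param(d_scale: float, t: float) -> float:
    """Gaussian concentration a = 2/(D²t); the implied variance is D²t/4."""
    if d_scale <= 0:
        raise ValueError("d_scale must be > 0")
    if t <= 0:
        raise ValueError("t must be > 0")
    return 2.0 / (d_scale**2 * t)


def log_erfc(z):
    """ln Erfc(z), stable for arbitrarily large z.

    Uses Erfc(z) = 2·Φ(−z√2), evaluated through the log-scale normal CDF, so
    the deep-underflow regime (z ≳ 27, Erfc below the smallest double) stays
    finite and accurate on the log scale with no branch switch.
    """
    return _LN2 + log_ndtr(-_SQRT2 * np.asarray(z, dtype=float))


def log_erfc_asymptotic(z):
    """Leading asymptotic ln Erfc(z) ≈ −z² − ln(√π·z), valid for large z."""
    z = np.asarray(z, dtype=float)
    return -(z**2) - np.log(math.sqrt(math.pi) * z)


def brownian_escape_log_probability(d_scale: float, r_walk: float, t: float):
    """ln of the Brownian escape probability Erfc(√(aR²)) after t generations.

    The argument is z = √(aR²) = √2·R/(D√t); R = 0 gives ln Erfc(0) = 0.
    """
    if d_scale <= 0 or t <= 0 or np.any(np.asarray(r_walk) < 0):
        raise ValueError("require d_scale > 0, t > 0, r_walk >= 0")
    z = _SQRT2 * np.asarray(r_walk, dtype=float) / (d_scale * math.sqrt(t))
    return log_erfc(z)


def brownian_predictor(d_scale: float, r_walk: float, t: float):
    """Brownian regressor ln(D√t/R) − 2(R/(D√t))² for ln(risk/N_sc)."""
    if d_scale <= 0 or r_walk <= 0 or np.any(np.asarray(t) <= 0):
        raise ValueError("all inputs must be positive")
    ratio = d_scale * np.sqrt(t) / r_walk
    return np.log(ratio) - 2.0 / ratio**2


def levy_tail_probability(d_scale: float, r_walk: float, nu: float = DEFAULT_NU):
    """Normalized single-jump exceedance probability (D/R)^(ν−1).

    This is the survival function at R of a Pareto jump-size law with scale D
    and tail exponent ν; any unnormalized proportionality constant of the
    tail integral D·∫_R^∞ dx/xᵛ is absorbed into the effective rate μ′.
    """
    if nu <= 1:
        raise ValueError("nu must be > 1 (the tail integral diverges otherwise)")
    if d_scale <= 0 or np.any(np.asarray(r_walk) < d_scale):
        raise ValueError("require 0 < d_scale <= r_walk (R in the tail)")
    return (d_scale / np.asarray(r_walk, dtype=float)) ** (nu - 1.0)


def levy_predictor(d_scale: float, r_walk: float, t: float):
    """Lévy regressor ln(D·t/R) for ln(risk/N_sc), at ν = 2."""
    if d_scale <= 0 or r_walk <= 0 or np.any(np.asarray(t) <= 0):
        raise ValueError("all inputs must be positive")
    return np.log(d_scale * np.asarray(t, dtype=float) / r_walk)


def levy_risk(params: ModelParams) -> float:
    """Absolute lifetime risk N_sc·μ′·(D/R)·t from the Lévy-jump mechanism.

    Requires ``params.mu`` (the effective jump rate μ′) and ν = 2; the result
    is clamped to [0, 1] with a warning, since the linear estimate is
    unbounded.
    """
    if params.mu is None:
        raise ValueError(
            "mu (effective jump rate) is not set; fit it or supply a value"
        )
    if params.nu != 2:
        raise ValueError("the closed-form risk is derived for nu = 2")
    raw = params.n_sc * params.mu * (params.d_scale / params.r_walk) * params.t_total
    if raw > 1.0:
        warnings.warn(f"risk estimate {raw:.3g} > 1 clamped to 1", stacklevel=2)
        return 1.0
    return max(raw, 0.0)


def ers_score(
    risk: float,
    n_sc: float,
    m_sc: float,
    age: float = DEFAULT_AGE,
    a_ref: float = DEFAULT_A_REF,
) -> float:
    """Extra risk score ERS = (risk/N_sc) / (a_ref·(t₀ + m_sc·age)).

    ERS rescales the per-stem-cell risk by the number of stem-cell
    generations times a universal reference rate a_ref = 2×10⁻¹⁴; tissues
    whose risk is driven by intrinsic replication noise fall in the
    1 < ERS < 6 band.
    """
    if not 0 < risk < 1:
        raise ValueError("risk must lie in (0, 1)")
    if a_ref <= 0:
        raise ValueError("a_ref must be > 0")
    t = total_generations(n_sc, m_sc, age)
    return (risk / n_sc) / (a_ref * t)


def ers_band(ers: float) -> str:
    """Classify an ERS value: 'normal' inside (1, 6), 'low' below, 'high' above."""
    lo, hi = ERS_NORMAL_BAND
    if ers <= lo:
        return "low"
    if ers >= hi:
        return "high"
    return "normal"
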