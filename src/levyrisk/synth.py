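"""Synthetic-data generators.

Two generators back the offline test path:

* :func:`generate_cohort` builds a two-cloud expression cohort with a
  planted separation axis — normal samples around the origin of log-fold
  space, tumor samples displaced by a planted x̄₁ along a unit direction u,
  with planted r.m.s. radii along u and isotropic off-axis noise — so the
  geometry stage (PCA direction, cloud centers/radii, fluctuation scale)
  can be validated by parameter recovery without any real cohort.
* :func:`generate_planted_table` draws tissue tables whose risks follow the
  Lévy-jump generative law ln(risk/N_sc) = intercept + slope·ln(D·t/R) plus
  Gaussian scatter, so the regression stage can be validated end to end
  (noiseless recovery, unbiasedness under scatter).

Both are deterministic for a fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .geometry import ExpressionCohort
from .tissue_table import TissueRecord, TissueTable

__all__ = ["CohortSpec", "PlantedTableSpec", "generate_cohort", "generate_planted_table"]


@dataclass
class CohortSpec:
    """Specification of a planted two-cloud expression cohort.

    planted_direction is a unit vector over genes, or the string 'random';
    planted_xbar1/planted_rn/planted_rt set the tumor-cloud center and the
    r.m.s. radii of the two clouds along that direction; noise_sd_per_gene
    is isotropic Gaussian noise in log2 space; heavy_tail_fraction gives
    that fraction of genes symmetric Pareto-tailed noise instead (mimicking
    the heavy-tailed character of expression distributions).

    Defaults emulate a COAD-like cohort: well separated clouds
    (x̄₁ = 150 ≫ Rₙ + Rₜ = 40) with unit per-gene noise.
    """

    n_genes: int = 500
    n_normal: int = 50
    n_tumor: int = 50
    planted_direction: np.ndarray | str = "random"
    planted_xbar1: float = 150.0
    planted_rn: float = 12.0
    planted_rt: float = 28.0
    noise_sd_per_gene: float = 1.0
    heavy_tail_fraction: float = 0.0
    heavy_tail_nu: float = 3.0
    with_zeros: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 2 or self.n_normal < 2 or self.n_tumor < 2:
            raise ValueError("need >= 2 genes and >= 2 samples per class")
        if self.planted_xbar1 <= self.planted_rn + self.planted_rt:
            raise ValueError(
                "clouds overlap: planted_xbar1 must exceed planted_rn + planted_rt"
            )
        if min(self.planted_rn, self.planted_rt) < 0 or self.noise_sd_per_gene < 0:
            raise ValueError("radii and noise must be >= 0")
        if not 0.0 <= self.heavy_tail_fraction <= 1.0:
            raise ValueError("heavy_tail_fraction must lie in [0, 1]")


def _unit_direction(spec: CohortSpec, rng: np.random.Generator) -> np.ndarray:
    if isinstance(spec.planted_direction, str):
        if spec.planted_direction != "random":
            raise ValueError("planted_direction must be a vector or 'random'")
        u = rng.standard_normal(spec.n_genes)
    else:
        u = np.asarray(spec.planted_direction, dtype=float)
        if u.shape != (spec.n_genes,):
            raise ValueError("planted_direction length must equal n_genes")
    norm = np.linalg.norm(u)
    if norm == 0:
        raise ValueError("planted_direction must be non-zero")
    return u / norm


def _noise(rng: np.random.Generator, spec: CohortSpec, n_samples: int) -> np.ndarray:
    """Isotropic per-gene noise, optionally Pareto-tailed on a gene subset."""
    eps = rng.standard_normal((spec.n_genes, n_samples)) * spec.noise_sd_per_gene
    n_heavy = int(round(spec.heavy_tail_fraction * spec.n_genes))
    if n_heavy:
        # symmetric Pareto tail, scaled to the same order as the Gaussian part
        u = rng.random((n_heavy, n_samples))
        mag = u ** (-1.0 / (spec.heavy_tail_nu - 1.0)) - 1.0
        sign = rng.choice((-1.0, 1.0), size=(n_heavy, n_samples))
        eps[:n_heavy] = spec.noise_sd_per_gene * sign * mag
    return eps


def generate_cohort(spec: CohortSpec) -> ExpressionCohort:
    """Generate a two-cloud cohort with planted PC1 geometry.

    In log-fold space: normal samples are planted_rn·g·u plus isotropic
    noise (g standard normal), tumor samples planted_xbar1·u + planted_rt·g·u
    plus noise.  Expression values are reconstructed as e = e_ref·2^ê with
    positive per-gene references, so the geometric-mean reference stage is
    exercised on strictly positive data (``with_zeros`` injects a few zeros
    into normal samples to exercise the pseudocount path).
    """
    rng = np.random.default_rng(spec.seed)
    u = _unit_direction(spec, rng)

    # standardized latent coefficients (zero mean, unit rms) make the planted
    # radii exact by construction rather than subject to finite-sample drift
    def latent(n: int) -> np.ndarray:
        g = rng.standard_normal(n)
        g = g - g.mean()
        rms = np.sqrt(np.mean(g**2))
        return g / rms if rms > 0 else g

    ehat_n = spec.planted_rn * latent(spec.n_normal) * u[:, None]
    ehat_n += _noise(rng, spec, spec.n_normal)
    ehat_t = (spec.planted_xbar1 + spec.planted_rt * latent(spec.n_tumor)) * u[:, None]
    ehat_t += _noise(rng, spec, spec.n_tumor)
    ehat = np.hstack([ehat_n, ehat_t])

    e_ref = rng.uniform(1.0, 100.0, size=spec.n_genes)
    values = e_ref[:, None] * np.exp2(ehat)
    if spec.with_zeros:
        k = max(1, spec.n_genes // 100)
        values[rng.choice(spec.n_genes, k, replace=False), 0] = 0.0

    return ExpressionCohort(
        values=values,
        gene_ids=[f"g{i:05d}" for i in range(spec.n_genes)],
        sample_ids=[f"N{i:03d}" for i in range(spec.n_normal)]
        + [f"T{i:03d}" for i in range(spec.n_tumor)],
        labels=["normal"] * spec.n_normal + ["tumor"] * spec.n_tumor,
    )


@dataclass
class PlantedTableSpec:
    """Specification of a randomized tissue table with a planted risk law.

    Risks are generated from ln(risk/N_sc) = intercept_true +
    slope_true·ln(D·t/R) + N(0, scatter_sd²), t = log₂(N_sc) + m_sc·80.
    Ranges mirror the spread of the compiled 8-tissue table: D uniform in
    d_range, R in r_range, N_sc log-uniform in n_sc_range, m_sc log-uniform
    in m_sc_range.  intercept_true must be negative (a rare-jump rate below
    one); the default −28 keeps every planted risk below 1 over the whole
    parameter box, so the generative law stays exactly linear (no clamping)
    for moderate scatter.
    """

    n_tissues: int = 8
    slope_true: float = 1.0
    intercept_true: float = -28.0
    scatter_sd: float = 0.5
    d_range: tuple[float, float] = (0.044, 0.077)
    r_range: tuple[float, float] = (27.0, 147.0)
    n_sc_range: tuple[float, float] = (6.6e6, 8.7e9)
    m_sc_range: tuple[float, float] = (0.07, 73.0)
    age: float = 80.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_tissues < 2:
            raise ValueError("n_tissues must be >= 2")
        if self.intercept_true >= 0:
            raise ValueError("intercept_true must be negative")
        if self.scatter_sd < 0:
            raise ValueError("scatter_sd must be >= 0")
        for name in ("d_range", "r_range", "n_sc_range", "m_sc_range"):
            lo, hi = getattr(self, name)
            if not (0 < lo <= hi):
                raise ValueError(f"{name} must be positive with lo <= hi")


def generate_planted_table(spec: PlantedTableSpec) -> TissueTable:
    """Draw a tissue table whose risks follow the planted Lévy law."""
    rng = np.random.default_rng(spec.seed)
    n = spec.n_tissues
    d = rng.uniform(*spec.d_range, size=n)
    r = rng.uniform(*spec.r_range, size=n)
    n_sc = np.exp(rng.uniform(*np.log(spec.n_sc_range), size=n))
    m_sc = np.exp(rng.uniform(*np.log(spec.m_sc_range), size=n))
    t = np.log2(n_sc) + m_sc * spec.age

    log_rel_risk = (
        spec.intercept_true
        + spec.slope_true * np.log(d * t / r)
        + rng.normal(0.0, spec.scatter_sd, size=n)
    )
    risk = np.minimum(n_sc * np.exp(log_rel_risk), 1.0 - 1e-12)

    records = []
    for i in range(n):
        rn = r[i] * rng.uniform(0.1, 0.3)
        rt = r[i] * rng.uniform(0.2, 0.4)
        records.append(
            TissueRecord(
                tissue=f"SYN{i:02d}",
                xbar1=float(r[i] + rn + rt),
                rn=float(rn),
                rt=float(rt),
                r_walk=float(r[i]),
                d_scale=float(d[i]),
                n_sc=float(n_sc[i]),
                m_sc=float(m_sc[i]),
                risk=float(risk[i]),
                dev=float(risk[i]) * 0.3,
            )
        )
    return TissueTable(records=tuple(records), provenance=f"planted seed={spec.seed}")
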