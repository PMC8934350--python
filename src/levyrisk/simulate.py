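"""Discrete-time stochastic simulator of microstate trajectories.

Each walker is a tissue microstate coordinate x₁ along the cancer axis,
starting at the origin (normal-cloud center).  Per generation it takes a
small uniform step δx₁ = D·r with r ~ U(−1, 1), then with probability μ a
Lévy jump whose magnitude follows a Pareto law with scale D and tail
exponent ν (survival (D/x)^(ν−1) for x ≥ D), signed symmetrically by
default.  A walker is absorbed — counted as an escape to the tumor basin —
the first generation its position reaches the boundary at x₁ = R (checked
after the jump sub-step; generations are 0-based).  Escaped walkers stop
evolving.

The ensemble summary validates the closed-form risk expressions: with μ = 0
the displacement variance grows as t·D²/3 (the per-step variance of a
uniform step), and for rare jumps (μt ≪ 1, R/D ≫ 1) the escape fraction is
½·μ·t·(D/R)^(ν−1) with two-sided jumps.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SimConfig",
    "TrajectoryEnsembleSummary",
    "step_small",
    "step_levy",
    "sample_jump_magnitudes",
    "run_ensemble",
]

JUMP_SYMMETRIES = ("two-sided", "positive-only")


@dataclass
class SimConfig:
    """Configuration of one walker ensemble.

    d_scale is the small-step scale D; r_walk the absorbing-boundary
    distance R; mu the per-generation large-jump probability; nu the Pareto
    exponent of jump magnitudes; the ensemble runs n_walkers walkers for
    n_generations generations from a single seed.
    """

    d_scale: float
    r_walk: float
    mu: float = 0.0
    nu: float = 2.0
    n_walkers: int = 1000
    n_generations: int = 100
    seed: int = 0
    jump_symmetry: str = "two-sided"

    def __post_init__(self) -> None:
        if self.d_scale < 0:
            raise ValueError("d_scale must be >= 0")
        if self.r_walk <= 0:
            raise ValueError("r_walk must be > 0")
        if not 0.0 <= self.mu <= 1.0:
            raise ValueError("mu must lie in [0, 1]")
        if self.nu <= 1:
            raise ValueError("nu must be > 1")
        if self.n_walkers < 1 or self.n_generations < 1:
            raise ValueError("n_walkers and n_generations must be >= 1")
        if self.jump_symmetry not in JUMP_SYMMETRIES:
            raise ValueError(f"jump_symmetry must be one of {JUMP_SYMMETRIES}")


@dataclass
class TrajectoryEnsembleSummary:
    """First-passage counts and displacement moments of an ensemble run.

    mean_displacement and displacement_variance are computed over the
    surviving (never-absorbed) walkers; first_passage_times holds the
    0-based absorption generation of each escaped walker.
    """

    n_walkers: int
    n_generations: int
    n_escaped: int
    escape_fraction: float
    mean_displacement: float
    displacement_variance: float
    first_passage_times: np.ndarray
    seed: int

    def to_dict(self) -> dict:
        return {
            "n_walkers": self.n_walkers,
            "n_generations": self.n_generations,
            "n_escaped": self.n_escaped,
            "escape_fraction": self.escape_fraction,
            "mean_displacement": self.mean_displacement,
            "displacement_variance": self.displacement_variance,
            "seed": self.seed,
        }


def step_small(x1: np.ndarray, rng: np.random.Generator, d_scale: float) -> np.ndarray:
    """One small step per walker: x₁ + D·r with r ~ U(−1, 1)."""
    x1 = np.asarray(x1, dtype=float)
    return x1 + d_scale * rng.uniform(-1.0, 1.0, size=x1.shape)


def sample_jump_magnitudes(
    rng: np.random.Generator, d_scale: float, nu: float, size
) -> np.ndarray:
    """Pareto magnitudes with scale D and survival (D/x)^(ν−1), x ≥ D.

    Inverse-CDF sampling: x = D·U^(−1/(ν−1)) with U ~ U(0, 1).
    """
    if nu <= 1:
        raise ValueError("nu must be > 1")
    u = rng.random(size)
    return d_scale * u ** (-1.0 / (nu - 1.0))


def step_levy(
    x1: np.ndarray,
    rng: np.random.Generator,
    mu: float,
    nu: float,
    d_scale: float,
    jump_symmetry: str = "two-sided",
) -> np.ndarray:
    """With probability μ per walker, add a signed Pareto jump."""
    if jump_symmetry not in JUMP_SYMMETRIES:
        raise ValueError(f"jump_symmetry must be one of {JUMP_SYMMETRIES}")
    x1 = np.asarray(x1, dtype=float).copy()
    jumps = rng.random(x1.shape) < mu
    n_jump = int(jumps.sum())
    if n_jump:
        mag = sample_jump_magnitudes(rng, d_scale, nu, n_jump)
        if jump_symmetry == "two-sided":
            mag = mag * rng.choice((-1.0, 1.0), size=n_jump)
        x1[jumps] += mag
    return x1


def run_ensemble(config: SimConfig) -> TrajectoryEnsembleSummary:
    """Evolve the ensemble and summarize first passage at x₁ ≥ R.

    All walkers start at the origin; each generation applies the small step
    then the jump sub-step; absorption is checked once per generation, after
    the jump.  Identical config and seed give identical output.
    """
    rng = np.random.default_rng(config.seed)
    x1 = np.zeros(config.n_walkers)
    alive = np.ones(config.n_walkers, dtype=bool)
    fpt = np.full(config.n_walkers, -1, dtype=np.int64)

    for gen in range(config.n_generations):
        idx = np.flatnonzero(alive)
        if idx.size == 0:
            break
        x = step_small(x1[idx], rng, config.d_scale)
        x = step_levy(x, rng, config.mu, config.nu, config.d_scale, config.jump_symmetry)
        x1[idx] = x
        escaped = x >= config.r_walk
        if escaped.any():
            hit = idx[escaped]
            alive[hit] = False
            fpt[hit] = gen

    survivors = x1[alive]
    n_escaped = int((~alive).sum())
    return TrajectoryEnsembleSummary(
        n_walkers=config.n_walkers,
        n_generations=config.n_generations,
        n_escaped=n_escaped,
        escape_fraction=n_escaped / config.n_walkers,
        mean_displacement=float(survivors.mean()) if survivors.size else float("nan"),
        displacement_variance=float(survivors.var()) if survivors.size else float("nan"),
        first_passage_times=np.sort(fpt[fpt >= 0]),
        seed=config.seed,
    )
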