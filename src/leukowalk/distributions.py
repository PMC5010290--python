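"""Random-variate samplers for the four statistical families used to model
cell translational and turn speeds: uniform, Lévy, homogeneous Gaussian,
and the hierarchical "heterogeneous Gaussian" in which every cell (group)
owns a bespoke Gaussian whose mean and spread are themselves Gaussian draws
made once at creation.

The Lévy sampler follows the Chambers–Mallows–Stuck construction

    L(α, β) = β · sin(αX)/cos(X)^{1/α} · (cos((1−α)X)/Y)^{(1−α)/α}

with X uniform on [−π/2, π/2] and Y = −ln Z, Z uniform on [0, 1].  L is
symmetric about 0, so consumers take |L| for speed-like quantities.

Note on notation: the Gaussian families are written G(μ, σ²) in the
motility literature this package follows, but the second parameter is used
as the standard deviation of the normal sampler (it is itself drawn from a
Gaussian in the heterogeneous family, which can yield negative values —
these are clamped at 0, a degenerate point mass).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "UniformParams",
    "LevyParams",
    "HomoGaussianParams",
    "HeteroGaussianParams",
    "sample_uniform",
    "sample_levy",
    "sample_homo_gaussian",
    "make_hetero_gaussian_group",
]


@dataclass(frozen=True)
class UniformParams:
    """U(λ): uniform over (0, λ]. Units contextual (µm/min or °/min)."""

    lam: float

    def __post_init__(self):
        if not self.lam > 0:
            raise ValueError("uniform upper bound lam must be > 0")


@dataclass(frozen=True)
class LevyParams:
    """L(α, β): stability exponent α in (0, 2], scale β > 0."""

    alpha: float
    beta: float

    def __post_init__(self):
        if not (0 < self.alpha <= 2):
            raise ValueError(f"Levy alpha must lie in (0, 2], got {self.alpha}")
        if not self.beta > 0:
            raise ValueError("Levy beta must be > 0")


@dataclass(frozen=True)
class HomoGaussianParams:
    """G(μ, σ): one Gaussian shared by all cells; sigma is the SD."""

    mu: float
    sigma: float

    def __post_init__(self):
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")


@dataclass(frozen=True)
class HeteroGaussianParams:
    """Hyper-parameters of the per-cell Gaussian generator:
    μ_i ~ G(mu_m, sigma_m), σ_i ~ G(mu_s, sigma_s), drawn once per cell."""

    mu_m: float
    sigma_m: float
    mu_s: float
    sigma_s: float

    def __post_init__(self):
        if self.sigma_m < 0 or self.sigma_s < 0:
            raise ValueError("hyper-sigmas must be >= 0")


def sample_uniform(p: UniformParams, rng: np.random.Generator, n: int) -> np.ndarray:
    """n draws from (0, λ]; the open-at-zero endpoint is enforced by
    reflecting the half-open [0, λ) interval."""
    return p.lam * (1.0 - rng.random(n))


def sample_levy(p: LevyParams, rng: np.random.Generator, n: int) -> np.ndarray:
    """n non-negative Lévy variates |L(α, β)|; heavy-tailed for α < 2."""
    a = p.alpha
    x = rng.uniform(-np.pi / 2, np.pi / 2, size=n)
    y = -np.log(1.0 - rng.random(n))  # unit exponential, avoids log(0)
    core = np.sin(a * x) / np.cos(x) ** (1.0 / a)
    tail = (np.cos((1.0 - a) * x) / y) ** ((1.0 - a) / a)
    return np.abs(p.beta * core * tail)


def sample_homo_gaussian(
    p: HomoGaussianParams, rng: np.random.Generator, n: int, absolute: bool = False
) -> np.ndarray:
    """n Gaussian variates; ``absolute`` folds to |x| for magnitudes
    (cells do not move backwards)."""
    out = rng.normal(p.mu, p.sigma, size=n)
    return np.abs(out) if absolute else out


def make_hetero_gaussian_group(
    p: HeteroGaussianParams, rng: np.random.Generator
) -> HomoGaussianParams:
    """Instantiate one cell's bespoke Gaussian: draw (μ_i, σ_i) once.

    A negative drawn σ_i is clamped to 0 (point mass), keeping the sampler
    total; calibration avoids such regions if they fit poorly.
    """
    mu_i = rng.normal(p.mu_m, p.sigma_m)
    sigma_i = max(rng.normal(p.mu_s, p.sigma_s), 0.0)
    return HomoGaussianParams(mu=mu_i, sigma=sigma_i)
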