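"""Per-timestep update rules for the six 3D random-walk models.

Models (gene-vector ordering in parentheses, the calibration encoding):

* ``brownian``    (σ) — fresh uniform-sphere heading each step, speed |G(0, σ)|.
* ``levy``        (α_T, β_T, α_D, β_D) — straight runs at speed s ~ |L(α_T, β_T)|
  for duration d ~ |L(α_D, β_D)| seconds, uniform reorientation between runs.
* ``homoCRW``     (μ_P, σ_P, μ_T, σ_T) — turn speed ϕ_t ~ G(μ_P, σ_P) °/min and
  translation ζ_t = |G(μ_T, σ_T)| µm/min, shared by all cells.  The turn
  angle |ϕ_t|·dt/60 is applied about a uniformly random axis perpendicular
  to the current heading, so planes of successive turns are uncorrelated.
* ``heteroCRW``   (μ_PM, σ_PM, μ_PS, σ_PS, μ_TM, σ_TM, μ_TS, σ_TS) — as
  homoCRW but each cell owns bespoke Gaussians whose (μ_i, σ_i) are drawn
  once at birth from the hyper-Gaussians.
* ``ihomoCRW``    (homoCRW genes…, β) — inverse coupling: ζ_t is drawn first
  and the turn speed is scaled by (ζ_max^β − ζ_t^β)/ζ_max^β, so fast steps
  turn less.  ζ_max is fixed at 25 µm/min (empirical in vivo maximum).
* ``iheteroCRW``  (heteroCRW genes…, β) — heterogeneous + inverse coupling.

Turn-speed Gaussians may emit negative values; rotations use |ϕ_t| (the
random rotation axis already symmetrises direction).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .distributions import (
    HeteroGaussianParams,
    HomoGaussianParams,
    LevyParams,
    make_hetero_gaussian_group,
    sample_levy,
)

__all__ = [
    "WalkerParams",
    "CellState",
    "StepOutcome",
    "WalkerCohort",
    "MODEL_ARITY",
    "MODEL_NAMES",
    "ZETA_MAX",
    "inverse_turn_scale",
    "step_brownian",
    "step_levy",
    "step_crw",
    "step_inverse_crw",
]

#: Maximum translational speed (µm/min) in the inverse coupling factor.
ZETA_MAX = 25.0

#: Internal update interval (s) for the Lévy walk's run clock.
LEVY_UPDATE_S = 3.0

MODEL_ARITY = {
    "brownian": 1,
    "levy": 4,
    "homoCRW": 4,
    "heteroCRW": 8,
    "ihomoCRW": 5,
    "iheteroCRW": 9,
}
MODEL_NAMES = tuple(MODEL_ARITY)

#: Named genes per model, in calibration encoding order.
MODEL_GENES = {
    "brownian": ("sigma",),
    "levy": ("alpha_t", "beta_t", "alpha_d", "beta_d"),
    "homoCRW": ("mu_p", "sigma_p", "mu_t", "sigma_t"),
    "heteroCRW": (
        "mu_pm", "sigma_pm", "mu_ps", "sigma_ps",
        "mu_tm", "sigma_tm", "mu_ts", "sigma_ts",
    ),
    "ihomoCRW": ("mu_p", "sigma_p", "mu_t", "sigma_t", "beta"),
    "iheteroCRW": (
        "mu_pm", "sigma_pm", "mu_ps", "sigma_ps",
        "mu_tm", "sigma_tm", "mu_ts", "sigma_ts", "beta",
    ),
}


@dataclass(frozen=True)
class WalkerParams:
    """A model tag plus its gene vector (see MODEL_GENES for ordering)."""

    model: str
    values: tuple
    zeta_max: float = ZETA_MAX

    def __post_init__(self):
        if self.model not in MODEL_ARITY:
            raise ValueError(f"unknown model {self.model!r}")
        vals = tuple(float(v) for v in self.values)
        if len(vals) != MODEL_ARITY[self.model]:
            raise ValueError(
                f"{self.model} takes {MODEL_ARITY[self.model]} parameters, got {len(vals)}"
            )
        if self.zeta_max <= 0:
            raise ValueError("zeta_max must be > 0")
        if self.model in ("ihomoCRW", "iheteroCRW") and vals[-1] <= 0:
            raise ValueError("inverse-coupling exponent beta must be > 0")
        if self.model == "levy":
            for a in (vals[0], vals[2]):
                if not (0 < a <= 2):
                    raise ValueError("Levy alpha parameters must lie in (0, 2]")
        object.__setattr__(self, "values", vals)

    def __getattr__(self, name):
        if name.startswith("_"):
            raise AttributeError(name)
        genes = MODEL_GENES[object.__getattribute__(self, "model")]
        if name in genes:
            return self.values[genes.index(name)]
        raise AttributeError(name)

    def as_dict(self) -> dict:
        return dict(zip(MODEL_GENES[self.model], self.values))


@dataclass
class StepOutcome:
    new_heading: np.ndarray
    step_speed: float  # ζ_t, µm/min
    turn_speed: float  # ϕ_t magnitude actually applied, °/min


@dataclass
class CellState:
    """Mutable per-cell simulation state (scalar API)."""

    position: np.ndarray
    heading: np.ndarray
    radius: float = 5.0
    trans_dist: HomoGaussianParams | None = None  # bespoke (hetero models)
    turn_dist: HomoGaussianParams | None = None
    levy_run_remaining: float = 0.0
    levy_run_speed: float = 0.0

    def __post_init__(self):
        h = np.asarray(self.heading, dtype=float)
        n = np.linalg.norm(h)
        if abs(n - 1.0) > 1e-9:
            raise ValueError("heading must be unit length")
        self.heading = h
        self.position = np.asarray(self.position, dtype=float)
        if self.radius <= 0:
            raise ValueError("radius must be > 0")


def uniform_sphere(rng: np.random.Generator, n: int) -> np.ndarray:
    """n unit vectors uniform on the sphere (area-correct)."""
    v = rng.normal(size=(n, 3))
    return v / np.linalg.norm(v, axis=1, keepdims=True)


def _random_perpendicular(headings: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Unit vectors uniform on the circle perpendicular to each heading
    (Gram–Schmidt on isotropic Gaussian draws)."""
    g = rng.normal(size=headings.shape)
    g -= np.sum(g * headings, axis=1, keepdims=True) * headings
    norms = np.linalg.norm(g, axis=1, keepdims=True)
    # a Gaussian draw exactly parallel to the heading has measure zero;
    # guard anyway by redrawing deterministically off-axis
    bad = norms[:, 0] < 1e-12
    if bad.any():
        alt = np.zeros_like(g[bad])
        alt[:, 0] = 1.0
        alt -= np.sum(alt * headings[bad], axis=1, keepdims=True) * headings[bad]
        g[bad] = alt
        norms = np.linalg.norm(g, axis=1, keepdims=True)
    return g / norms


def rotate_headings(
    headings: np.ndarray, angles_rad: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Rotate each heading by its angle about a random perpendicular axis,
    i.e. tilt within a uniformly random plane containing the heading."""
    perp = _random_perpendicular(headings, rng)
    ang = angles_rad[:, None]
    out = np.cos(ang) * headings + np.sin(ang) * perp
    return out / np.linalg.norm(out, axis=1, keepdims=True)


def inverse_turn_scale(zeta: np.ndarray, beta: float, zeta_max: float = ZETA_MAX):
    """(ζ_max^β − ζ_t^β)/ζ_max^β with ζ_t clamped at ζ_max inside the factor
    only: 1 for a stationary cell, 0 at the maximum translational speed."""
    z = np.minimum(zeta, zeta_max)
    return (zeta_max**beta - z**beta) / zeta_max**beta


class WalkerCohort:
    """Vectorised stepping of n cells under one model parameterisation.

    Holds headings plus any per-cell state (bespoke Gaussians for the
    heterogeneous models, run clocks for the Lévy walk).  One ``step(dt)``
    call advances every cell and returns (headings, ζ µm/min, applied
    |ϕ| °/min); the caller owns positions.
    """

    def __init__(self, params: WalkerParams, n: int, rng: np.random.Generator):
        self.params = params
        self.n = n
        self.rng = rng
        self.headings = uniform_sphere(rng, n)
        m = params.model
        if m in ("heteroCRW", "iheteroCRW"):
            hp_turn = HeteroGaussianParams(
                params.mu_pm, params.sigma_pm, params.mu_ps, params.sigma_ps
            )
            hp_trans = HeteroGaussianParams(
                params.mu_tm, params.sigma_tm, params.mu_ts, params.sigma_ts
            )
            # vectorised once-at-birth draws, clamping negative per-cell sigmas
            self.mu_p = rng.normal(hp_turn.mu_m, hp_turn.sigma_m, n)
            self.sigma_p = np.maximum(rng.normal(hp_turn.mu_s, hp_turn.sigma_s, n), 0.0)
            self.mu_t = rng.normal(hp_trans.mu_m, hp_trans.sigma_m, n)
            self.sigma_t = np.maximum(rng.normal(hp_trans.mu_s, hp_trans.sigma_s, n), 0.0)
        elif m in ("homoCRW", "ihomoCRW"):
            self.mu_p = np.full(n, params.mu_p)
            self.sigma_p = np.full(n, params.sigma_p)
            self.mu_t = np.full(n, params.mu_t)
            self.sigma_t = np.full(n, params.sigma_t)
        elif m == "levy":
            self.run_remaining = np.zeros(n)  # expired: draw at first step
            self.run_speed = np.zeros(n)

    def step(self, dt: float):
        """Advance one update interval of dt seconds.

        Returns (headings (n,3), step speeds ζ_t µm/min, applied turn-speed
        magnitudes °/min).  For the Lévy walk the turn-speed channel is not
        meaningful (reorientations are instantaneous) and is returned as 0.
        """
        m, rng, n = self.params.model, self.rng, self.n
        if m == "brownian":
            self.headings = uniform_sphere(rng, n)
            zeta = np.abs(rng.normal(0.0, self.params.sigma, n))
            return self.headings, zeta, np.zeros(n)
        if m == "levy":
            expired = self.run_remaining <= 0
            k = int(expired.sum())
            if k:
                self.headings[expired] = uniform_sphere(rng, k)
                self.run_speed[expired] = sample_levy(
                    LevyParams(self.params.alpha_t, self.params.beta_t), rng, k
                )
                self.run_remaining[expired] = sample_levy(
                    LevyParams(self.params.alpha_d, self.params.beta_d), rng, k
                )
            self.run_remaining -= dt
            return self.headings, self.run_speed.copy(), np.zeros(n)
        # CRW family
        phi = rng.normal(self.mu_p, self.sigma_p)
        zeta = np.abs(rng.normal(self.mu_t, self.sigma_t))
        if m in ("ihomoCRW", "iheteroCRW"):
            phi = phi * inverse_turn_scale(zeta, self.params.beta, self.params.zeta_max)
        applied = np.abs(phi)
        angles = np.radians(applied * dt / 60.0)
        self.headings = rotate_headings(self.headings, angles, rng)
        return self.headings, zeta, applied


# ---------------------------------------------------------------------------
# Scalar per-cell API (thin wrappers over the vectorised core)


def _scalar_outcome(headings, zeta, phi) -> StepOutcome:
    return StepOutcome(headings[0], float(zeta[0]), float(phi[0]))


def step_brownian(
    state: CellState, params: WalkerParams, dt: float, rng: np.random.Generator
) -> StepOutcome:
    h = uniform_sphere(rng, 1)
    zeta = abs(rng.normal(0.0, params.sigma))
    state.heading = h[0]
    return StepOutcome(h[0], float(zeta), 0.0)


def step_levy(
    state: CellState, params: WalkerParams, dt: float, rng: np.random.Generator
) -> StepOutcome:
    if state.levy_run_remaining <= 0:
        state.heading = uniform_sphere(rng, 1)[0]
        state.levy_run_speed = float(
            sample_levy(LevyParams(params.alpha_t, params.beta_t), rng, 1)[0]
        )
        state.levy_run_remaining = float(
            sample_levy(LevyParams(params.alpha_d, params.beta_d), rng, 1)[0]
        )
    state.levy_run_remaining -= dt
    return StepOutcome(state.heading, state.levy_run_speed, 0.0)


def _crw_dists(state: CellState, params: WalkerParams):
    if params.model in ("heteroCRW", "iheteroCRW"):
        if state.turn_dist is None or state.trans_dist is None:
            raise ValueError(
                "heterogeneous models need per-cell distributions; "
                "initialise CellState via make_hetero_gaussian_group"
            )
        return state.turn_dist, state.trans_dist
    return (
        HomoGaussianParams(params.mu_p, params.sigma_p),
        HomoGaussianParams(params.mu_t, params.sigma_t),
    )


def step_crw(
    state: CellState, params: WalkerParams, dt: float, rng: np.random.Generator
) -> StepOutcome:
    """Shared homoCRW / heteroCRW update: turn then translate."""
    turn_d, trans_d = _crw_dists(state, params)
    phi = abs(rng.normal(turn_d.mu, turn_d.sigma))
    angle = np.radians(phi * dt / 60.0)
    state.heading = rotate_headings(state.heading[None, :], np.array([angle]), rng)[0]
    zeta = abs(rng.normal(trans_d.mu, trans_d.sigma))
    return StepOutcome(state.heading, float(zeta), float(phi))


def step_inverse_crw(
    state: CellState, params: WalkerParams, dt: float, rng: np.random.Generator
) -> StepOutcome:
    """ihomoCRW / iheteroCRW update: draw ζ_t first, damp the turn by the
    inverse-coupling factor, then rotate and translate."""
    turn_d, trans_d = _crw_dists(state, params)
    zeta = abs(rng.normal(trans_d.mu, trans_d.sigma))
    scale = float(inverse_turn_scale(np.array([zeta]), params.beta, params.zeta_max)[0])
    phi = abs(rng.normal(turn_d.mu, turn_d.sigma)) * scale
    angle = np.radians(phi * dt / 60.0)
    state.heading = rotate_headings(state.heading[None, :], np.array([angle]), rng)[0]
    return StepOutcome(state.heading, float(zeta), float(phi))
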