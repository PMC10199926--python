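"""Agent-based random walkers with position- and direction-dependent jumps.

One walker updates its position r = (x, y) once per run/tumble cycle:

    r(n+1) = r(n) + lambda(x(n)) * (1 + b cos(theta)) * e(theta),

with theta drawn uniformly on the circle (the *only* random factor),
lambda(x) = lambda0 + alpha * x the position-dependent jump length, and
``b`` the directional bias toward theta = 0 (down-gradient).  The chamber
walls are zero-flux: an overshoot is mirror-reflected back inside.

Two step modes are provided: the exact angular update above, and its
Gaussian surrogate

    x(n+1) = x(n) + (b/2) lambda(x) + lambda(x) N(0, sigma^2),

obtained by replacing the zero-mean random factor by white noise with
sigma = 1/sqrt(2), the standard deviation of cos(theta).  Both converge to
the same stationary law for small bias.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np

from .binning import BinnedDensity, bin_positions
from .exceptions import ConfigError, DomainError
from .laws import PositionJumpLaw

__all__ = [
    "SIGMA_COS_THETA",
    "WalkerParams",
    "DomainConfig",
    "SimConfig",
    "PositionSamples",
    "draw_direction",
    "bias_factor",
    "step_1d",
    "step_2d",
    "step_gaussian",
    "apply_boundary",
    "simulate_ensemble",
    "empirical_distribution",
]

#: Standard deviation of cos(theta) for uniform theta.
SIGMA_COS_THETA = 1.0 / math.sqrt(2.0)


@dataclass(frozen=True)
class WalkerParams:
    """Parameters of the discrete walker.

    ``lambda0`` and ``alpha`` define the jump-length field
    lambda(x) = lambda0 + alpha * x; ``b`` is the directional bias of the
    multiplier 1 + b cos(theta); ``step_time`` is the duration of one cycle.
    With step_time = 1 the SDE parameters (beta, lambda) coincide numerically
    with (b, l); for other step times beta = b * sqrt(step_time) and the
    length field is scaled by sqrt(step_time).
    """

    lambda0: float = 1.0
    alpha: float = 0.01
    b: float = 0.05
    step_time: float = 1.0

    def __post_init__(self) -> None:
        if not abs(self.b) < 1:
            raise ConfigError("|b| must be < 1 so that 1 + b cos(theta) stays positive")
        if not self.lambda0 > 0:
            raise ConfigError("lambda0 must be positive")
        if not self.step_time > 0:
            raise ConfigError("step_time must be positive")

    @property
    def beta(self) -> float:
        """Drift bias of the continuum limit, b * sqrt(step_time)."""
        return self.b * math.sqrt(self.step_time)

    def jump_length(self, x: Union[float, np.ndarray]) -> Union[float, np.ndarray]:
        lam = self.lambda0 + self.alpha * np.asarray(x, dtype=float)
        if np.any(lam <= 0):
            raise DomainError("lambda(x) must stay positive over the domain")
        return lam

    def sde_length_field(self) -> PositionJumpLaw:
        """lambda(x) of the continuum SDE, scaled by sqrt(step_time)."""
        s = math.sqrt(self.step_time)
        return PositionJumpLaw(slope_a=self.alpha * s, intercept_l0=self.lambda0 * s)

    @classmethod
    def from_position_law(
        cls, poslaw: PositionJumpLaw, b: float, step_time: float = 1.0
    ) -> "WalkerParams":
        return cls(
            lambda0=poslaw.intercept_l0, alpha=poslaw.slope_a, b=b, step_time=step_time
        )


@dataclass(frozen=True)
class DomainConfig:
    """The 1D chamber [0, L] with reflecting (zero-flux) walls."""

    length_L: float = 100.0
    boundary: str = "reflecting"

    def __post_init__(self) -> None:
        if not self.length_L > 0:
            raise ConfigError("length_L must be positive")
        if self.boundary != "reflecting":
            raise ConfigError(f"unknown boundary rule {self.boundary!r}")


@dataclass(frozen=True)
class SimConfig:
    """Ensemble size, horizon and reproducibility controls."""

    n_walkers: int = 2000
    n_steps: int = 5000
    burn_in: int = 2500
    seed: int = 0
    initial: Union[str, float, Sequence[float]] = "uniform"

    def __post_init__(self) -> None:
        if self.n_walkers < 1:
            raise ConfigError("n_walkers must be at least 1")
        if not self.n_steps > self.burn_in >= 0:
            raise ConfigError("need n_steps > burn_in >= 0")


@dataclass(frozen=True)
class PositionSamples:
    """Post-burn-in walker positions, pooled over walkers and steps.

    ``matrix`` has shape (n_recorded_steps, n_walkers); ``values`` is the
    pooled flat view.  Pooling over 2000 independent walkers or over the
    trials of a single long walker are statistically equivalent for
    stationary estimates; both views are available.
    """

    matrix: np.ndarray
    params: WalkerParams
    domain: DomainConfig
    config: SimConfig
    mode: str

    @property
    def values(self) -> np.ndarray:
        return self.matrix.ravel()

    @property
    def n_pooled(self) -> int:
        return int(self.matrix.size)

    def walker(self, i: int) -> np.ndarray:
        """Recorded positions of a single walker (single-trajectory pooling)."""
        return self.matrix[:, i]


def draw_direction(
    rng: np.random.Generator, size: Optional[int] = None
) -> Union[float, np.ndarray]:
    """Uniform jump direction(s) theta in [-pi, pi)."""
    out = rng.uniform(-math.pi, math.pi, size)
    return out


def bias_factor(b: float, theta: Union[float, np.ndarray]) -> Union[float, np.ndarray]:
    """Directional multiplier xi(theta) = 1 + b cos(theta); positive for |b| < 1."""
    if not abs(b) < 1:
        raise ConfigError("|b| must be < 1")
    return 1.0 + b * np.cos(theta)


def step_1d(
    x: Union[float, np.ndarray],
    theta: Union[float, np.ndarray],
    params: WalkerParams,
) -> Union[float, np.ndarray]:
    """x-projection of one biased jump, before boundary handling."""
    lam = params.jump_length(x)
    c = np.cos(theta)
    return x + lam * (1.0 + params.b * c) * c


def step_2d(
    r: np.ndarray, theta: Union[float, np.ndarray], params: WalkerParams
) -> np.ndarray:
    """Full 2D jump r + l(x) xi(theta) e(theta); the x-component equals step_1d."""
    r = np.asarray(r, dtype=float)
    x = r[..., 0]
    lam = params.jump_length(x)
    step = lam * bias_factor(params.b, theta)
    return np.stack([x + step * np.cos(theta), r[..., 1] + step * np.sin(theta)], axis=-1)


def step_gaussian(
    x: Union[float, np.ndarray],
    params: WalkerParams,
    sigma: float,
    rng: np.random.Generator,
) -> Union[float, np.ndarray]:
    """Gaussian-surrogate step: drift (b/2) lambda(x) plus lambda(x) N(0, sigma^2)."""
    if not sigma > 0:
        raise ConfigError("sigma must be positive")
    lam = params.jump_length(x)
    noise = rng.normal(0.0, sigma, np.shape(x) if np.ndim(x) else None)
    return x + 0.5 * params.b * lam + lam * noise


def apply_boundary(
    x: Union[float, np.ndarray], domain: DomainConfig
) -> Union[float, np.ndarray]:
    """Mirror-reflect an overshoot back into [0, L], repeatedly if needed.

    Implemented as the triangle-wave fold of period 2L, which applies the
    mirror rule (x < 0 -> -x, x > L -> 2L - x) any number of times at once.
    """
    xv = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(xv)):
        raise DomainError("cannot reflect a non-finite position")
    L = domain.length_L
    y = np.mod(xv, 2.0 * L)
    folded = np.where(y > L, 2.0 * L - y, y)
    return float(folded) if np.isscalar(x) else folded


def _initial_positions(sim: SimConfig, domain: DomainConfig, rng: np.random.Generator) -> np.ndarray:
    if isinstance(sim.initial, str):
        if sim.initial == "uniform":
            return rng.uniform(0.0, domain.length_L, sim.n_walkers)
        if sim.initial == "point":
            return np.full(sim.n_walkers, domain.length_L / 2.0)
        raise ConfigError(f"unknown initial-position rule {sim.initial!r}")
    if np.isscalar(sim.initial):
        x0 = float(sim.initial)
        if not 0.0 <= x0 <= domain.length_L:
            raise ConfigError("initial position outside [0, L]")
        return np.full(sim.n_walkers, x0)
    arr = np.asarray(sim.initial, dtype=float)
    if arr.shape != (sim.n_walkers,):
        raise ConfigError("explicit initial positions must have length n_walkers")
    if np.any(arr < 0) or np.any(arr > domain.length_L):
        raise ConfigError("initial positions outside [0, L]")
    return arr.copy()


def simulate_ensemble(
    params: WalkerParams,
    domain: DomainConfig,
    sim: SimConfig,
    mode: str = "angular",
    sigma: float = SIGMA_COS_THETA,
) -> PositionSamples:
    """Run N independent walkers and record positions after burn-in.

    The draw order is fixed for reproducibility: initial positions first
    (when the uniform rule is used), then one vector of theta (or Gaussian)
    draws for walkers 0..N-1 at each step.
    """
    if mode not in ("angular", "gaussian"):
        raise ConfigError(f"unknown step mode {mode!r}")
    # the whole domain must be valid before any stepping
    params.jump_length(np.array([0.0, domain.length_L]))

    rng = np.random.default_rng(sim.seed)
    x = _initial_positions(sim, domain, rng)
    n_record = sim.n_steps - sim.burn_in
    recorded = np.empty((n_record, sim.n_walkers))
    for step in range(sim.n_steps):
        if mode == "angular":
            theta = draw_direction(rng, sim.n_walkers)
            x = step_1d(x, theta, params)
        else:
            x = step_gaussian(x, params, sigma, rng)
        x = apply_boundary(x, domain)
        if step >= sim.burn_in:
            recorded[step - sim.burn_in] = x
    return PositionSamples(matrix=recorded, params=params, domain=domain, config=sim, mode=mode)


def empirical_distribution(samples: PositionSamples, n_bins: int) -> BinnedDensity:
    """Equal-width density histogram of the pooled positions over [0, L]."""
    return bin_positions(samples.values, n_bins, samples.domain.length_L)
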