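"""Continuum reduction of the biased walker and its stationary law.

Writing one cycle as

    x(n+1) = x(n) + (b/2) l(x) + l(x) (cos(theta) + (b/2) cos(2*theta)),

the zero-mean random factor has variance 1/2 + b^2/8 and is replaced by
Gaussian white noise with sigma = 1/sqrt(2) (the b = 0 value).  Under the
Ito interpretation the cycle-time continuum limit is

    dx = f(x) dt + g(x) dW,   f = (beta/2) lambda(x),   g = lambda(x) sigma,

whose Fokker-Planck equation

    dP/dt = -(beta/2) d/dx [lambda P] + (sigma^2/2) d^2/dx^2 [lambda^2 P]

has, for linear lambda(x) = lambda0 + alpha x on [0, L] with zero-flux
walls and sigma = 1/sqrt(2), the closed-form stationary solution

    P(x) = (1/c0) (lambda0 + alpha x)^(2 (kappa - 1)),   kappa = beta / alpha.

kappa is the chemotaxis switch: kappa > 1 accumulates walkers where jumps
are long (here: away from the Fe2+ source), kappa < 1 the opposite, and
kappa = 1 gives a uniform occupancy.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import NamedTuple, Optional

import numpy as np

from .exceptions import ConfigError, DomainError, StabilityError
from .simulate import SIGMA_COS_THETA, WalkerParams

__all__ = [
    "kappa_of",
    "RandomTermMoments",
    "random_term_moments",
    "normalization_c0",
    "StationaryDistribution",
    "FokkerPlanckSolution",
    "evolve_fokker_planck",
]

#: Below this distance from the removable singularity at 2*kappa - 1 = 0 the
#: logarithmic closed form is used.
_KAPPA_HALF_TOL = 1e-8


def kappa_of(alpha: float, beta: float) -> float:
    """Chemotaxis parameter kappa = beta / alpha.

    ``alpha = 0`` (homogeneous jump length, pure drift) has no stationary
    power law and is rejected.
    """
    if alpha == 0:
        raise DomainError(
            "kappa is undefined for alpha = 0 (homogeneous jump length); the "
            "pure-drift case has no power-law stationary distribution"
        )
    return beta / alpha


class RandomTermMoments(NamedTuple):
    mean: float
    variance: float
    #: the white-noise approximation actually used in the continuum limit
    variance_approx: float


def random_term_moments(b: float) -> RandomTermMoments:
    """Moments of the random factor cos(theta) + (b/2) cos(2*theta).

    For uniform theta the mean vanishes and the exact variance is
    1/2 + b^2/8 (the cross term integrates to zero).  The continuum
    reduction approximates it by the b-independent value 1/2.
    """
    if not abs(b) < 1:
        raise ConfigError("|b| must be < 1")
    return RandomTermMoments(mean=0.0, variance=0.5 + b * b / 8.0, variance_approx=0.5)


def normalization_c0(lambda0: float, alpha: float, kappa: float, length_L: float) -> float:
    """Normalization c0 = integral_0^L (lambda0 + alpha x)^(2 kappa - 2) dx.

    Closed form, with the removable singularity at kappa = 1/2 handled by
    the exact logarithmic antiderivative.
    """
    if not length_L > 0:
        raise ConfigError("length_L must be positive")
    lam_L = lambda0 + alpha * length_L
    if lambda0 <= 0 or lam_L <= 0:
        raise DomainError("lambda(x) must be positive on [0, L]")
    if alpha == 0:
        return length_L * lambda0 ** (2.0 * kappa - 2.0)
    p = 2.0 * kappa - 1.0
    if abs(p) < _KAPPA_HALF_TOL:
        return math.log(lam_L / lambda0) / alpha
    return (lam_L**p - lambda0**p) / (alpha * p)


@dataclass(frozen=True)
class StationaryDistribution:
    """Closed-form stationary occupancy P(x) = (lambda0 + alpha x)^(2(kappa-1)) / c0."""

    lambda0: float
    alpha: float
    kappa: float
    length_L: float
    c0: float = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "c0", normalization_c0(self.lambda0, self.alpha, self.kappa, self.length_L)
        )

    @classmethod
    def from_bias(
        cls, lambda0: float, alpha: float, beta: float, length_L: float
    ) -> "StationaryDistribution":
        return cls(lambda0=lambda0, alpha=alpha, kappa=kappa_of(alpha, beta), length_L=length_L)

    @classmethod
    def from_walker(cls, params: WalkerParams, length_L: float) -> "StationaryDistribution":
        law = params.sde_length_field()
        return cls.from_bias(law.intercept_l0, law.slope_a, params.beta, length_L)

    def pdf(self, x) -> np.ndarray:
        """Stationary density (per mm) at positions x in [0, L]."""
        xv = np.asarray(x, dtype=float)
        if np.any(xv < 0) or np.any(xv > self.length_L):
            raise DomainError("x outside [0, L]")
        out = (self.lambda0 + self.alpha * xv) ** (2.0 * (self.kappa - 1.0)) / self.c0
        return float(out) if np.isscalar(x) else out

    def _antiderivative(self, x: np.ndarray) -> np.ndarray:
        """Antiderivative of the unnormalized density, for exact bin masses."""
        lam = self.lambda0 + self.alpha * x
        if self.alpha == 0:
            return lam ** (2.0 * self.kappa - 2.0) * x
        p = 2.0 * self.kappa - 1.0
        if abs(p) < _KAPPA_HALF_TOL:
            return np.log(lam) / self.alpha
        return lam**p / (self.alpha * p)

    def bin_probabilities(self, bin_edges: np.ndarray) -> np.ndarray:
        """Exact probability mass of each bin, for histogram comparisons."""
        edges = np.asarray(bin_edges, dtype=float)
        if np.any(edges < 0) or np.any(edges > self.length_L):
            raise DomainError("bin edges outside [0, L]")
        F = self._antiderivative(edges) / self.c0
        return np.diff(F)


@dataclass(frozen=True)
class FokkerPlanckSolution:
    """Finite-volume solution of the drift-diffusion equation on [0, L]."""

    x_centers: np.ndarray
    density: np.ndarray
    time: float
    n_steps: int
    mass_error: float
    converged: bool

    @property
    def cell_width(self) -> float:
        return float(self.x_centers[1] - self.x_centers[0])


def evolve_fokker_planck(
    lambda0: float,
    alpha: float,
    beta: float,
    length_L: float,
    sigma: float = SIGMA_COS_THETA,
    n_cells: int = 512,
    dt: Optional[float] = None,
    t_max: float = 50_000.0,
    steady_rate_tol: float = 1e-8,
    p0: Optional[np.ndarray] = None,
    check_every: int = 500,
) -> FokkerPlanckSolution:
    """Integrate dP/dt = -(beta/2) d/dx [lam P] + (sigma^2/2) d2/dx2 [lam^2 P].

    A conservative finite-volume scheme with zero-flux walls: cell-face flux

        J = (beta/2) lam_f P_f - (sigma^2/2) d/dx (lam^2 P),

    with central (second-order) face interpolation, stepped explicitly until
    the density stops changing (max |dP/dt| < ``steady_rate_tol``) or
    ``t_max`` is reached.  This is a verification oracle for the closed-form
    stationary law, not a performance component.

    Raises
    ------
    StabilityError
        If an explicitly supplied ``dt`` exceeds the diffusive bound
        dx^2 / (2 max(sigma^2 lam^2 / 2)); the message reports the bound.
    """
    if n_cells < 8:
        raise ConfigError("n_cells must be at least 8")
    lam_check = np.array([lambda0, lambda0 + alpha * length_L])
    if np.any(lam_check <= 0):
        raise DomainError("lambda(x) must be positive on [0, L]")

    dx = length_L / n_cells
    x_c = (np.arange(n_cells) + 0.5) * dx
    x_f = np.arange(1, n_cells) * dx  # interior faces
    lam_c = lambda0 + alpha * x_c
    lam_f = lambda0 + alpha * x_f
    D_c = 0.5 * sigma**2 * lam_c**2

    dt_bound = dx * dx / (2.0 * float(D_c.max()))
    if dt is None:
        dt = 0.9 * dt_bound
    elif dt > dt_bound:
        raise StabilityError(
            f"explicit time step {dt:g} exceeds the stability bound {dt_bound:g} "
            f"(dx^2 / (2 max D))"
        )

    if p0 is None:
        P = np.full(n_cells, 1.0 / length_L)
    else:
        P = np.asarray(p0, dtype=float).copy()
        if P.shape != (n_cells,):
            raise ConfigError("p0 must have length n_cells")
        P /= P.sum() * dx

    mass0 = P.sum() * dx
    Q_coeff = lam_c**2  # Q = lam^2 P at cell centers
    adv_coeff = 0.5 * beta * lam_f
    flux = np.zeros(n_cells + 1)

    n_steps = 0
    t = 0.0
    converged = False
    max_steps = int(math.ceil(t_max / dt))
    while n_steps < max_steps:
        chunk = min(check_every, max_steps - n_steps)
        P_prev = P.copy()
        for _ in range(chunk):
            Q = Q_coeff * P
            flux[1:-1] = adv_coeff * 0.5 * (P[:-1] + P[1:]) - 0.5 * sigma**2 * (
                Q[1:] - Q[:-1]
            ) / dx
            P = P - (dt / dx) * (flux[1:] - flux[:-1])
        n_steps += chunk
        t += chunk * dt
        rate = float(np.abs(P - P_prev).max()) / (dt * chunk)
        if rate < steady_rate_tol:
            converged = True
            break

    mass_error = abs(P.sum() * dx - mass0)
    return FokkerPlanckSolution(
        x_centers=x_c,
        density=P,
        time=t,
        n_steps=n_steps,
        mass_error=mass_error,
        converged=converged,
    )
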