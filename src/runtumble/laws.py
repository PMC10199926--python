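"""Deterministic laws linking Fe2+ concentration, position and jump length.

A phenanthroline disk floating on an Fe2+ solution alternates between rest
("tumble") and bursts of rapid motion ("run").  The straight-line distance
covered by one run — the *jump length* — shrinks as the local Fe2+
concentration grows, following a logarithmic law

    l(c) = log_coeff * ln(c - c_crit) + offset        [mm, c in mM]

with a critical concentration ``c_crit`` below which the disk bifurcates to
uniform (non-intermittent) motion, i.e. an effectively infinite jump.  In a
gradient chamber the concentration field decays exponentially with the
distance ``x`` from the Fe2+ source,

    c(x) = amplitude * exp(-decay_rate * x) + baseline,

and when the profile baseline equals the critical concentration the
composition of the two laws is exactly linear in position,

    l(x) = a * x + l0,   a = -log_coeff * decay_rate,
                          l0 = offset + log_coeff * ln(amplitude).

All quantities are in mm, mM, seconds and radians package-wide.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Union

import numpy as np

from .exceptions import ConfigError, DomainError

ArrayLike = Union[float, np.ndarray]

__all__ = [
    "JumpConcentrationLaw",
    "ConcentrationProfile",
    "PositionJumpLaw",
    "PAPER_JUMP_LAW",
    "PAPER_PROFILE",
    "PAPER_POSITION_LAW",
    "jump_length_from_conc",
    "conc_at",
    "conc_gradient_at",
    "compose_position_law",
    "jump_length_at",
]


@dataclass(frozen=True)
class JumpConcentrationLaw:
    """Jump length as a function of Fe2+ concentration.

    Parameters
    ----------
    log_coeff : float
        Coefficient of the logarithm, mm per ln(mM); negative, because the
        jump length decreases with concentration.
    offset : float
        Additive offset, mm.
    critical_conc : float
        Critical concentration (mM) at which intermittent motion bifurcates
        to uniform motion ("infinite jump length").
    """

    log_coeff: float = -3.5
    offset: float = 15.5
    critical_conc: float = 0.33

    def __post_init__(self) -> None:
        if not self.critical_conc > 0:
            raise ConfigError("critical_conc must be positive")
        if not self.log_coeff < 0:
            raise ConfigError(
                "log_coeff must be negative (jump length decreases with concentration)"
            )

    def __call__(self, conc: ArrayLike) -> ArrayLike:
        return jump_length_from_conc(self, conc)


@dataclass(frozen=True)
class ConcentrationProfile:
    """Exponential Fe2+ field over the distance x from the source (mm)."""

    amplitude: float = 2.0
    decay_rate: float = 0.018
    baseline: float = 0.33

    def __post_init__(self) -> None:
        if not self.amplitude > 0:
            raise ConfigError("amplitude must be positive")
        if not self.decay_rate > 0:
            raise ConfigError("decay_rate must be positive")
        if self.baseline < 0:
            raise ConfigError("baseline must be non-negative")

    def __call__(self, x: ArrayLike) -> ArrayLike:
        return conc_at(self, x)


@dataclass(frozen=True)
class PositionJumpLaw:
    """Linear jump-length law l(x) = slope_a * x + intercept_l0 (mm).

    Also serves as the step-length field lambda(x) = lambda0 + alpha * x of
    the random walker, with (alpha, lambda0) = (slope_a, intercept_l0) under
    the unit-step-time convention.
    """

    slope_a: float = 0.063
    intercept_l0: float = 12.9
    slope_se: Optional[float] = None
    intercept_se: Optional[float] = None

    def __post_init__(self) -> None:
        if not self.intercept_l0 > 0:
            raise ConfigError("intercept_l0 must be positive")

    def __call__(self, x: ArrayLike) -> ArrayLike:
        """Raw linear evaluation, without the positivity guard."""
        return self.slope_a * np.asarray(x, dtype=float) + self.intercept_l0


#: Published fitted constants; the position law uses the printed rounded
#: coefficients rather than the exact composition (see compose_position_law).
PAPER_JUMP_LAW = JumpConcentrationLaw()
PAPER_PROFILE = ConcentrationProfile()
PAPER_POSITION_LAW = PositionJumpLaw()


def jump_length_from_conc(law: JumpConcentrationLaw, conc: ArrayLike) -> ArrayLike:
    """Jump length (mm) at Fe2+ concentration ``conc`` (mM).

    Raises
    ------
    DomainError
        If ``conc <= law.critical_conc``: below the critical concentration
        the disk bifurcates to uniform motion and the jump length diverges.
    """
    c = np.asarray(conc, dtype=float)
    if np.any(c <= law.critical_conc):
        raise DomainError(
            f"concentration must exceed the critical value {law.critical_conc} mM; "
            "below it the disk moves uniformly (infinite jump length)"
        )
    out = law.log_coeff * np.log(c - law.critical_conc) + law.offset
    return float(out) if np.isscalar(conc) else out


def conc_at(profile: ConcentrationProfile, x: ArrayLike) -> ArrayLike:
    """Fe2+ concentration (mM) at distance ``x`` >= 0 from the source (mm)."""
    xv = np.asarray(x, dtype=float)
    if np.any(xv < 0):
        raise DomainError("x must be non-negative (source sits at x = 0)")
    out = profile.amplitude * np.exp(-profile.decay_rate * xv) + profile.baseline
    return float(out) if np.isscalar(x) else out


def conc_gradient_at(profile: ConcentrationProfile, x: ArrayLike) -> ArrayLike:
    """Signed concentration gradient dc/dx (mM/mm); negative everywhere."""
    xv = np.asarray(x, dtype=float)
    if np.any(xv < 0):
        raise DomainError("x must be non-negative (source sits at x = 0)")
    out = -profile.amplitude * profile.decay_rate * np.exp(-profile.decay_rate * xv)
    return float(out) if np.isscalar(x) else out


def compose_position_law(
    law: JumpConcentrationLaw, profile: ConcentrationProfile
) -> PositionJumpLaw:
    """Compose the concentration law with the concentration profile.

    Substituting c(x) into l(c) is exactly linear in x only when the profile
    baseline equals the critical concentration, in which case

        l(x) = (-log_coeff * decay_rate) x + offset + log_coeff * ln(amplitude).

    Raises
    ------
    DomainError
        If ``profile.baseline != law.critical_conc`` — the composition would
        not be linear and we refuse to approximate.
    """
    if not math.isclose(profile.baseline, law.critical_conc, rel_tol=0.0, abs_tol=1e-12):
        raise DomainError(
            "composition is linear only when the profile baseline equals the "
            f"critical concentration (got baseline={profile.baseline}, "
            f"critical_conc={law.critical_conc})"
        )
    slope = -law.log_coeff * profile.decay_rate
    intercept = law.offset + law.log_coeff * math.log(profile.amplitude)
    return PositionJumpLaw(slope_a=slope, intercept_l0=intercept)


def jump_length_at(poslaw: PositionJumpLaw, x: ArrayLike) -> ArrayLike:
    """Jump length l(x) = a*x + l0 (mm); errors where the law is non-positive."""
    xv = np.asarray(x, dtype=float)
    out = poslaw.slope_a * xv + poslaw.intercept_l0
    if np.any(out <= 0):
        raise DomainError(
            "position law evaluates to a non-positive jump length; the model is "
            "invalid there"
        )
    return float(out) if np.isscalar(x) else out
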