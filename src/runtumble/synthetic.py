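"""Synthetic data with the statistical structure the analysis assumes.

Two generators make every pipeline stage testable without experimental
recordings:

* run/tumble trajectories: a walker obeying the jump law
  l(x) (1 + b cos(theta)) with uniform directions, dressed with rest/burst
  kinematics (zero speed during tumbles, a rapid straight run per cycle)
  and sampled at the camera frame rate.  Ground-truth jump events are
  always returned alongside the frame table.
* noisy concentration measurements at a few sampling positions with
  replicates, emulating the UV-Vis calibration of the Fe2+ field, plus the
  nonlinear refit of the exponential profile.

The x-walls of the chamber mirror-reflect: a jump whose proposed endpoint
leaves [0, L] is folded back, and the recorded event stores the *realized*
endpoints, length and angle, so the x-marginal dynamics coincide exactly
with the 1D reflecting walker.  The y-coordinate carries no gradient and
the analysis uses only x and theta, so the generated walk lives in an
unbounded y strip: y-walls would truncate recorded jump lengths and break
the very structure length = l(x) (1 + b cos(theta)) the estimators assume.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .exceptions import ConfigError, DataError
from .laws import ConcentrationProfile, PositionJumpLaw, conc_at, jump_length_at
from .simulate import DomainConfig
from .trajectory import JumpEvent, Trajectory

__all__ = [
    "TrajectoryGenConfig",
    "ConcMeasurementConfig",
    "gen_jump_sequence",
    "gen_trajectory",
    "gen_concentration_samples",
    "fit_concentration_profile",
]


def _fold(v: float, lim: float) -> float:
    """Mirror-reflect a coordinate into [0, lim] (triangle wave of period 2*lim)."""
    y = math.fmod(v, 2.0 * lim)
    if y < 0:
        y += 2.0 * lim
    return 2.0 * lim - y if y > lim else y


@dataclass(frozen=True)
class TrajectoryGenConfig:
    """Ground-truth walker plus camera/kinematics dressing.

    The default chamber is the 100 mm channel; ``width_y`` only sets the
    default start ordinate (the walk is unbounded in y).  Runs are traversed
    at ``peak_speed`` (constant-speed profile, so every intra-run frame
    clears the segmentation threshold and the analysis round-trips exactly),
    with an optional half-sine profile of fixed ``run_duration`` for stress
    tests.  ``fixed_x`` restarts every jump from the same position, which
    emulates pooling many jumps observed at one location.
    """

    poslaw: PositionJumpLaw
    b: float
    n_cycles: int
    domain: DomainConfig = DomainConfig()
    width_y: float = 65.0
    tumble_duration: float = 4.0
    run_duration: float = 1.0
    frame_rate: float = 30.0
    peak_speed: float = 30.0
    length_noise_sd: float = 0.0
    seed: int = 0
    start: Optional[Tuple[float, float]] = None
    fixed_x: Optional[float] = None
    speed_profile: str = "constant"
    speed_threshold: float = 10.0

    def __post_init__(self) -> None:
        if self.n_cycles < 1:
            raise ConfigError("n_cycles must be at least 1")
        if not abs(self.b) < 1:
            raise ConfigError("|b| must be < 1")
        if not self.peak_speed > self.speed_threshold:
            raise ConfigError(
                "peak_speed must exceed the segmentation threshold "
                f"({self.speed_threshold} mm/s)"
            )
        if self.tumble_duration <= 0 or self.run_duration <= 0:
            raise ConfigError("durations must be positive")
        if self.frame_rate <= 0:
            raise ConfigError("frame_rate must be positive")
        if self.length_noise_sd < 0:
            raise ConfigError("length_noise_sd must be non-negative")
        if self.width_y <= 0:
            raise ConfigError("width_y must be positive")
        if self.speed_profile not in ("constant", "half_sine"):
            raise ConfigError(f"unknown speed_profile {self.speed_profile!r}")

    @property
    def start_point(self) -> Tuple[float, float]:
        if self.start is not None:
            return self.start
        return (self.domain.length_L / 2.0, self.width_y / 2.0)


def gen_jump_sequence(cfg: TrajectoryGenConfig) -> List[JumpEvent]:
    """Draw the ground-truth jump chain.

    Each cycle draws theta uniformly, computes
    length = l(x_start) (1 + b cos(theta)) plus optional Gaussian noise
    (truncated at zero), and mirror-folds the endpoint at the chamber walls.
    Events record realized endpoints; their times use the nominal cycle
    kinematics (tumble, then run at peak speed).
    """
    rng = np.random.default_rng(cfg.seed)
    L = cfg.domain.length_L
    pos = cfg.start_point
    if not 0 <= pos[0] <= L:
        raise ConfigError("start position outside the chamber")
    events: List[JumpEvent] = []
    t = 0.0
    for _ in range(cfg.n_cycles):
        if cfg.fixed_x is not None:
            sx, sy = cfg.fixed_x, cfg.width_y / 2.0
        else:
            sx, sy = pos
        base = jump_length_at(cfg.poslaw, sx)  # raises if l(x) <= 0
        theta = rng.uniform(-math.pi, math.pi)
        length = base * (1.0 + cfg.b * math.cos(theta))
        if cfg.length_noise_sd > 0:
            length = max(length + rng.normal(0.0, cfg.length_noise_sd), 0.0)
        ex = _fold(sx + length * math.cos(theta), L)
        ey = sy + length * math.sin(theta)  # no y-walls: y is gradient-free
        run_time = (
            max(math.hypot(ex - sx, ey - sy), 1e-6) / cfg.peak_speed
            if cfg.speed_profile == "constant"
            else cfg.run_duration
        )
        t_start = t + cfg.tumble_duration
        events.append(
            JumpEvent.from_endpoints((sx, sy), (ex, ey), t_start, t_start + run_time)
        )
        t = t_start + run_time
        pos = (ex, ey)
    return events


def _run_fractions(cfg: TrajectoryGenConfig, length: float) -> np.ndarray:
    """Cumulative displacement fractions for one run's frames."""
    fps = cfg.frame_rate
    if cfg.speed_profile == "constant":
        m = max(1, round(length * fps / cfg.peak_speed))
        frame_speed = length * fps / m
        if frame_speed < cfg.speed_threshold:
            raise ConfigError(
                f"run of length {length:.3g} mm is too short to exceed the "
                f"{cfg.speed_threshold} mm/s threshold for a full frame; raise "
                "peak_speed or the jump-length scale"
            )
        return np.arange(1, m + 1) / m
    m = max(1, round(cfg.run_duration * fps))
    w = np.sin(math.pi * (np.arange(m) + 0.5) / m)
    if length * fps * w.max() / w.sum() < cfg.speed_threshold:
        raise ConfigError(
            "half-sine run never exceeds the segmentation threshold; raise "
            "peak speed or shorten run_duration"
        )
    return np.cumsum(w) / w.sum()


def gen_trajectory(cfg: TrajectoryGenConfig) -> Tuple[Trajectory, List[JumpEvent]]:
    """Dress the jump chain with rest/burst kinematics sampled at the camera.

    Each cycle is ``tumble_duration`` of rest at the start point followed by
    a straight run to the endpoint.  The returned events carry frame-aligned
    times; geometry is identical to :func:`gen_jump_sequence` with the same
    config.  Requires ``fixed_x`` unset (a pooled-position chain has no
    continuous path).
    """
    if cfg.fixed_x is not None:
        raise ConfigError("gen_trajectory requires fixed_x=None (continuous path)")
    events = gen_jump_sequence(cfg)
    fps = cfg.frame_rate
    m_t = max(1, round(cfg.tumble_duration * fps))
    xs: List[float] = []
    ys: List[float] = []
    timed_events: List[JumpEvent] = []
    for ev in events:
        frac = _run_fractions(cfg, ev.length)
        i_start = len(xs) + m_t - 1  # last rest frame sits at the run start
        xs.extend([ev.start_x] * m_t)
        ys.extend([ev.start_y] * m_t)
        xs.extend(ev.start_x + frac * (ev.end_x - ev.start_x))
        ys.extend(ev.start_y + frac * (ev.end_y - ev.start_y))
        timed_events.append(
            replace(
                ev,
                start_time=i_start / fps,
                end_time=(i_start + frac.size) / fps,
            )
        )
    times = np.arange(len(xs)) / fps
    return Trajectory(times=times, xs=np.array(xs), ys=np.array(ys)), timed_events


@dataclass(frozen=True)
class ConcMeasurementConfig:
    """UV-Vis-style concentration sampling: positions x replicates plus noise."""

    profile: ConcentrationProfile
    positions: Tuple[float, ...] = (20.0, 50.0, 70.0)
    replicates: int = 5
    noise_sd: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.replicates < 1:
            raise ConfigError("replicates must be at least 1")
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be non-negative")


def gen_concentration_samples(cfg: ConcMeasurementConfig) -> pd.DataFrame:
    """Table (x_mm, replicate, conc_mM) of noisy profile measurements."""
    rng = np.random.default_rng(cfg.seed)
    rows = []
    for x in cfg.positions:
        true = conc_at(cfg.profile, x)
        for r in range(cfg.replicates):
            noise = rng.normal(0.0, cfg.noise_sd) if cfg.noise_sd > 0 else 0.0
            rows.append((x, r, true + noise))
    return pd.DataFrame(rows, columns=["x_mm", "replicate", "conc_mM"])


def replicate_means(samples: pd.DataFrame) -> pd.DataFrame:
    """Replicate-averaged concentrations per sampling position."""
    return samples.groupby("x_mm", as_index=False)["conc_mM"].mean()


def fit_concentration_profile(
    samples: pd.DataFrame,
    fixed_baseline: Optional[float] = None,
    average_replicates: bool = True,
):
    """Nonlinear least squares of A exp(-k x) + c on concentration samples.

    With ``fixed_baseline`` the baseline c is held at that value (e.g. the
    critical concentration) and only (A, k) are fitted; otherwise all three
    parameters are free, which needs at least three distinct positions.

    Returns
    -------
    (profile, se) : ConcentrationProfile and a dict of standard errors
        (keys ``amplitude``, ``decay_rate``, ``baseline``; the baseline SE is
        0 when fixed).  SEs are residual-based and may be non-finite for an
        exactly interpolating fit.
    """
    df = replicate_means(samples) if average_replicates else samples
    x = df["x_mm"].to_numpy(float)
    y = df["conc_mM"].to_numpy(float)
    n_distinct = np.unique(x).size
    if fixed_baseline is None and n_distinct < 3:
        raise DataError("free-baseline fit needs at least three distinct positions")
    if n_distinct < 2:
        raise DataError("fit needs at least two distinct positions")

    c_guess = fixed_baseline if fixed_baseline is not None else max(0.0, 0.9 * y.min())
    # log-linear initials for the exponential part
    ypos = np.maximum(y - c_guess, 1e-6)
    k_guess, logA = np.polyfit(x, np.log(ypos), 1)
    p0_A = max(math.exp(logA), 1e-6)
    p0_k = max(-k_guess, 1e-6)

    try:
        if fixed_baseline is not None:
            popt, pcov = curve_fit(
                lambda xx, A, k: A * np.exp(-k * xx) + fixed_baseline,
                x,
                y,
                p0=(p0_A, p0_k),
                maxfev=10000,
            )
            A, k = popt
            c = fixed_baseline
            se = np.sqrt(np.diag(pcov))
            se_dict = {"amplitude": float(se[0]), "decay_rate": float(se[1]), "baseline": 0.0}
        else:
            popt, pcov = curve_fit(
                lambda xx, A, k, c: A * np.exp(-k * xx) + c,
                x,
                y,
                p0=(p0_A, p0_k, c_guess),
                maxfev=10000,
            )
            A, k, c = popt
            se = np.sqrt(np.diag(pcov))
            se_dict = {
                "amplitude": float(se[0]),
                "decay_rate": float(se[1]),
                "baseline": float(se[2]),
            }
    except RuntimeError as exc:
        raise DataError(
            f"concentration-profile fit did not converge (initial values "
            f"A={p0_A:.3g}, k={p0_k:.3g}, c={c_guess:.3g}): {exc}"
        ) from exc
    return ConcentrationProfile(amplitude=float(A), decay_rate=float(k), baseline=float(c)), se_dict
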