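"""Measurement pipeline for tracked run-and-tumble trajectories.

From a (time, x, y) table sampled at a fixed frame rate the pipeline
computes frame speeds, segments rapid-motion episodes above a speed
threshold (10 mm/s by default), extracts one jump event per episode
(straight-line displacement from the beginning to the end of the rapid
motion, not the arc length), and estimates

* the position law l(x) = a x + l0 by OLS of jump length on starting
  position, using only jumps perpendicular to the gradient
  (3pi/8 <= |theta| <= 5pi/8) so the directional bias cancels;
* the directional bias b from jumps starting in the chamber center
  (45 < x < 55 mm), where l(x) is nearly constant, by OLS of jump length
  on cos(theta): length = slope * cos(theta) + intercept, b = slope/intercept;
* the chemotaxis parameter kappa = b / a (unit cycle-time convention).

x increases away from the Fe2+ source, so theta = 0 points down-gradient.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from scipy import stats

from .binning import BinnedDensity, bin_positions
from .exceptions import ConfigError, DataError, DomainError
from .simulate import DomainConfig

logger = logging.getLogger(__name__)

__all__ = [
    "Trajectory",
    "SegmentationConfig",
    "JumpEvent",
    "BiasEstimate",
    "PositionLawEstimate",
    "DirectionHistogram",
    "compute_speed",
    "segment_runs",
    "extract_jumps",
    "select_perpendicular",
    "select_center_window",
    "trim_extremes",
    "fit_position_law",
    "fit_directional_bias",
    "estimate_kappa",
    "occupancy_distribution",
    "direction_histogram",
    "jumps_to_frame",
    "jumps_from_frame",
]

PERPENDICULAR_SECTOR = ((3 * math.pi / 8, 5 * math.pi / 8),)
"""Closed |theta| window (rad) of gradient-perpendicular jumps."""


@dataclass(frozen=True)
class Trajectory:
    """A tracked disk path: uniformly sampled times (s) and positions (mm)."""

    times: np.ndarray
    xs: np.ndarray
    ys: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        x = np.asarray(self.xs, dtype=float)
        y = np.asarray(self.ys, dtype=float)
        if not (t.shape == x.shape == y.shape) or t.ndim != 1:
            raise DataError("times, xs, ys must be 1D arrays of equal length")
        if t.size < 2:
            raise DataError("a trajectory needs at least two samples")
        if np.any(np.diff(t) <= 0):
            raise DataError("times must be strictly increasing")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "xs", x)
        object.__setattr__(self, "ys", y)

    def __len__(self) -> int:
        return self.times.size

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        time_col: str = "time_s",
        x_col: str = "x_mm",
        y_col: str = "y_mm",
    ) -> "Trajectory":
        missing = {time_col, x_col, y_col} - set(df.columns)
        if missing:
            raise DataError(f"trajectory table lacks columns {sorted(missing)}")
        return cls(
            times=df[time_col].to_numpy(float),
            xs=df[x_col].to_numpy(float),
            ys=df[y_col].to_numpy(float),
        )

    @classmethod
    def from_csv(cls, path, **kwargs) -> "Trajectory":
        try:
            df = pd.read_csv(path)
        except Exception as exc:  # noqa: BLE001 - surface as a data error
            raise DataError(f"cannot read trajectory CSV {path}: {exc}") from exc
        bad = df.isna().any(axis=1)
        if bad.any():
            raise DataError(
                f"trajectory CSV {path}: malformed row(s) at index "
                f"{df.index[bad][0]}"
            )
        return cls.from_dataframe(df, **kwargs)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time_s": self.times, "x_mm": self.xs, "y_mm": self.ys})


@dataclass(frozen=True)
class SegmentationConfig:
    """Run/tumble segmentation rule: speed threshold in mm/s."""

    speed_threshold: float = 10.0
    min_run_frames: int = 1
    smooth_window: Optional[int] = None  # odd moving-average length, off by default

    def __post_init__(self) -> None:
        if not self.speed_threshold > 0:
            raise ConfigError("speed_threshold must be positive")
        if self.min_run_frames < 1:
            raise ConfigError("min_run_frames must be at least 1")
        if self.smooth_window is not None and (
            self.smooth_window < 1 or self.smooth_window % 2 == 0
        ):
            raise ConfigError("smooth_window must be odd and positive")


@dataclass(frozen=True)
class JumpEvent:
    """One run: endpoint coordinates, direction and straight-line length."""

    start_x: float
    start_y: float
    end_x: float
    end_y: float
    theta: float
    length: float
    start_time: float
    end_time: float

    @classmethod
    def from_endpoints(
        cls,
        start: Tuple[float, float],
        end: Tuple[float, float],
        start_time: float,
        end_time: float,
    ) -> "JumpEvent":
        dx = end[0] - start[0]
        dy = end[1] - start[1]
        return cls(
            start_x=start[0],
            start_y=start[1],
            end_x=end[0],
            end_y=end[1],
            theta=math.atan2(dy, dx),
            length=math.hypot(dx, dy),
            start_time=start_time,
            end_time=end_time,
        )


@dataclass(frozen=True)
class BiasEstimate:
    """OLS fit length = slope * cos(theta) + intercept; b_hat = slope/intercept."""

    slope: float
    intercept: float
    b_hat: float
    b_se: float
    slope_se: float
    intercept_se: float
    n_used: int


@dataclass(frozen=True)
class PositionLawEstimate:
    """OLS fit length = a_hat * x + l0_hat over gradient-perpendicular jumps."""

    a_hat: float
    l0_hat: float
    a_se: float
    l0_se: float
    n_used: int


@dataclass(frozen=True)
class DirectionHistogram:
    """Binned jump-direction probabilities with a chi-square isotropy test."""

    bin_edges: np.ndarray
    probabilities: np.ndarray
    chi2: float
    pvalue: float
    n: int


def compute_speed(traj: Trajectory, smooth_window: Optional[int] = None) -> np.ndarray:
    """Frame speeds (mm/s) by forward finite differences.

    Frame spacing must be uniform to within 1%.  ``smooth_window`` applies an
    odd-length moving average to the speed series (off by default; tracking
    noise can chatter across the threshold).
    """
    dts = np.diff(traj.times)
    dt = float(np.median(dts))
    if np.any(np.abs(dts - dt) > 0.01 * dt):
        raise DataError("frame spacing is non-uniform beyond 1% tolerance")
    disp = np.hypot(np.diff(traj.xs), np.diff(traj.ys))
    speed = disp / dt
    if smooth_window is not None and smooth_window > 1:
        if smooth_window % 2 == 0:
            raise ConfigError("smooth_window must be odd")
        kernel = np.ones(smooth_window) / smooth_window
        speed = np.convolve(speed, kernel, mode="same")
    return speed


def segment_runs(
    speeds: Union[np.ndarray, Sequence[float]], cfg: SegmentationConfig = SegmentationConfig()
) -> List[Tuple[int, int]]:
    """Maximal frame intervals [i, j) with speed >= threshold.

    Speed frame k covers the motion between position frames k and k+1, so an
    interval [i, j) corresponds to displacement from position frame i to
    position frame j.
    """
    speeds = np.asarray(speeds, dtype=float)
    if speeds.size == 0:
        raise DataError("empty speed series")
    above = speeds >= cfg.speed_threshold
    padded = np.diff(np.concatenate(([0], above.view(np.int8), [0])))
    starts = np.flatnonzero(padded == 1)
    ends = np.flatnonzero(padded == -1)
    return [(int(i), int(j)) for i, j in zip(starts, ends) if j - i >= cfg.min_run_frames]


def extract_jumps(traj: Trajectory, runs: Sequence[Tuple[int, int]]) -> List[JumpEvent]:
    """One jump per run: straight-line displacement over the rapid episode.

    Zero-displacement runs have no direction; they are dropped with a logged
    warning.
    """
    events: List[JumpEvent] = []
    for i, j in runs:
        start = (float(traj.xs[i]), float(traj.ys[i]))
        end = (float(traj.xs[j]), float(traj.ys[j]))
        if start == end:
            logger.warning(
                "dropping zero-displacement run over frames [%d, %d): direction undefined",
                i,
                j,
            )
            continue
        events.append(
            JumpEvent.from_endpoints(
                start, end, float(traj.times[i]), float(traj.times[j])
            )
        )
    return events


def select_perpendicular(jumps: Sequence[JumpEvent]) -> List[JumpEvent]:
    """Jumps perpendicular to the gradient: 3pi/8 <= |theta| <= 5pi/8 (closed).

    Their length does not feel the directional bias (cos(theta) ~ 0), which
    isolates the position dependence of l(x).
    """
    lo, hi = PERPENDICULAR_SECTOR[0]
    return [j for j in jumps if lo <= abs(j.theta) <= hi]


def select_center_window(
    jumps: Sequence[JumpEvent], low: float = 45.0, high: float = 55.0
) -> List[JumpEvent]:
    """Jumps starting strictly inside the chamber-center window low < x < high,
    where l(x) is nearly constant and the cos(theta) modulation is isolated."""
    return [j for j in jumps if low < j.start_x < high]


def trim_extremes(jumps: Sequence[JumpEvent]) -> List[JumpEvent]:
    """Drop the largest, second-largest and smallest jump lengths (applied once).

    Ties are broken by removing the event with the earliest start time.
    Requires at least four jumps.
    """
    if len(jumps) < 4:
        raise DataError("trim_extremes needs at least four jumps")
    remaining = list(jumps)

    def pop_by(key) -> None:
        target = min(range(len(remaining)), key=lambda k: key(remaining[k]))
        remaining.pop(target)

    pop_by(lambda j: (-j.length, j.start_time))  # maximum
    pop_by(lambda j: (-j.length, j.start_time))  # second maximum
    pop_by(lambda j: (j.length, j.start_time))  # minimum
    return remaining


def _ols(y: np.ndarray, x: np.ndarray):
    import statsmodels.api as sm

    X = sm.add_constant(x)
    return sm.OLS(y, X).fit()


def fit_position_law(jumps: Sequence[JumpEvent]) -> PositionLawEstimate:
    """OLS of jump length on starting x: slope a_hat, intercept l0_hat."""
    if len(jumps) < 3:
        raise DataError("fit_position_law needs at least three jumps")
    x = np.array([j.start_x for j in jumps])
    y = np.array([j.length for j in jumps])
    if np.ptp(x) == 0:
        raise DataError("degenerate x spread: all jumps start at the same position")
    res = _ols(y, x)
    return PositionLawEstimate(
        a_hat=float(res.params[1]),
        l0_hat=float(res.params[0]),
        a_se=float(res.bse[1]),
        l0_se=float(res.bse[0]),
        n_used=len(jumps),
    )


def fit_directional_bias(jumps: Sequence[JumpEvent]) -> BiasEstimate:
    """OLS of jump length on cos(theta); b_hat = slope / intercept.

    The intercept estimates the direction-free jump length l(x); the slope
    measures its modulation by the movement direction.  The standard error
    of the ratio is first-order (delta-method) propagation using the full
    OLS coefficient covariance.
    """
    if len(jumps) < 3:
        raise DataError("fit_directional_bias needs at least three jumps")
    c = np.array([math.cos(j.theta) for j in jumps])
    y = np.array([j.length for j in jumps])
    if np.ptp(c) == 0:
        raise DataError("degenerate cos(theta) spread")
    res = _ols(y, c)
    intercept, slope = float(res.params[0]), float(res.params[1])
    if intercept <= 0:
        raise DataError("non-positive intercept: fitted l(x) is not a valid length")
    cov = np.asarray(res.cov_params())
    b = slope / intercept
    # delta method for slope/intercept with coefficient covariance
    grad = np.array([-slope / intercept**2, 1.0 / intercept])
    b_var = float(grad @ cov @ grad)
    return BiasEstimate(
        slope=slope,
        intercept=intercept,
        b_hat=b,
        b_se=math.sqrt(max(b_var, 0.0)),
        slope_se=float(res.bse[1]),
        intercept_se=float(res.bse[0]),
        n_used=len(jumps),
    )


def estimate_kappa(
    bias: Union[BiasEstimate, float], poslaw: Union[PositionLawEstimate, float]
) -> float:
    """Chemotaxis parameter kappa = b_hat / a_hat (unit cycle-time convention).

    kappa > 1: accumulation where jumps are long; kappa = 1: uniform;
    kappa < 1: accumulation where jumps are short.
    """
    b = bias.b_hat if isinstance(bias, BiasEstimate) else float(bias)
    a = poslaw.a_hat if isinstance(poslaw, PositionLawEstimate) else float(poslaw)
    if a == 0:
        raise DomainError("kappa is undefined for a = 0")
    return b / a


def occupancy_distribution(
    traj: Trajectory, n_bins: int, domain: DomainConfig
) -> BinnedDensity:
    """Fraction of frames per x-bin, normalized to a density over [0, L].

    Frames outside the domain raise rather than being clipped.
    """
    return bin_positions(traj.xs, n_bins, domain.length_L)


def direction_histogram(jumps: Sequence[JumpEvent], n_bins: int) -> DirectionHistogram:
    """Jump-direction probabilities on [-pi, pi) plus a chi-square isotropy test."""
    if n_bins < 4:
        raise DataError("n_bins must be at least 4")
    if len(jumps) == 0:
        raise DataError("no jumps to histogram")
    theta = np.array([j.theta for j in jumps])
    counts, edges = np.histogram(theta, bins=n_bins, range=(-math.pi, math.pi))
    chi2, p = stats.chisquare(counts)
    return DirectionHistogram(
        bin_edges=edges,
        probabilities=counts / counts.sum(),
        chi2=float(chi2),
        pvalue=float(p),
        n=len(jumps),
    )


_JUMP_COLUMNS = [
    "start_x_mm",
    "start_y_mm",
    "end_x_mm",
    "end_y_mm",
    "theta_rad",
    "length_mm",
    "start_time_s",
    "end_time_s",
]


def jumps_to_frame(jumps: Sequence[JumpEvent]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (
                j.start_x,
                j.start_y,
                j.end_x,
                j.end_y,
                j.theta,
                j.length,
                j.start_time,
                j.end_time,
            )
            for j in jumps
        ],
        columns=_JUMP_COLUMNS,
    )


def jumps_from_frame(df: pd.DataFrame) -> List[JumpEvent]:
    missing = set(_JUMP_COLUMNS) - set(df.columns)
    if missing:
        raise DataError(f"jump table lacks columns {sorted(missing)}")
    return [
        JumpEvent(
            start_x=float(r.start_x_mm),
            start_y=float(r.start_y_mm),
            end_x=float(r.end_x_mm),
            end_y=float(r.end_y_mm),
            theta=float(r.theta_rad),
            length=float(r.length_mm),
            start_time=float(r.start_time_s),
            end_time=float(r.end_time_s),
        )
        for r in df.itertuples()
    ]
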