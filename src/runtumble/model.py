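"""Statsmodels-style front end: a model built from a tracked trajectory whose
``fit()`` runs the full estimation pipeline and returns a results object.

    >>> model = RunTumbleChemotaxis.from_csv("trajectory.csv")
    >>> res = model.fit()
    >>> print(res.summary())
    >>> res.kappa

The fit estimates the position law l(x) = a x + l0 from gradient-
perpendicular jumps, the directional bias b from chamber-center jumps
regressed on cos(theta), and the chemotaxis parameter kappa = b / a.
kappa > 1 predicts accumulation away from the Fe2+ source.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .analytic import StationaryDistribution
from .binning import BinnedDensity
from .exceptions import DataError, NoEventsError
from .simulate import DomainConfig, PositionSamples, SimConfig, WalkerParams, simulate_ensemble
from .trajectory import (
    BiasEstimate,
    DirectionHistogram,
    JumpEvent,
    PositionLawEstimate,
    SegmentationConfig,
    Trajectory,
    compute_speed,
    direction_histogram,
    estimate_kappa,
    extract_jumps,
    fit_directional_bias,
    fit_position_law,
    jumps_to_frame,
    occupancy_distribution,
    segment_runs,
    select_center_window,
    select_perpendicular,
    trim_extremes,
)

__all__ = ["RunTumbleChemotaxis", "ChemotaxisResults"]


class RunTumbleChemotaxis:
    """Run-and-tumble chemotaxis model for one tracked disk trajectory.

    Parameters
    ----------
    trajectory : Trajectory
        Frame table (time, x, y), x measured from the Fe2+ source (mm).
    segmentation : SegmentationConfig, optional
        Speed threshold and smoothing for run detection.
    domain : DomainConfig, optional
        Chamber geometry; defaults to the 100 mm channel.
    """

    def __init__(
        self,
        trajectory: Trajectory,
        segmentation: Optional[SegmentationConfig] = None,
        domain: Optional[DomainConfig] = None,
    ) -> None:
        self.trajectory = trajectory
        self.segmentation = segmentation or SegmentationConfig()
        self.domain = domain or DomainConfig()

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, **kwargs) -> "RunTumbleChemotaxis":
        seg = kwargs.pop("segmentation", None)
        dom = kwargs.pop("domain", None)
        return cls(Trajectory.from_dataframe(df, **kwargs), segmentation=seg, domain=dom)

    @classmethod
    def from_csv(cls, path, **kwargs) -> "RunTumbleChemotaxis":
        seg = kwargs.pop("segmentation", None)
        dom = kwargs.pop("domain", None)
        return cls(Trajectory.from_csv(path, **kwargs), segmentation=seg, domain=dom)

    def extract(self) -> List[JumpEvent]:
        """Segment runs and extract one jump event per rapid episode."""
        speeds = compute_speed(self.trajectory, self.segmentation.smooth_window)
        runs = segment_runs(speeds, self.segmentation)
        return extract_jumps(self.trajectory, runs)

    def fit(
        self,
        center_window: Tuple[float, float] = (45.0, 55.0),
        trim: bool = True,
        position_law: Optional[PositionLawEstimate] = None,
    ) -> "ChemotaxisResults":
        """Run the estimation pipeline.

        Parameters
        ----------
        center_window : (low, high)
            Strict x-window of jump starts used for the bias regression.
        trim : bool
            Drop the two largest and the smallest jump length before the
            bias fit (outlier rule; skipped when fewer than four jumps
            remain in the window).
        position_law : PositionLawEstimate, optional
            Use a fixed position law (e.g. the published coefficients)
            instead of fitting it from perpendicular jumps.

        Raises
        ------
        NoEventsError
            If the trajectory contains no supra-threshold run.
        """
        jumps = self.extract()
        if not jumps:
            raise NoEventsError("no supra-threshold runs found in the trajectory")

        perpendicular = select_perpendicular(jumps)
        if position_law is None:
            if len(perpendicular) < 3:
                raise DataError(
                    "fewer than three gradient-perpendicular jumps; cannot fit "
                    "the position law (pass position_law= to fix it)"
                )
            poslaw = fit_position_law(perpendicular)
        else:
            poslaw = position_law

        centered = select_center_window(jumps, *center_window)
        if trim and len(centered) >= 4:
            centered_used = trim_extremes(centered)
        else:
            centered_used = list(centered)
        if len(centered_used) < 3:
            raise DataError(
                "fewer than three center-window jumps; cannot fit the "
                "directional bias"
            )
        bias = fit_directional_bias(centered_used)
        kappa = estimate_kappa(bias, poslaw)
        return ChemotaxisResults(
            model=self,
            jumps=jumps,
            n_perpendicular=len(perpendicular),
            n_center=len(centered_used),
            position_law=poslaw,
            bias=bias,
            kappa=kappa,
            center_window=center_window,
        )


@dataclass
class ChemotaxisResults:
    """Estimates, uncertainties and diagnostics from a fitted trajectory."""

    model: RunTumbleChemotaxis
    jumps: List[JumpEvent]
    n_perpendicular: int
    n_center: int
    position_law: PositionLawEstimate
    bias: BiasEstimate
    kappa: float
    center_window: Tuple[float, float]

    @property
    def params(self) -> pd.Series:
        return pd.Series(
            {
                "a": self.position_law.a_hat,
                "l0": self.position_law.l0_hat,
                "slope": self.bias.slope,
                "intercept": self.bias.intercept,
                "b": self.bias.b_hat,
                "kappa": self.kappa,
            }
        )

    @property
    def bse(self) -> pd.Series:
        return pd.Series(
            {
                "a": self.position_law.a_se,
                "l0": self.position_law.l0_se,
                "slope": self.bias.slope_se,
                "intercept": self.bias.intercept_se,
                "b": self.bias.b_se,
            }
        )

    def jumps_frame(self) -> pd.DataFrame:
        return jumps_to_frame(self.jumps)

    def direction_histogram(self, n_bins: int = 12) -> DirectionHistogram:
        """Isotropy diagnostic of all extracted jump directions."""
        return direction_histogram(self.jumps, n_bins)

    def occupancy(self, n_bins: int = 20) -> BinnedDensity:
        """Occupancy density of the trajectory frames over the chamber."""
        return occupancy_distribution(self.model.trajectory, n_bins, self.model.domain)

    def stationary(self) -> StationaryDistribution:
        """Predicted stationary occupancy from the fitted (a, l0, b)."""
        return StationaryDistribution(
            lambda0=self.position_law.l0_hat,
            alpha=self.position_law.a_hat,
            kappa=self.kappa,
            length_L=self.model.domain.length_L,
        )

    def simulate(
        self, sim: Optional[SimConfig] = None, mode: str = "angular"
    ) -> PositionSamples:
        """Walker ensemble under the fitted parameters, for posterior checks."""
        params = WalkerParams(
            lambda0=self.position_law.l0_hat,
            alpha=self.position_law.a_hat,
            b=self.bias.b_hat,
        )
        return simulate_ensemble(params, self.model.domain, sim or SimConfig(), mode=mode)

    def summary(self) -> str:
        iso = self.direction_histogram() if len(self.jumps) >= 12 else None
        pl, bi = self.position_law, self.bias
        window = f"  center window {self.center_window[0]:g}-{self.center_window[1]:g} mm"
        lines = [
            "Run-and-tumble chemotaxis fit",
            "=" * 46,
            f"{'jumps extracted':<30s}{len(self.jumps):>10d}",
            f"{'  perpendicular sector':<30s}{self.n_perpendicular:>10d}",
            f"{window:<30s}{self.n_center:>10d}",
            "-" * 46,
            f"position law  a        {pl.a_hat:>12.4f} +/- {pl.a_se:.4f}",
            f"              l0 (mm)  {pl.l0_hat:>12.3f} +/- {pl.l0_se:.3f}",
            f"bias fit      slope    {bi.slope:>12.3f} +/- {bi.slope_se:.3f}",
            f"              intercept{bi.intercept:>12.3f} +/- {bi.intercept_se:.3f}",
            f"directional bias b     {bi.b_hat:>12.4f} +/- {bi.b_se:.4f}",
            f"kappa = b / a          {self.kappa:>12.3f}",
            "-" * 46,
            (
                "chemotaxis: accumulation away from the source (kappa > 1)"
                if self.kappa > 1
                else "chemotaxis: accumulation toward the source (kappa < 1)"
                if self.kappa < 1
                else "chemotaxis: none (kappa = 1)"
            ),
        ]
        if iso is not None:
            lines.append(
                f"direction isotropy     chi2 = {iso.chi2:.2f}, p = {iso.pvalue:.3f}"
            )
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "a_hat": self.position_law.a_hat,
            "a_se": self.position_law.a_se,
            "l0_hat": self.position_law.l0_hat,
            "l0_se": self.position_law.l0_se,
            "slope": self.bias.slope,
            "intercept": self.bias.intercept,
            "b_hat": self.bias.b_hat,
            "b_se": self.bias.b_se,
            "kappa": self.kappa,
            "n_jumps": len(self.jumps),
            "n_perpendicular": self.n_perpendicular,
            "n_center": self.n_center,
        }

    def plot_jump_vs_cos(self, ax=None):
        """Jump length against cos(theta) with the fitted bias line."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        c = np.cos([j.theta for j in self.jumps])
        length = [j.length for j in self.jumps]
        ax.plot(c, length, "o", ms=3, alpha=0.5)
        grid = np.linspace(-1, 1, 50)
        ax.plot(grid, self.bias.slope * grid + self.bias.intercept, "-")
        ax.set_xlabel(r"cos $\theta$")
        ax.set_ylabel("jump length (mm)")
        return ax

    def plot_occupancy(self, n_bins: int = 20, ax=None):
        """Occupancy histogram with the fitted stationary-law overlay."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        occ = self.occupancy(n_bins)
        ax.bar(occ.centers, occ.density, width=occ.bin_width, alpha=0.5)
        grid = np.linspace(0, self.model.domain.length_L, 200)
        ax.plot(grid, self.stationary().pdf(grid), "k--")
        ax.set_xlabel("x (mm)")
        ax.set_ylabel("density (1/mm)")
        return ax
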