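"""Equal-width binned densities over a 1D interval, shared by the simulator
(walker histograms) and the trajectory analysis (occupancy distributions)."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import DataError

__all__ = ["BinnedDensity", "bin_positions", "total_variation"]


@dataclass(frozen=True)
class BinnedDensity:
    """A density histogram on equal-width bins spanning [0, L]."""

    bin_edges: np.ndarray  # length n_bins + 1
    density: np.ndarray  # per-mm, integrates to 1

    @property
    def bin_width(self) -> float:
        return float(self.bin_edges[1] - self.bin_edges[0])

    @property
    def probabilities(self) -> np.ndarray:
        """Per-bin probability mass (density * bin width); sums to 1."""
        return self.density * np.diff(self.bin_edges)

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin_left_mm": self.bin_edges[:-1],
                "bin_right_mm": self.bin_edges[1:],
                "density_per_mm": self.density,
            }
        )


def bin_positions(values: np.ndarray, n_bins: int, length_L: float) -> BinnedDensity:
    """Histogram positions in [0, L] into ``n_bins`` equal bins, normalized to
    a density (sum of density * width == 1)."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise DataError("cannot bin an empty sample")
    if n_bins < 2:
        raise DataError("n_bins must be at least 2")
    if np.any(values < 0) or np.any(values > length_L):
        raise DataError("positions outside [0, L]")
    density, edges = np.histogram(values, bins=n_bins, range=(0.0, length_L), density=True)
    return BinnedDensity(bin_edges=edges, density=density)


def total_variation(p: np.ndarray, q: np.ndarray) -> float:
    """Total-variation distance between two probability vectors."""
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if p.shape != q.shape:
        raise DataError("probability vectors must have the same shape")
    return 0.5 * float(np.abs(p - q).sum())
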