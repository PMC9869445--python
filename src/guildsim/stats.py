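"""Windowed summary statistics of repertoire trajectories.

The steady-state convention follows the simulation protocol used throughout:
runs of 500,000 steps with statistics taken over the window [200,000,
500,000).  Windows are half-open in step index and evaluated over recorded
steps only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .scenario import Trajectory

__all__ = ["SummaryStats", "window_stats", "retention", "DEFAULT_WINDOW"]

DEFAULT_WINDOW = (200_000, 500_000)


@dataclass(frozen=True)
class SummaryStats:
    """Mean/variance/min/max of the total repertoire over a step window.

    ``relative_range`` is (max - min) / max, the relative fluctuation band of
    the repertoire (0 for an identically-zero window); ``variance`` is the
    population (divide-by-n) variance over recorded values.
    """

    window: tuple[int, int]
    n_records: int
    mean: float
    variance: float
    min: int
    max: int
    relative_range: float

    def to_dict(self) -> dict:
        return {
            "window": list(self.window),
            "n_records": self.n_records,
            "mean": self.mean,
            "variance": self.variance,
            "min": self.min,
            "max": self.max,
            "relative_range": self.relative_range,
        }


def _window_values(trajectory: Trajectory, window: tuple[int, int]) -> np.ndarray:
    start, end = window
    if end <= start:
        raise ValueError(f"window must satisfy start < end, got {window}")
    mask = (trajectory.steps >= start) & (trajectory.steps < end)
    if not mask.any():
        raise ValueError(f"window {window} contains no recorded steps")
    return trajectory.total_repertoire[mask]


def window_stats(trajectory: Trajectory, window: tuple[int, int]) -> SummaryStats:
    """Summary statistics of the total repertoire over [start, end)."""
    vals = _window_values(trajectory, window)
    vmax = int(vals.max())
    vmin = int(vals.min())
    return SummaryStats(
        window=(int(window[0]), int(window[1])),
        n_records=int(vals.size),
        mean=float(vals.mean()),
        variance=float(vals.var()),
        min=vmin,
        max=vmax,
        relative_range=0.0 if vmax == 0 else (vmax - vmin) / vmax,
    )


def retention(
    trajectory: Trajectory,
    pre_window: tuple[int, int],
    post_window: tuple[int, int],
) -> float:
    """Fraction of repertoire retained across an intervening event.

    Mean total repertoire over ``post_window`` divided by the mean over
    ``pre_window``.  Both means zero is defined as 1 (nothing to lose,
    nothing lost); a zero pre-event mean with a nonzero post-event mean has
    no meaningful retention and returns NaN.
    """
    if pre_window[1] > post_window[0]:
        raise ValueError("pre_window must end before post_window begins")
    pre = float(_window_values(trajectory, pre_window).mean())
    post = float(_window_values(trajectory, post_window).mean())
    if pre == 0.0:
        return 1.0 if post == 0.0 else math.nan
    return post / pre
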