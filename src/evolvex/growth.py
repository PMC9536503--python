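"""Growth-profile analysis: smoothing-spline fit of log-transformed
signal, maximum specific growth rate, maximum level and lag time.

The signal (backscattered light, OD, cumulative CO2 loss ...) is
log-transformed and fitted with an order-3 smoothing spline.  Then

* ``mu_max`` is the maximum of the spline derivative (1/h) — on a clean
  exponential this recovers the specific growth rate exactly;
* ``max_level`` is the maximum of ``exp(spline)`` (signal units);
* ``lag`` is the first time, after the smoothed curve has passed its
  minimum, at which the smoothed signal reaches ``threshold_fraction``
  of its maximum level.  The threshold is applied on the signal scale,
  which makes all rate/time metrics invariant to rescaling the signal.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.interpolate import UnivariateSpline


@dataclass
class GrowthCurve:
    times: np.ndarray  # hours, strictly increasing
    values: np.ndarray  # nonnegative signal, arbitrary units
    spline_order: int = 3
    smoothing: float | None = None  # None: noise-scaled heuristic

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if len(self.times) < 5:
            raise ValueError("growth curve needs at least 5 points")
        if len(self.times) != len(self.values):
            raise ValueError("times and values differ in length")
        if not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.values < 0):
            raise ValueError("signal values must be nonnegative")
        if not np.any(self.values > 0):
            raise ValueError("all-zero signal")


@dataclass
class GrowthMetrics:
    mu_max: float  # 1/h
    max_level: float  # signal units
    lag: float  # hours
    threshold_fraction: float
    zero_floored: bool = False


def _default_smoothing(y: np.ndarray) -> float:
    """Noise-scaled smoothing factor: n * sigma^2 with sigma estimated
    robustly from second differences (zero for noiseless data, so the
    spline then interpolates)."""
    if len(y) < 3:
        return 0.0
    d2 = np.diff(y, n=2)
    sigma = np.median(np.abs(d2)) / (0.6745 * np.sqrt(6.0))
    s = len(y) * sigma ** 2
    # below numerical noise the spline should simply interpolate
    return s if s > 1e-10 * len(y) else 0.0


def growth_metrics(curve: GrowthCurve,
                   threshold_fraction: float = 0.10) -> GrowthMetrics:
    """Compute mu_max, max level and lag from one growth curve.

    ``threshold_fraction`` is 0.10 by default; 0.25 suits slow-starting
    profiles.  Zero signal values are floored to the smallest positive
    value before the log transform and flagged in the result.
    """
    if not 0.0 < threshold_fraction < 1.0:
        raise ValueError("threshold_fraction must lie in (0, 1)")
    values = curve.values.copy()
    zero_floored = bool(np.any(values == 0))
    if zero_floored:
        values[values == 0] = values[values > 0].min()
    y = np.log(values)
    s = curve.smoothing
    if s is None:
        s = _default_smoothing(y)
    spline = UnivariateSpline(curve.times, y, k=curve.spline_order, s=s)
    grid = np.linspace(curve.times[0], curve.times[-1],
                       max(1000, 10 * len(curve.times)))
    smoothed = spline(grid)
    mu_max = float(spline.derivative()(grid).max())
    max_level = float(np.exp(smoothed.max()))
    # first grid point at (numerically) the minimum — "after having
    # passed the minimum" must not drift on flat curves
    atol = 1e-9 * max(1.0, float(np.ptp(smoothed)))
    i_min = int(np.nonzero(smoothed <= smoothed.min() + atol)[0][0])
    threshold = np.log(threshold_fraction * max_level)
    after = np.nonzero(smoothed[i_min:] >= threshold)[0]
    lag = float(grid[i_min + after[0]]) if after.size else float(grid[-1])
    return GrowthMetrics(mu_max, max_level, lag, threshold_fraction,
                         zero_floored)


def read_growth_csv(path: str | Path) -> dict[str, GrowthCurve]:
    """Read growth curves from CSV (columns ``time_h``, ``value`` and an
    optional ``replicate`` id); returns one curve per replicate."""
    df = pd.read_csv(path)
    if "time_h" not in df.columns or "value" not in df.columns:
        raise ValueError("CSV needs 'time_h' and 'value' columns")
    if "replicate" not in df.columns:
        df["replicate"] = "1"
    out = {}
    for rep, sub in df.groupby("replicate", sort=False):
        sub = sub.sort_values("time_h")
        out[str(rep)] = GrowthCurve(sub["time_h"].to_numpy(),
                                    sub["value"].to_numpy())
    return out


def generations(initial_level: float, final_level: float) -> float:
    """Serial-transfer bookkeeping helper: number of doublings between two
    biomass levels, log10(final/initial)/0.3."""
    if initial_level <= 0 or final_level <= 0:
        raise ValueError("levels must be positive")
    return float(np.log10(final_level / initial_level) / 0.3)
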