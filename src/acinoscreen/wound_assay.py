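"""Relative Wound Density (RWD) quantitation for wounded monolayers.

A wounded monolayer is scored by comparing cell density inside the initial
wound region with density in the surrounding initial cell region:

    RWD(t) = 100 * (w(t) - w(0)) / (c(t) - w(0))

where w(t) and c(t) are the occupied fractions of the initial wound and
cell regions.  Conditions are compared at the time t = Max_1/2 (or
Max_1/4) at which the replicate-averaged *control* RWD first reaches 50%
(25%), located by linear interpolation between hourly frames, and each
well's RWD at that time is normalized to the control mean (control -> 1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "WoundSeries",
    "RWDCurve",
    "region_densities",
    "compute_rwd",
    "find_level_time",
    "normalized_rwd_at",
    "front_roughness",
    "analyze_wound_series",
]


@dataclass
class WoundSeries:
    """Per-well binary confluence masks with the fixed initial regions."""

    masks: np.ndarray            # (n_frames, H, W) bool
    wound_mask: np.ndarray       # initial cell-free band
    cell_mask: np.ndarray        # initial cell region
    times: np.ndarray            # hours, strictly increasing
    condition: str = ""
    replicate: int = 1
    well: str = ""

    def __post_init__(self) -> None:
        if self.masks.ndim != 3:
            raise ValueError("masks must be (n_frames, H, W)")
        if self.wound_mask.shape != self.masks.shape[1:] or \
                self.cell_mask.shape != self.masks.shape[1:]:
            raise ValueError("region masks must match frame size")
        if (self.wound_mask & self.cell_mask).any() or \
                not (self.wound_mask | self.cell_mask).all():
            raise ValueError("wound and cell regions must partition the frame")
        if (np.diff(self.times) <= 0).any():
            raise ValueError("times must be strictly increasing")


@dataclass
class RWDCurve:
    times: np.ndarray
    values: np.ndarray           # percent, [0, 100]; NaN where undefined
    condition: str = ""
    replicate: int = 1
    well: str = ""


def region_densities(series: WoundSeries) -> tuple[np.ndarray, np.ndarray]:
    """Per-frame occupied fraction of the wound region and cell region."""
    n_wound = series.wound_mask.sum()
    n_cell = series.cell_mask.sum()
    w = series.masks[:, series.wound_mask].sum(axis=1) / n_wound
    c = series.masks[:, series.cell_mask].sum(axis=1) / n_cell
    return w, c


def compute_rwd(series: WoundSeries) -> RWDCurve:
    """RWD(t) = 100 (w(t) - w(0)) / (c(t) - w(0)), clipped to [0, 100].

    Frames where the denominator is <= 0 are carried as missing (NaN); if
    every frame is undefined an error is raised.
    """
    w, c = region_densities(series)
    w0 = w[0]
    denom = c - w0
    with np.errstate(divide="ignore", invalid="ignore"):
        values = 100.0 * (w - w0) / denom
    values = np.where(denom > 0, values, np.nan)
    if np.isnan(values).all():
        raise ValueError("RWD undefined at every frame (empty cell region?)")
    values = np.clip(values, 0.0, 100.0)
    return RWDCurve(times=series.times.copy(), values=values,
                    condition=series.condition, replicate=series.replicate,
                    well=series.well)


def average_curves(curves: list[RWDCurve]) -> RWDCurve:
    """Pointwise mean over wells (NaN-aware); times must agree."""
    times = curves[0].times
    for c in curves[1:]:
        if not np.array_equal(c.times, times):
            raise ValueError("curves must share the same time base")
    stacked = np.vstack([c.values for c in curves])
    return RWDCurve(times=times.copy(),
                    values=np.nanmean(stacked, axis=0),
                    condition=curves[0].condition)


def find_level_time(control_curves: list[RWDCurve], level: float) -> float:
    """First time the replicate-averaged control RWD reaches ``level``.

    Linear interpolation between the bracketing frames, so by construction
    the averaged control RWD evaluated at the returned time equals the
    level exactly.
    """
    mean = average_curves(control_curves)
    v, t = mean.values, mean.times
    finite = np.isfinite(v)
    if not finite.any():
        raise ValueError("control RWD undefined everywhere")
    at_or_above = finite & (v >= level)
    if not at_or_above.any():
        raise ValueError(
            f"control RWD never reaches {level}% "
            f"(max attained {np.nanmax(v):.2f}%)"
        )
    i = int(np.argmax(at_or_above))
    if v[i] == level or i == 0:
        return float(t[i])
    t0, t1 = t[i - 1], t[i]
    v0, v1 = v[i - 1], v[i]
    return float(t0 + (level - v0) / (v1 - v0) * (t1 - t0))


def rwd_at(curve: RWDCurve, t_star: float) -> float:
    """Linear interpolation of one well's RWD at t_star."""
    v = curve.values
    finite = np.isfinite(v)
    return float(np.interp(t_star, curve.times[finite], v[finite]))


def normalized_rwd_at(
    curves: list[RWDCurve], t_star: float, control_condition: str
) -> pd.DataFrame:
    """Per-well RWD at t_star, normalized to the control mean (-> 1.0).

    Returns columns ``well, condition, replicate, rwd_at_tstar,
    normalized_rwd``.
    """
    if not (curves[0].times[0] <= t_star <= curves[0].times[-1]):
        raise ValueError("t_star outside the observed time range")
    raw = {c.well: rwd_at(c, t_star) for c in curves}
    control_values = [raw[c.well] for c in curves
                      if c.condition == control_condition]
    if not control_values:
        raise ValueError(f"no wells for control {control_condition!r}")
    control_mean = float(np.mean(control_values))
    records = [
        {
            "well": c.well,
            "condition": c.condition,
            "replicate": c.replicate,
            "rwd_at_tstar": raw[c.well],
            "normalized_rwd": raw[c.well] / control_mean
            if control_mean != 0 else np.nan,
        }
        for c in curves
    ]
    return pd.DataFrame.from_records(records)


def front_roughness(series: WoundSeries, frame: int = -1) -> float:
    """SD of the per-row front position inside the wound band.

    Descriptive statistic distinguishing smooth sheet fronts from
    finger-like chain fronts.  The front is the innermost occupied column
    per row advancing from the left wound edge.
    """
    cols = np.where(series.wound_mask.any(axis=0))[0]
    lo, hi = cols.min(), cols.max() + 1
    band = series.masks[frame][:, lo:hi]
    depths = np.empty(band.shape[0])
    for r, row in enumerate(band):
        occupied = np.where(~row)[0]
        depths[r] = occupied[0] if occupied.size else band.shape[1]
    return float(depths.std())


def analyze_wound_series(
    series: list[WoundSeries],
    control_condition: str = "Scr",
    level: float = 50.0,
) -> pd.DataFrame:
    """End-to-end wound analysis: RWD curves, t*, normalized values.

    Returns the per-well table ``well, condition, replicate, t_star,
    rwd_at_tstar, normalized_rwd, front_roughness``.
    """
    curves = [compute_rwd(s) for s in series]
    control = [c for c in curves if c.condition == control_condition]
    if not control:
        raise ValueError(f"no control wells ({control_condition!r})")
    t_star = find_level_time(control, level)
    table = normalized_rwd_at(curves, t_star, control_condition)
    table["t_star"] = t_star
    table["front_roughness"] = [front_roughness(s) for s in series]
    return table
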