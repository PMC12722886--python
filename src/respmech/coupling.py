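"""Respiration-posture coupling via normalized cross-correlation.

For each movement cycle and COM axis, the respiratory volume signal and the
COM displacement are linearly detrended over the cycle (movement cycles can
contain large monotone COM excursions that would otherwise dominate the
correlation), standardized, and cross-correlated over lags up to
``max_lag_s``.  The headline coupling statistic is ``ccf = max_tau |r(tau)|``
in [0, 1]; the signed correlation and lag at that extremum, and the zero-lag
correlation, are reported alongside for sensitivity analysis.  Higher ccf
means stronger synchronization between breathing and postural sway.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .chestwall import VolumeSeries
from .posture import ComTrajectory

__all__ = ["CouplingResult", "cross_correlation", "coupling_battery", "mean_ccf"]

AXIS_INDEX = {"X": 0, "Y": 1, "Z": 2}


@dataclass
class CouplingResult:
    cycle: tuple[str, int]  # (movement, cycle index)
    axis: str
    ccf: float  # max |r| over lags, in [0, 1]; NaN when flagged
    lag_s: float  # lag of the extremum (positive: volume leads COM)
    signed_r: float  # correlation at that lag, in [-1, 1]
    zero_lag_r: float
    flagged: bool = False  # zero-variance input in the window


def _corr_over_lags(a: np.ndarray, b: np.ndarray, max_lag: int) -> np.ndarray:
    """Pearson correlation of the overlapping parts at each integer lag.

    ``lag > 0`` means ``a`` shifted later (``a`` leads ``b``).  Both inputs
    are already detrended; each overlap segment is re-standardized so the
    result is a true correlation in [-1, 1] at every lag.
    """
    n = a.size
    out = np.empty(2 * max_lag + 1)
    for i, lag in enumerate(range(-max_lag, max_lag + 1)):
        if lag >= 0:
            x, y = a[: n - lag], b[lag:]
        else:
            x, y = a[-lag:], b[: n + lag]
        sx, sy = x.std(), y.std()
        if sx == 0 or sy == 0:
            out[i] = np.nan
        else:
            out[i] = float(np.mean((x - x.mean()) * (y - y.mean())) / (sx * sy))
    return out


def cross_correlation(
    vol: VolumeSeries,
    com: ComTrajectory,
    axis: str,
    window: tuple[float, float],
    max_lag_s: float = 2.0,
    cycle: tuple[str, int] = ("", 0),
) -> CouplingResult:
    """Cross-correlation between respiratory volume and one COM axis.

    Both signals must cover the window and share the analysis rate.  A
    zero-variance signal inside the window yields a NaN result flagged
    rather than raised.
    """
    if axis not in AXIS_INDEX:
        raise ValueError(f"axis must be one of {sorted(AXIS_INDEX)}, got {axis!r}")
    start, end = window
    if end - start <= 2 * max_lag_s:
        raise ValueError(f"max_lag {max_lag_s} s must be < half the window length")
    rate = vol.rate
    if abs(rate - com.rate) > 1e-6:
        raise ValueError("volume and COM series must share one analysis rate")
    for name, t in (("volume", vol.time), ("COM", com.time)):
        if start < t[0] - 1e-9 or end > t[-1] + 1e-9:
            raise ValueError(f"{name} series does not cover the window ({start}, {end}) s")

    sel = (vol.time >= start) & (vol.time <= end)
    v = vol.respiratory_signal()[sel]
    sel_c = (com.time >= start) & (com.time <= end)
    c = com.com[sel_c, AXIS_INDEX[axis]]
    n = min(v.size, c.size)
    v, c = v[:n], c[:n]

    flagged = (not np.all(np.isfinite(v))) or v.std() == 0 or c.std() == 0
    if flagged:
        return CouplingResult(cycle, axis, np.nan, np.nan, np.nan, np.nan, flagged=True)

    v = sps.detrend(v)
    c = sps.detrend(c)
    max_lag = int(round(max_lag_s * rate))
    r = _corr_over_lags(v, c, max_lag)
    score = np.abs(r)
    best = np.nanmax(score)
    # ties (e.g. periodic signals matching again half a period away) break
    # toward the smallest absolute lag
    ties = np.flatnonzero(score >= best - 1e-12)
    k = int(ties[np.argmin(np.abs(ties - max_lag))])
    return CouplingResult(
        cycle=cycle,
        axis=axis,
        ccf=float(abs(r[k])),
        lag_s=float((k - max_lag) / rate),
        signed_r=float(r[k]),
        zero_lag_r=float(r[max_lag]),
    )


def coupling_battery(
    vol: VolumeSeries,
    com: ComTrajectory,
    cycles: list[tuple[str, int, float, float]],
    axes: tuple[str, ...] = ("X", "Y", "Z"),
    max_lag_s: float = 2.0,
) -> list[CouplingResult]:
    """One CouplingResult per movement cycle x axis.

    ``cycles`` are ``(movement, index, start_s, end_s)`` tuples as produced
    by :meth:`EventTable.all_cycles`.  Per-cycle flags propagate; the
    per-trial value is the mean over cycles (see :func:`mean_ccf`).
    """
    if not cycles:
        raise ValueError("at least one movement cycle is required")
    out = []
    for movement, idx, start, end in cycles:
        for axis in axes:
            out.append(
                cross_correlation(
                    vol, com, axis, (start, end), max_lag_s=max_lag_s,
                    cycle=(movement, idx),
                )
            )
    return out


def mean_ccf(results: list[CouplingResult], axis: str) -> float:
    """Per-trial coupling for one axis: mean ccf over unflagged cycles."""
    vals = [r.ccf for r in results if r.axis == axis and not r.flagged]
    return float(np.mean(vals)) if vals else float("nan")
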