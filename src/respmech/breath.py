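"""Breath segmentation and respiratory parameters from a volume signal.

A breath is a trough -> peak -> trough excursion of the chest-wall volume
signal: the rising limb is inspiration (duration Ti), the falling limb
expiration (Te), and the trough-to-peak volume excursion the tidal volume.
Peaks and troughs are found by prominence-based extremum picking with a
robust (percentile-based) amplitude scale, so the detection threshold does
not blow up when sway artefacts widen the raw signal range.

Compartment contributions are the fraction of the tidal excursion carried by
each chest-wall band between the same trough and peak; they are signed (a
compartment moving paradoxically contributes negatively) and sum to 100% by
construction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .chestwall import COMPARTMENTS, VolumeSeries

__all__ = [
    "BreathCycle",
    "RespiratorySummary",
    "smooth_volume",
    "segment_breaths",
    "compartment_contributions",
    "summarize_respiration",
]


@dataclass
class BreathCycle:
    """One segmented breath with timing, tidal volume and contributions."""

    trough_start: float
    peak: float
    trough_end: float
    tidal_volume: float  # L
    contributions: dict[str, float]  # % of tidal volume per compartment

    def __post_init__(self) -> None:
        if not (self.trough_start < self.peak < self.trough_end):
            raise ValueError("breath must order trough_start < peak < trough_end")
        if not self.tidal_volume > 0:
            raise ValueError("tidal volume must be positive")
        if self.contributions:
            total = sum(self.contributions.values())
            if abs(total - 100.0) > 1e-6:
                raise ValueError(f"contributions sum to {total}, not 100")

    @property
    def Ti(self) -> float:
        """Inspiratory time (s)."""
        return self.peak - self.trough_start

    @property
    def Te(self) -> float:
        """Expiratory time (s)."""
        return self.trough_end - self.peak

    @property
    def duration(self) -> float:
        return self.trough_end - self.trough_start


@dataclass
class RespiratorySummary:
    """Mean respiratory parameters over one movement-cycle window."""

    n_breaths: int
    mean_Ti: float
    mean_Te: float
    max_respiratory_volume: float  # largest tidal volume in window, L
    mean_contributions: dict[str, float]
    complete: bool = True  # False when no breath fell inside the window


def smooth_volume(series: VolumeSeries, cutoff: float = 1.0) -> VolumeSeries:
    """Zero-phase low-pass (4th-order Butterworth, forward-backward).

    Default cutoff 1.0 Hz sits well above resting breathing rates
    (~0.15-0.4 Hz) while killing marker jitter and mesh noise.  Invalid
    frames are bridged by linear interpolation before filtering and stay
    flagged invalid in the output.
    """
    rate = series.rate
    if not cutoff < rate / 2:
        raise ValueError(f"cutoff {cutoff} Hz >= Nyquist {rate / 2} Hz")
    sos = sps.butter(4, cutoff, btype="low", fs=rate, output="sos")

    def run(x: np.ndarray) -> np.ndarray:
        y = x.copy()
        bad = ~np.isfinite(y)
        if bad.all():
            return y
        if bad.any():
            idx = np.arange(y.size)
            y[bad] = np.interp(idx[bad], idx[~bad], y[~bad])
        return sps.sosfiltfilt(sos, y)

    return VolumeSeries(
        time=series.time,
        total=run(series.total),
        compartments={k: run(v) for k, v in series.compartments.items()},
        valid_mask=series.valid_mask.copy(),
    )


def segment_breaths(
    series: VolumeSeries,
    min_duration: float = 1.0,
    min_prominence_frac: float = 0.2,
    refine: VolumeSeries | None = None,
    refine_window_s: float = 0.5,
) -> list[BreathCycle]:
    """Segment the volume signal into breaths.

    Peaks are local maxima with prominence at least ``min_prominence_frac``
    of the robust signal amplitude (95th minus 5th percentile over valid
    frames); troughs likewise on the negated signal.  Each consecutive
    trough-peak-trough triplet with total duration >= ``min_duration`` and a
    positive excursion becomes a breath.  A signal with no qualifying breath
    returns an empty list.

    Heavy smoothing keeps the detection stable but drags the extremum of an
    asymmetric breath toward its flatter limb, biasing Ti and Te.  When a
    lightly-smoothed twin of the signal is passed as ``refine``, each
    detected extremum time is re-located by local search on it within
    ``refine_window_s``; the volume values still come from ``series``.
    """
    v = series.total
    valid = series.valid_mask & np.isfinite(v)
    if valid.sum() < 3:
        return []
    lo, hi = np.percentile(v[valid], [5, 95])
    amplitude = hi - lo
    if amplitude <= 0:
        return []
    prominence = min_prominence_frac * amplitude

    x = v.copy()
    if (~valid).any():  # bridge invalid frames so find_peaks sees no NaN
        idx = np.arange(x.size)
        x[~valid] = np.interp(idx[~valid], idx[valid], x[valid])
    peaks, _ = sps.find_peaks(x, prominence=prominence)
    troughs, _ = sps.find_peaks(-x, prominence=prominence)
    # a record edge counts as a trough only when it actually sits near
    # trough level; an edge cutting a breath mid-limb must not spawn a
    # spurious partial breath
    first, last = np.flatnonzero(valid)[[0, -1]]
    trough_level = lo + 0.25 * amplitude
    boundary = []
    if peaks.size:
        if first < peaks[0] and x[first] <= trough_level:
            boundary.append(first)
        if last > peaks[-1] and x[last] <= trough_level:
            boundary.append(last)
    troughs = np.unique(np.concatenate([troughs, np.array(boundary, dtype=int)]))

    def refined(i: int, maximum: bool) -> int:
        # Around a breath extremum the signal switches between limbs of
        # different curvature, so the local model is a corner joining two
        # parabolic branches; fitting that corner averages the residual
        # noise without the asymmetry bias a single-vertex fit would have.
        if refine is None:
            return i
        from scipy.optimize import least_squares

        half = int(round(refine_window_s * series.rate))
        lo_i, hi_i = max(0, i - half), min(x.size, i + half + 1)
        seg = refine.total[lo_i:hi_i]
        ok = np.isfinite(seg)
        if ok.sum() < 8:
            return i
        u = (np.arange(lo_i, hi_i)[ok] - i) / series.rate
        y = seg[ok]
        sgn = -1.0 if maximum else 1.0

        def resid(p):
            f0, tau, c_left, c_right = p
            d = u - tau
            return f0 + sgn * np.where(d < 0, c_left, c_right) * d * d - y

        c0 = max(abs(np.polyfit(u, y, 2)[0]), 1e-9)
        fit = least_squares(
            resid,
            [y[y.size // 2], 0.0, c0, c0],
            bounds=([-np.inf, u[0], 0.0, 0.0], [np.inf, u[-1], np.inf, np.inf]),
        )
        return i + int(round(fit.x[1] * series.rate))

    t = series.time
    breaths: list[BreathCycle] = []
    for pk in peaks:
        before = troughs[troughs < pk]
        after = troughs[troughs > pk]
        if before.size == 0 or after.size == 0:
            continue
        t0, t1 = before[-1], after[0]
        t0, pk, t1 = refined(t0, False), refined(pk, True), refined(t1, False)
        if not (t0 < pk < t1):
            continue
        tidal = x[pk] - x[t0]
        if t[t1] - t[t0] < min_duration or tidal <= 0:
            continue
        if not (valid[t0] and valid[pk] and valid[t1]):
            continue
        breaths.append(
            BreathCycle(
                trough_start=float(t[t0]),
                peak=float(t[pk]),
                trough_end=float(t[t1]),
                tidal_volume=float(tidal),
                contributions=_contributions_at(series, t0, pk),
            )
        )
    return breaths


def _contributions_at(series: VolumeSeries, i_trough: int, i_peak: int) -> dict[str, float]:
    total_exc = series.total[i_peak] - series.total[i_trough]
    if not np.isfinite(total_exc) or total_exc == 0:
        return {}
    out = {
        k: float(100.0 * (v[i_peak] - v[i_trough]) / total_exc)
        for k, v in series.compartments.items()
    }
    # the compartments sum to the total by construction; renormalise the
    # residual float error so the 100% invariant is exact
    s = sum(out.values())
    if s != 0:
        out = {k: v * 100.0 / s for k, v in out.items()}
    return out


def compartment_contributions(series: VolumeSeries, cycle: BreathCycle) -> dict[str, float]:
    """Percentage of the tidal excursion carried by each compartment.

    contribution_k = 100 * (V_k(peak) - V_k(trough)) / (V_total(peak) -
    V_total(trough)).  May be negative for a paradoxically moving
    compartment; always sums to 100.
    """
    i_trough = int(np.argmin(np.abs(series.time - cycle.trough_start)))
    i_peak = int(np.argmin(np.abs(series.time - cycle.peak)))
    total_exc = series.total[i_peak] - series.total[i_trough]
    if total_exc == 0 or not np.isfinite(total_exc):
        raise ValueError("zero total volume excursion over the breath")
    return _contributions_at(series, i_trough, i_peak)


def summarize_respiration(
    cycles: list[BreathCycle], window: tuple[float, float]
) -> RespiratorySummary:
    """Mean Ti/Te/contributions and max tidal volume over one movement cycle.

    A breath belongs to the window when its peak lies inside it.  A window
    containing no breath yields a NaN summary flagged ``complete=False``
    rather than extrapolating.
    """
    start, end = window
    inside = [c for c in cycles if start <= c.peak <= end]
    if not inside:
        return RespiratorySummary(
            n_breaths=0, mean_Ti=float("nan"), mean_Te=float("nan"),
            max_respiratory_volume=float("nan"),
            mean_contributions={k: float("nan") for k in COMPARTMENTS},
            complete=False,
        )
    keys = inside[0].contributions.keys()
    return RespiratorySummary(
        n_breaths=len(inside),
        mean_Ti=float(np.mean([c.Ti for c in inside])),
        mean_Te=float(np.mean([c.Te for c in inside])),
        max_respiratory_volume=float(max(c.tidal_volume for c in inside)),
        mean_contributions={
            k: float(np.mean([c.contributions[k] for c in inside])) for k in keys
        },
    )
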