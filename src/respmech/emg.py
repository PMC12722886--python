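"""Surface-EMG conditioning and integrated EMG (iEMG) per movement cycle.

Raw channels are band-passed (default 20-450 Hz, zero-phase) to strip motion
artefact and out-of-band noise, then full-wave rectified and integrated over
the movement cycle with the trapezoidal rule at the native EMG rate — no
envelope or RMS smoothing is applied before integration.

Normalisation divides the integral by (reference peak x window duration), so
the normalised value is a duty-cycle-like fraction of the reference
contraction level, comparable across cycles of different lengths.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import signal as sps

from .mocap_io import EmgRecord

__all__ = ["IemgResult", "preprocess_emg", "integrated_emg"]


@dataclass
class IemgResult:
    muscle: str
    side: str
    window: tuple[float, float]
    iemg_raw: float  # mV·s
    iemg_norm: float | None  # fraction of reference peak; None if no reference

    def __post_init__(self) -> None:
        if self.iemg_raw < 0:
            raise ValueError("iEMG cannot be negative")
        if self.iemg_norm is not None and self.iemg_norm < 0:
            raise ValueError("normalised iEMG cannot be negative")


def preprocess_emg(emg: EmgRecord, band: tuple[float, float] = (20.0, 450.0)) -> EmgRecord:
    """Zero-phase band-pass and mean removal on every channel.

    The band must lie strictly inside (0, Nyquist); the high edge is clipped
    to 0.99 x Nyquist when the record was sampled too slowly to carry the
    default 450 Hz edge.
    """
    lo, hi = band
    nyq = emg.rate / 2
    if not 0 < lo < hi:
        raise ValueError(f"invalid band {band}")
    if lo >= nyq:
        raise ValueError(f"band low edge {lo} Hz >= Nyquist {nyq} Hz")
    hi = min(hi, 0.99 * nyq)
    sos = sps.butter(4, [lo, hi], btype="bandpass", fs=emg.rate, output="sos")
    out = {}
    for name, x in emg.channels.items():
        y = x - np.nanmean(x)
        out[name] = sps.sosfiltfilt(sos, y)
    return replace(emg, channels=out)


def integrated_emg(
    emg: EmgRecord,
    muscle: str,
    window: tuple[float, float],
    reference_peak: float | None = None,
    side: str = "",
) -> IemgResult:
    """Integral of the rectified signal over one movement cycle.

    ``iemg_raw = ∫ |v(t)| dt`` (mV·s, trapezoidal at the native rate);
    ``iemg_norm = iemg_raw / (reference_peak * window_duration)``.  Without a
    reference peak only the raw value is returned and the normalised field is
    None.
    """
    if muscle not in emg.channels:
        raise KeyError(f"no EMG channel {muscle!r}")
    start, end = window
    if start < -1e-9 or end > emg.duration + 1e-9 or start >= end:
        raise ValueError(f"window ({start}, {end}) s outside record of {emg.duration} s")
    t = emg.time
    sel = (t >= start) & (t <= end)
    if sel.sum() < 2:
        raise ValueError("window covers fewer than 2 EMG samples")
    raw = float(np.trapezoid(np.abs(emg.channels[muscle][sel]), t[sel]))
    norm = None
    if reference_peak is not None:
        if not reference_peak > 0:
            raise ValueError("reference_peak must be > 0")
        norm = raw / (reference_peak * (end - start))
    return IemgResult(muscle=muscle, side=side, window=window, iemg_raw=raw, iemg_norm=norm)
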