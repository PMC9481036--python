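"""Quality-factor estimation from ring-down traces and bandwidth measurements.

After the drive is switched off, the coil envelope decays as
``exp(-t/T)`` with ``T = 2Q/omega``, i.e. it halves every
``N = Q * ln2 / pi`` carrier cycles.  Counting the cycles to halve (N)
therefore gives ``Q = (pi/ln2) * N ~= 4.53 * N``.  Two estimators are
provided:

* ``integer-count`` — count whole carrier cycles until the per-cycle
  peak first drops to half the reference peak (the first peak after
  switch-off).  This mirrors the oscilloscope procedure.
* ``decimal-fit`` — straight-line fit of log(peak amplitude) against
  cycle index; ``N = ln2 / |slope|``.  Fractional N gives better
  precision than integer counting.

Q can also be computed from a -3 dB bandwidth measurement as
``Q = f_r / (f_H - f_L)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks

from .coil_model import Trace

__all__ = [
    "RingdownEstimate",
    "BandwidthMeasurement",
    "q_from_ringdown",
    "q_from_bandwidth",
    "implied_bandwidth",
    "cycles_to_halve",
    "EXACT_CONSTANT",
    "ROUNDED_CONSTANT",
]

#: pi/ln2, the exact constant relating Q to cycles-to-halve.
EXACT_CONSTANT = math.pi / math.log(2.0)
#: The two-decimal rounding of pi/ln2 in common bench use (Q = 4.53 N).
ROUNDED_CONSTANT = 4.53

# Relative slack applied to the half-amplitude threshold so that an
# envelope halving *exactly* at cycle N is counted as N rather than
# spilling to N+1 through floating-point / interpolation rounding.
_HALF_SLACK = 1e-6

# Decimal-fit ignores peaks below this fraction of the reference peak:
# in noisy traces the faintest peaks are dominated by the upward bias of
# per-cycle maximum picking and would flatten the fitted slope.
_FIT_FLOOR = 0.2


class RingdownError(ValueError):
    """Raised when a trace does not contain a usable ring-down."""


@dataclass(frozen=True)
class RingdownEstimate:
    """Result of a ring-down Q estimate.

    Attributes
    ----------
    n : float
        Cycles to halve (integer-valued for the counting method,
        fractional for the log-fit).
    q : float
        Estimated quality factor.
    fit_points : int
        Number of peaks used.
    residual : float
        RMS residual of the log-linear fit (0.0 for integer counting).
    method : str
        ``"integer-count"`` or ``"decimal-fit"``.
    carrier_hz : float
        Carrier frequency used for cycle bookkeeping.
    """

    n: float
    q: float
    fit_points: int
    residual: float
    method: str
    carrier_hz: float


@dataclass(frozen=True)
class BandwidthMeasurement:
    """A -3 dB bandwidth measurement: ``f_L < f_r < f_H`` (all Hz)."""

    f_r: float
    f_L: float
    f_H: float

    def __post_init__(self) -> None:
        if not (self.f_L < self.f_r < self.f_H):
            raise ValueError(
                f"require f_L < f_r < f_H, got f_L={self.f_L}, f_r={self.f_r}, f_H={self.f_H}"
            )


def q_from_bandwidth(m: BandwidthMeasurement) -> float:
    """Quality factor from a -3 dB bandwidth: ``f_r / (f_H - f_L)``."""
    return m.f_r / (m.f_H - m.f_L)


def implied_bandwidth(q: float, f_r: float) -> float:
    """-3 dB bandwidth ``f_r/Q`` implied by a quality factor (algebraic inverse)."""
    if q <= 0 or f_r <= 0:
        raise ValueError("q and f_r must be positive")
    return f_r / q


def cycles_to_halve(q: float) -> float:
    """Carrier cycles over which the ring-down envelope halves: ``N = Q ln2 / pi``."""
    if not q > 0:
        raise ValueError(f"Q must be positive, got {q}")
    return q * math.log(2.0) / math.pi


def _estimate_carrier(trace: Trace) -> float:
    """Carrier frequency from the magnitude spectrum, parabolically refined."""
    v = trace.v - np.mean(trace.v)
    n = len(v)
    mag = np.abs(np.fft.rfft(v * np.hanning(n)))
    k = int(np.argmax(mag[1:])) + 1
    # 3-point parabolic refinement of the spectral peak position
    if 1 <= k < len(mag) - 1:
        a, b, c = mag[k - 1], mag[k], mag[k + 1]
        denom = a - 2 * b + c
        delta = 0.5 * (a - c) / denom if denom != 0 else 0.0
        delta = float(np.clip(delta, -0.5, 0.5))
    else:
        delta = 0.0
    return (k + delta) * trace.rate / n


def _refined_peaks(trace: Trace, period_samples: float):
    """Positive carrier peaks (one per cycle) with parabolic refinement.

    Returns (times, values) of local maxima of v separated by at least
    0.7 carrier periods.

    The trace is pre-smoothed with a short zero-phase moving average
    (about a tenth of a carrier period).  Because the ring-down is
    self-similar from cycle to cycle, the smoothing attenuates every
    peak by the same factor, which cancels exactly in the halving ratio
    and in the log-fit slope while suppressing the upward bias of
    picking maxima in noise.
    """
    v = trace.v
    m = int(period_samples / 10)
    if m % 2 == 0:
        m += 1
    if m >= 3:
        v = np.convolve(v, np.ones(m) / m, mode="same")
    idx, _ = find_peaks(v, distance=max(1, int(0.7 * period_samples)))
    # drop peaks inside the convolution edge zone: the zero-padded ends
    # attenuate the signal there and can fabricate a biased first peak
    guard = max(m, 1)
    idx = idx[(idx >= guard) & (idx < len(v) - guard)]
    if idx.size == 0:
        return np.zeros(0), np.zeros(0)
    tp = np.empty(idx.size)
    vp = np.empty(idx.size)
    dt = 1.0 / trace.rate
    for j, k in enumerate(idx):
        if 0 < k < len(v) - 1:
            a, b, c = v[k - 1], v[k], v[k + 1]
            denom = a - 2 * b + c
            delta = 0.5 * (a - c) / denom if denom != 0 else 0.0
            delta = float(np.clip(delta, -0.5, 0.5))
            tp[j] = trace.t[k] + delta * dt
            vp[j] = b - 0.25 * (a - c) * delta
        else:
            tp[j] = trace.t[k]
            vp[j] = v[k]
    return tp, vp


def q_from_ringdown(
    trace: Trace,
    method: str = "decimal-fit",
    carrier_hz: float | None = None,
    rounded_constant: bool = False,
) -> RingdownEstimate:
    """Estimate Q from the ring-down portion of a trace.

    The switch-off point is taken as the global envelope maximum; the
    ring-down is the train of positive carrier peaks from there on, with
    the first of them serving as the reference amplitude.

    Parameters
    ----------
    trace : Trace
        Oscilloscope-style record containing a decaying oscillation with
        at least three detectable positive peaks after switch-off.
    method : {"integer-count", "decimal-fit"}
        Cycle counting to the half-amplitude crossing, or log-linear
        peak fit (fractional N, better precision).
    carrier_hz : float, optional
        Carrier frequency; estimated from the spectrum when omitted.
    rounded_constant : bool, optional
        Use the bench constant 4.53 instead of pi/ln2 ~= 4.5324 when
        converting N to Q (reproduces hand calculations such as
        Q = 4.53 x 11 = 49.83).

    Returns
    -------
    RingdownEstimate

    Raises
    ------
    RingdownError
        If fewer than three usable peaks are found, the peaks do not
        decay, or no half-amplitude crossing exists (integer-count).
    """
    if method not in ("integer-count", "decimal-fit"):
        raise ValueError(f"unknown method {method!r}")
    f_c = _estimate_carrier(trace) if carrier_hz is None else float(carrier_hz)
    if f_c <= 0:
        raise RingdownError("could not determine a positive carrier frequency")
    period_samples = trace.rate / f_c
    if period_samples < 4:
        raise RingdownError("sample rate too low relative to the carrier")

    tp, vp = _refined_peaks(trace, period_samples)
    # ring-down = peaks at/after the global envelope maximum
    k_off = int(np.argmax(np.abs(trace.v)))
    t_off = trace.t[k_off]
    sel = tp >= t_off - 0.5 / f_c
    tp, vp = tp[sel], vp[sel]
    if tp.size < 3:
        raise RingdownError(
            f"need at least 3 positive peaks after switch-off, found {tp.size}"
        )
    ref = vp[0]
    if ref <= 0:
        raise RingdownError("reference peak amplitude is not positive")
    cycles = np.round((tp - tp[0]) * f_c)

    constant = ROUNDED_CONSTANT if rounded_constant else EXACT_CONSTANT

    if method == "integer-count":
        below = np.nonzero(vp <= 0.5 * ref * (1.0 + _HALF_SLACK))[0]
        if below.size == 0:
            raise RingdownError(
                "envelope never drops to half the reference peak within the trace"
            )
        n = float(cycles[below[0]])
        if n <= 0:
            raise RingdownError("trace does not decay: half-crossing at cycle 0")
        return RingdownEstimate(
            n=n, q=constant * n, fit_points=int(below[0]) + 1,
            residual=0.0, method=method, carrier_hz=f_c,
        )

    keep = vp >= _FIT_FLOOR * ref
    x = cycles[keep]
    y = np.log(vp[keep])
    if x.size < 3:
        raise RingdownError("fewer than 3 peaks above the fit floor")
    # weight by peak amplitude: var(log v) ~ var(v)/v^2, and the upward
    # bias of per-cycle maximum picking also grows as the peaks fade
    slope, intercept = np.polyfit(x, y, 1, w=vp[keep])
    if slope >= 0:
        raise RingdownError("peak amplitudes do not decay")
    n = math.log(2.0) / abs(slope)
    resid = float(np.sqrt(np.mean((y - (slope * x + intercept)) ** 2)))
    return RingdownEstimate(
        n=n, q=constant * n, fit_points=int(x.size),
        residual=resid, method=method, carrier_hz=f_c,
    )
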