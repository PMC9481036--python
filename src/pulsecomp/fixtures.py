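"""Seeded synthetic oscilloscope traces: ring-downs and modulated pulse records.

These generators stand in for the bench (coil + sniffer loop + scope) so
that every estimator and design routine can be exercised offline.  Noise
is additive white Gaussian at the trace level; identical inputs and seed
give bit-identical traces.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .coil_model import CoilParams, PulseTrain, Trace, envelope_response
from .qfactor import EXACT_CONSTANT

__all__ = [
    "NoiseSpec",
    "gen_ringdown_trace",
    "gen_pulse_trace",
    "q_for_halving_cycles",
    "DEFAULT_RATE",
]

#: Default sample rate, 50 MS/s: 50 samples per cycle at a 1 MHz carrier,
#: typical of bench oscilloscopes used for ring-down measurements.
DEFAULT_RATE = 50e6


@dataclass(frozen=True)
class NoiseSpec:
    """Additive white Gaussian noise: standard deviation (volts) and seed."""

    sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError(f"noise sd must be >= 0, got {self.sd}")


def q_for_halving_cycles(n_cycles: float) -> float:
    """Quality factor whose ring-down envelope halves in exactly ``n_cycles``."""
    if not n_cycles > 0:
        raise ValueError("n_cycles must be positive")
    return EXACT_CONSTANT * n_cycles


def gen_ringdown_trace(
    f_hz: float,
    q: float,
    a0: float = 1.0,
    duration_s: float = 40e-6,
    rate: float = DEFAULT_RATE,
    noise: NoiseSpec | None = None,
) -> Trace:
    """Synthetic ring-down: ``a0 * exp(-t/T) * cos(2*pi*f*t)`` plus noise.

    ``T = 2Q/omega``; the drive is considered switched off at t = 0.
    The generating parameters are recorded in ``Trace.meta``.
    """
    if f_hz <= 0 or q <= 0 or duration_s <= 0:
        raise ValueError("f_hz, q and duration_s must be positive")
    if rate < 20 * f_hz:
        raise ValueError(
            f"rate {rate:g} too low: need >= {20 * f_hz:g} samples/s (20 per cycle)"
        )
    noise = noise or NoiseSpec()
    T = 2.0 * q / (2.0 * math.pi * f_hz)
    n = int(round(duration_s * rate)) + 1
    t = np.arange(n) / rate
    v = a0 * np.exp(-t / T) * np.cos(2.0 * math.pi * f_hz * t)
    if noise.sd > 0:
        rng = np.random.default_rng(noise.seed)
        v = v + rng.normal(0.0, noise.sd, size=n)
    return Trace(
        t=t, v=v, rate=rate,
        meta={"kind": "ringdown", "f_hz": f_hz, "q": q, "a0": a0,
              "noise_sd": noise.sd, "seed": noise.seed},
    )


def gen_pulse_trace(
    train: PulseTrain,
    coil: CoilParams,
    rate: float = DEFAULT_RATE,
    noise: NoiseSpec | None = None,
    tail_s: float | None = None,
) -> Trace:
    """Carrier-modulated coil response to a drive train, plus noise.

    The instantaneous voltage is ``A(t) * cos(2*pi*f_r*t)`` where
    ``A(t)`` is the signed model envelope (negative values implement the
    180-degree phase flip of damping lobes).  ``tail_s`` extends the
    record past the drive to capture ring-down (default: 10 time
    constants).
    """
    if rate < 20 * coil.f_r:
        raise ValueError(
            f"rate {rate:g} too low: need >= {20 * coil.f_r:g} samples/s (20 per cycle)"
        )
    noise = noise or NoiseSpec()
    if tail_s is None:
        tail_s = 10.0 * coil.time_constant
    duration = train.duration + tail_s
    n = int(round(duration * rate)) + 1
    t = np.arange(n) / rate
    env = envelope_response(train, coil, t)
    v = env * np.cos(2.0 * math.pi * coil.f_r * t)
    if noise.sd > 0:
        rng = np.random.default_rng(noise.seed)
        v = v + rng.normal(0.0, noise.sd, size=n)
    return Trace(
        t=t, v=v, rate=rate,
        meta={"kind": "pulse", "f_hz": coil.f_r, "q": coil.q,
              "noise_sd": noise.sd, "seed": noise.seed},
    )
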