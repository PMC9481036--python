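"""Compensation pulse design for a first-order resonant coil.

Two constructions:

**Square pulse.**  A bare square drive rises with time constant
``T = 2Q/omega`` and rings down just as slowly.  Prepending an
overdriven *pre-emphasis* segment of amplitude ``V0 > V1`` for

    tau0 = -T * ln(1 - V1/V0)

brings the envelope to the working level V1 exactly when the main pulse
starts; appending a 180-degree phase-inverted *damping* segment of
amplitude V2 for

    tau2 = T * ln(1 + (V1/V2) * (1 - exp(-tau1/T)))

cancels the stored energy, driving the envelope to exactly zero.  The
``(1 - exp(-tau1/T))`` factor is the fraction of the equilibrium level
actually reached by an *uncompensated* rise of length tau1; when
pre-emphasis holds the envelope at V1 the factor is 1 (the
``tau1 = inf`` limit).

**Arbitrary sampled target (e.g. sinc).**  Given target envelope values
``A_n`` at ``t_n = n*dt``, the piecewise-constant drive that makes the
model envelope pass through every sample is obtained by deconvolving the
first-order response one interval at a time:

    V_n = (A_n - A_{n-1} * E) / (1 - E),      E = exp(-dt/T),

with ``A_0 = 0``.  This incremental recursion is algebraically identical
to the explicit sum formulation (substituting each V_k back into the
envelope propagation), and it is exact: no iteration or fitting.

For a truncated sinc with ``N0`` zero crossings per side, sampling at
``N_S = 4*i*N0 + 1`` uniform points (integer density ``i >= 1``) places
a sample on every lobe centre and every zero crossing.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass
import numpy as np

from .coil_model import CoilParams, PulseSegment, PulseTrain

__all__ = [
    "SquareCompensation",
    "SincSpec",
    "SampledTarget",
    "pre_emphasis_duration",
    "damping_duration",
    "compensate_square",
    "sample_sinc",
    "sample_count",
    "compensation_train",
    "AmplifierLimitWarning",
]

logger = logging.getLogger(__name__)


class AmplifierLimitWarning(UserWarning):
    """Computed drive amplitudes exceed the configured amplifier ceiling."""


@dataclass(frozen=True)
class SquareCompensation:
    """Pre-emphasis / main / damping description of a compensated square pulse.

    ``v2`` is stored positive; it is applied with inverted sign (180
    degrees out of phase).  Durations in seconds.
    """

    v0: float
    v1: float
    v2: float
    tau0: float
    tau1: float
    tau2: float

    def __post_init__(self) -> None:
        if not (self.v0 >= self.v1 > 0):
            raise ValueError("require V0 >= V1 > 0")
        if not self.v2 > 0:
            raise ValueError("require V2 > 0")
        if self.tau0 < 0 or self.tau2 < 0 or self.tau1 <= 0:
            raise ValueError("require tau0, tau2 >= 0 and tau1 > 0")

    def as_train(self) -> PulseTrain:
        """Three-segment drive train: +V0, +V1, -V2."""
        segs = []
        if self.tau0 > 0:
            segs.append(PulseSegment(self.v0, self.tau0))
        segs.append(PulseSegment(self.v1, self.tau1))
        if self.tau2 > 0:
            segs.append(PulseSegment(-self.v2, self.tau2))
        return PulseTrain(tuple(segs))


@dataclass(frozen=True)
class SincSpec:
    """Provenance of a sinc-derived sampled target."""

    n0: int
    i: int
    ns: int
    bandwidth: float
    amplitude: float


@dataclass(frozen=True)
class SampledTarget:
    """Target envelope values ``A_1..A_n`` at times ``t_n = n*dt``.

    The implicit ``A_0 = 0`` at ``t = 0`` is the coil's initial state and
    is not stored.  ``sinc`` carries provenance when the target was
    generated from a sinc (then ``len(amplitudes) == ns - 1``).
    """

    dt: float
    amplitudes: np.ndarray
    sinc: SincSpec | None = None

    def __post_init__(self) -> None:
        amps = np.atleast_1d(np.asarray(self.amplitudes, dtype=float))
        object.__setattr__(self, "amplitudes", amps)
        if not (self.dt > 0 and math.isfinite(self.dt)):
            raise ValueError(f"dt must be positive and finite, got {self.dt}")
        if amps.size < 1:
            raise ValueError("a target needs at least one sample")
        if not np.all(np.isfinite(amps)):
            raise ValueError("target amplitudes must be finite")

    @property
    def times(self) -> np.ndarray:
        """Sample times ``dt, 2*dt, ..., n*dt``."""
        return self.dt * np.arange(1, self.amplitudes.size + 1)


def pre_emphasis_duration(v0: float, v1: float, coil: CoilParams) -> float:
    """Duration of the overdriven rise segment.

    ``tau0 = -T * ln(1 - V1/V0)``: driving at ``V0 > V1`` for tau0 brings
    the envelope from zero to exactly V1.

    Raises
    ------
    ValueError
        If ``V0 <= V1`` (the equilibrium level would never reach V1).
    """
    if not v1 > 0:
        raise ValueError(f"V1 must be positive, got {v1}")
    if not v0 > v1:
        raise ValueError(
            f"pre-emphasis requires V0 > V1 (equilibrium at V0 never reaches V1): "
            f"got V0={v0}, V1={v1}"
        )
    return -coil.time_constant * math.log1p(-v1 / v0)


def damping_duration(v1: float, v2: float, tau1: float, coil: CoilParams) -> float:
    """Duration of the phase-inverted damping segment that zeroes the envelope.

    ``tau2 = T * ln(1 + (V1/V2) * (1 - exp(-tau1/T)))`` where tau1 is the
    length of the preceding uncompensated rise at V1.  ``tau1 = inf``
    (envelope at equilibrium, e.g. after pre-emphasis) selects the
    simpler ``T * ln(1 + V1/V2)`` form.
    """
    if not (v1 > 0 and v2 > 0):
        raise ValueError(f"amplitudes must be positive, got V1={v1}, V2={v2}")
    if not tau1 > 0:
        raise ValueError(f"tau1 must be positive (or inf), got {tau1}")
    T = coil.time_constant
    reached = 1.0 if math.isinf(tau1) else 1.0 - math.exp(-tau1 / T)
    return T * math.log1p((v1 / v2) * reached)


def compensate_square(
    v1: float,
    tau1: float,
    coil: CoilParams,
    overdrive: float = 3.0,
    pre_emphasis: bool = True,
) -> SquareCompensation:
    """Design the three-segment compensated square pulse.

    ``V0 = V2 = overdrive * V1`` (default overdrive 3).  With
    pre-emphasis the envelope reaches V1 at tau0, is held at V1 through
    the main segment, and the damping duration is computed for the
    equilibrium switch-off level; without pre-emphasis (``tau0 = 0``)
    the envelope rises freely during tau1 and the damping duration
    accounts for the partially reached level.  In both cases the model
    envelope is exactly zero at the end of the train.

    Parameters
    ----------
    v1 : float
        Working (main pulse) amplitude, > 0.
    tau1 : float
        Main pulse duration in seconds, > 0.
    coil : CoilParams
        Coil description.
    overdrive : float, optional
        Ratio V0/V1 = V2/V1, must exceed 1.
    pre_emphasis : bool, optional
        Include the overdriven rise segment (default True).
    """
    if not overdrive > 1:
        raise ValueError(f"overdrive must exceed 1, got {overdrive}")
    if not tau1 > 0:
        raise ValueError(f"tau1 must be positive, got {tau1}")
    v0 = v2 = overdrive * v1
    if pre_emphasis:
        tau0 = pre_emphasis_duration(v0, v1, coil)
        tau2 = damping_duration(v1, v2, math.inf, coil)
    else:
        tau0 = 0.0
        tau2 = damping_duration(v1, v2, tau1, coil)
    return SquareCompensation(v0=v0, v1=v1, v2=v2, tau0=tau0, tau1=tau1, tau2=tau2)


def sample_count(n0: int, i: int) -> int:
    """Number of samples ``N_S = 4*i*N0 + 1`` covering a truncated sinc."""
    if n0 < 1 or i < 1:
        raise ValueError(f"N0 and i must be integers >= 1, got N0={n0}, i={i}")
    return 4 * i * n0 + 1


def sample_sinc(
    n0: int,
    i: int,
    bandwidth: float,
    amplitude: float = 1.0,
) -> SampledTarget:
    """Uniformly sample a truncated sinc envelope for compensation.

    The sinc has ``N0`` zero crossings on each side of the centre and
    zero-crossing spacing ``t0 = 1/bandwidth`` (null-to-null main-lobe
    width ``2/bandwidth``).  ``N_S = 4*i*N0 + 1`` samples span
    ``[-N0*t0, +N0*t0]``, so ``dt = t0/(2i)`` and the sample set contains
    every lobe centre and every zero crossing.  The leading sample (the
    sinc's starting zero) is the coil's initial state and is dropped,
    leaving ``N_S - 1`` drive intervals.

    Returns
    -------
    SampledTarget
        With ``sinc`` provenance recording (N0, i, N_S, bandwidth).
    """
    ns = sample_count(n0, i)
    if not bandwidth > 0:
        raise ValueError(f"bandwidth must be positive, got {bandwidth}")
    if not math.isfinite(amplitude):
        raise ValueError("amplitude must be finite")
    t0 = 1.0 / bandwidth
    dt = t0 / (2 * i)
    j = np.arange(1, ns)  # drop the leading t = -N0*t0 sample (value 0)
    x = -n0 + j / (2 * i)  # time in units of t0
    amps = amplitude * np.sinc(x)
    return SampledTarget(
        dt=dt,
        amplitudes=amps,
        sinc=SincSpec(n0=n0, i=i, ns=ns, bandwidth=bandwidth, amplitude=amplitude),
    )


def compensation_train(
    target: SampledTarget,
    coil: CoilParams,
    max_amplitude: float | None = None,
) -> PulseTrain:
    """Piecewise-constant drive forcing the envelope through every target sample.

    Solves the first-order model interval by interval:
    ``V_n = (A_n - A_{n-1}*E) / (1 - E)`` with ``E = exp(-dt/T)`` and
    ``A_0 = 0``.  Driving the coil with the returned train makes the
    model envelope equal ``A_n`` at every ``t_n`` exactly.

    Parameters
    ----------
    target : SampledTarget
        Envelope samples to hit.
    coil : CoilParams
        Coil description.
    max_amplitude : float, optional
        Amplifier ceiling.  Exceeding it emits an
        :class:`AmplifierLimitWarning` naming the offending segments
        (the train is still returned: controlled overdrive is the whole
        point of the method).
    """
    T = coil.time_constant
    E = math.exp(-target.dt / T)
    amps = target.amplitudes
    drive = np.empty(amps.size)
    prev = 0.0
    for n, a_n in enumerate(amps):
        drive[n] = (a_n - prev * E) / (1.0 - E)
        prev = a_n
    if max_amplitude is not None:
        over = np.nonzero(np.abs(drive) > max_amplitude)[0]
        if over.size:
            msg = (
                f"{over.size} segment(s) exceed the amplifier limit "
                f"{max_amplitude:g}: indices {over.tolist()} "
                f"(max |V| = {np.max(np.abs(drive)):.4g})"
            )
            logger.warning(msg)
            warnings.warn(msg, AmplifierLimitWarning, stacklevel=2)
    return PulseTrain(tuple(PulseSegment(float(v), target.dt) for v in drive))
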