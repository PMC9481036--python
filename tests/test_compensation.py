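"""Compensation design: pre-emphasis, damping, sinc sampling, deconvolution."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.optimize import brentq

from pulsecomp import (
    CoilParams,
    SampledTarget,
    compensate_square,
    compensation_train,
    damping_duration,
    envelope_response,
    pre_emphasis_duration,
    sample_count,
    sample_sinc,
)
from pulsecomp.compensation import AmplifierLimitWarning


def closed_form_amplitudes(targets: np.ndarray, E: float) -> np.ndarray:
    """Independent oracle: the explicit sum form of the deconvolution.

    V_n = (A_n - sum_{k=1}^{n-1} V_k (1-E) E^{n-k}) / (1 - E), with the
    k = 0 term identically zero (zero initial drive and envelope).
    """
    v = np.zeros(len(targets))
    for n in range(1, len(targets) + 1):
        s = sum(v[k - 1] * (1 - E) * E ** (n - k) for k in range(1, n))
        v[n - 1] = (targets[n - 1] - s) / (1 - E)
    return v


# -- pre-emphasis duration ---------------------------------------------------


def test_pre_emphasis_duration_values(coil):
    T = coil.time_constant
    # bench amplitudes: V0 = 120.3, V1 = 40.1 (ratio 1/3)
    tau0 = pre_emphasis_duration(120.3e-3, 40.1e-3, coil)
    assert tau0 == pytest.approx(T * math.log(1.5), rel=1e-12)
    assert tau0 == pytest.approx(6.431e-6, rel=1e-3)
    # vanishing target level -> vanishing duration
    assert pre_emphasis_duration(1.0, 1e-9, coil) == pytest.approx(1e-9 * T, rel=1e-6)


def test_pre_emphasis_requires_overdrive(coil):
    with pytest.raises(ValueError, match="V0 > V1"):
        pre_emphasis_duration(1.0, 1.0, coil)
    with pytest.raises(ValueError, match="V0 > V1"):
        pre_emphasis_duration(0.5, 1.0, coil)


def test_pre_emphasis_lands_exactly_on_v1(coil):
    """Driving at V0 for tau0 brings the model envelope to V1 exactly."""
    from pulsecomp import PulseSegment, PulseTrain

    v0, v1 = 3.0, 1.0
    tau0 = pre_emphasis_duration(v0, v1, coil)
    env = envelope_response(PulseTrain((PulseSegment(v0, tau0),)), coil, [tau0])[0]
    assert env == pytest.approx(v1, rel=1e-12)


# -- damping duration --------------------------------------------------------


def test_damping_duration_values(coil):
    T = coil.time_constant
    # equilibrium switch-off with V1 = V2: T ln 2
    assert damping_duration(1.0, 1.0, math.inf, coil) == pytest.approx(
        T * math.log(2), rel=1e-12
    )
    # short main pulse: almost nothing stored, tau2 ~ tau1 * V1/V2 -> 0
    assert damping_duration(1.0, 1.0, 1e-12, coil) == pytest.approx(1e-12, rel=1e-3)
    # partially risen main pulse, ratio 1/3, tau1 = 40 us
    tau2 = damping_duration(40.1e-3, 120.3e-3, 40e-6, coil)
    assert tau2 == pytest.approx(T * math.log1p((1 / 3) * (1 - math.exp(-40e-6 / T))), rel=1e-12)
    assert tau2 == pytest.approx(4.241e-6, rel=1e-3)


def test_damping_reduces_to_equilibrium_form_for_long_pulses(coil):
    """The finite-tau1 expression converges to the tau1->inf form by 20 T."""
    T = coil.time_constant
    finite = damping_duration(1.0, 3.0, 20 * T, coil)
    equil = damping_duration(1.0, 3.0, math.inf, coil)
    assert abs(finite - equil) / equil < 1e-6


def test_damping_monotonicity(coil):
    # tau2 grows with V1/V2 and with tau1
    t_small = damping_duration(1.0, 3.0, 20e-6, coil)
    t_big_ratio = damping_duration(2.0, 3.0, 20e-6, coil)
    t_long_pulse = damping_duration(1.0, 3.0, 60e-6, coil)
    assert t_big_ratio > t_small
    assert t_long_pulse > t_small
    # tau0 falls as the overdrive grows
    assert pre_emphasis_duration(4.0, 1.0, coil) < pre_emphasis_duration(2.0, 1.0, coil)


def test_durations_match_numerical_envelope_rootfind(coil):
    """Closed-form durations vs root-finding the model envelope crossings.

    Independent check at the bench voltage ratio (V0 = V2 = 3 V1): tau0
    is where the overdriven rise crosses V1, and tau2 is where the
    envelope, starting from the level reached after a free rise of tau1
    and driven at -V2, crosses zero.  Agreement to 1e-9 relative.
    """
    T = coil.time_constant
    v1, v0 = 40.1e-3, 120.3e-3
    tau1 = 40e-6

    tau0 = pre_emphasis_duration(v0, v1, coil)
    tau0_num = brentq(
        lambda t: v0 * (1 - math.exp(-t / T)) - v1, 1e-12, 10 * T, xtol=1e-18, rtol=1e-15
    )
    assert tau0 == pytest.approx(tau0_num, rel=1e-9)

    a_off = v1 * (1 - math.exp(-tau1 / T))  # free rise, no pre-emphasis
    v2 = v0
    tau2 = damping_duration(v1, v2, tau1, coil)
    tau2_num = brentq(
        lambda t: -v2 + (a_off + v2) * math.exp(-t / T), 1e-12, 10 * T,
        xtol=1e-18, rtol=1e-15,
    )
    assert tau2 == pytest.approx(tau2_num, rel=1e-9)


# -- compensate_square -------------------------------------------------------


def test_compensated_square_amplitudes_and_profile(coil):
    """Overdrive 3 on V1 = 40.1 mV gives the 120.3 / 40.1 / 120.3 mV triple,
    and the simulated envelope reaches V1 at tau0, holds it, and ends at 0."""
    comp = compensate_square(v1=40.1e-3, tau1=40e-6, coil=coil, overdrive=3.0)
    assert comp.v0 == pytest.approx(120.3e-3)
    assert comp.v2 == pytest.approx(120.3e-3)
    train = comp.as_train()
    probes = [comp.tau0, comp.tau0 + 0.5 * comp.tau1, comp.tau0 + comp.tau1,
              train.duration]
    env = envelope_response(train, coil, probes)
    assert env[0] == pytest.approx(40.1e-3, rel=1e-12)
    assert env[1] == pytest.approx(40.1e-3, rel=1e-12)
    assert env[2] == pytest.approx(40.1e-3, rel=1e-12)
    assert abs(env[3]) < 1e-9


def test_compensated_square_without_pre_emphasis_ends_at_zero(coil):
    comp = compensate_square(v1=1.0, tau1=25e-6, coil=coil, overdrive=3.0,
                             pre_emphasis=False)
    assert comp.tau0 == 0.0
    train = comp.as_train()
    assert abs(envelope_response(train, coil, [train.duration])[0]) < 1e-9


@given(
    v1=st.floats(1e-3, 10.0),
    tau1_us=st.floats(1.0, 100.0),
    overdrive=st.floats(1.1, 20.0),
    q=st.floats(5.0, 200.0),
    pre=st.booleans(),
)
def test_envelope_zero_at_train_end_for_random_designs(v1, tau1_us, overdrive, q, pre):
    coil = CoilParams(f_r=1e6, q=q)
    comp = compensate_square(v1=v1, tau1=tau1_us * 1e-6, coil=coil,
                             overdrive=overdrive, pre_emphasis=pre)
    train = comp.as_train()
    end = envelope_response(train, coil, [train.duration])[0]
    assert abs(end) < 1e-9 * max(1.0, v1)


def test_large_overdrive_shrinks_corrections(coil):
    """In the instantaneous-correction limit both durations vanish."""
    small = compensate_square(1.0, 40e-6, coil, overdrive=3.0)
    big = compensate_square(1.0, 40e-6, coil, overdrive=1e4)
    assert big.tau0 < small.tau0 / 1e3
    assert big.tau2 < small.tau2 / 1e3


# -- sample_sinc -------------------------------------------------------------


@pytest.mark.parametrize("n0,i,ns", [(3, 1, 13), (3, 2, 25), (3, 3, 37), (1, 1, 5)])
def test_sample_count_rule(n0, i, ns):
    assert sample_count(n0, i) == ns
    target = sample_sinc(n0, i, bandwidth=90e3)
    assert target.sinc.ns == ns
    # the stored drive intervals exclude the leading zero sample
    assert target.amplitudes.size == ns - 1


def test_sinc_samples_hit_zeros_and_lobe_centres():
    bw = 30e3
    t0 = 1 / bw
    target = sample_sinc(3, 1, bandwidth=bw, amplitude=1.0)
    # absolute sinc times of the stored samples: -N0*t0 + n*dt
    x = -3 + np.arange(1, 13) / 2  # in units of t0
    # every integer x is a zero crossing; the centre (x=0) is the peak
    zeros = np.isclose(x % 1, 0) & (x != 0)
    assert np.allclose(target.amplitudes[zeros], 0.0, atol=1e-12)
    assert target.amplitudes[np.isclose(x, 0)] == pytest.approx(1.0)
    # first side-lobe sample levels: sinc(1/2) = 2/pi
    assert target.amplitudes[np.isclose(x, 0.5)] == pytest.approx(2 / math.pi)
    assert target.amplitudes[np.isclose(x, -2.5)] == pytest.approx(
        math.sin(2.5 * math.pi) / (2.5 * math.pi)
    )
    assert target.dt == pytest.approx(t0 / 2)


def test_sample_sinc_validation():
    with pytest.raises(ValueError):
        sample_sinc(0, 1, 1e3)
    with pytest.raises(ValueError):
        sample_sinc(3, 0, 1e3)
    with pytest.raises(ValueError):
        sample_sinc(3, 1, -5.0)


# -- compensation_train ------------------------------------------------------


def test_zero_target_gives_zero_drive(coil):
    target = SampledTarget(dt=1e-6, amplitudes=np.zeros(10))
    train = compensation_train(target, coil)
    assert np.all(train.amplitudes() == 0.0)


def test_constant_target_closed_form(coil):
    """For A_n = A: V_1 = A/(1-E) jumps the envelope up, then V_n = A holds it."""
    A, dt = 0.7, 2e-6
    E = math.exp(-dt / coil.time_constant)
    target = SampledTarget(dt=dt, amplitudes=np.full(8, A))
    v = compensation_train(target, coil).amplitudes()
    assert v[0] == pytest.approx(A / (1 - E), rel=1e-12)
    np.testing.assert_allclose(v[1:], A, rtol=1e-12)


@pytest.mark.parametrize("i,ns", [(1, 13), (2, 25), (3, 37)])
@pytest.mark.parametrize("bw", [30e3, 90e3, 150e3])
def test_sinc_compensation_interpolates_exactly(coil, i, ns, bw):
    """The model envelope passes through every sinc sample to 1e-9."""
    target = sample_sinc(3, i, bandwidth=bw)
    train = compensation_train(target, coil)
    assert len(train) == ns - 1
    env = envelope_response(train, coil, target.times)
    np.testing.assert_allclose(env, target.amplitudes, atol=1e-9)


@given(
    n=st.integers(1, 200),
    dt_us=st.floats(0.05, 20.0),
    seed=st.integers(0, 2**31 - 1),
)
def test_recursion_equals_closed_form(n, dt_us, seed):
    """Incremental deconvolution == explicit sum form, to 1e-12 relative."""
    rng = np.random.default_rng(seed)
    amps = rng.uniform(-1, 1, size=n)
    coil = CoilParams(f_r=1e6, q=49.83)
    target = SampledTarget(dt=dt_us * 1e-6, amplitudes=amps)
    v_rec = compensation_train(target, coil).amplitudes()
    E = math.exp(-target.dt / coil.time_constant)
    v_sum = closed_form_amplitudes(amps, E)
    np.testing.assert_allclose(v_rec, v_sum, rtol=1e-12, atol=1e-12)


@given(seed=st.integers(0, 1000))
def test_random_target_interpolated_exactly(coil, seed):
    rng = np.random.default_rng(seed)
    target = SampledTarget(dt=rng.uniform(0.2, 5) * 1e-6,
                           amplitudes=rng.uniform(-2, 2, size=rng.integers(1, 40)))
    train = compensation_train(target, coil)
    env = envelope_response(train, coil, target.times)
    np.testing.assert_allclose(env, target.amplitudes, atol=1e-9)


def test_denser_sampling_needs_larger_drive(coil):
    """Shorter intervals demand stronger overdrive spikes at matched lobes."""
    v13 = np.abs(compensation_train(sample_sinc(3, 1, 90e3), coil).amplitudes())
    v37 = np.abs(compensation_train(sample_sinc(3, 3, 90e3), coil).amplitudes())
    assert v37.max() >= v13.max()


def test_amplifier_limit_warns_but_returns(coil):
    target = sample_sinc(3, 3, 150e3)
    with pytest.warns(AmplifierLimitWarning, match="exceed"):
        train = compensation_train(target, coil, max_amplitude=0.5)
    assert len(train) == 36
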