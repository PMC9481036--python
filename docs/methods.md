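# Methods

## Coil model

The transmit coil is modelled two ways.

**First-order envelope model (the working engine).** In the rotating
frame at the resonance frequency, the signed envelope A(t) of a
series-resonant coil driven by a piecewise-constant signed amplitude
V(t) obeys

    dA/dt = (ω / 2Q) (V(t) − A),   A(0) = 0,   T = 2Q/ω.

Within each constant segment this is propagated *analytically*
(A → V + (A₀ − V)e^{−Δ/T}), so the response to any square-segment train
is exact to machine precision — there is no integrator error anywhere
in the design path. Impedance is normalised to unit gain: the
equilibrium envelope equals the drive amplitude. Every design formula
in the package depends only on voltage ratios, which are gain-invariant;
an explicit scalar gain is available for dimensional traces. Signed
amplitudes encode carrier phase: a negative segment is 180° out of
phase (the damping-lobe convention), which makes cancellation of stored
energy an ordinary subtraction in the rotating frame.

**Second-order circuit model (the independent check).** The full series
RLC equation L di/dt + R i + q/C = V₀(t)·cos(ω_d t) is integrated at
carrier level with a fixed-step classical 4th-order Runge–Kutta scheme,
at least 40 steps per carrier cycle (local truncation error well below
10⁻⁶ of the signal for these smooth drives), from zero initial charge
and current. The output is R·i(t), so the on-resonance steady-state
envelope equals the drive amplitude, matching the normalised first-order
model. This model is used only as an oracle in tests, never in design.

**Agreement between the two.** The first-order model is a rotating-wave
approximation: the circuit's counter-rotating transient contributes a
relative deviation of order 1/(2Q) that decays within the first couple
of carrier cycles. Measured agreement (envelope extracted from the
simulated carrier trace vs the analytic envelope) is below 2% for
Q ∈ {20, 50, 100} once the first two carrier periods are excluded,
evaluated pointwise where the envelope exceeds 10% of the drive
(pointwise relative error is not meaningful near envelope zeros; below
the floor the absolute deviation stays under 0.6% of full scale). The
final partial cycle is also excluded — the envelope extractor has no
peak beyond it to interpolate to.

## Q estimation

After switch-off the envelope decays as e^{−t/T}, halving every
N = Q ln2/π carrier cycles, so Q = (π/ln2)·N ≈ 4.5324·N.

* **integer-count**: N is the number of whole carrier cycles from the
  first post-switch-off peak (the reference) to the first peak at or
  below half the reference. A relative slack of 10⁻⁶ on the threshold
  makes an envelope that halves *exactly* at cycle N count as N rather
  than spill to N+1 through rounding. By default the exact constant
  π/ln2 is used; `rounded_constant=True` reproduces the two-decimal
  bench arithmetic Q = 4.53·N (e.g. 4.53 × 11 = 49.83).
* **decimal-fit**: a straight-line fit of log(peak) against cycle
  index; N = ln2/|slope|. The fit is weighted by peak amplitude
  (var(log v) ≈ var(v)/v²) and restricted to peaks above 0.2× the
  reference, because the faintest peaks are dominated by the upward
  bias of picking maxima in noise.

Peak bookkeeping: the switch-off point is the global envelope maximum;
ring-down peaks are the positive local maxima of v (one per carrier
cycle) separated by at least 0.7 periods, each refined by a three-point
parabola. Before peak picking the trace is smoothed with a zero-phase
moving average about a tenth of a carrier period long; because the
ring-down is self-similar cycle to cycle, the smoothing attenuates all
peaks by the same factor — cancelling exactly in the halving ratio and
the fitted slope — while suppressing the noise-selection bias. Peaks
inside the convolution edge zone of the trace are discarded. The
carrier frequency, when not supplied, is estimated from the
parabolically refined FFT peak.

Performance under the synthetic study conditions (1 MHz carrier,
50 MS/s, 80 µs records): the decimal fit recovers the generating Q
exactly (to rounding) on noiseless traces and within ~2% at 40 dB
amplitude SNR, for Q between 10 and 100; the integer count is within
one cycle of the fractional N.

Bandwidth route: Q = f_r/(f_H − f_L) from a −3 dB measurement, with the
algebraic inverse (implied bandwidth f_r/Q) provided for round-trips.

## Compensation design

**Square pulse.** Pre-emphasis duration τ₀ = −T ln(1 − V₁/V₀) is the
exact crossing time of the overdriven rise through the working level;
damping duration τ₂ = T ln(1 + (V₁/V₂)(1 − e^{−τ₁/T})) is the exact
zero crossing of the envelope under inverted drive, starting from the
level a free rise of length τ₁ reaches. When pre-emphasis is used the
envelope is *held at equilibrium* (V₁) when the main pulse ends, so the
damping duration is computed in the τ₁ → ∞ limit, T ln(1 + V₁/V₂); the
finite-τ₁ factor applies to the uncompensated rise. Both forms leave
the model envelope at exactly zero at the train end (verified to 10⁻⁹
across random designs). Default overdrive is V₀ = V₂ = 3V₁, the ratio
used on the reference bench; it is configurable, and larger overdrive
shrinks both corrections toward the instantaneous-correction limit.

**Sampled targets.** For target values A_n at t_n = nΔt the drive is
the interval-by-interval deconvolution V_n = (A_n − A_{n−1}E)/(1 − E),
E = e^{−Δt/T}, with A₀ = 0 at t₀ = 0 (drive intervals are (t_{n−1},
t_n]). This is algebraically identical to the explicit superposition
sum over all previous segments (asserted to 10⁻¹² in tests) and is
exact: the model envelope interpolates every sample for any Q and Δt.
Negative targets are legal and become phase-inverted segments. An
optional amplifier ceiling turns excessive |V_n| into a logged warning
(never an error — controlled overdrive is the method's point).

**Sinc sampling.** A truncated sinc with N₀ zero crossings per side and
zero-crossing spacing t₀ is sampled at N_S = 4iN₀ + 1 uniform points
over [−N₀t₀, N₀t₀] (Δt = t₀/2i), which places a sample on every lobe
centre and every zero crossing. The leading sample (value 0 at the
truncation edge) coincides with the coil's initial state and is
dropped, leaving N_S − 1 drive intervals. The bandwidth convention is
t₀ = 1/BW, i.e. main-lobe null-to-null width 2/BW; the sinc spectrum is
then flat over [−BW/2, +BW/2]. Denser sampling tracks the shape more
smoothly but requires larger drive spikes, since 1 − E shrinks with Δt.

A note on the reference bench numbers: the published worked example
pairs Q = 49.83 (T = 15.86 µs) with τ₀ = 4.68 µs and τ₂ = 3.32 µs, but
those durations are mutually consistent only with T ≈ 11.55 µs
(Q ≈ 36.3). The formulas here give 6.43 µs and 4.24 µs at Q = 49.83 for
the same voltage ratios; the package follows the equations, and the
test suite cross-checks them against an independent numerical
root-find of the envelope crossings instead of the printed durations.

## Spectra and the flatness metric

The signed envelope of a carrier-level trace is extracted per half
carrier cycle: the parabolically refined peak of |v|, placed at the
refined peak time (placing it at the cycle centre would lag a rising
envelope by half a cycle), signed by correlation with the carrier
cosine so 180° lobes come out negative, then linearly interpolated to
the trace grid. Requires ≥ 4 samples per carrier cycle; accuracy
improves rapidly with oversampling (0.03% at 50 samples/cycle for a
smooth exponential envelope).

Magnitude spectra are zero-padded discrete Fourier transforms (default
≥ 16× the record length, rounded to an FFT-friendly size) normalised to
peak 1. The flatness metric over a band [f_lo, f_hi] is the mean
absolute deviation of the in-band magnitude from its in-band mean.
Dividing by the number of *in-band* points makes the metric independent
of the zero-padding resolution, and pre-normalisation makes it exactly
scale-invariant; it is zero iff the in-band profile is constant, and
can never exceed 0.5 for magnitudes in [0, 1]. The evaluation band is
[center − BW/2, center + BW/2], with center the carrier frequency for
RF traces and 0 for baseband envelopes (both paths give the same value;
the modulation only translates the spectrum).

**End-to-end simulation.** `sinc_flatness` drives the envelope model
with either the uncompensated sinc (emulated as a dense staircase, 32
steps per zero-crossing interval — zero-order-hold rolloff in band is
below 10⁻³) or a compensation train, on a grid of 32 samples per 1/BW
with an 8T ring-down tail so residual stored energy is captured, then
scores the band [0, BW/2]. At Q = 49.83 and f_r = 1 MHz the
uncompensated error is 0.132/0.200/0.194 over 30/90/150 kHz while the
N_S = 37 compensated pulses score ≈ 0.083–0.086 — flatter everywhere
and essentially bandwidth-independent.

One property of this metric is worth stating: for a normalised profile
shaped by the coil's first-order response, 1/√(1 + (2πfT)²), the
in-band mean absolute deviation grows with bandwidth only up to
(2πT)(BW/2) ≈ 5 — about 100 kHz at this Q — and plateaus near 0.20
beyond it (closed-form values 0.129/0.208/0.201 at 30/90/150 kHz match
the simulation). So "wider band ⇒ larger uncompensated error" holds up
to the plateau but not strictly beyond it; bench measurements that show
continued growth there are seeing effects outside this model (noise
floors, additional filter poles, different normalisation of the
metric).

## Synthetic traces

The generators emulate an oscilloscope watching the coil through a
sniffer loop: a ring-down a₀e^{−t/T}cos(2πft), or a carrier cosine
modulated by the model envelope of an arbitrary train, each with
optional additive white Gaussian noise (seeded; identical inputs and
seed are bit-identical). Default rate 50 MS/s — 50 samples per cycle at
1 MHz, oscilloscope-class. What they deliberately omit: amplifier
nonlinearity and droop, T/R-switch and band-pass-filter dynamics, cable
reflections, carrier-phase noise, and any non-white noise. Passing
recovery tests on these traces therefore validates the estimators and
the design algebra, not the behaviour of a full analog transmit chain.

## Numerical choices

* Envelope propagation and all design formulas: closed-form, no
  tolerances to tune. `log1p` is used where ratios can be small.
* RK4 step: ≥ 40 steps per carrier cycle, fixed; sample rates below 20
  per cycle are rejected with the minimum named.
* Peak refinement: three-point parabola with the offset clipped to
  ±half a sample.
* Integer-count threshold slack 10⁻⁶ (exact-halving tie-break);
  decimal-fit floor 0.2× reference; smoothing window ≈ period/10,
  forced odd.
* Uniform-grid check on traces: 10⁻⁶ relative on the sample period.
* Trace/pulse-table CSV written with 15 significant digits; pulse
  tables with non-positive durations are rejected on read.

## Limitations

* First-order envelope design is exact only for the model; on a real
  chain the achieved envelope inherits every un-modelled pole. The
  second-order oracle bounds the carrier-level discrepancy at 2% for
  Q ≥ 20 after the first two cycles, but only for the bare RLC.
* Off-resonance behaviour is modelled only by the oracle (the envelope
  model assumes on-resonance drive).
* The flatness metric saturates for bandwidths well beyond the coil
  bandwidth (see above); comparisons across very wide bands should use
  the compensated-vs-uncompensated difference, which remains monotone
  in the interesting regime.
* Compensation assumes the drive amplifier is linear up to the largest
  requested overdrive; the amplifier-ceiling warning is advisory only.
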