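"""Score excitation-band flatness of simulated sinc pulses.

The quality of a slice-selective pulse is how flat its magnitude
spectrum is across the excitation band.  The metric is the mean
absolute deviation of the normalised in-band magnitude from its in-band
mean (0 = perfectly flat).  Compensation is most valuable for wide-band
pulses, whose envelope changes faster than the coil can follow.
"""

from pulsecomp import CoilParams, sinc_flatness

coil = CoilParams(f_r=1e6, q=49.83)

print(f"{'bandwidth':>10} {'uncompensated':>14} {'N_S=13':>8} {'N_S=25':>8} {'N_S=37':>8}")
for bw in (30e3, 90e3, 150e3):
    unc = sinc_flatness(coil, bw, n0=3, i=None).relative_error
    comp = [sinc_flatness(coil, bw, n0=3, i=i).relative_error for i in (1, 2, 3)]
    print(f"{bw / 1e3:>8.0f}k {unc:>14.3f} "
          + " ".join(f"{c:>8.3f}" for c in comp))
# The uncompensated error grows as the bandwidth approaches the coil's
# own bandwidth (f_r/Q = 20 kHz), while the compensated pulses stay
# roughly equally flat at every bandwidth - and flatter than the
# uncompensated pulse everywhere.
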