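"""Expected autocorrelation and its sensitivity to particle size.

The forward model predicts the ensemble-averaged speckle autocorrelation
<A(u)> = |M(u)|^2 x |int r^2 Jinc(pi r|u|) p(r) dr / int r^2 p(r) dr|^2.
Sidelobe heights decay with particle size; the cross-sections below show
the size modulation on both pupils and the sensitivity map S(u, r).
"""

import numpy as np

from specklesize import grids
from specklesize.forward import expected_autocorrelation, sensitivity_map
from specklesize.pupil import (engineered_pupil, make_clear_pupil,
                               pupil_power_spectrum)
from specklesize.sizedist import sieve_psd

clear = pupil_power_spectrum(
    make_clear_pupil(5.0, grids.PUPIL_PITCH_MM, grids.PUPIL_GRID), 2)
eng = pupil_power_spectrum(engineered_pupil(), 2)

print("first-order x sidelobe of <A(u)> (lag ~0.73 cycles/mm):")
for low, high in [(106, 180), (250, 300), (425, 500)]:
    p = sieve_psd(low, high)
    a_c = expected_autocorrelation(clear, p).values[32, 32 + 9]
    a_e = expected_autocorrelation(eng, p).values[32, 32 + 9]
    print(f"  {low}-{high} um:  clear {a_c:.5f}   engineered {a_e:.4f}")

print()
print("Sidelobes weaken as particles grow (the size modulation), and the")
print("engineered pupil's sidelobes are orders of magnitude stronger.")
print()

p = sieve_psd(250, 300)
u = np.linspace(0.1, 2.5, 50)
s = sensitivity_map(eng, p, np.array([80.0, 250.0, 400.0]), u_per_mm=u)
mean_abs = np.abs(s.values).mean(axis=0)
print("mean |S(u, r)| over the x axis for a 250-300 um powder:")
for r, v in zip(s.r_um, mean_abs):
    print(f"  r = {r:4.0f} um: {v:.3e}")
print("small particles carry the least sensitivity -- the ill-posed end.")
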