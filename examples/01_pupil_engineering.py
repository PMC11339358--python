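"""Energy partition of the clear vs engineered illumination pupil.

The pupil's power spectral density (PSD) is the skeleton of the speckle
autocorrelation.  A clear disk concentrates almost all energy in the
non-informative zero-order lobe (Airy main lobe); the engineered mask
sacrifices two-thirds of the photons to move energy into strong sidelobes,
where the particle-size information lives.
"""

from specklesize import grids
from specklesize.pupil import (engineered_pupil, lobe_energy_report,
                               make_clear_pupil, pupil_power_spectrum)

clear = make_clear_pupil(5.0, grids.PUPIL_PITCH_MM, grids.PUPIL_GRID)
eng = engineered_pupil()

for name, mask in [("clear 5 mm disk", clear), ("engineered mask", eng)]:
    spec = pupil_power_spectrum(mask, pad_factor=2)
    rep = lobe_energy_report(spec)
    print(f"--- {name} ---")
    print(f"open-area fraction:        {mask.open_area_fraction():.3f}")
    print(rep.summary())
    print()

print("The engineered mask keeps ~1/3 of the photons but moves most PSD")
print("energy out of the zero-order lobe into sidelobes above the 0.023")
print("effective-region threshold; the clear disk leaves essentially no")
print("sidelobe above that threshold, which is why it needs frame averaging.")
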