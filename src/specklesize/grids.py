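"""Canonical grids tying the pupil plane, the simulator and the lag domain.

Everything downstream of the optics shares one spectral sampling: the
simulated camera field spans ``FIELD_MM`` in the powder plane, so one lag
pixel of the speckle autocorrelation equals 1/FIELD_MM cycles/mm of
normalized displacement.  The pupil PSD is computed on a grid whose pitch
divides that value exactly, so model and measurement land on identical lag
grids with no interpolation.
"""

from __future__ import annotations

import numpy as np

#: Physical side length (mm) of the simulated powder-plane field of view.
FIELD_MM = 12.288

#: Pupil-plane transmission grid: 512 cells of 24 um spanning FIELD_MM.
PUPIL_PITCH_MM = 0.024
PUPIL_GRID = 512
PUPIL_PAD = 2  # PSD grid 1024, spectral pitch 1/(2*FIELD_MM)

#: Canonical lag-domain crop fed to the estimator (64 x 64 pixels).
LAG_N = 64
LAG_U_PITCH = 1.0 / FIELD_MM  # cycles/mm per lag pixel


def lag_axis(n: int = LAG_N, u_pitch: float = LAG_U_PITCH) -> np.ndarray:
    """Centered lag axis in cycles/mm."""
    return (np.arange(n) - n // 2) * u_pitch


def sim_grid_for(min_diameter_um: float, min_samples: int = 6) -> tuple[int, float]:
    """Pick (grid_size, dx_um) so the smallest particle spans >= min_samples.

    The physical field stays FIELD_MM, so the lag pitch is unchanged; only
    the sampling density grows for finer powders.
    """
    if min_diameter_um <= 0:
        raise ValueError("min_diameter_um must be positive")
    dx_max = min_diameter_um / min_samples
    for n in (512, 768, 1024, 1536, 2048):
        dx = FIELD_MM * 1000.0 / n
        if dx <= dx_max:
            return n, dx
    raise ValueError(
        f"particles of {min_diameter_um} um need a simulation pitch below "
        f"{dx_max:.1f} um, finer than the supported grids")
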