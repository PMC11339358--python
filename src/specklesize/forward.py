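"""Forward model: expected speckle autocorrelation and its sensitivity.

The ensemble-averaged, zero-lag-normalized intensity autocorrelation of
speckle from a dense powder monolayer factorizes as

    <A(u)> = |M(u)|^2_norm * |int r^2 Jinc(kappa r |u|) p(r) dr|^2
                             ---------------------------------------
                             |int r^2 p(r) dr|^2

where |M(u)|^2 is the peak-normalized pupil power spectral density,
p(r) the particle diameter density, and Jinc(x) = 2 J1(x)/x the Fourier
profile of a uniform disk.  With u = u'/(lambda f) in cycles/length and r
the particle diameter, kappa = pi exactly (van Cittert-Zernike).  The pupil
term sets the sidelobe skeleton; the size term modulates sidelobe heights,
decaying with particle size.

The sensitivity S(u, r) = d<A(u)>/dp(r) (Gateaux derivative) quantifies how
adding particles of size r perturbs the autocorrelation, and is the figure
of merit pupil engineering improves.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy.special import j1

from .autocorr import AutocorrMap
from .config import DEFAULT_OPTICS, OpticalConfig
from .grids import LAG_N, LAG_U_PITCH
from .pupil import PupilSpectrum
from .sizedist import SizeDistribution

__all__ = ["jinc", "size_modulation", "expected_autocorrelation",
           "sensitivity_map", "SensitivityMap"]


def jinc(x) -> np.ndarray:
    """Jinc(x) = 2 J1(x) / x, even, with Jinc(0) = 1.

    The removable singularity is handled by the Taylor series
    1 - x^2/8 + x^4/192 for |x| < 1e-4 (error < 1e-26 there).
    """
    x = np.abs(np.asarray(x, dtype=float))
    small = x < 1e-4
    xs = np.where(small, 1.0, x)  # avoid 0/0 in the vector branch
    out = 2.0 * j1(xs) / xs
    series = 1.0 - x**2 / 8.0 + x**4 / 192.0
    return np.where(small, series, out)


def _mod_amplitude(p: SizeDistribution, u_abs_per_mm: np.ndarray,
                   cfg: OpticalConfig) -> np.ndarray:
    """int r^2 Jinc(kappa r|u|) p dr / int r^2 p dr (signed amplitude)."""
    r_mm = p.r_grid * 1e-3
    w = p.weights * p.density * r_mm**2
    denom = w.sum()
    u = np.asarray(u_abs_per_mm, dtype=float)
    arg = cfg.jinc_scale * np.multiply.outer(u, r_mm)
    return (jinc(arg) @ w) / denom


def size_modulation(p: SizeDistribution, u_abs_per_mm: np.ndarray,
                    cfg: OpticalConfig = DEFAULT_OPTICS) -> np.ndarray:
    """Squared size-modulation factor in [0, 1]; equals 1 at u = 0.

    Invariant under rescaling of the density (the expression is a ratio).
    """
    return _mod_amplitude(p, u_abs_per_mm, cfg) ** 2


def expected_autocorrelation(spec: PupilSpectrum, p: SizeDistribution,
                             cfg: OpticalConfig = DEFAULT_OPTICS,
                             n_lag: int = LAG_N,
                             u_pitch_per_mm: float = LAG_U_PITCH) -> AutocorrMap:
    """Model autocorrelation on an ``n_lag`` x ``n_lag`` lag grid."""
    psd = spec.on_lag_grid(n_lag, u_pitch_per_mm)
    u = (np.arange(n_lag) - n_lag // 2) * u_pitch_per_mm
    ux, uy = np.meshgrid(u, u, indexing="xy")
    values = psd * size_modulation(p, np.hypot(ux, uy), cfg)
    c = n_lag // 2
    values = values / values[c, c]
    return AutocorrMap(values, u_pitch_per_mm, n_frames_averaged=1)


@dataclasses.dataclass
class SensitivityMap:
    """S(u, r) on a (lag, diameter-probe) grid; ``flagged`` marks u where the
    size integral vanished and S was set to a signed-infinity sentinel."""

    u_per_mm: np.ndarray
    r_um: np.ndarray
    values: np.ndarray  # shape (len(u), len(r))
    flagged: np.ndarray


def sensitivity_map(spec: PupilSpectrum, p: SizeDistribution,
                    r_probe_um: np.ndarray,
                    cfg: OpticalConfig = DEFAULT_OPTICS,
                    u_per_mm: np.ndarray | None = None,
                    direction: tuple[float, float] = (1.0, 0.0)) -> SensitivityMap:
    """Sensitivity of <A> to the population of particles of size r.

        S(u, r) = 2 <A(u)> ( r^2 Jinc(kappa r|u|) / int r^2 Jinc(kappa r|u|) p dr
                             - r^2 / int r^2 p dr )

    evaluated along a lag-space ray ``direction`` (default the +x axis,
    matching horizontal cross-sections).  S integrates to zero against p at
    every u, and is the exact Gateaux derivative of
    ``expected_autocorrelation``: since <A> is a squared modulus, the
    derivative of the squared size integral contributes the leading factor
    of 2.
    """
    if u_per_mm is None:
        u_per_mm = np.arange(LAG_N // 2) * LAG_U_PITCH
    u = np.asarray(u_per_mm, dtype=float)
    dx, dy = direction
    nrm = np.hypot(dx, dy)
    psd = spec.sample(u * dx / nrm, u * dy / nrm)

    r_probe = np.asarray(r_probe_um, dtype=float)
    r_mm = r_probe * 1e-3
    amp = _mod_amplitude(p, u, cfg)                      # (len(u),)
    a_model = psd * amp**2

    w = p.weights * p.density * (p.r_grid * 1e-3) ** 2
    denom2 = w.sum()                                     # int r^2 p dr (mm^2 units)
    num = amp * denom2                                   # int r^2 Jinc p dr

    jr = jinc(cfg.jinc_scale * np.multiply.outer(u, r_mm))  # (len(u), len(r))
    r2 = r_mm**2
    flagged = np.abs(num) < 1e-300
    safe_num = np.where(flagged, 1.0, num)
    term1 = (jr * r2[None, :]) / safe_num[:, None]
    term2 = r2[None, :] / denom2
    values = 2.0 * a_model[:, None] * (term1 - term2)
    if flagged.any():
        sign = np.sign(jr[flagged, :])
        values[flagged, :] = np.where(sign >= 0, np.inf, -np.inf)
    return SensitivityMap(u, r_probe, values, flagged)
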