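"""Illumination-pupil construction and Fourier analysis.

The illumination aperture is described by an intensity transmission map
|m(x)|^2 on a physical grid (mm).  Its power spectral density |M(u)|^2 --
the squared modulus of the Fourier transform of the transmission -- sets the
skeleton of the speckle intensity autocorrelation: a clear disk gives the
Airy pattern, whose weak rings make particle sizing noise-sensitive, while a
structured (engineered) pupil redistributes energy into strong sidelobes.

Coordinates: pupil plane in mm, spectral plane in normalized displacement
u = u'/(lambda f), cycles per mm.
"""

from __future__ import annotations

import dataclasses
import importlib.resources
import warnings

import numpy as np
import yaml
from scipy import ndimage
from scipy.interpolate import RegularGridInterpolator
from skimage.feature import peak_local_max
from skimage.segmentation import watershed

__all__ = [
    "PupilMask",
    "PupilSpectrum",
    "LobeEnergyReport",
    "EffectiveRegionMask",
    "make_clear_pupil",
    "make_engineered_pupil",
    "pupil_power_spectrum",
    "lobe_energy_report",
    "effective_region_mask",
    "load_geometry",
    "save_geometry",
    "engineered_geometry",
    "engineered_pupil",
    "EFFECTIVE_THRESHOLD",
]

#: Normalized-PSD level above which a lag pixel counts as "effective":
#: sidelobes above this level stay above single-frame background fluctuation.
EFFECTIVE_THRESHOLD = 0.023


# --------------------------------------------------------------------------
# masks
# --------------------------------------------------------------------------

@dataclasses.dataclass
class PupilMask:
    """Intensity transmission |m(x)|^2 of the aperture on a square grid.

    Values are in [0, 1]; interior cells are strictly 0 or 1 (the physical
    masks are opaque/clear), boundary cells carry area-coverage values so
    open areas and spectral energies are grid-accurate.
    """

    transmission: np.ndarray
    pitch_mm: float
    aperture_diameter_mm: float

    def __post_init__(self) -> None:
        t = np.asarray(self.transmission, dtype=float)
        if t.ndim != 2 or t.shape[0] != t.shape[1]:
            raise ValueError("transmission must be a square 2-D grid")
        if t.min() < -1e-12 or t.max() > 1 + 1e-12:
            raise ValueError("transmission values must lie in [0, 1]")
        self.transmission = np.clip(t, 0.0, 1.0)

    @property
    def grid_size(self) -> int:
        return self.transmission.shape[0]

    @property
    def extent_mm(self) -> float:
        return self.grid_size * self.pitch_mm

    def open_area_mm2(self) -> float:
        return float(self.transmission.sum() * self.pitch_mm**2)

    def open_area_fraction(self) -> float:
        """Open area relative to the clear aperture disk."""
        return self.open_area_mm2() / (np.pi * (self.aperture_diameter_mm / 2) ** 2)

    def axes_mm(self) -> np.ndarray:
        n = self.grid_size
        return (np.arange(n) - n // 2) * self.pitch_mm


def _cell_axes(grid_size: int, pitch_mm: float) -> tuple[np.ndarray, np.ndarray]:
    c = (np.arange(grid_size) - grid_size // 2) * pitch_mm
    return np.meshgrid(c, c, indexing="xy")


def _disk_coverage(grid_size: int, pitch_mm: float, cx: float, cy: float,
                   diameter_mm: float) -> np.ndarray:
    """Area coverage of a disk on the cell grid (linear rim approximation)."""
    xx, yy = _cell_axes(grid_size, pitch_mm)
    rho = np.hypot(xx - cx, yy - cy)
    return np.clip(0.5 + (diameter_mm / 2 - rho) / pitch_mm, 0.0, 1.0)


def _rect_coverage(grid_size: int, pitch_mm: float, cx: float, cy: float,
                   w: float, h: float) -> np.ndarray:
    """Exact area coverage of an axis-aligned rectangle (separable overlap)."""
    c = (np.arange(grid_size) - grid_size // 2) * pitch_mm
    half = pitch_mm / 2

    def overlap(centers, c0, full):
        lo = np.maximum(centers - half, c0 - full / 2)
        hi = np.minimum(centers + half, c0 + full / 2)
        return np.clip(hi - lo, 0.0, None) / pitch_mm

    return np.outer(overlap(c, cy, h), overlap(c, cx, w))


def _sector_coverage(grid_size: int, pitch_mm: float, cx: float, cy: float,
                     r_in: float, r_out: float, theta0_deg: float,
                     theta1_deg: float, ss: int = 4) -> np.ndarray:
    """Supersampled coverage of an annular sector."""
    n = grid_size * ss
    sub = pitch_mm / ss
    c = (np.arange(n) - n // 2) * sub + (sub - pitch_mm) / 2 + 0.0
    xx, yy = np.meshgrid(c, c, indexing="xy")
    rho = np.hypot(xx - cx, yy - cy)
    th = np.degrees(np.arctan2(yy - cy, xx - cx)) % 360.0
    t0, t1 = theta0_deg % 360.0, theta1_deg % 360.0
    if t1 >= t0:
        ang = (th >= t0) & (th <= t1)
    else:
        ang = (th >= t0) | (th <= t1)
    ind = ((rho >= r_in) & (rho <= r_out) & ang).astype(float)
    return ind.reshape(grid_size, ss, grid_size, ss).mean(axis=(1, 3))


def make_clear_pupil(diameter_mm: float, pitch_mm: float, grid_size: int) -> PupilMask:
    """Uniform circular aperture (the unmodified laser beam footprint)."""
    if diameter_mm <= 0:
        raise ValueError("empty aperture: diameter must be positive")
    if pitch_mm <= 0 or grid_size < 8:
        raise ValueError("pitch must be positive and grid_size >= 8")
    extent = grid_size * pitch_mm
    if extent < 2 * diameter_mm:
        need = int(np.ceil(2 * diameter_mm / pitch_mm))
        raise ValueError(
            f"aperture of {diameter_mm} mm needs padding >= its diameter: "
            f"use grid_size >= {need} at pitch {pitch_mm} mm")
    cov = _disk_coverage(grid_size, pitch_mm, 0.0, 0.0, diameter_mm)
    return PupilMask(cov, pitch_mm, diameter_mm)


def make_engineered_pupil(geometry: list[dict], pitch_mm: float, grid_size: int,
                          aperture_diameter_mm: float = 5.0) -> PupilMask:
    """Compose a structured pupil from geometric primitives.

    Starts from the clear aperture disk and applies each primitive in order
    with a last-wins rule.  Primitives are dicts with a ``shape`` key
    (``disk``, ``rect`` or ``annular_sector``), mm-scale parameters and a
    binary ``transmission``.  An empty geometry list reproduces the clear
    pupil.
    """
    base = make_clear_pupil(aperture_diameter_mm, pitch_mm, grid_size)
    t = base.transmission.copy()
    half_ap = aperture_diameter_mm / 2
    for prim in geometry:
        shape = prim["shape"]
        trans = float(prim.get("transmission", 0.0))
        if trans not in (0.0, 1.0):
            raise ValueError("primitive transmission must be 0 or 1")
        cx, cy = float(prim.get("cx_mm", 0.0)), float(prim.get("cy_mm", 0.0))
        if shape == "disk":
            d = float(prim["diameter_mm"])
            cov = _disk_coverage(grid_size, pitch_mm, cx, cy, d)
            reach = np.hypot(cx, cy) + d / 2
        elif shape == "rect":
            w, h = float(prim["w_mm"]), float(prim["h_mm"])
            cov = _rect_coverage(grid_size, pitch_mm, cx, cy, w, h)
            reach = np.hypot(abs(cx) + w / 2, abs(cy) + h / 2)
        elif shape == "annular_sector":
            cov = _sector_coverage(grid_size, pitch_mm, cx, cy,
                                   float(prim["r_in_mm"]), float(prim["r_out_mm"]),
                                   float(prim["theta0_deg"]), float(prim["theta1_deg"]))
            reach = np.hypot(cx, cy) + float(prim["r_out_mm"])
        else:
            raise ValueError(f"unknown primitive shape {shape!r}")
        if reach > half_ap + pitch_mm and cov[base.transmission > 0].sum() == 0:
            warnings.warn(f"primitive {shape!r} lies outside the aperture", stacklevel=2)
        # last-wins: the primitive overrides previous transmission where it
        # covers; the aperture disk remains an upper bound (no opening
        # outside the beam footprint)
        t = cov * trans + (1 - cov) * t
        t = np.minimum(t, base.transmission)
    return PupilMask(t, pitch_mm, aperture_diameter_mm)


# --------------------------------------------------------------------------
# geometry config I/O
# --------------------------------------------------------------------------

def save_geometry(path, aperture_diameter_mm: float, primitives: list[dict]) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump({"aperture_diameter_mm": float(aperture_diameter_mm),
                        "primitives": primitives}, fh, sort_keys=False)


def load_geometry(path) -> tuple[float, list[dict]]:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    return float(cfg["aperture_diameter_mm"]), list(cfg.get("primitives", []))


def engineered_geometry() -> tuple[float, list[dict]]:
    """Packaged engineered-pupil geometry (synthetic design, see its file)."""
    ref = importlib.resources.files("specklesize.data") / "engineered_mask_synthetic.yaml"
    with importlib.resources.as_file(ref) as path:
        return load_geometry(path)


def engineered_pupil(pitch_mm: float = 0.024, grid_size: int = 512) -> PupilMask:
    """Render the packaged engineered pupil on a grid."""
    d, prims = engineered_geometry()
    return make_engineered_pupil(prims, pitch_mm, grid_size, d)


# --------------------------------------------------------------------------
# power spectral density
# --------------------------------------------------------------------------

@dataclasses.dataclass
class PupilSpectrum:
    """Power spectral density |M(u)|^2 of a pupil transmission map.

    ``psd`` is in continuous-FT units (mm^4), DC at the array center;
    ``u_pitch_per_mm`` is the spectral sample spacing in cycles/mm.
    """

    psd: np.ndarray
    u_pitch_per_mm: float
    pupil_pitch_mm: float

    def __post_init__(self) -> None:
        if np.any(self.psd < 0):
            raise ValueError("psd must be nonnegative")

    @property
    def grid_size(self) -> int:
        return self.psd.shape[0]

    @property
    def center(self) -> int:
        return self.grid_size // 2

    @property
    def peak_value(self) -> float:
        return float(self.psd[self.center, self.center])

    @property
    def total_energy(self) -> float:
        return float(self.psd.sum() * self.u_pitch_per_mm**2)

    def normalized(self) -> np.ndarray:
        return self.psd / self.peak_value

    def u_axis(self) -> np.ndarray:
        n = self.grid_size
        return (np.arange(n) - n // 2) * self.u_pitch_per_mm

    def sample(self, ux: np.ndarray, uy: np.ndarray) -> np.ndarray:
        """Peak-normalized PSD at arbitrary (ux, uy) in cycles/mm (bilinear)."""
        interp = RegularGridInterpolator(
            (self.u_axis(), self.u_axis()), self.normalized(),
            bounds_error=False, fill_value=0.0)
        pts = np.stack([np.broadcast_arrays(uy, ux)[0].ravel(),
                        np.broadcast_arrays(uy, ux)[1].ravel()], axis=-1)
        return interp(pts).reshape(np.broadcast(ux, uy).shape)

    def on_lag_grid(self, n_lag: int, u_pitch_per_mm: float) -> np.ndarray:
        """Peak-normalized PSD on an ``n_lag`` x ``n_lag`` lag grid.

        Uses an exact strided slice when the requested pitch is an integer
        multiple of the spectral pitch, bilinear interpolation otherwise.
        """
        ratio = u_pitch_per_mm / self.u_pitch_per_mm
        k = int(round(ratio))
        if abs(ratio - k) < 1e-9 and k >= 1:
            c, h = self.center, n_lag // 2
            idx = c + (np.arange(n_lag) - h) * k
            if idx[0] >= 0 and idx[-1] < self.grid_size:
                return self.normalized()[np.ix_(idx, idx)]
        u = (np.arange(n_lag) - n_lag // 2) * u_pitch_per_mm
        ux, uy = np.meshgrid(u, u, indexing="xy")
        return self.sample(ux, uy)


def pupil_power_spectrum(mask: PupilMask, pad_factor: int = 4) -> PupilSpectrum:
    """Discrete PSD of the transmission grid, DC centered.

    The transmission grid is zero-padded by ``pad_factor`` before the FFT, so
    the spectral pitch is 1/(grid_size * pad_factor * pitch) cycles/mm.
    """
    if pad_factor < 2:
        raise ValueError("pad_factor must be >= 2 for adequate u resolution")
    t = mask.transmission
    if t.sum() == 0:
        raise ValueError("opaque pupil: transmission is zero everywhere")
    n = mask.grid_size * pad_factor
    spec = np.fft.fft2(t, s=(n, n))
    psd = np.abs(np.fft.fftshift(spec)) ** 2 * mask.pitch_mm**4
    return PupilSpectrum(psd, 1.0 / (n * mask.pitch_mm), mask.pitch_mm)


# --------------------------------------------------------------------------
# lobe segmentation and the effective-region digital filter
# --------------------------------------------------------------------------

@dataclasses.dataclass
class LobeEnergyReport:
    """Energy partition of a pupil PSD between its zero-order lobe and sidelobes."""

    main_lobe_fraction: float
    sidelobe_fraction: float
    effective_sidelobe_fraction: float
    main_lobe_pixel_set: np.ndarray
    threshold: float
    first_ring_absorbed: bool
    radial_first_null_fraction: float

    def summary(self) -> str:
        conv = ("watershed basin + adjacent first ring" if self.first_ring_absorbed
                else "watershed basin of the central peak")
        return (
            f"main lobe ({conv}): {100 * self.main_lobe_fraction:.2f}%\n"
            f"main lobe (radial first null): {100 * self.radial_first_null_fraction:.2f}%\n"
            f"sidelobe energy: {100 * self.sidelobe_fraction:.2f}%\n"
            f"effective sidelobe energy (norm. PSD > {self.threshold}): "
            f"{100 * self.effective_sidelobe_fraction:.2f}%")


@dataclasses.dataclass
class EffectiveRegionMask:
    """Boolean lag-grid mask of pixels whose normalized PSD exceeds a threshold."""

    mask: np.ndarray
    threshold: float
    u_pitch_per_mm: float


def _main_lobe_basin(psd: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Watershed basin of the central maximum; returns (basin, label image)."""
    peaks = peak_local_max(psd, min_distance=1, threshold_rel=1e-8,
                           exclude_border=False)
    markers = np.zeros(psd.shape, dtype=np.int32)
    markers[tuple(peaks.T)] = np.arange(1, len(peaks) + 1)
    c = psd.shape[0] // 2
    if markers[c, c] == 0:  # ensure the DC peak itself is a marker
        markers[c, c] = len(peaks) + 1
    labels = watershed(-psd, markers)
    return labels == markers[c, c], labels


def _radial_first_null_fraction(psd: np.ndarray, u_pitch: float) -> float:
    """Energy share inside the first minimum of the azimuthally averaged PSD."""
    n = psd.shape[0]
    c = n // 2
    yy, xx = np.indices(psd.shape)
    rad = np.hypot(xx - c, yy - c).astype(int)
    prof = np.bincount(rad.ravel(), weights=psd.ravel()) / np.bincount(rad.ravel())
    kmin = 1
    while kmin < len(prof) - 1 and not (prof[kmin] < prof[kmin - 1]
                                        and prof[kmin] <= prof[kmin + 1]):
        kmin += 1
    inside = rad <= kmin
    return float(psd[inside].sum() / psd.sum())


def lobe_energy_report(spec: PupilSpectrum, threshold: float = EFFECTIVE_THRESHOLD,
                       absorb_first_ring: bool = False) -> LobeEnergyReport:
    """Partition PSD energy into zero-order lobe vs (effective) sidelobes.

    The zero-order lobe is the steepest-ascent (watershed) basin of the
    central peak.  With ``absorb_first_ring`` the basins touching it are
    folded in as well: at camera resolution the innermost ring is not
    separable from the main lobe, so its energy is conventionally counted as
    part of the zero order.  ``effective_sidelobe_fraction`` is the energy
    share of pixels outside the (possibly extended) main lobe whose
    peak-normalized PSD exceeds ``threshold``.
    """
    if not (0 < threshold <= 1):
        raise ValueError("threshold must lie in (0, 1]")
    psd = spec.psd
    main, labels = _main_lobe_basin(psd)
    if absorb_first_ring:
        ring = ndimage.binary_dilation(main, iterations=2) & ~main
        for lab in np.unique(labels[ring]):
            main |= labels == lab
    total = psd.sum()
    main_frac = float(psd[main].sum() / total)
    norm = psd / psd[spec.center, spec.center]
    eff = float(psd[(norm > threshold) & ~main].sum() / total)
    return LobeEnergyReport(
        main_lobe_fraction=main_frac,
        sidelobe_fraction=1.0 - main_frac,
        effective_sidelobe_fraction=eff,
        main_lobe_pixel_set=main,
        threshold=threshold,
        first_ring_absorbed=absorb_first_ring,
        radial_first_null_fraction=_radial_first_null_fraction(psd, spec.u_pitch_per_mm),
    )


def effective_region_mask(spec: PupilSpectrum, threshold: float = EFFECTIVE_THRESHOLD,
                          n_lag: int | None = None,
                          u_pitch_per_mm: float | None = None) -> EffectiveRegionMask:
    """Digital filter: lag pixels where the normalized PSD exceeds ``threshold``.

    With ``n_lag``/``u_pitch_per_mm`` the mask is produced on that lag grid
    (the grid the estimator operates on); otherwise on the PSD's own grid.
    """
    if not (0 < threshold <= 1):
        raise ValueError("threshold must lie in (0, 1]")
    if n_lag is None:
        norm = spec.normalized()
        pitch = spec.u_pitch_per_mm
    else:
        pitch = u_pitch_per_mm if u_pitch_per_mm is not None else spec.u_pitch_per_mm
        norm = spec.on_lag_grid(n_lag, pitch)
    return EffectiveRegionMask(norm > threshold, threshold, pitch)
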