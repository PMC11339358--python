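"""Speckle autocorrelation estimation, averaging and filtering.

A frame's autocorrelation is the mean-subtracted circular autocorrelation
computed with the correlation theorem (two FFTs), normalized to unit zero
lag and shifted so lag (0, 0) sits at the array center.  Ensemble averaging
over frames with fresh powder surfaces drives its background fluctuation
down as 1/sqrt(N), which is what multi-frame probes exploit and what the
engineered pupil renders unnecessary.
"""

from __future__ import annotations

import dataclasses
import json

import numpy as np
import tifffile

from .pupil import EffectiveRegionMask

__all__ = [
    "AutocorrMap",
    "FluctuationReport",
    "frame_autocorrelation",
    "ensemble_autocorrelation",
    "background_fluctuation",
    "apply_digital_filter",
    "center_crop",
    "write_autocorr",
    "read_autocorr",
]


@dataclasses.dataclass
class AutocorrMap:
    """Normalized speckle intensity autocorrelation on a centered lag grid."""

    values: np.ndarray
    u_pitch_per_mm: float
    n_frames_averaged: int = 1

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2:
            raise ValueError("autocorrelation values must be 2-D")
        self.values = v

    @property
    def center(self) -> tuple[int, int]:
        return self.values.shape[0] // 2, self.values.shape[1] // 2

    def zero_lag(self) -> float:
        return float(self.values[self.center])

    def u_axis(self, axis: int = 0) -> np.ndarray:
        n = self.values.shape[axis]
        return (np.arange(n) - n // 2) * self.u_pitch_per_mm


def _intensity_of(frame) -> tuple[np.ndarray, float]:
    if hasattr(frame, "intensity"):
        return np.asarray(frame.intensity, dtype=float), float(frame.u_pitch_per_mm)
    raise TypeError("frame must expose .intensity and .u_pitch_per_mm")


def frame_autocorrelation(frame, crop: tuple[int, int, int, int] | None = None) -> AutocorrMap:
    """Mean-subtracted, zero-lag-normalized autocorrelation of one frame.

    ``crop`` is an optional (row0, row1, col0, col1) region evaluated before
    the transform; the default is the full frame.
    """
    img, u_pitch = _intensity_of(frame)
    if crop is not None:
        r0, r1, c0, c1 = crop
        img = img[r0:r1, c0:c1]
        if img.size == 0:
            raise ValueError("crop region has zero area")
    x = img - img.mean()
    var = float((x * x).sum())
    if var == 0.0:
        raise ValueError("constant image: zero variance, autocorrelation undefined")
    acf = np.fft.ifft2(np.abs(np.fft.fft2(x)) ** 2).real / var
    return AutocorrMap(np.fft.fftshift(acf), u_pitch, n_frames_averaged=1)


def ensemble_autocorrelation(frames, crop=None) -> AutocorrMap:
    """Arithmetic mean of per-frame normalized autocorrelations."""
    frames = list(frames)
    if not frames:
        raise ValueError("need at least one frame")
    maps = [frame_autocorrelation(f, crop) for f in frames]
    shape = maps[0].values.shape
    pitch = maps[0].u_pitch_per_mm
    for m in maps[1:]:
        if m.values.shape != shape or not np.isclose(m.u_pitch_per_mm, pitch):
            raise ValueError("frames have mixed geometries")
    mean = np.mean([m.values for m in maps], axis=0)
    return AutocorrMap(mean, pitch, n_frames_averaged=len(maps))


@dataclasses.dataclass
class FluctuationReport:
    """Standard deviation of the autocorrelation in a background annulus."""

    n_frames: int
    sigma: float
    inner_halfwidth_px: int
    outer_halfwidth_px: int


def _annulus(shape: tuple[int, int], inner: int, outer: int) -> np.ndarray:
    cy, cx = shape[0] // 2, shape[1] // 2
    yy, xx = np.indices(shape)
    cheb = np.maximum(np.abs(yy - cy), np.abs(xx - cx))
    return (cheb > inner) & (cheb <= outer)


def background_fluctuation(acorr: AutocorrMap, inner_halfwidth_px: int,
                           outer_halfwidth_px: int) -> FluctuationReport:
    """Fluctuation level: std of values between two concentric squares.

    The region should exclude the main lobe and all effective sidelobes; its
    bounds are caller-declared (in lag pixels from the center).
    """
    if not (0 <= inner_halfwidth_px < outer_halfwidth_px):
        raise ValueError("need 0 <= inner < outer half-widths")
    sel = _annulus(acorr.values.shape, inner_halfwidth_px, outer_halfwidth_px)
    if not sel.any():
        raise ValueError("empty background region")
    return FluctuationReport(acorr.n_frames_averaged,
                             float(acorr.values[sel].std()),
                             inner_halfwidth_px, outer_halfwidth_px)


def apply_digital_filter(acorr: AutocorrMap, mask: EffectiveRegionMask) -> AutocorrMap:
    """Zero the autocorrelation outside the effective region."""
    if mask.mask.shape != acorr.values.shape:
        raise ValueError(
            f"mask shape {mask.mask.shape} does not match map shape {acorr.values.shape}")
    if not mask.mask.any():
        import warnings
        warnings.warn("effective-region mask is empty; filtered map is zero",
                      stacklevel=2)
    return AutocorrMap(np.where(mask.mask, acorr.values, 0.0),
                       acorr.u_pitch_per_mm, acorr.n_frames_averaged)


def center_crop(acorr: AutocorrMap, n: int) -> AutocorrMap:
    """Central n x n lag window (same pitch)."""
    cy, cx = acorr.center
    h = n // 2
    sub = acorr.values[cy - h:cy - h + n, cx - h:cx - h + n]
    if sub.shape != (n, n):
        raise ValueError("crop larger than the lag grid")
    return AutocorrMap(sub.copy(), acorr.u_pitch_per_mm, acorr.n_frames_averaged)


def write_autocorr(path, acorr: AutocorrMap, **extra) -> None:
    """32-bit float TIFF plus a JSON sidecar with lag metadata."""
    tifffile.imwrite(path, acorr.values.astype(np.float32))
    meta = {"u_pitch_per_mm": acorr.u_pitch_per_mm,
            "n_frames_averaged": acorr.n_frames_averaged, **extra}
    with open(str(path) + ".json", "w") as fh:
        json.dump(meta, fh, indent=2)


def read_autocorr(path) -> AutocorrMap:
    values = tifffile.imread(path).astype(float)
    with open(str(path) + ".json") as fh:
        meta = json.load(fh)
    return AutocorrMap(values, meta["u_pitch_per_mm"], meta["n_frames_averaged"])
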