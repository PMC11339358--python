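"""Physical speckle simulator: masked beam on a random powder monolayer.

The powder surface is a random-sequential-adsorption (RSA) monolayer of
non-overlapping disks with iid diameters from a target size distribution.
Each particle's top facet is optically rough well below the grid scale, so
the exit field carries an independent uniform phase at every illuminated
sample inside a particle ("delta-correlated facets"); gaps between
particles are opaque.  The camera sits in the Fourier plane: its intensity
is the squared modulus of the DFT of the exit field, giving fully developed
speckle whose ensemble autocorrelation converges to the forward model's
two-factor form (pupil PSD envelope x particle-size modulation).

Optional shot noise (Poisson at a configurable photon budget) and Gaussian
read noise emulate the camera; both default off for oracle work.
"""

from __future__ import annotations

import dataclasses
import json
import warnings

import numpy as np
import tifffile

from .config import DEFAULT_OPTICS, OpticalConfig
from .grids import FIELD_MM, sim_grid_for
from .pupil import PupilMask
from .sizedist import SizeDistribution

__all__ = [
    "ParticleField",
    "SpeckleFrame",
    "NoiseSpec",
    "sample_particle_field",
    "render_frame",
    "simulate_ensemble",
    "write_frame",
    "read_frame",
]


@dataclasses.dataclass
class NoiseSpec:
    """Camera noise model: mean photons per pixel for shot noise (None = off),
    Gaussian read noise in counts, and optional 16-bit quantization."""

    photons_per_pixel: float | None = None
    read_noise: float = 0.0
    quantize_16bit: bool = False


@dataclasses.dataclass
class ParticleField:
    """One realization of the powder monolayer."""

    centers_mm: np.ndarray       # (n, 2) particle centers
    diameters_um: np.ndarray     # (n,)
    extent_mm: float             # side of the square packing region
    coverage: float              # achieved area fraction
    seed: int
    coverage_shortfall: bool = False

    @property
    def n_particles(self) -> int:
        return len(self.diameters_um)


@dataclasses.dataclass
class SpeckleFrame:
    """Camera-plane intensity image of one surface realization."""

    intensity: np.ndarray
    pixel_pitch_um_powder: float   # simulation sample spacing in the powder plane
    u_pitch_per_mm: float          # lag step of one camera pixel, cycles/mm
    seed: int
    exposure: dict = dataclasses.field(default_factory=dict)

    def contrast(self) -> float:
        """Speckle contrast std/mean over the frame."""
        m = self.intensity.mean()
        return float(self.intensity.std() / m) if m > 0 else 0.0


def sample_particle_field(p: SizeDistribution, extent_mm: float,
                          target_coverage: float = 0.45,
                          seed: int = 0,
                          max_attempts: int = 200_000) -> ParticleField:
    """RSA packing of disks with iid diameters from ``p``.

    The diameter population is drawn iid from ``p`` up front (its count set
    by the target coverage), and each disk keeps retrying random positions
    until it fits -- so the packed diameter law equals the target law
    exactly, free of the small-particle acceptance bias of plain RSA.
    Deterministic under ``seed``.  If placement stalls before the target
    coverage within ``max_attempts`` trials, the achieved packing is
    returned with ``coverage_shortfall`` set.
    """
    if not (0.0 < target_coverage <= 0.55):
        raise ValueError("target_coverage must lie in (0, 0.55] (RSA regime)")
    rng = np.random.default_rng(seed)
    area = extent_mm**2
    w = p.weights
    mean_area = float(w @ (p.density * np.pi * (p.r_grid * 1e-3 / 2) ** 2))
    n_target = int(np.round(target_coverage * area / mean_area))
    pending = np.sort(p.sample(rng, n_target) * 1e-3 / 2)[::-1]  # radii, large first
    xs = np.empty(n_target)
    ys = np.empty(n_target)
    radii = np.empty(n_target)
    n_acc = 0
    covered = 0.0
    attempts = 0
    stagnant_rounds = 0
    while pending.size and attempts < max_attempts:
        cand_x, cand_y = (rng.random((2, pending.size)) - 0.5) * extent_mm
        attempts += pending.size
        if n_acc:
            d2 = (cand_x[:, None] - xs[None, :n_acc]) ** 2 \
                + (cand_y[:, None] - ys[None, :n_acc]) ** 2
            ok = np.all(d2 >= (pending[:, None] + radii[None, :n_acc]) ** 2, axis=1)
        else:
            ok = np.ones(pending.size, dtype=bool)
        first_new = n_acc
        placed = np.zeros(pending.size, dtype=bool)
        for i in np.flatnonzero(ok):
            x, y, r = cand_x[i], cand_y[i], pending[i]
            new = slice(first_new, n_acc)
            if n_acc > first_new and np.any(
                    (xs[new] - x) ** 2 + (ys[new] - y) ** 2
                    < (radii[new] + r) ** 2):
                continue
            xs[n_acc], ys[n_acc], radii[n_acc] = x, y, r
            n_acc += 1
            covered += np.pi * r * r
            placed[i] = True
        stagnant_rounds = 0 if placed.any() else stagnant_rounds + 1
        pending = pending[~placed]
        if stagnant_rounds >= 40 and pending.size:
            # the largest pending disk no longer fits anywhere it has tried;
            # drop it -- the top-up below redraws (typically smaller) mass
            pending = pending[1:]
            stagnant_rounds = 0
        gap = target_coverage - covered / area
        if (not pending.size and gap * area > 0.5 * mean_area
                and attempts < max_attempts):
            # sampled population came up light by at least half a particle
            extra = max(int(np.ceil(gap * area / mean_area)), 1)
            pending = np.sort(p.sample(rng, extra) * 1e-3 / 2)[::-1]
            grow = n_acc + extra - xs.size
            if grow > 0:
                xs = np.concatenate([xs, np.empty(grow)])
                ys = np.concatenate([ys, np.empty(grow)])
                radii = np.concatenate([radii, np.empty(grow)])
    # small deficits are inherent to packing the last few disks; only a
    # genuinely short packing (> 0.02 absolute coverage) is flagged
    shortfall = target_coverage - covered / area > 0.02
    if shortfall:
        warnings.warn(
            f"RSA placed {n_acc}/{n_target} disks (coverage "
            f"{covered / area:.3f} < target {target_coverage}) after "
            f"{attempts} attempts", stacklevel=2)
    return ParticleField(
        centers_mm=np.stack([xs[:n_acc], ys[:n_acc]], axis=1),
        diameters_um=radii[:n_acc] * 2e3,
        extent_mm=extent_mm,
        coverage=covered / area,
        seed=seed,
        coverage_shortfall=shortfall,
    )


def _rasterize(field: ParticleField, n: int, dx_mm: float) -> np.ndarray:
    """Boolean occupancy of particle disks on the n x n simulation grid."""
    occ = np.zeros((n, n), dtype=bool)
    half = n // 2
    for (x, y), d_um in zip(field.centers_mm, field.diameters_um):
        r = d_um * 1e-3 / 2
        i0 = max(int(np.floor((y - r) / dx_mm)) + half, 0)
        i1 = min(int(np.ceil((y + r) / dx_mm)) + half + 1, n)
        j0 = max(int(np.floor((x - r) / dx_mm)) + half, 0)
        j1 = min(int(np.ceil((x + r) / dx_mm)) + half + 1, n)
        if i0 >= i1 or j0 >= j1:
            continue
        ys = (np.arange(i0, i1) - half) * dx_mm - y
        xs = (np.arange(j0, j1) - half) * dx_mm - x
        occ[i0:i1, j0:j1] |= (ys[:, None] ** 2 + xs[None, :] ** 2) <= r * r
    return occ


def _rasterize_weighted(field: ParticleField, n: int, dx_mm: float,
                        beam_t: np.ndarray) -> np.ndarray:
    """Source intensity map: each particle disk filled with the beam
    transmission at its center; gaps are dark."""
    src = np.zeros((n, n), dtype=float)
    half = n // 2
    for (x, y), d_um in zip(field.centers_mm, field.diameters_um):
        ic = min(max(int(round(y / dx_mm)) + half, 0), n - 1)
        jc = min(max(int(round(x / dx_mm)) + half, 0), n - 1)
        b = beam_t[ic, jc]
        if b <= 0.0:
            continue
        r = d_um * 1e-3 / 2
        i0 = max(int(np.floor((y - r) / dx_mm)) + half, 0)
        i1 = min(int(np.ceil((y + r) / dx_mm)) + half + 1, n)
        j0 = max(int(np.floor((x - r) / dx_mm)) + half, 0)
        j1 = min(int(np.ceil((x + r) / dx_mm)) + half + 1, n)
        if i0 >= i1 or j0 >= j1:
            continue
        ys = (np.arange(i0, i1) - half) * dx_mm - y
        xs = (np.arange(j0, j1) - half) * dx_mm - x
        inside = (ys[:, None] ** 2 + xs[None, :] ** 2) <= r * r
        np.maximum(src[i0:i1, j0:j1], b * inside, out=src[i0:i1, j0:j1])
    return src


def render_frame(field: ParticleField, mask: PupilMask,
                 cfg: OpticalConfig = DEFAULT_OPTICS,
                 noise: NoiseSpec | None = None,
                 grid_size: int | None = None,
                 seed: int | None = None) -> SpeckleFrame:
    """Fourier-plane intensity of one surface realization.

    The exit field is sqrt(beam intensity) x occupancy x exp(i phi) with phi
    iid uniform per illuminated sample (delta-correlated facet roughness);
    the camera intensity is |DFT|^2.  One camera pixel corresponds to
    1/(grid extent) cycles/mm of normalized displacement.
    """
    d_min = float(field.diameters_um.min())
    if grid_size is None:
        grid_size, dx_um = sim_grid_for(d_min)
    else:
        dx_um = FIELD_MM * 1000.0 / grid_size
        if d_min / dx_um < 6:
            need = FIELD_MM * 1000.0 / (d_min / 6)
            raise ValueError(
                f"smallest particle ({d_min:.0f} um) spans < 6 samples at "
                f"dx={dx_um:.1f} um; need grid_size >= {int(np.ceil(need))}")
    dx_mm = dx_um * 1e-3
    n = grid_size

    # beam amplitude on the simulation grid
    if abs(mask.pitch_mm - dx_mm) < 1e-12 and mask.grid_size == n:
        beam_t = mask.transmission
    else:
        from scipy.ndimage import zoom
        factor = mask.pitch_mm / dx_mm
        beam_t = zoom(mask.transmission, factor, order=1)
        pad = n - beam_t.shape[0]
        if pad < 0:
            s = (-pad) // 2
            beam_t = beam_t[s:s + n, s:s + n]
        elif pad > 0:
            s = pad // 2
            beam_t = np.pad(beam_t, ((s, pad - s), (s, pad - s)))
    beam_t = np.clip(beam_t, 0.0, None)

    rng = np.random.default_rng(field.seed + 0x5EED if seed is None else seed)
    # Each particle's facet is weighted by the beam intensity at its center:
    # the illumination structure is mm-scale and diffraction-blurred by the
    # time it reaches the powder, so a particle samples the local beam level
    # rather than imprinting sharp mask edges across its facet.
    source = _rasterize_weighted(field, n, dx_mm, beam_t)
    phase = rng.random((n, n)) * (2 * np.pi)
    exit_field = np.sqrt(source) * np.exp(1j * phase)
    intensity = np.abs(np.fft.fftshift(np.fft.fft2(exit_field))) ** 2

    meta = {"grid_size": n, "dx_um": dx_um}
    if noise is not None:
        if noise.photons_per_pixel is not None:
            scale = noise.photons_per_pixel / max(intensity.mean(), 1e-300)
            intensity = rng.poisson(intensity * scale).astype(float) / scale
        if noise.read_noise > 0:
            intensity = intensity + rng.normal(0.0, noise.read_noise, intensity.shape)
        intensity = np.clip(intensity, 0.0, None)
        if noise.quantize_16bit:
            peak = intensity.max()
            if peak > 0:
                intensity = np.round(intensity / peak * 65535.0) / 65535.0 * peak
        meta["noise"] = dataclasses.asdict(noise)

    return SpeckleFrame(intensity=intensity,
                        pixel_pitch_um_powder=dx_um,
                        u_pitch_per_mm=1.0 / (n * dx_mm),
                        seed=field.seed,
                        exposure=meta)


def simulate_ensemble(p: SizeDistribution, mask: PupilMask,
                      cfg: OpticalConfig = DEFAULT_OPTICS,
                      n_frames: int = 1, seed: int = 0,
                      target_coverage: float = 0.45,
                      noise: NoiseSpec | None = None,
                      grid_size: int | None = None,
                      extent_mm: float | None = None):
    """Yield ``n_frames`` independent frames (fresh surface each frame).

    Frame k is reproducible from (seed, k) alone.
    """
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    if extent_mm is None:
        extent_mm = mask.aperture_diameter_mm + 2.2e-3 * float(p.r_grid[-1])
    for k in range(n_frames):
        sub = int(np.random.default_rng([seed, k]).integers(0, 2**31 - 1))
        field = sample_particle_field(p, extent_mm, target_coverage, seed=sub)
        yield render_frame(field, mask, cfg, noise=noise, grid_size=grid_size,
                          seed=sub + 1)


def write_frame(path, frame: SpeckleFrame, **extra) -> None:
    """16-bit grayscale TIFF plus a JSON sidecar."""
    peak = frame.intensity.max()
    img = np.zeros_like(frame.intensity, dtype=np.uint16) if peak == 0 else \
        np.round(frame.intensity / peak * 65535.0).astype(np.uint16)
    tifffile.imwrite(path, img)
    meta = {"u_pitch_per_mm": frame.u_pitch_per_mm,
            "pixel_pitch_um_powder": frame.pixel_pitch_um_powder,
            "seed": frame.seed, "peak_intensity": float(peak),
            "exposure": frame.exposure, **extra}
    with open(str(path) + ".json", "w") as fh:
        json.dump(meta, fh, indent=2)


def read_frame(path) -> SpeckleFrame:
    """Load a frame from 16-bit TIFF or PNG plus its JSON sidecar."""
    if str(path).lower().endswith(".png"):
        import imageio.v3 as iio
        img = iio.imread(path).astype(float)
    else:
        img = tifffile.imread(path).astype(float)
    with open(str(path) + ".json") as fh:
        meta = json.load(fh)
    img *= meta.get("peak_intensity", 1.0) / 65535.0
    return SpeckleFrame(intensity=img,
                        pixel_pitch_um_powder=meta["pixel_pitch_um_powder"],
                        u_pitch_per_mm=meta["u_pitch_per_mm"],
                        seed=meta.get("seed", -1),
                        exposure=meta.get("exposure", {}))
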