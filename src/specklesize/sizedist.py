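"""Particle size distributions, their cumulative form, and the W1 metric.

Sizes are particle *diameters* in micrometres. A distribution is a density
p(r) sampled on a strictly increasing diameter grid; integrals use trapezoid
node weights, and the cumulative form is the running weighted sum with those
same weights, so that density <-> CDF conversion round-trips exactly.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

__all__ = [
    "SizeDistribution",
    "SizeCDF",
    "default_r_grid",
    "trapezoid_weights",
    "sieve_psd",
    "monodisperse_psd",
    "truncated_gaussian_psd",
    "mixture_psd",
    "random_size_distribution",
    "cdf_to_psd",
    "w1_distance",
    "read_distribution_csv",
    "write_distribution_csv",
]

#: Sieve opening sizes (um) of the shaker stack used for calibration powders.
SIEVE_OPENINGS_UM = (106.0, 180.0, 250.0, 300.0, 355.0, 425.0, 500.0)


def default_r_grid(n: int = 96, low_um: float = 50.0, high_um: float = 1000.0) -> np.ndarray:
    """Log-spaced diameter grid covering the 50 um - 1 mm sizing range."""
    return np.geomspace(low_um, high_um, n)


def trapezoid_weights(r_grid: np.ndarray) -> np.ndarray:
    """Trapezoid quadrature node weights for ``r_grid`` (same length)."""
    r = np.asarray(r_grid, dtype=float)
    w = np.empty_like(r)
    w[0] = 0.5 * (r[1] - r[0])
    w[-1] = 0.5 * (r[-1] - r[-2])
    w[1:-1] = 0.5 * (r[2:] - r[:-2])
    return w


def _check_grid(r_grid: np.ndarray) -> np.ndarray:
    r = np.asarray(r_grid, dtype=float)
    if r.ndim != 1 or r.size < 4:
        raise ValueError("diameter grid must be 1-D with at least 4 nodes")
    if not np.all(np.diff(r) > 0):
        raise ValueError("diameter grid must be strictly increasing")
    return r


@dataclasses.dataclass
class SizeDistribution:
    """Probability density of particle diameters on a fixed grid.

    ``density`` is per-micrometre and is normalized at construction so the
    trapezoid integral equals 1.
    """

    r_grid: np.ndarray
    density: np.ndarray

    def __post_init__(self) -> None:
        self.r_grid = _check_grid(self.r_grid)
        d = np.asarray(self.density, dtype=float)
        if d.shape != self.r_grid.shape:
            raise ValueError("density and r_grid shapes differ")
        if np.any(d < 0):
            raise ValueError("density must be nonnegative")
        total = float(trapezoid_weights(self.r_grid) @ d)
        if total <= 0:
            raise ValueError("empty distribution: density integrates to zero")
        self.density = d / total

    @property
    def weights(self) -> np.ndarray:
        return trapezoid_weights(self.r_grid)

    def cdf(self) -> "SizeCDF":
        values = np.cumsum(self.weights * self.density)
        values[-1] = 1.0  # exact by normalization; pin the endpoint
        return SizeCDF(self.r_grid.copy(), values)

    def mean(self) -> float:
        return float(self.weights @ (self.r_grid * self.density))

    def peak_position(self) -> float:
        """Diameter of the density mode (um)."""
        return float(self.r_grid[int(np.argmax(self.density))])

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        """Draw ``n`` iid diameters by inverse-CDF interpolation."""
        cdf = self.cdf().values
        u = rng.random(n)
        return np.interp(u, cdf, self.r_grid)


@dataclasses.dataclass
class SizeCDF:
    """Cumulative particle size distribution on a diameter grid."""

    r_grid: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.r_grid = _check_grid(self.r_grid)
        v = np.asarray(self.values, dtype=float)
        if v.shape != self.r_grid.shape:
            raise ValueError("cdf values and r_grid shapes differ")
        if np.any(np.diff(v) < -1e-9):
            raise ValueError("cdf must be nondecreasing")
        if v[0] < -1e-6 or abs(v[-1] - 1.0) > 1e-6:
            raise ValueError("cdf endpoints must be within [0, 1] with cdf(last)=1")
        self.values = np.clip(v, 0.0, 1.0)

    def median(self) -> float:
        return float(np.interp(0.5, self.values, self.r_grid))


def cdf_to_psd(cdf: SizeCDF) -> SizeDistribution:
    """Differentiate a CDF back to a density (exact inverse of ``.cdf()``)."""
    q = np.diff(cdf.values, prepend=0.0)
    q = np.clip(q, 0.0, None)
    w = trapezoid_weights(cdf.r_grid)
    return SizeDistribution(cdf.r_grid.copy(), q / w)


def w1_distance(a: SizeCDF, b: SizeCDF) -> float:
    """1-Wasserstein distance in micrometres (L1 between CDFs)."""
    if a.r_grid.shape != b.r_grid.shape or not np.allclose(a.r_grid, b.r_grid):
        raise ValueError("W1 requires both CDFs on the same diameter grid")
    w = trapezoid_weights(a.r_grid)
    return float(w @ np.abs(a.values - b.values))


def _on_grid(r_grid: np.ndarray | None) -> np.ndarray:
    return default_r_grid() if r_grid is None else _check_grid(r_grid)


def sieve_psd(low_um: float, high_um: float, r_grid: np.ndarray | None = None) -> SizeDistribution:
    """Uniform density on a sieve interval [low, high] um.

    Models the near-uniform diameter law of a powder retained between two
    sieve openings.
    """
    if not (50.0 <= low_um < high_um <= 1000.0):
        raise ValueError("sieve bounds must satisfy 50 <= low < high <= 1000 um")
    r = _on_grid(r_grid)
    density = ((r >= low_um) & (r <= high_um)).astype(float)
    if not density.any():
        raise ValueError("sieve interval does not overlap the diameter grid")
    return SizeDistribution(r, density)


def monodisperse_psd(r0_um: float, r_grid: np.ndarray | None = None) -> SizeDistribution:
    """Quasi-delta density concentrated at the grid node nearest ``r0_um``."""
    r = _on_grid(r_grid)
    density = np.zeros_like(r)
    density[int(np.argmin(np.abs(r - r0_um)))] = 1.0
    return SizeDistribution(r, density)


def truncated_gaussian_psd(mean_um: float, sigma_um: float,
                           r_grid: np.ndarray | None = None) -> SizeDistribution:
    """Gaussian density truncated to the grid support (calibrated sample sets)."""
    if sigma_um <= 0:
        raise ValueError("sigma must be positive")
    r = _on_grid(r_grid)
    density = np.exp(-0.5 * ((r - mean_um) / sigma_um) ** 2)
    return SizeDistribution(r, density)


def mixture_psd(components: list[tuple[SizeDistribution, float]]) -> SizeDistribution:
    """Convex mixture of distributions sharing one grid."""
    if not components:
        raise ValueError("mixture needs at least one component")
    r = components[0][0].r_grid
    density = np.zeros_like(r)
    for dist, weight in components:
        if weight < 0:
            raise ValueError("mixture weights must be nonnegative")
        if not np.allclose(dist.r_grid, r):
            raise ValueError("mixture components must share one diameter grid")
        density = density + weight * dist.density
    return SizeDistribution(r.copy(), density)


def random_size_distribution(rng: np.random.Generator,
                             r_grid: np.ndarray | None = None,
                             bimodal_prob: float = 0.15) -> SizeDistribution:
    """Random training/test distribution on [50, 1000] um.

    Draws either a sieve-like uniform interval, a truncated Gaussian, or
    (with probability ``bimodal_prob``) a bimodal mixture of two Gaussians.
    The ranges mirror sieve-calibration practice: interval ratios up to
    ~1.9 (adjacent-sieve fractions are narrower), Gaussian spreads of
    15-90 um, modes spanning the 90-650 um working range.
    """
    r = _on_grid(r_grid)
    if rng.random() < bimodal_prob:
        m1 = float(rng.uniform(100.0, 350.0))
        m2 = float(rng.uniform(m1 + 120.0, 700.0))
        s1 = float(rng.uniform(15.0, 60.0))
        s2 = float(rng.uniform(15.0, 80.0))
        wgt = float(rng.uniform(0.3, 0.7))
        return mixture_psd([(truncated_gaussian_psd(m1, s1, r), wgt),
                            (truncated_gaussian_psd(m2, s2, r), 1.0 - wgt)])
    if rng.random() < 0.5:
        low = float(rng.uniform(80.0, 550.0))
        high = float(low * rng.uniform(1.1, 1.9))
        return sieve_psd(low, min(high, 1000.0), r)
    m = float(rng.uniform(90.0, 650.0))
    s = float(rng.uniform(15.0, 90.0))
    return truncated_gaussian_psd(m, s, r)


def write_distribution_csv(path, dist: SizeDistribution) -> None:
    cdf = dist.cdf()
    pd.DataFrame({"r_um": dist.r_grid,
                  "density_per_um": dist.density,
                  "cdf": cdf.values}).to_csv(path, index=False)


def read_distribution_csv(path) -> SizeDistribution:
    df = pd.read_csv(path)
    if "density_per_um" in df.columns:
        return SizeDistribution(df["r_um"].to_numpy(), df["density_per_um"].to_numpy())
    return cdf_to_psd(SizeCDF(df["r_um"].to_numpy(), df["cdf"].to_numpy()))
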