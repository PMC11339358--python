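"""Optical and numerical configuration shared across the package.

All physical lengths are carried in the unit stated on each field; spatial
frequencies ("normalized displacement" u = u'/(lambda*f)) are in cycles/mm.
"""

from __future__ import annotations

import dataclasses
import json
import math


@dataclasses.dataclass(frozen=True)
class OpticalConfig:
    """Constants of the speckle probe.

    Parameters
    ----------
    wavelength_um : float
        Laser wavelength in micrometres (532 nm frequency-doubled Nd:YAG).
    focal_length_mm : float
        Focal length of the Fourier (collection) lens in millimetres.
    camera_pixel_pitch_um : float
        Effective camera pixel pitch in micrometres (2.4 um sensor pixels,
        2x2 binned -> 4.8 um).
    beam_diameter_mm : float
        Diameter of the clear illumination beam at the pupil plane.
    jinc_scale : float
        Constant kappa multiplying ``r * |u|`` inside the Jinc size-modulation
        term, with r the particle *diameter* and u in cycles per length.
        kappa = pi is the exact van Cittert-Zernike value for a uniform
        circular patch of diameter r.
    """

    wavelength_um: float = 0.532
    focal_length_mm: float = 50.0
    camera_pixel_pitch_um: float = 4.8
    beam_diameter_mm: float = 5.0
    jinc_scale: float = math.pi

    def __post_init__(self) -> None:
        for name in ("wavelength_um", "focal_length_mm", "camera_pixel_pitch_um",
                     "beam_diameter_mm", "jinc_scale"):
            if getattr(self, name) <= 0:
                raise ValueError(f"OpticalConfig.{name} must be positive")

    @property
    def lambda_f_mm2(self) -> float:
        """lambda * f in mm^2 (converts u in cycles/mm to camera-plane mm)."""
        return self.wavelength_um * 1e-3 * self.focal_length_mm

    @property
    def camera_u_pitch_per_mm(self) -> float:
        """Normalized-displacement step of one camera pixel, cycles/mm."""
        return self.camera_pixel_pitch_um * 1e-3 / self.lambda_f_mm2

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "OpticalConfig":
        return cls(**d)

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)


#: Default optics used throughout tests, examples and the CLI.
DEFAULT_OPTICS = OpticalConfig()
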