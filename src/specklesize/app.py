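"""Pipeline orchestration: training, single-frame estimation, monitoring.

These are the operations the command-line tool wraps: train an estimator
for a pupil, invert one frame into a size distribution, and run the
time-lapse monitoring mode over a stream of frames (one single-shot
estimate per frame, peak trace smoothed by a moving median) -- the mode
used to follow size dynamics in drying processes.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .autocorr import (AutocorrMap, apply_digital_filter, center_crop,
                       frame_autocorrelation)
from .config import DEFAULT_OPTICS, OpticalConfig
from .estimator import (EstimatorConfig, EstimatorModel, build_model,
                        generate_training_set, fine_tune,
                        measure_noise_model, measure_noise_residuals,
                        predict_cdf, pretrain,
                        simulator_training_set)
from .grids import LAG_N, LAG_U_PITCH, PUPIL_GRID, PUPIL_PITCH_MM
from .pupil import (PupilMask, engineered_geometry, make_engineered_pupil,
                    pupil_power_spectrum)
from .sizedist import (SizeCDF, SizeDistribution, cdf_to_psd, sieve_psd,
                       write_distribution_csv)
from .simulate import SpeckleFrame, read_frame

log = logging.getLogger("specklesize")

__all__ = ["pupil_geometry_hash", "train_estimator", "run_estimate",
           "run_timelapse", "peak_track", "TimelapseRecord"]


def pupil_geometry_hash(aperture_diameter_mm: float, primitives: list[dict]) -> str:
    """Stable hash of a pupil geometry config."""
    import hashlib
    blob = json.dumps({"d": aperture_diameter_mm, "p": primitives},
                      sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def train_estimator(aperture_diameter_mm: float | None = None,
                    primitives: list[dict] | None = None,
                    n_synth: int = 9000,
                    n_fine_tune: int = 120,
                    n_frames_equivalent: int = 1,
                    seed: int = 0,
                    cfg: EstimatorConfig | None = None,
                    calibration_dist: SizeDistribution | None = None,
                    optics: OpticalConfig = DEFAULT_OPTICS) -> EstimatorModel:
    """Full physics-informed training pipeline for one pupil.

    Calibrates the single-frame background fluctuation from the simulator,
    pretrains on ``n_synth`` synthetic forward-model maps, then fine-tunes
    the first stage on ``n_fine_tune`` simulated-frame autocorrelations.
    Defaults to the packaged engineered pupil when no geometry is given.
    """
    if primitives is None:
        aperture_diameter_mm, primitives = engineered_geometry()
    mask = make_engineered_pupil(primitives, PUPIL_PITCH_MM, PUPIL_GRID,
                                 aperture_diameter_mm)
    spec = pupil_power_spectrum(mask, pad_factor=2)
    if calibration_dist is None:
        calibration_dist = sieve_psd(250, 300)
    sigma_bg, alpha, floor = measure_noise_model(calibration_dist, mask, spec,
                                                 seed=seed + 7001)
    residuals = measure_noise_residuals(calibration_dist, mask,
                                        seed=seed + 7002)
    if cfg is None:
        cfg = EstimatorConfig(noise_sigma=sigma_bg, noise_signal_frac=alpha,
                              density_floor_factor=floor,
                              n_frames_equivalent=n_frames_equivalent,
                              seed=seed)
    log.info("calibrated single-frame noise: background sigma %.4f, "
             "signal fraction %.3f, floor factor %.2f", sigma_bg, alpha, floor)
    tset = generate_training_set(n_synth, spec, cfg, seed=seed + 1,
                                 optics=optics, noise_residuals=residuals)
    model = build_model(cfg, tset.mask, psd_lag=tset.psd_lag)
    model.pupil_hash = pupil_geometry_hash(aperture_diameter_mm, primitives)
    trace = pretrain(model, tset, seed=seed + 2)
    log.info("pretraining loss: %.1f -> %.1f um", trace[0], trace[-1])
    if n_fine_tune > 0:
        fset = simulator_training_set(n_fine_tune, mask, spec, cfg,
                                      seed=seed + 3)
        ft = fine_tune(model, fset, seed=seed + 4)
        log.info("fine-tuning loss: %.1f -> %.1f um", ft[0], ft[-1])
    return model


def _frame_to_map(frame: SpeckleFrame, model: EstimatorModel) -> AutocorrMap:
    a = center_crop(frame_autocorrelation(frame), model.cfg.input_size)
    return apply_digital_filter(a, model.mask)


def run_estimate(frame_path, model: EstimatorModel, out_dir=None,
                 expected_pupil_hash: str | None = None
                 ) -> tuple[SizeCDF, SizeDistribution]:
    """Single-shot PSD estimate from one stored frame.

    Refuses frames whose sidecar records a pupil geometry different from
    the one the model was trained for.
    """
    frame_path = Path(frame_path)
    try:
        frame = read_frame(frame_path)
    except Exception as exc:
        raise IOError(f"cannot read frame {frame_path}: {exc}") from exc
    side = Path(str(frame_path) + ".json")
    if side.exists():
        meta = json.loads(side.read_text())
        fhash = meta.get("pupil_hash")
        mhash = getattr(model, "pupil_hash", None)
        want = expected_pupil_hash or mhash
        if fhash is not None and want is not None and fhash != want:
            raise ValueError(
                f"pupil geometry mismatch: frame recorded {fhash}, model "
                f"was trained for {want}; refusing to estimate")
    cdf = predict_cdf(model, _frame_to_map(frame, model))
    dist = cdf_to_psd(cdf)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        write_distribution_csv(out_dir / (frame_path.stem + "_psd.csv"), dist)
        log.info("wrote %s", out_dir / (frame_path.stem + "_psd.csv"))
    return cdf, dist


@dataclasses.dataclass
class TimelapseRecord:
    timestamp_s: float
    distribution: SizeDistribution
    peak_um: float
    smoothed_peak_um: float = float("nan")


def peak_track(series: list[SizeDistribution], window: int = 5) -> np.ndarray:
    """Per-frame density-mode positions smoothed by a moving median."""
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be odd and >= 1")
    peaks = np.array([d.peak_position() for d in series], dtype=float)
    if window == 1 or len(peaks) == 0:
        return peaks
    h = window // 2
    out = np.empty_like(peaks)
    for i in range(len(peaks)):
        out[i] = np.median(peaks[max(0, i - h):i + h + 1])
    return out


def run_timelapse(frames, model: EstimatorModel, out_csv=None,
                  window: int = 5) -> list[TimelapseRecord]:
    """Monitoring mode: one single-pass estimate per frame, sorted by time.

    ``frames`` is a directory of TIFF+sidecar frames, or an iterable of
    (timestamp_s, SpeckleFrame) pairs.  Unreadable frames are logged and
    skipped, not fatal.
    """
    items: list[tuple[float, SpeckleFrame]] = []
    if isinstance(frames, (str, Path)):
        paths = sorted(p for p in Path(frames).iterdir()
                       if p.suffix.lower() in (".tif", ".tiff", ".png"))
        for k, path in enumerate(paths):
            try:
                fr = read_frame(path)
                meta = json.loads(Path(str(path) + ".json").read_text())
                t = float(meta.get("timestamp_s", k))
            except Exception as exc:
                log.warning("skipping frame %s: %s", path, exc)
                continue
            items.append((t, fr))
    else:
        items = [(float(t), fr) for t, fr in frames]
    items.sort(key=lambda tf: tf[0])
    if not items:
        warnings.warn("no readable frames; timelapse is empty", stacklevel=2)
    records = []
    for t, fr in items:
        cdf = predict_cdf(model, _frame_to_map(fr, model))
        dist = cdf_to_psd(cdf)
        records.append(TimelapseRecord(t, dist, dist.peak_position()))
    smooth = peak_track([r.distribution for r in records], window)
    for r, s in zip(records, smooth):
        r.smoothed_peak_um = float(s)
    if out_csv is not None:
        pd.DataFrame({
            "timestamp_s": [r.timestamp_s for r in records],
            "peak_um": [r.peak_um for r in records],
            "smoothed_peak_um": [r.smoothed_peak_um for r in records],
        }).to_csv(out_csv, index=False)
    return records
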