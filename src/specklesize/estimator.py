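"""Learning-based inversion: masked autocorrelation -> cumulative size CDF.

The estimator is a small CNN (four conv stages + fully connected head,
~640k parameters) whose output head emits nonnegative increments summing to
one, so every prediction is a valid CDF and the L1 training loss on CDF
bins equals the 1-Wasserstein distance in micrometres.

Training follows the physics-informed recipe: pretrain the whole network on
synthetic autocorrelations generated from the forward model -- with the
calibrated finite-density floor added and measured single-frame residual
fields injected as noise, both emulating an N-frame-averaged measurement --
then freeze the final three stages and the head and fine-tune only the
first stage (~4.2k parameters) on domain data (here: autocorrelations of
simulated frames).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json

import numpy as np
from scipy.ndimage import gaussian_filter

from .autocorr import (AutocorrMap, apply_digital_filter, background_fluctuation,
                       center_crop, frame_autocorrelation)
from .config import DEFAULT_OPTICS, OpticalConfig
from .forward import jinc
from .grids import LAG_N, LAG_U_PITCH
from .nn import Adam, SpeckleNet, w1_batch_loss
from .pupil import EffectiveRegionMask, PupilSpectrum, effective_region_mask
from .sizedist import (SizeCDF, SizeDistribution, default_r_grid,
                       random_size_distribution, trapezoid_weights, w1_distance)

__all__ = [
    "EstimatorConfig",
    "TrainingSet",
    "build_model",
    "generate_training_set",
    "pretrain",
    "fine_tune",
    "predict_cdf",
    "w1_loss",
    "measure_background_sigma",
    "measure_noise_model",
    "measure_noise_residuals",
    "autocorr_to_input",
    "save_model",
    "load_model",
]

#: Printed parameter budgets the architecture must honor (+-10%).
TOTAL_PARAM_BUDGET = 625_000
STAGE1_PARAM_BUDGET = 4_200


@dataclasses.dataclass
class EstimatorConfig:
    """Architecture and training hyperparameters.

    The channel plan (21, 40, 64, 96) with a 256-unit hidden layer puts the
    first stage at 4284 parameters and the whole network at ~643.7k, inside
    the +-10% budgets.  ``noise_sigma``/``noise_signal_frac`` parametrize
    the fallback heteroscedastic training noise and
    ``density_floor_factor`` scales the analytic occupancy floor; all three
    are calibrated from the simulator with ``measure_noise_model``.
    ``n_frames_equivalent`` rescales the noise by 1/sqrt(N) for models
    meant to read N-frame-averaged inputs.
    """

    input_size: int = LAG_N
    channels: tuple[int, int, int, int] = (21, 40, 64, 96)
    hidden: int = 256
    n_bins: int = 96
    seed: int = 0
    epochs: int = 16
    batch_size: int = 32
    learning_rate: float = 1e-3
    fine_tune_epochs: int = 30
    fine_tune_lr: float = 5e-4
    noise_sigma: float = 0.02
    noise_signal_frac: float = 0.08
    noise_corr_px: float = 1.2
    n_frames_equivalent: int = 1
    mask_threshold: float = 0.023
    input_power: float = 1.0
    input_mode: str = "map"  # "map", "psd_norm", or "both"
    include_density_floor: bool = True
    density_floor_factor: float = 0.35
    surface_coverage: float = 0.45
    huber_delta_cdf: float = 0.02

    @property
    def input_channels(self) -> int:
        return 2 if self.input_mode == "both" else 1

    def r_grid(self) -> np.ndarray:
        return default_r_grid(self.n_bins)


@dataclasses.dataclass
class TrainingSet:
    """Paired (masked autocorrelation input, target CDF) arrays."""

    inputs: np.ndarray            # (n, 1, s, s) float32
    targets: np.ndarray           # (n, n_bins) float32
    r_grid: np.ndarray
    mask: EffectiveRegionMask
    psd_lag: np.ndarray | None = None   # pupil PSD on the lag grid
    provenance: str = "synthetic"

    def __post_init__(self):
        if len(self.inputs) != len(self.targets):
            raise ValueError("input/target counts differ")

    def __len__(self) -> int:
        return len(self.inputs)

    def content_hash(self) -> str:
        h = hashlib.sha256()
        h.update(np.ascontiguousarray(self.inputs).tobytes())
        h.update(np.ascontiguousarray(self.targets).tobytes())
        return h.hexdigest()


class EstimatorModel:
    """SpeckleNet plus the preprocessing contract it was trained with."""

    def __init__(self, net: SpeckleNet, cfg: EstimatorConfig,
                 mask: EffectiveRegionMask,
                 psd_lag: np.ndarray | None = None):
        self.net = net
        self.cfg = cfg
        self.mask = mask
        self.psd_lag = psd_lag
        self.pretrained = False
        self.loss_trace: list[float] = []

    def _input(self, acorr: AutocorrMap) -> np.ndarray:
        return autocorr_to_input(acorr, self.mask, self.cfg.input_power,
                                 self.psd_lag, self.cfg.input_mode)

    def mask_hash(self) -> str:
        return hashlib.sha256(np.packbits(self.mask.mask).tobytes()).hexdigest()


def build_model(cfg: EstimatorConfig, mask: EffectiveRegionMask,
                seed: int | None = None,
                psd_lag: np.ndarray | None = None) -> EstimatorModel:
    """Deterministically initialized network honoring the parameter budgets."""
    net = SpeckleNet(cfg.channels, cfg.hidden, cfg.n_bins, cfg.input_size,
                     cfg.seed if seed is None else seed,
                     in_channels=cfg.input_channels)
    counts = net.stage_param_counts()
    total = sum(counts)
    if not (0.9 * TOTAL_PARAM_BUDGET <= total <= 1.1 * TOTAL_PARAM_BUDGET):
        raise ValueError(f"total parameter count {total} violates the "
                         f"{TOTAL_PARAM_BUDGET} +-10% budget (stages: {counts})")
    if not (0.9 * STAGE1_PARAM_BUDGET <= counts[0] <= 1.1 * STAGE1_PARAM_BUDGET):
        raise ValueError(f"stage-1 parameter count {counts[0]} violates the "
                         f"{STAGE1_PARAM_BUDGET} +-10% budget")
    return EstimatorModel(net, cfg, mask, psd_lag=psd_lag)


# ---------------------------------------------------------------------------
# synthetic data
# ---------------------------------------------------------------------------

def _model_map_basis(spec: PupilSpectrum, r_grid: np.ndarray,
                     n_lag: int, u_pitch: float,
                     cfg: OpticalConfig) -> tuple[np.ndarray, np.ndarray]:
    """Precompute (PSD on lag grid, Jinc basis) for fast map synthesis."""
    psd = spec.on_lag_grid(n_lag, u_pitch)
    u = (np.arange(n_lag) - n_lag // 2) * u_pitch
    ux, uy = np.meshgrid(u, u, indexing="xy")
    uabs = np.hypot(ux, uy).ravel()
    basis = jinc(cfg.jinc_scale * np.outer(uabs, r_grid * 1e-3))
    return psd, basis


def synthesize_map(density: np.ndarray, psd: np.ndarray, basis: np.ndarray,
                   r_weights: np.ndarray, r_grid: np.ndarray,
                   floor_scale: float | None = None) -> np.ndarray:
    """Forward-model autocorrelation for one density vector.

    With ``floor_scale`` = 1/(rho * open_area_mm2) the analytic
    finite-particle-number occupancy floor is added: packing fluctuations
    of a finite number of particles bias measured sidelobes upward by
    (1/N_p) E[a^2 Jinc^2]/E[a]^2, the same term single-frame measurements
    contain.  ``rho`` is the particle number density, ``a`` the particle
    area.
    """
    r_mm = r_grid * 1e-3
    area = np.pi * r_mm**2 / 4
    wp = r_weights * density
    w = wp * r_mm**2
    amp = basis @ w / w.sum()
    m = psd * (amp.reshape(psd.shape) ** 2)
    m = m / m[psd.shape[0] // 2, psd.shape[1] // 2]
    if floor_scale is not None:
        # E[(a Jinc)^2](u) / E[a]^2; basis holds Jinc(pi r |u|) columns
        num = (basis**2) @ (wp * area**2)
        floor = floor_scale * num / float(wp @ area) ** 2
        m = m + floor.reshape(psd.shape)
        m = m / m[psd.shape[0] // 2, psd.shape[1] // 2]
    return m


def autocorr_to_input(acorr: AutocorrMap, mask: EffectiveRegionMask,
                      power: float = 1.0,
                      psd_lag: np.ndarray | None = None,
                      mode: str = "both") -> np.ndarray:
    """Network input channels from a filtered autocorrelation map.

    Channel "map" is the raw filtered autocorrelation; channel "psd_norm"
    divides it by the peak-normalized pupil PSD on the same lag grid, which
    isolates the size-modulation factor the inversion is after (clipped to
    [0, 1.5] to bound noise amplification at weak pixels).  ``mode``
    selects either channel or both stacked.  ``power`` < 1 optionally
    compresses the dynamic range.  Raises if the map was not filtered with
    (a geometry matching) ``mask``.
    """
    v = acorr.values
    if v.shape != mask.mask.shape:
        raise ValueError(f"map shape {v.shape} does not match the digital "
                         f"filter {mask.mask.shape}")
    outside = np.abs(v[~mask.mask])
    if outside.size and outside.max() > 1e-12:
        raise ValueError("input map is not filtered with the training mask; "
                         "apply apply_digital_filter first")
    if mode not in ("map", "psd_norm", "both"):
        raise ValueError(f"unknown input mode {mode!r}")
    chans = []
    if mode in ("map", "both"):
        chans.append(np.clip(v, 0.0, None) ** power)
    if mode in ("psd_norm", "both"):
        if psd_lag is None:
            raise ValueError("psd_norm input mode requires the pupil PSD")
        q = np.where(mask.mask, v / np.where(mask.mask, psd_lag, 1.0), 0.0)
        chans.append(np.clip(q, 0.0, 1.5) ** power)
    return np.stack(chans).astype(np.float32)


def generate_training_set(n: int, spec: PupilSpectrum, cfg: EstimatorConfig,
                          seed: int = 0,
                          optics: OpticalConfig = DEFAULT_OPTICS,
                          sampler=random_size_distribution,
                          noise_residuals: np.ndarray | None = None,
                          residual_prob: float = 0.7) -> TrainingSet:
    """Synthetic pretraining set: forward-model maps + background noise.

    Each item draws a random size distribution, evaluates the forward model
    on the canonical lag grid, adds heteroscedastic correlated Gaussian
    noise emulating an N-frame-averaged measurement -- a background
    component of std ``noise_sigma`` plus a signal-proportional component
    ``noise_signal_frac x A(u)`` (speckle autocorrelation estimates
    fluctuate in proportion to their local value), both scaled by
    1/sqrt(n_frames_equivalent) -- applies the digital filter, and stores
    the transformed map with the true CDF.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    r_grid = cfg.r_grid()
    w = trapezoid_weights(r_grid)
    psd, basis = _model_map_basis(spec, r_grid, cfg.input_size, LAG_U_PITCH,
                                  optics)
    mask = effective_region_mask(spec, cfg.mask_threshold,
                                 n_lag=cfg.input_size, u_pitch_per_mm=LAG_U_PITCH)
    scale = 1.0 / np.sqrt(cfg.n_frames_equivalent)
    sigma_bg = cfg.noise_sigma * scale
    alpha = cfg.noise_signal_frac * scale
    psd32 = psd.astype(np.float32)
    inputs = np.empty((n, cfg.input_channels, cfg.input_size, cfg.input_size),
                      dtype=np.float32)
    targets = np.empty((n, cfg.n_bins), dtype=np.float32)

    def correlated(shape):
        g = gaussian_filter(rng.standard_normal(shape), cfg.noise_corr_px)
        return g / g.std()

    open_mm2 = float(np.sqrt(spec.peak_value))  # binary mask: peak = area^2
    for i in range(n):
        dist = sampler(rng, r_grid)
        fs = None
        if cfg.include_density_floor and cfg.density_floor_factor > 0:
            mean_area = float((w * dist.density)
                              @ (np.pi * (r_grid * 1e-3) ** 2 / 4))
            rho = cfg.surface_coverage / mean_area
            fs = cfg.density_floor_factor / (rho * open_mm2)
        m = synthesize_map(dist.density, psd, basis, w, r_grid, floor_scale=fs)
        if noise_residuals is not None and rng.random() < residual_prob:
            # measured single-frame residual field (flipped/scaled variant)
            res = noise_residuals[rng.integers(len(noise_residuals))]
            if rng.random() < 0.5:
                res = res[:, ::-1]
            m = m + scale * float(rng.uniform(0.8, 1.2)) * res
        elif sigma_bg > 0 or alpha > 0:
            m = m + sigma_bg * correlated(m.shape) \
                + alpha * m * correlated(m.shape)
        m = np.where(mask.mask, m, 0.0)
        inputs[i] = autocorr_to_input(AutocorrMap(m, LAG_U_PITCH), mask,
                                      cfg.input_power, psd32, cfg.input_mode)
        targets[i] = dist.cdf().values
    return TrainingSet(inputs, targets, r_grid, mask, psd_lag=psd32,
                       provenance="synthetic")


def simulator_training_set(n: int, pupil_mask, spec: PupilSpectrum,
                           cfg: EstimatorConfig, seed: int = 0,
                           sampler=random_size_distribution) -> TrainingSet:
    """Domain-shifted set: autocorrelations of physically simulated frames.

    One fresh surface realization and single rendered frame per item;
    targets are the generating distributions' CDFs.  Used for first-stage
    fine-tuning (the simulator plays the role of the instrument).
    """
    from .simulate import simulate_ensemble
    rng = np.random.default_rng(seed)
    r_grid = cfg.r_grid()
    mask = effective_region_mask(spec, cfg.mask_threshold,
                                 n_lag=cfg.input_size, u_pitch_per_mm=LAG_U_PITCH)
    psd32 = spec.on_lag_grid(cfg.input_size, LAG_U_PITCH).astype(np.float32)
    inputs = np.empty((n, cfg.input_channels, cfg.input_size, cfg.input_size),
                      dtype=np.float32)
    targets = np.empty((n, cfg.n_bins), dtype=np.float32)
    navg = cfg.n_frames_equivalent
    for i in range(n):
        dist = sampler(rng, r_grid)
        frames = simulate_ensemble(dist, pupil_mask, n_frames=navg,
                                   seed=int(rng.integers(2**31 - 1)))
        maps = [center_crop(frame_autocorrelation(f), cfg.input_size).values
                for f in frames]
        a = AutocorrMap(np.mean(maps, axis=0), LAG_U_PITCH, navg)
        filt = apply_digital_filter(a, mask)
        inputs[i] = autocorr_to_input(filt, mask, cfg.input_power, psd32,
                                      cfg.input_mode)
        targets[i] = dist.cdf().values
    return TrainingSet(inputs, targets, r_grid, mask, psd_lag=psd32,
                       provenance="simulator")


def measure_background_sigma(p: SizeDistribution, pupil_mask,
                             n_frames: int = 12, seed: int = 777,
                             inner_px: int = 20, outer_px: int = 28) -> float:
    """Single-frame background fluctuation level from the simulator.

    Median over frames of the std in a lag annulus outside the effective
    region; the generated-noise calibration for synthetic pretraining.
    """
    from .simulate import simulate_ensemble
    sigmas = []
    for fr in simulate_ensemble(p, pupil_mask, n_frames=n_frames, seed=seed):
        a = center_crop(frame_autocorrelation(fr), LAG_N)
        sigmas.append(background_fluctuation(a, inner_px, outer_px).sigma)
    return float(np.median(sigmas))


def measure_noise_residuals(p: SizeDistribution, pupil_mask,
                            n_frames: int = 32, seed: int = 777) -> np.ndarray:
    """Library of single-frame autocorrelation residuals from the simulator.

    Residual = frame autocorrelation minus the ensemble mean over the same
    frames: zero-mean fields carrying the true spatial correlation and
    signal-dependence of single-shot measurement noise.  Injected into
    synthetic pretraining maps they emulate single-frame statistics far
    more faithfully than parametric noise.
    """
    from .simulate import simulate_ensemble
    maps = np.array([
        center_crop(frame_autocorrelation(fr), LAG_N).values
        for fr in simulate_ensemble(p, pupil_mask, n_frames=n_frames,
                                    seed=seed)], dtype=np.float32)
    return maps - maps.mean(axis=0, keepdims=True)


def analytic_density_floor(p: SizeDistribution, basis: np.ndarray,
                           open_mm2: float, coverage: float = 0.45) -> np.ndarray:
    """Poisson occupancy floor (1/N_p) E[(a Jinc)^2]/E[a]^2 on the lag grid."""
    r_mm = p.r_grid * 1e-3
    area = np.pi * r_mm**2 / 4
    wp = p.weights * p.density
    mean_area = float(wp @ area)
    rho = coverage / mean_area
    num = (basis**2) @ (wp * area**2)
    return (num / float(wp @ area) ** 2 / (rho * open_mm2)).reshape(LAG_N, LAG_N)


def measure_noise_model(p: SizeDistribution, pupil_mask,
                        spec: PupilSpectrum, n_frames: int = 12,
                        seed: int = 777,
                        optics: OpticalConfig = DEFAULT_OPTICS
                        ) -> tuple[float, float, float]:
    """Calibrate the single-frame noise and floor model.

    Renders ``n_frames`` frames of the calibration powder and returns
    (sigma_bg, alpha, floor_factor):

    - ``sigma_bg``: flat background fluctuation (median per-pixel std over
      a lag annulus outside the effective region);
    - ``alpha``: signal-proportional noise fraction fitted on strong
      sidelobe pixels, std(u) ~ sqrt(sigma_bg^2 + (alpha A(u))^2);
    - ``floor_factor``: least-squares scale of the analytic Poisson
      occupancy floor against the measured ensemble-mean deviation from
      the forward model (the packing structure factor suppresses the
      Poisson value, so the factor is typically 0.2-0.6).
    """
    from .forward import expected_autocorrelation
    from .simulate import simulate_ensemble
    maps = np.array([
        center_crop(frame_autocorrelation(fr), LAG_N).values
        for fr in simulate_ensemble(p, pupil_mask, n_frames=n_frames,
                                    seed=seed)])
    std = maps.std(axis=0, ddof=1)
    yy, xx = np.indices((LAG_N, LAG_N))
    cheb = np.maximum(np.abs(yy - LAG_N // 2), np.abs(xx - LAG_N // 2))
    sigma_bg = float(np.median(std[(cheb > 20) & (cheb <= 28)]))
    model = expected_autocorrelation(spec, p).values
    strong = (model > 0.05) & (cheb > 2)
    if strong.any():
        excess = np.sqrt(np.clip(std[strong] ** 2 - sigma_bg**2, 0.0, None))
        alpha = float(np.median(excess / model[strong]))
    else:
        alpha = 0.0
    _, basis = _model_map_basis(spec, p.r_grid, LAG_N, LAG_U_PITCH, optics)
    floor = analytic_density_floor(p, basis, float(np.sqrt(spec.peak_value)))
    dev = maps.mean(axis=0) - model
    sel = (cheb > 2) & (floor > 0)
    denom = float((floor[sel] ** 2).sum())
    factor = float((dev[sel] * floor[sel]).sum() / denom) if denom > 0 else 0.0
    return sigma_bg, alpha, float(np.clip(factor, 0.0, 1.0))


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

def _run_epochs(model: EstimatorModel, tset: TrainingSet, epochs: int,
                lr: float, seed: int, stall_check: bool = False) -> list[float]:
    rng = np.random.default_rng(seed)
    w_bins = trapezoid_weights(tset.r_grid).astype(np.float32)
    opt = Adam(lr=lr)
    n = len(tset)
    bs = model.cfg.batch_size
    trace = []
    for ep in range(epochs):
        if stall_check and ep == 3 and trace[2] > 0.9 * trace[0]:
            return trace  # optimizer stalled out of the gate; caller restarts
        # linear warmup over the first two epochs, then cosine decay to 5%
        warm = min(1.0, (ep + 1) / 2.0)
        opt.lr = warm * lr * (0.05 + 0.95 * 0.5
                              * (1 + np.cos(np.pi * ep / max(epochs - 1, 1))))
        order = rng.permutation(n)
        total = 0.0
        for k in range(0, n, bs):
            idx = order[k:k + bs]
            cdf = model.net.forward(tset.inputs[idx], train=True)
            loss, grad = w1_batch_loss(cdf, tset.targets[idx], w_bins,
                                       model.cfg.huber_delta_cdf)
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"training diverged (loss={loss}); trace so far: {trace}")
            model.net.backward(grad)
            opt.step(model.net.trainable_layers())
            total += loss * len(idx)
        trace.append(total / n)
    return trace


def pretrain(model: EstimatorModel, tset: TrainingSet,
             epochs: int | None = None, seed: int = 0) -> list[float]:
    """Train all stages on the synthetic set; returns the epoch loss trace.

    Cold starts occasionally stall (the softmax head collapses toward a
    constant CDF); a stalled run is detected after three epochs and the
    network is deterministically reinitialized from a shifted seed, up to
    three attempts.
    """
    if len(tset) == 0:
        raise ValueError("empty training set")
    cfg = model.cfg
    n_epochs = cfg.epochs if epochs is None else epochs
    for attempt in range(3):
        model.net.trainable = [True] * len(model.net.trainable)
        trace = _run_epochs(model, tset, n_epochs, cfg.learning_rate, seed,
                            stall_check=n_epochs > 3)
        if len(trace) == n_epochs:
            break
        model.net = SpeckleNet(cfg.channels, cfg.hidden, cfg.n_bins,
                               cfg.input_size, cfg.seed + 7919 * (attempt + 1),
                               in_channels=cfg.input_channels)
    model.pretrained = True
    model.loss_trace = trace
    return trace


def fine_tune(model: EstimatorModel, tset: TrainingSet,
              epochs: int | None = None, seed: int = 1) -> list[float]:
    """Adapt only the first convolutional stage to domain-shifted data.

    Stages 2-4 and the head are frozen (bitwise unchanged); the ~4.2k
    stage-1 parameters absorb the domain transfer.
    """
    if not model.pretrained:
        raise RuntimeError("fine_tune requires a pretrained model")
    model.net.trainable = [True] + [False] * (len(model.net.trainable) - 1)
    trace = _run_epochs(model, tset,
                        model.cfg.fine_tune_epochs if epochs is None else epochs,
                        model.cfg.fine_tune_lr, seed)
    model.net.trainable = [True] * len(model.net.trainable)
    model.loss_trace = model.loss_trace + trace
    return trace


def predict_cdf(model: EstimatorModel, acorr: AutocorrMap) -> SizeCDF:
    """Invert one masked autocorrelation map into a cumulative distribution."""
    x = model._input(acorr)
    cdf = model.net.forward(x[None, ...])[0]
    cdf = np.clip(cdf.astype(float), 0.0, 1.0)
    cdf[-1] = 1.0
    return SizeCDF(model.cfg.r_grid(), cdf)


def w1_loss(a: SizeCDF, b: SizeCDF) -> float:
    """1-Wasserstein distance between two CDFs, micrometres."""
    return w1_distance(a, b)


# ---------------------------------------------------------------------------
# persistence
# ---------------------------------------------------------------------------

def save_model(path, model: EstimatorModel) -> None:
    """Single-file .npz checkpoint with config, mask and stage digests."""
    meta = json.dumps({
        "config": dataclasses.asdict(model.cfg),
        "digests": model.net.digests(),
        "mask_threshold": model.mask.threshold,
        "u_pitch_per_mm": model.mask.u_pitch_per_mm,
        "pretrained": model.pretrained,
        "loss_trace": model.loss_trace,
    })
    extra = {}
    if model.psd_lag is not None:
        extra["__psd__"] = model.psd_lag
    np.savez_compressed(path, __meta__=np.frombuffer(meta.encode(), dtype=np.uint8),
                        __mask__=model.mask.mask, **extra,
                        **model.net.state_arrays())


def load_model(path) -> EstimatorModel:
    data = np.load(path)
    meta = json.loads(bytes(data["__meta__"]).decode())
    cfg_d = meta["config"]
    cfg_d["channels"] = tuple(cfg_d["channels"])
    cfg = EstimatorConfig(**cfg_d)
    mask = EffectiveRegionMask(data["__mask__"].astype(bool),
                               meta["mask_threshold"], meta["u_pitch_per_mm"])
    psd_lag = data["__psd__"] if "__psd__" in data.files else None
    model = build_model(cfg, mask, psd_lag=psd_lag)
    model.net.load_state_arrays(data)
    model.pretrained = bool(meta["pretrained"])
    model.loss_trace = list(meta["loss_trace"])
    return model
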