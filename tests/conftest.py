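"""Shared fixtures: canonical pupils, spectra, and a small trained model."""

import numpy as np
import pytest

from specklesize import grids
from specklesize.estimator import (EstimatorConfig, build_model, fine_tune,
                                   generate_training_set, measure_noise_model,
                                   measure_noise_residuals, pretrain,
                                   simulator_training_set)
from specklesize.pupil import (engineered_pupil, make_clear_pupil,
                               pupil_power_spectrum)
from specklesize.sizedist import sieve_psd


@pytest.fixture(scope="session")
def clear_mask():
    return make_clear_pupil(5.0, grids.PUPIL_PITCH_MM, grids.PUPIL_GRID)


@pytest.fixture(scope="session")
def clear_spec(clear_mask):
    return pupil_power_spectrum(clear_mask, pad_factor=grids.PUPIL_PAD)


@pytest.fixture(scope="session")
def eng_mask():
    return engineered_pupil(grids.PUPIL_PITCH_MM, grids.PUPIL_GRID)


@pytest.fixture(scope="session")
def eng_spec(eng_mask):
    return pupil_power_spectrum(eng_mask, pad_factor=grids.PUPIL_PAD)


@pytest.fixture(scope="session")
def p_mid():
    return sieve_psd(250, 300)


@pytest.fixture(scope="session")
def mini_model(eng_mask, eng_spec, p_mid):
    """Small but functional estimator (engineered pupil, single-frame noise).

    Pretrained on a reduced synthetic set and fine-tuned on a handful of
    simulated frames; shared by the closed-loop application tests.
    """
    sigma_bg, alpha, floor = measure_noise_model(p_mid, eng_mask, eng_spec,
                                                 n_frames=10)
    residuals = measure_noise_residuals(p_mid, eng_mask, n_frames=32)
    cfg = EstimatorConfig(noise_sigma=sigma_bg, noise_signal_frac=alpha,
                          density_floor_factor=floor, epochs=16, seed=0)
    tset = generate_training_set(1200, eng_spec, cfg, seed=41,
                                 noise_residuals=residuals)
    model = build_model(cfg, tset.mask, psd_lag=tset.psd_lag)
    pretrain(model, tset, seed=42)

    def instrument_sampler(rng, r):
        """Sieve fractions and calibrated Gaussians over the working range,
        bounded below ~105 um so the simulation grid stays coarse."""
        from specklesize.sizedist import truncated_gaussian_psd
        if rng.random() < 0.5:
            low = float(rng.uniform(110.0, 420.0))
            return sieve_psd(low, low * float(rng.uniform(1.15, 1.6)), r)
        mu = float(rng.uniform(160.0, 450.0))
        s = float(rng.uniform(20.0, min(60.0, (mu - 105.0) / 3)))
        return truncated_gaussian_psd(mu, s, r)

    fset = simulator_training_set(128, eng_mask, eng_spec, cfg, seed=43,
                                  sampler=instrument_sampler)
    fine_tune(model, fset, epochs=40, seed=44)
    return model
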