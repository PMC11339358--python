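"""Estimator: architecture budgets, training contracts, prediction."""

import numpy as np
import pytest

from specklesize import grids
from specklesize.autocorr import AutocorrMap
from specklesize.estimator import (EstimatorConfig, autocorr_to_input,
                                   build_model, fine_tune,
                                   generate_training_set, load_model,
                                   predict_cdf, pretrain, save_model,
                                   simulator_training_set, w1_loss)
from specklesize.nn import w1_batch_loss
from specklesize.sizedist import SizeCDF, trapezoid_weights


@pytest.fixture(scope="module")
def small_set(eng_spec):
    cfg = EstimatorConfig(noise_sigma=0.007, seed=0, epochs=3)
    return cfg, generate_training_set(96, eng_spec, cfg, seed=17)


class TestArchitecture:
    def test_parameter_budgets(self, small_set):
        cfg, tset = small_set
        model = build_model(cfg, tset.mask)
        counts = model.net.stage_param_counts()
        assert 562_500 <= sum(counts) <= 687_500        # 625k +- 10%
        assert 3_780 <= counts[0] <= 4_620              # 4.2k +- 10%

    def test_budget_violation_rejected(self, small_set):
        cfg, tset = small_set
        bad = EstimatorConfig(channels=(8, 16, 24, 32), seed=0)
        with pytest.raises(ValueError, match="budget"):
            build_model(bad, tset.mask)

    def test_same_seed_bitwise_identical_init(self, small_set):
        cfg, tset = small_set
        a = build_model(cfg, tset.mask, seed=5)
        b = build_model(cfg, tset.mask, seed=5)
        assert a.net.digests() == b.net.digests()
        c = build_model(cfg, tset.mask, seed=6)
        assert a.net.digests() != c.net.digests()


class TestTrainingSet:
    def test_targets_are_valid_cdfs(self, small_set):
        cfg, tset = small_set
        assert len(tset) == 96
        t = tset.targets
        assert np.all(np.diff(t, axis=1) >= -1e-6)
        assert np.all(t >= -1e-6) and np.all(t <= 1 + 1e-6)
        assert np.allclose(t[:, -1], 1.0, atol=1e-6)

    def test_regeneration_hash_stable(self, eng_spec):
        cfg = EstimatorConfig(noise_sigma=0.007, seed=0)
        a = generate_training_set(24, eng_spec, cfg, seed=3)
        b = generate_training_set(24, eng_spec, cfg, seed=3)
        assert a.content_hash() == b.content_hash()
        c = generate_training_set(24, eng_spec, cfg, seed=4)
        assert a.content_hash() != c.content_hash()

    def test_inputs_respect_digital_filter(self, small_set):
        cfg, tset = small_set
        outside = tset.inputs[:, 0][:, ~tset.mask.mask]
        assert np.abs(outside).max() == 0.0

    def test_n_validation(self, eng_spec):
        with pytest.raises(ValueError):
            generate_training_set(0, eng_spec, EstimatorConfig())


class TestPretraining:
    def test_loss_improves_and_is_deterministic(self, small_set):
        cfg, tset = small_set
        m1 = build_model(cfg, tset.mask, seed=1)
        tr1 = pretrain(m1, tset, epochs=3, seed=2)
        assert tr1[-1] < tr1[0]
        m2 = build_model(cfg, tset.mask, seed=1)
        tr2 = pretrain(m2, tset, epochs=3, seed=2)
        assert tr1 == tr2
        assert m1.net.digests() == m2.net.digests()

    def test_empty_set_rejected(self, small_set, eng_spec):
        cfg, tset = small_set
        model = build_model(cfg, tset.mask)
        bad = generate_training_set(1, eng_spec, cfg, seed=0)
        bad.inputs = bad.inputs[:0]
        bad.targets = bad.targets[:0]
        with pytest.raises(ValueError):
            pretrain(model, bad)


class TestFineTuning:
    def test_freezing_contract_and_update_size(self, small_set, eng_mask,
                                               eng_spec):
        cfg, tset = small_set
        model = build_model(cfg, tset.mask, seed=1)
        pretrain(model, tset, epochs=2, seed=2)
        before = model.net.digests()
        fset = simulator_training_set(6, eng_mask, eng_spec, cfg, seed=3)
        fine_tune(model, fset, epochs=2, seed=4)
        after = model.net.digests()
        # stages 2-4 and the head bitwise unchanged; stage 1 updated
        assert after[1:] == before[1:]
        assert after[0] != before[0]
        counts = model.net.stage_param_counts()
        assert 3_780 <= counts[0] <= 4_620

    def test_requires_pretrained_model(self, small_set):
        cfg, tset = small_set
        model = build_model(cfg, tset.mask)
        with pytest.raises(RuntimeError):
            fine_tune(model, tset)

    def test_transfer_improves_on_simulator_domain(self, mini_model, eng_mask,
                                                   eng_spec, p_mid):
        """Fine-tuning on simulated frames must help on that domain."""
        from specklesize.estimator import measure_noise_residuals

        def sieve_sampler(rng, r):
            from specklesize.sizedist import sieve_psd
            low = float(rng.uniform(110.0, 420.0))
            return sieve_psd(low, low * float(rng.uniform(1.15, 1.6)), r)

        cfg = mini_model.cfg
        test_set = simulator_training_set(10, eng_mask, eng_spec, cfg, seed=91,
                                          sampler=sieve_sampler)

        def mean_w1(model):
            w = trapezoid_weights(model.cfg.r_grid()).astype(np.float32)
            cdf = model.net.forward(test_set.inputs)
            return w1_batch_loss(cdf, test_set.targets, w)[0]

        # rebuild the pretrained-only model from the same seeds as mini_model
        residuals = measure_noise_residuals(p_mid, eng_mask, n_frames=32)
        pre = build_model(cfg, mini_model.mask, psd_lag=mini_model.psd_lag)
        tset = generate_training_set(900, eng_spec, cfg, seed=41,
                                     noise_residuals=residuals)
        pretrain(pre, tset, seed=42)
        assert mean_w1(mini_model) < mean_w1(pre)


class TestPrediction:
    def test_output_is_structurally_monotone(self, small_set):
        cfg, tset = small_set
        # untrained model: arbitrary weights still yield a valid CDF
        model = build_model(cfg, tset.mask, psd_lag=tset.psd_lag)
        a = AutocorrMap(np.where(tset.mask.mask,
                                 np.random.default_rng(0).random((64, 64)), 0.0),
                        grids.LAG_U_PITCH)
        cdf = predict_cdf(model, a)
        assert np.all(np.diff(cdf.values) >= -1e-7)
        assert 0 <= cdf.values[0] and cdf.values[-1] == 1.0

    def test_memorization_sanity(self, mini_model, eng_mask, eng_spec, p_mid):
        """On a training item the error sits below the mean training loss."""
        from specklesize.estimator import measure_noise_residuals
        cfg = mini_model.cfg
        residuals = measure_noise_residuals(p_mid, eng_mask, n_frames=32)
        tset = generate_training_set(900, eng_spec, cfg, seed=41,
                                     noise_residuals=residuals)
        r = tset.r_grid
        w = trapezoid_weights(r).astype(np.float32)
        errs = []
        for i in range(0, 40):
            cdf = mini_model.net.forward(tset.inputs[i:i + 1])[0]
            errs.append(float(w @ np.abs(cdf - tset.targets[i])))
        assert np.median(errs) < np.mean(mini_model.loss_trace[:1])

    def test_unfiltered_input_rejected(self, small_set):
        cfg, tset = small_set
        model = build_model(cfg, tset.mask)
        a = AutocorrMap(np.random.default_rng(0).random((64, 64)),
                        grids.LAG_U_PITCH)
        with pytest.raises(ValueError, match="not filtered"):
            predict_cdf(model, a)

    def test_geometry_mismatch_rejected(self, small_set):
        cfg, tset = small_set
        model = build_model(cfg, tset.mask)
        a = AutocorrMap(np.zeros((32, 32)), grids.LAG_U_PITCH)
        with pytest.raises(ValueError, match="does not match"):
            predict_cdf(model, a)


def test_w1_loss_alias(small_set):
    cfg, _ = small_set
    r = cfg.r_grid()
    a = SizeCDF(r, np.linspace(0, 1, r.size))
    assert w1_loss(a, a) == 0.0


def test_model_round_trip(tmp_path, small_set):
    cfg, tset = small_set
    model = build_model(cfg, tset.mask, seed=9, psd_lag=tset.psd_lag)
    pretrain(model, tset, epochs=1, seed=2)
    path = tmp_path / "model.npz"
    save_model(path, model)
    back = load_model(path)
    assert back.net.digests() == model.net.digests()
    assert back.cfg == model.cfg
    a = AutocorrMap(np.where(tset.mask.mask, 0.1, 0.0), grids.LAG_U_PITCH)
    assert np.allclose(predict_cdf(back, a).values,
                       predict_cdf(model, a).values)
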