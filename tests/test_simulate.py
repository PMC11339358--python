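"""Physical speckle simulator: packing, rendering, ensembles."""

import numpy as np
import pytest

from specklesize import grids
from specklesize.autocorr import frame_autocorrelation, center_crop
from specklesize.simulate import (NoiseSpec, render_frame, read_frame,
                                  sample_particle_field, simulate_ensemble,
                                  write_frame)
from specklesize.sizedist import sieve_psd, monodisperse_psd


class TestPacking:
    def test_deterministic_under_seed(self):
        p = monodisperse_psd(300.0)
        a = sample_particle_field(p, 7.0, 0.4, seed=7)
        b = sample_particle_field(p, 7.0, 0.4, seed=7)
        assert np.array_equal(a.centers_mm, b.centers_mm)
        assert np.array_equal(a.diameters_um, b.diameters_um)
        c = sample_particle_field(p, 7.0, 0.4, seed=8)
        assert not np.array_equal(a.centers_mm, c.centers_mm)

    def test_diameters_within_sieve_support(self):
        p = sieve_psd(106, 180)
        f = sample_particle_field(p, 6.0, 0.3, seed=1)
        assert f.diameters_um.min() >= 106 - 11  # one log-grid cell
        assert f.diameters_um.max() <= 180 + 11

    def test_no_overlaps(self):
        p = sieve_psd(250, 300)
        f = sample_particle_field(p, 6.0, 0.45, seed=2)
        xy = f.centers_mm
        r = f.diameters_um * 1e-3 / 2
        d2 = ((xy[:, None, :] - xy[None, :, :]) ** 2).sum(-1)
        lim = (r[:, None] + r[None, :]) ** 2
        np.fill_diagonal(d2, np.inf)
        assert np.all(d2 >= lim * (1 - 1e-12))

    def test_reaches_target_coverage(self):
        p = sieve_psd(250, 300)
        f = sample_particle_field(p, 7.0, 0.45, seed=3)
        assert f.coverage == pytest.approx(0.45, abs=0.01)
        assert not f.coverage_shortfall

    def test_unreachable_coverage_warns(self):
        # ~1200 disks needed but only 500 trial insertions allowed
        p = sieve_psd(106, 180)
        with pytest.warns(UserWarning, match="RSA placed"):
            f = sample_particle_field(p, 6.0, 0.54, seed=4, max_attempts=500)
        assert f.coverage_shortfall
        assert f.coverage < 0.54

    def test_empirical_diameter_law_matches_target(self):
        """KS distance of ~5000 packed diameters against the drawing CDF."""
        p = sieve_psd(106, 180)
        diams = np.concatenate([
            sample_particle_field(p, 13.0, 0.45, seed=s).diameters_um
            for s in (10, 11)])
        assert diams.size >= 5000
        cdf = p.cdf()
        xs = np.sort(diams)
        emp = np.arange(1, xs.size + 1) / xs.size
        theo = np.interp(xs, cdf.r_grid, cdf.values)
        # packing slightly favors small disks at high coverage; 0.03 bound
        assert np.abs(emp - theo).max() < 0.03

    def test_coverage_bounds_validated(self):
        with pytest.raises(ValueError):
            sample_particle_field(sieve_psd(250, 300), 6.0, 0.7, seed=0)


class TestRenderFrame:
    def test_speckle_contrast_near_unity(self, eng_mask, p_mid):
        f = sample_particle_field(p_mid, 7.0, 0.45, seed=5)
        fr = render_frame(f, eng_mask, grid_size=512)
        assert fr.intensity.min() >= 0
        assert np.isfinite(fr.intensity).all()
        assert 0.8 <= fr.contrast() <= 1.2

    def test_sampling_criterion_enforced(self, eng_mask):
        p = sieve_psd(106, 180)
        f = sample_particle_field(p, 6.0, 0.3, seed=6)
        with pytest.raises(ValueError, match="grid_size >="):
            render_frame(f, eng_mask, grid_size=512)  # 24 um/px too coarse

    def test_energy_tracks_pupil_open_area(self, eng_mask, clear_mask, p_mid):
        """Parseval: total image energy scales with the pupil's open area."""
        f = sample_particle_field(p_mid, 7.0, 0.45, seed=7)
        e_eng = render_frame(f, eng_mask, grid_size=512, seed=1).intensity.sum()
        e_clear = render_frame(f, clear_mask, grid_size=512, seed=1).intensity.sum()
        ratio = e_eng / e_clear
        expected = eng_mask.open_area_fraction() / clear_mask.open_area_fraction()
        assert ratio == pytest.approx(expected, rel=0.12)

    def test_engineered_texture_is_anisotropic(self, eng_mask, clear_mask, p_mid):
        """The engineered pupil elongates speckle grains (x/y asymmetry)."""

        def anisotropy(mask):
            maps = [center_crop(frame_autocorrelation(fr), 16).values
                    for fr in simulate_ensemble(p_mid, mask, n_frames=8,
                                                seed=21, grid_size=512)]
            a = np.mean(maps, axis=0)
            c = 8
            x_width = a[c, c - 3:c + 4].sum()
            y_width = a[c - 3:c + 4, c].sum()
            return abs(x_width - y_width) / (x_width + y_width)

        assert anisotropy(eng_mask) > anisotropy(clear_mask) + 0.02

    def test_shot_noise_and_quantization(self, eng_mask, p_mid):
        f = sample_particle_field(p_mid, 7.0, 0.45, seed=8)
        clean = render_frame(f, eng_mask, grid_size=512, seed=2)
        noisy = render_frame(f, eng_mask, grid_size=512, seed=2,
                             noise=NoiseSpec(photons_per_pixel=50.0,
                                             read_noise=0.05,
                                             quantize_16bit=True))
        assert noisy.intensity.min() >= 0
        assert not np.array_equal(noisy.intensity, clean.intensity)
        # mean level roughly preserved by the photon scaling
        assert noisy.intensity.mean() == pytest.approx(clean.intensity.mean(),
                                                       rel=0.05)


class TestEnsemble:
    def test_frames_reproducible_and_distinct(self, eng_mask, p_mid):
        a = list(simulate_ensemble(p_mid, eng_mask, n_frames=2, seed=9,
                                   grid_size=512))
        b = list(simulate_ensemble(p_mid, eng_mask, n_frames=2, seed=9,
                                   grid_size=512))
        assert np.array_equal(a[0].intensity, b[0].intensity)
        assert np.array_equal(a[1].intensity, b[1].intensity)
        assert not np.array_equal(a[0].intensity, a[1].intensity)

    def test_seed_streams_statistically_consistent(self, eng_mask, p_mid,
                                                   eng_spec):
        """Disjoint seeds give indistinguishable sidelobe estimates."""
        from scipy import stats

        def sidelobe_samples(seed):
            vals = []
            for fr in simulate_ensemble(p_mid, eng_mask, n_frames=12,
                                        seed=seed, grid_size=512):
                a = center_crop(frame_autocorrelation(fr), grids.LAG_N)
                vals.append(a.values[32, 32 + 9])  # first-order x sidelobe
            return np.array(vals)

        s1 = sidelobe_samples(100)
        s2 = sidelobe_samples(200)
        assert stats.ks_2samp(s1, s2).pvalue > 0.01

    def test_frame_count_validated(self, eng_mask, p_mid):
        with pytest.raises(ValueError):
            list(simulate_ensemble(p_mid, eng_mask, n_frames=0, seed=0))


def test_png_frame_read(tmp_path, eng_mask, p_mid):
    """16-bit PNG frames load through the same path as TIFF."""
    import imageio.v3 as iio
    import json
    f = sample_particle_field(p_mid, 7.0, 0.45, seed=13)
    fr = render_frame(f, eng_mask, grid_size=512)
    img = np.round(fr.intensity / fr.intensity.max() * 65535).astype(np.uint16)
    path = tmp_path / "frame.png"
    iio.imwrite(path, img)
    meta = {"u_pitch_per_mm": fr.u_pitch_per_mm,
            "pixel_pitch_um_powder": fr.pixel_pitch_um_powder,
            "peak_intensity": float(fr.intensity.max()), "seed": 13}
    (tmp_path / "frame.png.json").write_text(json.dumps(meta))
    back = read_frame(path)
    assert back.intensity.shape == fr.intensity.shape
    assert np.abs(back.intensity - fr.intensity).max() <= fr.intensity.max() / 65000


def test_frame_io_round_trip(tmp_path, eng_mask, p_mid):
    f = sample_particle_field(p_mid, 7.0, 0.45, seed=12)
    fr = render_frame(f, eng_mask, grid_size=512)
    path = tmp_path / "frame.tif"
    write_frame(path, fr, pupil_hash="abc123", timestamp_s=4.0)
    back = read_frame(path)
    assert back.u_pitch_per_mm == pytest.approx(fr.u_pitch_per_mm)
    # 16-bit quantization bounds the round-trip error
    assert np.abs(back.intensity - fr.intensity).max() <= fr.intensity.max() / 65000
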