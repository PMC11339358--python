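"""Pupil construction, power spectra and lobe-energy analysis."""

import numpy as np
import pytest
import yaml
from hypothesis import given, settings, strategies as st

from specklesize import grids
from specklesize.pupil import (EFFECTIVE_THRESHOLD, effective_region_mask,
                               engineered_geometry, engineered_pupil,
                               load_geometry, lobe_energy_report,
                               make_clear_pupil, make_engineered_pupil,
                               pupil_power_spectrum, save_geometry)


# ---------------------------------------------------------------- masks ---

def test_clear_disk_open_area_matches_analytic():
    # pitch <= d/100 resolves the rim to better than 1%
    mask = make_clear_pupil(5.0, 0.05, 256)
    assert mask.open_area_mm2() == pytest.approx(np.pi * 2.5**2, rel=0.01)


def test_clear_disk_grid_fraction():
    mask = make_clear_pupil(5.0, 0.025, 512)
    frac = mask.transmission.sum() / 512**2
    assert frac == pytest.approx(np.pi * 2.5**2 / 12.8**2, rel=0.01)


def test_empty_aperture_rejected():
    with pytest.raises(ValueError, match="empty aperture"):
        make_clear_pupil(0.0, 0.025, 512)


def test_undersized_grid_names_requirement():
    with pytest.raises(ValueError, match="grid_size >="):
        make_clear_pupil(5.0, 0.025, 128)


def test_empty_geometry_falls_back_to_clear_disk():
    a = make_engineered_pupil([], 0.024, 512, 5.0)
    b = make_clear_pupil(5.0, 0.024, 512)
    assert np.array_equal(a.transmission, b.transmission)


def test_last_wins_composition():
    block = dict(shape="rect", cx_mm=0, cy_mm=0, w_mm=2, h_mm=2, transmission=0)
    reopen = dict(shape="disk", cx_mm=0, cy_mm=0, diameter_mm=1, transmission=1)
    m = make_engineered_pupil([block, reopen], 0.024, 512, 5.0)
    c = 256
    assert m.transmission[c, c] == 1.0          # reopened by the later disk
    assert m.transmission[c, c + 35] == 0.0     # still blocked at 0.84 mm


def test_out_of_aperture_primitive_warns():
    prim = dict(shape="disk", cx_mm=4.0, cy_mm=0, diameter_mm=0.5, transmission=0)
    with pytest.warns(UserWarning, match="outside the aperture"):
        make_engineered_pupil([prim], 0.024, 512, 5.0)


def test_engineered_fixture_keeps_one_third_of_photons(eng_mask):
    assert eng_mask.open_area_fraction() == pytest.approx(1 / 3, abs=0.03)


def test_geometry_yaml_round_trip(tmp_path):
    d, prims = engineered_geometry()
    path = tmp_path / "mask.yaml"
    save_geometry(path, d, prims)
    d2, prims2 = load_geometry(path)
    assert d2 == d and prims2 == prims
    m1 = make_engineered_pupil(prims, 0.048, 256, d)
    m2 = make_engineered_pupil(prims2, 0.048, 256, d2)
    assert np.array_equal(m1.transmission, m2.transmission)


# ------------------------------------------------------------- spectrum ---

def test_parseval_identities(clear_mask, clear_spec):
    # total PSD energy equals the integral of |m|^4 (= open area, binary mask)
    energy = clear_spec.total_energy
    m4 = float((clear_mask.transmission**2).sum() * clear_mask.pitch_mm**2)
    assert energy == pytest.approx(m4, rel=1e-9)
    # the DC peak equals (open area)^2
    assert clear_spec.peak_value == pytest.approx(clear_mask.open_area_mm2()**2,
                                                  rel=1e-9)


def test_opaque_pupil_rejected():
    mask = make_clear_pupil(5.0, 0.024, 512)
    mask.transmission[:] = 0.0
    with pytest.raises(ValueError, match="opaque"):
        pupil_power_spectrum(mask)


def test_pad_factor_must_give_resolution():
    mask = make_clear_pupil(5.0, 0.024, 512)
    with pytest.raises(ValueError):
        pupil_power_spectrum(mask, pad_factor=1)


def test_clear_psd_first_null_at_airy_radius(clear_spec):
    prof = clear_spec.normalized()[clear_spec.center, clear_spec.center:]
    falling = np.flatnonzero(np.diff(prof) > 0)
    first_null_u = falling[0] * clear_spec.u_pitch_per_mm
    assert abs(first_null_u - 1.22 / 5.0) <= clear_spec.u_pitch_per_mm


def test_rotated_mask_same_psd():
    d, prims = engineered_geometry()
    m = make_engineered_pupil(prims, 0.048, 256, d)
    rot = [dict(p, cx_mm=-p["cx_mm"], cy_mm=-p["cy_mm"]) for p in prims]
    m2 = make_engineered_pupil(rot, 0.048, 256, d)
    s1 = pupil_power_spectrum(m, pad_factor=2).psd
    s2 = pupil_power_spectrum(m2, pad_factor=2).psd
    assert np.allclose(s1, s2, rtol=1e-7, atol=s1.max() * 1e-10)


@settings(deadline=None, max_examples=10, derandomize=True)
@given(st.integers(0, 10_000))
def test_psd_nonnegative_and_centrosymmetric_for_random_geometry(seed):
    rng = np.random.default_rng(seed)
    prims = []
    for _ in range(rng.integers(1, 5)):
        kind = rng.choice(["rect", "disk", "annular_sector"])
        if kind == "rect":
            prims.append(dict(shape="rect", cx_mm=float(rng.uniform(-1.5, 1.5)),
                              cy_mm=float(rng.uniform(-1.5, 1.5)),
                              w_mm=float(rng.uniform(0.3, 2)),
                              h_mm=float(rng.uniform(0.3, 2)),
                              transmission=float(rng.integers(0, 2))))
        elif kind == "disk":
            prims.append(dict(shape="disk", cx_mm=float(rng.uniform(-1.5, 1.5)),
                              cy_mm=float(rng.uniform(-1.5, 1.5)),
                              diameter_mm=float(rng.uniform(0.3, 2)),
                              transmission=float(rng.integers(0, 2))))
        else:
            t0 = float(rng.uniform(0, 360))
            prims.append(dict(shape="annular_sector", cx_mm=0.0, cy_mm=0.0,
                              r_in_mm=float(rng.uniform(0.2, 1.0)),
                              r_out_mm=float(rng.uniform(1.2, 2.4)),
                              theta0_deg=t0, theta1_deg=t0 + float(rng.uniform(30, 300)),
                              transmission=0.0))
    mask = make_engineered_pupil(prims, 0.048, 256, 5.0)
    if mask.transmission.sum() == 0:
        return
    spec = pupil_power_spectrum(mask, pad_factor=2)
    psd = spec.psd
    assert psd.min() >= 0
    # centrosymmetry |M(u)|^2 = |M(-u)|^2 (real transmission)
    flipped = psd[1:, 1:][::-1, ::-1]
    assert np.allclose(psd[1:, 1:], flipped, rtol=1e-6, atol=psd.max() * 1e-9)


def test_energy_fractions_stable_under_padding():
    d, prims = engineered_geometry()
    mask = make_engineered_pupil(prims, 0.048, 256, d)
    reps = [lobe_energy_report(pupil_power_spectrum(mask, pad_factor=pf))
            for pf in (2, 4)]
    assert abs(reps[0].main_lobe_fraction - reps[1].main_lobe_fraction) < 0.005
    assert abs(reps[0].effective_sidelobe_fraction
               - reps[1].effective_sidelobe_fraction) < 0.005


# ------------------------------------------------------ lobes and filter ---

def test_lobe_report_fractions_are_a_partition(eng_spec):
    rep = lobe_energy_report(eng_spec)
    assert rep.main_lobe_fraction + rep.sidelobe_fraction == pytest.approx(1.0)
    assert 0 <= rep.effective_sidelobe_fraction <= rep.sidelobe_fraction


def test_threshold_one_leaves_no_effective_sidelobes(eng_spec):
    rep = lobe_energy_report(eng_spec, threshold=1.0)
    assert rep.effective_sidelobe_fraction == 0.0


def test_threshold_bounds(eng_spec):
    with pytest.raises(ValueError):
        lobe_energy_report(eng_spec, threshold=0.0)
    with pytest.raises(ValueError):
        effective_region_mask(eng_spec, threshold=1.5)


def test_effective_mask_tiny_threshold_covers_positive_pixels(eng_spec):
    m = effective_region_mask(eng_spec, threshold=1e-12)
    norm = eng_spec.normalized()
    assert np.array_equal(m.mask, norm > 1e-12)


def test_effective_mask_centrosymmetric_on_lag_grid(eng_spec):
    m = effective_region_mask(eng_spec, n_lag=grids.LAG_N,
                              u_pitch_per_mm=grids.LAG_U_PITCH).mask
    # excluding the row/col without a mirror partner on an even grid
    assert np.array_equal(m[1:, 1:], m[1:, 1:][::-1, ::-1])


def test_effective_mask_records_threshold(eng_spec):
    m = effective_region_mask(eng_spec)
    assert m.threshold == EFFECTIVE_THRESHOLD


def test_engineered_psd_has_eight_strong_sidelobes(eng_spec):
    """Eight sidelobe islands above threshold, x/y peak radii different."""
    from scipy import ndimage
    rep = lobe_energy_report(eng_spec)
    norm = eng_spec.normalized()
    strong = (norm > EFFECTIVE_THRESHOLD) & ~rep.main_lobe_pixel_set
    labels, n = ndimage.label(strong)
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, np.arange(1, n + 1))
    assert (sizes >= 4).sum() >= 8
    c = eng_spec.center
    x_prof = norm[c, c:]
    y_prof = norm[c:, c]
    # first significant sidelobe peak radius differs between axes
    def first_peak(prof):
        from scipy.signal import find_peaks
        pk, _ = find_peaks(prof, prominence=0.02)
        return pk[0]
    assert first_peak(x_prof) != first_peak(y_prof)
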