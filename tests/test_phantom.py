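"""Phantom module: paradigm boxcar, wave physics, and the encoded acquisition."""
import dataclasses

import numpy as np
import pytest

import elastofun as ef
from elastofun.phantom import (
    PlaneWaveSource,
    build_paradigm_regressor,
    draw_sources,
    encode_acquisition,
    simulate_wavefield,
)
from elastofun.recon import decode_hadamard


@pytest.mark.parametrize(
    "paradigm_kwargs, dt, length, n_on",
    [
        ({}, 1.0, 384, 192),  # default design: 384 s, half ON
        ({"n_blocks": 2, "block_s": 24.0}, 12.0, 4, 2),
        ({}, 12.0, 32, 16),  # one sample per elastogram bin
    ],
)
def test_paradigm_boxcar(paradigm_kwargs, dt, length, n_on):
    par = ef.ParadigmSpec(**paradigm_kwargs)
    box = build_paradigm_regressor(par, dt)
    assert box.size == length
    assert box.sum() == n_on
    assert set(np.unique(box)) <= {0.0, 1.0}


def test_paradigm_boxcar_off_first():
    box = build_paradigm_regressor(ef.ParadigmSpec(n_blocks=2, block_s=24.0), 12.0)
    assert box.tolist() == [0, 0, 1, 1]


def test_paradigm_non_divisible_dt_errors():
    with pytest.raises(ValueError, match="7.0.*24"):
        build_paradigm_regressor(ef.ParadigmSpec(), 7.0)


def test_spec_invariants():
    with pytest.raises(ValueError, match="n_offsets"):
        ef.AcquisitionSpec(n_offsets=2)
    with pytest.raises(ValueError, match="integer multiple"):
        ef.AcquisitionSpec(tr_s=1.0, bin_s=12.5)
    with pytest.raises(ValueError, match="f_vib_hz"):
        ef.AcquisitionSpec(f_vib_hz=0.0)
    assert ef.AcquisitionSpec().period_s == pytest.approx(1 / 60)


def test_roi_must_be_interior(small_acq):
    bad = np.ones(small_acq.shape, dtype=bool)
    ph = ef.PhantomSpec(roi_mask=bad, seed=1)
    with pytest.raises(ValueError, match="strictly inside"):
        ph.resolve_roi(small_acq)


def test_wavefield_dispersion_relation():
    """A single plane wave in a homogeneous medium has |grad phase| = omega*sqrt(rho/mu)."""
    acq = ef.AcquisitionSpec(matrix_xy=32, n_slices=8, voxel_size_mm=1.0)
    ph = ef.PhantomSpec(mu_background_kpa=4.0, seed=1)
    src = [PlaneWaveSource(np.array([1.0, 0, 0]), np.array([0, 0, 1.0]), 0.0, 1.0)]
    u = simulate_wavefield(ph, acq, np.full(acq.shape, 4.0), sources=src)
    # phase advance per voxel along x
    dphi = np.angle(u[1:, 0, 0, 2] / u[:-1, 0, 0, 2])
    k = np.median(dphi) / acq.voxel_size_mm  # rad/mm
    lam_mm = 2 * np.pi / k
    c = np.sqrt(4000.0 / 1000.0)  # m/s
    assert lam_mm == pytest.approx(c / 60.0 * 1000.0, rel=1e-6)  # 33.33 mm
    assert lam_mm == pytest.approx(33.33, abs=0.01)


def test_wavefield_rejects_nonpositive_mu(small_acq):
    ph = ef.PhantomSpec(seed=1)
    mu = np.full(small_acq.shape, 3.0)
    mu[0, 0, 0] = 0.0
    with pytest.raises(ValueError, match="positive"):
        simulate_wavefield(ph, small_acq, mu)


def test_transverse_wave_is_divergence_free():
    """Axis-aligned transverse wave: discrete divergence vanishes to machine
    precision while the curl does not; oblique waves converge as h^2."""
    ph = ef.PhantomSpec(seed=3)

    def div_curl_ratio(voxel_mm, direction, pol, n=24):
        acq = ef.AcquisitionSpec(matrix_xy=n, n_slices=n, voxel_size_mm=voxel_mm)
        src = [PlaneWaveSource(direction, pol, 0.1, 1.0)]
        u = simulate_wavefield(ph, acq, np.full(acq.shape, 3.0), sources=src)
        h = acq.voxel_size_mm
        div = sum(np.gradient(u[..., i], h, axis=i) for i in range(3))
        c, _ = ef.curl(u, h)
        sl = (slice(2, -2),) * 3
        return np.abs(div[sl]).max() / np.abs(c[sl]).max()

    assert div_curl_ratio(2.0, np.array([1.0, 0, 0]), np.array([0, 1.0, 0])) < 1e-6

    d = np.array([0.8, 0.5, 0.2])
    d /= np.linalg.norm(d)
    p = np.cross(d, [0.0, 0.0, 1.0])
    p /= np.linalg.norm(p)
    coarse = div_curl_ratio(2.0, d, p)
    fine = div_curl_ratio(1.0, d, p, n=48)
    assert coarse > 1e-6  # finite-difference anisotropy is visible when oblique
    assert fine < coarse / 3  # ~second-order convergence


def test_encode_requires_seed(small_acq, short_paradigm):
    ph = ef.PhantomSpec(seed=None)
    with pytest.raises(ValueError, match="seed"):
        encode_acquisition(ph, small_acq, short_paradigm)


def test_encode_is_deterministic(small_acq, short_paradigm):
    ph = ef.PhantomSpec(seed=9)
    s1, _ = encode_acquisition(ph, small_acq, short_paradigm)
    s2, _ = encode_acquisition(ph, small_acq, short_paradigm)
    assert np.array_equal(s1.data, s2.data)


def test_encode_decode_roundtrip(quiet_phantom, short_paradigm):
    """Noiseless, zero-effect: Hadamard decode recovers the simulated
    displacement exactly (H+ H = I) and all bins are identical."""
    acq = ef.AcquisitionSpec(matrix_xy=20, n_slices=6)
    series, _ = encode_acquisition(quiet_phantom, acq, short_paradigm)
    disp = decode_hadamard(series) / acq.encoding_rad_per_um  # um
    src = draw_sources(
        quiet_phantom.n_sources, np.random.default_rng(quiet_phantom.seed), quiet_phantom.amp_um
    )
    u = simulate_wavefield(quiet_phantom, acq, np.full(acq.shape, 3.0), sources=src)
    assert np.abs(disp[..., 0, 0] - u.real).max() < 1e-12
    assert np.abs(disp[..., 0] - disp[..., -1]).max() < 1e-12  # bins identical


def test_default_paradigm_frame_count(quiet_phantom):
    """16 blocks x 24 s at TR = 1 s yield 384 magnitude frames (32 bins)."""
    acq = ef.AcquisitionSpec(matrix_xy=16, n_slices=6)
    series, _ = encode_acquisition(quiet_phantom, acq, ef.ParadigmSpec())
    assert series.n_bins == 32
    assert series.n_frames == 384
    assert series.magnitude_frames().shape == (16, 16, 6, 384)


def test_magnitude_frames_carry_the_bold_time_course(short_paradigm):
    """ROI magnitude follows 1 + bold_frac * h(t) frame by frame (ordering check)."""
    acq = ef.AcquisitionSpec(matrix_xy=16, n_slices=6)
    ph = ef.PhantomSpec(seed=4, noise_sd=0.0, delta_mu_frac_at_100=0.0)
    series, truth = encode_acquisition(ph, acq, short_paradigm)
    mags = series.magnitude_frames()
    roi = truth.active_mask
    course = mags[roi].mean(axis=0) / 100.0 - 1.0
    assert np.allclose(course, truth.bold_frac_t, atol=1e-10)
    assert truth.bold_frac_t.max() > 0


def test_ground_truth_structure(short_paradigm):
    acq = ef.AcquisitionSpec(matrix_xy=16, n_slices=6)
    ph = ef.PhantomSpec(seed=4, noise_sd=0.0)
    _, truth = encode_acquisition(ph, acq, short_paradigm)
    outside = ~truth.active_mask
    assert np.all(truth.mu_map_t[outside] == ph.mu_background_kpa)
    assert np.all(truth.mu_map_t[truth.active_mask] >= ph.mu_background_kpa)
    assert truth.delta_mu_peak_kpa > 0
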