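"""Reconstruction operators: decode, unwrap, high-pass, curl, harmonic, smoothing."""
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import elastofun as ef
from elastofun.phantom import PlaneWaveSource, encode_acquisition, simulate_wavefield
from elastofun.recon import (
    HADAMARD4,
    decode_hadamard,
    quartic_kernel,
    reconstruct_wavefield,
    unwrap_phase,
)


class TestDecode:
    def test_zero_phases_decode_to_zero(self, small_acq, short_paradigm, quiet_phantom):
        import dataclasses

        ph = dataclasses.replace(quiet_phantom, amp_um=0.0)
        series, _ = encode_acquisition(ph, small_acq, short_paradigm)
        assert np.abs(decode_hadamard(series)).max() < 1e-12

    def test_non_tetrahedral_scheme_rejected(self, short_paradigm):
        acq = ef.AcquisitionSpec(matrix_xy=8, n_slices=6, n_meg=3, tr_s=1.0, bin_s=9.0)
        par = ef.ParadigmSpec(n_blocks=2, block_s=18.0)
        data = np.zeros(acq.shape + (3, 3, 4), dtype=complex)
        series = ef.ComplexSeries(data=data, spec=acq, paradigm=par)
        with pytest.raises(ValueError, match="unsupported"):
            decode_hadamard(series)

    def test_decoded_noise_variance(self, rng):
        """Phase noise sigma^2 per MEG maps to sigma^2/4 per displacement
        component (3/4 sigma^2 total = trace of H+ H+^T)."""
        sigma = 0.05
        noise = rng.normal(0, sigma, size=(200_000, 4))
        decoded = noise @ np.linalg.pinv(HADAMARD4).T
        per_comp = decoded.var(axis=0)
        assert per_comp == pytest.approx([sigma**2 / 4] * 3, rel=0.02)
        assert per_comp.sum() == pytest.approx(0.75 * sigma**2, rel=0.02)


class TestUnwrap:
    def test_wrap_free_volume_unchanged(self, rng):
        vol = 0.3 * rng.standard_normal((8, 8, 4))
        out = unwrap_phase(vol)
        assert np.array_equal(out, vol)

    def test_wrapped_ramp_restored(self):
        x = np.linspace(0, 4 * np.pi, 32)
        ramp = np.broadcast_to(x[:, None, None], (32, 8, 4)).copy()
        wrapped = np.angle(np.exp(1j * ramp))
        out = unwrap_phase(wrapped)
        resid = out - ramp
        # congruent mod 2*pi and equal up to one global 2*pi*k offset
        assert np.allclose(resid - resid.flat[0], 0.0, atol=1e-9)
        assert np.allclose((out - wrapped) % (2 * np.pi), 0.0, atol=1e-9) or np.allclose(
            (wrapped - out) % (2 * np.pi), 0.0, atol=1e-9
        )

    def test_unwrapping_rescues_high_amplitude_inversion(self):
        """At 3x the default encoding the phase wraps; only the unwrapped
        reconstruction recovers the true stiffness."""
        acq = ef.AcquisitionSpec(matrix_xy=32, n_slices=10, encoding_rad_per_um=0.3)
        par = ef.ParadigmSpec(n_blocks=2, block_s=24.0)
        ph = ef.PhantomSpec(
            seed=5, noise_sd=0.0, delta_mu_frac_at_100=0.0, bold_frac_at_100=0.0
        )
        series, _ = encode_acquisition(ph, acq, par)
        err = {}
        for unwrap in (True, False):
            wf, rim = reconstruct_wavefield(series, unwrap=unwrap)
            el = ef.elastogram_series(wf, ph.rho_kg_m3, acq.voxel_size_mm, rim_mask=rim)
            med = np.nanmedian(el.mu[..., 0])
            err[unwrap] = abs(med - 3.0) / 3.0
        assert err[True] < 0.05
        assert err[False] > 0.05


class TestHighpass:
    def test_constant_slice_removed_exactly(self):
        vol = np.full((16, 16, 4), 7.5)
        out = ef.highpass_inplane(vol, 3.5)
        assert np.abs(out).max() == 0.0

    def test_shear_wave_preserved(self):
        """An in-plane wave near the background shear wavelength (well above
        the cutoff wavenumber) passes within 2% of its amplitude."""
        voxel = 3.5
        lam = 8 * voxel  # 28 mm, commensurate with the 64-voxel slice
        k = 2 * np.pi / lam
        x = np.arange(64) * voxel
        vol = np.broadcast_to(np.cos(k * x)[:, None, None], (64, 64, 4)).copy()
        out = ef.highpass_inplane(vol, voxel)
        # keep clear of the ~4 sigma boundary apron; compare the transmitted
        # oscillation amplitude (a per-slice constant offset carries no wave
        # energy and is annihilated by the curl downstream)
        core = out[27:-27, 27:-27, :]
        ref = vol[27:-27, 27:-27, :]
        core = core - core.mean(axis=(0, 1))
        ref = ref - ref.mean(axis=(0, 1))
        assert np.abs(core - ref).max() < 0.02

    def test_offset_invariance(self, rng):
        vol = rng.standard_normal((20, 20, 3))
        out1 = ef.highpass_inplane(vol, 3.5)
        out2 = ef.highpass_inplane(vol + 42.0, 3.5)
        assert np.allclose(out1, out2, atol=1e-9)


class TestCurl:
    def test_gradient_field_is_irrotational(self):
        x, y, z = np.meshgrid(
            np.arange(16.0), np.arange(16.0), np.arange(8.0), indexing="ij"
        )
        phi = np.sin(0.3 * x) * np.cos(0.2 * y) + 0.1 * z**2
        h = 1.0
        grad = np.stack(np.gradient(phi, h), axis=3)
        c, interior = ef.curl(grad, h)
        scale = np.abs(grad).max()
        assert np.abs(c[interior]).max() / scale < 5e-3  # discretisation only
        # analytic gradient of a linear-quadratic field -> exact zero curl
        phi_lin = 0.7 * x + 0.2 * y - 0.1 * z
        grad_lin = np.stack(np.gradient(phi_lin, h), axis=3)
        c_lin, _ = ef.curl(grad_lin, h)
        assert np.abs(c_lin[interior]).max() < 1e-12

    def test_analytic_plane_shear_curl(self):
        k = 0.25
        x = np.arange(40.0)
        u = np.zeros((40, 8, 8, 3))
        u[..., 2] = np.sin(k * x)[:, None, None]
        c, interior = ef.curl(u, 1.0)
        got = c[1:-1, 1:-1, 1:-1, 1]
        # central differences report sin(kh)/h in place of k
        exact = (-np.sin(k) * np.cos(k * x))[1:-1, None, None]
        assert np.allclose(got, exact * np.ones_like(got), atol=1e-12)
        analytic = (-k * np.cos(k * x))[1:-1, None, None]
        assert np.abs(got - analytic).max() < 0.02 * k
        assert np.abs(c[1:-1, 1:-1, 1:-1, 0]).max() < 1e-12
        assert np.abs(c[1:-1, 1:-1, 1:-1, 2]).max() < 1e-12

    def test_linearity(self, rng):
        u = rng.standard_normal((10, 9, 8, 3))
        v = rng.standard_normal((10, 9, 8, 3))
        a, b = 2.3, -0.7
        c1, _ = ef.curl(a * u + b * v, 2.0)
        c2, _ = ef.curl(u, 2.0)
        c3, _ = ef.curl(v, 2.0)
        assert np.allclose(c1, a * c2 + b * c3, atol=1e-10)

    def test_too_small_axis_errors(self):
        with pytest.raises(ValueError, match=">= 3"):
            ef.curl(np.zeros((2, 8, 8, 3)), 1.0)


class TestFirstHarmonic:
    def test_pure_cosine_amplitude_and_phase(self):
        t = 2 * np.pi * np.arange(3) / 3
        for amp, phase in [(2.0, 0.0), (1.0, 0.7), (0.5, -2.0)]:
            x = amp * np.cos(t + phase)
            c = ef.first_harmonic(x, axis=0)
            assert np.abs(c) == pytest.approx(amp, abs=1e-12)
            assert np.angle(c) == pytest.approx(phase, abs=1e-12)

    def test_dc_rejected(self):
        t = 2 * np.pi * np.arange(3) / 3
        assert np.abs(ef.first_harmonic(np.full(3, 5.0), axis=0)) < 1e-12
        x = np.cos(t) + 0.5
        assert np.abs(ef.first_harmonic(x, axis=0)) == pytest.approx(1.0, abs=1e-12)

    def test_uneven_offsets_rejected(self):
        with pytest.raises(ValueError, match="evenly spaced"):
            ef.first_harmonic(np.zeros(3), axis=0, sample_phases=np.array([0.0, 1.0, 4.0]))

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_linearity(self, seed):
        r = np.random.default_rng(seed)
        x, y = r.standard_normal((2, 4, 5, 3))
        a, b = r.standard_normal(2)
        lhs = ef.first_harmonic(a * x + b * y, axis=-1)
        rhs = a * ef.first_harmonic(x, axis=-1) + b * ef.first_harmonic(y, axis=-1)
        assert np.allclose(lhs, rhs, atol=1e-12)


class TestSmoothQuartic:
    def test_kernel_normalised(self):
        k = quartic_kernel((7, 7, 5))
        assert k.shape == (7, 7, 5)
        assert k.sum() == pytest.approx(1.0, abs=1e-12)
        assert k.max() == k[3, 3, 2]

    def test_constant_field_unchanged(self):
        vol = np.full((12, 12, 8), 3.3)
        out = ef.smooth_quartic(vol)
        assert np.allclose(out, vol, rtol=1e-6)

    def test_impulse_reproduces_kernel(self):
        vol = np.zeros((13, 13, 9))
        vol[6, 6, 4] = 1.0
        out = ef.smooth_quartic(vol)
        assert np.allclose(out[3:10, 3:10, 2:7], quartic_kernel((7, 7, 5)), atol=1e-9)
        assert out.sum() == pytest.approx(1.0, abs=1e-6)

    def test_noise_variance_reduced(self, rng):
        vol = rng.standard_normal((24, 24, 10))
        out = ef.smooth_quartic(vol)
        assert out.var() < 0.2 * vol.var()

    def test_volume_smaller_than_kernel_errors(self):
        with pytest.raises(ValueError, match="pad"):
            ef.smooth_quartic(np.zeros((6, 6, 4)))


def test_full_chain_reproduces_simulated_curl(quiet_phantom):
    """Noiseless chain output equals the simulated displacement passed through
    the same linear filters (high-pass, curl, smoothing) — an oracle for the
    encode/decode/first-harmonic core, which must be exactly transparent."""
    acq = ef.AcquisitionSpec(matrix_xy=32, n_slices=10)
    par = ef.ParadigmSpec(n_blocks=2, block_s=24.0)
    series, _ = encode_acquisition(quiet_phantom, acq, par)
    wf, interior = reconstruct_wavefield(series)

    from elastofun.phantom import draw_sources

    src = draw_sources(
        quiet_phantom.n_sources, np.random.default_rng(quiet_phantom.seed), quiet_phantom.amp_um
    )
    u = simulate_wavefield(quiet_phantom, acq, np.full(acq.shape, 3.0), sources=src)
    u = ef.highpass_inplane(u, acq.voxel_size_mm)
    c_true, _ = ef.curl(u, acq.voxel_size_mm)
    c_true = ef.smooth_quartic(c_true)
    got = wf.curl[..., 0][interior]
    want = c_true[interior]
    rel = np.linalg.norm(got - want) / np.linalg.norm(want)
    assert rel < 1e-9
    assert np.all(np.isfinite(wf.curl))
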