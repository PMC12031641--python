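"""Digital phantom: synthetic complex-valued concurrent fMRI-fMRE acquisitions.

The phantom emulates a visual-stimulation experiment with a known ground
truth. A "visual cortex" ROI carries a stimulus-locked stiffness increase
that follows the block paradigm convolved with a slow stiffness response
kernel (double gamma peaking at 8 s with a long undershoot), and a BOLD-like
magnitude increase following the canonical hemodynamic response. Both effects
scale with stimulus contrast through an affine contrast-response curve.

The shear wave field is a superposition of transverse plane waves whose local
wavenumber obeys the dispersion relation k(x) = omega * sqrt(rho / mu(x)).
Phase is accumulated as a straight-ray path integral of k, so the field stays
continuous across stiffness interfaces and the local phase gradient matches
the local wavenumber - exactly the regime the direct Helmholtz inversion
assumes.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.ndimage import map_coordinates

from .specs import AcquisitionSpec, ParadigmSpec
from .recon import HADAMARD4, ComplexSeries

#: Baseline magnitude of the complex signal (arbitrary units).
BASELINE_MAGNITUDE = 100.0


def default_roi_mask(acq: AcquisitionSpec) -> np.ndarray:
    """Default activation ROI: a posterior block standing in for V1.

    In-plane extent matrix/4 (centred in x, posterior in y), spanning all
    slices except the outermost two (strictly inside the slab). Large enough
    that the 7x7x5 smoothing support leaves a partial-volume-free core.
    """
    nx, ny, nz = acq.shape
    ex = max(4, nx // 4)
    x0 = (nx - ex) // 2
    y0 = min(ny - ex - 1, (3 * ny) // 4 - ex // 2)
    y0 = max(1, y0)
    z0, z1 = 1, max(2, nz - 1)
    mask = np.zeros(acq.shape, dtype=bool)
    mask[x0 : x0 + ex, y0 : y0 + ex, z0:z1] = True
    return mask


@dataclass(frozen=True)
class PhantomSpec:
    """Ground-truth tissue and effect parameters of the digital phantom.

    Defaults emulate the study's reported group effects with a 3.0 kPa
    baseline: peak stiffness change at 100% contrast of 0.16 kPa
    (delta_mu_frac_at_100 = 0.16/3), a contrast response proportional to
    0.03 + 0.0013 * c (normalised to 1 at c = 100), and a 0.9% BOLD-like
    magnitude increase at full contrast.
    """

    mu_background_kpa: float = 3.0
    rho_kg_m3: float = 1000.0
    roi_mask: np.ndarray | None = None  # None -> default_roi_mask(acq)
    delta_mu_frac_at_100: float = 0.16 / 3.0
    contrast_slope_per_pct: float = 0.0013 / 0.16
    contrast_intercept_frac: float = 0.03 / 0.16
    bold_frac_at_100: float = 0.009
    noise_sd: float = 0.01  # relative to the mean magnitude
    n_sources: int = 4
    amp_um: float = 10.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.mu_background_kpa <= 0:
            raise ValueError("mu_background_kpa must be positive")
        if self.rho_kg_m3 <= 0:
            raise ValueError("rho_kg_m3 must be positive")
        if not (0 <= self.delta_mu_frac_at_100 < 1):
            raise ValueError("delta_mu_frac_at_100 must lie in [0, 1)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.n_sources < 1:
            raise ValueError("n_sources must be >= 1")

    def contrast_fraction(self, contrast_pct: float) -> float:
        """Fraction of the 100%-contrast effect elicited at a given contrast."""
        return self.contrast_intercept_frac + self.contrast_slope_per_pct * contrast_pct

    def resolve_roi(self, acq: AcquisitionSpec) -> np.ndarray:
        roi = self.roi_mask if self.roi_mask is not None else default_roi_mask(acq)
        roi = np.asarray(roi, dtype=bool)
        if roi.shape != acq.shape:
            raise ValueError(f"roi_mask shape {roi.shape} != acquisition shape {acq.shape}")
        boundary = roi.copy()
        boundary[1:-1, 1:-1, 1:-1] = False
        if boundary.any():
            raise ValueError("roi_mask must lie strictly inside the slab (no boundary voxels)")
        return roi


@dataclass
class GroundTruth:
    """What the phantom actually embedded, for parameter-recovery tests."""

    mu_map_t: np.ndarray  # (x, y, z, n_bins) stiffness in kPa
    bold_frac_t: np.ndarray  # (n_frames,) fractional magnitude modulation in the ROI
    active_mask: np.ndarray  # the ROI used
    delta_mu_peak_kpa: float  # peak stiffness change embedded in the ROI

    def bold_map(self, frame: int) -> np.ndarray:
        """Fractional magnitude modulation volume at one frame."""
        out = np.zeros(self.active_mask.shape)
        out[self.active_mask] = self.bold_frac_t[frame]
        return out


@dataclass(frozen=True)
class PlaneWaveSource:
    direction: np.ndarray  # unit propagation direction
    polarization: np.ndarray  # unit vector, perpendicular to direction
    phase: float
    amplitude_um: float


def draw_sources(
    n: int, rng: np.random.Generator, amp_um: float, axis_aligned: bool = False
) -> list[PlaneWaveSource]:
    """Draw random transverse plane-wave sources (isotropic directions)."""
    sources = []
    a = amp_um / math.sqrt(n)
    for i in range(n):
        if axis_aligned:
            d = np.zeros(3)
            d[i % 3] = 1.0
        else:
            d = rng.normal(size=3)
            d /= np.linalg.norm(d)
        p = rng.normal(size=3)
        p -= d * (p @ d)
        p /= np.linalg.norm(p)
        sources.append(PlaneWaveSource(d, p, float(rng.uniform(0, 2 * np.pi)), a))
    return sources


def build_paradigm_regressor(paradigm: ParadigmSpec, dt: float) -> np.ndarray:
    """Boxcar task series: 1 during ON blocks, 0 during OFF, sampled at dt."""
    per_block = paradigm.block_s / dt
    if abs(per_block - round(per_block)) > 1e-9:
        raise ValueError(
            f"dt={dt} s does not divide the block duration {paradigm.block_s} s"
        )
    per_block = int(round(per_block))
    return np.repeat(np.asarray(paradigm.block_labels, dtype=float), per_block)


def _path_integral(
    f: np.ndarray, direction: np.ndarray, voxel_size_mm: float, step_mm: float | None = None
) -> np.ndarray:
    """Straight-ray line integral of a scalar field up to each voxel.

    Approximates integral of ``f`` along ``-direction`` from outside the grid
    (where f is taken as 0) to each voxel centre, in mm units, by Riemann
    summation with trilinear sampling.
    """
    if step_mm is None:
        step_mm = voxel_size_mm / 2.0
    nx, ny, nz = f.shape
    diag_mm = voxel_size_mm * math.sqrt(nx**2 + ny**2 + nz**2)
    n_steps = int(math.ceil(diag_mm / step_mm)) + 1
    fdtype = np.float32 if np.asarray(f).dtype == np.float32 else np.float64
    idx = np.indices(f.shape, dtype=fdtype).reshape(3, -1)
    d = np.asarray(direction, dtype=fdtype)
    d = d / np.linalg.norm(d)
    step_vox = fdtype(step_mm / voxel_size_mm)
    out = np.zeros(idx.shape[1], dtype=fdtype)
    ff = np.asarray(f, dtype=fdtype)
    coords = np.empty_like(idx)
    for j in range(n_steps):
        coords[:] = idx
        coords -= (j * step_vox) * d[:, None]
        out += map_coordinates(ff, coords, order=1, mode="constant", cval=0.0)
    return (out * step_mm).reshape(f.shape)


def _wavenumber_per_mm(mu_kpa: np.ndarray | float, rho_kg_m3: float, f_hz: float) -> np.ndarray:
    """Local shear wavenumber k = omega*sqrt(rho/mu) in rad/mm."""
    mu_pa = np.asarray(mu_kpa, dtype=float) * 1000.0
    return 2.0 * np.pi * f_hz * np.sqrt(rho_kg_m3 / mu_pa) / 1000.0


def simulate_wavefield(
    phantom: PhantomSpec,
    acq: AcquisitionSpec,
    mu_map: np.ndarray,
    sources: list[PlaneWaveSource] | None = None,
    path_step_mm: float | None = None,
) -> np.ndarray:
    """Time-harmonic complex displacement field (x, y, z, 3) in um.

    Superposition of transverse plane waves at ``acq.f_vib_hz``; each wave's
    phase is the path integral of the local wavenumber along its ray, so
    |grad phase| = k(x) away from interfaces and the field is divergence-free
    by transverse polarization.
    """
    mu_map = np.asarray(mu_map, dtype=float)
    if mu_map.shape != acq.shape:
        raise ValueError(f"mu_map shape {mu_map.shape} != acquisition shape {acq.shape}")
    if np.any(mu_map <= 0):
        raise ValueError("mu_map must be positive everywhere")
    if sources is None:
        if phantom.seed is None:
            raise ValueError("PhantomSpec.seed must be set (reproducibility is mandatory)")
        rng = np.random.default_rng(phantom.seed)
        sources = draw_sources(phantom.n_sources, rng, phantom.amp_um)

    k_map = _wavenumber_per_mm(mu_map, phantom.rho_kg_m3, acq.f_vib_hz)
    k_ref = float(np.median(k_map))
    dk = k_map - k_ref
    homogeneous = bool(np.ptp(mu_map) == 0)

    coords = np.indices(acq.shape, dtype=float) * acq.voxel_size_mm  # (3,x,y,z) mm
    u = np.zeros(acq.shape + (3,), dtype=complex)
    for s in sources:
        s_coord = np.tensordot(s.direction, coords, axes=(0, 0))  # n . x, mm
        phase = k_ref * s_coord + s.phase
        if not homogeneous:
            phase = phase + _path_integral(dk, s.direction, acq.voxel_size_mm, path_step_mm)
        u += s.amplitude_um * np.exp(1j * phase)[..., None] * s.polarization
    return u


def _modulation(paradigm: ParadigmSpec, params, sample_times: np.ndarray) -> np.ndarray:
    """Paradigm convolved with a response kernel, peak-normalised, sampled at given times."""
    from .glm import hrf  # lazy: glm imports ParadigmSpec from specs, no cycle

    dt = 0.1
    if abs(paradigm.block_s / dt - round(paradigm.block_s / dt)) > 1e-9:
        dt = paradigm.block_s / 240.0
    box = build_paradigm_regressor(paradigm, dt)
    kern = hrf(params, dt)
    conv = np.convolve(box, kern)[: box.size]
    peak = conv.max()
    if peak > 0:
        conv = conv / peak
    idx = np.clip(np.round(sample_times / dt).astype(int), 0, conv.size - 1)
    return conv[idx]


def precompute_geometry(
    phantom: PhantomSpec,
    acq: AcquisitionSpec,
    roi: np.ndarray,
    sources: list[PlaneWaveSource],
    path_step_mm: float | None = None,
    dtype=np.complex128,
):
    """Bin-independent wave geometry: carrier waves and ROI ray-shadow paths.

    Returns (k_bg, per-source list of (source, carrier, shadow, chord length),
    background displacement field). Reusable across scans that share the same
    subject (sources and ROI), e.g. the four contrast levels of one session.
    """
    fdtype = np.float32 if dtype == np.complex64 else np.float64
    coords = np.indices(acq.shape, dtype=fdtype) * fdtype(acq.voxel_size_mm)
    k_bg = float(
        _wavenumber_per_mm(phantom.mu_background_kpa, phantom.rho_kg_m3, acq.f_vib_hz)
    )
    geo = []
    for s in sources:
        s_coord = np.tensordot(s.direction.astype(fdtype), coords, axes=(0, 0))
        base = (s.amplitude_um * np.exp(1j * (k_bg * s_coord + s.phase))).astype(dtype)
        if roi.any():
            L = _path_integral(
                roi.astype(np.float32), s.direction, acq.voxel_size_mm, path_step_mm
            ).astype(np.float32)
            shadow = L > 1e-6
            L = L[shadow]
        else:
            shadow, L = None, None
        geo.append((s, base, shadow, L))
    u_bg = np.zeros(acq.shape + (3,), dtype=dtype)
    for s, base, _, _ in geo:
        u_bg += base[..., None] * s.polarization.astype(dtype)
    return k_bg, geo, u_bg


def encode_acquisition(
    phantom: PhantomSpec,
    acq: AcquisitionSpec,
    paradigm: ParadigmSpec,
    dtype=np.complex128,
    sources: list[PlaneWaveSource] | None = None,
    path_step_mm: float | None = None,
    geometry=None,
) -> tuple[ComplexSeries, GroundTruth]:
    """Simulate one full concurrent fMRI-fMRE scan.

    For each bin the ROI stiffness is ``mu_bg * (1 + dmu_frac * cr(c) * m(t))``
    with ``m`` the paradigm convolved with the slow stiffness-response kernel
    (peak-normalised, sampled at bin centres); the wave field is re-simulated
    per bin. Voxel phase is ``encoding_rad_per_um * (H . u)`` at each of the
    three vibration phase offsets; voxel magnitude follows the canonical-HRF
    BOLD modulation sampled at each 1 s frame. Complex Gaussian noise with
    standard deviation ``noise_sd`` x the baseline magnitude is added to the
    real and imaginary parts.
    """
    from .glm import DoubleGammaParams  # lazy import, see _modulation

    if phantom.seed is None:
        raise ValueError("PhantomSpec.seed must be set (reproducibility is mandatory)")
    n_bins = paradigm.total_s / acq.bin_s
    if abs(n_bins - round(n_bins)) > 1e-9:
        raise ValueError(
            f"bin duration {acq.bin_s} s does not divide the paradigm duration {paradigm.total_s} s"
        )
    n_bins = int(round(n_bins))
    fpb = acq.frames_per_bin
    if fpb != acq.n_meg * acq.n_offsets:
        raise ValueError(
            f"frames per bin ({fpb}) must equal n_meg*n_offsets "
            f"({acq.n_meg}*{acq.n_offsets}) for concurrent magnitude sampling"
        )
    n_frames = n_bins * fpb
    roi = phantom.resolve_roi(acq)
    rng = np.random.default_rng(phantom.seed)
    if sources is None:
        sources = draw_sources(phantom.n_sources, rng, phantom.amp_um)

    cr = phantom.contrast_fraction(paradigm.contrast_pct)
    bin_centers = (np.arange(n_bins) + 0.5) * acq.bin_s
    m_bin = _modulation(paradigm, DoubleGammaParams.stiffness_response(), bin_centers)
    d_bin = phantom.delta_mu_frac_at_100 * cr * m_bin  # fractional d_mu per bin
    frame_centers = (np.arange(n_frames) + 0.5) * acq.tr_s
    bold_t = phantom.bold_frac_at_100 * cr * _modulation(
        paradigm, DoubleGammaParams.canonical(), frame_centers
    )

    mu_bg = phantom.mu_background_kpa
    mu_map_t = np.full(acq.shape + (n_bins,), mu_bg)
    mu_map_t[roi, :] = mu_bg * (1.0 + d_bin)[None, :]

    # Per-source geometry, shared by all bins (stiffness is constant within a
    # bin). The background carrier wave is bin-independent; only the voxels in
    # the ROI's ray shadow acquire a bin-dependent extra phase (k_roi-k_bg)*L.
    work = np.complex64 if dtype == np.complex64 else np.complex128
    if geometry is None:
        geometry = precompute_geometry(
            phantom, acq, roi, sources, path_step_mm=path_step_mm, dtype=work
        )
    k_bg, geo, u_bg = geometry

    theta = 2.0 * np.pi * np.arange(acq.n_offsets) / acq.n_offsets
    cos_t, sin_t = np.cos(theta), np.sin(theta)
    H = HADAMARD4.astype(u_bg.real.dtype)
    data = np.empty(acq.shape + (acq.n_meg, acq.n_offsets, n_bins), dtype=dtype)
    roi_idx = np.nonzero(roi)
    enc = acq.encoding_rad_per_um
    frame_grid = np.arange(acq.n_offsets)[:, None] * acq.n_meg + np.arange(acq.n_meg)[None, :]
    for b in range(n_bins):
        k_roi = float(
            _wavenumber_per_mm(mu_bg * (1.0 + d_bin[b]), phantom.rho_kg_m3, acq.f_vib_hz)
        )
        u = u_bg.copy()
        if roi.any() and k_roi != k_bg:
            for s, base, shadow, L in geo:
                factor = np.exp(1j * (k_roi - k_bg) * L).astype(work) - work(1.0)
                u[shadow] += (factor * base[shadow])[:, None] * s.polarization.astype(work)
        # encoded phase phi_j = enc * H (Re u cos(th_j) - Im u sin(th_j))
        A = np.einsum("xyzc,mc->xyzm", u.real, H)
        B = np.einsum("xyzc,mc->xyzm", u.imag, H)
        for j in range(acq.n_offsets):
            phi = (enc * cos_t[j]) * A
            phi -= (enc * sin_t[j]) * B
            vox = np.cos(phi).astype(dtype)
            vox += 1j * np.sin(phi).astype(dtype)
            vox *= BASELINE_MAGNITUDE
            if roi.any():
                frames = b * fpb + frame_grid[j]  # (meg,)
                scale = (1.0 + bold_t[frames]).astype(vox.real.dtype)
                vox[roi_idx] *= scale
            data[..., j, b] = vox

    if phantom.noise_sd > 0:
        sd = phantom.noise_sd * BASELINE_MAGNITUDE
        real_dtype = np.float32 if dtype == np.complex64 else np.float64
        data.real += rng.standard_normal(data.shape, dtype=real_dtype) * real_dtype(sd)
        data.imag += rng.standard_normal(data.shape, dtype=real_dtype) * real_dtype(sd)

    series = ComplexSeries(data=data, spec=acq, paradigm=paradigm)
    truth = GroundTruth(
        mu_map_t=mu_map_t,
        bold_frac_t=bold_t,
        active_mask=roi,
        delta_mu_peak_kpa=float(mu_bg * phantom.delta_mu_frac_at_100 * cr * m_bin.max()),
    )
    return series, truth
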