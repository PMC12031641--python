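"""Raw complex MRE series -> first-harmonic curl wave images.

Processing chain (applied by :func:`reconstruct_wavefield`):

1. phase extraction and unwrapping of each measured (MEG, offset, bin) volume,
2. Hadamard pseudo-inverse decode to x/y/z displacement phase,
3. in-plane high-pass filtering (removes slowly varying phase offsets and
   inter-slice discontinuities),
4. central-difference curl (suppresses longitudinal waves),
5. first-harmonic extraction across the phase offsets (temporal FFT at the
   vibration frequency),
6. 7x7x5 quartic-kernel smoothing.

All operators except unwrapping are linear.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter1d
from scipy.signal import fftconvolve

from .specs import AcquisitionSpec, ParadigmSpec

#: Tetrahedral Hadamard motion-encoding matrix. Rows are the 4 MEG
#: directions, columns the x, y, z displacement components.
HADAMARD4 = np.array(
    [[+1.0, +1.0, +1.0],
     [+1.0, -1.0, -1.0],
     [-1.0, +1.0, -1.0],
     [-1.0, -1.0, +1.0]]
)

#: Default in-plane high-pass width: 0.8 x the background shear wavelength of
#: a 3 kPa / 1000 kg/m^3 medium vibrated at 60 Hz (sqrt(3)/60 m ~= 28.9 mm).
DEFAULT_HP_SIGMA_MM = 0.8 * math.sqrt(3.0) / 60.0 * 1000.0


@dataclass
class ComplexSeries:
    """Raw complex-valued MRE image series.

    ``data`` is indexed (x, y, z, meg, offset, bin). The magnitude carries the
    BOLD-weighted fMRI signal, the phase the motion-encoded displacement.
    """

    data: np.ndarray
    spec: AcquisitionSpec
    paradigm: ParadigmSpec

    def __post_init__(self) -> None:
        if self.data.ndim != 6:
            raise ValueError(
                f"ComplexSeries data must be 6-D (x,y,z,meg,offset,bin), got shape {self.data.shape}"
            )
        nx, ny, nz, nm, no, nb = self.data.shape
        if nm != self.spec.n_meg:
            raise ValueError(f"meg axis has length {nm}, spec says {self.spec.n_meg}")
        if no != self.spec.n_offsets:
            raise ValueError(f"offset axis has length {no}, spec says {self.spec.n_offsets}")
        expected_bins = self.paradigm.total_s / self.spec.bin_s
        if abs(expected_bins - round(expected_bins)) > 1e-9 or nb != round(expected_bins):
            raise ValueError(
                f"bin axis has length {nb}; paradigm duration {self.paradigm.total_s} s "
                f"at {self.spec.bin_s} s/bin implies {expected_bins}"
            )

    @property
    def n_bins(self) -> int:
        return self.data.shape[-1]

    @property
    def n_frames(self) -> int:
        return self.n_bins * self.spec.frames_per_bin

    def magnitude_frames(self) -> np.ndarray:
        """|data| reordered into the (x, y, z, t) fMRI frame series.

        One frame per TR: within a bin, frames run offset-major with the MEG
        direction fastest, matching the simulated acquisition order.
        """
        nx, ny, nz, nm, no, nb = self.data.shape
        mags = np.abs(self.data)  # (x,y,z,meg,off,bin)
        # -> (x,y,z,bin,off,meg) -> flatten trailing three axes in time order
        mags = np.moveaxis(mags, (5, 4, 3), (3, 4, 5))
        return np.ascontiguousarray(mags.reshape(nx, ny, nz, nb * no * nm))


@dataclass
class WaveField:
    """First-harmonic complex curl components per voxel per bin.

    ``curl`` is indexed (x, y, z, component, bin); units are 1/mm times the
    displacement unit of the decoded field (um by default).
    """

    curl: np.ndarray
    f_hz: float

    def __post_init__(self) -> None:
        if self.curl.ndim not in (4, 5):
            raise ValueError(
                f"WaveField curl must be (x,y,z,3[,bin]), got shape {self.curl.shape}"
            )
        if self.curl.shape[3] != 3:
            raise ValueError("WaveField needs 3 curl components on axis 3")

    @property
    def n_bins(self) -> int:
        return 1 if self.curl.ndim == 4 else self.curl.shape[-1]


def _has_wraps(phase: np.ndarray) -> bool:
    """True if any neighbouring-voxel phase jump exceeds pi along a spatial axis."""
    for ax in range(min(phase.ndim, 3)):
        if phase.shape[ax] > 1 and np.abs(np.diff(phase, axis=ax)).max() > np.pi:
            return True
    return False


def unwrap_phase(phase: np.ndarray) -> np.ndarray:
    """Unwrap a 1-3D wrapped phase volume (values in (-pi, pi]).

    Reliability-ordered unwrapping (scikit-image); the output differs from the
    input by voxelwise multiples of 2*pi. Volumes whose largest neighbour jump
    is already below pi are returned unchanged (no wraps present).
    """
    phase = np.asarray(phase)
    if phase.ndim > 3:
        flat = phase.reshape(phase.shape[:3] + (-1,))
        # vectorized screen: which volumes contain any wrap at all
        need = np.zeros(flat.shape[-1], dtype=bool)
        for ax in range(3):
            if flat.shape[ax] > 1:
                d = np.abs(np.diff(flat, axis=ax))
                need |= (d > np.pi).any(axis=(0, 1, 2))
        out = flat.copy()
        for i in np.nonzero(need)[0]:
            out[..., i] = unwrap_phase(flat[..., i])
        return out.reshape(phase.shape)
    if not _has_wraps(phase):
        return phase.copy()
    from skimage.restoration import unwrap_phase as _sk_unwrap

    return np.asarray(_sk_unwrap(phase), dtype=phase.dtype)


def decode_hadamard(series: ComplexSeries, unwrap: bool = True) -> np.ndarray:
    """Decode measured phases into x/y/z displacement-phase series.

    Returns phases indexed (x, y, z, component, offset, bin) in radians.
    Unwrapping is applied to each measured MEG phase volume *before* the
    linear pseudo-inverse decode, because wrapping does not commute with the
    decode; with sub-pi encoded phase the two orders coincide.
    """
    if series.spec.n_meg != 4:
        raise ValueError(
            f"unsupported motion-encoding scheme: n_meg={series.spec.n_meg} "
            "(only the 4-direction tetrahedral Hadamard scheme is implemented)"
        )
    phi = np.angle(series.data)
    if unwrap:
        phi = unwrap_phase(phi.reshape(phi.shape[:3] + (-1,))).reshape(phi.shape)
    hinv = np.linalg.pinv(HADAMARD4).astype(phi.dtype)  # (3, 4)
    return np.einsum("cm,xyzmob->xyzcob", hinv, phi)


def highpass_inplane(
    vol: np.ndarray,
    voxel_size_mm: float,
    sigma_mm: float | None = None,
) -> np.ndarray:
    """Per-slice high-pass: subtract an in-plane Gaussian low-pass.

    Removes slowly varying phase (inter-slice discontinuities, encoding
    offsets) while preserving the shear wave, whose wavelength lies well
    below the cutoff. The residual DC of every slice is forced to exactly
    zero. Works on any array whose first three axes are (x, y, z).
    """
    if sigma_mm is None:
        sigma_mm = DEFAULT_HP_SIGMA_MM
    sigma_vox = sigma_mm / voxel_size_mm
    low = gaussian_filter1d(vol, sigma_vox, axis=0, mode="nearest")
    low = gaussian_filter1d(low, sigma_vox, axis=1, mode="nearest")
    out = vol - low
    out -= out.mean(axis=(0, 1), keepdims=True)
    return out


def curl(u: np.ndarray, voxel_size_mm: float) -> tuple[np.ndarray, np.ndarray]:
    """Central-difference curl of a 3-component field.

    Parameters
    ----------
    u : ndarray, shape (x, y, z, 3, ...)
        Displacement components on a common grid; trailing axes are carried
        through.
    voxel_size_mm : float
        Isotropic grid spacing; the curl comes out per mm.

    Returns
    -------
    curl : ndarray, same shape as ``u``
    interior_mask : bool ndarray (x, y, z)
        False on the one-voxel rim where one-sided differences were used;
        only interior voxels are trusted downstream.
    """
    if u.shape[3] != 3:
        raise ValueError("curl needs 3 components on axis 3")
    if any(s < 3 for s in u.shape[:3]):
        raise ValueError(f"every spatial axis must have length >= 3, got {u.shape[:3]}")
    h = float(voxel_size_mm)
    d = lambda c, ax: np.gradient(u[:, :, :, c, ...], h, axis=ax)
    cx = d(2, 1) - d(1, 2)
    cy = d(0, 2) - d(2, 0)
    cz = d(1, 0) - d(0, 1)
    out = np.stack([cx, cy, cz], axis=3)
    interior = np.zeros(u.shape[:3], dtype=bool)
    interior[1:-1, 1:-1, 1:-1] = True
    return out, interior


def first_harmonic(
    arr: np.ndarray,
    axis: int = -1,
    sample_phases: np.ndarray | None = None,
) -> np.ndarray:
    """Complex first-harmonic coefficient across evenly spaced phase offsets.

    Scaled so a sampled ``A*cos(w*t + phi)`` yields ``A*exp(1j*phi)``; any DC
    component is rejected exactly (orthogonality over one period).
    """
    arr = np.asarray(arr)
    n = arr.shape[axis]
    if n < 3:
        raise ValueError(f"need >= 3 phase offsets, got {n}")
    if sample_phases is not None:
        sample_phases = np.asarray(sample_phases, dtype=float)
        if sample_phases.shape != (n,):
            raise ValueError("sample_phases length must match the offset axis")
        diffs = np.diff(sample_phases)
        if not np.allclose(diffs, 2.0 * np.pi / n, rtol=0, atol=1e-9):
            raise ValueError(
                f"phase offsets must be evenly spaced over one period; got spacings {diffs}"
            )
        theta = sample_phases
    else:
        theta = 2.0 * np.pi * np.arange(n) / n
    w = np.exp(-1j * theta) * (2.0 / n)
    if arr.dtype in (np.float32, np.complex64):
        w = w.astype(np.complex64)
    return np.tensordot(arr, w, axes=([axis % arr.ndim], [0]))


def quartic_kernel(support: tuple[int, int, int] = (7, 7, 5)) -> np.ndarray:
    """Separably-normalised quartic (biweight) kernel on the given odd support.

    Weights are (1 - (d/d_max)^2)^2 with d the anisotropy-corrected Euclidean
    distance in voxel units and d_max one voxel beyond the support half-width
    per axis (so the whole stated support carries weight); the kernel sums
    to 1.
    """
    if any(s % 2 == 0 or s < 1 for s in support):
        raise ValueError(f"support must be odd and positive per axis, got {support}")
    half = [(s - 1) // 2 for s in support]
    axes = [np.arange(-hw, hw + 1) / (hw + 1.0) for hw in half]
    gx, gy, gz = np.meshgrid(*axes, indexing="ij")
    r2 = gx**2 + gy**2 + gz**2
    w = np.clip(1.0 - r2, 0.0, None) ** 2
    return w / w.sum()


def smooth_quartic(
    vol: np.ndarray, support: tuple[int, int, int] = (7, 7, 5)
) -> np.ndarray:
    """Convolve the first three axes with the quartic smoothing kernel.

    Boundary weights are renormalised over the in-volume part of the kernel
    support, so a constant field passes through unchanged everywhere.
    """
    if any(vol.shape[i] < support[i] for i in range(3)):
        raise ValueError(
            f"volume spatial shape {vol.shape[:3]} is smaller than the kernel "
            f"support {support}; pad the volume or shrink the kernel"
        )
    kern = quartic_kernel(support)
    single = np.float32 if vol.dtype in (np.float32, np.complex64) else np.float64
    kern = kern.astype(single)
    norm = fftconvolve(np.ones(vol.shape[:3], dtype=single), kern, mode="same")
    kern = kern.reshape(kern.shape + (1,) * (vol.ndim - 3))
    if np.iscomplexobj(vol):
        kern = kern.astype(np.complex64 if single == np.float32 else complex)
    out = fftconvolve(vol, kern, mode="same", axes=(0, 1, 2))
    out /= norm.reshape(norm.shape + (1,) * (vol.ndim - 3))
    return out.astype(vol.dtype, copy=False)


def reconstruct_wavefield(
    series: ComplexSeries,
    unwrap: bool = True,
    hp_sigma_mm: float | None = None,
    smooth: bool = True,
    support: tuple[int, int, int] = (7, 7, 5),
) -> tuple[WaveField, np.ndarray]:
    """Full reconstruction chain: raw complex series -> first-harmonic curl.

    Returns the wave field (displacement units um, curl per mm) and the
    interior mask excluding the one-voxel finite-difference rim.
    """
    spec = series.spec
    phases = decode_hadamard(series, unwrap=unwrap)  # (x,y,z,3,off,bin) rad
    disp = phases / spec.encoding_rad_per_um  # um
    disp = highpass_inplane(disp, spec.voxel_size_mm, hp_sigma_mm)
    c, interior = curl(disp, spec.voxel_size_mm)
    q = first_harmonic(c, axis=4)  # over offsets -> (x,y,z,3,bin)
    if smooth:
        q = smooth_quartic(q, support)
        # the smoothing half-support near the volume edge mixes in boundary-
        # renormalised values; widen the flagged rim accordingly
        hw = [(s - 1) // 2 for s in support]
        interior = np.zeros_like(interior)
        interior[
            1 + hw[0] : -(1 + hw[0]), 1 + hw[1] : -(1 + hw[1]), 1 + hw[2] : -(1 + hw[2])
        ] = True
    if not np.all(np.isfinite(q)):
        raise FloatingPointError("non-finite values in reconstructed wavefield")
    return WaveField(curl=q, f_hz=spec.f_vib_hz), interior
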