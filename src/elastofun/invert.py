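"""Shear-stiffness elastograms by algebraic direct inversion.

Each first-harmonic curl component q_c obeys the homogeneous Helmholtz
equation mu * laplacian(q_c) + rho * omega^2 * q_c = 0 locally, so

    mu_c = -rho * omega^2 * q_c / laplacian(q_c).

Components are combined with weights |laplacian(q_c)|^2 (the noise-robust
choice: the combination becomes -rho*omega^2 * sum q_c conj(lap_c) / sum
|lap_c|^2, with no per-component division), and the reported stiffness is the
magnitude |mu| in kPa. Voxels whose Laplacian falls below a stability floor,
and the finite-difference rim, are marked invalid rather than clipped.

The 2nd-order central-difference Laplacian underestimates k^2 by the factor
(2 - 2cos(kh)) / (kh)^2; keep at least ~15 voxels per wavelength for
percent-level accuracy.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .recon import WaveField


@dataclass
class Elastogram:
    """Shear-stiffness map time series (kPa), one volume per bin."""

    mu: np.ndarray  # (x, y, z, n_bins), NaN off valid_mask
    valid_mask: np.ndarray  # (x, y, z)
    f_hz: float
    rho_kg_m3: float

    @property
    def n_bins(self) -> int:
        return self.mu.shape[-1]


def _laplacian(q: np.ndarray, h_m: float) -> np.ndarray:
    """Second-order central-difference Laplacian over the first three axes.

    The one-voxel rim is left at zero (invalid downstream).
    """
    out = np.zeros_like(q)
    inner = out[1:-1, 1:-1, 1:-1]
    inner += q[2:, 1:-1, 1:-1] + q[:-2, 1:-1, 1:-1]
    inner += q[1:-1, 2:, 1:-1] + q[1:-1, :-2, 1:-1]
    inner += q[1:-1, 1:-1, 2:] + q[1:-1, 1:-1, :-2]
    inner -= 6.0 * q[1:-1, 1:-1, 1:-1]
    out /= h_m**2
    return out


def _invert_array(
    q: np.ndarray,
    f_hz: float,
    rho_kg_m3: float,
    voxel_size_mm: float,
    floor_rel: float = 1e-8,
    rim_mask: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Inversion core on q shaped (x, y, z, 3[, bins]); returns (mu_kpa, valid)."""
    if q.shape[3] != 3:
        raise ValueError("wavefield needs 3 curl components on axis 3")
    if any(s < 5 for s in q.shape[:3]):
        raise ValueError(
            f"need >= 5 voxels per axis for the Laplacian stencil plus rim, got {q.shape[:3]}"
        )
    h_m = voxel_size_mm * 1e-3
    omega = 2.0 * np.pi * f_hz
    lap = _laplacian(q, h_m)
    num = np.sum(q * np.conj(lap), axis=3)
    den = np.sum(np.abs(lap) ** 2, axis=3)
    interior = np.zeros(q.shape[:3], dtype=bool)
    interior[1:-1, 1:-1, 1:-1] = True
    if rim_mask is not None:
        interior &= rim_mask
    # stability floor relative to the typical Laplacian magnitude
    if not interior.any():
        raise ValueError(
            f"no interior voxels remain after rim flagging for shape {q.shape[:3]}; "
            "the volume is too small relative to the stencil/smoothing rims"
        )
    scale = np.sqrt(np.mean(den[interior])) if den.ndim == 3 else np.sqrt(
        np.mean(den[interior, :], axis=0)
    )
    floor = (floor_rel * scale) ** 2
    stable = den > floor
    with np.errstate(divide="ignore", invalid="ignore"):
        mu_pa = -rho_kg_m3 * omega**2 * num / den
    mu_kpa = np.abs(mu_pa) / 1000.0
    valid = stable & (interior if den.ndim == 3 else interior[..., None])
    mu_kpa = np.where(valid, mu_kpa, np.nan)
    return mu_kpa, valid


def direct_invert(
    wavefield: WaveField | np.ndarray,
    rho_kg_m3: float = 1000.0,
    voxel_size_mm: float = 3.5,
    f_hz: float | None = None,
    floor_rel: float = 1e-8,
    rim_mask: np.ndarray | None = None,
) -> Elastogram:
    """Direct Helmholtz inversion of a single-bin first-harmonic curl field."""
    if isinstance(wavefield, WaveField):
        q = wavefield.curl
        f_hz = wavefield.f_hz
        if q.ndim == 5:
            if q.shape[-1] != 1:
                raise ValueError("multi-bin wavefield: use elastogram_series")
            q = q[..., 0]
    else:
        q = np.asarray(wavefield)
        if f_hz is None:
            raise ValueError("f_hz must be given when passing a bare array")
    mu, valid = _invert_array(q, f_hz, rho_kg_m3, voxel_size_mm, floor_rel, rim_mask)
    return Elastogram(
        mu=mu[..., None], valid_mask=valid, f_hz=float(f_hz), rho_kg_m3=float(rho_kg_m3)
    )


def elastogram_series(
    wavefield: WaveField,
    rho_kg_m3: float = 1000.0,
    voxel_size_mm: float = 3.5,
    floor_rel: float = 1e-8,
    rim_mask: np.ndarray | None = None,
) -> Elastogram:
    """One stiffness volume per bin; valid mask is the per-bin intersection."""
    q = wavefield.curl
    if q.ndim == 4:
        q = q[..., None]
    if q.shape[-1] == 0:
        raise ValueError("empty bin list: wavefield has no bins")
    mu, valid = _invert_array(
        q, wavefield.f_hz, rho_kg_m3, voxel_size_mm, floor_rel, rim_mask
    )
    mask = np.all(valid, axis=-1)
    mu = np.where(mask[..., None], mu, np.nan)
    return Elastogram(
        mu=mu, valid_mask=mask, f_hz=float(wavefield.f_hz), rho_kg_m3=float(rho_kg_m3)
    )
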