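"""File formats and reproducibility plumbing.

Volumes travel as NIfTI-1; complex data is stored portably with a trailing
2-length real/imaginary axis. Every simulated dataset carries JSON sidecars
describing the acquisition, the paradigm, and provenance (tool version,
config hash, seed). Checksums of gzipped NIfTI are computed on the
decompressed stream so reruns with the same seed produce identical
manifests.
"""
from __future__ import annotations

import gzip
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np

from . import __version__
from .recon import ComplexSeries
from .invert import Elastogram
from .specs import AcquisitionSpec, ParadigmSpec

SERIES_AXES = ["meg", "offset", "bin"]  # flattening order of the 4th NIfTI axis


def config_hash(obj) -> str:
    """Stable short hash of a JSON-serialisable configuration."""
    blob = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def checksum(path: str | Path) -> str:
    """SHA-256 of a file; gzipped files are hashed on the decompressed stream."""
    path = Path(path)
    data = path.read_bytes()
    if path.suffix == ".gz":
        data = gzip.decompress(data)
    return hashlib.sha256(data).hexdigest()


@dataclass
class Sidecar:
    """Acquisition + paradigm description and provenance for one dataset."""

    acquisition: AcquisitionSpec
    paradigm: ParadigmSpec
    seed: int | None = None
    extra: dict | None = None

    def to_dict(self) -> dict:
        d = {
            "acquisition": self.acquisition.to_dict(),
            "paradigm": self.paradigm.to_dict(),
            "provenance": {
                "tool": "elastofun",
                "version": __version__,
                "seed": self.seed,
            },
            "dim_order": SERIES_AXES,
        }
        d["provenance"]["config_hash"] = config_hash(
            {"acquisition": d["acquisition"], "paradigm": d["paradigm"], "seed": self.seed}
        )
        if self.extra:
            d.update(self.extra)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "Sidecar":
        return cls(
            acquisition=AcquisitionSpec.from_dict(d["acquisition"]),
            paradigm=ParadigmSpec.from_dict(d["paradigm"]),
            seed=d.get("provenance", {}).get("seed"),
        )


def _affine(voxel_size_mm: float) -> np.ndarray:
    return np.diag([voxel_size_mm, voxel_size_mm, voxel_size_mm, 1.0])


def save_volume(path: str | Path, data: np.ndarray, voxel_size_mm: float) -> Path:
    path = Path(path)
    img = nib.Nifti1Image(np.asarray(data), _affine(voxel_size_mm))
    nib.save(img, str(path))
    return path


def load_volume(path: str | Path) -> np.ndarray:
    return np.asarray(nib.load(str(path)).dataobj)


def write_complex_series(series: ComplexSeries, out_dir: str | Path, seed: int | None = None) -> Path:
    """Write one scan: ``series.nii.gz`` + ``acquisition.json``/``paradigm.json``.

    The 6-D complex array is flattened to (x, y, z, meg*offset*bin, 2) with
    the real/imaginary parts on the trailing axis; the sidecar declares the
    flattening order.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    d = series.data
    nx, ny, nz, nm, no, nb = d.shape
    flat = d.reshape(nx, ny, nz, nm * no * nb)
    stacked = np.stack([flat.real, flat.imag], axis=-1)
    save_volume(out_dir / "series.nii.gz", stacked, series.spec.voxel_size_mm)
    side = Sidecar(series.spec, series.paradigm, seed=seed).to_dict()
    (out_dir / "acquisition.json").write_text(json.dumps(side, indent=2))
    (out_dir / "paradigm.json").write_text(json.dumps(series.paradigm.to_dict(), indent=2))
    return out_dir


def read_complex_series(in_dir: str | Path) -> ComplexSeries:
    """Read a scan written by :func:`write_complex_series`."""
    in_dir = Path(in_dir)
    side_path = in_dir / "acquisition.json"
    if not side_path.exists():
        raise FileNotFoundError(
            f"missing sidecar {side_path}; generate data with `elastofun simulate` "
            "(every series needs its acquisition.json)"
        )
    side = json.loads(side_path.read_text())
    sidecar = Sidecar.from_dict(side)
    spec, paradigm = sidecar.acquisition, sidecar.paradigm
    raw = load_volume(in_dir / "series.nii.gz")
    n_bins = int(round(paradigm.total_s / spec.bin_s))
    expected = (
        spec.matrix_xy,
        spec.matrix_xy,
        spec.n_slices,
        spec.n_meg * spec.n_offsets * n_bins,
        2,
    )
    if raw.shape != expected:
        raise ValueError(
            f"series file shape {raw.shape} does not match the sidecar-implied shape {expected}"
        )
    flat = raw[..., 0] + 1j * raw[..., 1]
    data = flat.reshape(
        spec.matrix_xy, spec.matrix_xy, spec.n_slices, spec.n_meg, spec.n_offsets, n_bins
    )
    return ComplexSeries(data=data, spec=spec, paradigm=paradigm)


def write_elastogram(el: Elastogram, out_dir: str | Path, voxel_size_mm: float) -> Path:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    mu = np.where(el.valid_mask[..., None], el.mu, 0.0)
    for b in range(el.n_bins):
        save_volume(out_dir / f"elastogram_bin{b:03d}.nii.gz", mu[..., b], voxel_size_mm)
    save_volume(out_dir / "valid_mask.nii.gz", el.valid_mask.astype(np.uint8), voxel_size_mm)
    meta = {"f_hz": el.f_hz, "rho_kg_m3": el.rho_kg_m3, "n_bins": el.n_bins, "units": "kPa"}
    (out_dir / "elastogram.json").write_text(json.dumps(meta, indent=2))
    return out_dir


def read_elastogram(in_dir: str | Path) -> Elastogram:
    in_dir = Path(in_dir)
    meta = json.loads((in_dir / "elastogram.json").read_text())
    vols = [
        load_volume(in_dir / f"elastogram_bin{b:03d}.nii.gz") for b in range(meta["n_bins"])
    ]
    mask = load_volume(in_dir / "valid_mask.nii.gz").astype(bool)
    mu = np.stack(vols, axis=-1)
    mu = np.where(mask[..., None], mu, np.nan)
    return Elastogram(mu=mu, valid_mask=mask, f_hz=meta["f_hz"], rho_kg_m3=meta["rho_kg_m3"])
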