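"""Acquisition and stimulus-paradigm descriptions shared by every pipeline stage.

The defaults reproduce the study conditions of a concurrent fMRI-fMRE visual
experiment: a 12-slice, 64x64, 3.5 mm isotropic slab over the visual cortex;
60 Hz harmonic vibration encoded with 4 Hadamard-combined motion-encoding
gradient (MEG) directions and 3 phase offsets per vibration period; one
magnitude frame per second and one elastogram per 12 s bin; a 16-block x 24 s
ON/OFF block paradigm (384 s total) at one of four visual contrast levels.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict


@dataclass(frozen=True)
class AcquisitionSpec:
    """Geometry, vibration and motion-encoding parameters of one scan.

    Attributes
    ----------
    matrix_xy : int
        In-plane matrix size (voxels per axis).
    n_slices : int
        Number of slices (the z axis).
    voxel_size_mm : float
        Isotropic voxel edge length in mm.
    f_vib_hz : float
        Mechanical vibration (and MEG) frequency in Hz.
    n_meg : int
        Number of motion-encoding directions (4 = tetrahedral Hadamard).
    n_offsets : int
        Phase offsets sampled over one vibration period; >= 3 so the first
        harmonic can be isolated.
    tr_s : float
        Repetition time of one magnitude frame in seconds.
    bin_s : float
        Seconds of acquisition per elastogram volume.
    encoding_rad_per_um : float
        Phase accrued per micron of harmonic displacement amplitude. The
        default keeps peak encoded phase near 1.5 rad, below the wrap limit.
    """

    matrix_xy: int = 64
    n_slices: int = 12
    voxel_size_mm: float = 3.5
    f_vib_hz: float = 60.0
    n_meg: int = 4
    n_offsets: int = 3
    tr_s: float = 1.0
    bin_s: float = 12.0
    encoding_rad_per_um: float = 0.05

    def __post_init__(self) -> None:
        for name in ("matrix_xy", "n_slices", "n_meg", "n_offsets"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1, got {getattr(self, name)}")
        if self.f_vib_hz <= 0:
            raise ValueError(f"f_vib_hz must be positive, got {self.f_vib_hz}")
        if self.voxel_size_mm <= 0:
            raise ValueError("voxel_size_mm must be positive")
        if self.n_offsets < 3:
            raise ValueError(
                "n_offsets must be >= 3 to isolate a single harmonic, "
                f"got {self.n_offsets}"
            )
        if self.tr_s <= 0 or self.bin_s <= 0:
            raise ValueError("tr_s and bin_s must be positive")
        ratio = self.bin_s / self.tr_s
        if abs(ratio - round(ratio)) > 1e-9:
            raise ValueError(
                f"bin_s ({self.bin_s}) must be an integer multiple of tr_s ({self.tr_s})"
            )

    @property
    def shape(self) -> tuple[int, int, int]:
        return (self.matrix_xy, self.matrix_xy, self.n_slices)

    @property
    def period_s(self) -> float:
        """One vibration period in seconds (16.67 ms at 60 Hz)."""
        return 1.0 / self.f_vib_hz

    @property
    def omega(self) -> float:
        """Angular vibration frequency in rad/s."""
        return 2.0 * math.pi * self.f_vib_hz

    @property
    def frames_per_bin(self) -> int:
        return int(round(self.bin_s / self.tr_s))

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "AcquisitionSpec":
        return cls(**d)


@dataclass(frozen=True)
class ParadigmSpec:
    """ON/OFF block stimulation paradigm at one visual contrast level.

    The default is the study design: 16 blocks of 24 s, alternating OFF-first
    (8 ON + 8 OFF, 384 s total).
    """

    n_blocks: int = 16
    block_s: float = 24.0
    contrast_pct: float = 100.0
    order: tuple[int, ...] | None = None  # None -> alternating, OFF first

    def __post_init__(self) -> None:
        if self.n_blocks < 1:
            raise ValueError("n_blocks must be >= 1")
        if self.block_s <= 0:
            raise ValueError("block_s must be positive")
        if self.contrast_pct < 0:
            raise ValueError("contrast_pct must be non-negative")
        if self.order is not None:
            if len(self.order) != self.n_blocks:
                raise ValueError(
                    f"order has {len(self.order)} labels for {self.n_blocks} blocks"
                )
            if any(v not in (0, 1) for v in self.order):
                raise ValueError("order labels must be 0 (OFF) or 1 (ON)")

    @property
    def block_labels(self) -> tuple[int, ...]:
        if self.order is not None:
            return tuple(self.order)
        return tuple(i % 2 for i in range(self.n_blocks))

    @property
    def total_s(self) -> float:
        return self.n_blocks * self.block_s

    def to_dict(self) -> dict:
        d = asdict(self)
        d["order"] = list(self.order) if self.order is not None else None
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ParadigmSpec":
        d = dict(d)
        if d.get("order") is not None:
            d["order"] = tuple(d["order"])
        return cls(**d)
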