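"""Volumes, masks and seed sets, with NIfTI-1 and CSV round-trips.

Conventions
-----------
* Voxel coordinates are 0-based ``(x, y, z)`` integer indices matching the
  array axes of :class:`Volume.data`.
* Structural volumes hold integer luminance values in ``[0, 2**bit_depth - 1]``
  (12-bit by default, i.e. 0..4095).
* Masks are stored on disk as uint8 NIfTI with values {0, 1}.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np

__all__ = [
    "Volume",
    "TumorMask",
    "SeedSet",
    "read_volume",
    "write_volume",
    "read_mask",
    "write_mask",
    "read_seeds",
    "write_seeds",
]

Coord = tuple[int, int, int]


@dataclass
class Volume:
    """A 3D scalar luminance image with voxel spacing and bit depth."""

    data: np.ndarray
    bit_depth: int = 12
    voxel_spacing_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3 or min(self.data.shape) < 1:
            raise ValueError(f"volume must be 3D with each dim >= 1, got shape {self.data.shape}")
        if not np.issubdtype(self.data.dtype, np.integer):
            if not np.allclose(self.data, np.round(self.data)):
                raise ValueError("volume data must be integer-valued")
            self.data = np.round(self.data).astype(np.int32)
        if self.bit_depth < 1:
            raise ValueError("bit_depth must be positive")
        lo, hi = int(self.data.min()), int(self.data.max())
        top = 2**self.bit_depth - 1
        if lo < 0 or hi > top:
            raise ValueError(
                f"voxel values [{lo}, {hi}] outside [0, {top}] for bit_depth {self.bit_depth}"
            )
        sp = tuple(float(s) for s in self.voxel_spacing_mm)
        if len(sp) != 3 or any(s <= 0 for s in sp):
            raise ValueError(f"voxel spacing must be 3 positive reals, got {self.voxel_spacing_mm}")
        self.voxel_spacing_mm = sp

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]


@dataclass
class TumorMask:
    """Binary 3D mask aligned to a :class:`Volume`."""

    data: np.ndarray
    source: str = "manual"  # manual | segmented | ground_truth

    _SOURCES = ("manual", "segmented", "ground_truth")

    def __post_init__(self) -> None:
        arr = np.asarray(self.data)
        if arr.ndim != 3:
            raise ValueError(f"mask must be 3D, got shape {arr.shape}")
        uniq = np.unique(arr)
        if not np.all(np.isin(uniq, (0, 1))):
            raise ValueError("mask values must be binary {0, 1}")
        self.data = arr.astype(bool)
        if self.source not in self._SOURCES:
            raise ValueError(f"source must be one of {self._SOURCES}, got {self.source!r}")

    @property
    def n_voxels(self) -> int:
        return int(self.data.sum())

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]


@dataclass
class SeedSet:
    """User-supplied tumor and background seed voxels for segmentation."""

    tumor_seeds: list[Coord] = field(default_factory=list)
    background_seeds: list[Coord] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.tumor_seeds = [tuple(int(c) for c in s) for s in self.tumor_seeds]  # type: ignore[misc]
        self.background_seeds = [tuple(int(c) for c in s) for s in self.background_seeds]  # type: ignore[misc]
        if not self.tumor_seeds or not self.background_seeds:
            raise ValueError("both tumor and background seed lists must be nonempty")
        clash = set(self.tumor_seeds) & set(self.background_seeds)
        if clash:
            raise ValueError(f"coordinates listed as both tumor and background seeds: {sorted(clash)}")

    def validate_bounds(self, shape: Sequence[int]) -> None:
        for role, seeds in (("tumor", self.tumor_seeds), ("background", self.background_seeds)):
            for s in seeds:
                if any(c < 0 or c >= n for c, n in zip(s, shape)):
                    raise ValueError(f"{role} seed {s} outside volume bounds {tuple(shape)}")


def _affine(spacing: Sequence[float]) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = spacing
    return aff


def write_volume(v: Volume, path: str | Path) -> None:
    """Write a volume as NIfTI-1 (.nii or .nii.gz); int16 on disk."""
    img = nib.Nifti1Image(np.asarray(v.data, dtype=np.int16), _affine(v.voxel_spacing_mm))
    img.header.set_data_dtype(np.int16)
    nib.save(img, str(path))


def read_volume(path: str | Path, bit_depth: int = 12) -> Volume:
    """Read a NIfTI-1 volume; values are range-checked against ``bit_depth``."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return Volume(data=data, bit_depth=bit_depth, voxel_spacing_mm=spacing)  # range check in Volume


def write_mask(m: TumorMask, path: str | Path, spacing: Sequence[float] = (1.0, 1.0, 1.0)) -> None:
    img = nib.Nifti1Image(m.data.astype(np.uint8), _affine(spacing))
    img.header.set_data_dtype(np.uint8)
    nib.save(img, str(path))


def read_mask(path: str | Path, source: str = "manual") -> TumorMask:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    data = np.asanyarray(nib.load(str(path)).dataobj)
    return TumorMask(data=data, source=source)


_SEED_ROLES = ("tumor", "background")


def write_seeds(seeds: SeedSet, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["x", "y", "z", "role"])
        for s in seeds.tumor_seeds:
            w.writerow([*s, "tumor"])
        for s in seeds.background_seeds:
            w.writerow([*s, "background"])


def read_seeds(path: str | Path, volume_shape: Sequence[int] | None = None) -> SeedSet:
    """Load seeds from a CSV of ``x,y,z,role`` rows (header required).

    Roles must be ``tumor`` or ``background``; coordinates are 0-based voxel
    indices and, when ``volume_shape`` is given, must lie inside it.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    tumor: list[Coord] = []
    background: list[Coord] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        required = {"x", "y", "z", "role"}
        if reader.fieldnames is None or not required.issubset(reader.fieldnames):
            raise ValueError(f"seeds CSV must have header columns {sorted(required)}")
        for i, row in enumerate(reader):
            role = row["role"].strip().lower()
            if role not in _SEED_ROLES:
                raise ValueError(f"row {i}: unknown seed role {row['role']!r} (expected tumor/background)")
            coord = (int(row["x"]), int(row["y"]), int(row["z"]))
            (tumor if role == "tumor" else background).append(coord)
    seeds = SeedSet(tumor_seeds=tumor, background_seeds=background)
    if volume_shape is not None:
        seeds.validate_bounds(volume_shape)
    return seeds
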