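"""Synthetic 3D MRI phantoms for the lymphoma / glioblastoma contrast.

The generator emulates the class-conditional structure the classifier
exploits on real structural MRI:

* **Lymphomas** — a single, fairly homogeneous intensity compartment, so the
  whole-tumor luminance histogram is narrow.
* **Glioblastomas** — an enhancing bright rim around a darker (necrotic)
  core, so the histogram is bimodal and spans a wide dynamic range.
* **ADC** — one scalar apparent-diffusion-coefficient value per case
  (units 10⁻³ mm²/s), lower on average for lymphomas but drawn from
  distributions that overlap between classes, so that a single ADC cut
  separates the classes only modestly above chance.

Tumors are axis-aligned ellipsoids with mild random anisotropy, placed away
from the volume border; the rim is the outermost 30 % of the tumor radius.
Each tissue compartment has its own mean and texture sd (12-bit units), and
independent scanner noise (Gaussian by default, Rician optional) is added on
top, after which values are clipped to [0, 4095] and rounded.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
import yaml

from .volume_io import TumorMask, Volume, write_mask, write_volume

__all__ = [
    "LYMPHOMA",
    "GLIOBLASTOMA",
    "LABELS",
    "PhantomParams",
    "LabeledCase",
    "generate_phantom",
    "generate_cohort",
    "default_seeds_for_case",
    "write_cohort",
    "load_cohort",
]

LYMPHOMA = "lymphoma"
GLIOBLASTOMA = "glioblastoma"
LABELS = (LYMPHOMA, GLIOBLASTOMA)

_MAX_12BIT = 4095


@dataclass
class PhantomParams:
    """Generator configuration; defaults define the study conditions.

    Intensity statistics are in 12-bit luminance units; ADC statistics in
    10⁻³ mm²/s.
    """

    volume_shape: tuple[int, int, int] = (64, 64, 40)
    voxel_spacing_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)
    tumor_radius_range_vox: tuple[float, float] = (8.0, 13.0)
    lymphoma_mean_lum: float = 1400.0
    lymphoma_sd_lum: float = 80.0
    gbm_rim_mean_lum: float = 2800.0
    gbm_core_mean_lum: float = 1000.0
    gbm_sd_lum: float = 150.0
    background_mean_lum: float = 600.0
    background_sd_lum: float = 60.0
    adc_lym_mean: float = 0.7
    adc_lym_sd: float = 0.3
    adc_gbm_mean: float = 1.0
    adc_gbm_sd: float = 0.3
    noise_sigma: float = 40.0
    noise_model: str = "gaussian"  # gaussian | rician
    rim_fraction: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "lymphoma_mean_lum",
            "gbm_rim_mean_lum",
            "gbm_core_mean_lum",
            "background_mean_lum",
        ):
            v = getattr(self, name)
            if not 0 <= v <= _MAX_12BIT:
                raise ValueError(f"{name}={v} outside [0, {_MAX_12BIT}]")
        if self.gbm_rim_mean_lum <= self.gbm_core_mean_lum:
            raise ValueError("glioblastoma rim must be brighter than core")
        if self.adc_lym_mean >= self.adc_gbm_mean:
            raise ValueError("lymphoma ADC mean must be below glioblastoma ADC mean")
        if self.adc_lym_mean + 2 * self.adc_lym_sd <= self.adc_gbm_mean - 2 * self.adc_gbm_sd:
            raise ValueError("ADC distributions must overlap (lym mean + 2sd > gbm mean - 2sd)")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be nonnegative")
        if self.noise_model not in ("gaussian", "rician"):
            raise ValueError(f"unknown noise_model {self.noise_model!r}")
        if not 0 < self.rim_fraction < 1:
            raise ValueError("rim_fraction must be in (0, 1)")
        lo, hi = self.tumor_radius_range_vox
        if lo <= 0 or hi < lo:
            raise ValueError("tumor_radius_range_vox must be 0 < lo <= hi")
        self.volume_shape = tuple(int(n) for n in self.volume_shape)  # type: ignore[assignment]
        if len(self.volume_shape) != 3 or any(n < 1 for n in self.volume_shape):
            raise ValueError("volume_shape must be 3 positive integers")


@dataclass
class LabeledCase:
    """One patient-equivalent: volume, ground-truth mask, scalar ADC, label."""

    case_id: str
    volume: Volume
    truth_mask: TumorMask
    adc_value: float | None
    label: str

    def __post_init__(self) -> None:
        if self.label not in LABELS:
            raise ValueError(f"unknown label {self.label!r}")
        if self.truth_mask.shape != self.volume.shape:
            raise ValueError("truth mask shape must equal volume shape")
        if self.truth_mask.n_voxels < 1:
            raise ValueError("truth mask must contain at least one voxel")


def _case_rng(label: str, case_seed: int) -> np.random.Generator:
    # label folded into the stream so lymphoma/glioblastoma draws are decoupled
    return np.random.default_rng(np.random.SeedSequence([int(case_seed), LABELS.index(label)]))


def generate_phantom(label: str, params: PhantomParams | None = None, case_seed: int = 0) -> LabeledCase:
    """Generate one labeled phantom; bit-identical for fixed (label, params, case_seed)."""
    if label not in LABELS:
        raise ValueError(f"unknown label {label!r}; expected one of {LABELS}")
    if case_seed < 0:
        raise ValueError("case_seed must be >= 0")
    p = params or PhantomParams()
    rng = _case_rng(label, case_seed)
    shape = np.array(p.volume_shape)

    lo, hi = p.tumor_radius_range_vox
    margin = 2
    max_semi = (shape - 1) / 2 - margin
    if lo > max_semi.min():
        raise ValueError(
            f"tumor radius {lo} cannot fit in volume of shape {tuple(shape)} with margin {margin}"
        )
    # per-axis semi-axes: mild anisotropy, capped so the ellipsoid fits
    semi = rng.uniform(lo, hi, size=3)
    semi = np.minimum(semi, max_semi)
    center = np.array(
        [rng.uniform(s + margin, n - 1 - s - margin) for s, n in zip(semi, shape)]
    )

    xx, yy, zz = np.meshgrid(*(np.arange(n) for n in shape), indexing="ij")
    rho2 = (
        ((xx - center[0]) / semi[0]) ** 2
        + ((yy - center[1]) / semi[1]) ** 2
        + ((zz - center[2]) / semi[2]) ** 2
    )
    tumor = rho2 <= 1.0

    img = rng.normal(p.background_mean_lum, p.background_sd_lum, size=tuple(shape))
    if label == LYMPHOMA:
        img[tumor] = rng.normal(p.lymphoma_mean_lum, p.lymphoma_sd_lum, size=int(tumor.sum()))
        adc = rng.normal(p.adc_lym_mean, p.adc_lym_sd)
    else:
        rim = tumor & (rho2 > (1.0 - p.rim_fraction) ** 2)
        core = tumor & ~rim
        img[rim] = rng.normal(p.gbm_rim_mean_lum, p.gbm_sd_lum, size=int(rim.sum()))
        img[core] = rng.normal(p.gbm_core_mean_lum, p.gbm_sd_lum, size=int(core.sum()))
        adc = rng.normal(p.adc_gbm_mean, p.adc_gbm_sd)
    adc = float(max(adc, 0.05))

    if p.noise_sigma > 0:
        if p.noise_model == "gaussian":
            img = img + rng.normal(0.0, p.noise_sigma, size=img.shape)
        else:  # rician: magnitude of complex signal with iid Gaussian channels
            re = img + rng.normal(0.0, p.noise_sigma, size=img.shape)
            im = rng.normal(0.0, p.noise_sigma, size=img.shape)
            img = np.hypot(re, im)
    img = np.clip(np.round(img), 0, _MAX_12BIT).astype(np.int16)

    return LabeledCase(
        case_id=f"{label[:3]}_{case_seed:06d}",
        volume=Volume(data=img, bit_depth=12, voxel_spacing_mm=p.voxel_spacing_mm),
        truth_mask=TumorMask(data=tumor, source="ground_truth"),
        adc_value=adc,
        label=label,
    )


def _per_case_seed(cohort_seed: int, index: int) -> int:
    """Counter-based mix of (cohort seed, case index), stable across platforms."""
    h = hashlib.sha256(f"{cohort_seed}:{index}".encode()).digest()
    return int.from_bytes(h[:4], "little") & 0x7FFFFFFF


def generate_cohort(
    n_lym: int, n_gbm: int, params: PhantomParams | None = None, seed: int = 0
) -> list[LabeledCase]:
    """Generate ``n_lym + n_gbm`` phantoms with deterministic per-case seeds."""
    if n_lym < 0 or n_gbm < 0:
        raise ValueError("case counts must be nonnegative")
    p = params or PhantomParams()
    cases: list[LabeledCase] = []
    labels = [LYMPHOMA] * n_lym + [GLIOBLASTOMA] * n_gbm
    for i, label in enumerate(labels):
        case = generate_phantom(label, p, case_seed=_per_case_seed(seed, i))
        case.case_id = f"{label[:3]}_{i:03d}"
        cases.append(case)
    return cases


def default_seeds_for_case(case: LabeledCase, n_background: int = 3):
    """Derive a plausible user seed placement from a phantom's ground truth.

    Tumor seeds: the mask centroid plus two points at ~85 % of the tumor
    radius along +x and -x — one per visually distinct compartment for
    rim/core tumors. Background seeds: far corners of the volume.
    """
    from .volume_io import SeedSet

    mask = case.truth_mask.data
    coords = np.argwhere(mask)
    centroid = coords.mean(axis=0)
    center = tuple(int(round(c)) for c in centroid)
    xs = coords[coords[:, 1] == center[1]]
    xs = xs[xs[:, 2] == center[2]]
    x_lo, x_hi = int(xs[:, 0].min()), int(xs[:, 0].max())
    rx = (x_hi - x_lo) / 2
    cx = (x_hi + x_lo) / 2
    tumor_seeds = [
        center,
        (int(round(cx - 0.85 * rx)), center[1], center[2]),
        (int(round(cx + 0.85 * rx)), center[1], center[2]),
    ]
    tumor_seeds = [s for s in dict.fromkeys(tumor_seeds) if mask[s]]
    shape = mask.shape
    corners = [
        (1, 1, 1),
        (shape[0] - 2, shape[1] - 2, shape[2] - 2),
        (1, shape[1] - 2, shape[2] - 2),
        (shape[0] - 2, 1, 1),
    ]
    background_seeds = [c for c in corners if not mask[c]][:n_background]
    return SeedSet(tumor_seeds=tumor_seeds, background_seeds=background_seeds)


def write_cohort(cases: Iterable[LabeledCase], out_dir: str | Path, params: PhantomParams | None = None) -> Path:
    """Write volumes/masks as .nii.gz plus a CSV manifest; returns manifest path."""
    out_dir = Path(out_dir)
    (out_dir / "volumes").mkdir(parents=True, exist_ok=True)
    rows = []
    for case in cases:
        vpath = out_dir / "volumes" / f"{case.case_id}.nii.gz"
        mpath = out_dir / "volumes" / f"{case.case_id}_mask.nii.gz"
        write_volume(case.volume, vpath)
        write_mask(case.truth_mask, mpath, spacing=case.volume.voxel_spacing_mm)
        rows.append(
            {
                "case_id": case.case_id,
                "label": case.label,
                "adc_value": case.adc_value if case.adc_value is not None else "",
                "volume_path": str(vpath.relative_to(out_dir)),
                "mask_path": str(mpath.relative_to(out_dir)),
            }
        )
    manifest = out_dir / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    if params is not None:
        with open(out_dir / "phantom_params.yaml", "w") as fh:
            yaml.safe_dump(asdict(params), fh, sort_keys=True)
    return manifest


def load_cohort(manifest_path: str | Path) -> list[LabeledCase]:
    """Load a cohort previously written by :func:`write_cohort`."""
    from .volume_io import read_mask, read_volume

    manifest_path = Path(manifest_path)
    base = manifest_path.parent
    df = pd.read_csv(manifest_path)
    cases = []
    for _, row in df.iterrows():
        adc = row.get("adc_value")
        adc = None if pd.isna(adc) or adc == "" else float(adc)
        cases.append(
            LabeledCase(
                case_id=str(row["case_id"]),
                volume=read_volume(base / row["volume_path"]),
                truth_mask=read_mask(base / row["mask_path"], source="ground_truth"),
                adc_value=adc,
                label=str(row["label"]),
            )
        )
    return cases
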