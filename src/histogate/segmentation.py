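"""Seed-based 3D tumor segmentation.

The segmenter only has to be good enough to support histogram extraction: a
moderately accurate whole-tumor mask changes the normalized histogram very
little. The algorithm is an intensity-model region growing:

* Each seed contributes an intensity *mode*: the mean of its 3x3x3
  neighborhood. Tumor seeds may sit in visually distinct compartments (e.g.
  a glioblastoma's bright rim and dark core), so the tumor model is the set
  of tumor-seed modes rather than one pooled mean.
* A voxel is *acceptable* when (a) it is strictly closer in intensity to the
  nearest tumor mode than to the nearest background mode, and (b) it lies
  within ``tolerance * sigma`` of the nearest tumor mode, where ``sigma`` is
  the pooled within-neighborhood standard deviation of the tumor seeds
  (floored at 1 luminance unit so noiseless images remain well defined).
* The output mask is grown from the tumor seeds through the acceptable set
  by iterative 26-connected dilation (equivalent to a FIFO flood fill),
  which makes the result deterministic and monotone in ``tolerance``.

Tumor seeds are always included; background seeds never are.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .volume_io import SeedSet, TumorMask, Volume

__all__ = ["segment_tumor", "dice"]

_STRUCT_26 = np.ones((3, 3, 3), dtype=bool)


def _neighborhood_stats(data: np.ndarray, coord: tuple[int, int, int]) -> tuple[float, float]:
    sl = tuple(slice(max(c - 1, 0), min(c + 2, n)) for c, n in zip(coord, data.shape))
    patch = data[sl].astype(float)
    return float(patch.mean()), float(patch.std())


def segment_tumor(
    v: Volume,
    seeds: SeedSet,
    tolerance: float = 2.5,
    max_iters: int | None = None,
) -> TumorMask:
    """Grow a tumor mask from seeds; deterministic for fixed inputs.

    Parameters
    ----------
    v : Volume
        Structural volume (any bit depth).
    seeds : SeedSet
        Nonempty tumor and background seed lists, inside the volume.
    tolerance : float
        Acceptance band half-width in units of the pooled tumor-seed
        neighborhood standard deviation. Larger values never shrink the mask.
    max_iters : int, optional
        Cap on dilation sweeps; default is the voxel count (full convergence).
    """
    if tolerance <= 0:
        raise ValueError("tolerance must be positive")
    data = np.asarray(v.data)
    seeds.validate_bounds(data.shape)
    if max_iters is None:
        max_iters = int(data.size)

    tumor_stats = [_neighborhood_stats(data, s) for s in seeds.tumor_seeds]
    bg_stats = [_neighborhood_stats(data, s) for s in seeds.background_seeds]
    tumor_modes = np.array([m for m, _ in tumor_stats])
    bg_modes = np.array([m for m, _ in bg_stats])
    if np.min(np.abs(tumor_modes[:, None] - bg_modes[None, :])) < 1e-9:
        raise ValueError(
            "tumor and background seed intensity models coincide; "
            "place seeds in regions of distinct intensity (more seeds may help)"
        )
    sigma = max(float(np.sqrt(np.mean([sd**2 for _, sd in tumor_stats]))), 1.0)

    dist = data.astype(float)[..., None]
    d_tumor = np.min(np.abs(dist - tumor_modes), axis=-1)
    d_bg = np.min(np.abs(dist - bg_modes), axis=-1)
    accept = (d_tumor < d_bg) & (d_tumor <= tolerance * sigma)
    for s in seeds.background_seeds:
        accept[s] = False
    for s in seeds.tumor_seeds:
        accept[s] = True

    region = np.zeros_like(accept)
    for s in seeds.tumor_seeds:
        region[s] = True
    for _ in range(max_iters):
        grown = ndimage.binary_dilation(region, structure=_STRUCT_26) & accept
        grown |= region
        if np.array_equal(grown, region):
            break
        region = grown
    return TumorMask(data=region, source="segmented")


def dice(a: TumorMask, b: TumorMask) -> float:
    """Dice overlap ``2|A∩B| / (|A|+|B|)``; 1.0 iff identical nonempty masks."""
    if a.shape != b.shape:
        raise ValueError(f"mask shapes differ: {a.shape} vs {b.shape}")
    na, nb = a.n_voxels, b.n_voxels
    if na == 0 and nb == 0:
        raise ValueError("Dice is undefined for two empty masks")
    inter = int((a.data & b.data).sum())
    return 2.0 * inter / (na + nb)
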