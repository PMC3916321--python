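"""Regional homogeneity (ReHo): voxelwise Kendall's coefficient of concordance.

For every in-mask voxel, the time series of the voxel and its stencil
neighbors (6 face, 18 face+edge, or 26 full neighbors) are ranked in time
and their concordance measured by Kendall's W:

    W = 12 * sum_i (R_i - Rbar)^2 / (k^2 (n^3 - n))

where ``r_ij`` is the rank of time point ``i`` within series ``j``,
``R_i = sum_j r_ij`` the rank sum of time point ``i``, ``Rbar = k(n+1)/2``
the mean rank sum, ``k`` the number of series (27 for an interior voxel with
the full stencil) and ``n`` the number of time points.  W is 1 when all
series rise and fall in lockstep and 0 under perfect discordance.

Ties receive average ranks and W is computed with the no-tie denominator
(tie inflation is clamped at 1); continuous BOLD data make exact ties a
measure-zero event.

A subject-level ReHo map is normalized by its whole-brain-mask mean (mReHo,
mask mean exactly 1) before spatial smoothing, and smoothing is restricted
to the mask with kernel renormalization so that zeros outside the brain do
not bleed into edge voxels.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import ndimage, stats

from .io import Scan4D, voxel_sizes_mm

__all__ = [
    "NeighborhoodSpec",
    "ReHoMap",
    "FWHM_PER_SIGMA",
    "fwhm_to_sigma",
    "rank_time_series",
    "kendall_w",
    "reho_map",
    "normalize_reho",
    "gaussian_smooth",
    "stencil_offsets",
]

#: FWHM = sigma * 2*sqrt(2*ln 2)
FWHM_PER_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))


def fwhm_to_sigma(fwhm_mm: float) -> float:
    """Gaussian sigma (mm) for a given full width at half maximum (mm)."""
    return float(fwhm_mm) / FWHM_PER_SIGMA


@dataclasses.dataclass
class NeighborhoodSpec:
    """Voxel neighborhood over which concordance is computed.

    ``stencil`` counts the neighbors around the center voxel (6, 18 or 26);
    ``edge_policy`` controls mask-boundary behavior: ``"shrink"`` uses the
    in-mask neighbors that exist (k = their count + 1), ``"exclude"`` drops
    voxels whose neighborhood is not fully inside the mask.
    """

    stencil: int = 26
    edge_policy: str = "shrink"

    def __post_init__(self) -> None:
        if self.stencil not in (6, 18, 26):
            raise ValueError(f"stencil must be 6, 18 or 26, got {self.stencil}")
        if self.edge_policy not in ("shrink", "exclude"):
            raise ValueError("edge_policy must be 'shrink' or 'exclude'")


@dataclasses.dataclass
class ReHoMap:
    """Voxelwise Kendall's W with bookkeeping of normalization/smoothing."""

    values: np.ndarray
    mask: np.ndarray
    affine: np.ndarray
    normalized: bool = False
    smoothed_fwhm_mm: float | None = None
    #: per-voxel number of series k that entered the concordance
    k_map: np.ndarray | None = None


def stencil_offsets(stencil: int) -> list[tuple[int, int, int]]:
    """Neighbor offsets for a 6/18/26 stencil (center excluded)."""
    offsets = []
    for dx in (-1, 0, 1):
        for dy in (-1, 0, 1):
            for dz in (-1, 0, 1):
                order = abs(dx) + abs(dy) + abs(dz)
                if order == 0:
                    continue
                if stencil == 6 and order > 1:
                    continue
                if stencil == 18 and order > 2:
                    continue
                offsets.append((dx, dy, dz))
    return offsets


def rank_time_series(series: np.ndarray) -> np.ndarray:
    """Ranks 1..n along the last axis; ties get average ranks."""
    series = np.asarray(series)
    if series.shape[-1] < 2:
        raise ValueError("ranking requires at least 2 time points")
    return stats.rankdata(series, axis=-1)


def kendall_w(ranks: np.ndarray) -> float:
    """Kendall's coefficient of concordance of a rank matrix.

    Parameters
    ----------
    ranks:
        ``(n, k)`` matrix; entry ``(i, j)`` is the rank of time point ``i``
        within series ``j``.
    """
    ranks = np.asarray(ranks, dtype=np.float64)
    if ranks.ndim != 2:
        raise ValueError("ranks must be a (n_timepoints, k_series) matrix")
    n, k = ranks.shape
    if k < 2:
        raise ValueError(f"concordance is undefined for k={k} series (need k >= 2)")
    if n < 2:
        raise ValueError(f"need at least 2 time points, got n={n}")
    row_sums = ranks.sum(axis=1)
    mean_rank = k * (n + 1) / 2.0
    s = float(((row_sums - mean_rank) ** 2).sum())
    w = 12.0 * s / (k * k * (n**3 - n))
    return float(np.clip(w, 0.0, 1.0))


def reho_map(
    scan: Scan4D,
    mask: np.ndarray,
    spec: NeighborhoodSpec | None = None,
) -> ReHoMap:
    """Kendall's W over the stencil neighborhood of every in-mask voxel.

    The scan should already be temporally preprocessed.  Voxels outside the
    mask get value 0.  Under ``edge_policy="shrink"`` the neighborhood at
    mask boundaries is restricted to in-mask voxels (k = count + 1, never
    below 2); under ``"exclude"`` boundary voxels are removed from the map's
    mask.
    """
    spec = spec or NeighborhoodSpec()
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != scan.shape3d:
        raise ValueError(
            f"mask grid {mask.shape} does not match scan grid {scan.shape3d}"
        )
    data = np.asarray(scan.data, dtype=np.float64)
    n = data.shape[-1]
    if n < 2:
        raise ValueError("need at least 2 time points")

    # Rank every in-mask voxel's series once, then accumulate neighborhood
    # rank sums R_i over the stencil.
    ranks = np.zeros(data.shape)
    ranks[mask] = _rank_rows(data[mask])

    offsets = stencil_offsets(spec.stencil)
    if spec.stencil == 26:
        # full 3x3x3 box including the center: exact separable sliding sum
        rank_sums = _box_sum(ranks, n_spatial_axes=3)
        k_map = _box_sum(mask.astype(np.int64), n_spatial_axes=3)
    else:
        rank_sums = ranks.copy()  # center voxel contribution
        k_map = mask.astype(np.int64)
        for off in offsets:
            rank_sums += _shift4d(ranks, off)
            k_map += _shift3d(mask.astype(np.int64), off)

    k_in = k_map[mask].astype(np.float64)
    mean_rank = k_in * (n + 1) / 2.0
    s = ((rank_sums[mask] - mean_rank[:, None]) ** 2).sum(axis=-1)
    with np.errstate(divide="ignore", invalid="ignore"):
        w_in = 12.0 * s / (k_in * k_in * (n**3 - n))
    w = np.zeros(mask.shape)
    w[mask] = np.clip(np.nan_to_num(w_in, nan=0.0, posinf=0.0), 0.0, 1.0)

    out_mask = mask.copy()
    if spec.edge_policy == "exclude":
        out_mask &= k_map == (len(offsets) + 1)
    else:
        out_mask &= k_map >= 2  # lone voxels have no concordance partner
    w[~out_mask] = 0.0
    return ReHoMap(values=w, mask=out_mask, affine=scan.affine.copy(), k_map=k_map)


def _rank_rows(rows: np.ndarray) -> np.ndarray:
    """Ranks 1..n along the last axis of a 2D array; average ranks at ties.

    Fast path via argsort for the (typical) tie-free continuous series, with
    a scipy ``rankdata`` fallback on rows containing ties.
    """
    n = rows.shape[-1]
    order = np.argsort(rows, axis=-1, kind="stable")
    ranks = np.empty(rows.shape)
    np.put_along_axis(ranks, order, np.arange(1.0, n + 1.0), axis=-1)
    sorted_vals = np.take_along_axis(rows, order, axis=-1)
    tied = (np.diff(sorted_vals, axis=-1) == 0).any(axis=-1)
    if tied.any():
        ranks[tied] = stats.rankdata(rows[tied], axis=-1)
    return ranks


def _box_sum(arr: np.ndarray, n_spatial_axes: int = 3) -> np.ndarray:
    """Exact 3-point sliding sum (zero padded) along each spatial axis."""
    out = arr
    for axis in range(n_spatial_axes):
        size = out.shape[axis]
        acc = out.copy()

        def sl(a, b):
            idx = [slice(None)] * out.ndim
            idx[axis] = slice(a, b)
            return tuple(idx)

        acc[sl(1, size)] += out[sl(0, size - 1)]
        acc[sl(0, size - 1)] += out[sl(1, size)]
        out = acc
    return out


def _shift4d(arr: np.ndarray, off: tuple[int, int, int]) -> np.ndarray:
    out = np.zeros_like(arr)
    src = []
    dst = []
    for axis, d in enumerate(off):
        size = arr.shape[axis]
        if d >= 0:
            src.append(slice(0, size - d))
            dst.append(slice(d, size))
        else:
            src.append(slice(-d, size))
            dst.append(slice(0, size + d))
    out[tuple(dst)] = arr[tuple(src)]
    return out


def _shift3d(arr: np.ndarray, off: tuple[int, int, int]) -> np.ndarray:
    return _shift4d(arr, off)


def normalize_reho(rmap: ReHoMap, mask: np.ndarray | None = None) -> ReHoMap:
    """Divide by the whole-brain-mask mean so the mask mean becomes 1 (mReHo)."""
    if rmap.normalized:
        raise ValueError("map is already normalized")
    mask = rmap.mask if mask is None else (np.asarray(mask, bool) & rmap.mask)
    mean = float(rmap.values[mask].mean()) if mask.any() else 0.0
    if mean <= 0:
        raise ValueError(f"whole-brain mean KCC is {mean}; cannot normalize")
    values = np.where(mask, rmap.values / mean, 0.0)
    return ReHoMap(
        values=values,
        mask=mask,
        affine=rmap.affine,
        normalized=True,
        smoothed_fwhm_mm=rmap.smoothed_fwhm_mm,
        k_map=rmap.k_map,
    )


def gaussian_smooth(rmap: ReHoMap, fwhm_mm: float) -> ReHoMap:
    """Smooth with a 3D Gaussian kernel of the given FWHM (mm), inside the mask.

    sigma per axis is ``fwhm / (2*sqrt(2 ln 2))`` converted to voxel units
    from the affine.  The convolution is renormalized by the smoothed mask so
    edge voxels average only over in-mask neighbors.
    """
    if fwhm_mm < 0:
        raise ValueError(f"fwhm_mm must be nonnegative, got {fwhm_mm}")
    if fwhm_mm == 0:
        return dataclasses.replace(rmap, smoothed_fwhm_mm=0.0)
    sigma_vox = fwhm_to_sigma(fwhm_mm) / voxel_sizes_mm(rmap.affine)
    mask = rmap.mask.astype(np.float64)
    num = ndimage.gaussian_filter(rmap.values * mask, sigma=sigma_vox)
    den = ndimage.gaussian_filter(mask, sigma=sigma_vox)
    with np.errstate(divide="ignore", invalid="ignore"):
        smoothed = np.where(rmap.mask, num / den, 0.0)
    return ReHoMap(
        values=np.nan_to_num(smoothed),
        mask=rmap.mask,
        affine=rmap.affine,
        normalized=rmap.normalized,
        smoothed_fwhm_mm=float(fwhm_mm),
        k_map=rmap.k_map,
    )
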