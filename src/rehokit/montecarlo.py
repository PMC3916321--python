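"""Monte Carlo cluster-extent correction (AlphaSim-style) and cluster reporting.

Family-wise control of voxelwise tests at a lenient per-voxel threshold is
obtained by requiring suprathreshold voxels to form a contiguous cluster at
least ``k_min`` voxels large, where ``k_min`` is calibrated by simulation:
repeatedly generate Gaussian white noise on the analysis grid, smooth it to
the nominal FWHM, standardize over the mask, threshold at the two-sided
per-voxel p, and record the largest connected component.  ``k_min`` for a
corrected level alpha is the smallest extent whose exceedance frequency in
the null distribution is at most alpha.

Positive and negative clusters are labeled separately (group differences
carry a sign) and the null records the maximum component over both tails.
Following the classical AlphaSim convention, ``voxel_p`` is the
suprathreshold probability *per tail* (threshold at the one-sided Gaussian
quantile); ``tail_convention="split"`` instead halves ``voxel_p`` across
the two tails.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy import stats as sps

from .io import voxel_sizes_mm
from .reho import ReHoMap, fwhm_to_sigma
from .stats import TMap

__all__ = [
    "McParams",
    "NullMaxClusterDist",
    "simulate_null_max_cluster",
    "cluster_threshold_for_alpha",
    "label_clusters",
    "cluster_report",
    "connectivity_structure",
]


@dataclasses.dataclass
class McParams:
    """Monte Carlo null-simulation settings.

    Defaults are the classical AlphaSim inputs for a 3-mm grid: two-sided
    per-voxel p of 0.01, 1000 iterations, 8-mm nominal smoothness, corrected
    alpha 0.05.
    """

    mask: np.ndarray
    voxel_size_mm: float | tuple[float, float, float] = 3.0
    voxel_p: float = 0.01
    n_iterations: int = 1000
    fwhm_mm: float = 8.0
    connectivity: int = 18
    alpha: float = 0.05
    seed: int = 0
    #: "per-tail": voxel_p is the suprathreshold probability of each tail
    #: (AlphaSim convention); "split": voxel_p is shared across both tails.
    tail_convention: str = "per-tail"

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if not (0 < self.voxel_p < 1):
            raise ValueError("voxel_p must lie in (0, 1)")
        if self.n_iterations < 100:
            raise ValueError("n_iterations must be at least 100")
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must lie in (0, 1)")
        if self.connectivity not in (6, 18, 26):
            raise ValueError("connectivity must be 6, 18 or 26")
        if self.tail_convention not in ("per-tail", "split"):
            raise ValueError("tail_convention must be 'per-tail' or 'split'")

    @property
    def tail_p(self) -> float:
        """Suprathreshold probability of each tail."""
        return self.voxel_p if self.tail_convention == "per-tail" else self.voxel_p / 2.0

    @property
    def voxel_sizes(self) -> np.ndarray:
        return np.broadcast_to(np.asarray(self.voxel_size_mm, float), (3,)).astype(float)

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.voxel_sizes))


@dataclasses.dataclass
class NullMaxClusterDist:
    """Per-iteration maximum suprathreshold cluster sizes under the null."""

    max_sizes: np.ndarray
    params_voxel_p: float
    params_fwhm_mm: float
    voxel_volume_mm3: float
    #: suprathreshold voxels per iteration, both tails (None for synthetic dists)
    suprathreshold_counts: np.ndarray | None = None

    def k_min(self, alpha: float) -> int:
        return cluster_threshold_for_alpha(self, alpha)

    def min_volume_mm3(self, alpha: float) -> float:
        return self.k_min(alpha) * self.voxel_volume_mm3

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "iteration": np.arange(len(self.max_sizes)),
                "max_cluster_voxels": self.max_sizes,
            }
        )


def connectivity_structure(connectivity: int) -> np.ndarray:
    """3x3x3 binary adjacency footprint for 6/18/26 connectivity."""
    rank = {6: 1, 18: 2, 26: 3}[connectivity]
    return ndimage.generate_binary_structure(3, rank)


def simulate_null_max_cluster(params: McParams) -> NullMaxClusterDist:
    """Null distribution of the maximum cluster extent under smoothed noise.

    Each iteration draws white Gaussian noise on the full grid, smooths it
    with the nominal FWHM, standardizes by its in-mask sample mean/SD (so
    the voxel threshold is exact regardless of the variance change induced
    by smoothing), thresholds both tails at the per-tail probability and
    records the largest connected component over both tails.
    """
    mask = params.mask
    if not mask.any():
        raise ValueError("mask is empty")
    sigma_vox = fwhm_to_sigma(params.fwhm_mm) / params.voxel_sizes
    if params.fwhm_mm > 0 and np.any(sigma_vox * 2.354820045 < 1.0):
        warnings.warn(
            "FWHM is smaller than the voxel size; null noise is effectively "
            "unsmoothed",
            stacklevel=2,
        )
    z_thr = float(sps.norm.isf(params.tail_p))
    structure = connectivity_structure(params.connectivity)
    rng = np.random.default_rng(params.seed)

    max_sizes = np.zeros(params.n_iterations, dtype=np.int64)
    counts = np.zeros(params.n_iterations, dtype=np.int64)
    for it in range(params.n_iterations):
        field = rng.standard_normal(mask.shape)
        if params.fwhm_mm > 0:
            field = ndimage.gaussian_filter(field, sigma=sigma_vox)
        vals = field[mask]
        field = (field - vals.mean()) / vals.std()
        best = 0
        for tail in (field > z_thr, field < -z_thr):
            supra = tail & mask
            counts[it] += int(supra.sum())
            labeled, n = ndimage.label(supra, structure=structure)
            if n:
                sizes = np.bincount(labeled.ravel())[1:]
                best = max(best, int(sizes.max()))
        max_sizes[it] = best
    return NullMaxClusterDist(
        max_sizes=max_sizes,
        params_voxel_p=params.voxel_p,
        params_fwhm_mm=params.fwhm_mm,
        voxel_volume_mm3=params.voxel_volume_mm3,
        suprathreshold_counts=counts,
    )


def cluster_threshold_for_alpha(dist: NullMaxClusterDist, alpha: float) -> int:
    """Smallest extent k whose null exceedance frequency is at most alpha."""
    sizes = np.asarray(dist.max_sizes)
    if sizes.size == 0:
        raise ValueError("null distribution is empty")
    if alpha < 1.0 / sizes.size:
        raise ValueError(
            f"alpha={alpha} is below the 1/{sizes.size} resolution of the "
            "null distribution; increase n_iterations"
        )
    for k in range(1, int(sizes.max()) + 2):
        if (sizes >= k).mean() <= alpha:
            return k
    raise AssertionError("unreachable: exceedance fraction reaches 0")


def label_clusters(
    stat_map: TMap | np.ndarray,
    mask: np.ndarray,
    voxel_threshold: float,
    connectivity: int = 18,
) -> tuple[np.ndarray, int]:
    """Connected components of ``|t| > voxel_threshold``, tails kept separate.

    Returns ``(labels, n_clusters)``; labels are 1..n ordered by descending
    extent, ties broken by the first voxel index in array order.  A voxel in
    a positive-tail cluster never joins a negative-tail cluster.
    """
    t = stat_map.t if isinstance(stat_map, TMap) else np.asarray(stat_map, float)
    mask = np.asarray(mask, dtype=bool)
    if t.shape != mask.shape:
        raise ValueError(f"stat map grid {t.shape} does not match mask {mask.shape}")
    if voxel_threshold <= 0:
        raise ValueError("voxel_threshold must be positive (applied to |t|)")
    structure = connectivity_structure(connectivity)

    components = []
    for tail_mask in ((t > voxel_threshold) & mask, (t < -voxel_threshold) & mask):
        labeled, n = ndimage.label(tail_mask, structure=structure)
        for lab in range(1, n + 1):
            comp = labeled == lab
            first_idx = int(np.flatnonzero(comp.ravel())[0])
            components.append((int(comp.sum()), first_idx, comp))
    components.sort(key=lambda c: (-c[0], c[1]))

    labels = np.zeros(t.shape, dtype=np.int32)
    for new_label, (_, _, comp) in enumerate(components, start=1):
        labels[comp] = new_label
    return labels, len(components)


def cluster_report(
    labels: np.ndarray,
    stat_map: TMap,
    affine: np.ndarray,
    k_min: int = 1,
    group_maps: dict[str, list[ReHoMap]] | None = None,
) -> pd.DataFrame:
    """Tabulate suprathreshold clusters surviving the extent threshold.

    One row per cluster with extent (voxels and mm^3), the signed peak t and
    its world coordinate (``affine @ (i, j, k, 1)``), and — when per-group
    subject maps are supplied — each group's mean normalized ReHo (mean ± sd
    of subject means) over the cluster.
    """
    labels = np.asarray(labels)
    t = stat_map.t
    if labels.shape != t.shape:
        raise ValueError("labels and stat map must share a grid")
    affine = np.asarray(affine, dtype=float)
    voxel_volume = float(abs(np.linalg.det(affine[:3, :3])))

    rows = []
    for lab in np.unique(labels[labels > 0]):
        comp = labels == lab
        extent = int(comp.sum())
        if extent < k_min:
            continue
        idx = np.argwhere(comp)
        peak_local = np.abs(t[comp]).argmax()
        peak_ijk = idx[peak_local]
        peak_t = float(t[tuple(peak_ijk)])
        world = affine @ np.array([*peak_ijk, 1.0])
        row = {
            "label": int(lab),
            "extent_voxels": extent,
            "volume_mm3": extent * voxel_volume,
            "peak_t": peak_t,
            "peak_i": int(peak_ijk[0]),
            "peak_j": int(peak_ijk[1]),
            "peak_k": int(peak_ijk[2]),
            "peak_x_mm": float(world[0]),
            "peak_y_mm": float(world[1]),
            "peak_z_mm": float(world[2]),
        }
        if group_maps:
            for group, maps in group_maps.items():
                subject_means = [float(m.values[comp].mean()) for m in maps]
                row[f"mean_mreho_{group}"] = float(np.mean(subject_means))
                row[f"sd_mreho_{group}"] = float(np.std(subject_means, ddof=1))
        rows.append(row)
    columns = [
        "label",
        "extent_voxels",
        "volume_mm3",
        "peak_t",
        "peak_i",
        "peak_j",
        "peak_k",
        "peak_x_mm",
        "peak_y_mm",
        "peak_z_mm",
    ]
    if group_maps:
        for group in group_maps:
            columns += [f"mean_mreho_{group}", f"sd_mreho_{group}"]
    return pd.DataFrame(rows, columns=columns)
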