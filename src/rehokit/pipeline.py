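"""End-to-end orchestration: scans -> ReHo maps -> group t-map -> clusters.

``run_pipeline`` executes the full analysis for a cohort on disk —
temporal preprocessing, voxelwise Kendall's W, whole-brain-mean
normalization, spatial smoothing, the covariate-adjusted group t-test, the
Monte Carlo cluster-extent threshold and the cluster report — and writes a
reproducibility manifest (config snapshot, content hashes, stage timings).
The per-subject stages are also exposed as :func:`subject_mreho` for
library use on in-memory scans.
"""

from __future__ import annotations

import dataclasses
import json
import time
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import stats as sps

from . import __version__
from .io import (
    Scan4D,
    array_sha256,
    read_mask,
    read_metadata,
    read_scan,
    write_map,
)
from .montecarlo import (
    McParams,
    cluster_report,
    cluster_threshold_for_alpha,
    label_clusters,
    simulate_null_max_cluster,
)
from .preprocess import PreprocessParams, preprocess_scan
from .reho import NeighborhoodSpec, ReHoMap, gaussian_smooth, normalize_reho, reho_map
from .stats import (
    build_design_matrix,
    demographics_table,
    fdr_correct,
    glm_group_ttest,
    one_sample_ttest_map,
)

__all__ = ["PipelineConfig", "RunManifest", "subject_mreho", "run_pipeline"]


@dataclasses.dataclass
class PipelineConfig:
    """Everything a full run needs; loadable from a YAML file."""

    scan_paths: list[str]
    mask_path: str
    metadata_path: str
    out_dir: str
    preprocess: PreprocessParams = dataclasses.field(default_factory=PreprocessParams)
    neighborhood: NeighborhoodSpec = dataclasses.field(default_factory=NeighborhoodSpec)
    smooth_fwhm_mm: float = 8.0
    covariates: tuple[str, ...] = ("age_y", "education_y")
    voxel_p: float = 0.01
    mc_iterations: int = 1000
    mc_fwhm_mm: float = 8.0
    connectivity: int = 18
    alpha: float = 0.05
    seed: int = 0
    tr_s: float | None = None
    tail_convention: str = "per-tail"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if "preprocess" in raw:
            raw["preprocess"] = PreprocessParams(**raw["preprocess"])
        if "neighborhood" in raw:
            raw["neighborhood"] = NeighborhoodSpec(**raw["neighborhood"])
        if "covariates" in raw:
            raw["covariates"] = tuple(raw["covariates"])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["covariates"] = list(self.covariates)
        return d


@dataclasses.dataclass
class RunManifest:
    """Reproducibility record written next to the outputs."""

    config: dict
    version: str
    started: str
    finished: str
    stage_seconds: dict
    hashes: dict
    k_min_voxels: int
    min_cluster_volume_mm3: float
    n_clusters_reported: int

    def write(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(dataclasses.asdict(self), indent=2))
        return path


def subject_mreho(
    scan: Scan4D,
    mask: np.ndarray,
    preprocess: PreprocessParams | None = None,
    neighborhood: NeighborhoodSpec | None = None,
    smooth_fwhm_mm: float = 8.0,
) -> ReHoMap:
    """Preprocess one scan and return its smoothed, normalized ReHo map.

    Order of operations: discard/detrend/band-pass, Kendall's W over the
    stencil, division by the whole-brain mean of the *unsmoothed* map, then
    Gaussian smoothing inside the mask.
    """
    pre = preprocess_scan(scan, preprocess, mask=mask)
    rmap = reho_map(pre, mask, neighborhood)
    rmap = normalize_reho(rmap)
    if smooth_fwhm_mm > 0:
        rmap = gaussian_smooth(rmap, smooth_fwhm_mm)
    return rmap


def cohort_mreho(
    sim_config,
    preprocess: PreprocessParams | None = None,
    neighborhood: NeighborhoodSpec | None = None,
    smooth_fwhm_mm: float = 8.0,
):
    """Simulate a cohort and return its smoothed mReHo maps without file I/O.

    Scans are generated one at a time and discarded after their map is
    computed, so memory stays at one 4D volume.  Returns
    ``(maps, metadata, mask, affine)`` with maps in metadata row order.
    """
    from .synthetic import _cohort_metadata, _subject_seed, generate_subject_scan

    meta_rng = np.random.default_rng(np.random.SeedSequence((sim_config.seed, 999983)))
    meta = _cohort_metadata(sim_config, meta_rng)
    mask = sim_config.brain_mask()
    maps = []
    for index, row in meta.iterrows():
        scan = generate_subject_scan(
            sim_config, row["group"], _subject_seed(sim_config.seed, int(index))
        )
        maps.append(
            subject_mreho(
                scan,
                mask,
                preprocess=preprocess,
                neighborhood=neighborhood,
                smooth_fwhm_mm=smooth_fwhm_mm,
            )
        )
    return maps, meta, mask, sim_config.affine()


def run_pipeline(config: PipelineConfig) -> RunManifest:
    """Run the complete group analysis described by ``config``.

    Outputs written to ``config.out_dir``: the group t-map
    (``group_tmap.nii.gz`` plus a df sidecar), within-group one-sample
    t-maps with their FDR(q=0.01) rejection masks, per-iteration null
    maximum cluster sizes (``null_max_cluster.tsv``) with a k_min summary,
    the surviving-cluster table (``clusters.tsv``), a demographics
    comparison (``demographics.tsv``) and ``manifest.json``.
    """
    started = time.strftime("%Y-%m-%dT%H:%M:%S")
    t0 = time.time()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    stage_seconds: dict[str, float] = {}
    hashes: dict[str, str] = {}

    mask, mask_affine = read_mask(config.mask_path)
    meta = read_metadata(config.metadata_path)
    if len(meta) != len(config.scan_paths):
        raise ValueError(
            f"{len(config.scan_paths)} scans but {len(meta)} metadata rows"
        )

    mreho_maps: list[ReHoMap] = []
    t_stage = time.time()
    for path, (_, row) in zip(config.scan_paths, meta.iterrows()):
        try:
            scan = read_scan(path, tr_s=config.tr_s)
            mreho_maps.append(
                subject_mreho(
                    scan,
                    mask,
                    preprocess=config.preprocess,
                    neighborhood=config.neighborhood,
                    smooth_fwhm_mm=config.smooth_fwhm_mm,
                )
            )
        except Exception as exc:
            raise RuntimeError(
                f"stage 'subject_mreho' failed for subject {row['id']!r} ({path}): {exc}"
            ) from exc
    stage_seconds["subject_mreho"] = time.time() - t_stage

    t_stage = time.time()
    design = build_design_matrix(meta, covariates=config.covariates)
    tmap = glm_group_ttest(mreho_maps, design, mask)
    stage_seconds["glm_group_ttest"] = time.time() - t_stage
    write_map(tmap.t, mask_affine, out_dir / "group_tmap.nii.gz")
    (out_dir / "group_tmap_df.txt").write_text(
        f"df\t{tmap.df}\ncontrast\t{tmap.contrast}\n"
    )
    hashes["group_tmap"] = array_sha256(tmap.t)

    # within-group one-sample maps (mReHo vs the normalized baseline 1),
    # FDR-thresholded at q = 0.01
    t_stage = time.time()
    groups = list(meta["group"].unique())
    for g in groups:
        g_maps = [m for m, (_, row) in zip(mreho_maps, meta.iterrows()) if row["group"] == g]
        if len(g_maps) < 2:
            continue
        one = one_sample_ttest_map(g_maps, null_value=1.0, mask=mask)
        write_map(one.t, mask_affine, out_dir / f"onesample_{g}_tmap.nii.gz")
        finite = np.isfinite(one.t[mask])
        p_vals = np.ones(int(mask.sum()))
        p_vals[finite] = 2 * sps.t.sf(np.abs(one.t[mask][finite]), one.df)
        reject = np.zeros(mask.shape, dtype=np.uint8)
        reject[mask] = fdr_correct(p_vals, q=0.01)
        write_map(reject, mask_affine, out_dir / f"onesample_{g}_fdr01_mask.nii.gz")
    stage_seconds["one_sample_maps"] = time.time() - t_stage

    t_stage = time.time()
    mc = McParams(
        mask=mask,
        voxel_size_mm=tuple(np.sqrt((mask_affine[:3, :3] ** 2).sum(axis=0))),
        voxel_p=config.voxel_p,
        n_iterations=config.mc_iterations,
        fwhm_mm=config.mc_fwhm_mm,
        connectivity=config.connectivity,
        alpha=config.alpha,
        seed=config.seed,
        tail_convention=config.tail_convention,
    )
    null_dist = simulate_null_max_cluster(mc)
    k_min = cluster_threshold_for_alpha(null_dist, config.alpha)
    stage_seconds["monte_carlo"] = time.time() - t_stage
    null_dist.to_frame().to_csv(out_dir / "null_max_cluster.tsv", sep="\t", index=False)
    summary = {
        str(a): cluster_threshold_for_alpha(null_dist, a)
        for a in (0.05, 0.01)
        if a >= 1.0 / config.mc_iterations
    }
    (out_dir / "null_summary.txt").write_text(
        "".join(
            f"alpha\t{a}\tk_min_voxels\t{k}\tmin_volume_mm3\t{k * mc.voxel_volume_mm3}\n"
            for a, k in summary.items()
        )
    )

    t_stage = time.time()
    t_thr = float(sps.t.isf(mc.tail_p, tmap.df))
    labels, _ = label_clusters(tmap, mask, t_thr, config.connectivity)
    group_maps = {
        g: [m for m, (_, row) in zip(mreho_maps, meta.iterrows()) if row["group"] == g]
        for g in meta["group"].unique()
    }
    clusters = cluster_report(labels, tmap, mask_affine, k_min=k_min, group_maps=group_maps)
    stage_seconds["cluster_report"] = time.time() - t_stage
    clusters.to_csv(out_dir / "clusters.tsv", sep="\t", index=False)

    demographics_table(meta).to_csv(out_dir / "demographics.tsv", sep="\t", index=False)

    manifest = RunManifest(
        config=config.to_dict(),
        version=__version__,
        started=started,
        finished=time.strftime("%Y-%m-%dT%H:%M:%S"),
        stage_seconds={k: round(v, 3) for k, v in stage_seconds.items()},
        hashes=hashes,
        k_min_voxels=int(k_min),
        min_cluster_volume_mm3=float(k_min * mc.voxel_volume_mm3),
        n_clusters_reported=int(len(clusters)),
    )
    manifest.write(out_dir / "manifest.json")
    stage_seconds["total"] = time.time() - t0
    return manifest
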