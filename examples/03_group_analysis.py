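"""Group comparison: covariate-adjusted voxelwise t-test on mReHo maps.

Simulates a small two-group cohort with a patient>control ROI, computes
each subject's smoothed mReHo map, fits the per-voxel OLS model
(intercept + group + age + education) and reports the group t-map and the
clusters above the per-tail p=0.01 threshold.
"""

import numpy as np
from scipy import stats as sps

from rehokit import SimConfig, build_design_matrix, glm_group_ttest, label_clusters
from rehokit.montecarlo import cluster_report
from rehokit.pipeline import cohort_mreho

config = SimConfig(n_per_group=6, seed=3)
maps, meta, mask, affine = cohort_mreho(config)

design = build_design_matrix(meta, covariates=("age_y", "education_y"))
tmap = glm_group_ttest(maps, design, mask)
print(f"fit {int(mask.sum())} voxelwise models, df = {tmap.df}")
print(f"contrast: {tmap.contrast}")

t_thr = sps.t.isf(0.01, tmap.df)  # per-tail cluster-forming threshold
labels, n = label_clusters(tmap, mask, t_thr, connectivity=18)
group_maps = {
    g: [m for m, grp in zip(maps, meta["group"]) if grp == g]
    for g in ("patient", "control")
}
table = cluster_report(labels, tmap, affine, k_min=20, group_maps=group_maps)
print(f"\nclusters with |t| > {t_thr:.2f} and extent >= 20 voxels:")
print(table.to_string(index=False))
print(
    "\nPositive peak t means patient mReHo above control after adjusting for"
    "\nage and education; the largest cluster should sit on the implanted ROI"
    "\n(center voxel (20, 23, 18), i.e. near the world origin)."
)
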