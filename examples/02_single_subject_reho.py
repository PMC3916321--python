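"""Compute one subject's ReHo map and see the implanted coherence.

Generates a single scan with a coherent ROI, runs the temporal preprocessing
(discard, detrend, 0.01-0.08 Hz band-pass), computes Kendall's W over each
voxel's 27-series neighborhood, normalizes by the whole-brain mean and
smooths, then compares mReHo inside vs outside the ROI.
"""

from rehokit import (
    NeighborhoodSpec,
    PreprocessParams,
    SimConfig,
    gaussian_smooth,
    generate_subject_scan,
    normalize_reho,
    preprocess_scan,
    reho_map,
)

config = SimConfig(group_effect={"patient": 1.6, "control": 0.0}, seed=7)
scan = generate_subject_scan(config, group="patient", subject_seed=42)
mask = config.brain_mask()

pre = preprocess_scan(scan, PreprocessParams(n_discard=10), mask=mask)
raw = reho_map(pre, mask, NeighborhoodSpec(stencil=26))
mreho = normalize_reho(raw)
smoothed = gaussian_smooth(mreho, fwhm_mm=8.0)

roi = config.roi_specs[0].voxel_mask(config.grid_shape, config.voxel_size_mm)
print(f"time points entering the ranks: n = {pre.n_volumes}")
print(f"interior neighborhood size:     k = {raw.k_map[16, 19, 16]}")
print(f"raw Kendall's W, mask mean:     {raw.values[mask].mean():.4f}")
print(f"mReHo mask mean (must be 1):    {mreho.values[mask].mean():.6f}")
print(f"smoothed mReHo inside ROI:      {smoothed.values[roi & mask].mean():.3f}")
print(f"smoothed mReHo background:      {smoothed.values[mask & ~roi].mean():.3f}")
print(
    "\nThe ROI mean sits well above the background mean because every ROI"
    "\nvoxel shares one band-limited time course - exactly the local temporal"
    "\nconcordance that Kendall's W measures."
)
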