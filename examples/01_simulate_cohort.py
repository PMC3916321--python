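"""Simulate a small resting-state cohort and look at what was generated.

Builds a two-group cohort of 4D BOLD scans on a desk-scale 3-mm grid with
one coherent-signal ROI (patients get a stronger shared in-band signal than
controls), writes NIfTI scans plus a metadata table, and prints the cohort
layout.
"""

import tempfile
from pathlib import Path

from rehokit import RoiSpec, SimConfig, generate_cohort

config = SimConfig(
    grid_shape=(24, 28, 24),
    n_volumes=80,          # full study scans use 160 volumes at TR = 3 s
    n_per_group=4,
    roi_specs=[RoiSpec(center_voxel=(15, 17, 13), radius_mm=9.0, label="roi_a")],
    group_effect={"patient": 1.6, "control": 0.0},
    seed=1,
)

out = Path(tempfile.mkdtemp(prefix="rehokit_cohort_"))
cohort = generate_cohort(config, out_dir=out)

print(f"wrote {len(cohort.scan_paths)} scans to {out}")
print(f"brain mask: {int(cohort.mask.sum())} voxels of {config.voxel_size_mm} mm")
print(cohort.metadata.to_string(index=False))
print(
    "\nEach scan holds smooth spatial noise plus a band-limited (0.01-0.08 Hz)"
    "\ntime course shared inside roi_a; the patient rows carry the stronger"
    "\namplitude, which is what the group comparison should later recover."
)
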