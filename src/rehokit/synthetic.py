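"""Synthetic resting-state BOLD cohorts with controllable regional coherence.

The generator emulates what the analysis assumes about its input: aligned
4D scans on a common MNI-style grid, containing (a) spatially smooth
Gaussian noise, independent across volumes, (b) an independent white-noise
floor per voxel, and (c) for each configured spherical region a single
band-limited (0.01-0.08 Hz) time course shared by every voxel of the
region, scaled by a per-group amplitude.  A shared in-band time course is
exactly what regional homogeneity detects, so the implanted amplitude is a
direct dial on the group ReHo difference; the white-noise floor keeps
Kendall's W strictly below 1.

Temporal autocorrelation of the BOLD signal is deliberately not modeled:
no downstream stage assumes it, and per-volume-independent noise keeps the
null calibration analytically checkable.

Cohort metadata mirrors a hemodialysis case-control table: age, sex (fixed
15:5 male:female ratio per 20 subjects), years of education, cigarettes/day
(a small minority of smokers), months on dialysis (patients only, missing
for a few outpatients) and MMSE.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .io import Scan4D, write_mask, write_metadata, write_scan
from .reho import fwhm_to_sigma

__all__ = [
    "RoiSpec",
    "SimConfig",
    "CohortResult",
    "ellipsoid_mask",
    "make_affine",
    "bandlimited_timecourse",
    "generate_subject_scan",
    "generate_cohort",
    "mni_3mm_preset",
]


@dataclasses.dataclass
class RoiSpec:
    """A spherical region carrying the implanted coherent signal."""

    center_voxel: tuple[int, int, int]
    radius_mm: float = 9.0
    label: str = "roi"

    def voxel_mask(self, shape: Sequence[int], voxel_size_mm: float) -> np.ndarray:
        center = np.asarray(self.center_voxel, dtype=float)
        radius_vox = self.radius_mm / voxel_size_mm
        lo = center - radius_vox
        hi = center + radius_vox
        if (lo < 0).any() or (hi > np.asarray(shape) - 1).any():
            raise ValueError(
                f"ROI {self.label!r} (center {self.center_voxel}, radius "
                f"{self.radius_mm} mm) does not fit inside grid {tuple(shape)}"
            )
        grids = np.ogrid[tuple(slice(0, s) for s in shape)]
        dist2 = sum((g - c) ** 2 for g, c in zip(grids, center))
        return dist2 <= radius_vox**2


@dataclasses.dataclass
class SimConfig:
    """Study conditions for a simulated cohort.

    Defaults follow the acquisition the pipeline targets — 160 volumes at
    TR = 3 s on a 3-mm isotropic grid — on a desk-scale 32x38x32 grid with
    an ellipsoidal brain mask (~15k voxels); :func:`mni_3mm_preset` switches
    to the full 61x73x61 MNI-like grid.  One default ROI carries a coherent
    signal with a larger amplitude in patients than controls.
    """

    grid_shape: tuple[int, int, int] = (32, 38, 32)
    voxel_size_mm: float = 3.0
    n_volumes: int = 160
    tr_s: float = 3.0
    noise_sd: float = 1.0
    white_noise_sd: float = 0.5
    spatial_noise_fwhm_mm: float = 6.0
    signal_band_hz: tuple[float, float] = (0.01, 0.08)
    roi_specs: list[RoiSpec] = dataclasses.field(
        default_factory=lambda: [RoiSpec(center_voxel=(20, 23, 18), radius_mm=9.0, label="roi_a")]
    )
    mask_semi_axes_vox: tuple[float, float, float] | None = None
    group_effect: dict = dataclasses.field(
        default_factory=lambda: {"patient": 1.6, "control": 0.0}
    )
    n_per_group: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.grid_shape) != 3 or any(s < 8 for s in self.grid_shape):
            raise ValueError("grid_shape must be 3 dimensions, each >= 8")
        if self.n_volumes < 20:
            raise ValueError("n_volumes must be >= 20")
        if self.tr_s <= 0:
            raise ValueError("tr_s must be positive")
        for group, amp in self.group_effect.items():
            amps = amp.values() if isinstance(amp, Mapping) else [amp]
            if any(a < 0 for a in amps):
                raise ValueError(f"amplitudes must be nonnegative ({group})")
        # fail early if any ROI falls outside the grid
        for roi in self.roi_specs:
            roi.voxel_mask(self.grid_shape, self.voxel_size_mm)

    def brain_mask(self) -> np.ndarray:
        return ellipsoid_mask(self.grid_shape, self.mask_semi_axes_vox)

    def affine(self) -> np.ndarray:
        return make_affine(self.grid_shape, self.voxel_size_mm, self.brain_mask())

    def amplitude(self, group: str, roi_label: str) -> float:
        spec = self.group_effect.get(group, 0.0)
        if isinstance(spec, Mapping):
            return float(spec.get(roi_label, 0.0))
        return float(spec)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["roi_specs"] = [dataclasses.asdict(r) for r in self.roi_specs]
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "SimConfig":
        d = dict(d)
        if "roi_specs" in d:
            d["roi_specs"] = [
                r if isinstance(r, RoiSpec) else RoiSpec(
                    center_voxel=tuple(r["center_voxel"]),
                    radius_mm=float(r.get("radius_mm", 9.0)),
                    label=str(r.get("label", "roi")),
                )
                for r in d["roi_specs"]
            ]
        for key in ("grid_shape", "signal_band_hz"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


def mni_3mm_preset(**overrides) -> SimConfig:
    """Full-size preset: 61x73x61 grid at 3 mm with a ~54k-voxel brain mask.

    The mask semi-axes (69, 84, 60 mm) approximate a whole-brain extent of
    roughly 140 x 170 x 120 mm, giving 53,911 in-mask voxels at 3 mm.
    """
    cfg = dict(
        grid_shape=(61, 73, 61),
        voxel_size_mm=3.0,
        mask_semi_axes_vox=(23.0, 28.0, 20.0),
        roi_specs=[RoiSpec(center_voxel=(38, 44, 32), radius_mm=9.0, label="roi_a")],
    )
    cfg.update(overrides)
    return SimConfig(**cfg)


def ellipsoid_mask(
    shape: Sequence[int], semi_axes_vox: Sequence[float] | None = None
) -> np.ndarray:
    """Ellipsoidal brain mask centered on the grid.

    Default semi-axes are 45% of each grid dimension (~15k voxels on the
    desk grid); pass explicit semi-axes for anatomically scaled masks.
    """
    shape = tuple(shape)
    if semi_axes_vox is None:
        semi_axes_vox = [0.45 * s for s in shape]
    center = [(s - 1) / 2.0 for s in shape]
    grids = np.ogrid[tuple(slice(0, s) for s in shape)]
    q = sum(((g - c) / a) ** 2 for g, c, a in zip(grids, center, semi_axes_vox))
    return q <= 1.0


def make_affine(
    shape: Sequence[int], voxel_size_mm: float, mask: np.ndarray | None = None
) -> np.ndarray:
    """Isotropic affine whose world origin sits at the mask centroid."""
    if mask is None:
        mask = ellipsoid_mask(shape)
    centroid = np.array(ndimage.center_of_mass(mask.astype(float)))
    affine = np.eye(4)
    affine[:3, :3] = np.eye(3) * voxel_size_mm
    affine[:3, 3] = -voxel_size_mm * centroid
    return affine


def bandlimited_timecourse(
    n: int,
    tr_s: float,
    band: tuple[float, float] = (0.01, 0.08),
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Unit-RMS random time course with all energy in ``band`` (Hz).

    Built by assigning independent complex-Gaussian coefficients to the
    in-band Fourier bins and inverse transforming, so the spectrum is
    exactly band-limited.
    """
    rng = rng or np.random.default_rng()
    freqs = np.fft.rfftfreq(n, d=tr_s)
    in_band = (freqs >= band[0]) & (freqs <= band[1])
    in_band[0] = False
    if not in_band.any():
        raise ValueError(f"no Fourier bin of an n={n}, TR={tr_s}s series lies in {band}")
    coeffs = np.zeros(len(freqs), dtype=complex)
    k = int(in_band.sum())
    coeffs[in_band] = rng.standard_normal(k) + 1j * rng.standard_normal(k)
    x = np.fft.irfft(coeffs, n=n)
    return x / np.sqrt(np.mean(x**2))


def _smooth_noise_gain(shape: Sequence[int], sigma_vox: float) -> float:
    """Std of unit white noise after Gaussian filtering (kernel L2 norm)."""
    impulse = np.zeros(shape)
    impulse[tuple(s // 2 for s in shape)] = 1.0
    kernel = ndimage.gaussian_filter(impulse, sigma=sigma_vox)
    return float(np.sqrt((kernel**2).sum()))


def generate_subject_scan(
    config: SimConfig, group: str, subject_seed: int
) -> Scan4D:
    """One subject's 4D scan under the configured study conditions.

    The scan is smooth spatial noise (independent across volumes) plus a
    white-noise floor, plus each ROI's shared band-limited time course
    scaled by the group's amplitude.  Identical config and seed give a
    bit-identical array.
    """
    rng = np.random.default_rng(subject_seed)
    shape = config.grid_shape
    n = config.n_volumes
    sigma_vox = fwhm_to_sigma(config.spatial_noise_fwhm_mm) / config.voxel_size_mm

    data = rng.standard_normal((*shape, n), dtype=np.float32)
    if sigma_vox > 0:
        ndimage.gaussian_filter(data, sigma=(sigma_vox, sigma_vox, sigma_vox, 0), output=data)
        data *= np.float32(config.noise_sd / _smooth_noise_gain(shape, sigma_vox))
    else:
        data *= np.float32(config.noise_sd)
    if config.white_noise_sd > 0:
        data += np.float32(config.white_noise_sd) * rng.standard_normal(
            (*shape, n), dtype=np.float32
        )

    for roi in config.roi_specs:
        tc = bandlimited_timecourse(n, config.tr_s, config.signal_band_hz, rng)
        amp = config.amplitude(group, roi.label)
        if amp > 0:
            data[roi.voxel_mask(shape, config.voxel_size_mm)] += amp * tc

    return Scan4D(data=data, affine=config.affine(), tr_s=config.tr_s)


@dataclasses.dataclass
class CohortResult:
    """Outputs of :func:`generate_cohort`."""

    metadata: pd.DataFrame
    mask: np.ndarray
    affine: np.ndarray
    scans: list[Scan4D] | None = None
    scan_paths: list[Path] | None = None
    mask_path: Path | None = None
    metadata_path: Path | None = None


def _subject_seed(master_seed: int, index: int) -> int:
    return int(np.random.SeedSequence((master_seed, index)).generate_state(1)[0] % (2**31))


def _cohort_metadata(config: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Case-control covariate table with the configured group sizes.

    Distribution centers follow a typical hemodialysis cohort (ages late
    30s, ~12 years of education, near-ceiling MMSE, ~1 year on dialysis);
    counts that must be exact — the 15:5 sex ratio per 20 subjects, 2/3
    smokers, 3 outpatients with unknown dialysis duration — are deterministic.
    """
    rows = []
    per_group = {
        "patient": dict(age=(37.1, 8.6, 19, 49), edu=(12.0, 2.9, 5, 22), mmse=29.2),
        "control": dict(age=(38.3, 6.5, 19, 49), edu=(12.9, 3.2, 5, 22), mmse=29.5),
    }
    n = config.n_per_group
    n_male = int(round(0.75 * n))
    n_smokers = {"patient": min(2, n), "control": min(3, n)}
    n_outpatients = min(3, n)
    for group in ("patient", "control"):
        p = per_group[group]
        ages = np.clip(rng.normal(p["age"][0], p["age"][1], n), p["age"][2], p["age"][3])
        edus = np.clip(rng.normal(p["edu"][0], p["edu"][1], n), p["edu"][2], p["edu"][3])
        mmse = np.clip(np.round(rng.normal(p["mmse"], 0.8, n)), 28, 30)
        smoker_idx = set(rng.choice(n, size=n_smokers[group], replace=False).tolist())
        cigs = np.where(
            [i in smoker_idx for i in range(n)],
            np.clip(np.round(rng.normal(15.0, 10.0, n)), 5, 40),
            0.0,
        )
        outpatient_idx = set(rng.choice(n, size=n_outpatients, replace=False).tolist())
        dialysis = np.clip(rng.normal(10.7, 6.4, n), 1.0, 36.0)
        for i in range(n):
            rows.append(
                {
                    "id": f"{group[0]}{i + 1:02d}",
                    "group": group,
                    "age_y": round(float(ages[i]), 1),
                    "sex": "M" if i < n_male else "F",
                    "education_y": round(float(edus[i]), 1),
                    "cigarettes_per_day": float(cigs[i]),
                    "dialysis_months": (
                        round(float(dialysis[i]), 1)
                        if group == "patient" and i not in outpatient_idx
                        else np.nan
                    ),
                    "mmse": float(mmse[i]),
                }
            )
    return pd.DataFrame(rows)


def generate_cohort(config: SimConfig, out_dir: str | Path | None = None) -> CohortResult:
    """Simulate a full two-group cohort: scans, brain mask, metadata table.

    Subject seeds are derived deterministically from the master seed.  With
    ``out_dir`` set, one ``<id>_bold.nii.gz`` per subject plus
    ``brain_mask.nii.gz`` and ``participants.tsv`` are written and scans are
    not kept in memory; otherwise the scans are returned in metadata row
    order.
    """
    if config.n_per_group < 2:
        raise ValueError("n_per_group must be >= 2")
    meta_rng = np.random.default_rng(np.random.SeedSequence((config.seed, 999983)))
    meta = _cohort_metadata(config, meta_rng)
    mask = config.brain_mask()
    affine = config.affine()

    result = CohortResult(metadata=meta, mask=mask, affine=affine)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        result.scan_paths = []
    else:
        result.scans = []

    for index, row in meta.iterrows():
        scan = generate_subject_scan(config, row["group"], _subject_seed(config.seed, int(index)))
        if out_dir is not None:
            result.scan_paths.append(write_scan(scan, out_dir / f"{row['id']}_bold.nii.gz"))
        else:
            result.scans.append(scan)
    if out_dir is not None:
        result.mask_path = write_mask(mask, affine, out_dir / "brain_mask.nii.gz")
        result.metadata_path = write_metadata(meta, out_dir / "participants.tsv")
    return result
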