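"""Group-level statistics for ReHo maps and cohort demographics.

The voxelwise group comparison is a mass-univariate ordinary least squares
fit of each voxel's (smoothed, normalized) ReHo value on an intercept, a
patient-group indicator and optional confound covariates (age and years of
education by default); the reported statistic is the t of the group
coefficient, so positive t means patient mean above control mean after
covariate adjustment.  Demographic comparisons (two-sample t from summary
statistics, chi-square for sex composition, Mann-Whitney U, Pearson
correlation with dialysis duration) mirror the univariate tests a clinical
table is built from.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .reho import ReHoMap

__all__ = [
    "DesignMatrix",
    "TMap",
    "SummaryStats",
    "TTestResult",
    "build_design_matrix",
    "glm_group_ttest",
    "one_sample_ttest_map",
    "fdr_correct",
    "summary_two_sample_t",
    "chi_square_2x2",
    "mann_whitney_u",
    "pearson_corr",
    "demographics_table",
]

PATIENT_LABEL = "patient"
CONTROL_LABEL = "control"


@dataclasses.dataclass
class DesignMatrix:
    """Subjects x predictors matrix: intercept, group indicator, covariates."""

    X: np.ndarray
    column_names: list[str]
    group_column: int = 1

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=np.float64)
        if self.X.ndim != 2 or self.X.shape[1] != len(self.column_names):
            raise ValueError("X shape does not match column_names")

    def check_full_rank(self) -> None:
        rank = np.linalg.matrix_rank(self.X)
        if rank < self.X.shape[1]:
            collinear = _collinear_columns(self.X, self.column_names)
            raise ValueError(
                f"design matrix is rank deficient (rank {rank} of "
                f"{self.X.shape[1]}); collinear columns: {collinear}"
            )


def _collinear_columns(X: np.ndarray, names: Sequence[str]) -> list[str]:
    """Columns whose removal restores full rank (greedy scan)."""
    bad = []
    for j in range(X.shape[1]):
        others = np.delete(X, j, axis=1)
        if np.linalg.matrix_rank(others) == np.linalg.matrix_rank(X):
            bad.append(names[j])
    return bad or list(names)


@dataclasses.dataclass
class TMap:
    """Voxelwise t statistics with degrees of freedom and contrast label."""

    t: np.ndarray
    df: int
    contrast: str
    mask: np.ndarray
    affine: np.ndarray
    #: voxels where the statistic degenerated (zero residual variance)
    degenerate: np.ndarray | None = None


@dataclasses.dataclass
class SummaryStats:
    """Group summary of one variable: mean, standard deviation, group size."""

    mean: float
    sd: float
    n: int

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError("sd must be nonnegative")
        if self.n < 2:
            raise ValueError("need n >= 2 per group")


@dataclasses.dataclass
class TTestResult:
    t: float
    df_pooled: float
    df_welch: float
    p_pooled: float
    p_welch: float


def build_design_matrix(
    meta: pd.DataFrame,
    covariates: Sequence[str] = ("age_y", "education_y"),
    patient_label: str = PATIENT_LABEL,
) -> DesignMatrix:
    """Intercept + patient indicator + mean-centered covariates from metadata."""
    group = (meta["group"].astype(str) == patient_label).to_numpy(dtype=float)
    if group.sum() == 0 or group.sum() == len(group):
        raise ValueError("both groups must be present in the metadata")
    cols = [np.ones(len(meta)), group]
    names = ["intercept", "group"]
    for cov in covariates:
        v = meta[cov].to_numpy(dtype=float)
        if np.isnan(v).any():
            raise ValueError(f"covariate {cov!r} contains missing values")
        cols.append(v - v.mean())
        names.append(cov)
    return DesignMatrix(X=np.column_stack(cols), column_names=names)


def glm_group_ttest(
    maps: Sequence[ReHoMap] | np.ndarray,
    design: DesignMatrix,
    mask: np.ndarray,
) -> TMap:
    """Voxelwise OLS t test of the group coefficient.

    ``maps`` is one ReHo map (or raw 3D array) per subject, in the row order
    of the design matrix.  Each voxel is fit independently:
    ``y = X beta + e``; ``t = beta_group / se(beta_group)`` with
    ``df = n_subjects - n_columns``.
    """
    design.check_full_rank()
    mask = np.asarray(mask, dtype=bool)
    Y, affine = _stack_maps(maps, mask)
    X = design.X
    n, p = X.shape
    if Y.shape[0] != n:
        raise ValueError(f"{Y.shape[0]} maps but design has {n} rows")
    n_per_group = np.bincount(X[:, design.group_column].astype(int), minlength=2)
    if n_per_group.min() < 2:
        raise ValueError("need at least 2 subjects per group")
    df = n - p

    xtx_inv = np.linalg.inv(X.T @ X)
    beta = xtx_inv @ (X.T @ Y)
    resid = Y - X @ beta
    rss = (resid**2).sum(axis=0)
    # residuals indistinguishable from rounding noise => zero-variance voxel
    scale = (Y**2).sum(axis=0)
    degenerate_flat = rss <= 1e4 * np.finfo(float).eps * np.maximum(scale, 1.0)
    sigma2 = rss / df
    se = np.sqrt(sigma2 * xtx_inv[design.group_column, design.group_column])
    b = beta[design.group_column]
    with np.errstate(divide="ignore", invalid="ignore"):
        t_vals = b / se
    b_zero = np.abs(b) <= 1e-8 * np.sqrt(np.maximum(scale, 1.0))
    with np.errstate(invalid="ignore"):
        sentinel = np.where(b_zero, 0.0, np.sign(b) * np.inf)
    t_vals = np.where(degenerate_flat, sentinel, t_vals)
    t_vals = np.nan_to_num(t_vals, nan=0.0, posinf=np.inf, neginf=-np.inf)

    t_map = np.zeros(mask.shape)
    t_map[mask] = t_vals
    degenerate = np.zeros(mask.shape, dtype=bool)
    degenerate[mask] = degenerate_flat
    return TMap(
        t=t_map,
        df=df,
        contrast="group: patient - control (covariate adjusted)",
        mask=mask,
        affine=affine,
        degenerate=degenerate,
    )


def one_sample_ttest_map(
    maps: Sequence[ReHoMap] | np.ndarray,
    null_value: float = 1.0,
    mask: np.ndarray | None = None,
) -> TMap:
    """Voxelwise one-sample t against ``null_value`` (1 = the mReHo baseline).

    Voxels with zero variance across subjects get a signed infinite sentinel
    and are flagged in ``degenerate``.
    """
    if mask is None:
        raise ValueError("mask is required")
    mask = np.asarray(mask, dtype=bool)
    Y, affine = _stack_maps(maps, mask)
    n = Y.shape[0]
    if n < 2:
        raise ValueError("one-sample t-test requires at least 2 subjects")
    mean = Y.mean(axis=0)
    sd = Y.std(axis=0, ddof=1)
    degenerate_flat = sd <= 1e2 * np.finfo(float).eps * np.maximum(np.abs(mean), 1.0)
    shift = mean - null_value
    with np.errstate(divide="ignore", invalid="ignore"):
        t_vals = shift / (sd / np.sqrt(n))
    shift_zero = np.abs(shift) <= 1e-8 * np.maximum(np.abs(mean), 1.0)
    with np.errstate(invalid="ignore"):
        sentinel = np.where(shift_zero, 0.0, np.sign(shift) * np.inf)
    t_vals = np.where(degenerate_flat, sentinel, t_vals)
    t_vals = np.nan_to_num(t_vals, nan=0.0, posinf=np.inf, neginf=-np.inf)

    t_map = np.zeros(mask.shape)
    t_map[mask] = t_vals
    degenerate = np.zeros(mask.shape, dtype=bool)
    degenerate[mask] = degenerate_flat
    return TMap(
        t=t_map,
        df=n - 1,
        contrast=f"mean vs {null_value}",
        mask=mask,
        affine=affine,
        degenerate=degenerate,
    )


def _stack_maps(
    maps: Sequence[ReHoMap] | np.ndarray, mask: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Stack subject maps to (n_subjects, n_mask_voxels); return with affine."""
    if isinstance(maps, np.ndarray) and maps.ndim == 4:
        arrays = [maps[i] for i in range(maps.shape[0])]
        affine = np.eye(4)
    else:
        arrays = []
        affine = np.eye(4)
        for m in maps:
            if isinstance(m, ReHoMap):
                arrays.append(m.values)
                affine = m.affine
            else:
                arrays.append(np.asarray(m, dtype=np.float64))
    shapes = {a.shape for a in arrays}
    if len(shapes) != 1 or arrays[0].shape != mask.shape:
        raise ValueError(f"subject maps must share the mask grid {mask.shape}")
    return np.stack([a[mask] for a in arrays], axis=0), affine


def fdr_correct(p_values: np.ndarray, q: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg step-up rejection mask at FDR level ``q``."""
    p = np.asarray(p_values, dtype=np.float64)
    if p.size == 0:
        return np.zeros(0, dtype=bool)
    if not (0 < q < 1):
        raise ValueError("q must be in (0, 1)")
    if (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    reject, _, _, _ = multipletests(p.ravel(), alpha=q, method="fdr_bh")[:4]
    return reject.reshape(p.shape)


def summary_two_sample_t(a: SummaryStats, b: SummaryStats) -> TTestResult:
    """Two-sample t from printed summary statistics (mean, sd, n per group).

    The statistic is the unpooled-SE form
    ``t = (mean_a - mean_b) / sqrt(sd_a^2/n_a + sd_b^2/n_b)`` (identical to
    the pooled-variance t when group sizes are equal); degrees of freedom are
    reported under both the pooled (n_a+n_b-2) and Welch-Satterthwaite
    conventions.
    """
    se2_a = a.sd**2 / a.n
    se2_b = b.sd**2 / b.n
    se = np.sqrt(se2_a + se2_b)
    if se == 0:
        raise ValueError("both groups have zero variance")
    t = (a.mean - b.mean) / se
    df_pooled = a.n + b.n - 2
    df_welch = (se2_a + se2_b) ** 2 / (
        se2_a**2 / (a.n - 1) + se2_b**2 / (b.n - 1)
    )
    return TTestResult(
        t=float(t),
        df_pooled=float(df_pooled),
        df_welch=float(df_welch),
        p_pooled=float(2 * sps.t.sf(abs(t), df_pooled)),
        p_welch=float(2 * sps.t.sf(abs(t), df_welch)),
    )


def chi_square_2x2(table: np.ndarray) -> tuple[float, int]:
    """Pearson chi-square (no continuity correction) of a 2x2 count table."""
    table = np.asarray(table, dtype=np.float64)
    if table.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if (table < 0).any():
        raise ValueError("counts must be nonnegative")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError("all margins must be positive")
    stat, _, dof, _ = sps.chi2_contingency(table, correction=False)
    return float(stat), int(dof)


def mann_whitney_u(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Mann-Whitney U statistic and two-sided p (ties handled by scipy)."""
    res = sps.mannwhitneyu(x, y, alternative="two-sided")
    return float(res.statistic), float(res.pvalue)


def pearson_corr(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Sample Pearson correlation with its two-sided p-value."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("x and y must be equal-length vectors of length >= 3")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("correlation is undefined for zero-variance input")
    r, p = sps.pearsonr(x, y)
    return float(r), float(p)


def demographics_table(meta: pd.DataFrame) -> pd.DataFrame:
    """Group comparison table for the standard cohort covariates.

    Continuous variables get the summary two-sample t (smokers only for
    cigarettes/day); sex composition gets the 2x2 chi-square.
    """
    rows = []
    groups = [PATIENT_LABEL, CONTROL_LABEL]
    sub = {g: meta[meta["group"] == g] for g in groups}

    def _cont(name: str, values: dict[str, np.ndarray]) -> None:
        stats_by_group = {}
        for g in groups:
            v = values[g]
            stats_by_group[g] = SummaryStats(float(v.mean()), float(v.std(ddof=1)), len(v))
        res = summary_two_sample_t(stats_by_group[groups[0]], stats_by_group[groups[1]])
        rows.append(
            {
                "variable": name,
                "patient": f"{stats_by_group[groups[0]].mean:.1f}±{stats_by_group[groups[0]].sd:.1f}",
                "control": f"{stats_by_group[groups[1]].mean:.1f}±{stats_by_group[groups[1]].sd:.1f}",
                "statistic": res.t,
                "test": "two-sample t",
                "p": res.p_pooled,
            }
        )

    _cont("age_y", {g: sub[g]["age_y"].to_numpy(float) for g in groups})
    _cont("education_y", {g: sub[g]["education_y"].to_numpy(float) for g in groups})
    smokers = {
        g: sub[g].loc[sub[g]["cigarettes_per_day"] > 0, "cigarettes_per_day"].to_numpy(float)
        for g in groups
    }
    if all(len(v) >= 2 for v in smokers.values()):
        _cont("cigarettes_per_day (smokers)", smokers)
    _cont("mmse", {g: sub[g]["mmse"].to_numpy(float) for g in groups})

    sex_table = np.array(
        [
            [(sub[g]["sex"] == "M").sum(), (sub[g]["sex"] == "F").sum()]
            for g in groups
        ]
    )
    chi2, dof = chi_square_2x2(sex_table)
    rows.append(
        {
            "variable": "sex (M/F)",
            "patient": f"{sex_table[0, 0]}/{sex_table[0, 1]}",
            "control": f"{sex_table[1, 0]}/{sex_table[1, 1]}",
            "statistic": chi2,
            "test": f"chi-square (df={dof})",
            "p": float(sps.chi2.sf(chi2, dof)),
        }
    )
    return pd.DataFrame(rows)
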