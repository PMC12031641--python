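"""Group-level statistics across subjects.

Per-subject summaries (median percent signal change, active-voxel counts,
peak stiffness change) are pooled into a tidy table with one row per
subject x contrast x branch. On top of that: subject-level bootstrap
medians and confidence intervals, ordinary least squares of the response on
percent contrast intensity, a random-intercept linear mixed model (REML,
Wald test on the contrast slope), one-sample Cohen's d, and temporal-SNR
maps.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf

GROUP_COLUMNS = [
    "subject_id",
    "contrast_pct",
    "branch",
    "median_psc_pct",
    "n_active",
    "delta_mu_kpa",
]


def validate_group_table(table: pd.DataFrame) -> pd.DataFrame:
    """Check the tidy per-subject summary table (one row per cell)."""
    missing = [c for c in ("subject_id", "contrast_pct", "branch") if c not in table.columns]
    if missing:
        raise ValueError(f"group table is missing columns: {missing}")
    if table.duplicated(["subject_id", "contrast_pct", "branch"]).any():
        raise ValueError("group table must have one row per subject x contrast x branch")
    bad = set(table["branch"]) - {"fmre", "fmri"}
    if bad:
        raise ValueError(f"unknown branch labels: {sorted(bad)}")
    return table


@dataclass
class BootstrapResult:
    median: float
    ci_low: float
    ci_high: float
    n_resamples: int
    seed: int


def bootstrap_median(
    values: np.ndarray, n_resamples: int = 10_000, seed: int | None = None
) -> BootstrapResult:
    """Percentile bootstrap of the median over subjects.

    Subjects are resampled with replacement ``n_resamples`` times; the 95%
    interval is the 2.5/97.5 percentile of the resampled medians.
    """
    if seed is None:
        raise ValueError("bootstrap_median requires a seed (reproducibility is mandatory)")
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ValueError(f"need >= 2 subjects, got {values.size}")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, values.size, size=(n_resamples, values.size))
    meds = np.median(values[idx], axis=1)
    return BootstrapResult(
        median=float(np.median(values)),
        ci_low=float(np.percentile(meds, 2.5)),
        ci_high=float(np.percentile(meds, 97.5)),
        n_resamples=int(n_resamples),
        seed=int(seed),
    )


def bootstrap_by_contrast(
    table: pd.DataFrame,
    response: str,
    branch: str = "fmre",
    n_resamples: int = 10_000,
    seed: int | None = None,
) -> pd.DataFrame:
    """Bootstrap the per-contrast median of one response, one row per contrast."""
    validate_group_table(table)
    sub = table[table["branch"] == branch]
    rows = []
    for i, (c, grp) in enumerate(sub.groupby("contrast_pct", sort=True)):
        res = bootstrap_median(grp[response].to_numpy(), n_resamples, seed=None if seed is None else seed + i)
        rows.append(
            {"contrast_pct": c, "median": res.median, "ci_low": res.ci_low, "ci_high": res.ci_high}
        )
    return pd.DataFrame(rows)


@dataclass
class RegressionFit:
    slope: float
    intercept: float
    rms_error: float
    p_value: float

    def predict(self, contrast_pct: float) -> float:
        return self.slope * contrast_pct + self.intercept


def fit_contrast_regression(
    table: pd.DataFrame, response: str, branch: str | None = "fmre"
) -> RegressionFit:
    """OLS of a response on percent contrast intensity across all rows.

    ``rms_error`` is the root-mean-square residual of the fit.
    """
    validate_group_table(table)
    sub = table if branch is None else table[table["branch"] == branch]
    c = sub["contrast_pct"].to_numpy(dtype=float)
    y = sub[response].to_numpy(dtype=float)
    if np.unique(c).size < 2:
        raise ValueError("need >= 2 distinct contrast levels for a regression")
    X = sm.add_constant(c)
    fit = sm.OLS(y, X).fit()
    return RegressionFit(
        slope=float(fit.params[1]),
        intercept=float(fit.params[0]),
        rms_error=float(np.sqrt(np.mean(fit.resid**2))),
        p_value=float(fit.pvalues[1]),
    )


def bootstrap_regression_slope(
    table: pd.DataFrame,
    response: str,
    branch: str = "fmre",
    n_resamples: int = 10_000,
    seed: int | None = None,
) -> BootstrapResult:
    """Bootstrap CI of the contrast-regression slope, resampling whole subjects.

    Within-subject rows travel together (the subject is the exchangeable
    unit, matching a 16-volunteer cohort design).
    """
    if seed is None:
        raise ValueError("bootstrap_regression_slope requires a seed")
    validate_group_table(table)
    sub = table[table["branch"] == branch]
    subjects = sub["subject_id"].unique()
    if subjects.size < 2:
        raise ValueError("need >= 2 subjects")
    by_subj = {
        s: (g["contrast_pct"].to_numpy(float), g[response].to_numpy(float))
        for s, g in sub.groupby("subject_id")
    }
    rng = np.random.default_rng(seed)
    slopes = np.empty(n_resamples)
    for r in range(n_resamples):
        pick = rng.choice(subjects, size=subjects.size, replace=True)
        c = np.concatenate([by_subj[s][0] for s in pick])
        y = np.concatenate([by_subj[s][1] for s in pick])
        slopes[r] = np.polyfit(c, y, 1)[0]
    full = fit_contrast_regression(table, response, branch).slope
    return BootstrapResult(
        median=float(full),
        ci_low=float(np.percentile(slopes, 2.5)),
        ci_high=float(np.percentile(slopes, 97.5)),
        n_resamples=int(n_resamples),
        seed=int(seed),
    )


@dataclass
class MixedModelFit:
    slope: float
    slope_se: float
    p_value: float
    intercept: float


def fit_mixed_model(
    table: pd.DataFrame, response: str, branch: str | None = "fmre"
) -> MixedModelFit:
    """Random-intercept linear mixed model of the response on contrast.

    response_ij = b0 + b1 * contrast_ij + u_i + e_ij, fit by REML with a
    Wald test on the contrast fixed effect b1.
    """
    validate_group_table(table)
    sub = table if branch is None else table[table["branch"] == branch]
    if sub["subject_id"].nunique() < 2 or sub["contrast_pct"].nunique() < 2:
        raise ValueError("need >= 2 subjects and >= 2 contrast levels for a mixed model")
    data = sub[["subject_id", "contrast_pct", response]].rename(columns={response: "y"})
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = smf.mixedlm("y ~ contrast_pct", data, groups=data["subject_id"])
        fit = model.fit(reml=True)
    return MixedModelFit(
        slope=float(fit.params["contrast_pct"]),
        slope_se=float(fit.bse["contrast_pct"]),
        p_value=float(fit.pvalues["contrast_pct"]),
        intercept=float(fit.params["Intercept"]),
    )


def cohens_d(values: np.ndarray) -> float:
    """One-sample Cohen's d against zero: mean / sd of per-subject values."""
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ValueError("need >= 2 subjects")
    sd = values.std(ddof=1)
    if sd == 0:
        raise ValueError("zero variance: Cohen's d is undefined")
    return float(values.mean() / sd)


def tsnr(series: np.ndarray, axis: int = -1) -> tuple[np.ndarray, np.ndarray]:
    """Temporal SNR: voxelwise temporal mean over temporal standard deviation.

    Returns (tsnr_map, valid_mask); zero-variance voxels are invalid (NaN).
    """
    series = np.asarray(series, dtype=float)
    if series.shape[axis] < 2:
        raise ValueError("need >= 2 frames for temporal SNR")
    mean = series.mean(axis=axis)
    sd = series.std(axis=axis, ddof=1)
    valid = (sd > 0) & np.isfinite(sd) & np.isfinite(mean)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(valid, mean / sd, np.nan)
    return out, valid
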