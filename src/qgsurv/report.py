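"""Subgroup analyses, heterogeneity testing, collinearity screening, tables.

Subgroup fits refit the single-pollutant Cox models and the qgcomp mixture
model within each stratum of a covariate, adjusting for all confounders
except the stratifying variable itself.  Between-stratum differences of
log-scale estimates are tested with a two-sample z statistic,

    z = (b1 - b2) / sqrt(se1^2 + se2^2),

with two-sided normal p-values, Bonferroni-corrected over the C(levels, 2)
pairwise comparisons within a variable.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

from .cohort import Cohort
from .cox import fit_cox
from .qgcomp import fit_qgcomp

__all__ = [
    "SubgroupResult",
    "HeterogeneityTest",
    "z_between",
    "bonferroni",
    "vif",
    "se_from_ci",
    "subgroup_fits",
    "heterogeneity_table",
    "build_report",
]

_Z95 = norm.ppf(0.975)


@dataclass
class HeterogeneityTest:
    b1: float
    se1: float
    b2: float
    se2: float
    z: float
    p_raw: float
    m: int = 1
    p_adjusted: float = np.nan


def z_between(b1: float, se1: float, b2: float, se2: float) -> HeterogeneityTest:
    """Two-sample z test for a difference of log-scale estimates."""
    if se1 <= 0 or se2 <= 0:
        raise ValueError("standard errors must be positive")
    z = (b1 - b2) / np.hypot(se1, se2)
    p = 2.0 * norm.sf(abs(z))
    return HeterogeneityTest(b1=b1, se1=se1, b2=b2, se2=se2, z=float(z), p_raw=float(p))


def bonferroni(p_values, m: int | None = None):
    """Bonferroni adjustment ``p -> min(1, m*p)``; m defaults to len(p)."""
    p = np.asarray(list(p_values), dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    mm = len(p) if m is None else int(m)
    return np.minimum(1.0, mm * p)


def se_from_ci(lower: float, upper: float) -> float:
    """Back-calculate a log-scale SE from a printed 95% HR interval.

    ``(ln U - ln L) / (2 * 1.96)`` — a reporting-consistency utility for
    checking published tables, not part of the estimation pipeline.
    """
    if not (0 < lower < upper):
        raise ValueError("need 0 < lower < upper")
    return float((np.log(upper) - np.log(lower)) / (2.0 * _Z95))


def vif(design) -> pd.Series:
    """Variance inflation factor per column: ``1 / (1 - R^2_k)`` where
    ``R^2_k`` regresses column k on the remaining columns (plus intercept).
    Exact collinearity is reported as ``inf``.
    """
    X = design.to_numpy(dtype=float) if isinstance(design, pd.DataFrame) else np.asarray(design, float)
    names = list(design.columns) if isinstance(design, pd.DataFrame) else [
        f"x{i}" for i in range(X.shape[1])
    ]
    n, p = X.shape
    if p < 2:
        raise ValueError("need at least 2 columns")
    out = np.empty(p)
    ones = np.ones((n, 1))
    for k in range(p):
        yk = X[:, k]
        Z = np.hstack([ones, np.delete(X, k, axis=1)])
        coef, *_ = np.linalg.lstsq(Z, yk, rcond=None)
        resid = yk - Z @ coef
        sst = float(((yk - yk.mean()) ** 2).sum())
        r2 = 1.0 - float((resid**2).sum()) / sst if sst > 0 else 1.0
        out[k] = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return pd.Series(out, index=names)


def add_temperature_quartiles(cohort: Cohort, column: str = "temp_quartile") -> Cohort:
    """Attach a subject-level temperature-quartile stratum label.

    Strata are quartiles of each subject's mean annual temperature (Q1-Q4).
    When stratifying on this column, drop ``temp`` from the adjustment set as
    well: the stratum variable replaces the continuous adjustment.
    """
    subj_mean = cohort.data.groupby("subject_id", sort=False)["temp"].transform("mean")
    per_subject = cohort.data.assign(_m=subj_mean).groupby("subject_id", sort=False)["_m"].first()
    cuts = np.percentile(per_subject.to_numpy(), [25, 50, 75])
    labels = np.array(["Q1", "Q2", "Q3", "Q4"])
    cat = labels[np.searchsorted(cuts, subj_mean.to_numpy(), side="left")]
    df = cohort.data.copy()
    df[column] = cat
    schema = dict(cohort.covariate_schema)
    schema[column] = list(labels)
    return Cohort(df, list(cohort.exposure_names), schema)


@dataclass
class SubgroupResult:
    variable: str
    level: str
    n_subjects: int
    n_events: int
    model: str               # "o3" | "pm25" | ... | "joint"
    hr: float
    ci_low: float
    ci_high: float
    beta: float
    se: float


def _hr_row(variable, level, n_subj, n_ev, model, beta, se) -> SubgroupResult:
    return SubgroupResult(
        variable=variable, level=str(level), n_subjects=n_subj, n_events=n_ev,
        model=model, hr=float(np.exp(beta)),
        ci_low=float(np.exp(beta - _Z95 * se)), ci_high=float(np.exp(beta + _Z95 * se)),
        beta=float(beta), se=float(se),
    )


def subgroup_fits(
    cohort: Cohort,
    subgroup_variable: str,
    exposures=("pm25", "o3"),
    covariates=(),
    models=("o3", "pm25", "joint"),
    ties: str = "efron",
) -> list[SubgroupResult]:
    """Refit the single-pollutant and mixture models within each stratum.

    The stratifying variable is dropped from the adjustment set; strata with
    no events are skipped (with a warning).  Returns one row per stratum and
    model.
    """
    import warnings

    adj = [c for c in covariates if c != subgroup_variable]
    if subgroup_variable in cohort.covariate_schema:
        levels = cohort.covariate_schema[subgroup_variable]
    else:
        levels = sorted(cohort.data[subgroup_variable].astype(str).unique())
    results: list[SubgroupResult] = []
    for level in levels:
        mask = (cohort.data[subgroup_variable].astype(str) == str(level)).to_numpy()
        if not mask.any():
            continue
        stratum = cohort.subset(mask)
        if stratum.n_events == 0:
            warnings.warn(
                f"stratum {subgroup_variable}={level}: no events, skipped", stacklevel=2
            )
            continue
        for model in models:
            if model == "joint":
                fit = fit_qgcomp(stratum, exposures, adj, ties=ties)
                results.append(_hr_row(
                    subgroup_variable, level, stratum.n_subjects, stratum.n_events,
                    "joint", fit.psi_, fit.psi_se_,
                ))
            else:
                fit = fit_cox(stratum, model, adj, ties=ties)
                results.append(_hr_row(
                    subgroup_variable, level, stratum.n_subjects, stratum.n_events,
                    model, fit.coef_[0], fit.standard_errors_[0],
                ))
    return results


def heterogeneity_table(results: list[SubgroupResult]) -> pd.DataFrame:
    """All pairwise between-stratum z tests, per model, within each variable.

    Bonferroni m = C(levels, 2) per variable; both raw and adjusted p-values
    are reported.
    """
    rows = []
    df = pd.DataFrame([r.__dict__ for r in results])
    for (variable, model), g in df.groupby(["variable", "model"], sort=False):
        levels = list(g["level"])
        m = len(levels) * (len(levels) - 1) // 2
        for la, lb in itertools.combinations(levels, 2):
            ra = g[g["level"] == la].iloc[0]
            rb = g[g["level"] == lb].iloc[0]
            t = z_between(ra["beta"], ra["se"], rb["beta"], rb["se"])
            rows.append({
                "variable": variable, "model": model,
                "level_1": la, "level_2": lb,
                "z": t.z, "p_raw": t.p_raw,
                "p_adjusted": min(1.0, m * t.p_raw), "m": m,
            })
    return pd.DataFrame(rows)


def build_report(
    total_fits: dict,
    subgroup_results: list[SubgroupResult],
    paf_estimates: dict,
) -> dict[str, pd.DataFrame]:
    """Assemble the output tables: stratum HRs, heterogeneity tests, PAFs.

    ``total_fits`` maps model name -> (beta, se) or fitted estimator summary
    rows; ``paf_estimates`` maps label -> PafEstimate.  Returns named frames
    ready for CSV serialization (the table layouts mirror a subgroup HR table
    and a PAF-by-group figure).
    """
    hr_rows = []
    for model, (beta, se) in total_fits.items():
        hr_rows.append({
            "variable": "total", "level": "all", "model": model,
            "hr": float(np.exp(beta)),
            "ci_low": float(np.exp(beta - _Z95 * se)),
            "ci_high": float(np.exp(beta + _Z95 * se)),
            "beta": float(beta), "se": float(se),
        })
    for r in subgroup_results:
        hr_rows.append({
            "variable": r.variable, "level": r.level, "model": r.model,
            "hr": r.hr, "ci_low": r.ci_low, "ci_high": r.ci_high,
            "beta": r.beta, "se": r.se,
        })
    hr_table = pd.DataFrame(
        hr_rows, columns=["variable", "level", "model", "hr", "ci_low", "ci_high", "beta", "se"]
    )

    paf_rows = []
    for label, est in paf_estimates.items():
        paf_rows.append({
            "label": label,
            "paf_pct": 100.0 * est.point,
            "ci_low_pct": 100.0 * est.ci[0] if est.ci else np.nan,
            "ci_high_pct": 100.0 * est.ci[1] if est.ci else np.nan,
            "n_draws": est.n_draws,
        })
    paf_table = pd.DataFrame(
        paf_rows, columns=["label", "paf_pct", "ci_low_pct", "ci_high_pct", "n_draws"]
    )
    het = heterogeneity_table(subgroup_results) if subgroup_results else pd.DataFrame(
        columns=["variable", "model", "level_1", "level_2", "z", "p_raw", "p_adjusted", "m"]
    )
    return {"hr_table": hr_table, "paf_table": paf_table, "heterogeneity": het}
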