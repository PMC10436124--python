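"""Calibrated synthetic cohort generator.

Emulates the statistical structure of a Chinese ageing-cohort air-pollution
study: ~8,500 adults followed ~7 years, annual-mean PM2.5 / MDA8 ozone /
temperature exposures that are cross-correlated and slowly varying year to
year, baseline-table categorical covariates, and first-onset asthmatic-symptom
events generated from a proportional-hazards model on quartile-scored
exposures.  Default calibration targets:

* PM2.5 mean 42.85, SD 12.74 ug/m3; MDA8 O3 mean 94.19, SD 5.62 ug/m3;
  temperature mean 15.0, SD 4.5 C (Gaussian marginals, clipped at 0 for the
  concentrations; the clip moves < 0.05% of PM2.5 mass).
* cross-correlations r(PM2.5, O3) = 0.663, r(PM2.5, temp) = 0.090,
  r(O3, temp) = 0.428; year-to-year AR(1) persistence 0.8 on the latent
  Gaussian scale, which preserves the cross-sectional correlations.
* covariate margins matching the study's baseline table (12 covariates).
* mean follow-up 6.9 (SD 2.3) years, truncated to [1, 11]; cumulative event
  incidence calibrated to 6.9% by bisection on the baseline hazard.
* true per-quantile log hazard ratios default to the joint-world split:
  0.68 * ln(1.18) for PM2.5 and 0.32 * ln(1.18) for O3.

Everything is driven by one integer seed through numpy SeedSequence spawning,
so each stage (exposures, covariates, follow-up, events) has an independent,
reproducible substream.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml

from .cohort import Cohort, expand_counting_process

__all__ = [
    "GeneratorConfig",
    "ConfigError",
    "CalibrationError",
    "BASELINE_MARGINS",
    "generate_exposures",
    "generate_covariates",
    "simulate_events",
    "make_cohort",
]

#: Baseline covariate category probabilities (reference level first).
BASELINE_MARGINS: dict[str, dict[str, float]] = {
    "age_group": {"50-64": 0.6525, "65+": 0.3475},
    "sex": {"male": 0.4789, "female": 0.5211},
    "urbanicity": {"rural": 0.5743, "urban": 0.4257},
    "region": {"south": 0.6194, "north": 0.3806},
    "marital": {"married": 0.8645, "unmarried": 0.1355},
    "bmi_group": {"normal": 0.5516, "overweight": 0.3265, "obese": 0.1219},
    "fuel": {"clean": 0.5466, "unclean": 0.4534},
    "smoking": {"never": 0.6680, "ever": 0.3320},
    "drinking": {"never": 0.6801, "ever": 0.3199},
    "income": {"high": 0.5072, "low": 0.4928},
    "education": {"none": 0.3997, "primary": 0.2122, "middle+": 0.3881},
}

_LN118 = math.log(1.18)

#: Alternative PM2.5 marginal matching the baseline table rather than the
#: text (the two printed summaries disagree; the text value is the default).
PM25_BASELINE_TABLE_PRESET = (46.20, 12.74)


class ConfigError(ValueError):
    pass


class CalibrationError(RuntimeError):
    pass


@dataclass
class GeneratorConfig:
    """Simulation truth and calibration targets for one synthetic cohort."""

    n_subjects: int = 8490
    baseline_year: int = 2008
    followup_mean: float = 6.9
    followup_sd: float = 2.3
    followup_range: tuple[float, float] = (1.0, 11.0)
    exposure_targets: dict = field(
        default_factory=lambda: {
            "pm25": (42.85, 12.74),
            "o3": (94.19, 5.62),
            "temp": (15.0, 4.5),
        }
    )
    # order follows exposure_targets keys
    exposure_correlations: list = field(
        default_factory=lambda: [
            [1.0, 0.663, 0.090],
            [0.663, 1.0, 0.428],
            [0.090, 0.428, 1.0],
        ]
    )
    ar1: float = 0.8
    covariate_margins: dict = field(default_factory=lambda: {
        k: dict(v) for k, v in BASELINE_MARGINS.items()
    })
    true_log_hr: dict = field(
        default_factory=lambda: {"pm25": 0.68 * _LN118, "o3": 0.32 * _LN118}
    )
    effect_modifiers: dict = field(default_factory=dict)
    baseline_hazard: float | str = "calibrate_to_incidence"
    target_incidence: float = 0.069
    seed: int = 0

    def __post_init__(self) -> None:
        C = np.asarray(self.exposure_correlations, dtype=float)
        k = len(self.exposure_targets)
        if C.shape != (k, k) or not np.allclose(C, C.T):
            raise ConfigError("exposure correlation matrix must be symmetric k x k")
        if np.linalg.eigvalsh(C).min() <= 1e-10:
            raise ConfigError("exposure correlation matrix must be positive definite")
        for cov, margin in self.covariate_margins.items():
            tot = sum(margin.values())
            if abs(tot - 1.0) > 1e-9:
                raise ConfigError(f"margins for {cov!r} sum to {tot}, not 1")

    @property
    def exposure_names(self) -> list[str]:
        return list(self.exposure_targets)

    @property
    def covariate_schema(self) -> dict[str, list[str]]:
        return {k: list(v) for k, v in self.covariate_margins.items()}

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "GeneratorConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if "exposure_targets" in raw:
            raw["exposure_targets"] = {
                k: tuple(v) for k, v in raw["exposure_targets"].items()
            }
        if "followup_range" in raw:
            raw["followup_range"] = tuple(raw["followup_range"])
        return cls(**raw)


def _rngs(config: GeneratorConfig, seed=None) -> dict[str, np.random.Generator]:
    """Fan one seed out to independent named substreams."""
    root = np.random.SeedSequence(config.seed if seed is None else seed)
    names = ["exposures", "covariates", "followup", "events"]
    return {n: np.random.default_rng(s) for n, s in zip(names, root.spawn(len(names)))}


# ---------------------------------------------------------------------------
# exposures


def generate_exposures(
    config: GeneratorConfig,
    n_subjects: int | None = None,
    n_years: int = 13,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Draw subject-year exposures from a Gaussian copula with AR(1) memory.

    The latent process per subject is Z_1 ~ N(0, C) and
    Z_y = ar1 * Z_{y-1} + sqrt(1 - ar1^2) * eps_y with eps_y ~ N(0, C), so the
    stationary cross-correlation is C and the within-exposure year-to-year
    autocorrelation is ``ar1``.  Marginals are scaled to the target mean/SD
    and clipped at zero (concentrations cannot be negative).

    Returns a frame with ``subject_id, year`` and one column per exposure,
    covering ``n_years`` calendar years from ``baseline_year``.
    """
    if rng is None:
        rng = _rngs(config)["exposures"]
    n = int(n_subjects or config.n_subjects)
    names = config.exposure_names
    k = len(names)
    C = np.asarray(config.exposure_correlations, dtype=float)
    L = np.linalg.cholesky(C)
    rho = float(config.ar1)

    Z = np.empty((n_years, n, k))
    Z[0] = rng.standard_normal((n, k)) @ L.T
    scale = math.sqrt(1.0 - rho * rho)
    for y in range(1, n_years):
        Z[y] = rho * Z[y - 1] + scale * (rng.standard_normal((n, k)) @ L.T)

    years = config.baseline_year + np.arange(n_years)
    out = {
        "subject_id": np.tile([f"s{i:06d}" for i in range(n)], n_years),
        "year": np.repeat(years, n),
    }
    for j, name in enumerate(names):
        mean, sd = config.exposure_targets[name]
        vals = mean + sd * Z[:, :, j].reshape(-1)
        if name != "temp":  # concentrations are non-negative
            vals = np.maximum(vals, 0.0)
        out[name] = vals
    return pd.DataFrame(out)


# ---------------------------------------------------------------------------
# covariates


def generate_covariates(
    config: GeneratorConfig,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Independent categorical draws per covariate at the configured margins."""
    if rng is None:
        rng = _rngs(config)["covariates"]
    n = config.n_subjects
    out = {"subject_id": [f"s{i:06d}" for i in range(n)]}
    for cov, margin in config.covariate_margins.items():
        levels = list(margin)
        probs = np.array([margin[lev] for lev in levels], dtype=float)
        out[cov] = rng.choice(levels, size=n, p=probs / probs.sum())
    return pd.DataFrame(out)


# ---------------------------------------------------------------------------
# events


def _truncnorm(rng, mean, sd, lo, hi, size):
    from scipy.stats import truncnorm

    a, b = (lo - mean) / sd, (hi - mean) / sd
    return truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def _linear_predictors(
    subjects: pd.DataFrame,
    annual_exposures: pd.DataFrame,
    config: GeneratorConfig,
) -> tuple[pd.DataFrame, dict[str, np.ndarray]]:
    """Per subject-year log relative hazard, using quartile scores of the
    generated exposure table (cut points from all generated subject-years)."""
    lp = np.zeros(len(annual_exposures))
    exp_part = np.zeros(len(annual_exposures))
    cuts_used: dict[str, np.ndarray] = {}
    for name, beta in config.true_log_hr.items():
        if name in annual_exposures.columns:
            vals = annual_exposures[name].to_numpy(dtype=float)
            cuts = np.percentile(vals, [25.0, 50.0, 75.0])
            cuts_used[name] = cuts
            q = np.searchsorted(cuts, vals, side="left").astype(float)
            exp_part += float(beta) * q
        elif name in subjects.columns:
            level_map = config.true_log_hr[name]
            per_subj = subjects[name].map(lambda lev: float(level_map.get(lev, 0.0)))
            per_subj = per_subj.to_numpy()
            sid_to_lp = dict(zip(subjects["subject_id"].astype(str), per_subj))
            lp += annual_exposures["subject_id"].astype(str).map(sid_to_lp).to_numpy()
        else:
            raise ConfigError(f"true_log_hr names unknown variable {name!r}")
    # effect modifiers multiply the exposure part for subjects in the level
    if config.effect_modifiers:
        mult_subj = np.ones(len(subjects))
        for cov, level_map in config.effect_modifiers.items():
            labels = subjects[cov].astype(str)
            for lev, m in level_map.items():
                mult_subj *= np.where(labels == lev, float(m), 1.0)
        sid_to_m = dict(zip(subjects["subject_id"].astype(str), mult_subj))
        mult = annual_exposures["subject_id"].astype(str).map(sid_to_m).to_numpy()
        exp_part = exp_part * mult
    lp = lp + exp_part
    out = annual_exposures[["subject_id", "year"]].copy()
    out["lp"] = lp
    return out, cuts_used


def simulate_events(
    subjects: pd.DataFrame,
    annual_exposures: pd.DataFrame,
    config: GeneratorConfig,
    rng: np.random.Generator | None = None,
    followup_rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Piecewise-exponential event simulation with optional incidence calibration.

    Within each subject-calendar-year the hazard is
    ``lambda0 * exp(sum_j beta_j q_j(year) + covariate terms)``; event times
    come from inverse-transform sampling of the accumulated hazard across
    years.  Follow-up durations are truncated-normal; the event is recorded
    only if it precedes censoring.  With
    ``baseline_hazard="calibrate_to_incidence"``, lambda0 is solved by
    bisection so the expected event fraction (given the drawn follow-up and
    covariates) equals ``target_incidence``.

    Returns a follow-up frame (``subject_id, entry, exit, event``) and a dict
    of realized-calibration details (lambda0, expected incidence, cut points).
    """
    rngs = _rngs(config)
    if rng is None:
        rng = rngs["events"]
    if followup_rng is None:
        followup_rng = rngs["followup"]
    n = len(subjects)
    entry = config.baseline_year + followup_rng.uniform(0.0, 1.0, size=n)
    dur = _truncnorm(
        followup_rng, config.followup_mean, config.followup_sd,
        config.followup_range[0], config.followup_range[1], n,
    )

    lp_df, cuts_used = _linear_predictors(subjects, annual_exposures, config)
    # pivot to (subject, year) matrix of relative hazards
    years = np.sort(annual_exposures["year"].unique())
    lp_mat = (
        lp_df.pivot(index="subject_id", columns="year", values="lp")
        .loc[subjects["subject_id"].astype(str), years]
        .to_numpy()
    )
    rel = np.exp(lp_mat)  # (n, n_years)

    # per subject-year at-risk fraction within each calendar year
    year0 = years[0]
    exit_cal = entry + dur
    frac = np.zeros_like(rel)
    for j, y in enumerate(years):
        lo = np.maximum(entry, float(y))
        hi = np.minimum(exit_cal, float(y + 1))
        frac[:, j] = np.maximum(hi - lo, 0.0)
    cum_rel = (rel * frac).sum(axis=1)  # integral of exp(lp) dt over follow-up

    if config.baseline_hazard == "calibrate_to_incidence":
        if np.all(cum_rel <= 0):
            raise CalibrationError("all-zero hazard: cannot calibrate incidence")
        target = float(config.target_incidence)

        def expected_incidence(lam: float) -> float:
            return float(np.mean(1.0 - np.exp(-lam * cum_rel)))

        lo_l, hi_l = 1e-10, 1.0
        while expected_incidence(hi_l) < target:
            hi_l *= 2.0
            if hi_l > 1e6:
                raise CalibrationError("cannot reach target incidence")
        for _ in range(100):
            mid = 0.5 * (lo_l + hi_l)
            if expected_incidence(mid) < target:
                lo_l = mid
            else:
                hi_l = mid
        lam0 = 0.5 * (lo_l + hi_l)
    else:
        lam0 = float(config.baseline_hazard)

    # inverse-transform event times across the piecewise-constant hazard
    E = rng.exponential(1.0, size=n)
    haz = lam0 * rel * frac  # cumulative hazard contributed by each year slice
    cum = np.cumsum(haz, axis=1)
    total = cum[:, -1]
    event = E < total
    t_event = np.full(n, np.nan)
    if lam0 > 0:
        idx = np.argmax(cum >= E[:, None], axis=1)  # first slice where crossed
        prev = np.where(idx > 0, cum[np.arange(n), idx - 1], 0.0)
        within = (E - prev) / (lam0 * rel[np.arange(n), idx])
        slice_start = np.maximum(entry, year0 + idx.astype(float))
        t_event = slice_start + within
    exit_final = np.where(event, t_event, exit_cal)

    followup = pd.DataFrame(
        {
            "subject_id": subjects["subject_id"].astype(str),
            "entry": entry,
            "exit": exit_final,
            "event": event.astype(int),
        }
    )
    info = {
        "lambda0": float(lam0),
        "expected_incidence": float(np.mean(1.0 - np.exp(-lam0 * cum_rel))),
        "realized_incidence": float(event.mean()),
        "cut_points": {k: list(map(float, v)) for k, v in cuts_used.items()},
    }
    return followup, info


# ---------------------------------------------------------------------------
# full pipeline


def make_cohort(config: GeneratorConfig, seed: int | None = None) -> tuple[Cohort, dict]:
    """Generate a full counting-process cohort and its calibration summary.

    Composes exposures, covariates, follow-up/events, and the
    counting-process expansion.  The summary reports realized incidence,
    person-years, and exposure correlations so calibration can be audited.
    """
    rngs = _rngs(config, seed)
    n_years = int(math.ceil(config.followup_range[1])) + 2
    exposures = generate_exposures(config, rng=rngs["exposures"], n_years=n_years)
    subjects = generate_covariates(config, rng=rngs["covariates"])
    followup, info = simulate_events(
        subjects, exposures, config, rng=rngs["events"], followup_rng=rngs["followup"]
    )
    cohort = expand_counting_process(
        subjects, exposures, followup,
        exposure_names=config.exposure_names,
        covariate_schema=config.covariate_schema,
    )
    names = config.exposure_names
    corr = cohort.data[names].corr().to_numpy()
    summary = {
        **info,
        "n_subjects": cohort.n_subjects,
        "n_events": cohort.n_events,
        "incidence": cohort.n_events / cohort.n_subjects,
        "person_years": cohort.person_years,
        "exposure_correlations": {
            f"{a}~{b}": float(corr[i, j])
            for i, a in enumerate(names)
            for j, b in enumerate(names)
            if i < j
        },
    }
    return cohort, summary
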