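"""End-to-end orchestration: simulate -> quantize -> fit -> PAF -> report.

One :class:`RunConfig` drives a full reproducible run.  A single global seed
is fanned out (via numpy SeedSequence) to the generator and the Monte-Carlo
PAF stage; all other stages are deterministic.  Every run writes its inputs,
fitted summaries, PAF draws, and report tables into an output directory,
plus a ``run.log`` recording versions, seeds, and realized calibration.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .cohort import Cohort, read_cohort, write_cohort
from .cox import fit_cox, spline_curve
from .paf import paf_mc_ci
from .qgcomp import fit_qgcomp
from .report import build_report, subgroup_fits
from .simulate import GeneratorConfig, make_cohort

__all__ = ["RunConfig", "run_pipeline", "DEFAULT_COVARIATES"]

log = logging.getLogger("qgsurv")

#: The study's main-model adjustment set (temperature enters as a numeric
#: covariate, not a mixture member).
DEFAULT_COVARIATES = [
    "age_group", "sex", "urbanicity", "region", "smoking", "drinking",
    "bmi_group", "marital", "income", "fuel", "education", "temp",
]


@dataclass
class RunConfig:
    generator: GeneratorConfig | str = field(default_factory=GeneratorConfig)
    mixture: list[str] = field(default_factory=lambda: ["pm25", "o3"])
    covariates: list[str] = field(default_factory=lambda: list(DEFAULT_COVARIATES))
    fit_single: bool = True
    fit_joint: bool = True
    fit_splines: bool = False
    paf_prevalence_model: str = "single-increment"
    paf_draws: int = 10_000
    subgroups: list[str] = field(default_factory=list)
    seed: int = 0
    output_dir: str = "qgsurv_run"

    def __post_init__(self) -> None:
        overlap = set(self.mixture) & set(self.covariates)
        if overlap:
            raise ValueError(f"mixture and covariates overlap: {sorted(overlap)}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        gen = raw.get("generator")
        if isinstance(gen, dict):
            raw["generator"] = GeneratorConfig(**gen)
        return cls(**raw)


def _fit_payload(names, coef, cov, loglik, n_events, converged) -> dict:
    return {
        "coefficients": dict(zip(names, map(float, coef))),
        "covariance": np.asarray(cov).tolist(),
        "log_likelihood": float(loglik),
        "n_events": int(n_events),
        "converged": bool(converged),
    }


def run_pipeline(config: RunConfig, output_dir: str | None = None) -> Path:
    """Execute the configured analysis; returns the run directory."""
    outdir = Path(output_dir or config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    try:
        return _run(config, outdir)
    finally:
        log.removeHandler(handler)
        handler.close()


def _run(config: RunConfig, outdir: Path) -> Path:
    seed_seq = np.random.SeedSequence(config.seed)
    sim_seed, paf_seed = (int(s.generate_state(1)[0] % (2**31)) for s in seed_seq.spawn(2))
    log.info("qgsurv %s, seed=%d (sim=%d, paf=%d)", __version__, config.seed, sim_seed, paf_seed)

    stage = "simulate"
    try:
        if isinstance(config.generator, (str, Path)):
            gen = GeneratorConfig()  # schema defaults for CSV input
            cohort = read_cohort(
                config.generator, gen.covariate_schema, gen.exposure_names
            )
            log.info("loaded cohort from %s", config.generator)
        else:
            cohort, summary = make_cohort(config.generator, seed=sim_seed)
            write_cohort(cohort, outdir / "cohort.csv")
            log.info("simulated cohort: %s", json.dumps(summary))
            (outdir / "calibration.json").write_text(json.dumps(summary, indent=2))

        fits = {}
        total_fits = {}
        stage = "fit-single"
        if config.fit_single:
            for exposure in config.mixture:
                fit = fit_cox(cohort, exposure, config.covariates)
                fits[exposure] = fit
                total_fits[exposure] = (fit.coef_[0], fit.standard_errors_[0])
                payload = _fit_payload(
                    fit.feature_names_in_, fit.coef_, fit.covariance_,
                    fit.log_likelihood_, fit.n_events_, fit.converged_,
                )
                payload["hazard_ratios"] = json.loads(
                    fit.hazard_ratios().to_json(orient="index")
                )
                (outdir / f"fit_{exposure}.json").write_text(json.dumps(payload, indent=2))

        stage = "fit-joint"
        qg = None
        if config.fit_joint:
            qg = fit_qgcomp(cohort, config.mixture, config.covariates)
            lo, hi = qg.joint_hr_ci()
            payload = _fit_payload(
                qg.cox_.feature_names_in_, qg.cox_.coef_, qg.cox_.covariance_,
                qg.cox_.log_likelihood_, qg.cox_.n_events_, qg.cox_.converged_,
            )
            payload.update({
                "psi": qg.psi_, "psi_se": qg.psi_se_,
                "joint_hr": qg.joint_hr_, "joint_hr_ci": [lo, hi],
                "weights": qg.weights_.to_dict(),
                "directions": {k: int(v) for k, v in qg.directions_.items()},
            })
            (outdir / "qgfit.json").write_text(json.dumps(payload, indent=2))
            total_fits["joint"] = (qg.psi_, qg.psi_se_)

        stage = "splines"
        if config.fit_splines:
            for exposure in config.mixture:
                curve = spline_curve(cohort, exposure, config.covariates)
                df = {
                    "grid": curve.grid.tolist(), "log_hr": curve.log_hr.tolist(),
                    "ci_low": curve.ci_low.tolist(), "ci_high": curve.ci_high.tolist(),
                    "reference": curve.reference,
                }
                (outdir / f"spline_{exposure}.json").write_text(json.dumps(df, indent=2))

        stage = "paf"
        pafs = {}
        if config.fit_single:
            for i, exposure in enumerate(config.mixture):
                pafs[exposure] = paf_mc_ci(
                    fits[exposure], exposure,
                    config.paf_prevalence_model, config.paf_draws, seed=paf_seed + i,
                )
        if qg is not None:
            pafs["joint"] = paf_mc_ci(
                qg, "mixture", config.paf_prevalence_model, config.paf_draws,
                seed=paf_seed + len(config.mixture),
            )
        (outdir / "paf.json").write_text(json.dumps({
            k: {"paf_pct": 100 * v.point,
                "ci_pct": [100 * v.ci[0], 100 * v.ci[1]],
                "n_draws": v.n_draws}
            for k, v in pafs.items()
        }, indent=2))

        stage = "subgroups"
        sub_results = []
        for var in config.subgroups:
            sub_results.extend(
                subgroup_fits(cohort, var, config.mixture, config.covariates)
            )

        stage = "report"
        tables = build_report(total_fits, sub_results, pafs)
        tables["hr_table"].to_csv(outdir / "table2.csv", index=False, float_format="%.17g")
        tables["paf_table"].to_csv(outdir / "paf_by_group.csv", index=False, float_format="%.17g")
        tables["heterogeneity"].to_csv(outdir / "heterogeneity.csv", index=False, float_format="%.17g")
        log.info("run complete: %s", outdir)
        return outdir
    except Exception as exc:
        log.error("stage %r failed: %s", stage, exc)
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
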