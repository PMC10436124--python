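import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from qgsurv import (
    GeneratorConfig,
    bonferroni,
    make_cohort,
    se_from_ci,
    subgroup_fits,
    vif,
    z_between,
)
from qgsurv.paf import PafEstimate
from qgsurv.report import add_temperature_quartiles, build_report, heterogeneity_table


class TestZBetween:
    def test_equal_estimates_give_p_one(self):
        t = z_between(0.3, 0.1, 0.3, 0.2)
        assert t.z == 0.0
        assert t.p_raw == 1.0

    def test_antisymmetry(self):
        a = z_between(0.5, 0.1, 0.2, 0.15)
        b = z_between(0.2, 0.15, 0.5, 0.1)
        assert a.z == pytest.approx(-b.z, abs=1e-15)
        assert a.p_raw == pytest.approx(b.p_raw, abs=1e-15)

    def test_quantile_identity_p_is_005(self):
        se1, se2 = 0.08, 0.06
        gap = 1.959963984540054 * np.hypot(se1, se2)
        t = z_between(0.1 + gap, se1, 0.1, se2)
        assert t.p_raw == pytest.approx(0.05, abs=1e-12)

    def test_rural_urban_pm25_difference_is_significant(self):
        # published subgroup table: rural HR 1.54 (1.30-1.83), urban 0.89
        # (0.76-1.05); back-calculated z-test must reproduce p < .001
        b_rural, se_rural = np.log(1.54), se_from_ci(1.30, 1.83)
        b_urban, se_urban = np.log(0.89), se_from_ci(0.76, 1.05)
        t = z_between(b_rural, se_rural, b_urban, se_urban)
        assert t.z == pytest.approx(4.57, abs=0.05)
        assert t.p_raw < 0.001
        assert t.p_raw == pytest.approx(5e-6, rel=0.5)

    def test_nonpositive_se_rejected(self):
        with pytest.raises(ValueError):
            z_between(0.1, 0.0, 0.2, 0.1)


class TestBonferroni:
    def test_simple_scaling(self):
        assert bonferroni([0.01], m=3)[0] == pytest.approx(0.03)

    def test_capped_at_one(self):
        assert bonferroni([0.5], m=4)[0] == 1.0

    @settings(derandomize=True, max_examples=50)
    @given(
        p=st.lists(st.floats(0, 1), min_size=1, max_size=6),
        m=st.integers(1, 10),
    )
    def test_adjusted_at_least_raw(self, p, m):
        adj = bonferroni(p, m=m)
        assert np.all(adj >= np.asarray(p) - 1e-15)
        assert np.all(adj <= 1.0)

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            bonferroni([1.2])


class TestVif:
    def test_orthogonal_columns_give_one(self):
        rng = np.random.default_rng(0)
        q, _ = np.linalg.qr(rng.normal(size=(200, 3)))
        q = q - q.mean(axis=0)  # orthogonal to the implicit intercept too
        q, _ = np.linalg.qr(q)
        out = vif(pd.DataFrame(q, columns=list("abc")))
        assert np.allclose(out, 1.0, atol=1e-8)

    def test_closed_form_for_known_correlation(self):
        # two standardized columns with correlation r: VIF = 1/(1 - r^2);
        # at the study's PM2.5-O3 correlation 0.663 that is 1.784
        rng = np.random.default_rng(1)
        n = 200_000
        z1 = rng.standard_normal(n)
        z2 = 0.663 * z1 + np.sqrt(1 - 0.663**2) * rng.standard_normal(n)
        out = vif(np.column_stack([z1, z2]))
        assert np.allclose(out, 1 / (1 - 0.663**2), atol=0.02)

    def test_exact_collinearity_reported_infinite(self):
        x = np.arange(50, dtype=float)
        out = vif(np.column_stack([x, 2 * x, np.random.default_rng(2).normal(size=50)]))
        assert np.isinf(out.iloc[0]) and np.isinf(out.iloc[1])

    def test_study_design_matrix_below_ten(self):
        from qgsurv.cohort import design_matrix, quantize
        from qgsurv.pipeline import DEFAULT_COVARIATES

        cfg = GeneratorConfig(n_subjects=3000)
        cohort, _ = make_cohort(cfg, seed=14)
        work, _ = quantize(cohort, "pm25")
        work, _ = quantize(work, "o3")
        X = design_matrix(work, ["pm25_q", "o3_q"] + DEFAULT_COVARIATES)
        assert vif(X).max() < 10


@pytest.fixture(scope="module")
def cohort():
    cfg = GeneratorConfig(n_subjects=3000, target_incidence=0.12)
    cohort, _ = make_cohort(cfg, seed=31)
    return cohort


class TestSubgroups:
    def test_levels_partition_subjects(self, cohort):
        res = subgroup_fits(cohort, "sex", covariates=["age_group"], models=("pm25",))
        assert sum(r.n_subjects for r in res) == cohort.n_subjects
        assert {r.level for r in res} == {"male", "female"}

    def test_subgroup_variable_dropped_from_adjustment(self, cohort):
        res = subgroup_fits(
            cohort, "sex", covariates=["sex", "age_group"], models=("pm25",)
        )
        # a sex dummy inside a single-sex stratum would be constant and fail
        # with a singular-information error; successful fits prove the drop
        assert len(res) == 2

    def test_homogeneous_truth_strata_agree(self, cohort):
        res = subgroup_fits(cohort, "sex", covariates=["age_group"], models=("joint",))
        het = heterogeneity_table(res)
        assert het["p_raw"].iloc[0] > 0.001  # no planted modification
        assert het["m"].iloc[0] == 1

    def test_planted_obesity_modifier_detected(self):
        mult = 3.0
        hr_obese, hr_rest = [], []
        for seed in range(3):
            cfg = GeneratorConfig(
                n_subjects=6000,
                effect_modifiers={"bmi_group": {"obese": mult}},
                target_incidence=0.12,
            )
            cohort, _ = make_cohort(cfg, seed=seed)
            res = subgroup_fits(
                cohort, "bmi_group", covariates=["sex"], models=("joint",)
            )
            by_level = {r.level: r.hr for r in res}
            hr_obese.append(by_level["obese"])
            hr_rest.append(by_level["normal"])
        assert np.mean(hr_obese) > np.mean(hr_rest)

    def test_temperature_quartile_strata(self, cohort):
        c2 = add_temperature_quartiles(cohort)
        counts = (
            c2.data.groupby("subject_id", sort=False)["temp_quartile"].first().value_counts()
        )
        assert set(counts.index) == {"Q1", "Q2", "Q3", "Q4"}
        assert counts.max() - counts.min() < 0.1 * cohort.n_subjects


class TestNullHeterogeneityCalibration:
    def test_false_positive_rate_near_nominal(self):
        # no effect modification planted: |z| > 1.96 should fire ~5% of runs
        rejections = 0
        n_runs = 60
        for seed in range(n_runs):
            cfg = GeneratorConfig(n_subjects=1500, target_incidence=0.15)
            cohort, _ = make_cohort(cfg, seed=1000 + seed)
            res = subgroup_fits(cohort, "sex", covariates=[], models=("pm25",))
            het = heterogeneity_table(res)
            rejections += abs(het["z"].iloc[0]) > 1.96
        rate = rejections / n_runs
        # 3-sigma binomial band around 0.05 at n=60
        assert rate <= 0.05 + 3 * np.sqrt(0.05 * 0.95 / n_runs)


class TestBuildReport:
    def test_empty_subgroups_total_rows_only(self):
        tables = build_report({"pm25": (0.1, 0.05)}, [], {})
        assert list(tables["hr_table"]["variable"]) == ["total"]
        assert tables["heterogeneity"].empty

    def test_roundtrip_csv(self, tmp_path):
        est = PafEstimate(point=0.043, ci=(0.011, 0.075), n_draws=100)
        tables = build_report({"joint": (np.log(1.18), 0.06)}, [], {"joint": est})
        p = tmp_path / "paf.csv"
        tables["paf_table"].to_csv(p, index=False, float_format="%.17g")
        back = pd.read_csv(p)
        assert np.allclose(back["paf_pct"], tables["paf_table"]["paf_pct"], atol=1e-12)

    def test_column_contract(self):
        tables = build_report({}, [], {})
        assert list(tables["hr_table"].columns) == [
            "variable", "level", "model", "hr", "ci_low", "ci_high", "beta", "se",
        ]
        assert list(tables["paf_table"].columns) == [
            "label", "paf_pct", "ci_low_pct", "ci_high_pct", "n_draws",
        ]
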