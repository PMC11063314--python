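"""Mixed-effects cohort models: estimates, Satterthwaite p-values, LRTs."""

import shutil
import subprocess

import numpy as np
import pytest

from ofsca import (
    CohortDesign,
    ComponentSpec,
    ConditionEffect,
    OfscaResult,
    build_cohort_table,
    fit_interaction_model,
    fit_model1,
    fit_model2,
    generate_cohort_truth,
    likelihood_ratio_test,
)

HR_EFFECT = -12.895  # degrees, the head-rotation shift used throughout


def _design(effect_deg=0.0, **kw):
    effect_map = {}
    if effect_deg:
        effect_map = {
            ("EyesOpen", "HeadRotation"): ConditionEffect(delta_theta_deg=effect_deg),
            ("EyesClosed", "HeadRotation"): ConditionEffect(delta_theta_deg=effect_deg),
        }
    # baseline axis separation 81.2 deg, mirroring a quiet-stance cohort
    return CohortDesign(
        effect_map=effect_map,
        base_spec1=ComponentSpec(0.9, 90.0),
        base_spec2=ComponentSpec(0.6, 8.8),
        **kw,
    )


def _with_covariates(table, seed=0):
    rng = np.random.default_rng(seed)
    t = table.copy()
    t["sd_h"] = 0.10 + 0.02 * rng.standard_normal(len(t))
    t["h1"] = 0.85 + 0.05 * rng.standard_normal(len(t))
    t["h2"] = 0.60 + 0.05 * rng.standard_normal(len(t))
    return t


def _result(participant, vision, phase, delta=80.0, degenerate=False):
    return OfscaResult(
        theta1_deg=90.0,
        theta2_deg=(90.0 - delta) % 180.0,
        delta_theta_deg=delta,
        h1=0.9,
        h2=0.6,
        sd_h=0.1,
        theta_max_deg=0.0,
        theta_min_deg=0.0,
        degenerate=degenerate,
        meta={"participant": participant, "vision": vision, "phase": phase},
    )


class TestCohortTable:
    def test_all_labelled_results_become_rows(self):
        results = [
            _result(f"P{p}", v, ph)
            for p in range(17)
            for v in ("EyesOpen", "EyesClosed")
            for ph in ("Before", "HeadRotation", "After")
        ]
        table = build_cohort_table(results)
        assert len(table) == 102

    def test_degenerate_trials_are_excluded_with_warning(self, caplog):
        results = [
            _result("P1", "EyesOpen", "Before"),
            _result("P1", "EyesOpen", "HeadRotation", degenerate=True),
            _result("P2", "EyesClosed", "After"),
        ]
        with caplog.at_level("WARNING"):
            table = build_cohort_table(results)
        assert len(table) == 2
        assert "degenerate" in caplog.text

    def test_unknown_phase_level_rejected(self):
        with pytest.raises(ValueError, match="During"):
            build_cohort_table([_result("P1", "EyesOpen", "During")])

    def test_missing_labels_rejected(self):
        r = _result("P1", "EyesOpen", "Before")
        del r.meta["participant"]
        with pytest.raises(ValueError, match="participant"):
            build_cohort_table([r])


class TestModel1:
    def test_null_cohort_coefficients_are_within_2se_of_zero(self):
        fit = fit_model1(generate_cohort_truth(_design(0.0), seed=0))
        for term in ("Vision[EyesClosed]", "Phase[HeadRotation]", "Phase[After]"):
            row = fit.terms.loc[term]
            assert abs(row["B"]) < 2.0 * row["SE"]

    def test_injected_head_rotation_effect_recovered_within_2se(self):
        fit = fit_model1(generate_cohort_truth(_design(HR_EFFECT), seed=0))
        row = fit.terms.loc["Phase[HeadRotation]"]
        assert abs(row["B"] - HR_EFFECT) < 2.0 * row["SE"]

    def test_t_equals_b_over_se_exactly(self):
        fit = fit_model1(generate_cohort_truth(_design(HR_EFFECT), seed=3))
        assert np.allclose(fit.terms["t"], fit.terms["B"] / fit.terms["SE"])

    def test_single_participant_rejected(self):
        table = generate_cohort_truth(_design(0.0, n_participants=1), seed=0)
        with pytest.raises(ValueError, match="participants"):
            fit_model1(table)

    def test_type_one_error_is_near_nominal_on_null_cohorts(self):
        """~5% of null cohorts reject the head-rotation term at alpha=0.05."""
        rejections = 0
        n_cohorts = 50
        for s in range(n_cohorts):
            table = generate_cohort_truth(_design(0.0), seed=20_000 + s)
            p = fit_model1(table).terms.loc["Phase[HeadRotation]", "p"]
            rejections += p < 0.05
        # binomial(50, 0.05): mean 2.5, sd 1.54; allow 3 sigma upward
        assert rejections <= 7


class TestModel2:
    def test_uninformative_covariates_stay_within_2se_of_zero(self):
        table = _with_covariates(generate_cohort_truth(_design(0.0), seed=1), seed=11)
        fit = fit_model2(table)
        for term in ("SD_H", "H1", "H2"):
            row = fit.terms.loc[term]
            assert abs(row["B"]) < 2.0 * row["SE"]

    def test_positive_sd_h_dependence_recovers_sign(self):
        """delta built with +300 deg per unit SD_H: sign found in >=19/20."""
        hits = 0
        for s in range(20):
            rng = np.random.default_rng(500 + s)
            table = _with_covariates(
                generate_cohort_truth(_design(0.0), seed=600 + s), seed=s
            )
            table["delta_theta"] = (
                50.0 + 300.0 * table["sd_h"] + rng.normal(0, 5, len(table))
            )
            hits += fit_model2(table).terms.loc["SD_H", "B"] > 0
        assert hits >= 19

    def test_collinear_h_columns_rejected(self):
        table = _with_covariates(generate_cohort_truth(_design(0.0), seed=2))
        table["h2"] = table["h1"]
        with pytest.raises(ValueError, match="rank deficient"):
            fit_model2(table)


@pytest.fixture(scope="module")
def fits():
    table = _with_covariates(generate_cohort_truth(_design(HR_EFFECT), seed=4))
    return fit_model1(table), fit_model2(table), fit_interaction_model(table)


class TestLrt:
    def test_self_comparison_is_null(self, fits):
        res = likelihood_ratio_test(fits[0], fits[0])
        assert res.chi2 == pytest.approx(0.0, abs=1e-8)
        assert res.p == pytest.approx(1.0)

    def test_model1_vs_model2_has_3_df(self, fits):
        res = likelihood_ratio_test(fits[0], fits[1])
        assert res.df == 3
        assert res.chi2 >= 0.0
        assert 0.0 <= res.p <= 1.0

    def test_model1_vs_interaction_has_2_df(self, fits):
        res = likelihood_ratio_test(fits[0], fits[2])
        assert res.df == 2
        assert res.chi2 >= 0.0

    def test_non_nested_pair_rejected(self, fits):
        with pytest.raises(ValueError, match="not nested"):
            likelihood_ratio_test(fits[1], fits[2])


@pytest.mark.skipif(shutil.which("Rscript") is None, reason="Rscript not available")
class TestAgainstLmerTest:
    """Independent oracle: R lme4/lmerTest on the same table."""

    def test_model1_matches_lmer_coefficients_df_and_loglik(self, tmp_path):
        table = _with_covariates(generate_cohort_truth(_design(HR_EFFECT), seed=0))
        csv = tmp_path / "table.csv"
        table.to_csv(csv, index=False)
        script = tmp_path / "check.R"
        script.write_text(
            f"""
            suppressMessages(library(lmerTest))
            t <- read.csv("{csv}")
            t$vision <- relevel(factor(t$vision), ref="EyesOpen")
            t$phase <- relevel(factor(t$phase), ref="Before")
            m <- lmer(delta_theta ~ vision + phase + (1|participant), data=t)
            co <- summary(m)$coefficients
            for (r in rownames(co))
              cat(r, co[r,"Estimate"], co[r,"Std. Error"], co[r,"df"],
                  co[r,"Pr(>|t|)"], "\\n")
            cat("REML", logLik(m), "\\n")
            m2 <- lmer(delta_theta ~ vision + phase + (1|participant),
                       data=t, REML=FALSE)
            cat("ML", logLik(m2), "\\n")
            """
        )
        out = subprocess.run(
            ["Rscript", str(script)], capture_output=True, text=True, check=True
        ).stdout
        r_rows = {}
        for line in out.strip().splitlines():
            parts = line.split()
            r_rows[parts[0]] = [float(v) for v in parts[1:]]

        fit = fit_model1(table)
        name_map = {
            "(Intercept)": "Intercept",
            "visionEyesClosed": "Vision[EyesClosed]",
            "phaseHeadRotation": "Phase[HeadRotation]",
            "phaseAfter": "Phase[After]",
        }
        for r_name, term in name_map.items():
            b, se, df, p = r_rows[r_name]
            row = fit.terms.loc[term]
            assert row["B"] == pytest.approx(b, rel=1e-5)
            assert row["SE"] == pytest.approx(se, rel=1e-4)
            assert row["df"] == pytest.approx(df, rel=0.02)
            assert row["p"] == pytest.approx(p, rel=0.05, abs=1e-12)
        assert fit.loglik_reml == pytest.approx(r_rows["REML"][0], abs=1e-3)
        assert fit.loglik_ml == pytest.approx(r_rows["ML"][0], abs=1e-3)
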