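"""Tests for cohort-level analyses: HOMA-IR, quartile gradients,
adjusted associations, sensitivity and descriptives."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from med4child import (
    adjusted_association,
    describe_cohort,
    homa_ir,
    quartile_summary,
    sensitivity_exclude,
)
from med4child.analysis import p_trend
from med4child.errors import (
    ConfigurationError,
    DomainError,
    InsufficientDataError,
    RankDeficiencyError,
)
from med4child.scoring import score_table


class TestHomaIR:
    def test_zero_insulin(self):
        assert homa_ir(90.0, 0.0) == 0.0

    def test_cited_closed_form(self):
        assert homa_ir(90.0, 4.5) == pytest.approx(1.0)

    def test_denominator_identity(self):
        assert homa_ir(405.0, 1.0) == pytest.approx(1.0)

    def test_vectorized(self):
        out = homa_ir([90.0, 405.0], [4.5, 1.0])
        assert np.allclose(out, [1.0, 1.0])

    def test_domain_errors(self):
        with pytest.raises(DomainError):
            homa_ir(0.0, 4.0)
        with pytest.raises(DomainError):
            homa_ir(90.0, -1.0)


def make_scores(totals, quartiles):
    return pd.DataFrame(
        {
            "child_id": [f"c{i}" for i in range(len(totals))],
            "total": totals,
            "quartile": quartiles,
        }
    )


class TestQuartileSummary:
    def test_textbook_anova_arithmetic(self):
        """Three observations per group; F from hand-computed sums of
        squares (SSB=6 over df 2, SSW=6 over df 6, F=3) fixes the p."""
        values = [1, 2, 3, 2, 3, 4, 3, 4, 5, 4, 5, 6]
        quartiles = ["Q1"] * 3 + ["Q2"] * 3 + ["Q3"] * 3 + ["Q4"] * 3
        scores = make_scores(range(12), quartiles)
        ffq = pd.DataFrame({"child_id": scores["child_id"], "x": values})
        out = quartile_summary(ffq, scores, ["x"])
        row = out.iloc[0]
        # group means 2,3,4,5; grand mean 3.5; SSB = 3*(2.25+0.25+0.25+2.25)=15
        # SSW = 2 per group = 8; F = (15/3)/(8/8) = 5
        assert row["Q1_mean"] == pytest.approx(2.0)
        assert row["Q4_mean"] == pytest.approx(5.0)
        assert row["anova_p"] == pytest.approx(stats.f.sf(5.0, 3, 8), abs=1e-12)

    def test_perfect_gradient(self):
        rng = np.random.default_rng(0)
        quartiles = np.repeat(["Q1", "Q2", "Q3", "Q4"], 25)
        values = np.repeat([10.0, 20.0, 30.0, 40.0], 25) + rng.normal(0, 0.01, 100)
        scores = make_scores(range(100), quartiles)
        ffq = pd.DataFrame({"child_id": scores["child_id"], "x": values})
        out = quartile_summary(ffq, scores, ["x"])
        assert out.iloc[0]["trend_p"] < 1e-20
        assert out.iloc[0]["trend_slope"] == pytest.approx(10.0, abs=0.01)

    def test_null_case_flat(self):
        rng = np.random.default_rng(1)
        quartiles = np.repeat(["Q1", "Q2", "Q3", "Q4"], 500)
        values = rng.normal(0, 1, 2000)
        scores = make_scores(range(2000), quartiles)
        ffq = pd.DataFrame({"child_id": scores["child_id"], "x": values})
        out = quartile_summary(ffq, scores, ["x"])
        assert abs(out.iloc[0]["trend_slope"]) < 0.1

    def test_zero_variance_flagged(self):
        quartiles = np.repeat(["Q1", "Q2"], 5)
        scores = make_scores(range(10), quartiles)
        ffq = pd.DataFrame({"child_id": scores["child_id"], "x": [3.0] * 10})
        out = quartile_summary(ffq, scores, ["x"])
        assert out.iloc[0]["flag"] == "zero_variance"
        assert np.isnan(out.iloc[0]["anova_p"])

    def test_p_trend_null_is_uniform(self):
        """Under a simulated null the trend p-value is uniform
        (Kolmogorov-Smirnov at alpha = 0.01)."""
        rng = np.random.default_rng(42)
        rank = np.repeat([1, 2, 3, 4], 20)
        pvals = [
            p_trend(rng.normal(0, 1, 80), rank)[1] for _ in range(1000)
        ]
        assert stats.kstest(pvals, "uniform").pvalue > 0.01


class TestAdjustedAssociation:
    def make_outcomes(self, n, rng, score, beta=0.0, sd=1.0):
        age = rng.uniform(3, 6, n)
        sex = rng.choice(["boy", "girl"], n)
        y = 10 + beta * score + 0.5 * age + rng.normal(0, sd, n)
        return pd.DataFrame(
            {"child_id": [f"c{i}" for i in range(n)], "age": age, "sex": sex, "y": y}
        )

    def test_exact_linear_recovery(self):
        rng = np.random.default_rng(3)
        score = rng.integers(0, 19, 200)
        scores = make_scores(score, ["Q1"] * 200)
        out = self.make_outcomes(200, rng, score, beta=2.0, sd=1e-12)
        res = adjusted_association(scores, out, "y")
        assert res.beta == pytest.approx(2.0, abs=1e-6)
        assert res.ci[1] - res.ci[0] < 1e-6

    def test_null_outcome(self):
        rng = np.random.default_rng(4)
        score = rng.integers(0, 19, 2000)
        scores = make_scores(score, ["Q1"] * 2000)
        out = self.make_outcomes(2000, rng, score, beta=0.0, sd=1.0)
        res = adjusted_association(scores, out, "y")
        assert res.ci[0] < 0.0 < res.ci[1]

    def test_simple_regression_closed_form_no_covariates(self):
        """With no covariates the slope equals cov(x,y)/var(x)."""
        rng = np.random.default_rng(5)
        score = rng.integers(0, 19, 300).astype(float)
        y = 1.5 * score + rng.normal(0, 2, 300)
        scores = make_scores(score, ["Q1"] * 300)
        out = pd.DataFrame({"child_id": scores["child_id"], "y": y})
        res = adjusted_association(scores, out, "y", covariates=())
        closed = np.cov(score, y, ddof=1)[0, 1] / np.var(score, ddof=1)
        assert res.beta == pytest.approx(closed, rel=1e-10)

    def test_collinear_design_rejected(self):
        rng = np.random.default_rng(6)
        score = rng.integers(0, 19, 50)
        scores = make_scores(score, ["Q1"] * 50)
        out = pd.DataFrame(
            {
                "child_id": scores["child_id"],
                "y": rng.normal(0, 1, 50),
                "dup": score.astype(float),  # exactly collinear with the score
            }
        )
        with pytest.raises(RankDeficiencyError):
            adjusted_association(scores, out, "y", covariates=("dup",))

    def test_too_few_cases(self):
        scores = make_scores([1, 2, 3], ["Q1"] * 3)
        out = pd.DataFrame(
            {"child_id": scores["child_id"], "age": [4, 5, 6],
             "sex": ["boy", "girl", "boy"], "y": [1.0, 2.0, 3.0]}
        )
        with pytest.raises(InsufficientDataError):
            adjusted_association(scores, out, "y")

    def test_recovers_generator_effect(self, registry):
        """Parameter recovery on a synthetic cohort: the fitted waist-
        circumference slope agrees with the generating slope within three
        standard errors."""
        from med4child import generate_cohort, preset_calibrated

        cohort = generate_cohort(preset_calibrated(n=5000, seed=17))
        scored = score_table(cohort.questionnaire, registry)
        res = adjusted_association(scored, cohort.outcomes, "wc")
        beta_true = cohort.config.outcome_effects["wc"].beta_score
        se = (res.ci[1] - res.ci[0]) / (2 * 1.96)
        assert abs(res.beta - beta_true) < 3 * se


@pytest.fixture(scope="module")
def cohort():
    from med4child import generate_cohort, preset_calibrated

    return generate_cohort(preset_calibrated(n=800, seed=23))


class TestSensitivity:

    def test_dropping_nothing_is_identity(self, cohort, registry):
        out = sensitivity_exclude(
            [], cohort.questionnaire, cohort.outcomes, ["wc", "hdl"], registry
        )
        assert np.allclose(out["beta_full"], out["beta_reduced"])

    def test_dropping_all_items_rejected(self, cohort, registry):
        with pytest.raises(ConfigurationError):
            sensitivity_exclude(
                range(1, 19), cohort.questionnaire, cohort.outcomes, ["wc"], registry
            )

    def test_reduced_score_beta_close_when_effect_on_healthy_items(
        self, cohort, registry
    ):
        out = sensitivity_exclude(
            (12, 13, 14, 15, 16, 17, 18),
            cohort.questionnaire,
            cohort.outcomes,
            ["wc"],
            registry,
        )
        row = out.iloc[0]
        se = (row["ci_high_full"] - row["ci_low_full"]) / (2 * 1.96)
        assert abs(row["beta_full"] - row["beta_reduced"]) < 4 * se


class TestDescribeCohort:
    def make_table(self, shift=0.0, n=60, seed=0):
        rng = np.random.default_rng(seed)
        sex = np.repeat(["boy", "girl"], n // 2)
        vals = rng.normal(50, 5, n) + np.where(sex == "girl", shift, 0.0)
        return pd.DataFrame(
            {"child_id": [f"c{i}" for i in range(n)], "sex": sex, "wc": vals,
             "tg": rng.lognormal(4, 0.3, n)}
        )

    def test_identical_groups_high_p(self):
        out = describe_cohort(self.make_table(0.0), by="sex", variables=["wc"])
        assert out.iloc[0]["p_value"] > 0.05

    def test_separated_groups_tiny_p(self):
        out = describe_cohort(self.make_table(50.0), by="sex", variables=["wc"])
        assert out.iloc[0]["p_value"] < 1e-10

    def test_hand_computed_t(self):
        """Equal-size equal-variance groups: Welch equals the pooled t."""
        df = pd.DataFrame(
            {"child_id": list("abcdef"), "sex": ["boy"] * 3 + ["girl"] * 3,
             "x": [1.0, 2.0, 3.0, 4.0, 5.0, 6.0]}
        )
        out = describe_cohort(df, by="sex", variables=["x"])
        t_hand = -3.0 / np.sqrt(1.0 * (1 / 3 + 1 / 3))
        p_hand = 2 * stats.t.sf(abs(t_hand), 4)
        assert out.iloc[0]["p_value"] == pytest.approx(p_hand, abs=1e-12)

    def test_skewed_variables_use_median_and_ranks(self):
        out = describe_cohort(self.make_table(), by="sex", variables=["tg"])
        assert out.iloc[0]["kind"] == "median_iqr"
        assert ";" in out.iloc[0]["summary"]
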