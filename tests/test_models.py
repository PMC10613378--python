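"""Univariate screens, logistic fits, model reduction and the null
calibration of Wald inference."""

import numpy as np
import pandas as pd
import pytest

from peernet.exceptions import ConfigurationError
from peernet.models import (
    ModelSpec,
    fit_logistic,
    fit_random_intercept,
    reduce_model,
    univariate_tests,
)


def two_by_two(a, b, c, d):
    """Binary outcome/exposure data with cell counts (a,b,c,d):
    a = exposed participants, b = exposed decliners,
    c = unexposed participants, d = unexposed decliners."""
    y = [1] * a + [0] * b + [1] * c + [0] * d
    x = [1] * (a + b) + [0] * (c + d)
    return pd.DataFrame({"participated": y, "x": x})


class TestModelSpec:
    def test_age_requires_observed_indicator(self):
        with pytest.raises(ConfigurationError, match="age_observed"):
            ModelSpec(outcome="participated", terms=("age",))

    def test_age_pair_allowed(self):
        spec = ModelSpec(outcome="participated", terms=("age", "age_observed"))
        assert spec.column_names() == ["const", "age", "age_observed"]


class TestFitLogistic:
    def test_saturated_two_by_two_matches_odds_ratio(self):
        data = two_by_two(20, 10, 10, 20)
        spec = ModelSpec(outcome="participated", terms=("x",))
        fit = fit_logistic(spec, data)
        assert fit.table.loc["x", "odds_ratio"] == pytest.approx(4.0, abs=1e-6)

    def test_ci_is_exp_of_coefficient_ci(self):
        data = two_by_two(25, 15, 12, 22)
        fit = fit_logistic(ModelSpec(outcome="participated", terms=("x",)), data)
        row = fit.table.loc["x"]
        z = 1.959963984540054
        assert row["ci_low"] == pytest.approx(np.exp(row["coef"] - z * row["se"]))
        assert row["ci_high"] == pytest.approx(np.exp(row["coef"] + z * row["se"]))

    def test_duplicated_predictor_reported_singular(self):
        data = two_by_two(20, 10, 10, 20).assign(x2=lambda d: d["x"])
        spec = ModelSpec(outcome="participated", terms=("x", "x2"))
        with pytest.raises(ConfigurationError, match="collinear"):
            fit_logistic(spec, data)

    def test_complete_separation_flagged_not_raised(self):
        data = pd.DataFrame(
            {"participated": [0] * 20 + [1] * 20, "x": list(range(40))}
        )
        fit = fit_logistic(ModelSpec(outcome="participated", terms=("x",)), data)
        assert fit.warnings

    def test_null_wald_type_one_error_calibrated(self):
        """Under beta=0 the Wald test for a standard-normal covariate rejects
        at close to its nominal 5% level."""
        rng = np.random.default_rng(77)
        rejections = 0
        reps = 400
        for _ in range(reps):
            n = 2000
            x = rng.normal(size=n)
            y = rng.integers(0, 2, size=n)
            data = pd.DataFrame({"participated": y, "x": x})
            fit = fit_logistic(ModelSpec(outcome="participated", terms=("x",)), data)
            rejections += fit.table.loc["x", "p"] < 0.05
        assert 0.025 <= rejections / reps <= 0.08


class TestRandomInterceptInterface:
    def test_requires_grouping_column(self):
        data = two_by_two(5, 5, 5, 5)
        spec = ModelSpec(
            outcome="participated", terms=("x",), random_intercept="hospital"
        )
        with pytest.raises(Exception, match="hospital"):
            fit_random_intercept(spec, data)

    def test_reports_tau(self):
        rng = np.random.default_rng(9)
        n_groups, size = 25, 16
        g = np.repeat(np.arange(n_groups), size)
        theta = rng.normal(0, 1.0, n_groups)
        x = rng.normal(size=n_groups * size)
        eta = 0.2 + 0.5 * x + theta[g]
        y = (rng.random(n_groups * size) < 1 / (1 + np.exp(-eta))).astype(int)
        data = pd.DataFrame({"participated": y, "x": x, "hospital": g})
        spec = ModelSpec(
            outcome="participated", terms=("x",), random_intercept="hospital"
        )
        fit = fit_random_intercept(spec, data)
        assert fit.tau is not None and fit.tau > 0.3
        assert fit.method == "glmm-gauss-hermite"


class TestUnivariate:
    def test_chi_squared_without_continuity_correction(self):
        data = two_by_two(20, 10, 10, 20).assign(
            grp=lambda d: np.where(d["x"] == 1, "yes", "no")
        )
        out = univariate_tests(data, categorical=("grp",))
        row = out[out.variable == "grp"].iloc[0]
        assert row["statistic"] == pytest.approx(6.66667, abs=1e-4)

    def test_equal_groups_t_zero(self):
        data = pd.DataFrame(
            {"participated": [1, 1, 0, 0], "v": [3.0, 5.0, 3.0, 5.0]}
        )
        out = univariate_tests(data, continuous=("v",))
        assert out.iloc[0]["statistic"] == pytest.approx(0.0)

    def test_constant_variable_skipped(self):
        data = pd.DataFrame({"participated": [1, 0, 1, 0], "v": [2.0] * 4})
        out = univariate_tests(data, continuous=("v",))
        assert "skipped" in out.iloc[0]["note"]

    def test_missing_values_excluded_from_t_test(self):
        data = pd.DataFrame(
            {
                "participated": [1, 1, 1, 0, 0, 0],
                "age": [40.0, np.nan, 44.0, 50.0, 52.0, np.nan],
            }
        )
        out = univariate_tests(data, continuous=("age",))
        row = out.iloc[0]
        assert row["n_missing"] == 2
        assert row["mean_participated"] == pytest.approx(42.0)
        assert row["mean_declined"] == pytest.approx(51.0)

    def test_null_p_values_roughly_uniform(self):
        """With permuted labels the t-test p-value distribution is uniform:
        about alpha of replicates fall below alpha."""
        rng = np.random.default_rng(15)
        hits = 0
        reps = 300
        for _ in range(reps):
            data = pd.DataFrame(
                {
                    "participated": rng.permutation([1] * 100 + [0] * 100),
                    "v": rng.normal(size=200),
                }
            )
            out = univariate_tests(data, continuous=("v",))
            hits += out.iloc[0]["p"] < 0.1
        assert 0.05 < hits / reps < 0.16


class TestReduceModel:
    def simulated_frame(self, seed=0, n=1500):
        rng = np.random.default_rng(seed)
        strong = rng.normal(size=n)
        noise1 = rng.normal(size=n)
        noise2 = rng.normal(size=n)
        eta = -0.1 + 1.0 * strong
        y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(int)
        return pd.DataFrame(
            {"participated": y, "strong": strong, "noise1": noise1, "noise2": noise2}
        )

    def test_keeps_significant_terms(self):
        data = self.simulated_frame()
        spec = ModelSpec(outcome="participated", terms=("strong",))
        final, trace, _ = reduce_model(spec, data)
        assert final.terms == ("strong",)
        assert trace == []

    def test_drops_noise_keeps_signal(self):
        data = self.simulated_frame(seed=3)
        spec = ModelSpec(
            outcome="participated", terms=("strong", "noise1", "noise2")
        )
        final, trace, fit = reduce_model(spec, data)
        assert "strong" in final.terms
        assert len(trace) == len(spec.terms) - len(final.terms)
        assert (fit.table.drop(index="const")["p"] < 0.05).all()

    def test_pure_noise_reduces_to_intercept_only(self):
        rng = np.random.default_rng(8)
        n = 2000
        data = pd.DataFrame(
            {
                "participated": rng.integers(0, 2, n),
                "a": rng.normal(size=n),
                "b": rng.normal(size=n),
            }
        )
        final, trace, _ = reduce_model(
            ModelSpec(outcome="participated", terms=("a", "b")), data
        )
        assert final.terms == ()
        assert len(trace) == 2

    def test_marginality_interaction_removed_before_main_effects(self):
        rng = np.random.default_rng(12)
        n = 1200
        a = rng.normal(size=n)
        b = rng.normal(size=n)
        eta = 0.8 * a + 0.8 * b  # no interaction signal
        y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(int)
        data = pd.DataFrame({"participated": y, "a": a, "b": b})
        spec = ModelSpec(
            outcome="participated", terms=("a", "b"), interactions=(("a", "b"),)
        )
        final, trace, _ = reduce_model(spec, data)
        assert final.interactions == ()
        assert set(final.terms) == {"a", "b"}

    def test_age_pair_travels_together(self):
        rng = np.random.default_rng(30)
        n = 1500
        obs = (rng.random(n) < 0.85).astype(float)
        age_c = rng.normal(size=n) * obs
        noise = rng.normal(size=n)
        y = rng.integers(0, 2, n)  # pure noise outcome: everything should go
        data = pd.DataFrame(
            {"participated": y, "age": age_c, "age_observed": obs, "noise": noise}
        )
        spec = ModelSpec(
            outcome="participated", terms=("age", "age_observed", "noise")
        )
        final, trace, _ = reduce_model(spec, data)
        # the pair leaves as one unit; no intermediate spec ever had age alone
        assert ("age" in final.terms) == ("age_observed" in final.terms)
        for step in trace:
            assert step["removed"] != ["age"]
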