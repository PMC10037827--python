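import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from symnetmap import (
    CollinearityError,
    DegenerateInputError,
    cohens_d,
    correlation_matrix,
    group_tests,
    moderation_analysis,
    pearson_fc,
    property_interaction_glm,
)


class TestCohensD:
    @pytest.mark.parametrize(
        "m1, s1, n1, m2, s2, n2, expected",
        [
            (28.33, 1.43, 58, 26.70, 1.71, 73, 1.024),   # general cognition screen
            (82.62, 7.15, 58, 77.07, 7.09, 73, 0.780),   # cognitive examination
            (6.71, 1.88, 58, 2.07, 1.47, 73, 2.790),     # long-term delayed recall
        ],
    )
    def test_reproduces_reported_group_effect_sizes(self, m1, s1, n1, m2, s2, n2, expected):
        assert cohens_d(m1, s1, n1, m2, s2, n2).d == pytest.approx(expected, abs=0.005)

    def test_ci_matches_reported_interval(self):
        eff = cohens_d(28.33, 1.43, 58, 26.70, 1.71, 73)
        assert eff.ci_low == pytest.approx(0.656, abs=0.01)
        assert eff.ci_high == pytest.approx(1.389, abs=0.01)

    def test_identical_groups_give_zero(self):
        eff = cohens_d(5.0, 1.0, 30, 5.0, 1.0, 30)
        assert eff.d == 0.0

    def test_symmetry_under_group_swap(self):
        a = cohens_d(3.0, 1.1, 20, 5.0, 1.4, 25)
        b = cohens_d(5.0, 1.4, 25, 3.0, 1.1, 20)
        assert a.d == pytest.approx(b.d, abs=1e-12)

    def test_zero_pooled_sd_with_unequal_means(self):
        with pytest.raises(DegenerateInputError):
            cohens_d(1.0, 0.0, 10, 2.0, 0.0, 10)


class TestGroupTests:
    def _table(self, rng, n=40):
        g = np.repeat(["HC", "aMCI"], n // 2)
        return pd.DataFrame(
            {
                "group": g,
                "score": rng.standard_normal(n) + (g == "HC") * 0.5,
                "sex": rng.choice(["F", "M"], n),
            }
        )

    def test_equal_samples_give_null_t(self):
        x = [1.0, 2.0, 3.0, 4.0]
        df = pd.DataFrame({"group": ["a"] * 4 + ["b"] * 4, "v": x + x})
        out = group_tests(df, continuous=["v"])
        row = out.iloc[0]
        assert row["stat"] == pytest.approx(0.0, abs=1e-12)
        assert row["p"] == pytest.approx(1.0)
        assert row["cohens_d"] == pytest.approx(0.0)

    def test_t_statistic_matches_hand_formula(self, rng):
        df = self._table(rng)
        out = group_tests(df, continuous=["score"]).iloc[0]
        a = df.loc[df.group == "HC", "score"]
        b = df.loc[df.group == "aMCI", "score"]
        sp = np.sqrt(((len(a) - 1) * a.var(ddof=1) + (len(b) - 1) * b.var(ddof=1))
                     / (len(a) + len(b) - 2))
        t = (a.mean() - b.mean()) / (sp * np.sqrt(1 / len(a) + 1 / len(b)))
        assert abs(out["stat"]) == pytest.approx(abs(t), abs=1e-12)

    def test_balanced_contingency_gives_zero_chi2(self):
        df = pd.DataFrame(
            {"group": ["a"] * 20 + ["b"] * 20, "flag": (["y"] * 10 + ["n"] * 10) * 2}
        )
        out = group_tests(df, categorical=["flag"]).iloc[0]
        assert out["stat"] == pytest.approx(0.0, abs=1e-12)

    def test_single_level_group_rejected(self, rng):
        df = self._table(rng)
        df["group"] = "HC"
        with pytest.raises(Exception):
            group_tests(df, continuous=["score"])


class TestCorrelations:
    def test_self_correlation_is_one(self, rng):
        df = pd.DataFrame({"a": rng.standard_normal(30)})
        df["b"] = df["a"]
        out = correlation_matrix(df, ["a", "b"])
        assert out.iloc[0]["r"] == pytest.approx(1.0)

    def test_bonferroni_arithmetic(self, rng):
        df = pd.DataFrame(rng.standard_normal((50, 5)), columns=list("abcde"))
        out = correlation_matrix(df, list("abcde"), family_size=10)
        np.testing.assert_allclose(
            out["p_adj"], np.minimum(1.0, 10 * out["p"]), atol=1e-15
        )
        assert (out["p_adj"] >= out["p"] - 1e-15).all()
        assert (out["p_adj"] <= 1.0).all()

    def test_consistent_with_pearson_fc(self, rng):
        df = pd.DataFrame(rng.standard_normal((40, 2)), columns=["a", "b"])
        out = correlation_matrix(df, ["a", "b"]).iloc[0]
        assert out["r"] == pytest.approx(pearson_fc(df["a"], df["b"]), abs=1e-12)

    def test_constant_column_yields_sentinel(self):
        df = pd.DataFrame({"a": [1.0] * 10, "b": np.arange(10.0)})
        out = correlation_matrix(df, ["a", "b"])
        assert np.isnan(out.iloc[0]["r"])


class TestPropertyGLM:
    def _data(self, rng, n=120, effect=0.0):
        group = np.repeat(["HC", "aMCI"], n // 2)
        props = pd.DataFrame(
            rng.standard_normal((n, 3)), columns=["Cp", "Lp", "Eglobal"],
            index=[f"s{i}" for i in range(n)],
        )
        g = (group == "aMCI").astype(float)
        y = 2.0 + effect * g * props["Cp"].to_numpy() + rng.standard_normal(n)
        table = pd.DataFrame({"group": group, "avlt5": y}, index=props.index)
        return table, props

    def test_planted_interaction_detected_only_where_planted(self, rng):
        table, props = self._data(rng, effect=1.5)
        out = property_interaction_glm(table, props, "avlt5")
        ints = out[out.term.str.startswith("group[aMCI]:")].set_index("property")
        assert ints.loc["Cp", "p_adj"] < 0.05
        assert ints.loc["Lp", "p"] > 0.001  # no planted effect

    def test_bonferroni_family_is_number_of_properties(self, rng):
        table, props = self._data(rng)
        out = property_interaction_glm(table, props, "avlt5")
        assert out.attrs["family_size"] == 3

    def test_null_familywise_error_controlled(self):
        """Under the global null the Bonferroni-corrected family of 8
        property interactions rejects in at most ~5% of replicates."""
        rng = np.random.default_rng(55)
        fwer = 0
        reps = 300
        for _ in range(reps):
            n = 100
            group = np.repeat(["HC", "aMCI"], n // 2)
            props = pd.DataFrame(
                rng.standard_normal((n, 8)),
                columns=[f"m{j}" for j in range(8)],
                index=[f"s{i}" for i in range(n)],
            )
            y = rng.standard_normal(n)
            table = pd.DataFrame({"group": group, "avlt5": y}, index=props.index)
            out = property_interaction_glm(table, props, "avlt5")
            ints = out[out.term.str.contains(":")]
            fwer += (ints["p_adj"] < 0.05).any()
        # true FWER <= 0.05; allow 2.5 binomial SDs above
        assert fwer / reps <= 0.05 + 2.5 * np.sqrt(0.05 * 0.95 / reps)

    def test_constant_property_rejected(self, rng):
        table, props = self._data(rng)
        props["Cp"] = 1.0
        with pytest.raises(CollinearityError):
            property_interaction_glm(table, props, "avlt5")


class TestModeration:
    def _planted(self, rng, n=200, b_int=0.5, noise=1.0):
        x = rng.standard_normal(n)
        m = rng.standard_normal(n)
        y = 1.0 + x + 0.3 * m + b_int * x * m + noise * rng.standard_normal(n)
        return y, x, m

    def test_no_interaction_estimate_is_zero_with_ci_covering_zero(self, rng):
        x = rng.standard_normal(50)
        m = rng.standard_normal(50)
        y = 2.0 * x  # exact, no moderation
        fit = moderation_analysis(y, x, m, n_boot=1000, rng_seed=1)
        assert fit.interaction == pytest.approx(0.0, abs=1e-10)
        assert fit.ci_low <= 1e-10 and fit.ci_high >= -1e-10

    def test_planted_interaction_recovered_small_noise(self, rng):
        y, x, m = self._planted(rng, noise=0.1)
        fit = moderation_analysis(y, x, m, n_boot=2000, rng_seed=2)
        assert fit.interaction == pytest.approx(0.5, abs=0.05)
        assert not (fit.ci_low <= 0.0 <= fit.ci_high)

    def test_simple_slopes_reconstructed_from_coefficients(self, rng):
        y, x, m = self._planted(rng)
        fit = moderation_analysis(y, x, m, n_boot=1000, rng_seed=3)
        b = fit.coefficients
        sd = np.std(m, ddof=1)
        assert fit.simple_slopes.loc["mean-1sd", "slope"] == pytest.approx(
            b["x"] - sd * b["x:m"], abs=1e-12
        )
        assert fit.simple_slopes.loc["mean+1sd", "slope"] == pytest.approx(
            b["x"] + sd * b["x:m"], abs=1e-12
        )

    def test_bootstrap_ci_bit_reproducible(self, rng):
        y, x, m = self._planted(rng)
        a = moderation_analysis(y, x, m, n_boot=5000, rng_seed=11)
        b = moderation_analysis(y, x, m, n_boot=5000, rng_seed=11)
        assert (a.ci_low, a.ci_high) == (b.ci_low, b.ci_high)
        c = moderation_analysis(y, x, m, n_boot=5000, rng_seed=12)
        assert (a.ci_low, a.ci_high) != (c.ci_low, c.ci_high)

    def test_ci_brackets_estimate(self, rng):
        y, x, m = self._planted(rng)
        fit = moderation_analysis(y, x, m, n_boot=2000, rng_seed=4)
        assert fit.ci_low <= fit.interaction <= fit.ci_high

    def test_null_interaction_centered_at_zero(self):
        """Replicated interaction estimates under a zero planted
        interaction are centered at 0."""
        rng = np.random.default_rng(8)
        ests = []
        for _ in range(200):
            y, x, m = self._planted(rng, n=80, b_int=0.0)
            xc, mc = x - x.mean(), m - m.mean()
            X = np.column_stack([np.ones(80), xc, mc, xc * mc])
            beta = np.linalg.solve(X.T @ X, X.T @ y)
            ests.append(beta[3])
        ests = np.asarray(ests)
        assert abs(ests.mean()) < 2 * ests.std(ddof=1) / np.sqrt(len(ests))

    def test_small_sample_and_low_boot_rejected(self, rng):
        y, x, m = self._planted(rng)
        with pytest.raises(ValueError):
            moderation_analysis(y[:10], x[:10], m[:10], n_boot=1000)
        with pytest.raises(ValueError):
            moderation_analysis(y, x, m, n_boot=100)
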