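import numpy as np
import pandas as pd
import pytest

from ibrtox.anova import (
    DesignError,
    FactorialModel,
    build_design,
    default_terms,
    fit_least_squares,
    full_factorial_terms,
    sum_coding,
    type3_anova,
)


def _balanced(rng, factors_levels, n_per_cell=3, effects=None):
    """Balanced factorial dataset with optional additive cell effects."""
    import itertools

    rows = []
    for combo in itertools.product(*factors_levels.values()):
        for _ in range(n_per_cell):
            row = dict(zip(factors_levels.keys(), combo))
            mu = 0.0
            if effects:
                mu = sum(effects.get((f, lv), 0.0) for f, lv in row.items())
            row["value"] = mu + rng.normal()
            rows.append(row)
    return pd.DataFrame(rows)


class TestDesign:
    def test_sum_coding_columns_sum_to_zero_on_balanced_design(self, rng):
        df = _balanced(rng, {"Treatment": ["CTRL", "C1", "C2", "C3"]})
        x, slices, names = build_design(df, ["Treatment"], [("Treatment",)])
        block = x[:, slices[("Treatment",)]]
        assert block.shape[1] == 3
        assert np.allclose(block.sum(axis=0), 0.0)

    def test_interaction_column_count(self, rng):
        df = _balanced(rng, {"Treatment": list("abcd"), "Day": ["10", "20"]})
        x, slices, _ = build_design(
            df, ["Treatment", "Day"], [("Treatment",), ("Day",), ("Treatment", "Day")]
        )
        sl = slices[("Treatment", "Day")]
        assert sl.stop - sl.start == 3  # (4-1)(2-1)

    def test_default_term_df_sequence(self, rng):
        levels = {
            "Treatment": ["CTRL", "C1", "C2", "C3"],
            "Day": ["10", "20"],
            "Matrix": ["gills", "hemolymph", "hepatopancreas", "muscle"],
            "Biomarker": ["SOD", "GPx", "GST", "MDA", "viability"],
        }
        df = _balanced(rng, levels, n_per_cell=2)
        factors = list(levels)
        _, slices, _ = build_design(df, factors, default_terms(factors))
        dfs = [sl.stop - sl.start for sl in slices.values()]
        b = 5
        assert dfs == [3, 1, 3, b - 1, 3, 3 * (b - 1), 3 * (b - 1)]

    def test_single_level_factor_rejected(self):
        df = pd.DataFrame({"Treatment": ["CTRL"] * 4, "value": [1.0, 2, 3, 4]})
        with pytest.raises(DesignError, match="single level"):
            build_design(df, ["Treatment"], [("Treatment",)])

    def test_dummy_coding_refused(self, rng):
        df = _balanced(rng, {"Treatment": list("abc")})
        with pytest.raises(DesignError, match="sum-to-zero"):
            build_design(df, ["Treatment"], [("Treatment",)], contrasts="treatment")

    def test_sum_coding_rows(self):
        rows = sum_coding(["a", "b", "c"])
        assert np.allclose(rows["a"], [1, 0])
        assert np.allclose(rows["c"], [-1, -1])


class TestFit:
    def test_exact_linear_response_has_zero_residuals(self, rng):
        x = np.column_stack([np.ones(20), rng.normal(size=20)])
        beta = np.array([2.0, -1.5])
        coef, fitted, resid, rss = fit_least_squares(x, x @ beta)
        assert np.allclose(coef, beta)
        assert rss == pytest.approx(0.0, abs=1e-18)

    def test_intercept_only_returns_mean(self, rng):
        y = rng.normal(size=15)
        coef, *_ = fit_least_squares(np.ones((15, 1)), y)
        assert coef[0] == pytest.approx(y.mean())

    def test_residuals_orthogonal_to_design(self, rng):
        df = _balanced(rng, {"A": list("abc"), "B": ["x", "y"]})
        m = FactorialModel(df, "value", ["A", "B"], [("A",), ("B",), ("A", "B")])
        res = m.fit()
        assert np.max(np.abs(m.design.T @ res.resid)) < 1e-8

    def test_2x2_cell_means_give_half_contrasts(self):
        # balanced 2x2 with cell means: effects are half the classical contrasts
        rows = []
        means = {("a", "x"): 1.0, ("a", "y"): 3.0, ("b", "x"): 5.0, ("b", "y"): 7.0}
        for (a, b), mu in means.items():
            rows += [dict(A=a, B=b, value=mu)] * 2
        df = pd.DataFrame(rows)
        m = FactorialModel(df, "value", ["A", "B"], [("A",), ("B",), ("A", "B")])
        res = m.fit()
        coef = dict(zip(m.column_names, res.params))
        # main effect of A: (mean_a - mean_b)/2 = (2 - 6)/2 = -2
        assert coef["A[0]"] == pytest.approx(-2.0)
        assert coef["B[0]"] == pytest.approx(-1.0)
        assert coef["Intercept"] == pytest.approx(4.0)


class TestTypeThree:
    def test_balanced_design_type3_equals_sequential(self, rng):
        df = _balanced(
            rng,
            {"A": list("abc"), "B": ["x", "y"]},
            n_per_cell=4,
            effects={("A", "a"): 1.0, ("B", "x"): -0.5},
        )
        terms = [("A",), ("B",), ("A", "B")]
        table = type3_anova(df, "value", ["A", "B"], terms)
        # sequential (Type I) via successive RSS differences in listed order
        from ibrtox.anova import build_design, fit_least_squares

        y = df["value"].to_numpy()
        x, slices, _ = build_design(df, ["A", "B"], terms)
        rss_prev = fit_least_squares(np.ones((len(df), 1)), y)[3]
        seq = {}
        cols = [0]
        for t in terms:
            cols.extend(range(slices[t].start, slices[t].stop))
            rss = fit_least_squares(x[:, cols], y)[3]
            seq[":".join(t)] = rss_prev - rss
            rss_prev = rss
        for row in table.itertuples(index=False):
            assert row.sum_sq == pytest.approx(seq[row.term], rel=1e-9, abs=1e-9)

    def test_matches_statsmodels_car_style_oracle(self, rng):
        """Independent route: statsmodels OLS + anova_lm(typ=3, Sum contrasts)."""
        import statsmodels.api as sm
        import statsmodels.formula.api as smf

        df = _balanced(
            rng,
            {"A": list("abc"), "B": ["x", "y", "z"]},
            n_per_cell=2,
            effects={("A", "a"): 0.8},
        )
        # unbalance it so Type I and Type III genuinely differ
        df = df.drop(index=[0, 5]).reset_index(drop=True)
        fit = smf.ols("value ~ C(A, Sum) * C(B, Sum)", data=df).fit()
        ref = sm.stats.anova_lm(fit, typ=3)
        mine = type3_anova(df, "value", ["A", "B"], [("A",), ("B",), ("A", "B")])
        lookup = {"A": "C(A, Sum)", "B": "C(B, Sum)", "A:B": "C(A, Sum):C(B, Sum)"}
        for row in mine.itertuples(index=False):
            assert row.sum_sq == pytest.approx(ref.loc[lookup[row.term], "sum_sq"], rel=1e-8)
            assert row.F == pytest.approx(ref.loc[lookup[row.term], "F"], rel=1e-8)
            assert row.p == pytest.approx(ref.loc[lookup[row.term], "PR(>F)"], rel=1e-6)

    def test_row_permutation_invariance(self, rng):
        df = _balanced(rng, {"A": list("abc"), "B": ["x", "y"]}, n_per_cell=3)
        a = type3_anova(df, "value", ["A", "B"])
        b = type3_anova(df.sample(frac=1.0, random_state=9), "value", ["A", "B"])
        pd.testing.assert_frame_equal(a, b.reset_index(drop=True))

    def test_constant_shift_changes_only_intercept(self, rng):
        df = _balanced(rng, {"A": list("abc"), "B": ["x", "y"]}, n_per_cell=3)
        shifted = df.assign(value=df["value"] + 100.0)
        a = type3_anova(df, "value", ["A", "B"])
        b = type3_anova(shifted, "value", ["A", "B"])
        pd.testing.assert_frame_equal(a, b)

    def test_term_order_invariance(self, rng):
        df = _balanced(rng, {"A": list("abc"), "B": ["x", "y"]}, n_per_cell=2)
        df = df.drop(index=[0, 7]).reset_index(drop=True)  # unbalanced
        t1 = [("A",), ("B",), ("A", "B")]
        t2 = [("B",), ("A",), ("A", "B")]
        a = type3_anova(df, "value", ["A", "B"], t1).set_index("term")
        b = type3_anova(df, "value", ["A", "B"], t2).set_index("term")
        for term in ("A", "B", "A:B"):
            assert a.loc[term, "F"] == pytest.approx(b.loc[term, "F"], rel=1e-10)

    def test_interaction_without_main_effect_rejected(self, rng):
        df = _balanced(rng, {"A": list("ab"), "B": ["x", "y"]})
        with pytest.raises(DesignError, match="main effect"):
            FactorialModel(df, "value", ["A", "B"], [("A",), ("A", "B")])

    def test_full_factorial_helper(self):
        terms = full_factorial_terms(["A", "B", "C"])
        assert len(terms) == 7
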