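"""Two-way ANOVA (Type I), Tukey HSD and stratified Welch t-tests."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from cuegene.group_stats import per_group_ttests, tukey_hsd, two_way_anova


def sequential_ss_oracle(y, a, b):
    """Brute-force Type I sums of squares via nested least-squares projections.

    Fits the increasing model sequence 1, 1+A, 1+A+B, 1+A+B+A:B and takes
    differences in residual sums of squares.
    """
    y = np.asarray(y, dtype=float)
    a = pd.Categorical(a)
    b = pd.Categorical(b)

    def dummies(codes, k):
        out = np.zeros((len(codes), k))
        out[np.arange(len(codes)), codes] = 1.0
        return out

    da = dummies(a.codes, len(a.categories))
    db = dummies(b.codes, len(b.categories))
    inter = np.einsum("ij,ik->ijk", da, db).reshape(len(y), -1)
    ones = np.ones((len(y), 1))

    def rss(X):
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        r = y - X @ beta
        return float(r @ r)

    r0 = rss(ones)
    r1 = rss(np.hstack([ones, da]))
    r2 = rss(np.hstack([ones, da, db]))
    r3 = rss(np.hstack([ones, da, db, inter]))
    return {"factor_a": r0 - r1, "factor_b": r1 - r2, "interaction": r2 - r3,
            "residual": r3}


def random_unbalanced_design(rng, min_cell=1, max_cell=5):
    levels_a = rng.integers(2, 4)
    levels_b = 2
    rows = []
    for i in range(levels_a):
        for j in range(levels_b):
            for _ in range(rng.integers(min_cell, max_cell + 1)):
                rows.append((f"a{i}", f"b{j}"))
    a, b = zip(*rows)
    n = len(rows)
    y = rng.normal(0, 1, n) + rng.normal(0, 1, levels_a)[
        [int(x[1:]) for x in a]
    ]
    # guarantee estimability: more observations than cell parameters
    return y, list(a), list(b)


class TestTwoWayAnova:
    def test_constant_response_reports_zero(self):
        aov = two_way_anova([3.0] * 8, ["a", "a", "b", "b"] * 2, ["x", "y"] * 4)
        assert (aov.table["sum_sq"] == 0).all()
        assert (aov.table.loc[["factor_a", "factor_b", "interaction"], "f_value"] == 0).all()
        assert aov.model_r2 == 0.0
        assert "constant" in aov.note

    def test_balanced_2x2_hand_decomposition(self):
        # cell means (0, 0, 0, 4), 2 replicates, no noise:
        # SS_A = SS_B = SS_int = 8, residual 0, total 24
        a = ["a1"] * 4 + ["a2"] * 4
        b = (["b1"] * 2 + ["b2"] * 2) * 2
        y = [0, 0, 0, 0, 0, 0, 4, 4]
        aov = two_way_anova(y, a, b)
        assert aov.table.loc["factor_a", "sum_sq"] == pytest.approx(8.0, abs=1e-10)
        assert aov.table.loc["factor_b", "sum_sq"] == pytest.approx(8.0, abs=1e-10)
        assert aov.table.loc["interaction", "sum_sq"] == pytest.approx(8.0, abs=1e-10)
        assert aov.table.loc["residual", "sum_sq"] == pytest.approx(0.0, abs=1e-10)
        assert aov.model_r2 == pytest.approx(1.0, abs=1e-12)

    def test_matches_sequential_projection_oracle(self):
        rng = np.random.default_rng(17)
        for _ in range(10):
            y, a, b = random_unbalanced_design(rng, min_cell=2)
            aov = two_way_anova(y, a, b)
            ref = sequential_ss_oracle(y, a, b)
            for term, ss in ref.items():
                assert aov.table.loc[term, "sum_sq"] == pytest.approx(ss, abs=1e-8)
            assert aov.model_r2 == pytest.approx(
                1 - ref["residual"] / sum(ref.values()), abs=1e-10
            )

    def test_df_sum_to_n_minus_one(self):
        rng = np.random.default_rng(23)
        y, a, b = random_unbalanced_design(rng, min_cell=2)
        aov = two_way_anova(y, a, b)
        assert aov.table["df"].sum() == len(y) - 1

    def test_permutation_invariance(self):
        rng = np.random.default_rng(29)
        y, a, b = random_unbalanced_design(rng, min_cell=2)
        perm = rng.permutation(len(y))
        aov1 = two_way_anova(y, a, b)
        aov2 = two_way_anova(
            np.asarray(y)[perm], np.asarray(a)[perm], np.asarray(b)[perm]
        )
        pd.testing.assert_frame_equal(aov1.table, aov2.table, atol=1e-10)

    def test_balanced_type1_is_order_invariant(self):
        rng = np.random.default_rng(31)
        a = np.repeat(["a1", "a2", "a3"], 6)
        b = np.tile(["b1", "b2"], 9)
        y = rng.normal(0, 1, 18)
        ab = two_way_anova(y, a, b)
        ba = two_way_anova(y, b, a)
        assert ab.table.loc["factor_a", "sum_sq"] == pytest.approx(
            ba.table.loc["factor_b", "sum_sq"], abs=1e-10
        )
        assert ab.table.loc["factor_b", "sum_sq"] == pytest.approx(
            ba.table.loc["factor_a", "sum_sq"], abs=1e-10
        )

    def test_single_level_factor_rejected(self):
        with pytest.raises(ValueError):
            two_way_anova([1, 2, 3, 4], ["a"] * 4, ["x", "y", "x", "y"])

    def test_empty_cell_rejected_with_cells_listed(self):
        y = [1.0, 2.0, 3.0, 4.0, 5.0, 6.0]
        a = ["a1", "a1", "a1", "a2", "a2", "a2"]
        b = ["x", "x", "y", "x", "x", "x"]  # (a2, y) empty
        with pytest.raises(ValueError, match="a2"):
            two_way_anova(y, a, b)


class TestTukeyHsd:
    def test_identical_groups_share_letters(self):
        vals = [1.0, 2.0, 3.0, 1.0, 2.0, 3.0]
        groups = ["g1"] * 3 + ["g2"] * 3
        res = tukey_hsd(vals, groups)
        assert res.table["adjusted_p"].iloc[0] == pytest.approx(1.0, abs=1e-9)
        assert res.letters["g1"] == res.letters["g2"]

    def test_separated_groups_distinct_letters(self):
        rng = np.random.default_rng(2)
        vals = np.concatenate([rng.normal(0, 0.1, 6), rng.normal(50, 0.1, 6)])
        groups = ["lo"] * 6 + ["hi"] * 6
        res = tukey_hsd(vals, groups)
        assert res.table["adjusted_p"].iloc[0] < 1e-4
        assert res.letters["lo"] != res.letters["hi"]

    def test_matches_scipy_reference(self):
        rng = np.random.default_rng(13)
        data = [rng.normal(m, 1.0, 7) for m in (0.0, 0.5, 2.0, 2.2)]
        vals = np.concatenate(data)
        groups = np.repeat([f"g{i}" for i in range(4)], 7)
        res = tukey_hsd(vals, groups)
        ref = stats.tukey_hsd(*data)
        got = {
            frozenset((r.group_i, r.group_j)): r.adjusted_p
            for r in res.table.itertuples()
        }
        for i in range(4):
            for j in range(i + 1, 4):
                key = frozenset((f"g{i}", f"g{j}"))
                assert got[key] == pytest.approx(ref.pvalue[i, j], rel=5e-3, abs=1e-4)

    def test_singleton_group_rejected(self):
        with pytest.raises(ValueError):
            tukey_hsd([1.0, 2.0, 3.0], ["a", "a", "b"])


class TestPerGroupTtests:
    def test_identical_groups_t_zero(self):
        vals = [1, 2, 3, 1, 2, 3]
        medium = ["poor", "poor", "poor", "rich", "rich", "rich"]
        out = per_group_ttests(vals, medium, ["iso1"] * 6)
        assert out.loc[0, "t"] == pytest.approx(0.0, abs=1e-12)
        assert out.loc[0, "p"] == pytest.approx(1.0, abs=1e-12)

    def test_welch_hand_example(self):
        # (0,1) vs (10,11): s^2 = 0.5 each, se = sqrt(0.25+0.25),
        # t = -10/sqrt(0.5), Welch df = 2
        vals = [0.0, 1.0, 10.0, 11.0]
        medium = ["a", "a", "b", "b"]
        out = per_group_ttests(vals, medium, ["iso"] * 4)
        assert out.loc[0, "t"] == pytest.approx(-10.0 / np.sqrt(0.5), rel=1e-10)
        assert out.loc[0, "df"] == pytest.approx(2.0, rel=1e-10)
        ref = stats.ttest_ind([0.0, 1.0], [10.0, 11.0], equal_var=False)
        assert out.loc[0, "p"] == pytest.approx(ref.pvalue, rel=1e-12)

    def test_stratum_missing_level_reported_missing(self):
        vals = [1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0, 8.0]
        medium = ["a", "a", "b", "b", "a", "a", "a", "a"]
        strata = ["s1"] * 4 + ["s2"] * 4
        out = per_group_ttests(vals, medium, strata).set_index("stratum")
        assert np.isnan(out.loc["s2", "t"])
        assert not np.isnan(out.loc["s1", "t"])

    def test_student_option(self):
        vals = [0.0, 1.0, 2.0, 10.0, 12.0, 14.0]
        medium = ["a", "a", "a", "b", "b", "b"]
        out = per_group_ttests(vals, medium, ["iso"] * 6, welch=False)
        ref = stats.ttest_ind(vals[:3], vals[3:], equal_var=True)
        assert out.loc[0, "t"] == pytest.approx(ref.statistic, rel=1e-12)
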