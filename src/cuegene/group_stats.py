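"""Factorial group comparisons: two-way ANOVA, Tukey HSD and stratified t-tests.

The experimental design is isolate x growth medium with replicates.
Effects on fluxes, marker expression and the gene index are tested by a
two-way ANOVA with interaction (sequential, Type I sums of squares with
isolate entered first, matching R's ``aov`` default), followed by Tukey
HSD between isolates.  Because variances differ strongly between
isolates, medium effects are tested per isolate with Welch t-tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.formula.api import ols
from statsmodels.stats.anova import anova_lm
from statsmodels.stats.multicomp import pairwise_tukeyhsd

__all__ = [
    "AnovaTable",
    "PairwiseComparisons",
    "two_way_anova",
    "tukey_hsd",
    "per_group_ttests",
]


@dataclass(frozen=True)
class AnovaTable:
    """Sequential two-way ANOVA with interaction.

    table rows: factor_a, factor_b, interaction, residual; columns
    sum_sq, df, f_value, p_value.  model_r2 = 1 - SS_resid/SS_total.
    """

    table: pd.DataFrame
    model_r2: float
    note: str = ""


@dataclass(frozen=True)
class PairwiseComparisons:
    """All-pairs Tukey comparisons plus a compact-letter display."""

    table: pd.DataFrame  # group_i, group_j, mean_diff, adjusted_p, significant
    letters: dict[str, str]
    alpha: float


def two_way_anova(values, factor_a, factor_b) -> AnovaTable:
    """Two-way ANOVA with interaction, sequential (Type I) sums of squares.

    factor_a is entered before factor_b before the interaction; with a
    balanced design the decomposition coincides with the classical
    factorial one and is order-invariant.  An all-constant response is
    reported with zero sums of squares and F = 0 (noted) rather than as
    an error.
    """
    df = pd.DataFrame(
        {
            "y": np.asarray(values, dtype=float),
            "A": pd.Categorical(factor_a),
            "B": pd.Categorical(factor_b),
        }
    )
    if df["A"].nunique() < 2 or df["B"].nunique() < 2:
        raise ValueError("each factor needs >= 2 levels")
    cells = df.groupby(["A", "B"], observed=False).size()
    empty = cells.index[cells == 0].tolist()
    if empty:
        raise ValueError(f"empty design cells make the interaction inestimable: {empty}")
    n_par = df["A"].nunique() * df["B"].nunique()
    if len(df) <= n_par:
        raise ValueError("need more observations than cell-mean parameters")

    note = ""
    sst = float(((df["y"] - df["y"].mean()) ** 2).sum())
    if sst == 0:
        # constant response: every SS is zero, F undefined; report zeros
        note = "constant response: all sums of squares zero, F reported as 0"
        rows = pd.DataFrame(
            {
                "sum_sq": [0.0, 0.0, 0.0, 0.0],
                "df": [
                    df["A"].nunique() - 1,
                    df["B"].nunique() - 1,
                    (df["A"].nunique() - 1) * (df["B"].nunique() - 1),
                    len(df) - n_par,
                ],
                "f_value": [0.0, 0.0, 0.0, np.nan],
                "p_value": [1.0, 1.0, 1.0, np.nan],
            },
            index=["factor_a", "factor_b", "interaction", "residual"],
        )
        return AnovaTable(table=rows, model_r2=0.0, note=note)

    fit = ols("y ~ C(A) + C(B) + C(A):C(B)", data=df).fit()
    aov = anova_lm(fit, typ=1)
    aov.index = ["factor_a", "factor_b", "interaction", "residual"]
    table = pd.DataFrame(
        {
            "sum_sq": aov["sum_sq"],
            "df": aov["df"].astype(int),
            "f_value": aov["F"],
            "p_value": aov["PR(>F)"],
        }
    )
    r2 = 1.0 - float(aov.loc["residual", "sum_sq"]) / sst
    return AnovaTable(table=table, model_r2=r2, note=note)


def _letter_display(groups: list[str], insignificant: set[frozenset]) -> dict[str, str]:
    """Greedy compact-letter display from the non-significance graph.

    Groups are processed in input order; a group joins an existing letter
    class only if it is statistically indistinguishable from every member.
    """
    classes: list[list[str]] = []
    for g in groups:
        placed = False
        for cls in classes:
            if all(frozenset((g, member)) in insignificant for member in cls):
                cls.append(g)
                placed = True
        if not placed:
            classes.append([g])
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    letters: dict[str, str] = {g: "" for g in groups}
    for i, cls in enumerate(classes):
        for g in cls:
            letters[g] += alphabet[i % len(alphabet)]
    return letters


def tukey_hsd(values, groups, alpha: float = 0.05) -> PairwiseComparisons:
    """Tukey honest-significant-difference comparisons between groups.

    Adjusted p-values come from the studentized range distribution; each
    unordered pair appears once.  A compact-letter display is derived
    greedily from the non-significant pairs (groups in sorted order).
    """
    y = np.asarray(values, dtype=float)
    g = pd.Categorical(groups)
    counts = pd.Series(g).value_counts()
    if len(counts) < 2:
        raise ValueError("need >= 2 groups")
    singletons = counts.index[counts < 2].tolist()
    if singletons:
        raise ValueError(f"groups with fewer than 2 observations: {singletons}")

    res = pairwise_tukeyhsd(y, np.asarray(g), alpha=alpha)
    table = pd.DataFrame(
        {
            "group_i": res.groupsunique[res._multicomp.pairindices[0]],
            "group_j": res.groupsunique[res._multicomp.pairindices[1]],
            "mean_diff": res.meandiffs,
            "adjusted_p": res.pvalues,
            "significant": res.reject,
        }
    )
    insignificant = {
        frozenset((str(r.group_i), str(r.group_j)))
        for r in table.itertuples()
        if not r.significant
    }
    letters = _letter_display([str(x) for x in sorted(set(map(str, g)))], insignificant)
    return PairwiseComparisons(table=table, letters=letters, alpha=alpha)


def per_group_ttests(values, medium_factor, stratum_factor, welch: bool = True) -> pd.DataFrame:
    """Two-sample t-test of the medium effect within each stratum.

    Welch (unequal-variance) by default because within-isolate variances
    differ; Student's t is available via ``welch=False``.  A stratum
    missing one medium level is reported with NaN statistics rather than
    raising.  Returns columns stratum, t, df, p, n_a, n_b.
    """
    df = pd.DataFrame(
        {
            "y": np.asarray(values, dtype=float),
            "medium": np.asarray(medium_factor),
            "stratum": np.asarray(stratum_factor),
        }
    )
    media = sorted(df["medium"].unique())
    if len(media) != 2:
        raise ValueError(f"expected exactly 2 medium levels, got {media}")
    rows = []
    for stratum, sub in df.groupby("stratum", sort=True):
        a = sub.loc[sub["medium"] == media[0], "y"].to_numpy()
        b = sub.loc[sub["medium"] == media[1], "y"].to_numpy()
        if len(a) < 2 or len(b) < 2:
            rows.append({"stratum": stratum, "t": np.nan, "df": np.nan, "p": np.nan,
                         "n_a": len(a), "n_b": len(b)})
            continue
        res = stats.ttest_ind(a, b, equal_var=not welch)
        rows.append(
            {
                "stratum": stratum,
                "t": float(res.statistic),
                "df": float(res.df),
                "p": float(res.pvalue),
                "n_a": len(a),
                "n_b": len(b),
            }
        )
    return pd.DataFrame(rows)
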