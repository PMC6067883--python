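"""Group statistics: serial Bonferroni t-tests, two-way ANOVA + Tukey-Kramer,
chi-square, and plain two-sample t-tests.

The chemoresponse comparison scheme is a two-tailed two-sample t-test at
every compared minute, with the familywise alpha Bonferroni-divided by the
number of minutes actually compared (44 for the full juvenile protocol,
fewer when minutes are missing in either group).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

FAMILYWISE_ALPHA = 0.05


@dataclass
class StatResult:
    """One hypothesis-test outcome."""

    test_name: str
    statistic: float
    df: float | tuple
    p_value: float
    adjusted_alpha: float | None = None
    significant: bool | None = None
    minute: int | None = None
    n: tuple | None = None


def bonferroni_threshold(familywise_alpha: float, n_comparisons: int) -> float:
    """Per-comparison alpha = familywise alpha / number of comparisons."""
    if n_comparisons < 1:
        raise ValueError("need at least one comparison")
    return familywise_alpha / n_comparisons


def two_sample_ttest(group_a, group_b, welch: bool = False) -> StatResult:
    """Two-tailed two-sample t-test (pooled variance; Welch on request).

    Degenerate case: both groups constant with equal means gives t = 0,
    p = 1 by convention.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least two observations per group")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        df = a.size + b.size - 2
        if a.mean() == b.mean():
            return StatResult("t-test", 0.0, df, 1.0, n=(a.size, b.size))
        return StatResult("t-test", np.inf, df, 0.0, n=(a.size, b.size))
    res = sps.ttest_ind(a, b, equal_var=not welch)
    return StatResult(
        "welch-t" if welch else "t-test",
        float(res.statistic), float(res.df), float(res.pvalue),
        n=(a.size, b.size),
    )


def serial_group_tests(
    group_a: np.ndarray | list,
    group_b: np.ndarray | list,
    familywise_alpha: float = FAMILYWISE_ALPHA,
    welch: bool = False,
) -> list[StatResult]:
    """Per-minute two-sample t-tests with Bonferroni control.

    Parameters
    ----------
    group_a, group_b
        Minute x animal matrices of normalized values (NaN = missing
        minute), or lists of :class:`~plethykit.chemoresponse.NormalizedResponse`.
    familywise_alpha
        Familywise error rate; each compared minute is flagged significant
        iff its p-value is below ``familywise_alpha / n_compared``, where
        ``n_compared`` counts only minutes with >= 2 animals in both groups.
    """
    def _as_matrix(g):
        if len(g) and hasattr(g[0], "values"):
            return np.column_stack([r.values for r in g])
        return np.asarray(g, dtype=float)

    A = _as_matrix(group_a)
    B = _as_matrix(group_b)
    if A.shape[0] != B.shape[0]:
        raise ValueError("groups cover different numbers of minutes")

    tested: list[tuple[int, StatResult]] = []
    for m in range(A.shape[0]):
        a = A[m][~np.isnan(A[m])]
        b = B[m][~np.isnan(B[m])]
        if a.size < 2 or b.size < 2:
            continue
        tested.append((m + 1, two_sample_ttest(a, b, welch=welch)))
    n_compared = len(tested)
    if n_compared == 0:
        raise ValueError("no minute has two animals in both groups")
    thr = bonferroni_threshold(familywise_alpha, n_compared)
    results = []
    for minute, r in tested:
        r.minute = minute
        r.adjusted_alpha = thr
        r.significant = r.p_value < thr
        r.test_name = "serial-" + r.test_name
        results.append(r)
    return results


def chi_square_2x2(table) -> StatResult:
    """Pearson chi-square on a 2x2 count table, df = 1, no continuity
    correction."""
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if np.any(t < 0) or not np.allclose(t, np.round(t)):
        raise ValueError("counts must be non-negative integers")
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        raise ValueError("zero row/column margin")
    res = sps.chi2_contingency(t, correction=False)
    return StatResult("chi-square", float(res.statistic), 1,
                      float(res.pvalue))


def two_way_anova_tukey(
    values,
    genotype,
    treatment,
    alpha: float = 0.05,
    ss_type: int = 2,
) -> tuple[pd.DataFrame, pd.DataFrame | None]:
    """Two-way ANOVA (genotype x treatment) with Tukey-Kramer post-hoc.

    Type-II sums of squares by default (cells may be unbalanced).  The
    post-hoc compares the four genotype-treatment cells pairwise and runs
    only when at least one omnibus effect reaches `alpha`.

    Returns
    -------
    (anova_table, tukey_table or None)
        ``anova_table`` has sum_sq, df, F, p rows for both main effects,
        the interaction and the residual.
    """
    import statsmodels.api as sm
    from statsmodels.formula.api import ols
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    df = pd.DataFrame({
        "value": np.asarray(values, dtype=float),
        "genotype": pd.Categorical(genotype),
        "treatment": pd.Categorical(treatment),
    })
    for factor in ("genotype", "treatment"):
        if df[factor].nunique() < 2:
            raise ValueError(f"factor {factor!r} needs at least 2 levels")
    counts = df.groupby(["genotype", "treatment"], observed=False).size()
    if (counts < 2).any():
        bad = counts[counts < 2].index.tolist()
        raise ValueError(f"cells with fewer than 2 observations: {bad}")

    if np.ptp(df["value"].to_numpy()) == 0:
        # all observations identical: every SS is zero, F undefined -> 0
        idx = ["C(genotype)", "C(treatment)",
               "C(genotype):C(treatment)", "Residual"]
        table = pd.DataFrame(
            {"sum_sq": 0.0, "df": [1.0, 1.0, 1.0, float(len(df) - 4)],
             "F": [0.0, 0.0, 0.0, np.nan], "PR(>F)": [1.0, 1.0, 1.0, np.nan]},
            index=idx,
        )
        return table, None

    model = ols("value ~ C(genotype) * C(treatment)", data=df).fit()
    table = sm.stats.anova_lm(model, typ=ss_type)

    effect_p = table["PR(>F)"].drop("Residual", errors="ignore").dropna()
    if (effect_p < alpha).any():
        cell = (df["genotype"].astype(str) + ":" + df["treatment"].astype(str))
        tk = pairwise_tukeyhsd(df["value"].to_numpy(), cell.to_numpy(),
                               alpha=alpha)
        tukey = pd.DataFrame(tk.summary().data[1:],
                             columns=tk.summary().data[0])
    else:
        tukey = None
    return table, tukey


def results_to_frame(results: list[StatResult]) -> pd.DataFrame:
    """Tidy one-row-per-test view of a result list."""
    return pd.DataFrame(
        {
            "test": [r.test_name for r in results],
            "minute": [r.minute for r in results],
            "statistic": [r.statistic for r in results],
            "df": [r.df for r in results],
            "p_value": [r.p_value for r in results],
            "adjusted_alpha": [r.adjusted_alpha for r in results],
            "significant": [r.significant for r in results],
        }
    )
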