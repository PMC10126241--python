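"""Two-group comparisons for clinical characteristic tables.

Continuous variables are described as mean +/- SD when near-normal and median
(IQR) otherwise, and compared by the pooled-variance t-test or the
Mann-Whitney U-test; categorical variables by the Pearson chi-square test
(uncorrected, the classic large-sample form) or Fisher's exact test.  The
``auto`` method picks the test from a skewness screen or from expected cell
counts, mirroring routine "as appropriate" practice.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "Descriptive",
    "ComparisonRow",
    "describe",
    "compare_continuous",
    "compare_continuous_summary",
    "compare_categorical",
    "table_one",
]


@dataclass
class Descriptive:
    style: str  # "mean_sd" | "median_iqr"
    n: int
    loc: float       # mean or median
    spread: tuple    # (sd,) or (q1, q3)

    def __str__(self) -> str:
        if self.style == "mean_sd":
            return f"{self.loc:.4g} ± {self.spread[0]:.4g}"
        q1, q3 = self.spread
        return f"{self.loc:.4g} ({q1:.4g}–{q3:.4g})"


@dataclass
class ComparisonRow:
    variable: str
    group_a: str
    group_b: str
    test: str       # t_test | mann_whitney | chi_square | fisher_exact
    statistic: float
    p_value: float
    flags: tuple = ()


def _clean(values) -> np.ndarray:
    v = np.asarray(values, dtype=float)
    return v[~np.isnan(v)]


def describe(values, style: str = "mean_sd") -> Descriptive:
    """Mean +/- sample SD, or median with linear-interpolation quartiles."""
    v = _clean(values)
    if v.size == 0:
        raise ValueError("no non-missing values to describe")
    if style == "mean_sd":
        sd = float(v.std(ddof=1)) if v.size > 1 else 0.0
        return Descriptive("mean_sd", v.size, float(v.mean()), (sd,))
    if style == "median_iqr":
        q1, med, q3 = np.percentile(v, [25, 50, 75])  # linear interpolation
        return Descriptive("median_iqr", v.size, float(med), (float(q1), float(q3)))
    raise ValueError(f"unknown style {style!r}")


def _skew_ok(v: np.ndarray, threshold: float) -> bool:
    if v.size < 3 or v.std(ddof=1) == 0:
        return True
    return abs(float(sps.skew(v, bias=False))) < threshold


def compare_continuous(
    a,
    b,
    variable: str = "",
    method: str = "auto",
    skew_threshold: float = 1.0,
) -> ComparisonRow:
    """Two-sided pooled-variance t-test or Mann-Whitney U (normal approximation
    with tie correction); ``auto`` uses the t-test when both groups pass the
    skewness screen."""
    a, b = _clean(a), _clean(b)
    if a.size < 2 or b.size < 2:
        raise ValueError("both groups need at least 2 non-missing values")
    if method == "auto":
        method = "t_test" if (_skew_ok(a, skew_threshold) and _skew_ok(b, skew_threshold)) else "mann_whitney"
    if np.concatenate([a, b]).std() == 0:
        # degenerate: no variation anywhere
        return ComparisonRow(variable, str(describe(a)), str(describe(b)),
                             method, 0.0, 1.0, flags=("zero_variance",))
    if method == "t_test":
        res = sps.ttest_ind(a, b, equal_var=True)
        row_test, stat, p = "t_test", float(res.statistic), float(res.pvalue)
        da, db = describe(a, "mean_sd"), describe(b, "mean_sd")
    elif method == "mann_whitney":
        res = sps.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
        row_test, stat, p = "mann_whitney", float(res.statistic), float(res.pvalue)
        da, db = describe(a, "median_iqr"), describe(b, "median_iqr")
    else:
        raise ValueError(f"unknown method {method!r}")
    return ComparisonRow(variable, str(da), str(db), row_test, stat, p)


def compare_continuous_summary(
    mean_a: float, sd_a: float, n_a: int,
    mean_b: float, sd_b: float, n_b: int,
    variable: str = "",
    welch: bool = False,
) -> ComparisonRow:
    """t-test from published summary statistics (pooled variance by default)."""
    res = sps.ttest_ind_from_stats(mean_a, sd_a, n_a, mean_b, sd_b, n_b,
                                   equal_var=not welch)
    return ComparisonRow(
        variable,
        f"{mean_a:.4g} ± {sd_a:.4g}",
        f"{mean_b:.4g} ± {sd_b:.4g}",
        "t_test" if not welch else "welch_t",
        float(res.statistic),
        float(res.pvalue),
    )


def compare_categorical(table, variable: str = "", method: str = "auto") -> ComparisonRow:
    """Pearson chi-square (no continuity correction) or Fisher's exact test on a
    2x2 table; ``auto`` switches to Fisher when any expected count is < 5."""
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2) or np.any(t < 0):
        raise ValueError("expected a 2x2 table of non-negative counts")
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        raise ValueError("zero margin in contingency table")
    expected = np.outer(t.sum(axis=1), t.sum(axis=0)) / t.sum()
    if method == "auto":
        method = "fisher_exact" if np.any(expected < 5) else "chi_square"
    if method == "chi_square":
        chi2, p, _, _ = sps.chi2_contingency(t, correction=False)
        stat, test = float(chi2), "chi_square"
    elif method == "chi_square_corrected":
        chi2, p, _, _ = sps.chi2_contingency(t, correction=True)
        stat, test = float(chi2), "chi_square_corrected"
    elif method == "fisher_exact":
        odds, p = sps.fisher_exact(t.astype(int), alternative="two-sided")
        stat, test = float(odds), "fisher_exact"
    else:
        raise ValueError(f"unknown method {method!r}")
    counts = t.astype(int)
    return ComparisonRow(
        variable,
        f"{counts[0,0]}/{counts[0,0]+counts[0,1]}",
        f"{counts[1,0]}/{counts[1,0]+counts[1,1]}",
        test,
        stat,
        float(p),
    )


#: Variables described as median (IQR) in clinical tables of this cohort;
#: everything else is mean +/- SD.
SKEWED_VARIABLES = frozenset(
    {"hb", "rdw", "mcv", "serum_iron", "ferritin", "tsat", "tibc", "creatinine"}
)


def table_one(
    df: pd.DataFrame,
    group: np.ndarray,
    variables: list[str],
    group_names: tuple[str, str] = ("absent", "present"),
) -> pd.DataFrame:
    """Characteristics table: per-group descriptives and two-group p-values.

    ``group`` is a boolean vector (True = second column).  Continuous
    variables use the descriptive style conventional for that measurement and
    the matching test.
    """
    group = np.asarray(group, dtype=bool)
    rows = []
    for var in variables:
        vals = df[var].to_numpy(dtype=float)
        a, b = vals[~group], vals[group]
        style = "median_iqr" if var in SKEWED_VARIABLES else "mean_sd"
        method = "mann_whitney" if style == "median_iqr" else "t_test"
        cmp = compare_continuous(a, b, variable=var, method=method)
        rows.append(
            {
                "variable": var,
                group_names[0]: str(describe(a, style)),
                group_names[1]: str(describe(b, style)),
                "test": cmp.test,
                "p_value": cmp.p_value,
            }
        )
    return pd.DataFrame(rows)
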