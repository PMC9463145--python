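"""Cluster and case-control characterisation statistics.

Summary tables in the style of epidemiological baseline tables: counts and
percentages per group with uncorrected Pearson chi-square tests for
categorical characteristics and two-sided Wilcoxon-Mann-Whitney rank-sum
tests for continuous ones, plus Welch difference-in-means confidence
intervals for standardised markers and covariate-adjusted logistic odds
ratios with Wald intervals. Small cells (0 < n < 5) can be suppressed as
"<5", the usual disclosure-control rule for cohort data. P-values are not
adjusted for multiple comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "TwoByTwoTable",
    "OddsRatioResult",
    "chi_square_test",
    "rank_sum_test",
    "diff_in_means_ci",
    "logistic_or",
    "characterisation_report",
]


@dataclass
class TwoByTwoTable:
    """Counts with rows = groups and columns = outcome yes/no."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("counts must be nonnegative")
        if self.a + self.b + self.c + self.d == 0:
            raise ValueError("table total must be positive")

    @property
    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=float)


@dataclass
class OddsRatioResult:
    or_estimate: float
    ci_low: float
    ci_high: float
    adjusted_for: tuple[str, ...] = ()


def chi_square_test(table: TwoByTwoTable) -> tuple[float, float]:
    """Uncorrected Pearson chi-square test on a 2x2 table (df = 1)."""
    arr = table.as_array
    if np.any(arr.sum(axis=0) == 0) or np.any(arr.sum(axis=1) == 0):
        raise ValueError("zero row/column margin: expected count zero")
    chi2, p, _, _ = stats.chi2_contingency(arr, correction=False)
    return float(chi2), float(p)


def rank_sum_test(x1, x2) -> float:
    """Two-sided Wilcoxon-Mann-Whitney p-value.

    Exact enumeration when the combined sample has at most 20 values and no
    ties; normal approximation with tie correction otherwise.
    """
    x1 = np.asarray(x1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    if len(x1) == 0 or len(x2) == 0:
        raise ValueError("both groups need at least one observation")
    combined = np.concatenate([x1, x2])
    no_ties = len(np.unique(combined)) == len(combined)
    method = "exact" if (len(combined) <= 20 and no_ties) else "asymptotic"
    res = stats.mannwhitneyu(x1, x2, alternative="two-sided", method=method)
    return float(res.pvalue)


def diff_in_means_ci(x1, x2, alpha: float = 0.05) -> tuple[float, float, float]:
    """mean(x2) - mean(x1) with a Welch-t 95% CI (group 1 as reference)."""
    x1 = np.asarray(x1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    if len(x1) < 2 or len(x2) < 2:
        raise ValueError("each group needs at least 2 values")
    diff = x2.mean() - x1.mean()
    v1, v2 = x1.var(ddof=1), x2.var(ddof=1)
    if v1 == 0 and v2 == 0:
        return float(diff), float(diff), float(diff)
    se = np.sqrt(v1 / len(x1) + v2 / len(x2))
    df = (v1 / len(x1) + v2 / len(x2)) ** 2 / (
        (v1 / len(x1)) ** 2 / (len(x1) - 1) + (v2 / len(x2)) ** 2 / (len(x2) - 1)
    )
    t = stats.t.ppf(1 - alpha / 2, df)
    return float(diff), float(diff - t * se), float(diff + t * se)


def logistic_or(
    outcome, predictor, covariates: pd.DataFrame | None = None
) -> OddsRatioResult:
    """Maximum-likelihood logistic regression odds ratio with 95% Wald CI."""
    y = np.asarray(outcome, dtype=float)
    if not set(np.unique(y)) <= {0.0, 1.0}:
        raise ValueError("outcome must be binary (0/1)")
    x = np.asarray(predictor, dtype=float)
    cols = {"predictor": x}
    names: tuple[str, ...] = ()
    if covariates is not None:
        for c in covariates.columns:
            cols[str(c)] = np.asarray(covariates[c], dtype=float)
        names = tuple(str(c) for c in covariates.columns)
    design = sm.add_constant(pd.DataFrame(cols), has_constant="add")
    if np.linalg.matrix_rank(design.to_numpy()) < design.shape[1]:
        raise ValueError("design matrix is rank-deficient")
    try:
        fit = sm.Logit(y, design).fit(disp=False, maxiter=100)
    except Exception as err:  # perfect separation raised by statsmodels
        raise ValueError(f"logistic fit failed: {err}") from err
    if not fit.mle_retvals.get("converged", True):
        raise ValueError("logistic fit did not converge")
    coef = fit.params["predictor"]
    se = fit.bse["predictor"]
    if not np.isfinite(se) or se > 50:
        raise ValueError("unstable standard error: possible complete separation")
    z = stats.norm.ppf(0.975)
    return OddsRatioResult(
        or_estimate=float(np.exp(coef)),
        ci_low=float(np.exp(coef - z * se)),
        ci_high=float(np.exp(coef + z * se)),
        adjusted_for=names,
    )


def _fmt_count(n: int, total: int, suppress: bool) -> str:
    if suppress and 0 < n < 5:
        bound = 5 / total * 100 if total else 0.0
        return f"<5 (<{bound:.1f}%)"
    pct = 100.0 * n / total if total else 0.0
    return f"{n} ({pct:.1f}%)"


def characterisation_report(
    cohort: pd.DataFrame,
    labels: pd.Series,
    characteristics: list[str] | None = None,
    suppress_small_cells: bool = True,
) -> pd.DataFrame:
    """Per-characteristic counts/percentages by cluster with test p-values.

    ``labels`` maps subject_id to cluster (1..K); only labelled subjects are
    summarised. Numeric characteristics are compared with the rank-sum test
    and reported as mean (SD); categoricals with the uncorrected chi-square
    test over the full contingency table (p is NaN when a margin is empty).
    """
    sub = cohort.set_index("subject_id").loc[labels.index]
    groups = sorted(labels.unique())
    if characteristics is None:
        characteristics = [
            c
            for c in sub.columns
            if c not in ("group",) and (sub[c].dtype != object or sub[c].nunique() < 10)
        ]
    rows = []
    for char in characteristics:
        col = sub[char]
        if pd.api.types.is_numeric_dtype(col) and col.nunique() > 2:
            samples = [col[labels == g].dropna() for g in groups]
            try:
                p = rank_sum_test(*samples) if len(groups) == 2 else np.nan
            except ValueError:
                p = np.nan
            row = {"characteristic": char, "type": "continuous", "p_value": p}
            for g, s in zip(groups, samples):
                row[f"cluster_{g}"] = f"{s.mean():.1f} ({s.std(ddof=1):.1f})"
            rows.append(row)
        else:
            cats = sorted(col.dropna().unique(), key=str)
            counts = {
                g: col[labels == g].value_counts() for g in groups
            }
            totals = {g: int(col[labels == g].notna().sum()) for g in groups}
            table = np.array(
                [[counts[g].get(c, 0) for c in cats] for g in groups], dtype=float
            )
            if table.shape[1] >= 2 and not (
                np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0)
            ):
                _, p, _, _ = stats.chi2_contingency(table, correction=False)
            else:
                p = np.nan
            if set(cats) <= {0, 1, True, False}:
                report_cats = [c for c in cats if c in (1, True)] or cats[-1:]
            else:
                report_cats = cats
            for c in report_cats:
                row = {
                    "characteristic": f"{char}={c}" if len(report_cats) > 1 else char,
                    "type": "categorical",
                    "p_value": p,
                }
                for g in groups:
                    row[f"cluster_{g}"] = _fmt_count(
                        int(counts[g].get(c, 0)), totals[g], suppress_small_cells
                    )
                rows.append(row)
    return pd.DataFrame(rows)
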