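"""Statistical layer: descriptives, group tests, OLS, variance shares,
Bland-Altman agreement.

All p-values are two-sided; no multiple-testing correction is applied
(alpha = 0.05 is the working significance level).  Natural logs are used
for skewed variables (AWT, %LAA-950); the log base changes coefficients
but not p-values or R^2.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

LOG_TRANSFORMED = ("awt35_mm", "laa950_pct")


@dataclass
class Term:
    name: str
    coef: float
    se: float
    p_value: float


@dataclass
class RegressionResult:
    outcome: str
    terms: list[Term]
    r_squared: float
    n: int
    variance_share_sequential: dict[str, float] = field(default_factory=dict)
    variance_share_semipartial: dict[str, float] = field(default_factory=dict)
    log_base: str = "natural"

    def term(self, name: str) -> Term:
        for t in self.terms:
            if t.name == name:
                return t
        raise KeyError(name)


@dataclass
class AgreementResult:
    bias: float
    loa_low: float
    loa_high: float
    sd_diff: float
    n_pairs: int
    p_value_bias: float  # one-sample t-test of the differences against 0


# ---------------------------------------------------------------------------
# descriptives
# ---------------------------------------------------------------------------


def describe_cohort(
    table: pd.DataFrame, skewed: tuple[str, ...] = ("pack_years", "awt35_mm",
                                                    "laa950_pct", "perc15_hu")
) -> pd.DataFrame:
    """Summary rows: mean +/- SD for near-normal columns, median (Q1-Q3)
    for columns flagged as skewed, percentage for booleans."""
    if len(table) == 0:
        raise ValueError("empty cohort table")
    rows = []
    for col in table.columns:
        if col == "subject_id":
            continue
        s = table[col]
        if s.isna().all():
            rows.append({"variable": col, "summary": "all missing", "kind": "flagged"})
            continue
        if s.dtype == bool:
            rows.append(
                {
                    "variable": col,
                    "summary": f"{100.0 * s.mean():.1f}",
                    "kind": "percent",
                    "value": 100.0 * float(s.mean()),
                }
            )
        elif col in skewed:
            q1, med, q3 = np.percentile(s.dropna(), [25, 50, 75])
            rows.append(
                {
                    "variable": col,
                    "summary": f"{med:.2f} ({q1:.2f} - {q3:.2f})",
                    "kind": "median_iqr",
                    "value": float(med),
                    "q1": float(q1),
                    "q3": float(q3),
                }
            )
        else:
            rows.append(
                {
                    "variable": col,
                    "summary": f"{s.mean():.2f} ± {s.std(ddof=1):.2f}",
                    "kind": "mean_sd",
                    "value": float(s.mean()),
                    "sd": float(s.std(ddof=1)),
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# group comparisons
# ---------------------------------------------------------------------------


def compare_groups(
    values, group=None, kind: str = "mann_whitney", paired=None
) -> tuple[float, float]:
    """Two-sided group comparison.

    ``kind`` is one of ``mann_whitney`` (rank test for two independent
    samples; exact p for small groups, normal approximation with continuity
    correction above n = 20), ``t_test``, ``chi_square`` (2x2 counts of two
    boolean vectors), or ``wilcoxon_signed_rank`` (``values`` vs ``paired``,
    equal lengths).  Returns (statistic, p_value).
    """
    if kind == "wilcoxon_signed_rank":
        a = np.asarray(values, dtype=float)
        b = np.asarray(paired, dtype=float)
        if a.shape != b.shape or len(a) < 3:
            raise ValueError("signed-rank test needs >= 3 equal-length pairs")
        method = "exact" if len(a) <= 25 else "approx"
        res = stats.wilcoxon(a, b, method=method, correction=True)
        return float(res.statistic), float(res.pvalue)

    values = np.asarray(values)
    group = np.asarray(group, dtype=bool)
    a, b = values[group], values[~group]
    if len(a) < 3 or len(b) < 3:
        raise ValueError("each group needs at least 3 observations")
    if kind == "mann_whitney":
        method = "exact" if max(len(a), len(b)) <= 20 else "asymptotic"
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
        return float(res.statistic), float(res.pvalue)
    if kind == "t_test":
        if np.std(a) == 0 and np.std(b) == 0:
            raise ValueError("zero variance in both groups: t-test undefined")
        res = stats.ttest_ind(a, b)
        return float(res.statistic), float(res.pvalue)
    if kind == "chi_square":
        av = values.astype(bool)
        contingency = np.array(
            [
                [np.sum(av & group), np.sum(~av & group)],
                [np.sum(av & ~group), np.sum(~av & ~group)],
            ]
        )
        chi2, p, _, _ = stats.chi2_contingency(contingency)
        return float(chi2), float(p)
    raise ValueError(f"unknown test kind {kind!r}")


# ---------------------------------------------------------------------------
# regression
# ---------------------------------------------------------------------------


def _design(table: pd.DataFrame, cols: list[str], transform_map: dict | None):
    transform_map = transform_map or {}
    X = pd.DataFrame(index=table.index)
    for c in cols:
        x = table[c].astype(float)
        t = transform_map.get(c, "identity")
        if t == "log":
            if (x <= 0).any():
                raise ValueError(f"log transform of non-positive values in {c!r}")
            X[f"log_{c}"] = np.log(x)
        elif t == "identity":
            X[c] = x
        else:
            raise ValueError(f"unknown transform {t!r}")
    return X


def _fit(y: pd.Series, X: pd.DataFrame, outcome: str) -> RegressionResult:
    mask = y.notna() & X.notna().all(axis=1)
    yv = y[mask]
    Xv = sm.add_constant(X[mask])
    if len(yv) <= Xv.shape[1]:
        raise ValueError("not enough observations for the design")
    rank = np.linalg.matrix_rank(Xv.values)
    if rank < Xv.shape[1]:
        corr = X[mask].corr().abs()
        np.fill_diagonal(corr.values, 0.0)
        worst = corr.stack().idxmax() if corr.size else ("?", "?")
        raise ValueError(
            f"rank-deficient design (rank {rank} < {Xv.shape[1]}); "
            f"most collinear columns: {worst}"
        )
    fit = sm.OLS(yv, Xv).fit()
    terms = [
        Term(name, float(fit.params[name]), float(fit.bse[name]),
             float(fit.pvalues[name]))
        for name in Xv.columns
    ]
    return RegressionResult(
        outcome=outcome, terms=terms, r_squared=float(fit.rsquared), n=int(len(yv))
    )


def univariate_ols(
    table: pd.DataFrame, y: str, x: str, transform_map: dict | None = None
) -> RegressionResult:
    """OLS of a single predictor, transforms applied first."""
    X = _design(table, [x], transform_map)
    if np.isclose(X.iloc[:, 0].std(), 0.0):
        raise ValueError(f"predictor {x!r} is constant")
    yv = _design(table, [y], transform_map).iloc[:, 0]
    return _fit(yv, X, outcome=yv.name)


def multivariate_ols(
    table: pd.DataFrame, y: str, xs: list[str], transform_map: dict | None = None
) -> RegressionResult:
    """OLS on all named terms jointly."""
    X = _design(table, xs, transform_map)
    yv = _design(table, [y], transform_map).iloc[:, 0]
    res = _fit(yv, X, outcome=yv.name)
    seq, semi = _variance_shares(yv, X)
    res.variance_share_sequential = seq
    res.variance_share_semipartial = semi
    return res


def select_significant_univariate(
    table: pd.DataFrame,
    y: str,
    candidates: list[str],
    transform_map: dict | None = None,
    alpha: float = 0.05,
) -> list[str]:
    """Entry gate for the multivariable model: candidates whose univariate
    association with the outcome reaches ``alpha``."""
    keep = []
    for c in candidates:
        res = univariate_ols(table, y, c, transform_map)
        if res.terms[-1].p_value < alpha:
            keep.append(c)
    return keep


def _variance_shares(y: pd.Series, X: pd.DataFrame):
    mask = y.notna() & X.notna().all(axis=1)
    yv, Xv = y[mask], X[mask]

    def r2(cols: list[str]) -> float:
        if not cols:
            return 0.0
        return float(sm.OLS(yv, sm.add_constant(Xv[cols])).fit().rsquared)

    cols = list(Xv.columns)
    full = r2(cols)
    sequential, semipartial = {}, {}
    prev = 0.0
    for i, c in enumerate(cols):
        cur = r2(cols[: i + 1])
        sequential[c] = cur - prev
        prev = cur
    for c in cols:
        semipartial[c] = full - r2([x for x in cols if x != c])
    return sequential, semipartial


def variance_explained(
    table: pd.DataFrame,
    y: str,
    ordered_terms: list[str],
    transform_map: dict | None = None,
) -> dict[str, dict[str, float]]:
    """Per-term variance shares of an OLS model, by two conventions.

    ``sequential``: R^2 increments as terms enter in the stated order (they
    sum exactly to the full-model R^2); ``semipartial``: squared
    semi-partial correlations from the full model (unique contribution of
    each term).  Both are reported, labelled by method.
    """
    X = _design(table, ordered_terms, transform_map)
    yv = _design(table, [y], transform_map).iloc[:, 0]
    seq, semi = _variance_shares(yv, X)
    return {"sequential": seq, "semipartial": semi}


# ---------------------------------------------------------------------------
# agreement
# ---------------------------------------------------------------------------


def bland_altman(a, b) -> AgreementResult:
    """Bland-Altman agreement of paired measurements: bias = mean(a - b),
    95% limits of agreement = bias -/+ 1.96 * SD of the differences."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or len(a) < 3:
        raise ValueError("Bland-Altman needs >= 3 pairs of equal length")
    d = a - b
    bias = float(np.mean(d))
    sd = float(np.std(d, ddof=1))
    if sd == 0:
        p = 1.0 if bias == 0 else 0.0
    else:
        p = float(stats.ttest_1samp(d, 0.0).pvalue)
    return AgreementResult(
        bias=bias,
        loa_low=bias - 1.96 * sd,
        loa_high=bias + 1.96 * sd,
        sd_diff=sd,
        n_pairs=len(d),
        p_value_bias=p,
    )
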