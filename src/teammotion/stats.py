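"""Rater aggregation, interrater reliability, normality screening,
feature-score association and covariate-adjusted regression.

The rating instrument is the team-level NOTSS (Non-Technical Skills for
Surgeons) scale: 12 behavioural items in 4 categories (situational
awareness, decision-making, communication & teamwork, leadership), each
scored 1-4 by each rater.  Scores are averaged across raters; interrater
reliability is the mean-measures consistency ICC from a two-way mixed
model — Shrout-Fleiss ICC(3,k) — computed from the two-way ANOVA mean
squares with an exact F-based 95% CI.

Because per-case motion features are typically non-normal (screened with a
Lilliefors-style Kolmogorov-Smirnov test), Spearman rank correlation is the
default association measure, with Pearson available by flag.  Features that
associate significantly with the total score are further examined by OLS
regression adjusted for bypass duration and 30-day morbidity risk.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats as st
import statsmodels.api as sm
from statsmodels.stats.diagnostic import lilliefors
from statsmodels.stats.multitest import multipletests

__all__ = [
    "NOTSS_CATEGORIES",
    "NOTSS_ITEMS",
    "StatsWarning",
    "IccResult",
    "KsResult",
    "AssociationResult",
    "RegressionResult",
    "average_notss",
    "icc_two_way_mixed_consistency",
    "ks_normality",
    "associate",
    "fit_adjusted_regression",
]

#: the 12 NOTSS items, 3 per category
NOTSS_CATEGORIES = [
    "situational_awareness",
    "decision_making",
    "communication_teamwork",
    "leadership",
]
NOTSS_ITEMS = {
    "situational_awareness": ["SA1", "SA2", "SA3"],
    "decision_making": ["DM1", "DM2", "DM3"],
    "communication_teamwork": ["CT1", "CT2", "CT3"],
    "leadership": ["LD1", "LD2", "LD3"],
}
_ITEM_TO_CATEGORY = {i: c for c, items in NOTSS_ITEMS.items() for i in items}
ALL_ITEMS = [i for items in NOTSS_ITEMS.values() for i in items]


class StatsWarning(UserWarning):
    """Non-fatal statistical condition (exclusions, degenerate inputs)."""


@dataclass(frozen=True)
class IccResult:
    icc: float
    ci_low: float
    ci_high: float
    p_value: float
    n_cases: int
    n_raters: int


@dataclass(frozen=True)
class KsResult:
    statistic: float
    p_value: float
    n: int
    degenerate: bool = False
    #: the null parameters are estimated from the sample (Lilliefors variant)
    estimated_parameters: bool = True


@dataclass(frozen=True)
class AssociationResult:
    feature: str
    coefficient: float
    p_value: float
    method: str
    n: int
    significant: bool
    degenerate: bool = False
    q_value: float | None = None


@dataclass(frozen=True)
class RegressionResult:
    """OLS of the outcome on [intercept, feature, bypass, morbidity]."""

    feature: str
    params: dict[str, float]
    bse: dict[str, float]
    p_values: dict[str, float]
    conf_int: dict[str, tuple[float, float]]
    r2: float
    adj_r2: float
    n: int


def average_notss(table: pd.DataFrame) -> pd.DataFrame:
    """Per-case category means and total score, averaged across raters.

    Expects long-format rows ``(case_id, rater_id, item_id, score)`` with
    the 12 canonical item ids.  The category score is the mean of its three
    items averaged over raters; the total is the mean of the four category
    scores.  Cases missing any item from any rater are excluded with a
    warning.
    """
    unknown = set(table["item_id"]) - set(ALL_ITEMS)
    if unknown:
        raise ValueError(f"unknown NOTSS item ids: {sorted(unknown)}")
    if not table["score"].isin([1, 2, 3, 4]).all():
        raise ValueError("scores must be integers in 1..4")

    complete_ids = []
    for case_id, g in table.groupby("case_id", sort=True):
        ok = all(
            set(rg["item_id"]) == set(ALL_ITEMS)
            for _, rg in g.groupby("rater_id")
        )
        if ok:
            complete_ids.append(case_id)
        else:
            warnings.warn(
                f"case {case_id}: incomplete ratings, excluded from NOTSS "
                "summaries", StatsWarning, stacklevel=2,
            )
    sub = table[table["case_id"].isin(complete_ids)].copy()
    sub["category"] = sub["item_id"].map(_ITEM_TO_CATEGORY)
    cat = (
        sub.groupby(["case_id", "category"], sort=True)["score"]
        .mean()
        .unstack("category")
        .loc[:, NOTSS_CATEGORIES]
    )
    cat["total"] = cat[NOTSS_CATEGORIES].mean(axis=1)
    return cat.reset_index()


def notss_case_rater_matrix(table: pd.DataFrame) -> pd.DataFrame:
    """Cases x raters matrix of per-rater total scores (for the ICC)."""
    per_rater = (
        table.assign(category=table["item_id"].map(_ITEM_TO_CATEGORY))
        .groupby(["case_id", "rater_id", "category"])["score"]
        .mean()
        .groupby(["case_id", "rater_id"])
        .mean()
        .unstack("rater_id")
    )
    return per_rater


def icc_two_way_mixed_consistency(matrix: np.ndarray | pd.DataFrame) -> IccResult:
    """Mean-measures consistency ICC from a two-way mixed model, ICC(3,k).

    With ``n`` cases (rows) rated by the same ``k`` raters (columns), the
    two-way ANOVA partitions the total sum of squares into rows (cases),
    columns (raters) and residual.  With between-cases mean square BMS and
    residual mean square EMS,

        ICC(3,k) = (BMS - EMS) / BMS

    The 95% CI is the exact F-based (Shrout-Fleiss) interval from
    ``F = BMS/EMS`` with ``(n-1, (n-1)(k-1))`` degrees of freedom, and the
    p-value tests ICC = 0 via that same F.  Consistency ICC ignores additive
    rater offsets by construction (the rater sum of squares is removed).

    Rows containing missing values are dropped (listwise) with a warning.
    """
    x = np.asarray(matrix, dtype=float)
    if x.ndim != 2:
        raise ValueError("matrix must be 2-D (cases x raters)")
    complete = ~np.isnan(x).any(axis=1)
    if not complete.all():
        warnings.warn(
            f"{(~complete).sum()} incomplete case(s) dropped before ICC",
            StatsWarning, stacklevel=2,
        )
        x = x[complete]
    n, k = x.shape
    if n < 2 or k < 2:
        raise ValueError(f"need >= 2 complete cases and >= 2 raters, got {n}x{k}")

    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    # residuals formed directly (not by SS subtraction): rater offsets then
    # cancel exactly instead of leaving catastrophic-cancellation dust
    resid = x - row_means[:, None] - col_means[None, :] + grand
    ss_err = np.sum(resid**2)

    df_rows = n - 1
    df_err = (n - 1) * (k - 1)
    bms = ss_rows / df_rows
    ems = ss_err / df_err

    if bms == 0.0:
        # no between-case variance at all: reliability undefined
        return IccResult(float("nan"), float("nan"), float("nan"),
                         float("nan"), n, k)
    if ems == 0.0:
        return IccResult(1.0, 1.0, 1.0, 0.0, n, k)

    icc = (bms - ems) / bms
    f_obs = bms / ems
    p = float(st.f.sf(f_obs, df_rows, df_err))
    fl = f_obs / st.f.ppf(0.975, df_rows, df_err)
    fu = f_obs * st.f.ppf(0.975, df_err, df_rows)
    return IccResult(float(icc), float(1 - 1 / fl), float(1 - 1 / fu), p, n, k)


def ks_normality(values: np.ndarray | pd.Series) -> KsResult:
    """Kolmogorov-Smirnov normality screen with estimated parameters.

    One-sample KS against a normal with the sample's mean and SD — the
    Lilliefors variant, whose p-values account for parameter estimation.
    A zero-variance sample is reported as non-normal with a degenerate flag.
    """
    x = np.asarray(values, dtype=float)
    x = x[~np.isnan(x)]
    if x.size < 5:
        raise ValueError("need at least 5 observations for the KS screen")
    if np.ptp(x) == 0.0:
        return KsResult(float("nan"), 0.0, x.size, degenerate=True)
    stat, p = lilliefors(x, dist="norm")
    return KsResult(float(stat), float(p), x.size)


def associate(
    features: pd.DataFrame,
    scores: pd.DataFrame,
    method: str = "spearman",
    feature_columns: list[str] | None = None,
    alpha: float = 0.05,
    bh: bool = False,
) -> list[AssociationResult]:
    """Correlate each motion feature with the per-case total NOTSS score.

    ``features`` must carry ``case_id`` plus feature columns; ``scores``
    carries ``case_id`` and ``total``.  Pairs with missing values are
    dropped per feature; at least 4 complete pairs are required.  The
    two-sided p-value uses the t approximation of either method.  With
    ``bh=True`` Benjamini-Hochberg q-values across the tested features are
    attached (raw p-values are always reported).
    """
    if method not in ("spearman", "pearson"):
        raise ValueError(f"unknown correlation method {method!r}")
    if feature_columns is None:
        feature_columns = [c for c in features.columns if c != "case_id"]
    merged = features.merge(scores[["case_id", "total"]], on="case_id")
    results = []
    for col in feature_columns:
        pair = merged[[col, "total"]].dropna()
        n = len(pair)
        if n < 4:
            warnings.warn(
                f"feature {col}: only {n} complete pairs (< 4), "
                "correlation not estimated", StatsWarning, stacklevel=2,
            )
            results.append(AssociationResult(col, float("nan"), float("nan"),
                                             method, n, False, degenerate=True))
            continue
        x, y = pair[col].to_numpy(), pair["total"].to_numpy()
        if np.ptp(x) == 0.0 or np.ptp(y) == 0.0:
            warnings.warn(
                f"feature {col}: zero variance, correlation undefined",
                StatsWarning, stacklevel=2,
            )
            results.append(AssociationResult(col, float("nan"), float("nan"),
                                             method, n, False, degenerate=True))
            continue
        if method == "spearman":
            r, p = st.spearmanr(x, y)
        else:
            r, p = st.pearsonr(x, y)
        results.append(
            AssociationResult(col, float(r), float(p), method, n,
                              significant=bool(p < alpha))
        )
    if bh:
        ok = [r for r in results if not r.degenerate]
        if ok:
            _, q, _, _ = multipletests([r.p_value for r in ok], method="fdr_bh")
            qmap = {r.feature: float(qi) for r, qi in zip(ok, q)}
            results = [
                AssociationResult(r.feature, r.coefficient, r.p_value, r.method,
                                  r.n, r.significant, r.degenerate,
                                  q_value=qmap.get(r.feature))
                for r in results
            ]
    return results


def fit_adjusted_regression(
    y: pd.DataFrame,
    features: pd.DataFrame,
    feature: str,
    covariates: pd.DataFrame,
) -> RegressionResult:
    """OLS of total NOTSS on one motion feature plus clinical covariates.

    The design matrix is ``[1, feature, bypass_minutes, morbidity30d]``;
    coefficients, standard errors, t-based p-values and 95% CIs, R² and
    adjusted R² are reported.  Raises on rank deficiency, naming the
    collinear columns.
    """
    merged = (
        features[["case_id", feature]]
        .merge(y[["case_id", "total"]], on="case_id")
        .merge(covariates[["case_id", "bypass_minutes", "morbidity30d"]],
               on="case_id")
        .dropna()
    )
    n = len(merged)
    cols = [feature, "bypass_minutes", "morbidity30d"]
    if n <= len(cols) + 1:
        raise ValueError(f"need more than {len(cols) + 1} complete cases, got {n}")
    X = sm.add_constant(merged[cols], has_constant="add")
    if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        bad = [
            c for c in cols
            if np.linalg.matrix_rank(X.drop(columns=c).to_numpy())
            == np.linalg.matrix_rank(X.to_numpy())
        ]
        raise ValueError(f"design matrix is rank deficient; collinear: {bad}")
    fit = sm.OLS(merged["total"], X).fit()
    ci = fit.conf_int()
    return RegressionResult(
        feature=feature,
        params={k: float(v) for k, v in fit.params.items()},
        bse={k: float(v) for k, v in fit.bse.items()},
        p_values={k: float(v) for k, v in fit.pvalues.items()},
        conf_int={k: (float(ci.loc[k, 0]), float(ci.loc[k, 1])) for k in ci.index},
        r2=float(fit.rsquared),
        adj_r2=float(fit.rsquared_adj),
        n=n,
    )
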