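"""Downstream analyses over the item norms.

Reliability of the rating scales (Cronbach's alpha per presentation
list), the inter-dimension correlation structure, cross-dataset
correlations through a translation mapping, ladenness transforms, and
the two-step hierarchical regression on lexical-decision latencies with
its nested-model F test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.outliers_influence import variance_inflation_factor


# ---------------------------------------------------------------------------
# reliability
# ---------------------------------------------------------------------------

def cronbach_alpha(
    matrix: pd.DataFrame, max_missing: float = 0.5
) -> float:
    """Cronbach's alpha with raters as the scale's "test items".

    ``matrix`` is items (rows) x raters (columns).  alpha =
    k/(k-1) * (1 - sum_j var_j / var_total), where var_j is the variance
    of rater j over items and var_total the variance of the per-item
    rater sums.  Missing-data policy: raters missing more than
    ``max_missing`` of the items are dropped; remaining missing cells are
    imputed with the item (row) mean.  Needs >= 2 usable raters.
    """
    m = matrix.astype(float)
    keep = m.isna().mean(axis=0) <= max_missing
    m = m.loc[:, keep]
    k = m.shape[1]
    if k < 2:
        raise ValueError("fewer than 2 usable raters after missing-data policy")
    row_means = m.mean(axis=1)
    m = m.apply(lambda col: col.fillna(row_means))
    var_total = m.sum(axis=1).var(ddof=1)
    if var_total == 0:
        raise ValueError("zero total-score variance; alpha undefined")
    var_sum = m.var(axis=0, ddof=1).sum()
    return float(k / (k - 1) * (1.0 - var_sum / var_total))


@dataclass
class ReliabilityReport:
    list_id: str
    dimension: str
    alpha: float
    n_raters: int
    n_items: int


def reliability_by_list(
    ratings: pd.DataFrame, design, max_missing: float = 0.5
) -> pd.DataFrame:
    """Cronbach's alpha per (presentation list, Likert dimension)."""
    rows = []
    for list_id, items in design.lists.items():
        item_set = set(items)
        for dim in design.likert_dimensions:
            sub = ratings[
                (ratings["dimension"] == dim)
                & ratings["item_id"].isin(item_set)
            ]
            if sub.empty:
                continue
            wide = sub.pivot_table(
                index="item_id",
                columns="participant_id",
                values="value",
                aggfunc="first",
            ).astype(float)
            try:
                alpha = cronbach_alpha(wide, max_missing=max_missing)
            except ValueError:
                alpha = np.nan
            rows.append(
                {
                    "list_id": list_id,
                    "dimension": dim,
                    "alpha": alpha,
                    "n_raters": wide.shape[1],
                    "n_items": wide.shape[0],
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# correlation structure
# ---------------------------------------------------------------------------

def correlation_matrix(
    norms: pd.DataFrame, highlight_threshold: float = 0.18
) -> tuple[pd.DataFrame, list[tuple[str, str, float]]]:
    """Pairwise Pearson correlations over items, with a highlighted set.

    ``norms`` is items x variables.  Pairwise-complete observations
    (>= 3 per pair); zero-variance variables yield missing entries with a
    warning.  Returns the symmetric unit-diagonal matrix and the list of
    off-diagonal pairs with \\|r\\| strictly above the threshold.
    """
    numeric = norms.astype(float)
    zero_var = numeric.std(ddof=1) == 0
    if zero_var.any():
        warnings.warn(
            "zero variance in: "
            + ", ".join(numeric.columns[zero_var])
        )
    corr = numeric.corr(method="pearson", min_periods=3)
    corr.values[np.diag_indices_from(corr.values)] = np.where(
        zero_var, np.nan, 1.0
    )
    highlighted = [
        (a, b, float(corr.loc[a, b]))
        for i, a in enumerate(corr.columns)
        for b in corr.columns[i + 1:]
        if np.isfinite(corr.loc[a, b])
        and abs(corr.loc[a, b]) > highlight_threshold
    ]
    return corr, highlighted


@dataclass
class CrossDatasetCorrelation:
    r: float
    n: int
    df: int
    p: float


def cross_dataset_correlation(
    norms_a: pd.Series,
    norms_b: pd.Series,
    mapping: pd.DataFrame,
    duplicates: str = "mean",
) -> CrossDatasetCorrelation:
    """Pearson correlation of two norm sets through a translation mapping.

    ``mapping`` has columns ``item_a``/``item_b``.  Many-to-one
    translations are resolved per ``duplicates``: "mean" averages dataset
    B values per A item, "first" keeps the first pair, "error" raises.
    Scale orientations are never auto-flipped — a reversed scale shows up
    as a negative r.
    """
    pairs = mapping[["item_a", "item_b"]].copy()
    pairs["a"] = pairs["item_a"].map(norms_a)
    pairs["b"] = pairs["item_b"].map(norms_b)
    pairs = pairs.dropna(subset=["a", "b"])
    if pairs["item_a"].duplicated().any():
        if duplicates == "error":
            raise ValueError("many-to-one translation pairs present")
        if duplicates == "first":
            pairs = pairs.drop_duplicates("item_a", keep="first")
        elif duplicates == "mean":
            pairs = (
                pairs.groupby("item_a", sort=False)[["a", "b"]]
                .mean()
                .reset_index()
            )
        else:
            raise ValueError(f"unknown duplicates policy {duplicates!r}")
    n = len(pairs)
    if n < 3:
        raise ValueError(f"only {n} comparable pairs; need at least 3")
    r, p = stats.pearsonr(pairs["a"], pairs["b"])
    return CrossDatasetCorrelation(r=float(r), n=n, df=n - 2, p=float(p))


# ---------------------------------------------------------------------------
# ladenness + hierarchical regression
# ---------------------------------------------------------------------------

def compute_ladenness(
    likert_norms: pd.DataFrame,
    dimensions: tuple[str, ...] = ("gender", "location", "political"),
) -> pd.DataFrame:
    """Ladenness per item: the absolute mean rating on bipolar dimensions.

    Distance from the neutral midpoint regardless of direction — extreme
    items on either pole score high, neutral items near 0.  Input is the
    tidy norms table (item_id, dimension, mean); output is wide with one
    ``<dimension>_ladenness`` column per requested dimension.
    """
    sub = likert_norms[likert_norms["dimension"].isin(dimensions)]
    wide = sub.pivot(index="item_id", columns="dimension", values="mean")
    out = pd.DataFrame(index=wide.index)
    for d in dimensions:
        out[f"{d}_ladenness"] = wide[d].abs()
    return out.reset_index()


@dataclass
class RegressionResult:
    """One step of the hierarchical regression.

    ``coefficients`` is indexed by predictor (incl. the intercept) with
    columns beta/se/t/p.  Step 2 additionally carries the R-squared
    change and its nested-model F test against step 1.
    """

    step: int
    coefficients: pd.DataFrame
    r2: float
    n: int
    max_vif: float
    delta_r2: float | None = None
    f_stat: float | None = None
    f_df1: int | None = None
    f_df2: int | None = None
    f_p: float | None = None


def _check_design(x: pd.DataFrame) -> None:
    zero_var = x.columns[x.std(ddof=0) == 0]
    if len(zero_var):
        raise ValueError(
            "zero-variance predictor(s): " + ", ".join(zero_var)
        )
    xm = sm.add_constant(x, has_constant="add")
    if np.linalg.matrix_rank(xm.to_numpy()) < xm.shape[1]:
        # name the offenders: columns whose removal restores full rank
        offenders = []
        for col in x.columns:
            rest = xm.drop(columns=[col])
            if np.linalg.matrix_rank(rest.to_numpy()) == rest.shape[1]:
                offenders.append(col)
        raise ValueError(
            "collinear design; offending predictor(s): "
            + ", ".join(offenders or list(x.columns))
        )


def _fit_step(y: pd.Series, x: pd.DataFrame, step: int) -> RegressionResult:
    _check_design(x)
    xm = sm.add_constant(x, has_constant="add")
    fit = sm.OLS(y, xm).fit()
    coefs = pd.DataFrame(
        {
            "beta": fit.params,
            "se": fit.bse,
            "t": fit.tvalues,
            "p": fit.pvalues,
        }
    )
    arr = xm.to_numpy()
    vifs = [
        variance_inflation_factor(arr, i) for i in range(1, arr.shape[1])
    ]
    return RegressionResult(
        step=step,
        coefficients=coefs,
        r2=float(fit.rsquared),
        n=int(fit.nobs),
        max_vif=float(max(vifs)) if vifs else np.nan,
    )


def hierarchical_regression(
    data: pd.DataFrame,
    outcome: str,
    step1_predictors: tuple[str, ...],
    step2_additions: tuple[str, ...],
) -> tuple[RegressionResult, RegressionResult]:
    """Two-step OLS hierarchical regression with a nested-model F test.

    Listwise deletion: rows missing the outcome or any predictor of
    either step are dropped so both steps fit the same cases.  Step 2 is
    step 1 plus ``step2_additions``; its R-squared change is tested with
    F(q, n - p2 - 1) where q = number of added predictors and p2 the
    step-2 predictor count.
    """
    cols = [outcome, *step1_predictors, *step2_additions]
    complete = data[cols].dropna()
    y = complete[outcome].astype(float)
    res1 = _fit_step(y, complete[list(step1_predictors)].astype(float), 1)
    x2 = complete[list(step1_predictors) + list(step2_additions)].astype(
        float
    )
    res2 = _fit_step(y, x2, 2)
    q = len(step2_additions)
    n = res2.n
    p2 = x2.shape[1]
    delta = res2.r2 - res1.r2
    df2 = n - p2 - 1
    f = (delta / q) / ((1.0 - res2.r2) / df2)
    res2.delta_r2 = float(delta)
    res2.f_stat = float(f)
    res2.f_df1 = q
    res2.f_df2 = df2
    res2.f_p = float(stats.f.sf(f, q, df2))
    return res1, res2


def standardized_coefficients(
    data: pd.DataFrame, outcome: str, predictors: tuple[str, ...]
) -> pd.Series:
    """Fully standardised OLS coefficients (z-scored outcome and
    predictors), for effect-size comparison across predictors."""
    complete = data[[outcome, *predictors]].dropna().astype(float)
    z = (complete - complete.mean()) / complete.std(ddof=1)
    xm = sm.add_constant(z[list(predictors)], has_constant="add")
    fit = sm.OLS(z[outcome], xm).fit()
    return fit.params.drop("const")
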