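"""Age norms: weighted proportions, mode categories and PCA summaries.

Each participant's multi-select age response gives total weight 1, split
equally across the selected bands (1/n_selected each); an empty selection
puts the whole weight on the explicit "no age" category.  Per item the
weights are summed and divided by the number of participants who knew the
item, yielding an 8-category weighted-proportion vector that sums to 1 —
an associative-strength profile over the age categories.  A PCA over the
items x 8 proportion matrix yields compact per-item summary scores.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .core_io import AGE_BANDS, AGE_CATEGORIES, NO_AGE, split_bands

#: Default sign-orientation rules: (category, required loading sign) per
#: component.  PCA component signs are arbitrary; pinning the 66-80
#: loading negative on PC1 (older = negative), the 31-50 loading negative
#: on PC2 (middle-aged = negative) and the no-age loading negative on PC3
#: makes scores comparable across runs and matches the conventional
#: younger/older, middle-aged, no-age reading of the components.
DEFAULT_ORIENTATION = (("66-80", -1), ("31-50", -1), (NO_AGE, -1))


class UnknownAgeResponseError(ValueError):
    """Weighting was asked for a response marked unknown."""


def weight_responses(selected_bands, unknown: bool = False) -> pd.Series:
    """Weights over the 8 age categories for one participant response.

    Each selected band receives 1/n_selected; an empty selection puts
    weight 1 on "no age".  Weights always sum to 1.  UNKNOWN responses
    must be dropped by the caller.
    """
    if unknown:
        raise UnknownAgeResponseError(
            "unknown responses carry no age weight; drop them first"
        )
    bands = tuple(selected_bands)
    bad = [b for b in bands if b not in AGE_BANDS]
    if bad:
        raise ValueError(f"unknown age band(s): {bad}")
    w = pd.Series(0.0, index=list(AGE_CATEGORIES))
    if not bands:
        w[NO_AGE] = 1.0
    else:
        for b in bands:
            w[b] += 1.0 / len(bands)
    return w


def weighted_proportions(responses: pd.DataFrame) -> pd.Series:
    """8-category weighted proportion vector for one item.

    ``responses`` holds that item's age rows (columns ``bands``,
    ``unknown``).  Unknown responses are excluded from both numerator and
    denominator; with no known response the vector is all-missing.
    """
    known = responses[~responses["unknown"]]
    n_known = len(known)
    if n_known == 0:
        return pd.Series(np.nan, index=list(AGE_CATEGORIES))
    total = pd.Series(0.0, index=list(AGE_CATEGORIES))
    for cell in known["bands"]:
        total += weight_responses(split_bands(cell))
    return total / n_known


def summarize_ages(ages: pd.DataFrame) -> pd.DataFrame:
    """Weighted proportions per item: one row per item, 8 proportion
    columns plus ``n_known`` (rows with zero known responses keep NaN
    proportions)."""
    rows = []
    for item, grp in ages.groupby("item_id", sort=True):
        props = weighted_proportions(grp)
        row = {"item_id": item, "n_known": int((~grp["unknown"]).sum())}
        row.update({c: props[c] for c in AGE_CATEGORIES})
        rows.append(row)
    return pd.DataFrame(
        rows, columns=["item_id", *AGE_CATEGORIES, "n_known"]
    )


def mode_category(
    weighted_props: pd.Series, rng: np.random.Generator, tol: float = 1e-9
) -> str:
    """The age category with the largest weighted proportion.

    Ties (within ``tol``) are broken by a uniform draw from ``rng`` among
    the tied categories, so results are reproducible under a fixed seed.
    """
    props = weighted_props.reindex(list(AGE_CATEGORIES)).astype(float)
    if props.isna().any() or not (props > 0).any():
        raise ValueError("mode undefined for an all-zero or missing vector")
    top = props.max()
    tied = [c for c in AGE_CATEGORIES if props[c] >= top - tol]
    if len(tied) == 1:
        return tied[0]
    return tied[int(rng.integers(len(tied)))]


@dataclass
class AgePCAModel:
    """Column-centred PCA over the items x 8 weighted-proportion matrix.

    ``loadings`` is the 8 x K orthonormal loading matrix (categories as
    rows), ``explained_variance_fraction`` the per-component fractions of
    total variance, ``column_means``/``column_scales`` the centring (and
    optional scaling) applied before projection, and ``orientation``
    records any sign flip applied per component.
    """

    loadings: pd.DataFrame
    explained_variance_fraction: np.ndarray
    column_means: pd.Series
    column_scales: pd.Series
    orientation: tuple[int, ...]
    n_items: int

    def transform(self, props: pd.DataFrame) -> pd.DataFrame:
        x = (props[list(AGE_CATEGORIES)] - self.column_means) / (
            self.column_scales
        )
        scores = x.to_numpy() @ self.loadings.to_numpy()
        return pd.DataFrame(
            scores,
            index=props.index,
            columns=[f"pc{k + 1}" for k in range(self.loadings.shape[1])],
        )


def fit_age_pca(
    props: pd.DataFrame,
    n_components: int = 3,
    scale: bool = False,
    orientation=DEFAULT_ORIENTATION,
) -> tuple[AgePCAModel, pd.DataFrame]:
    """PCA of the weighted-proportion matrix; returns (model, item scores).

    Input rows must be complete (no missing proportions).  Columns are
    centred; set ``scale`` for a correlation-style PCA.  Explained
    fractions are of the total variance over all 8 categories.  Each
    retained component's sign is pinned by the orientation rules; if the
    matrix supports fewer than ``n_components`` components, the available
    ones are returned with a warning.
    """
    x = props[list(AGE_CATEGORIES)].astype(float)
    if x.isna().any().any():
        raise ValueError("missing proportions; drop incomplete items first")
    if len(x) < len(AGE_CATEGORIES):
        raise ValueError("need at least 8 items for the age PCA")
    means = x.mean()
    scales = x.std(ddof=1) if scale else pd.Series(1.0, index=x.columns)
    if scale and (scales == 0).any():
        raise ValueError("zero-variance category; cannot scale")
    xc = (x - means) / scales

    full = PCA(n_components=len(AGE_CATEGORIES))
    full.fit(xc.to_numpy())
    rank = int(np.sum(full.explained_variance_ > 1e-12 * max(
        full.explained_variance_[0], 1e-30
    )))
    k = min(n_components, rank)
    if k < n_components:
        warnings.warn(
            f"proportion matrix supports only {k} components "
            f"(requested {n_components})"
        )
    loadings = full.components_[:k].T.copy()  # 8 x k
    flips = []
    for j in range(k):
        sign = 1
        if j < len(orientation):
            cat, wanted = orientation[j]
            ci = list(AGE_CATEGORIES).index(cat)
            if loadings[ci, j] * wanted < 0:
                sign = -1
        flips.append(sign)
        loadings[:, j] *= sign
    model = AgePCAModel(
        loadings=pd.DataFrame(
            loadings,
            index=list(AGE_CATEGORIES),
            columns=[f"pc{j + 1}" for j in range(k)],
        ),
        explained_variance_fraction=full.explained_variance_ratio_.copy(),
        column_means=means,
        column_scales=scales,
        orientation=tuple(flips),
        n_items=len(x),
    )
    scores = model.transform(props)
    return model, scores


def summarize_study_ages(
    ages: pd.DataFrame,
    rng: np.random.Generator,
    n_components: int = 3,
    scale: bool = False,
) -> tuple[pd.DataFrame, AgePCAModel]:
    """Full age norms table: proportions, mode and PC scores per item.

    Items without any known response keep missing proportions and are
    excluded from the PCA (their scores stay missing).
    """
    table = summarize_ages(ages)
    modes = []
    for _, row in table.iterrows():
        props = row[list(AGE_CATEGORIES)].astype(float)
        modes.append(mode_category(props, rng) if row["n_known"] else np.nan)
    table["mode"] = modes
    complete = table[table["n_known"] > 0].set_index("item_id")
    model, scores = fit_age_pca(
        complete, n_components=n_components, scale=scale
    )
    for col in scores.columns:
        table[col] = table["item_id"].map(scores[col])
    return table, model
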