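"""Per-item normative estimates for the Likert dimensions.

For every (item, dimension) pair: mean and sample SD of the known
responses treated as integers -3..3, response counts and proportions per
scale point, Shannon entropy of the response distribution, and — via the
cumulative-link mixed model in :mod:`socionorm.clmm` — a latent mean that
corrects for participant response bias.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .clmm import CLMMFit, fit_clmm
from .core_io import SCALE_POINTS, SOCIODEM_QUESTIONS

_COUNT_COLS = [f"count_{k}" for k in SCALE_POINTS]
_PROP_COLS = [f"prop_{k}" for k in SCALE_POINTS]


def shannon_entropy(proportions, tol: float = 1e-8) -> float:
    """Shannon entropy in bits, H = -sum p_i log2 p_i with 0 log 0 = 0.

    ``proportions`` must be non-negative and sum to 1 within ``tol``.
    """
    p = np.asarray(proportions, dtype=float)
    if np.any(p < 0):
        raise ValueError("proportions must be non-negative")
    total = p.sum()
    if abs(total - 1.0) > tol:
        raise ValueError(f"proportions sum to {total}, not 1")
    nz = p[p > 0]
    return float(-(nz * np.log2(nz)).sum())


def summarize_item(values: pd.Series | np.ndarray) -> dict:
    """Descriptive summary of one (item, dimension)'s responses.

    ``values`` are the raw responses including UNKNOWN entries (NA).
    Mean/SD (sample SD, n-1 denominator) and entropy are computed over
    known responses only; with no known responses they are missing and
    counts are all zero.
    """
    s = pd.Series(values).astype("Int64")
    n = int(len(s))
    known = s.dropna().astype(int)
    n_known = int(len(known))
    out = {
        "n": n,
        "n_known": n_known,
        "prop_known": n_known / n if n else np.nan,
    }
    counts = known.value_counts().reindex(SCALE_POINTS, fill_value=0)
    for k, c in zip(SCALE_POINTS, counts):
        out[f"count_{k}"] = int(c)
    if n_known == 0:
        out.update(
            mean=np.nan, sd=np.nan, entropy=np.nan,
            **{f"prop_{k}": np.nan for k in SCALE_POINTS},
        )
        return out
    props = counts / n_known
    out.update({f"prop_{k}": float(v) for k, v in props.items()})
    out["mean"] = float(known.mean())
    out["sd"] = float(known.std(ddof=1)) if n_known > 1 else 0.0
    out["entropy"] = shannon_entropy(props.to_numpy())
    return out


def summarize_likert(ratings: pd.DataFrame) -> pd.DataFrame:
    """Descriptive norms table: one row per (item, dimension)."""
    rows = []
    for (item, dim), grp in ratings.groupby(
        ["item_id", "dimension"], sort=True
    ):
        row = {"item_id": item, "dimension": dim}
        row.update(summarize_item(grp["value"]))
        rows.append(row)
    cols = (
        ["item_id", "dimension", "mean", "sd", "n", "n_known", "prop_known"]
        + _COUNT_COLS
        + _PROP_COLS
        + ["entropy"]
    )
    return pd.DataFrame(rows, columns=cols)


def fit_latent_means(
    ratings: pd.DataFrame, dimension: str, **fit_kwargs
) -> CLMMFit:
    """Latent means for one dimension via the cumulative-link mixed model.

    Known responses of the given dimension are modelled as an ordinal
    outcome with crossed random intercepts for item and participant; the
    conditional modes of the item intercepts (link scale, centred) are the
    latent means.
    """
    sub = ratings[ratings["dimension"] == dimension]
    known = sub[sub["value"].notna()]
    if known.empty:
        raise ValueError(f"no known responses for dimension {dimension!r}")
    return fit_clmm(
        known["value"].astype(int).to_numpy(),
        known["item_id"].to_numpy(),
        known["participant_id"].to_numpy(),
        **fit_kwargs,
    )


def summarize_study(
    ratings: pd.DataFrame, latent: bool = True, **fit_kwargs
) -> tuple[pd.DataFrame, dict[str, CLMMFit]]:
    """Full Likert norms table, optionally with latent means per dimension.

    Returns the table and the per-dimension model fits (empty when
    ``latent`` is false).
    """
    table = summarize_likert(ratings)
    fits: dict[str, CLMMFit] = {}
    table["latent_mean"] = np.nan
    if latent:
        for dim in sorted(ratings["dimension"].unique()):
            fit = fit_latent_means(ratings, dim, **fit_kwargs)
            fits[dim] = fit
            mask = table["dimension"] == dim
            table.loc[mask, "latent_mean"] = (
                table.loc[mask, "item_id"].map(fit.item_effects).to_numpy()
            )
    return table, fits


def demographic_profiles(
    ratings: pd.DataFrame,
    participants: pd.DataFrame,
    questions: tuple[str, ...] = SOCIODEM_QUESTIONS,
) -> pd.DataFrame:
    """Per-item mean ratings within demographic self-rating groups.

    For each socio-demographic question, participants split into three
    groups by the side of the scale they used for themselves: negative
    side, neutral (0) and positive side.  Returns a tidy frame with one
    row per (question, group, item, dimension), carrying the group mean
    and its n; empty groups simply contribute no rows.
    """
    known = ratings[ratings["value"].notna()].copy()
    known["value"] = known["value"].astype(int)
    merged = known.merge(
        participants[["participant_id", *questions]], on="participant_id"
    )
    frames = []
    for q in questions:
        vals = pd.to_numeric(merged[q], errors="coerce")
        group = pd.Series(
            np.select(
                [vals < 0, vals == 0, vals > 0],
                ["negative", "neutral", "positive"],
                default="missing",
            ),
            index=merged.index,
        )
        sub = merged[group != "missing"]
        agg = (
            sub.groupby(
                [group[sub.index].rename("group"), "item_id", "dimension"],
                sort=True,
            )["value"]
            .agg(["mean", "size"])
            .rename(columns={"size": "n"})
            .reset_index()
        )
        agg.insert(0, "question", q)
        frames.append(agg)
    if not frames:
        return pd.DataFrame(
            columns=["question", "group", "item_id", "dimension", "mean", "n"]
        )
    return pd.concat(frames, ignore_index=True)
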