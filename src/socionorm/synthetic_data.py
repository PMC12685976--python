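"""Synthetic norming studies with known ground truth.

Generates complete studies — Likert ratings, multi-select age responses,
per-dimension completion timings, participant metadata — from a
cumulative-logit response model so every downstream stage (QC filtering,
aggregation, latent-mean modelling) has a recoverable target.

Response model for attentive (NORMAL) participants on item i, dimension d:

    P(response <= k) = logistic(c_k - a * theta_d(i) - b_p)

with ordered cutpoints c_k, item latent location theta_d(i) in [-3, 3],
participant threshold shift b_p ~ N(0, sigma_p^2) and discrimination a
(unit by default) — the same family the latent-mean estimator fits, so
parameter recovery is a fair test.  Valence latent values are drawn from
a right-shifted distribution to emulate the positivity skew typical of
valence ratings.

Bad actors are planted with labels recorded in the ground truth, each
designed to violate exactly the quality filter its label targets:
STRAIGHTLINERs repeat one response on every Likert dimension (but answer
the calibrators attentively and mark pseudowords unknown); SPEEDERs log
two dimensions far below the population mean duration;
CALIBRATOR_VIOLATORs flip the expected sign on exactly two calibrators;
PSEUDOWORD_RATERs rate every pseudoword instead of marking it unknown.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit

from .core_io import (
    AGE_BANDS,
    Calibrator,
    StudyDesign,
    write_norms,
    write_responses,
)

NORMAL = "NORMAL"
STRAIGHTLINER = "STRAIGHTLINER"
SPEEDER = "SPEEDER"
CALIBRATOR_VIOLATOR = "CALIBRATOR_VIOLATOR"
PSEUDOWORD_RATER = "PSEUDOWORD_RATER"

BEHAVIORS = (
    NORMAL,
    STRAIGHTLINER,
    SPEEDER,
    CALIBRATOR_VIOLATOR,
    PSEUDOWORD_RATER,
)

LIKERT_DIMENSIONS = ("gender", "location", "political", "valence")

_SCALE_LABELS = {
    "gender": (
        "very masculine", "masculine", "slightly masculine", "neutral",
        "slightly feminine", "feminine", "very feminine",
    ),
    "location": (
        "very rural", "rural", "slightly rural", "neutral",
        "slightly urban", "urban", "very urban",
    ),
    "political": (
        "very liberal", "liberal", "slightly liberal", "neutral",
        "slightly conservative", "conservative", "very conservative",
    ),
    "valence": (
        "very negative", "negative", "slightly negative", "neutral",
        "slightly positive", "positive", "very positive",
    ),
}

#: Expected calibrator directions: necklace->feminine (+), subway->urban
#: (+), tradition->conservative (+), bully->negative (-).
_CALIBRATOR_SIGNS = {
    "gender": 1,
    "location": 1,
    "political": 1,
    "valence": -1,
}

#: Age-profile archetypes items are drawn around (Dirichlet concentration).
AGE_ARCHETYPES = {
    "young": np.array([0.25, 0.35, 0.25, 0.06, 0.04, 0.03, 0.02]),
    "middle": np.array([0.02, 0.05, 0.25, 0.40, 0.20, 0.05, 0.03]),
    "old": np.array([0.02, 0.02, 0.04, 0.07, 0.20, 0.35, 0.30]),
    "uniform": np.full(7, 1.0 / 7.0),
}


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the generator.

    Defaults emulate one list of a word-norming study: 100 real items, a
    calibrator per Likert dimension, four pseudoword controls, unit
    discrimination, participant shift SD 0.5, symmetric unit-spaced
    cutpoints, a 0.75 positivity shift on valence, ~98% word knowledge and
    log-normal per-dimension timings around exp(6) ~ 400 s.
    """

    n_items: int = 100
    n_participants: int = 60
    n_lists: int = 1
    sigma_participant: float = 0.5
    discrimination: float = 1.0
    cutpoints: tuple[float, ...] = (-2.5, -1.5, -0.5, 0.5, 1.5, 2.5)
    known_prob: float = 0.98
    valence_shift: float = 0.75
    n_pseudowords: int = 4
    n_straightliners: int = 0
    n_speeders: int = 0
    n_calibrator_violators: int = 0
    n_pseudoword_raters: int = 0
    timing_log_mean: float = 6.0
    timing_log_sd: float = 0.35
    speeder_sd_offset: float = 6.0
    speeder_n_dims: int = 2
    no_age_beta: tuple[float, float] = (1.0, 6.0)
    age_hit_rate: float = 0.9
    min_participant_age: int = 18
    max_participant_age: int = 30
    native_language: str = "Czech"
    include_age_dimension: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        c = np.asarray(self.cutpoints, dtype=float)
        if c.size != 6 or np.any(np.diff(c) <= 0):
            raise ValueError("cutpoints must be 6 strictly increasing reals")
        n_bad = (
            self.n_straightliners
            + self.n_speeders
            + self.n_calibrator_violators
            + self.n_pseudoword_raters
        )
        if n_bad > self.n_participants:
            raise ValueError("bad-actor counts exceed n_participants")
        if not (0.0 < self.known_prob <= 1.0):
            raise ValueError("known_prob must be in (0, 1]")


@dataclass
class SimulatedStudy:
    """A generated study plus its ground truth.

    ``items_truth`` holds each item's latent locations (theta per Likert
    dimension), age profile, no-age propensity and role flags;
    ``participants_truth`` the planted behaviour label and threshold shift
    of every participant.
    """

    design: StudyDesign
    ratings: pd.DataFrame
    ages: pd.DataFrame
    timings: pd.DataFrame
    participants: pd.DataFrame
    items_truth: pd.DataFrame
    participants_truth: pd.DataFrame
    config: SimulationConfig = field(repr=False, default=None)

    def write(self, out_dir: str | Path) -> None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        self.design.save(out_dir / "design.yaml")
        write_responses(self.ratings, self.ages, out_dir / "responses.csv")
        write_norms(
            {
                "participants": self.participants,
                "timings": self.timings,
                "items_truth": self.items_truth,
                "participants_truth": self.participants_truth,
            },
            out_dir,
        )


def likert_probs(theta, cutpoints, discrimination=1.0, shift=0.0):
    """Closed-form response probabilities of the cumulative-logit model.

    Returns the length-7 probability vector over scale points -3..3 for a
    single (item, participant) cell.
    """
    c = np.asarray(cutpoints, dtype=float)
    cum = expit(c - discrimination * theta - shift)
    return np.diff(np.concatenate(([0.0], cum, [1.0])))


def _sample_likert(theta, cutpoints, discrimination, shifts, rng):
    """Vectorised draw: theta (n,), shifts (n,) -> responses in -3..3."""
    c = np.asarray(cutpoints, dtype=float)
    cum = expit(c[None, :] - discrimination * theta[:, None] - shifts[:, None])
    u = rng.uniform(size=(theta.size, 1))
    return (u > cum).sum(axis=1) - 3


def sample_age_response(
    age_profile, no_age_propensity, rng, hit_rate: float = 0.9
):
    """Draw one multi-select age response from an item's age profile.

    With probability ``no_age_propensity`` the selection is empty (the
    explicit no-age outcome).  Otherwise each band is selected
    independently with probability proportional to the profile, rescaled
    so the strongest band is selected with probability ``hit_rate``; if
    the independent draws select nothing, one band is drawn from the
    profile so that a taken age branch always yields at least one band.
    """
    profile = np.asarray(age_profile, dtype=float)
    if rng.uniform() < no_age_propensity:
        return ()
    probs = profile / profile.max() * hit_rate
    picks = rng.uniform(size=profile.size) < probs
    if not picks.any():
        picks[rng.choice(profile.size, p=profile / profile.sum())] = True
    return tuple(np.asarray(AGE_BANDS)[picks])


def build_design(config: SimulationConfig) -> tuple[StudyDesign, pd.DataFrame]:
    """Create the study design and the item ground-truth table."""
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 101]))
    width = max(4, len(str(config.n_items)))
    item_ids = [f"w{idx:0{width}d}" for idx in range(1, config.n_items + 1)]
    lists = {
        f"list{li + 1}": tuple(item_ids[li::config.n_lists])
        for li in range(config.n_lists)
    }
    pseudo_ids = tuple(f"pseudo{j + 1}" for j in range(config.n_pseudowords))
    controls = {k: pseudo_ids for k in lists}
    calibrators = {
        d: Calibrator(d, f"calib_{d}", _CALIBRATOR_SIGNS[d])
        for d in LIKERT_DIMENSIONS
    }
    design = StudyDesign(
        likert_dimensions=LIKERT_DIMENSIONS,
        scale_labels=dict(_SCALE_LABELS),
        lists=lists,
        calibrators=calibrators,
        controls=controls,
        age_dimension="age" if config.include_age_dimension else None,
    )

    all_ids = (
        item_ids
        + [c.item_id for c in calibrators.values()]
        + list(pseudo_ids)
    )
    n_all = len(all_ids)
    truth = pd.DataFrame({"item_id": all_ids})
    truth["is_pseudoword"] = truth["item_id"].str.startswith("pseudo")
    truth["is_calibrator"] = truth["item_id"].str.startswith("calib_")
    for d in LIKERT_DIMENSIONS:
        theta = rng.uniform(-3.0, 3.0, size=n_all)
        if d == "valence":
            theta = np.clip(theta + config.valence_shift, -3.0, 3.0)
        truth[f"theta_{d}"] = theta
    # calibrators sit firmly on their expected side
    for d, cal in calibrators.items():
        truth.loc[
            truth["item_id"] == cal.item_id, f"theta_{d}"
        ] = 2.5 * cal.expected_sign
    archetypes = list(AGE_ARCHETYPES)
    kinds = rng.choice(len(archetypes), size=n_all)
    profiles = np.vstack(
        [
            rng.dirichlet(AGE_ARCHETYPES[archetypes[k]] * 40.0 + 0.5)
            for k in kinds
        ]
    )
    truth["age_archetype"] = [archetypes[k] for k in kinds]
    for j, band in enumerate(AGE_BANDS):
        truth[f"age_profile_{band}"] = profiles[:, j]
    truth["no_age_propensity"] = rng.beta(*config.no_age_beta, size=n_all)
    truth["known_prob"] = np.where(
        truth["is_pseudoword"], 0.0, config.known_prob
    )
    return design, truth


def _assign_behaviors(config: SimulationConfig) -> list[str]:
    labels = (
        [STRAIGHTLINER] * config.n_straightliners
        + [SPEEDER] * config.n_speeders
        + [CALIBRATOR_VIOLATOR] * config.n_calibrator_violators
        + [PSEUDOWORD_RATER] * config.n_pseudoword_raters
    )
    labels += [NORMAL] * (config.n_participants - len(labels))
    return labels


def _calibrator_margin_response(expected_sign: int, rng) -> int:
    """Attentive calibrator answer: expected sign, magnitude 1..3."""
    return int(expected_sign * rng.choice([1, 2, 3], p=[0.2, 0.4, 0.4]))


def simulate_study(config: SimulationConfig) -> SimulatedStudy:
    """Generate a full study; byte-identical outputs for a fixed seed."""
    design, truth = build_design(config)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 202]))
    behaviors = _assign_behaviors(config)
    list_ids = sorted(design.lists)
    n = config.n_participants
    width = max(4, len(str(n)))
    pids = [f"p{idx:0{width}d}" for idx in range(1, n + 1)]
    shifts = rng.normal(0.0, config.sigma_participant, size=n)

    participants = pd.DataFrame(
        {
            "participant_id": pids,
            "native_language": config.native_language,
            "age": rng.integers(
                config.min_participant_age,
                config.max_participant_age + 1,
                size=n,
            ),
            "gender": rng.choice(
                ["female", "male", "nonbinary"], p=[0.72, 0.25, 0.03], size=n
            ),
            "list_id": [list_ids[i % len(list_ids)] for i in range(n)],
            "source": "synthetic",
        }
    )
    for col in (
        "sociodem_gender",
        "sociodem_character",
        "sociodem_location",
        "sociodem_political",
    ):
        participants[col] = rng.integers(-3, 4, size=n)

    truth_ix = truth.set_index("item_id")
    cal_items = {d: c.item_id for d, c in design.calibrators.items()}
    age_cols = [f"age_profile_{b}" for b in AGE_BANDS]

    rating_rows: list[tuple] = []
    age_rows: list[tuple] = []
    timing_rows: list[tuple] = []
    speeder_counter = 0
    timing_dims = (
        list(design.all_dimensions)
        if design.experiment_kind == "words"
        else ["whole_experiment"]
    )

    for p_idx, pid in enumerate(pids):
        behavior = behaviors[p_idx]
        shift = shifts[p_idx]
        list_id = participants.loc[p_idx, "list_id"]
        real = list(design.lists[list_id])
        pseudos = list(design.controls.get(list_id, ()))
        items = real + pseudos  # calibrators handled per-dimension below
        known = rng.uniform(size=len(items)) < truth_ix.loc[
            items, "known_prob"
        ].to_numpy()
        straight_value = (
            int(rng.integers(-3, 4)) if behavior == STRAIGHTLINER else None
        )
        violated_dims = (
            set(rng.choice(list(cal_items), size=2, replace=False))
            if behavior == CALIBRATOR_VIOLATOR
            else set()
        )

        for dim in design.likert_dimensions:
            order = 0
            # calibrator is always the first item of the dimension block
            cal_id = cal_items.get(dim)
            if cal_id is not None:
                cal = design.calibrators[dim]
                if dim in violated_dims:
                    val = int(-cal.expected_sign * 2)
                else:
                    val = _calibrator_margin_response(cal.expected_sign, rng)
                rating_rows.append((pid, cal_id, dim, val, order))
                order += 1
            theta = truth_ix.loc[items, f"theta_{dim}"].to_numpy()
            drawn = _sample_likert(
                theta,
                config.cutpoints,
                config.discrimination,
                np.full(len(items), shift),
                rng,
            )
            for j, item in enumerate(items):
                is_pseudo = j >= len(real)
                if is_pseudo:
                    if behavior == PSEUDOWORD_RATER:
                        val = int(drawn[j])
                    else:
                        val = None  # attentive: pseudoword marked unknown
                elif not known[j]:
                    val = None
                elif behavior == STRAIGHTLINER:
                    val = straight_value
                else:
                    val = int(drawn[j])
                rating_rows.append((pid, item, dim, val, order))
                order += 1

        if design.age_dimension is not None:
            for j, item in enumerate(real):
                if not known[j]:
                    age_rows.append((pid, item, "", True))
                    continue
                row = truth_ix.loc[item]
                bands = sample_age_response(
                    row[age_cols].to_numpy(dtype=float),
                    float(row["no_age_propensity"]),
                    rng,
                    hit_rate=config.age_hit_rate,
                )
                age_rows.append((pid, item, ";".join(bands), False))

        # rotate each speeder's fast dimensions so no single dimension's
        # duration statistics are dominated by the planted outliers
        if behavior == SPEEDER:
            fast_dims = {
                timing_dims[(speeder_counter + j) % len(timing_dims)]
                for j in range(config.speeder_n_dims)
            }
            speeder_counter += 1
        else:
            fast_dims = set()
        for dim in timing_dims:
            log_t = rng.normal(config.timing_log_mean, config.timing_log_sd)
            if dim in fast_dims:
                log_t = (
                    config.timing_log_mean
                    - config.speeder_sd_offset * config.timing_log_sd
                    + rng.normal(0.0, 0.05)
                )
            timing_rows.append((pid, dim, float(np.exp(log_t))))

    ratings = pd.DataFrame(
        rating_rows,
        columns=[
            "participant_id",
            "item_id",
            "dimension",
            "value",
            "presentation_order",
        ],
    )
    ratings["value"] = ratings["value"].astype("Int64")
    ages = pd.DataFrame(
        age_rows, columns=["participant_id", "item_id", "bands", "unknown"]
    )
    timings = pd.DataFrame(
        timing_rows, columns=["participant_id", "dimension", "duration"]
    )
    participants_truth = pd.DataFrame(
        {
            "participant_id": pids,
            "behavior": behaviors,
            "threshold_shift": shifts,
            "discrimination": config.discrimination,
        }
    )
    return SimulatedStudy(
        design=design,
        ratings=ratings,
        ages=ages,
        timings=timings,
        participants=participants,
        items_truth=truth,
        participants_truth=participants_truth,
        config=config,
    )


def with_bad_actors(config: SimulationConfig, n_each: int) -> SimulationConfig:
    """Convenience: the same study conditions with n_each of every bad type."""
    return replace(
        config,
        n_straightliners=n_each,
        n_speeders=n_each,
        n_calibrator_violators=n_each,
        n_pseudoword_raters=n_each,
    )
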