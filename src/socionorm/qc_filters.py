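"""Data-quality filtering cascade for rating studies.

Five rules applied in a fixed order — word knowledge, straightlining,
calibrator check, control (pseudoword) check, timing — with each stage
seeing only data surviving the previous stages.  All proportion
thresholds are strict inequalities ("more than", "over"); boundary values
are retained.  Participant-level exclusions drop every response of a
participant; dimension-level removals drop one (participant, dimension)
block while retaining the rest.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_io import StudyDesign, WHOLE_EXPERIMENT

PARTICIPANT_REASONS = (
    "word_knowledge",
    "straightlining",
    "calibrator",
    "control",
    "timing",
)
DIMENSION_REASONS = ("straightlining_95", "timing")


@dataclass(frozen=True)
class QCConfig:
    """Thresholds of the cleaning cascade.

    ``straightline_dims_for_exclusion`` is the count a participant must
    *exceed*: the word-study default 3 excludes at >=4 straightlined
    dimensions out of 5 ("more than three out of the five"); image
    studies use 2 (">= 3 of 4").  ``timing_population`` controls whether
    the per-dimension log-duration mean/SD are computed over participants
    entering the timing stage (cascade order) or over the full input.
    """

    unknown_word_threshold: float = 0.20
    straightline_participant_threshold: float = 0.80
    straightline_dims_for_exclusion: int = 3
    straightline_dimension_threshold: float = 0.95
    calibrator_violations_for_exclusion: int = 2
    timing_sd_multiplier: float = 2.5
    timing_granularity: str = "per-dimension"  # or "whole-experiment"
    timing_population: str = "cascade"  # or "input"

    def __post_init__(self) -> None:
        for name in (
            "unknown_word_threshold",
            "straightline_participant_threshold",
            "straightline_dimension_threshold",
        ):
            v = getattr(self, name)
            if not (0.0 < v <= 1.0):
                raise ValueError(f"{name} must lie in (0, 1], got {v}")
        if self.timing_sd_multiplier <= 0:
            raise ValueError("timing_sd_multiplier must be positive")


#: Word-study defaults (5 dimensions, per-dimension timing).
WORD_STUDY_QC = QCConfig()

#: Image-study defaults: straightline exclusion at >2 of 4 dimensions and a
#: single whole-experiment timing filter.
IMAGE_STUDY_QC = QCConfig(
    straightline_dims_for_exclusion=2, timing_granularity="whole-experiment"
)


@dataclass
class QCReport:
    """Full provenance of a cascade run.

    ``participant_exclusions``: one row per excluded participant with the
    stage that removed them (a participant appears at most once).
    ``dimension_removals``: per-(participant, dimension) blocks removed
    from otherwise retained participants.  ``stage_counts`` summarises
    both.  ``reconcile`` checks input rows = retained rows + rows removed
    with excluded participants + rows removed with dimension blocks.
    """

    participant_exclusions: pd.DataFrame
    dimension_removals: pd.DataFrame
    stage_counts: dict[str, int] = field(default_factory=dict)
    n_input_rows: int = 0
    n_retained_rows: int = 0
    n_rows_removed_participants: int = 0
    n_rows_removed_dimensions: int = 0

    def reconcile(self) -> bool:
        return (
            self.n_input_rows
            == self.n_retained_rows
            + self.n_rows_removed_participants
            + self.n_rows_removed_dimensions
        )


def _real_item_mask(ratings: pd.DataFrame, design: StudyDesign) -> pd.Series:
    return ~ratings["item_id"].isin(design.control_items)


def filter_word_knowledge(
    ratings: pd.DataFrame, design: StudyDesign, cfg: QCConfig
) -> set[str]:
    """Participants who did not know strictly more than the threshold
    proportion of the real items presented to them.

    An item counts as unknown for a participant if any of its dimension
    responses is UNKNOWN; pseudoword controls never enter the denominator.
    """
    real = ratings[_real_item_mask(ratings, design)]
    if real.empty:
        return set()
    unknown_any = (
        real.assign(unk=real["value"].isna())
        .groupby(["participant_id", "item_id"], sort=False)["unk"]
        .any()
    )
    prop = unknown_any.groupby("participant_id").mean()
    return set(prop.index[prop > cfg.unknown_word_threshold])


def straightline_shares(
    ratings: pd.DataFrame, design: StudyDesign
) -> pd.DataFrame:
    """Modal-response share of non-UNKNOWN responses per participant and
    Likert dimension (the straightlining statistic)."""
    known = ratings[ratings["value"].notna()]
    known = known[known["dimension"].isin(design.likert_dimensions)]
    if known.empty:
        return pd.DataFrame(columns=["participant_id", "dimension", "share"])
    counts = (
        known.groupby(
            ["participant_id", "dimension", "value"], sort=False, observed=True
        )
        .size()
        .rename("n")
        .reset_index()
    )
    g = counts.groupby(["participant_id", "dimension"], sort=False)["n"]
    shares = (g.max() / g.sum()).rename("share").reset_index()
    return shares


def detect_straightlining(
    ratings: pd.DataFrame, design: StudyDesign, cfg: QCConfig
) -> tuple[set[str], list[tuple[str, str]]]:
    """(participants excluded, (participant, dimension) removals).

    A (participant, dimension) straightlines at level t iff the modal
    response's share of non-UNKNOWN responses exceeds t.  Participants
    straightlining (at the participant-level threshold) on strictly more
    than ``straightline_dims_for_exclusion`` dimensions are excluded;
    retained participants lose any dimension straightlined at the
    dimension-level threshold.
    """
    shares = straightline_shares(ratings, design)
    if shares.empty:
        return set(), []
    flagged = shares[
        shares["share"] > cfg.straightline_participant_threshold
    ]
    per_participant = flagged.groupby("participant_id").size()
    excluded = set(
        per_participant.index[
            per_participant > cfg.straightline_dims_for_exclusion
        ]
    )
    removals = [
        (row.participant_id, row.dimension)
        for row in shares.itertuples(index=False)
        if row.share > cfg.straightline_dimension_threshold
        and row.participant_id not in excluded
    ]
    return excluded, removals


def check_calibrators(
    ratings: pd.DataFrame, design: StudyDesign, cfg: QCConfig
) -> tuple[set[str], list[str]]:
    """Participants violating at least the configured number of calibrators.

    A calibrator is violated iff the response sign is opposite to the
    expected sign, at any magnitude; neutral (0) and UNKNOWN responses are
    never violations.  Missing calibrator responses count as
    non-violations and are returned for logging.
    """
    violations: dict[str, int] = {}
    missing: list[str] = []
    participants = ratings["participant_id"].unique()
    for dim, cal in design.calibrators.items():
        rows = ratings[
            (ratings["dimension"] == dim)
            & (ratings["item_id"] == cal.item_id)
        ]
        seen = set(rows["participant_id"])
        missing.extend(
            f"{pid}:{dim}" for pid in participants if pid not in seen
        )
        vals = rows["value"].dropna()
        bad = rows.loc[vals.index, "participant_id"][
            np.sign(vals.astype(int)) == -cal.expected_sign
        ]
        for pid in bad:
            violations[pid] = violations.get(pid, 0) + 1
    flagged = {
        pid
        for pid, k in violations.items()
        if k >= cfg.calibrator_violations_for_exclusion
    }
    return flagged, missing


def check_controls(ratings: pd.DataFrame, design: StudyDesign) -> set[str]:
    """Participants who rated every pseudoword presentation (never marked
    a single one UNKNOWN)."""
    pseudo = ratings[ratings["item_id"].isin(design.control_items)]
    if pseudo.empty:
        return set()
    all_rated = pseudo.groupby("participant_id")["value"].apply(
        lambda s: s.notna().all()
    )
    return set(all_rated.index[all_rated])


def filter_timing(
    timings: pd.DataFrame, cfg: QCConfig
) -> tuple[set[str], list[tuple[str, str]]]:
    """(participants excluded, (participant, dimension) removals).

    Per dimension, a participant is "fast" iff ln(duration) falls strictly
    below mean - multiplier * SD of the ln durations of all participants
    entering this stage.  Fast on >= 2 dimensions excludes the
    participant; a single fast dimension removes only that dimension's
    data.  In whole-experiment mode a single fast flag excludes.  There is
    no upper cut-off.  Degenerate SD = 0 flags nobody.
    """
    if (timings["duration"] <= 0).any():
        raise ValueError("durations must be strictly positive")
    t = timings.copy()
    t["log_duration"] = np.log(t["duration"])
    fast_pairs: list[tuple[str, str]] = []
    for dim, grp in t.groupby("dimension", sort=False):
        mu = grp["log_duration"].mean()
        sd = grp["log_duration"].std(ddof=1)
        if not np.isfinite(sd) or sd == 0:
            continue
        cut = mu - cfg.timing_sd_multiplier * sd
        for pid in grp.loc[grp["log_duration"] < cut, "participant_id"]:
            fast_pairs.append((pid, dim))
    whole = cfg.timing_granularity == "whole-experiment" or (
        set(t["dimension"]) == {WHOLE_EXPERIMENT}
    )
    counts: dict[str, int] = {}
    for pid, _ in fast_pairs:
        counts[pid] = counts.get(pid, 0) + 1
    if whole:
        excluded = {pid for pid, _ in fast_pairs}
        removals: list[tuple[str, str]] = []
    else:
        excluded = {pid for pid, k in counts.items() if k >= 2}
        removals = [
            (pid, dim) for pid, dim in fast_pairs if pid not in excluded
        ]
    return excluded, removals


def run_qc_cascade(
    ratings: pd.DataFrame,
    ages: pd.DataFrame,
    timings: pd.DataFrame,
    design: StudyDesign,
    cfg: QCConfig | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, QCReport]:
    """Run the full cascade; returns (clean ratings, clean ages, report).

    Stage order: word knowledge -> straightlining -> calibrator ->
    control -> timing, each stage seeing survivors of the previous ones.
    Clean outputs drop excluded participants, removed (participant,
    dimension) blocks, and the pseudoword control items (attention checks
    are not normed).  Age responses follow their participant's fate; an
    age-dimension timing removal drops the participant's age responses.
    """
    cfg = cfg or QCConfig()
    n_input = len(ratings) + len(ages)
    exclusions: list[tuple[str, str]] = []
    excluded: set[str] = set()

    def survivors(df: pd.DataFrame) -> pd.DataFrame:
        return df[~df["participant_id"].isin(excluded)]

    stage_counts: dict[str, int] = {}

    wk = filter_word_knowledge(ratings, design, cfg)
    exclusions += [(pid, "word_knowledge") for pid in sorted(wk)]
    excluded |= wk
    stage_counts["word_knowledge"] = len(wk)

    sl_excl, sl_removals = detect_straightlining(
        survivors(ratings), design, cfg
    )
    exclusions += [(pid, "straightlining") for pid in sorted(sl_excl)]
    excluded |= sl_excl
    stage_counts["straightlining"] = len(sl_excl)

    cal, _missing = check_calibrators(survivors(ratings), design, cfg)
    exclusions += [(pid, "calibrator") for pid in sorted(cal)]
    excluded |= cal
    stage_counts["calibrator"] = len(cal)

    ctrl = check_controls(survivors(ratings), design)
    exclusions += [(pid, "control") for pid in sorted(ctrl)]
    excluded |= ctrl
    stage_counts["control"] = len(ctrl)

    timing_pop = (
        survivors(timings) if cfg.timing_population == "cascade" else timings
    )
    tim_excl, tim_removals = filter_timing(timing_pop, cfg)
    tim_excl -= excluded
    tim_removals = [(p, d) for p, d in tim_removals if p not in excluded]
    exclusions += [(pid, "timing") for pid in sorted(tim_excl)]
    excluded |= tim_excl
    stage_counts["timing"] = len(tim_excl)

    dim_removals = [
        (p, d, "straightlining_95")
        for p, d in sl_removals
        if p not in excluded
    ] + [(p, d, "timing") for p, d in tim_removals]

    clean_ratings = survivors(ratings)
    n_removed_participants = (len(ratings) - len(clean_ratings)) + (
        len(ages) - len(survivors(ages))
    )
    clean_ages = survivors(ages)
    removal_pairs = {(p, d) for p, d, _ in dim_removals}
    if removal_pairs:
        pair_index = pd.MultiIndex.from_frame(
            clean_ratings[["participant_id", "dimension"]]
        )
        keep = ~pair_index.isin(removal_pairs)
        n_dim_rows = int((~keep).sum())
        clean_ratings = clean_ratings[keep]
        age_dim = design.age_dimension
        age_removed = {
            p for p, d, _ in dim_removals if age_dim is not None and d == age_dim
        }
        if age_removed:
            drop = clean_ages["participant_id"].isin(age_removed)
            n_dim_rows += int(drop.sum())
            clean_ages = clean_ages[~drop]
    else:
        n_dim_rows = 0

    # control pseudowords are attention checks, not normed items
    n_retained_rows = len(clean_ratings) + len(clean_ages)
    clean_ratings = clean_ratings[
        ~clean_ratings["item_id"].isin(design.control_items)
    ].reset_index(drop=True)
    clean_ages = clean_ages.reset_index(drop=True)

    report = QCReport(
        participant_exclusions=pd.DataFrame(
            exclusions, columns=["participant_id", "reason"]
        ),
        dimension_removals=pd.DataFrame(
            dim_removals, columns=["participant_id", "dimension", "reason"]
        ),
        stage_counts=stage_counts,
        n_input_rows=n_input,
        n_retained_rows=n_retained_rows,
        n_rows_removed_participants=n_removed_participants,
        n_rows_removed_dimensions=n_dim_rows,
    )
    return clean_ratings, clean_ages, report
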