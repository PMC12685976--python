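"""Shared data model and tabular input/output.

The canonical interchange format is UTF-8 CSV with a header row.  Likert
responses are integers in [-3, 3]; the literal string ``"NA"`` marks a
response where the participant reported not knowing the item (a distinct
sentinel — in memory it becomes :data:`pandas.NA` in a nullable-integer
column, never a silently missing row).  Multi-select age responses store
the selected bands joined with ``";"`` (empty string = no band selected,
``"NA"`` = item unknown).  Study designs travel as YAML.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
import yaml

#: On-disk marker for an "I don't know this item" response.
UNKNOWN_TOKEN = "NA"

#: Separator for multi-select age bands in the CSV value column.
BAND_SEP = ";"

#: The seven age bands of the checkbox scale, youngest to oldest.
AGE_BANDS = ("0-6", "7-17", "18-30", "31-50", "51-65", "66-80", "81+")

#: Extra category receiving weight when no band is selected.
NO_AGE = "no_age"

#: All eight age categories entering the weighted proportions and the PCA.
AGE_CATEGORIES = AGE_BANDS + (NO_AGE,)

#: Timing "dimension" label used when only a whole-experiment duration exists.
WHOLE_EXPERIMENT = "whole_experiment"

#: Scale points of every Likert dimension (7 points, 0 midpoint).
SCALE_POINTS = tuple(range(-3, 4))

#: Names of the four socio-demographic self-rating columns on participants.
SOCIODEM_QUESTIONS = (
    "sociodem_gender",
    "sociodem_character",
    "sociodem_location",
    "sociodem_political",
)

RESPONSE_COLUMNS = ("participant_id", "item_id", "dimension", "value")
PARTICIPANT_COLUMNS = ("participant_id", "native_language", "age", "gender")
TIMING_COLUMNS = ("participant_id", "dimension", "duration")


class MalformedFileError(ValueError):
    """A hard structural problem in an input file (missing column, bad row)."""


@dataclass(frozen=True)
class Calibrator:
    """A calibrator item with its expected response direction on one dimension."""

    dimension: str
    item_id: str
    expected_sign: int  # -1 or +1

    def __post_init__(self) -> None:
        if self.expected_sign not in (-1, 1):
            raise ValueError(
                f"calibrator for {self.dimension!r} must have expected_sign "
                f"-1 or +1, got {self.expected_sign}"
            )


@dataclass
class StudyDesign:
    """Structure of a norming study.

    Parameters
    ----------
    likert_dimensions
        Ordered names of the bipolar 7-point dimensions (e.g. gender,
        location, political, valence).  Pole orientation is fixed by the
        ordered ``scale_labels``: the first label maps to -3, the last to +3.
    scale_labels
        Per-dimension ordered tuple of exactly 7 response labels.
    age_dimension
        Name of the multi-select age dimension, or ``None`` (image studies).
    lists
        Partition of real item ids into presentation lists.
    calibrators
        Per-Likert-dimension calibrator item and expected sign.
    controls
        Per-list pseudoword item ids (attention checks), disjoint from the
        real items.
    """

    likert_dimensions: tuple[str, ...]
    scale_labels: dict[str, tuple[str, ...]]
    lists: dict[str, tuple[str, ...]]
    calibrators: dict[str, Calibrator] = field(default_factory=dict)
    controls: dict[str, tuple[str, ...]] = field(default_factory=dict)
    age_dimension: str | None = "age"
    age_bands: tuple[str, ...] = AGE_BANDS
    experiment_kind: str = "words"

    def __post_init__(self) -> None:
        self.validate()

    # -- derived views ---------------------------------------------------
    @property
    def all_dimensions(self) -> tuple[str, ...]:
        if self.age_dimension is None:
            return self.likert_dimensions
        return self.likert_dimensions + (self.age_dimension,)

    @property
    def real_items(self) -> frozenset[str]:
        return frozenset(i for items in self.lists.values() for i in items)

    @property
    def control_items(self) -> frozenset[str]:
        return frozenset(i for items in self.controls.values() for i in items)

    @property
    def calibrator_items(self) -> frozenset[str]:
        return frozenset(c.item_id for c in self.calibrators.values())

    def validate(self) -> None:
        for dim in self.likert_dimensions:
            labels = self.scale_labels.get(dim)
            if labels is None or len(labels) != len(SCALE_POINTS):
                raise ValueError(
                    f"Likert dimension {dim!r} needs exactly "
                    f"{len(SCALE_POINTS)} ordered scale labels"
                )
        for dim, cal in self.calibrators.items():
            if dim not in self.likert_dimensions:
                raise ValueError(
                    f"calibrator declared for unknown dimension {dim!r}"
                )
            if cal.dimension != dim:
                raise ValueError(
                    f"calibrator keyed {dim!r} declares dimension "
                    f"{cal.dimension!r}"
                )
        overlap = self.real_items & self.control_items
        if overlap:
            raise ValueError(
                f"control pseudowords overlap real items: {sorted(overlap)}"
            )

    def label_to_value(self, dimension: str, label: str) -> int:
        """Map a verbal scale label (e.g. 'very feminine') to its integer."""
        labels = self.scale_labels[dimension]
        try:
            return SCALE_POINTS[labels.index(label)]
        except ValueError:
            raise KeyError(
                f"{label!r} is not a scale label of dimension {dimension!r}"
            ) from None

    # -- (de)serialisation ------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "experiment_kind": self.experiment_kind,
            "likert_dimensions": list(self.likert_dimensions),
            "age_dimension": self.age_dimension,
            "age_bands": list(self.age_bands),
            "scale_labels": {d: list(v) for d, v in self.scale_labels.items()},
            "lists": {k: list(v) for k, v in self.lists.items()},
            "calibrators": {
                d: {"item_id": c.item_id, "expected_sign": c.expected_sign}
                for d, c in self.calibrators.items()
            },
            "controls": {k: list(v) for k, v in self.controls.items()},
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "StudyDesign":
        return cls(
            likert_dimensions=tuple(d["likert_dimensions"]),
            scale_labels={k: tuple(v) for k, v in d["scale_labels"].items()},
            lists={k: tuple(v) for k, v in d["lists"].items()},
            calibrators={
                dim: Calibrator(dim, c["item_id"], int(c["expected_sign"]))
                for dim, c in d.get("calibrators", {}).items()
            },
            controls={k: tuple(v) for k, v in d.get("controls", {}).items()},
            age_dimension=d.get("age_dimension"),
            age_bands=tuple(d.get("age_bands", AGE_BANDS)),
            experiment_kind=d.get("experiment_kind", "words"),
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(
            yaml.safe_dump(self.to_dict(), sort_keys=False), encoding="utf-8"
        )

    @classmethod
    def load(cls, path: str | Path) -> "StudyDesign":
        return cls.from_dict(
            yaml.safe_load(Path(path).read_text(encoding="utf-8"))
        )


@dataclass
class LoadedResponses:
    """Parsed response file: Likert ratings, age selections, malformed rows.

    ``ratings.value`` is a nullable Int64 column where :data:`pandas.NA`
    is the UNKNOWN sentinel.  ``ages.bands`` holds ``";"``-joined band
    labels ('' = explicit no-band selection) and ``ages.unknown`` the
    unknown flag.  ``malformed`` has one row per rejected input line with
    its 1-based line number and reason; rows_in == rows_parsed +
    len(malformed) always holds.
    """

    ratings: pd.DataFrame
    ages: pd.DataFrame
    malformed: pd.DataFrame


def _require_columns(df: pd.DataFrame, required: Iterable[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise MalformedFileError(
            f"{path}: missing required column(s): {', '.join(missing)}"
        )


def load_responses(path: str | Path, design: StudyDesign) -> LoadedResponses:
    """Read the canonical responses CSV.

    Likert rows may carry numeric values ("-3".."3"), verbal scale labels
    from the design, or "NA" (unknown).  Age rows carry ";"-joined band
    labels, "" (no band) or "NA".  Rows with an unrecognised dimension or
    an unparseable value are collected into the malformed report; a value
    that parses to an out-of-range integer is a hard error (it signals a
    scale misconfiguration rather than a stray cell).
    """
    path = Path(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if df.empty and df.columns.size == 0:
        warnings.warn(f"{path}: empty responses file")
        return LoadedResponses(
            empty_ratings(), empty_ages(), _empty_malformed()
        )
    _require_columns(df, RESPONSE_COLUMNS, path)
    has_order = "presentation_order" in df.columns

    likert_dims = set(design.likert_dimensions)
    band_set = set(design.age_bands)
    ratings_rows: list[tuple] = []
    age_rows: list[tuple] = []
    malformed: list[tuple[int, str]] = []

    for pos, row in enumerate(df.itertuples(index=False)):
        line = pos + 2  # 1-based, after the header
        dim = row.dimension
        raw = row.value
        order = int(row.presentation_order) if has_order else pos
        if dim in likert_dims:
            if raw == UNKNOWN_TOKEN:
                val: object = pd.NA
            else:
                try:
                    val = int(raw)
                except ValueError:
                    try:
                        val = design.label_to_value(dim, raw)
                    except KeyError:
                        malformed.append(
                            (line, f"unparseable Likert value {raw!r}")
                        )
                        continue
                if val is not pd.NA and not (-3 <= val <= 3):
                    raise MalformedFileError(
                        f"{path}:{line}: Likert value {raw!r} out of "
                        f"range [-3, 3] for dimension {dim!r}"
                    )
            ratings_rows.append(
                (row.participant_id, row.item_id, dim, val, order)
            )
        elif design.age_dimension is not None and dim == design.age_dimension:
            if raw == UNKNOWN_TOKEN:
                age_rows.append((row.participant_id, row.item_id, "", True))
                continue
            bands = [b for b in raw.split(BAND_SEP) if b]
            bad = [b for b in bands if b not in band_set]
            if bad:
                malformed.append((line, f"unknown age band(s) {bad!r}"))
                continue
            age_rows.append(
                (row.participant_id, row.item_id, BAND_SEP.join(bands), False)
            )
        else:
            malformed.append((line, f"unknown dimension {dim!r}"))

    ratings = pd.DataFrame(
        ratings_rows,
        columns=[
            "participant_id",
            "item_id",
            "dimension",
            "value",
            "presentation_order",
        ],
    )
    if not ratings.empty:
        ratings["value"] = ratings["value"].astype("Int64")
    else:
        ratings = empty_ratings()
    ages = (
        pd.DataFrame(
            age_rows, columns=["participant_id", "item_id", "bands", "unknown"]
        )
        if age_rows
        else empty_ages()
    )
    mal = (
        pd.DataFrame(malformed, columns=["line", "reason"])
        if malformed
        else _empty_malformed()
    )
    if df.empty:
        warnings.warn(f"{path}: responses file has a header but no rows")
    return LoadedResponses(ratings, ages, mal)


def empty_ratings() -> pd.DataFrame:
    df = pd.DataFrame(
        {
            "participant_id": pd.Series(dtype=str),
            "item_id": pd.Series(dtype=str),
            "dimension": pd.Series(dtype=str),
            "value": pd.Series(dtype="Int64"),
            "presentation_order": pd.Series(dtype=int),
        }
    )
    return df


def empty_ages() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "participant_id": pd.Series(dtype=str),
            "item_id": pd.Series(dtype=str),
            "bands": pd.Series(dtype=str),
            "unknown": pd.Series(dtype=bool),
        }
    )


def _empty_malformed() -> pd.DataFrame:
    return pd.DataFrame(
        {"line": pd.Series(dtype=int), "reason": pd.Series(dtype=str)}
    )


def split_bands(bands: str) -> tuple[str, ...]:
    """Decode a ';'-joined band cell into a tuple of band labels."""
    return tuple(b for b in bands.split(BAND_SEP) if b)


def load_participants(path: str | Path) -> pd.DataFrame:
    """Read participants.csv; one validated record per row.

    Hard errors: duplicate participant ids, non-integer or non-positive
    ages, socio-demographic self-ratings outside [-3, 3].
    """
    path = Path(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    _require_columns(df, PARTICIPANT_COLUMNS, path)
    dup = df["participant_id"][df["participant_id"].duplicated()]
    if not dup.empty:
        raise MalformedFileError(
            f"{path}: duplicate participant id(s): {sorted(set(dup))}"
        )
    try:
        ages = df["age"].astype(int)
    except ValueError as exc:
        raise MalformedFileError(f"{path}: non-integer age: {exc}") from None
    if (ages <= 0).any():
        bad = df.loc[ages <= 0, "participant_id"].tolist()
        raise MalformedFileError(f"{path}: non-positive age for {bad}")
    df = df.copy()
    df["age"] = ages
    for col in SOCIODEM_QUESTIONS:
        if col in df.columns:
            vals = pd.to_numeric(df[col], errors="coerce")
            out = vals.notna() & ((vals < -3) | (vals > 3))
            if out.any():
                bad = df.loc[out, "participant_id"].tolist()
                raise MalformedFileError(
                    f"{path}: {col} outside [-3, 3] for {bad}"
                )
            df[col] = vals.astype("Int64")
    return df


def load_timings(path: str | Path) -> pd.DataFrame:
    """Read timings.csv (participant_id, dimension, duration seconds)."""
    path = Path(path)
    df = pd.read_csv(path, dtype={"participant_id": str, "dimension": str})
    _require_columns(df, TIMING_COLUMNS, path)
    df["duration"] = df["duration"].astype(float)
    if (df["duration"] <= 0).any():
        raise MalformedFileError(f"{path}: durations must be strictly positive")
    return df


def apply_eligibility(
    participants: pd.DataFrame,
    min_age: int = 18,
    max_age: int = 30,
    required_language: str = "Czech",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split participants into (retained, excluded-with-reason).

    Retains exactly the participants with the required native language and
    min_age <= age <= max_age (both bounds inclusive).  Exclusions carry a
    reason tag; language takes precedence when both fail.
    """
    lang_bad = participants["native_language"] != required_language
    age_bad = ~participants["age"].between(min_age, max_age)
    reason = pd.Series("", index=participants.index, dtype=str)
    reason[age_bad] = "age"
    reason[lang_bad] = "language"
    excluded_mask = lang_bad | age_bad
    retained = participants[~excluded_mask].reset_index(drop=True)
    excluded = participants.loc[excluded_mask, ["participant_id"]].copy()
    excluded["reason"] = reason[excluded_mask].to_numpy()
    return retained, excluded.reset_index(drop=True)


def write_norms(
    tables: Mapping[str, pd.DataFrame], out_dir: str | Path
) -> dict[str, Path]:
    """Write each norms table as ``<out_dir>/<name>.csv``.

    Column order is preserved; floats are written with Python's shortest
    round-tripping repr, so a write/read cycle reproduces values exactly.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, table in tables.items():
        p = out_dir / f"{name}.csv"
        table.to_csv(p, index=False, na_rep=UNKNOWN_TOKEN)
        paths[name] = p
    return paths


def write_responses(
    ratings: pd.DataFrame, ages: pd.DataFrame, path: str | Path
) -> None:
    """Write Likert + age responses back to the canonical single-file CSV."""
    lik = ratings.copy()
    lik["value"] = lik["value"].astype(object)
    lik.loc[lik["value"].isna(), "value"] = UNKNOWN_TOKEN
    age = ages.copy()
    if not age.empty:
        age["dimension"] = "age"
        age["value"] = age["bands"].where(~age["unknown"], UNKNOWN_TOKEN)
        age["presentation_order"] = range(len(age))
        age = age[
            ["participant_id", "item_id", "dimension", "value",
             "presentation_order"]
        ]
    cols = ["participant_id", "item_id", "dimension", "value",
            "presentation_order"]
    out = pd.concat([lik[cols], age], ignore_index=True) if not age.empty \
        else lik[cols]
    out.to_csv(path, index=False)
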