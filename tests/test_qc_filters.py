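import numpy as np
import pandas as pd
import pytest

from socionorm import QCConfig, run_qc_cascade
from socionorm.core_io import Calibrator, StudyDesign
from socionorm.qc_filters import (
    check_calibrators,
    check_controls,
    detect_straightlining,
    filter_timing,
    filter_word_knowledge,
)
from socionorm.synthetic_data import SimulationConfig, simulate_study

from conftest import make_ratings

DIMS = ("gender", "location", "political", "valence")


@pytest.fixture(scope="module")
def design():
    labels = {
        d: tuple(f"{d}{k}" for k in range(7)) for d in DIMS
    }
    items = tuple(f"w{i:03d}" for i in range(100))
    return StudyDesign(
        likert_dimensions=DIMS,
        scale_labels=labels,
        lists={"list1": items},
        calibrators={d: Calibrator(d, f"cal_{d}", 1) for d in DIMS},
        controls={"list1": ("x1", "x2", "x3", "x4")},
    )


def varied_responses(pid, design, rng):
    """One participant's spread-out ratings over all real items."""
    rows = []
    for d in design.likert_dimensions:
        for i, item in enumerate(sorted(design.lists["list1"])):
            rows.append((pid, item, d, int(rng.integers(-3, 4))))
    return rows


class TestWordKnowledge:
    def make(self, n_unknown, design):
        rows = []
        items = sorted(design.lists["list1"])
        for i, item in enumerate(items):
            val = None if i < n_unknown else 1
            rows.append(("p1", item, "gender", val))
        return make_ratings(rows)

    def test_strictly_over_threshold_flags(self, design):
        cfg = QCConfig()
        assert filter_word_knowledge(self.make(21, design), design, cfg) == {
            "p1"
        }

    def test_exactly_at_threshold_is_retained(self, design):
        cfg = QCConfig()
        assert filter_word_knowledge(self.make(20, design), design, cfg) == set()
        assert filter_word_knowledge(self.make(0, design), design, cfg) == set()

    def test_pseudowords_never_enter_the_denominator(self, design):
        rows = [("p1", f"x{j}", "gender", None) for j in (1, 2, 3, 4)]
        rows += [("p1", f"w{i:03d}", "gender", 1) for i in range(10)]
        cfg = QCConfig()
        assert filter_word_knowledge(
            make_ratings(rows), design, cfg
        ) == set()


class TestStraightlining:
    def make(self, n_same, n_dims, design):
        """n_same identical responses out of 100 on n_dims dimensions."""
        rng = np.random.default_rng(0)
        rows = []
        items = sorted(design.lists["list1"])
        for di, d in enumerate(design.likert_dimensions):
            for i, item in enumerate(items):
                if di < n_dims and i < n_same:
                    val = 2
                else:
                    # cycle the remaining responses so no accidental mode
                    val = [-3, -1, 0, 1, 3][i % 5]
                rows.append(("p1", item, d, val))
        return make_ratings(rows)

    def test_81_percent_on_4_dimensions_excludes_participant(self, design):
        excl, removals = detect_straightlining(
            self.make(81, 4, design), design, QCConfig()
        )
        assert excl == {"p1"}
        assert removals == []

    def test_96_percent_on_one_dimension_removes_only_that_dimension(
        self, design
    ):
        excl, removals = detect_straightlining(
            self.make(96, 1, design), design, QCConfig()
        )
        assert excl == set()
        assert removals == [("p1", "gender")]

    def test_varied_responses_are_untouched(self, design):
        rng = np.random.default_rng(5)
        ratings = make_ratings(varied_responses("p1", design, rng))
        excl, removals = detect_straightlining(ratings, design, QCConfig())
        assert excl == set() and removals == []

    def test_unknowns_leave_the_denominator(self, design):
        # 40 identical of 50 known (0.80, not >0.80) plus 50 UNKNOWN
        rows = []
        items = sorted(design.lists["list1"])
        for i, item in enumerate(items):
            val = None if i >= 50 else (2 if i < 40 else [-3, -1, 0, 1, 3][i % 5])
            rows.append(("p1", item, "gender", val))
        excl, removals = detect_straightlining(
            make_ratings(rows), design, QCConfig()
        )
        assert excl == set() and removals == []


class TestCalibrators:
    def make(self, responses, design):
        rows = [
            ("p1", f"cal_{d}", d, responses.get(d))
            for d in design.likert_dimensions
            if d in responses
        ]
        return make_ratings(rows)

    def test_any_opposite_magnitude_counts_as_violation(self, design):
        # expected +, answered "slightly opposite" (-1) on two dimensions
        ratings = self.make(
            {"gender": -1, "location": -1, "political": 2, "valence": 1},
            design,
        )
        flagged, _ = check_calibrators(ratings, design, QCConfig())
        assert flagged == {"p1"}

    def test_single_violation_is_not_enough(self, design):
        ratings = self.make(
            {"gender": -3, "location": 2, "political": 2, "valence": 1},
            design,
        )
        flagged, _ = check_calibrators(ratings, design, QCConfig())
        assert flagged == set()

    def test_neutral_midpoint_is_never_a_violation(self, design):
        ratings = self.make({d: 0 for d in DIMS}, design)
        flagged, _ = check_calibrators(ratings, design, QCConfig())
        assert flagged == set()

    def test_missing_calibrator_counts_as_non_violation_and_is_logged(
        self, design
    ):
        ratings = self.make({"gender": -2}, design)
        flagged, missing = check_calibrators(ratings, design, QCConfig())
        assert flagged == set()
        assert any("location" in m for m in missing)


class TestControls:
    def make(self, unknown_slots, design):
        rows = []
        for d in design.likert_dimensions:
            for j in (1, 2, 3, 4):
                val = None if (f"x{j}", d) in unknown_slots else 1
                rows.append(("p1", f"x{j}", d, val))
        return make_ratings(rows)

    def test_rating_every_pseudoword_presentation_flags(self, design):
        assert check_controls(self.make(set(), design), design) == {"p1"}

    def test_one_unknown_presentation_spares_the_participant(self, design):
        flagged = check_controls(
            self.make({("x2", "political")}, design), design
        )
        assert flagged == set()

    def test_always_unknown_is_the_attentive_pattern(self, design):
        all_slots = {(f"x{j}", d) for j in (1, 2, 3, 4) for d in DIMS}
        assert check_controls(self.make(all_slots, design), design) == set()


class TestTiming:
    def make(self, fast):
        """30 participants at ~exp(6) s; `fast` maps pid -> fast dims.

        Normal durations have bounded (uniform) noise so only the
        designated fast cells can fall past the 2.5-SD cut.
        """
        rng = np.random.default_rng(7)
        rows = []
        for i in range(30):
            pid = f"p{i:02d}"
            for d in DIMS:
                log_t = rng.uniform(5.7, 6.3)
                if d in fast.get(pid, ()):
                    log_t = 3.0
                rows.append((pid, d, float(np.exp(log_t))))
        return pd.DataFrame(
            rows, columns=["participant_id", "dimension", "duration"]
        )

    def test_fast_on_two_dimensions_excludes(self):
        excl, removals = filter_timing(
            self.make({"p00": ("gender", "valence")}), QCConfig()
        )
        assert excl == {"p00"} and removals == []

    def test_fast_on_one_dimension_removes_that_dimension(self):
        excl, removals = filter_timing(
            self.make({"p00": ("valence",)}), QCConfig()
        )
        assert excl == set() and removals == [("p00", "valence")]

    def test_equal_durations_flag_nobody(self):
        t = pd.DataFrame(
            {
                "participant_id": [f"p{i}" for i in range(10)],
                "dimension": "gender",
                "duration": 300.0,
            }
        )
        assert filter_timing(t, QCConfig()) == (set(), [])

    def test_whole_experiment_mode_excludes_on_a_single_flag(self):
        t = self.make({"p00": ("gender",)})
        cfg = QCConfig(timing_granularity="whole-experiment")
        excl, removals = filter_timing(t, cfg)
        assert "p00" in excl and removals == []

    def test_nonpositive_duration_is_a_hard_error(self):
        t = pd.DataFrame(
            {
                "participant_id": ["p1"],
                "dimension": ["gender"],
                "duration": [-3.0],
            }
        )
        with pytest.raises(ValueError, match="positive"):
            filter_timing(t, QCConfig())


class TestCascade:
    EXPECTED_REASON = {
        "STRAIGHTLINER": "straightlining",
        "SPEEDER": "timing",
        "CALIBRATOR_VIOLATOR": "calibrator",
        "PSEUDOWORD_RATER": "control",
    }

    def test_planted_actors_are_each_caught_by_their_own_filter(
        self, study_bad_actors
    ):
        s = study_bad_actors
        clean_r, clean_a, report = run_qc_cascade(
            s.ratings, s.ages, s.timings, s.design
        )
        truth = s.participants_truth.set_index("participant_id")["behavior"]
        excluded = report.participant_exclusions.set_index("participant_id")
        planted = truth[truth != "NORMAL"]
        assert set(excluded.index) == set(planted.index)
        for pid, behavior in planted.items():
            assert excluded.loc[pid, "reason"] == self.EXPECTED_REASON[
                behavior
            ]
        assert report.reconcile()
        retained = set(clean_r["participant_id"])
        assert retained == set(truth.index[truth == "NORMAL"])

    def test_no_bad_actors_yields_an_empty_report(self, study_small):
        s = study_small
        _, _, report = run_qc_cascade(
            s.ratings, s.ages, s.timings, s.design
        )
        assert report.participant_exclusions.empty
        assert report.dimension_removals.empty
        assert report.reconcile()

    def test_per_participant_flags_are_population_independent(
        self, study_bad_actors
    ):
        # word-knowledge / straightlining / calibrator / control flags do
        # not change when another participant is removed from the data
        s = study_bad_actors
        cfg = QCConfig()
        drop = s.ratings["participant_id"].iloc[0]
        subset = s.ratings[s.ratings["participant_id"] != drop]
        for fn in (
            lambda r: filter_word_knowledge(r, s.design, cfg),
            lambda r: detect_straightlining(r, s.design, cfg)[0],
            lambda r: check_calibrators(r, s.design, cfg)[0],
            lambda r: check_controls(r, s.design),
        ):
            assert fn(subset) == fn(s.ratings) - {drop}

    def test_dimension_removal_drops_exactly_that_block(self, design):
        rng = np.random.default_rng(3)
        rows = []
        for p in range(8):
            rows += varied_responses(f"p{p}", design, rng)
        # p0 straightlines 96% of gender only
        ratings = make_ratings(rows)
        items = sorted(design.lists["list1"])
        mask = (
            (ratings["participant_id"] == "p0")
            & (ratings["dimension"] == "gender")
            & ratings["item_id"].isin(items[:96])
        )
        ratings.loc[mask, "value"] = 2
        timings = pd.DataFrame(
            {
                "participant_id": [f"p{p}" for p in range(8) for _ in DIMS],
                "dimension": list(DIMS) * 8,
                "duration": 300.0,
            }
        )
        ages = pd.DataFrame(
            columns=["participant_id", "item_id", "bands", "unknown"]
        )
        clean_r, _, report = run_qc_cascade(
            ratings, ages, timings, design
        )
        assert report.participant_exclusions.empty
        assert list(
            report.dimension_removals.itertuples(index=False, name=None)
        ) == [("p0", "gender", "straightlining_95")]
        assert clean_r[
            (clean_r["participant_id"] == "p0")
            & (clean_r["dimension"] == "gender")
        ].empty
        assert not clean_r[
            (clean_r["participant_id"] == "p0")
            & (clean_r["dimension"] == "valence")
        ].empty
        assert report.reconcile()
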