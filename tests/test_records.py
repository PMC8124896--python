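"""Data model: eligibility filtering, pattern and early/late classification."""

import pytest
from hypothesis import given, settings, strategies as st

from pnetrecur.records import (
    CohortValidationError,
    ERStatus,
    apply_eligibility_filters,
    classify_er_status,
    classify_recurrence_pattern,
    frame_to_records,
    records_to_frame,
)
from .conftest import make_record, make_recurrence


class TestEligibility:
    @pytest.mark.parametrize(
        "kwargs, reason",
        [
            ({"grade": "G3"}, "grade3"),
            ({"genetic_syndrome": True}, "genetic_syndrome"),
            ({"margin": "R2"}, "r2_resection"),
            ({"synchronous_metastases": True}, "synchronous_metastases"),
            ({"recurrence": None}, "missing_recurrence_status"),
            (
                {"recurrence": True, "rfs_months": 2.5, "prs_months": 5.0,
                 "prs_event": True, "os_months": 7.5,
                 "recurrence_sites": frozenset({"liver"})},
                "recurrence_lt_3mo",
            ),
        ],
    )
    def test_each_criterion_excludes(self, kwargs, reason):
        eligible, log = apply_eligibility_filters([make_record(**kwargs)])
        assert eligible == []
        assert log.reasons == {"p1": reason}

    def test_single_reason_in_precedence_order(self):
        # grade 3 *and* R2: logged once, under the earlier criterion.
        _, log = apply_eligibility_filters([make_record(grade="G3", margin="R2")])
        assert log.reasons == {"p1": "grade3"}
        assert log.counts["grade3"] == 1 and log.counts["r2_resection"] == 0

    def test_empty_input(self):
        eligible, log = apply_eligibility_filters([])
        assert eligible == [] and len(log) == 0

    def test_complete_eligible_record_retained(self):
        rec = make_recurrence(rfs=11.0)
        eligible, log = apply_eligibility_filters([rec])
        assert eligible == [rec] and len(log) == 0

    def test_malformed_enum_names_field_and_row(self):
        with pytest.raises(CohortValidationError, match=r"grade.*row 0"):
            apply_eligibility_filters([make_record(grade="grade-one")])

    def test_conservation_on_synthetic_cohort(self, cohort):
        records, _ = cohort
        eligible, log = apply_eligibility_filters(records)
        assert len(eligible) + len(log) == len(records)
        # generator output is eligible by construction
        assert len(log) == 0


class TestRecurrencePattern:
    @pytest.mark.parametrize(
        "sites, expected",
        [
            ({"remnant_pancreas"}, "local"),
            ({"cut_surface", "peripancreatic_nodes"}, "local"),
            ({"liver"}, "distant"),
            ({"other_organ"}, "distant"),
            ({"liver", "other_organ"}, "distant"),
            ({"liver", "cut_surface"}, "local_and_distant"),
            ({"other_organ", "remnant_pancreas"}, "local_and_distant"),
        ],
    )
    def test_classification(self, sites, expected):
        assert classify_recurrence_pattern(sites) == expected

    def test_empty_sites_error(self):
        with pytest.raises(ValueError):
            classify_recurrence_pattern(set())

    @given(
        st.sets(
            st.sampled_from(
                ["remnant_pancreas", "cut_surface", "peripancreatic_nodes",
                 "liver", "other_organ"]
            ),
            min_size=1,
        )
    )
    def test_totality(self, sites):
        """Every nonempty site set maps to exactly one of the three patterns."""
        assert classify_recurrence_pattern(sites) in (
            "local", "distant", "local_and_distant"
        )

    def test_pattern_counts_partition_recurred(self, recurred):
        patterns = [classify_recurrence_pattern(r.recurrence_sites) for r in recurred]
        assert len(patterns) == len(recurred)


class TestERStatus:
    def test_examples(self):
        assert classify_er_status(make_recurrence(rfs=11.0), 18).value == "early"
        assert classify_er_status(make_recurrence(rfs=41.0), 18).value == "late"
        assert classify_er_status(make_record(), 18).value == "none"
        # boundary: exactly at the cut-off counts as early
        assert classify_er_status(make_recurrence(rfs=18.0), 18).value == "early"

    def test_missing_rfs_error(self):
        rec = make_record(recurrence=True, rfs_months=None)
        with pytest.raises(CohortValidationError):
            classify_er_status(rec, 18)

    def test_cutoff_at_or_below_floor_rejected(self):
        with pytest.raises(ValueError):
            classify_er_status(make_record(), 3.0)

    @given(st.floats(min_value=3.1, max_value=120.0))
    @settings(max_examples=25, deadline=None)
    def test_trichotomy_and_monotonicity(self, cutoff):
        records = [make_record("n1")] + [
            make_recurrence(f"r{i}", rfs=float(rfs))
            for i, rfs in enumerate((4, 11, 18, 25, 41, 80))
        ]
        statuses = [classify_er_status(r, cutoff).value for r in records]
        assert len(statuses) == len(records)
        n_early = statuses.count("early")
        wider = [classify_er_status(r, cutoff + 5).value for r in records]
        assert wider.count("early") >= n_early
        assert statuses.count("none") + statuses.count("early") + statuses.count(
            "late"
        ) == len(records)


class TestCsvRoundtrip:
    def test_roundtrip_preserves_records(self, cohort, tmp_path):
        records, _ = cohort
        path = tmp_path / "cohort.csv"
        records_to_frame(records[:50]).to_csv(path, index=False)
        import pandas as pd

        back = frame_to_records(pd.read_csv(path, dtype={"patient_id": str}))
        assert back == records[:50]
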