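"""Condition detection window, weighted scoring, and cohort scoring oracle."""

from __future__ import annotations

from datetime import date

import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from snomedcci.cci import (
    apply_flag_hierarchy,
    compute_cci,
    detect_conditions,
    results_frame,
    score_cohort,
)
from snomedcci.codesets import (
    CONDITION_ORDER,
    MAX_SCORE_WITH_HIERARCHY,
    MAX_SCORE_WITHOUT_HIERARCHY,
    SUPERSEDED_BY,
    WEIGHTS,
    default_definitions,
)
from snomedcci.errors import ContractError
from snomedcci.vocab import ICD10CM

from conftest import adapt_all

DEFS = default_definitions()
INDEX = date(2018, 6, 1)


def _flags(*on):
    return {c: c in on for c in CONDITION_ORDER}


class TestDetection:
    def test_no_diagnoses_all_false(self):
        flags = detect_conditions([], INDEX, DEFS, "quan_icd10")
        assert not any(flags.values())

    @pytest.mark.parametrize("days_before, expected", [(365, True), (366, False), (0, True)])
    def test_lookback_window_closed_at_365_days(self, days_before, expected):
        d = INDEX - pd.Timedelta(days=days_before)
        flags = detect_conditions([("I21.0", ICD10CM, d.date() if hasattr(d, "date") else d)],
                                  INDEX, DEFS, "quan_icd10")
        assert flags["mi"] is expected

    def test_future_diagnosis_ignored(self):
        d = date(2018, 6, 2)
        flags = detect_conditions([("I21.0", ICD10CM, d)], INDEX, DEFS, "quan_icd10")
        assert not flags["mi"]

    def test_other_vocabulary_skipped_not_fatal(self):
        flags = detect_conditions([("410.1", "ICD9CM", INDEX)], INDEX, DEFS, "quan_icd10")
        assert not any(flags.values())

    def test_prefix_pattern_matches_deep_codes(self):
        flags = detect_conditions([("I21.A1", ICD10CM, INDEX)], INDEX, DEFS, "quan_icd10")
        assert flags["mi"]

    def test_unknown_algorithm_rejected(self):
        with pytest.raises(ContractError):
            detect_conditions([], INDEX, DEFS, "elixhauser")


class TestScoring:
    def test_no_flags_zero(self):
        assert compute_cci(_flags(), DEFS) == 0

    def test_two_single_weight_conditions(self):
        assert compute_cci(_flags("mi", "chf"), DEFS) == 2

    def test_hierarchy_drops_superseded_weight(self):
        f = _flags("malignancy", "metastatic_tumor")
        assert compute_cci(f, DEFS, apply_hierarchy=True) == 6
        assert compute_cci(f, DEFS, apply_hierarchy=False) == 8

    def test_all_conditions_max_scores(self):
        f = _flags(*CONDITION_ORDER)
        assert compute_cci(f, DEFS, apply_hierarchy=True) == MAX_SCORE_WITH_HIERARCHY
        assert compute_cci(f, DEFS, apply_hierarchy=False) == MAX_SCORE_WITHOUT_HIERARCHY

    def test_incomplete_flags_rejected(self):
        with pytest.raises(ContractError):
            compute_cci({"mi": True}, DEFS)

    def test_flag_hierarchy_clears_milder_flag(self):
        out = apply_flag_hierarchy(_flags("mild_liver", "severe_liver"))
        assert not out["mild_liver"] and out["severe_liver"]

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(bits=st.integers(0, 2 ** 17 - 1))
    def test_hierarchy_monotone_with_exact_difference(self, bits):
        """Hierarchy never raises the score; the gap is exactly the sum of
        superseded weights whose severe partner is flagged."""
        flags = {c: bool(bits >> i & 1) for i, c in enumerate(CONDITION_ORDER)}
        plain = compute_cci(flags, DEFS, apply_hierarchy=False)
        hier = compute_cci(flags, DEFS, apply_hierarchy=True)
        expected_gap = sum(
            WEIGHTS[mild] for mild, severe in SUPERSEDED_BY.items()
            if flags[mild] and flags[severe]
        )
        assert hier <= plain
        assert plain - hier == expected_gap


def _naive_scores(cohort, dx, definitions, algorithm, apply_hierarchy=True):
    """Per-patient loop oracle over detect_conditions + compute_cci."""
    out = {}
    dx = dx.copy()
    dx["date"] = pd.to_datetime(dx["date"])
    for _, row in cohort.iterrows():
        recs = dx[dx["person_id"] == row["person_id"]]
        diags = [(r.code, r.vocabulary, r.date.date())
                 for r in recs.itertuples(index=False)]
        idx = pd.to_datetime(row["index_date"]).date()
        flags = detect_conditions(diags, idx, definitions, algorithm)
        out[row["person_id"]] = (flags, compute_cci(flags, definitions, apply_hierarchy))
    return out


class TestCohortScoring:
    def test_empty_cohort(self):
        cohort = pd.DataFrame(columns=["person_id", "index_date"])
        dx = pd.DataFrame(columns=["person_id", "code", "vocabulary", "date"])
        assert score_cohort(cohort, dx, DEFS, "quan_icd10") == []

    def test_matches_naive_oracle_and_planted_truth(self, small_vocab, small_claims):
        """Vectorized scoring equals a per-patient loop exactly, and with
        zero discordance both algorithms recover the planted flags."""
        from snomedcci.report import _build_definitions

        snomed_sets, _, _ = adapt_all(small_vocab)
        defs = _build_definitions(small_vocab.quan_codesets, snomed_sets)
        bundle = small_claims.bundle
        from snomedcci.cohort import attach_outcome, build_cohort

        cohort = attach_outcome(build_cohort(bundle, 2018), bundle.deaths).rows
        assert len(cohort) == 500

        for algorithm in ("quan_icd10", "snomed"):
            results = score_cohort(cohort, bundle.condition_occurrences, defs, algorithm)
            naive = _naive_scores(cohort, bundle.condition_occurrences, defs, algorithm)
            truth = small_claims.truth.set_index("person_id")
            for r in results:
                flags_naive, score_naive = naive[r.person_id]
                assert r.flags_dict() == flags_naive
                assert r.score == score_naive
                planted = {c: bool(truth.loc[r.person_id, c]) for c in CONDITION_ORDER}
                assert r.flags_dict() == planted
                assert r.score == int(truth.loc[r.person_id, "cci_true"])

    def test_adding_evidence_is_monotone(self):
        cohort = pd.DataFrame({"person_id": [1], "index_date": ["2018-06-01"]})
        dx1 = pd.DataFrame({"person_id": [1], "code": ["I21.0"],
                            "vocabulary": [ICD10CM], "date": ["2018-05-01"]})
        dx2 = pd.concat([dx1, pd.DataFrame({
            "person_id": [1], "code": ["I50.9"], "vocabulary": [ICD10CM],
            "date": ["2018-05-02"]})], ignore_index=True)
        (r1,) = score_cohort(cohort, dx1, DEFS, "quan_icd10")
        (r2,) = score_cohort(cohort, dx2, DEFS, "quan_icd10")
        assert r2.score >= r1.score
        assert all(b or not a for a, b in zip(r1.flags, r2.flags))

    def test_results_frame_shape(self):
        cohort = pd.DataFrame({"person_id": [1], "index_date": ["2018-06-01"]})
        dx = pd.DataFrame({"person_id": [1], "code": ["I21.0"],
                           "vocabulary": [ICD10CM], "date": ["2018-05-01"]})
        frame = results_frame(score_cohort(cohort, dx, DEFS, "quan_icd10"))
        assert list(frame.columns) == ["person_id", "algorithm", *CONDITION_ORDER, "score"]
        assert frame.loc[0, "score"] == 1
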