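"""Unit and property tests for text normalization, lexicon scanning,
patient classification and the PPV audit."""

import pytest
from hypothesis import given, settings, strategies as st

from trauma_ehr.detector import (
    Detector,
    EmptyAuditError,
    classify_patient,
    flag_note,
    normalize_text,
    ppv_audit,
    scan_note,
    to_raw_span,
)
from trauma_ehr.lexicon import LexiconEntry, LexiconError, compile_lexicon, load_lexicon


class TestNormalizeText:
    @pytest.mark.parametrize(
        "raw,expected",
        [
            ("Childhood   Sexual ABUSE", "childhood sexual abuse"),
            ("", ""),
            ("Hx  of\tsexual abuse", "hx of sexual abuse"),
            ("  leading and trailing \n", "leading and trailing"),
        ],
    )
    def test_folding(self, raw, expected):
        norm, _ = normalize_text(raw)
        assert norm == expected

    def test_offset_map_points_back_to_raw(self):
        raw = "Childhood   Sexual ABUSE"
        norm, spans = normalize_text(raw)
        start, end = to_raw_span(spans, 0, len(norm))
        assert (start, end) == (0, len(raw))
        # the word "sexual" in normalized space maps to its raw position
        i = norm.index("sexual")
        s, e = to_raw_span(spans, i, i + len("sexual"))
        assert raw[s:e] == "Sexual"

    @given(st.text(alphabet=st.characters(codec="ascii"), max_size=80))
    @settings(max_examples=200, deadline=None)
    def test_roundtrip_property(self, raw):
        """Every normalized character maps into the raw string, monotonically."""
        norm, spans = normalize_text(raw)
        assert len(spans) == len(norm)
        last = 0
        for (s, e), ch in zip(spans, norm):
            assert 0 <= s < e <= len(raw)
            assert s >= last
            last = s
            if ch != " ":
                assert raw[s:e].lower() == ch


class TestScanNote:
    @pytest.mark.parametrize(
        "text,polarities,ages",
        [
            ("she was sexually abused as a child", ["include"], [()]),
            ("nil csa, no other trauma", ["exclude"], [()]),
            ("sexually abused between the ages of 6-9", ["include"], [(6, 9)]),
            ("patient denied a childhood history of sexual abuse", ["exclude"], [()]),
            ("no concerns raised at today's review", [], []),
        ],
    )
    def test_spec_examples(self, detector, text, polarities, ages):
        spans = detector.scan("n", text)
        assert [s.polarity for s in spans] == polarities
        assert [s.extracted_ages for s in spans] == ages

    def test_exclusion_blocks_embedded_inclusion(self, detector):
        spans = detector.scan("n", "nil csa")
        assert len(spans) == 1 and spans[0].polarity == "exclude"
        assert not flag_note(spans)

    def test_offsets_are_raw(self, detector):
        text = "Seen today.  Childhood   Sexual ABUSE documented."
        (span,) = detector.scan("n", text)
        assert text[span.start : span.end] == "Childhood   Sexual ABUSE"

    def test_case_and_whitespace_invariance(self, detector):
        base = "she was sexually abused as a child"
        variants = [base.upper(), "She  Was   Sexually\tAbused As A Child"]
        base_spans = detector.scan("n", base)
        for v in variants:
            spans = detector.scan("n", v)
            assert [(s.pattern_id, s.polarity) for s in spans] == [
                (s.pattern_id, s.polarity) for s in base_spans
            ]

    def test_three_digit_number_is_not_an_age(self, detector):
        spans = detector.scan("n", "sexually abused at age 123")
        assert all(not s.extracted_ages for s in spans)

    def test_malformed_template_rejected_at_load_time(self):
        with pytest.raises(LexiconError):
            LexiconEntry("bad", "abused at {wrong}", "include")


class TestClassifyPatient:
    def test_unqualified_include_is_exposed(self, detector):
        spans = detector.scan("n", "documented childhood sexual abuse")
        assert classify_patient("p", spans).status == "exposed"

    def test_indeterminate_only_is_removed(self, detector):
        spans = detector.scan("n", "there is a record of historical sexual abuse")
        assert classify_patient("p", spans).status == "removed_indeterminate"

    def test_no_spans_is_unexposed(self):
        assert classify_patient("p", []).status == "unexposed"

    def test_adult_age_demoted(self, detector):
        spans = detector.scan("n", "sexually abused at age 35")
        assert classify_patient("p", spans, cutoff=18).status == "unexposed"

    def test_childhood_age_exposed(self, detector):
        spans = detector.scan("n", "sexually abused at age 9")
        assert classify_patient("p", spans, cutoff=18).status == "exposed"

    def test_positive_note_dominates_negated_note(self, detector):
        spans = detector.scan("n1", "denies any history of sexual abuse")
        spans += detector.scan("n2", "she was sexually abused as a child")
        assert classify_patient("p", spans).status == "exposed"

    def test_include_monotonicity(self, lexicon):
        """Adding an include phrase can never turn an exposed patient unexposed."""
        texts = [
            "she was sexually abused as a child",
            "longstanding difficulties since her teens",
        ]
        base = Detector(lexicon)
        extended = Detector(
            lexicon + [LexiconEntry("inc_extra", "difficulties since her teens", "include")]
        )
        for det_pair in [(base, extended)]:
            spans_a = [s for t in texts for s in det_pair[0].scan("n", t)]
            spans_b = [s for t in texts for s in det_pair[1].scan("n", t)]
            assert classify_patient("p", spans_a).status == "exposed"
            assert classify_patient("p", spans_b).status == "exposed"


class TestPpvAudit:
    def test_paper_scale_audit(self):
        flagged = [f"n{i}" for i in range(200)]
        truth = set(flagged[:190])  # 95% of the pool is genuinely positive
        ppv, (lo, hi), k = ppv_audit(flagged, truth, 100, seed=0)
        assert ppv == k / 100 and 0.8 <= ppv <= 1.0

    def test_all_true_gives_unit_upper_bound(self):
        flagged = [f"n{i}" for i in range(50)]
        ppv, (lo, hi), _ = ppv_audit(flagged, set(flagged), 20, seed=1)
        assert ppv == 1.0 and hi == 1.0

    def test_clopper_pearson_derived_value(self):
        flagged = [f"n{i}" for i in range(10)]
        ppv, (lo, hi), _ = ppv_audit(flagged, set(flagged[:7]), 10, seed=3)
        assert ppv == 0.7
        assert lo == pytest.approx(0.3475, abs=1e-4)
        assert hi == pytest.approx(0.9333, abs=1e-4)

    def test_empty_audit_raises(self):
        with pytest.raises(EmptyAuditError):
            ppv_audit([], set(), 10, seed=0)

    def test_oversampling_raises(self):
        with pytest.raises(ValueError):
            ppv_audit(["a"], set(), 2, seed=0)
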