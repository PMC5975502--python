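"""Context-engine rules: segmentation, matching, and attribute assignment."""

import itertools

import pytest
from hypothesis import given, settings, strategies as st

from periscreen.nlp import (annotate_note, assign_doc_time_rel,
                            assign_experiencer, detect_polarity,
                            detect_section_title, is_relevant, match_terms,
                            segment_sentences)


def _note(text):
    return {"note_id": "n1", "patient_id": "p1", "doc_date": "2010-06-01",
            "text": text}


def _single_mention(text, term_lexicon, triggers):
    ms = annotate_note(_note(text), term_lexicon, triggers)
    assert len(ms) >= 1
    return ms


class TestSegmentation:
    def test_two_terminated_sentences(self):
        assert len(segment_sentences("A. B.")) == 2

    def test_newline_isolates_unpunctuated_lines(self):
        spans = segment_sentences("suicidal behavior: none\nPlan: follow up")
        assert len(spans) == 2
        text = "suicidal behavior: none\nPlan: follow up"
        assert text[slice(*spans[0])] == "suicidal behavior: none"

    def test_terminator_runs_absorbed(self):
        spans = segment_sentences("Really?! Yes.")
        assert len(spans) == 2

    def test_partition_against_character_scan_oracle(self):
        """Spans cover every non-whitespace character exactly once."""
        text = ("First visit today. Mood stable!\n"
                "HPI: no acute distress\n"
                "Will follow up in 2 weeks... Patient agreeable.\n\n"
                "Plan: continue meds")
        spans = segment_sentences(text)
        covered = [False] * len(text)
        for s, e in spans:
            for i in range(s, e):
                assert not covered[i], "span overlap"
                covered[i] = True
        for i, c in enumerate(text):
            if not c.isspace():
                assert covered[i], f"char {i} ({c!r}) uncovered"

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.text(alphabet=" \n.!?:abcdeABC,/-0123456789", max_size=120))
    def test_partition_property_on_arbitrary_text(self, text):
        """For any text: spans are disjoint, ordered, and cover exactly the
        non-whitespace characters."""
        spans = segment_sentences(text)
        prev_end = -1
        covered = [False] * len(text)
        for s, e in spans:
            assert 0 <= s < e <= len(text)
            assert s > prev_end or prev_end == -1 or s >= prev_end
            prev_end = e
            for i in range(s, e):
                assert not covered[i]
                covered[i] = True
        for i, c in enumerate(text):
            if not c.isspace():
                assert covered[i]

    def test_twenty_sentence_fixture_matches_oracle(self):
        sents = [f"Sentence number {i} here." for i in range(20)]
        text = " ".join(sents)
        spans = segment_sentences(text)
        assert [text[s:e] for s, e in spans] == sents


class TestMatchTerms:
    def test_case_insensitive(self, term_lexicon):
        out = match_terms("Patient denies SUICIDAL IDEATION.", term_lexicon)
        assert len(out) == 1

    def test_longest_match_wins(self, term_lexicon):
        out = match_terms("discussed suicidal ideation at length",
                          term_lexicon)
        assert len(out) == 1
        s, e, cid = out[0]
        assert cid == "C-SB-001"  # the two-word concept, not bare "suicidal"

    def test_word_boundary(self, term_lexicon):
        out = match_terms("discussed suicide risk assessment", term_lexicon)
        assert [cid for _, _, cid in out] == ["C-SB-007"]
        # no match inside longer words
        assert match_terms("quasidecision", term_lexicon) == []

    def test_offset_shifts_spans(self, term_lexicon):
        out = match_terms("suicide", term_lexicon, offset=100)
        assert out[0][:2] == (100, 107)


class TestPolarity:
    @pytest.mark.parametrize("text,expected", [
        ("suicidal behavior: none", "negated"),
        ("suicidal behavior: none reported", "negated"),
        ("suicidal behavior: denied", "negated"),
        ("patient reports feeling suicidal", "affirmed"),
        ("patient denies suicidal ideation", "negated"),
        ("no suicidal ideation", "negated"),
        ("suicidal ideation was ruled out", "negated"),
    ])
    def test_polarity_examples(self, term_lexicon, triggers, text, expected):
        (m,) = _single_mention(text, term_lexicon, triggers)
        assert m.polarity == expected

    def test_scope_breaker_restores_affirmation(self, term_lexicon, triggers):
        ms = _single_mention("denies SI but endorses suicidal thoughts tonight",
                             term_lexicon, triggers)
        assert [m.polarity for m in ms] == ["negated", "affirmed"]

    def test_colon_negation_does_not_fire_on_non_negation_word(
            self, term_lexicon, triggers):
        (m, m2) = _single_mention(
            "Suicide attempt/gesture: history of, hospitalized inpatient "
            "psych unit for suicide attempt in 1996", term_lexicon, triggers)
        assert m.polarity == "affirmed"

    def test_trigger_outside_scope_window(self, term_lexicon, triggers):
        text = ("denies chest pain shortness of breath nausea vomiting "
                "dizziness and suicidal ideation")
        (m,) = _single_mention(text, term_lexicon, triggers)
        assert m.polarity == "affirmed"  # 8 tokens past the 6-token window


class TestDocTimeRel:
    @pytest.mark.parametrize("text,expected", [
        ("patient attempted suicide when she was 14", "before"),
        ("She would not consider suicide an option if symptoms were to arise",
         "after"),
        ("patient states that she wants to kill herself", "overlap"),
        ("patient endorses passive suicidal ideation since the birth of "
         "her baby", "before_overlap"),
        ("hospitalized for suicide attempt in 1996", "before"),
        ("history of suicidal ideation", "before"),
        ("If she has significant side effects from it such as "
         "lethargy/depression/irritability/suicidal thought, we will "
         "change it to LTG.", "after"),
    ])
    def test_temporality_examples(self, term_lexicon, triggers, text, expected):
        ms = _single_mention(text, term_lexicon, triggers)
        assert ms[-1].doc_time_rel == expected

    def test_no_cue_defaults_to_overlap(self, term_lexicon, triggers):
        (m,) = _single_mention("patient reports suicidal ideation",
                               term_lexicon, triggers)
        assert m.doc_time_rel == "overlap"


class TestExperiencer:
    @pytest.mark.parametrize("text,expected", [
        ("mom attempted suicide", "family_member"),
        ("Pt also identifies strongly with father, who was often aggressive "
         "toward others and threatened suicide", "family_member"),
        ("patient reports feeling suicidal", "patient"),
        ("her friend attempted suicide last month", "other"),
        ("suicidal ideation noted", "patient"),   # default subject
    ])
    def test_experiencer_examples(self, term_lexicon, triggers, text, expected):
        ms = _single_mention(text, term_lexicon, triggers)
        assert ms[0].experiencer == expected


class TestSectionTitle:
    @pytest.mark.parametrize("text,expected", [
        ("Suicidal Behavior Hx of Suicidal Behavior:", True),
        ("patient reports feeling suicidal", False),
        ("Assessment: patient endorses suicidal ideation.", False),
    ])
    def test_header_detection(self, term_lexicon, triggers, text, expected):
        ms = _single_mention(text, term_lexicon, triggers)
        assert all(m.section_title is expected for m in ms)


class TestAnnotateNote:
    def test_colon_negation_note_not_relevant(self, term_lexicon, triggers):
        (m,) = annotate_note(_note("suicidal behavior: none"),
                             term_lexicon, triggers)
        assert m.relevant is False

    def test_current_affirmed_note_relevant(self, term_lexicon, triggers):
        (m,) = annotate_note(
            _note("patient states that she wants to kill herself"),
            term_lexicon, triggers)
        assert m.relevant is True

    def test_hypothetical_note_not_relevant(self, term_lexicon, triggers):
        (m,) = annotate_note(_note(
            "If she has significant side effects from it such as "
            "lethargy/depression/irritability/suicidal thought, we will "
            "change it to LTG."), term_lexicon, triggers)
        assert m.doc_time_rel == "after" and m.relevant is False

    def test_mentions_never_cross_sentence_boundaries(self, small_cohort,
                                                      term_lexicon, triggers):
        _, (_, _, notes) = small_cohort
        for rec in notes.head(200).to_dict("records"):
            spans = segment_sentences(rec["text"])
            for m in annotate_note(rec, term_lexicon, triggers):
                assert any(s <= m.start and m.end <= e for s, e in spans)

    def test_engine_recovers_template_ground_truth_exactly(
            self, small_cohort, term_lexicon, triggers):
        """100% per-attribute accuracy on the synthetic corpus."""
        _, (_, _, notes) = small_cohort
        n_checked = 0
        for rec in notes.to_dict("records"):
            if not rec["gt_mentions"]:
                continue
            got = annotate_note(rec, term_lexicon, triggers)
            gt = sorted(rec["gt_mentions"], key=lambda m: m["start"])
            assert len(got) == len(gt)
            for m, g in zip(got, gt):
                assert (m.start, m.end) == (g["start"], g["end"])
                assert m.concept_id == g["concept_id"]
                assert m.polarity == g["polarity"]
                assert m.doc_time_rel == g["doc_time_rel"]
                assert m.experiencer == g["experiencer"]
                assert m.section_title == g["section_title"]
                n_checked += 1
        assert n_checked > 100


class TestRelevanceConjunction:
    def test_flipping_any_attribute_breaks_relevance(self):
        """Exhaustive scan of the attribute lattice."""
        for pol, dtr, exp, sect in itertools.product(
                ("affirmed", "negated"),
                ("before", "after", "overlap", "before_overlap"),
                ("patient", "family_member", "other", "null"),
                (False, True)):
            expected = (pol == "affirmed"
                        and dtr in ("overlap", "before_overlap")
                        and exp == "patient" and not sect)
            assert is_relevant(pol, dtr, exp, sect) is expected
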