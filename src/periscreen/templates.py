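"""Clinical-note template library with fixed attribute ground truth.

Each template couples one sentence pattern to known context attributes for
every suicide-concept mention it contains, so the rule engine's accuracy on
generated notes is exactly assessable. The sentence inventory realizes the
documentation patterns the screen must handle: affirmed current mentions,
NegEx-style and colon-structure negation, historical mentions (past age /
past year), hypothetical and conditional mentions, family-member
experiencers, section-title header lines, and durative (before/overlap)
mentions. Filler sentences contain no lexicon terms (enforced by a build
check in the test suite).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

__all__ = [
    "GroundTruthMention",
    "NoteTemplate",
    "TEMPLATES",
    "RELEVANT_TEMPLATE_IDS",
    "IRRELEVANT_TEMPLATE_IDS",
    "FILLER_SENTENCES",
    "get_template",
]


@dataclass(frozen=True)
class GroundTruthMention:
    """Known attributes for one mention; span is 0-based half-open."""
    start: int
    end: int
    concept_id: str
    polarity: str
    doc_time_rel: str
    experiencer: str
    section_title: bool
    template_id: str

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class _GT:
    """Template-local mention spec: nth occurrence of a literal surface."""
    surface: str
    concept_id: str
    polarity: str
    doc_time_rel: str
    experiencer: str
    section_title: bool = False
    occurrence: int = 0


@dataclass(frozen=True)
class NoteTemplate:
    template_id: str
    text: str
    mentions: tuple[_GT, ...]
    category: str  # "relevant" | "irrelevant"

    def ground_truth(self, offset: int = 0) -> list[GroundTruthMention]:
        out = []
        for gt in self.mentions:
            pos = -1
            for _ in range(gt.occurrence + 1):
                pos = self.text.index(gt.surface, pos + 1)
            out.append(GroundTruthMention(
                start=offset + pos, end=offset + pos + len(gt.surface),
                concept_id=gt.concept_id, polarity=gt.polarity,
                doc_time_rel=gt.doc_time_rel, experiencer=gt.experiencer,
                section_title=gt.section_title, template_id=self.template_id))
        return out

    @property
    def n_relevant(self) -> int:
        return sum(1 for gt in self.mentions
                   if gt.polarity == "affirmed"
                   and gt.doc_time_rel in ("overlap", "before_overlap")
                   and gt.experiencer == "patient" and not gt.section_title)


def _t(tid, text, mentions, category) -> NoteTemplate:
    return NoteTemplate(tid, text, tuple(mentions), category)


TEMPLATES: dict[str, NoteTemplate] = {t.template_id: t for t in [
    # --- relevant: affirmed, current, patient-experienced -----------------
    _t("affirmed_current",
       "Patient reports feeling suicidal.",
       [_GT("suicidal", "C-SB-006", "affirmed", "overlap", "patient")],
       "relevant"),
    _t("affirmed_overlap",
       "Patient states that she wants to kill herself.",
       [_GT("kill herself", "C-SB-009", "affirmed", "overlap", "patient")],
       "relevant"),
    _t("affirmed_ideation",
       "Patient endorses active suicidal ideation today.",
       [_GT("suicidal ideation", "C-SB-001", "affirmed", "overlap", "patient")],
       "relevant"),
    _t("before_overlap",
       "Patient endorses passive suicidal ideation since the birth of her baby.",
       [_GT("suicidal ideation", "C-SB-001", "affirmed", "before_overlap",
            "patient")],
       "relevant"),
    _t("denies_but",
       "Patient denies SI but endorses suicidal thoughts tonight.",
       [_GT("SI", "C-SB-011", "negated", "overlap", "patient"),
        _GT("suicidal thoughts", "C-SB-004", "affirmed", "overlap", "patient")],
       "relevant"),
    # --- irrelevant: negated / historical / hypothetical / family / header
    _t("colon_negation",
       "Suicidal behavior: none",
       [_GT("Suicidal behavior", "C-SB-002", "negated", "overlap", "patient")],
       "irrelevant"),
    _t("colon_negation_reported",
       "Suicidal behavior: none reported",
       [_GT("Suicidal behavior", "C-SB-002", "negated", "overlap", "patient")],
       "irrelevant"),
    _t("colon_negation_denied",
       "Suicidal behavior: denied",
       [_GT("Suicidal behavior", "C-SB-002", "negated", "overlap", "patient")],
       "irrelevant"),
    _t("pre_negation",
       "Patient denies suicidal ideation.",
       [_GT("suicidal ideation", "C-SB-001", "negated", "overlap", "patient")],
       "irrelevant"),
    _t("history_age",
       "Patient attempted suicide when she was 14.",
       [_GT("suicide", "C-SB-007", "affirmed", "before", "patient")],
       "irrelevant"),
    _t("history_year",
       "Suicide attempt/gesture: history of, hospitalized inpatient psych "
       "unit for suicide attempt in 1996",
       [_GT("Suicide attempt", "C-SB-003", "affirmed", "before", "patient"),
        _GT("suicide attempt", "C-SB-003", "affirmed", "before", "patient")],
       "irrelevant"),
    _t("hypothetical",
       "If she has significant side effects from it such as "
       "lethargy/depression/irritability/suicidal thought, we will change "
       "it to LTG.",
       [_GT("suicidal thought", "C-SB-004", "affirmed", "after", "patient")],
       "irrelevant"),
    _t("conditional",
       "She would not consider suicide an option if symptoms were to arise.",
       [_GT("suicide", "C-SB-007", "negated", "after", "patient")],
       "irrelevant"),
    _t("family_history",
       "Mom attempted suicide.",
       [_GT("suicide", "C-SB-007", "affirmed", "overlap", "family_member")],
       "irrelevant"),
    _t("family_father",
       "Pt also identifies strongly with father, who was often aggressive "
       "toward others and threatened suicide.",
       [_GT("suicide", "C-SB-007", "affirmed", "overlap", "family_member")],
       "irrelevant"),
    _t("section_title",
       "Suicidal Behavior Hx of Suicidal Behavior:",
       [_GT("Suicidal Behavior", "C-SB-002", "affirmed", "before", "patient",
            True, 0),
        _GT("Suicidal Behavior", "C-SB-002", "affirmed", "before", "patient",
            True, 1)],
       "irrelevant"),
]}

RELEVANT_TEMPLATE_IDS = tuple(
    tid for tid, t in TEMPLATES.items() if t.category == "relevant")
IRRELEVANT_TEMPLATE_IDS = tuple(
    tid for tid, t in TEMPLATES.items() if t.category == "irrelevant")

#: neutral prose carrying no suicide-lexicon terms
FILLER_SENTENCES = (
    "Vital signs stable.",
    "Discussed nutrition and prenatal vitamins.",
    "Fetal heart tones normal.",
    "Routine prenatal visit today.",
    "Patient tolerated the visit well.",
    "Reviewed lab results from last week.",
    "Will continue current care plan.",
)


def get_template(template_id: str) -> NoteTemplate:
    try:
        return TEMPLATES[template_id]
    except KeyError:
        raise KeyError(f"unknown template_id {template_id!r}") from None
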