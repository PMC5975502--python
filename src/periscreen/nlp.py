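"""Rule-based concept and context extraction for clinical notes.

The notes arm of the screen first finds suicide-related term mentions, then
assigns each mention the context attributes that decide whether it counts as
evidence of current, patient-experienced suicidal behavior:

* **polarity** — affirmed vs. negated, via NegEx-style pre-mention triggers
  *and* the colon-structure dialect ("suicidal behavior: none") that plain
  trigger-window negation misses;
* **doc_time_rel** — the mention's temporal relation to the document
  creation time (before / after / overlap / before_overlap), via historical,
  hypothetical/conditional and durative cues;
* **experiencer** — patient vs. family member vs. other, via the nearest
  preceding subject cue;
* **section_title** — header lines ("Hx of Suicidal Behavior:") that name a
  topic without describing the patient.

A mention is **relevant** iff affirmed, temporally current (overlap or
before_overlap), experienced by the patient, and not a section title.

All rules are pure functions of (sentence, mention, lexicons): deterministic
and individually testable. Mentions never cross sentence boundaries.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, asdict

from .lexicons import TermLexicon, TriggerLexicon

__all__ = [
    "ConceptMention",
    "segment_sentences",
    "match_terms",
    "detect_polarity",
    "assign_doc_time_rel",
    "assign_experiencer",
    "detect_section_title",
    "annotate_note",
    "is_relevant",
]

_TERMINATORS = ".!?"
_WORD_RE = re.compile(r"[A-Za-z0-9']+")

POLARITIES = ("affirmed", "negated")
DOC_TIME_RELS = ("before", "after", "overlap", "before_overlap")
EXPERIENCERS = ("patient", "family_member", "other", "null")


@dataclass
class ConceptMention:
    """A matched suicide-related term with its context attributes.

    Spans are 0-based half-open character intervals into the note text.
    """
    note_id: str
    patient_id: str
    doc_date: object
    start: int
    end: int
    text: str
    concept_id: str
    polarity: str
    doc_time_rel: str
    experiencer: str
    section_title: bool

    @property
    def relevant(self) -> bool:
        return is_relevant(self.polarity, self.doc_time_rel,
                           self.experiencer, self.section_title)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["relevant"] = self.relevant
        return d


def is_relevant(polarity: str, doc_time_rel: str, experiencer: str,
                section_title: bool) -> bool:
    """The relevance conjunction: affirmed AND temporally current AND
    patient-experienced AND not a section header."""
    return (polarity == "affirmed"
            and doc_time_rel in ("overlap", "before_overlap")
            and experiencer == "patient"
            and not section_title)


def segment_sentences(text: str) -> list[tuple[int, int]]:
    """Split text into sentence spans (0-based, half-open).

    Terminators ``. ! ?`` end a sentence (runs are absorbed into it); a
    newline ends a sentence even without terminal punctuation, so unpunctuated
    lines — the colon-negation dialect — are isolated. The spans partition the
    non-whitespace characters of the text.
    """
    spans: list[tuple[int, int]] = []
    n = len(text)
    i = 0
    start: int | None = None
    last_nonspace = -1

    def close(end: int) -> None:
        nonlocal start
        if start is not None and end > start:
            spans.append((start, end))
        start = None

    while i < n:
        c = text[i]
        if c == "\n":
            close(last_nonspace + 1)
            i += 1
            continue
        if c in _TERMINATORS:
            j = i
            while j < n and text[j] in _TERMINATORS:
                j += 1
            if start is None:
                start = i
            last_nonspace = j - 1
            close(j)
            i = j
            continue
        if not c.isspace():
            if start is None:
                start = i
            last_nonspace = i
        i += 1
    close(last_nonspace + 1)
    return spans


def match_terms(sentence: str, lexicon: TermLexicon,
                offset: int = 0) -> list[tuple[int, int, str]]:
    """Find term mentions in one sentence; longest match wins on overlaps.

    Returns (start, end, concept_id) triples in reading order, with spans
    shifted by ``offset`` (the sentence's position in the note).
    """
    raw = sorted(lexicon.finditer(sentence),
                 key=lambda m: (-(m[1] - m[0]), m[0]))
    kept: list[tuple[int, int, str]] = []
    for s, e, cid in raw:
        if all(e <= ks or s >= ke for ks, ke, _ in kept):
            kept.append((s, e, cid))
    kept.sort()
    return [(s + offset, e + offset, cid) for s, e, cid in kept]


def _token_spans(text: str) -> list[tuple[int, int]]:
    return [(m.start(), m.end()) for m in _WORD_RE.finditer(text)]


def _tokens_between(text: str, a: int, b: int) -> int:
    """Number of word tokens fully inside text[a:b]."""
    if a >= b:
        return 0
    return sum(1 for s, e in _token_spans(text) if s >= a and e <= b)


def _find_all(patterns, text: str):
    for rx in patterns:
        for m in rx.finditer(text):
            yield m.start(), m.end()


def detect_polarity(mention: tuple[int, int], sentence: str,
                    triggers: TriggerLexicon) -> str:
    """Affirmed vs. negated, sentence-local coordinates.

    Negated iff (a) a pre-negation trigger lies within ``scope_window``
    tokens before the mention with no scope-breaking conjunction between,
    (b) the mention is followed — before any other colon or sentence
    punctuation — by a colon and a negation word (the colon-structure
    dialect), or (c) a post-negation phrase ("was ruled out") follows within
    the scope window.
    """
    ms, me = mention
    window = triggers.scope_window
    # (a) pre-mention triggers
    for ts, te in _find_all(triggers.compiled("negation_pre"), sentence):
        if te > ms:
            continue
        if _tokens_between(sentence, te, ms) >= window:
            continue
        broken = any(te <= bs and be <= ms for bs, be in
                     _find_all(triggers.compiled("scope_breakers"), sentence))
        if not broken:
            return "negated"
    # (b) colon-structure negation, scoped to end of sentence
    post = sentence[me:]
    words = sorted((w for w in triggers.negation_post_colon_words),
                   key=len, reverse=True)
    if words:
        alt = "|".join(re.escape(w) for w in words)
        if re.match(rf"[^.!?\n:]{{0,40}}:\s*(?:{alt})\b", post, re.IGNORECASE):
            return "negated"
    # (c) post-mention phrase negation
    for ts, te in _find_all(triggers.compiled("negation_post"), sentence):
        if ts >= me and _tokens_between(sentence, me, ts) < window:
            return "negated"
    return "affirmed"


_CUE_CLASSES = (("history_cues", "before"),
                ("hypothetical_cues", "after"),
                ("durative_cues", "before_overlap"))


def assign_doc_time_rel(mention: tuple[int, int], sentence: str,
                        triggers: TriggerLexicon) -> str:
    """Temporal relation of the mention to the document creation time.

    Temporal cues scope the whole sentence (historical cues such as
    "when she was 14" or "in 1996" typically *follow* the mention). The cue
    nearest to the mention in token distance wins; ties prefer cues before
    the mention, then the class order historical > hypothetical > durative.
    With no cue in scope the mention overlaps document time.
    """
    ms, me = mention
    best: tuple[int, int, int, str] | None = None  # (dist, side, class_rank, value)
    for rank, (key, value) in enumerate(_CUE_CLASSES):
        for ts, te in _find_all(triggers.compiled(key), sentence):
            if te <= ms:
                cand = (_tokens_between(sentence, te, ms), 0, rank, value)
            elif ts >= me:
                cand = (_tokens_between(sentence, me, ts), 1, rank, value)
            else:
                cand = (0, 0, rank, value)
            if best is None or cand[:3] < best[:3]:
                best = cand
    return best[3] if best else "overlap"


def assign_experiencer(mention: tuple[int, int], sentence: str,
                       triggers: TriggerLexicon) -> str:
    """Who experiences the event: nearest preceding subject cue wins.

    Family cues ("mom", "father") yield family_member, third-party cues
    ("friend") yield other, explicit patient cues ("patient", "she") yield
    patient. With no resolvable subject the experiencer defaults to patient,
    matching the convention of clinical context engines.
    """
    ms, _ = mention
    best: tuple[int, str] | None = None  # (cue end, value)
    for key, value in (("family_cues", "family_member"),
                       ("other_cues", "other"),
                       ("patient_cues", "patient")):
        for ts, te in _find_all(triggers.compiled(key), sentence):
            if te <= ms and (best is None or te > best[0]):
                best = (te, value)
    return best[1] if best else "patient"


def detect_section_title(mention: tuple[int, int], sentence: str,
                         triggers: TriggerLexicon) -> bool:
    """True iff the sentence is a header line.

    A header ends with ":" and contains no finite-verb cue — it names a
    topic ("Hx of Suicidal Behavior:") rather than describing the patient.
    A line with a header prefix but a following clause ("Assessment: patient
    endorses ...") is not a header.
    """
    stripped = sentence.rstrip()
    if not stripped.endswith(":"):
        return False
    return not any(True for _ in
                   _find_all(triggers.compiled("section_verb_cues"), sentence))


def annotate_note(note, term_lexicon: TermLexicon,
                  triggers: TriggerLexicon) -> list[ConceptMention]:
    """Full cascade for one note: segment, match, then attribute assignment.

    ``note`` is a mapping with keys note_id, patient_id, doc_date, text.
    Returns one ConceptMention per surviving term match, in reading order.
    """
    text = note["text"]
    mentions: list[ConceptMention] = []
    for ss, se in segment_sentences(text):
        sentence = text[ss:se]
        for gs, ge, cid in match_terms(sentence, term_lexicon, offset=ss):
            local = (gs - ss, ge - ss)
            mentions.append(ConceptMention(
                note_id=note.get("note_id", ""),
                patient_id=note.get("patient_id", ""),
                doc_date=note.get("doc_date"),
                start=gs, end=ge, text=text[gs:ge], concept_id=cid,
                polarity=detect_polarity(local, sentence, triggers),
                doc_time_rel=assign_doc_time_rel(local, sentence, triggers),
                experiencer=assign_experiencer(local, sentence, triggers),
                section_title=detect_section_title(local, sentence, triggers),
            ))
    return mentions
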