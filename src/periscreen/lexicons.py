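"""Code, term, and trigger lexicons.

Three lexicon families drive the screening cascade:

* :class:`CodeLexicon` — diagnostic-code lists (pregnancy/delivery, suicidal
  behavior, psychiatric comorbidities) with wildcard and numeric-range
  patterns, matched against structured facts.
* :class:`TermLexicon` — surface patterns for suicide-related terms in free
  text, each mapped to a flat concept identifier (a local stand-in for a
  UMLS CUI).
* :class:`TriggerLexicon` — NegEx/ConText-style trigger words for negation,
  temporality, experiencer and section-title rules.

All three are shipped as editable plain-text defaults under
``periscreen/data`` and can be replaced by site-specific files.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "LexiconError",
    "CodeLexicon",
    "TermLexicon",
    "TriggerLexicon",
    "code_matches",
    "default_lexicon_path",
    "load_pregnancy_lexicon",
    "load_suicide_lexicon",
    "load_comorbidity_lexicons",
    "load_term_lexicon",
    "load_trigger_lexicon",
]


class LexiconError(ValueError):
    """Raised when a lexicon file is malformed (always at load time)."""


def _normalize_code(code: str) -> str:
    """Canonical form for diagnostic codes: uppercase, no dots or spaces.

    Handles dialect drift such as "V22" vs "V22.0" entry styles; wildcard
    semantics then operate on the dot-free stem.
    """
    return str(code).strip().upper().replace(".", "").replace(" ", "")


_RANGE_RE = re.compile(
    r"^(?P<pfx>[A-Z]*)(?P<lo>\d+)(?:\.\*)?-(?P=pfx)?(?P<hi>\d+)(?:\.\*)?$"
)
#: a pattern that *looks like* a numeric range but fails the strict grammar
#: (e.g. mismatched alpha prefixes) is a load-time error, not an exact code
_LOOSE_RANGE_RE = re.compile(r"^[A-Z]{0,3}\d+(?:\.\*)?-[A-Z]{0,3}\d+(?:\.\*)?$")


@dataclass(frozen=True)
class _CodePattern:
    system: str
    raw: str
    label: str
    kind: str           # "exact" | "prefix" | "range"
    stem: str = ""      # normalized prefix / exact stem
    prefix: str = ""    # alpha prefix for ranges
    lo: int = 0
    hi: int = 0
    width: int = 0      # digit width of the range bounds

    @classmethod
    def parse(cls, system: str, raw: str, label: str = "") -> "_CodePattern":
        pat = raw.strip()
        if not pat:
            raise LexiconError(f"empty pattern for system {system!r}")
        compact = pat.upper().replace(" ", "")
        m = _RANGE_RE.match(compact)
        if m:
            lo, hi = m.group("lo"), m.group("hi")
            if len(lo) != len(hi):
                raise LexiconError(f"range bounds differ in width: {raw!r}")
            if int(lo) > int(hi):
                raise LexiconError(f"inverted range: {raw!r}")
            return cls(system, raw, label, "range", prefix=m.group("pfx"),
                       lo=int(lo), hi=int(hi), width=len(lo))
        if _LOOSE_RANGE_RE.match(compact):
            raise LexiconError(f"malformed range pattern: {raw!r}")
        if pat.endswith("*"):
            stem = _normalize_code(pat.rstrip("*"))
            if not stem:
                raise LexiconError(f"wildcard with empty stem: {raw!r}")
            return cls(system, raw, label, "prefix", stem=stem)
        return cls(system, raw, label, "exact", stem=_normalize_code(pat))

    def match_array(self, norm_codes: np.ndarray) -> np.ndarray:
        """Vectorized match against an array of normalized codes."""
        codes = norm_codes.astype(str)
        if self.kind == "exact":
            return codes == self.stem
        if self.kind == "prefix":
            return np.char.startswith(codes, self.stem)
        # range: strip the alpha prefix, compare the leading `width` digits
        out = np.zeros(codes.shape, dtype=bool)
        for i, c in enumerate(codes):
            if self.prefix:
                if not c.startswith(self.prefix):
                    continue
                c = c[len(self.prefix):]
            digits = re.match(r"\d+", c)
            if not digits or len(digits.group()) < self.width:
                continue
            out[i] = self.lo <= int(digits.group()[: self.width]) <= self.hi
        return out

    def match_one(self, code: str) -> bool:
        return bool(self.match_array(np.array([_normalize_code(code)]))[0])


@dataclass
class CodeLexicon:
    """A named list of (system, code-pattern) entries.

    Patterns support three forms, validated at load time:

    * exact codes ("V62.84"),
    * trailing wildcards ("V22.*" matches "V22" and "V22.1"),
    * numeric ranges ("640.*-679.*" matches any code whose leading digit
      stem of the bounds' width falls in the closed interval; "370-384"
      covers DRGs inclusively; "O0.*-O9.*" compares the first digit after
      the shared alpha prefix).
    """

    name: str
    patterns: list[_CodePattern] = field(default_factory=list)

    @classmethod
    def from_entries(cls, name: str,
                     entries: Iterable[tuple[str, str] | tuple[str, str, str]]
                     ) -> "CodeLexicon":
        pats: list[_CodePattern] = []
        seen: set[tuple[str, str]] = set()
        for entry in entries:
            system, pattern = entry[0], entry[1]
            label = entry[2] if len(entry) > 2 else ""
            key = (system.upper(), pattern)
            if key in seen:
                raise LexiconError(f"duplicate entry {key} in lexicon {name!r}")
            seen.add(key)
            pats.append(_CodePattern.parse(system.upper(), pattern, label))
        return cls(name, pats)

    @classmethod
    def from_file(cls, path: str | Path, name: str | None = None) -> "CodeLexicon":
        df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
        required = {"system", "pattern"}
        if not required.issubset(df.columns):
            raise LexiconError(f"{path}: expected columns {sorted(required)}")
        label = df["label"] if "label" in df.columns else [""] * len(df)
        return cls.from_entries(name or Path(path).stem,
                                zip(df["system"], df["pattern"], label))

    def matches(self, system: str, code: str) -> bool:
        system = system.upper()
        return any(p.system == system and p.match_one(code)
                   for p in self.patterns)

    def match_frame(self, facts: pd.DataFrame) -> pd.Series:
        """Boolean Series: does each fact row match any lexicon pattern?

        Expects columns ``system`` and ``code``.
        """
        norm = facts["code"].astype(str).map(_normalize_code).to_numpy()
        systems = facts["system"].astype(str).str.upper().to_numpy()
        out = np.zeros(len(facts), dtype=bool)
        for pat in self.patterns:
            sel = systems == pat.system
            if sel.any():
                out[sel] |= pat.match_array(norm[sel])
        return pd.Series(out, index=facts.index, name=self.name)


def code_matches(fact, lexicon: CodeLexicon) -> bool:
    """True iff the fact's code matches any pattern registered for its system.

    ``fact`` may be a mapping/namedtuple/Series with ``system`` and ``code``.
    """
    system = fact["system"] if isinstance(fact, (dict, pd.Series)) else fact.system
    code = fact["code"] if isinstance(fact, (dict, pd.Series)) else fact.code
    return lexicon.matches(system, code)


# ---------------------------------------------------------------------------
# term lexicon

@dataclass
class TermLexicon:
    """Case-insensitive word-boundary surface patterns -> concept ids."""

    entries: list[tuple[str, str, str]]              # (pattern, concept_id, label)
    _compiled: list[tuple[re.Pattern, str]] = field(default_factory=list, repr=False)

    def __post_init__(self) -> None:
        seen = set()
        self._compiled = []
        for pattern, concept_id, _label in self.entries:
            if not concept_id:
                raise LexiconError(f"empty concept_id for pattern {pattern!r}")
            key = (pattern, concept_id)
            if key in seen:
                raise LexiconError(f"duplicate term entry {key}")
            seen.add(key)
            try:
                rx = re.compile(rf"\b(?:{pattern})\b", re.IGNORECASE)
            except re.error as exc:
                raise LexiconError(f"bad term pattern {pattern!r}: {exc}") from exc
            self._compiled.append((rx, concept_id))

    @classmethod
    def from_file(cls, path: str | Path) -> "TermLexicon":
        df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
        if not {"pattern", "concept_id"}.issubset(df.columns):
            raise LexiconError(f"{path}: expected columns pattern, concept_id")
        label = df["label"] if "label" in df.columns else [""] * len(df)
        return cls(list(zip(df["pattern"], df["concept_id"], label)))

    def finditer(self, text: str):
        for rx, concept_id in self._compiled:
            for m in rx.finditer(text):
                yield m.start(), m.end(), concept_id


# ---------------------------------------------------------------------------
# trigger lexicon

_TRIGGER_KEYS = (
    "negation_pre", "scope_breakers", "negation_post_colon_words",
    "negation_post", "history_cues", "hypothetical_cues", "durative_cues",
    "family_cues", "other_cues", "patient_cues", "section_verb_cues",
)


@dataclass
class TriggerLexicon:
    """Trigger patterns for the context rules, compiled at construction."""

    scope_window: int = 6
    negation_pre: Sequence[str] = ()
    scope_breakers: Sequence[str] = ()
    negation_post_colon_words: Sequence[str] = ()
    negation_post: Sequence[str] = ()
    history_cues: Sequence[str] = ()
    hypothetical_cues: Sequence[str] = ()
    durative_cues: Sequence[str] = ()
    family_cues: Sequence[str] = ()
    other_cues: Sequence[str] = ()
    patient_cues: Sequence[str] = ()
    section_verb_cues: Sequence[str] = ()

    def __post_init__(self) -> None:
        if self.scope_window < 1:
            raise LexiconError("scope_window must be >= 1")
        self._compiled: dict[str, list[re.Pattern]] = {}
        for key in _TRIGGER_KEYS:
            pats = []
            for raw in getattr(self, key):
                try:
                    pats.append(re.compile(rf"\b(?:{raw})\b", re.IGNORECASE))
                except re.error as exc:
                    raise LexiconError(f"bad trigger {raw!r} in {key}: {exc}") from exc
            self._compiled[key] = pats

    def compiled(self, key: str) -> list[re.Pattern]:
        return self._compiled[key]

    @classmethod
    def from_file(cls, path: str | Path) -> "TriggerLexicon":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        kwargs = {k: [str(p) for p in raw.get(k, [])] for k in _TRIGGER_KEYS}
        return cls(scope_window=int(raw.get("scope_window", 6)), **kwargs)


# ---------------------------------------------------------------------------
# bundled defaults

def default_lexicon_path(filename: str) -> Path:
    return Path(resources.files("periscreen") / "data" / filename)


def load_pregnancy_lexicon() -> CodeLexicon:
    return CodeLexicon.from_file(default_lexicon_path("pregnancy_codes.tsv"),
                                 name="pregnancy")


def load_suicide_lexicon() -> CodeLexicon:
    return CodeLexicon.from_file(default_lexicon_path("suicide_codes.tsv"),
                                 name="suicidal_behavior")


def load_comorbidity_lexicons() -> dict[str, CodeLexicon]:
    """One CodeLexicon per psychiatric condition, keyed by condition name."""
    path = default_lexicon_path("comorbidity_codes.tsv")
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    out: dict[str, CodeLexicon] = {}
    for cond, sub in df.groupby("condition", sort=True):
        out[cond] = CodeLexicon.from_entries(
            cond, list(zip(sub["system"], sub["pattern"])))
    return out


def load_term_lexicon() -> TermLexicon:
    return TermLexicon.from_file(default_lexicon_path("terms.tsv"))


def load_trigger_lexicon() -> TriggerLexicon:
    return TriggerLexicon.from_file(default_lexicon_path("triggers.yaml"))
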