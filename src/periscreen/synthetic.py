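"""Synthetic EMR generator with planted ground truth.

Emulates the structured + unstructured datamart the screen runs on: a
cohort of women aged 10-64 with pregnancy/delivery codes, a rare suicidal
behavior phenotype (a few percent) documented sometimes as diagnostic
codes, sometimes only in clinical notes, and notes mixing affirmed,
negated (including colon-structure), historical, hypothetical,
family-member and section-title mentions from the template library.

The generator plants ground truth at two levels:

* per patient — ``true_case`` (has suicidal behavior in a perinatal
  window), the label a chart reviewer would assign;
* per mention — every rendered template mention carries its known context
  attributes (``gt_mentions``), so the rule engine is exactly gradeable.

Documentation behavior is controlled by four probabilities: the two
sensitivities (probability a true case is documented by an in-window code,
resp. an in-window relevant note) and the two planted chart-review PPVs
(fraction of code-positive, resp. notes-positive, women who are true
cases). The corresponding false-positive documentation rates among
non-cases are derived in closed form, so realized group PPVs match the
planted values in expectation.

Identical (config, seed) give byte-identical output.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .templates import (TEMPLATES, RELEVANT_TEMPLATE_IDS,
                        IRRELEVANT_TEMPLATE_IDS, FILLER_SENTENCES,
                        get_template)

__all__ = ["CohortConfig", "generate_cohort", "render_note",
           "write_cohort", "read_notes"]

_RACES = (("White", 0.44), ("Hispanic", 0.30), ("Black", 0.19),
          ("Asian", 0.03), ("Other", 0.04))
_LANGS = (("English", 0.85), ("Spanish", 0.12), ("Other", 0.03))
_MARITAL = (("Single", 0.68), ("Married", 0.26), ("Separated", 0.04),
            ("Other", 0.02))
_INSURANCE = (("Medicaid", 0.45), ("Private", 0.41), ("Medicare", 0.07),
              ("Self-pay", 0.03), ("Other", 0.04))

_PREGNANCY_CODES = (("ICD9", "V22.1"), ("ICD10", "Z3A.21"), ("ICD10", "O26.9"),
                    ("ICD9", "646.8"))
_DELIVERY_CODES = (("ICD9", "V27.0"), ("ICD10", "O80"), ("DRG", "375"))
_SUICIDE_CODES = (("ICD9", "E950.0"), ("ICD9", "E950.3"), ("ICD9", "V62.84"),
                  ("ICD9", "969.4"), ("ICD10", "T14.91"))
_BENIGN_CODES = (("ICD9", "401.9"), ("ICD9", "250.00"), ("ICD10", "J06.9"),
                 ("ICD10", "Z00.00"), ("ICD9", "780.79"), ("ICD10", "M54.5"))
_COMORBID_CODES = {
    "depression": (("ICD9", "311"), ("ICD10", "F32.9")),
    "schizophrenia": (("ICD9", "295.90"), ("ICD10", "F20.9")),
    "bipolar": (("ICD9", "296.40"), ("ICD10", "F31.9")),
    "ptsd": (("ICD9", "309.81"), ("ICD10", "F43.10")),
    "substance_abuse": (("ICD9", "305.00"), ("ICD10", "F10.10")),
    "anxiety": (("ICD9", "300.00"), ("ICD10", "F41.9")),
}


@dataclass
class CohortConfig:
    """Data-generating conditions for one synthetic cohort."""

    n_patients: int = 5000
    prevalence_true_case: float = 0.02
    #: P(in-window suicidality code | true case)
    code_documentation_sensitivity: float = 0.5
    #: P(in-window relevant note | true case)
    note_documentation_sensitivity: float = 0.9
    #: planted chart-review PPV of the diagnostic-codes group
    code_ppv: float = 0.76
    #: planted chart-review PPV of the notes-screen-positive group
    note_ppv: float = 0.30
    #: P(note with only non-relevant template mentions | no relevant note)
    irrelevant_note_rate: float = 0.18
    #: weights over irrelevant templates for noise notes
    template_mix: dict = field(default_factory=dict)
    #: Poisson mean of filler-only notes per patient
    notes_per_patient: float = 1.0
    #: Poisson mean of background (non-pregnancy) facts per patient
    facts_per_patient: float = 20.0
    observation_window: tuple[str, str] = ("1996-01-01", "2016-03-31")
    employee_rate: float = 0.102
    comorbidity_rate_case: float = 0.5
    comorbidity_rate_noncase: float = 0.12
    age_range: tuple[int, int] = (10, 64)
    seed: int = 0

    def __post_init__(self) -> None:
        fracs = dict(
            prevalence_true_case=self.prevalence_true_case,
            code_documentation_sensitivity=self.code_documentation_sensitivity,
            note_documentation_sensitivity=self.note_documentation_sensitivity,
            code_ppv=self.code_ppv, note_ppv=self.note_ppv,
            irrelevant_note_rate=self.irrelevant_note_rate,
            employee_rate=self.employee_rate,
            comorbidity_rate_case=self.comorbidity_rate_case,
            comorbidity_rate_noncase=self.comorbidity_rate_noncase)
        for name, v in fracs.items():
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.n_patients < 1:
            raise ValueError("n_patients must be positive")
        mix = self.template_mix or {t: 1.0 for t in IRRELEVANT_TEMPLATE_IDS}
        unknown = set(mix) - set(TEMPLATES)
        if unknown:
            raise ValueError(f"unknown template ids in mix: {sorted(unknown)}")
        if any(w < 0 for w in mix.values()) or sum(mix.values()) <= 0:
            raise ValueError("template weights must be nonnegative, sum > 0")
        self.template_mix = mix

    # closed-form false-positive documentation rates among non-cases ------
    @property
    def code_false_positive_rate(self) -> float:
        p, cs, cp = (self.prevalence_true_case,
                     self.code_documentation_sensitivity, self.code_ppv)
        if p in (0.0, 1.0) or cs == 0.0 or cp == 0.0:
            return 0.0
        return min(1.0, p * cs * (1.0 - cp) / ((1.0 - p) * cp))

    @property
    def note_false_positive_rate(self) -> float:
        p, cs, ns = (self.prevalence_true_case,
                     self.code_documentation_sensitivity,
                     self.note_documentation_sensitivity)
        if p in (0.0, 1.0) or ns == 0.0 or self.note_ppv == 0.0:
            return 0.0
        f = self.code_false_positive_rate
        no_code_true = p * (1.0 - cs)
        no_code_non = (1.0 - p) * (1.0 - f)
        if no_code_true + no_code_non == 0:
            return 0.0
        prev_nc = no_code_true / (no_code_true + no_code_non)
        if prev_nc == 1.0:
            return 0.0
        return min(1.0, prev_nc * ns * (1.0 - self.note_ppv)
                   / ((1.0 - prev_nc) * self.note_ppv))

    def to_dict(self) -> dict:
        return asdict(self)


def _choice(rng, items_weights):
    items = [i for i, _ in items_weights]
    w = np.array([w for _, w in items_weights], dtype=float)
    return items[rng.choice(len(items), p=w / w.sum())]


def render_note(template_id: str, concept_id: str | None = None,
                doc_date="2010-06-15", seed: int = 0,
                patient_id: str = "P000000", note_id: str = "N0") -> dict:
    """Render a single-template note with its ground-truth mentions.

    The note wraps the template sentence in one or two filler sentences
    chosen under ``seed``; ground-truth spans are offset accordingly.
    ``concept_id``, when given, must be among the template's concepts.
    """
    template = get_template(template_id)
    if concept_id is not None:
        cids = {gt.concept_id for gt in template.mentions}
        if concept_id not in cids:
            raise KeyError(f"template {template_id!r} has concepts "
                           f"{sorted(cids)}, not {concept_id!r}")
    rng = np.random.default_rng(seed)
    return _compose_note([template_id], doc_date, rng, patient_id, note_id,
                         n_filler=int(rng.integers(1, 3)))


def _compose_note(template_ids, doc_date, rng, patient_id, note_id,
                  n_filler: int = 1) -> dict:
    """Join filler and template sentences on newlines; track gt spans."""
    fillers = [FILLER_SENTENCES[i] for i in
               rng.choice(len(FILLER_SENTENCES), size=n_filler, replace=False)]
    # template sentences interleaved after the fillers, in drawn order
    parts: list[tuple[str, str | None]] = [(f, None) for f in fillers]
    parts += [(get_template(t).text, t) for t in template_ids]
    text_parts: list[str] = []
    gts: list[dict] = []
    offset = 0
    for sent, tid in parts:
        if tid is not None:
            gts.extend(g.to_dict()
                       for g in get_template(tid).ground_truth(offset))
        text_parts.append(sent)
        offset += len(sent) + 1  # newline separator
    text = "\n".join(text_parts)
    for g in gts:  # invariant: every gt span lies within text bounds
        assert 0 <= g["start"] < g["end"] <= len(text)
    return {"note_id": note_id, "patient_id": patient_id,
            "doc_date": pd.Timestamp(doc_date), "text": text,
            "gt_mentions": gts}


def generate_cohort(config: CohortConfig
                    ) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Generate (patients, facts, notes) tables with planted ground truth.

    Every patient has 1-3 pregnancy episodes of 182-301 days inside the
    observation window, with pregnancy codes at episode start, midpoint and
    end (the final code a delivery/abortion code). Suicidality evidence is
    planted per the sensitivity and planted-PPV knobs; all of it falls
    inside a perinatal window.
    """
    rng = np.random.default_rng(config.seed)
    w0 = pd.Timestamp(config.observation_window[0])
    w1 = pd.Timestamp(config.observation_window[1])
    total_days = (w1 - w0).days

    f_code = config.code_false_positive_rate
    q_note = config.note_false_positive_rate
    mix = sorted(config.template_mix.items())

    patients, facts, notes = [], [], []
    note_counter = 0
    for i in range(config.n_patients):
        pid = f"P{i:06d}"
        true_case = rng.random() < config.prevalence_true_case

        # --- pregnancy episodes -----------------------------------------
        n_ep = int(rng.integers(1, 4))
        lengths = rng.integers(182, 302, size=n_ep)
        gaps = rng.integers(200, 1001, size=n_ep)
        span = int(lengths.sum() + gaps[:-1].sum()) if n_ep else 0
        start0 = int(rng.integers(0, max(1, total_days - span - 43)))
        episodes = []
        day = start0
        for k in range(n_ep):
            episodes.append((day, day + int(lengths[k])))
            day += int(lengths[k]) + int(gaps[k])

        age_first = int(rng.integers(15, 45))
        birth = (w0 + pd.Timedelta(days=start0)
                 - pd.Timedelta(days=int(age_first * 365.25
                                         + rng.integers(0, 365))))

        patients.append({
            "patient_id": pid,
            "birth_date": birth.normalize(),
            "race": _choice(rng, _RACES),
            "ethnicity": "Hispanic" if rng.random() < 0.30 else "Non-Hispanic",
            "language": _choice(rng, _LANGS),
            "marital_status": _choice(rng, _MARITAL),
            "insurance": _choice(rng, _INSURANCE),
            "employee_flag": bool(rng.random() < config.employee_rate),
            "true_case": bool(true_case),
            "vital_status": "Deceased" if rng.random() < 0.02 else "Alive",
        })

        def add_fact(day_offset, system, code, clinic="other",
                     inpatient="outpatient"):
            # day offsets are converted to dates in one vectorized pass below
            facts.append((pid, int(day_offset), system, code, clinic,
                          inpatient))

        for es, ee in episodes:
            # prenatal visits every ~8 weeks from onset to term, then the
            # delivery/abortion code; visit spacing stays under the default
            # episode-merge gap so windowing reconstructs the full interval
            day_k = es
            while day_k < ee:
                code = _PREGNANCY_CODES[int(rng.integers(0, len(_PREGNANCY_CODES)))]
                add_fact(day_k, *code, clinic="Obstetrics")
                day_k += int(rng.integers(56, 71))
            end = _DELIVERY_CODES[int(rng.integers(0, len(_DELIVERY_CODES)))]
            add_fact(ee, *end, clinic="Obstetrics", inpatient="inpatient")

        n_bg = int(rng.poisson(config.facts_per_patient))
        for _ in range(n_bg):
            sys_code = _BENIGN_CODES[int(rng.integers(0, len(_BENIGN_CODES)))]
            add_fact(rng.integers(0, total_days + 1), *sys_code)
        com_rate = (config.comorbidity_rate_case if true_case
                    else config.comorbidity_rate_noncase)
        for cond, codes in _COMORBID_CODES.items():
            if rng.random() < com_rate:
                sys_code = codes[int(rng.integers(0, len(codes)))]
                add_fact(rng.integers(0, total_days + 1), *sys_code,
                         clinic="Psychiatry")

        def window_day():
            es, ee = episodes[int(rng.integers(0, len(episodes)))]
            return int(rng.integers(es, ee + 43))

        # --- planted suicidality evidence -------------------------------
        has_code = rng.random() < (config.code_documentation_sensitivity
                                   if true_case else f_code)
        if has_code:
            sys_code = _SUICIDE_CODES[int(rng.integers(0, len(_SUICIDE_CODES)))]
            add_fact(window_day(), *sys_code,
                     clinic="Emergency" if rng.random() < 0.6 else "Psychiatry",
                     inpatient="inpatient" if rng.random() < 0.4 else "outpatient")

        has_rel_note = rng.random() < (config.note_documentation_sensitivity
                                       if true_case else q_note)
        if has_rel_note:
            n_rel = int(rng.integers(1, 3))
            n_irr = int(rng.integers(0, 2))
            tids = [RELEVANT_TEMPLATE_IDS[j] for j in
                    rng.integers(0, len(RELEVANT_TEMPLATE_IDS), size=n_rel)]
            tids += [_choice(rng, mix) for _ in range(n_irr)]
            notes.append(_compose_note(
                tids, w0 + pd.Timedelta(days=window_day()), rng, pid,
                f"N{note_counter:07d}", n_filler=int(rng.integers(1, 3))))
            note_counter += 1
        elif rng.random() < config.irrelevant_note_rate:
            tids = [_choice(rng, mix) for _ in range(int(rng.integers(1, 3)))]
            notes.append(_compose_note(
                tids, w0 + pd.Timedelta(days=window_day()), rng, pid,
                f"N{note_counter:07d}", n_filler=int(rng.integers(1, 3))))
            note_counter += 1

        for _ in range(int(rng.poisson(config.notes_per_patient))):
            notes.append(_compose_note(
                [], w0 + pd.Timedelta(days=int(rng.integers(0, total_days + 1))),
                rng, pid, f"N{note_counter:07d}",
                n_filler=int(rng.integers(1, 4))))
            note_counter += 1

    patients_df = pd.DataFrame(patients)
    facts_df = pd.DataFrame(facts, columns=["patient_id", "day", "system",
                                            "code", "clinic", "inpatient_flag"])
    facts_df["date"] = w0 + pd.to_timedelta(facts_df.pop("day"), unit="D")
    facts_df = facts_df[["patient_id", "date", "system", "code", "clinic",
                         "inpatient_flag"]]
    notes_df = pd.DataFrame(notes,
                            columns=["note_id", "patient_id", "doc_date",
                                     "text", "gt_mentions"])
    return patients_df, facts_df, notes_df


# ---------------------------------------------------------------------------
# writers / readers (delimited tables + JSON-lines notes)

def write_cohort(patients: pd.DataFrame, facts: pd.DataFrame,
                 notes: pd.DataFrame, outdir: str | Path,
                 config: CohortConfig | None = None) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    p = patients.copy()
    p["birth_date"] = pd.to_datetime(p["birth_date"]).dt.strftime("%Y-%m-%d")
    p.to_csv(outdir / "patients.tsv", sep="\t", index=False)
    f = facts.copy()
    f["date"] = pd.to_datetime(f["date"]).dt.strftime("%Y-%m-%d")
    f.to_csv(outdir / "facts.tsv", sep="\t", index=False)
    with open(outdir / "notes.jsonl", "w") as fh:
        for rec in notes.to_dict("records"):
            rec = dict(rec)
            rec["doc_date"] = pd.Timestamp(rec["doc_date"]).strftime("%Y-%m-%d")
            fh.write(json.dumps(rec) + "\n")
    if config is not None:
        cfg = config.to_dict()
        with open(outdir / "config.yaml", "w") as fh:
            yaml.safe_dump(cfg, fh, sort_keys=True)


def read_notes(path: str | Path) -> pd.DataFrame:
    rows = []
    with open(path) as fh:
        for line in fh:
            if line.strip():
                rec = json.loads(line)
                rec["doc_date"] = pd.Timestamp(rec["doc_date"])
                rec.setdefault("gt_mentions", [])
                rows.append(rec)
    return pd.DataFrame(rows, columns=["note_id", "patient_id", "doc_date",
                                       "text", "gt_mentions"])
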