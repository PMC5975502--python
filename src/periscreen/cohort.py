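"""Pregnancy datamart construction and perinatal windowing.

The base cohort ("datamart") is every woman aged 10-64 (inclusive, completed
years) at the date of at least one pregnancy- or delivery-related diagnostic
code. Pregnancy episodes are inferred by merging consecutive pregnancy-code
facts separated by at most ``gap_days``; each episode opens a perinatal
window running from the episode start through 42 days after its end (both
boundaries inclusive), the eligibility period for suicidality evidence.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .lexicons import CodeLexicon

__all__ = [
    "PregnancyEpisode",
    "IntegrityError",
    "POSTPARTUM_DAYS",
    "age_at",
    "build_datamart",
    "infer_episodes",
    "infer_episodes_frame",
    "in_perinatal_window",
]

#: days after delivery or abortion still counted as perinatal
POSTPARTUM_DAYS = 42


class IntegrityError(ValueError):
    """A fact references a patient absent from the patient table."""


@dataclass(frozen=True)
class PregnancyEpisode:
    patient_id: str
    start_date: pd.Timestamp
    end_date: pd.Timestamp

    def __post_init__(self) -> None:
        if self.start_date > self.end_date:
            raise ValueError("episode start after end")

    @property
    def window_end(self) -> pd.Timestamp:
        return self.end_date + pd.Timedelta(days=POSTPARTUM_DAYS)


def age_at(birth_date: pd.Timestamp, date: pd.Timestamp) -> int:
    """Age in completed years at ``date``."""
    birth_date = pd.Timestamp(birth_date)
    date = pd.Timestamp(date)
    age = date.year - birth_date.year
    if (date.month, date.day) < (birth_date.month, birth_date.day):
        age -= 1
    return age


def build_datamart(patients: pd.DataFrame, facts: pd.DataFrame,
                   pregnancy_lexicon: CodeLexicon,
                   age_range: tuple[int, int] = (10, 64)) -> pd.DataFrame:
    """Return the patients with >=1 pregnancy code at an eligible age.

    Eligibility: at least one fact matching the pregnancy lexicon dated when
    the patient's completed-years age lies in ``age_range`` (both ends
    inclusive). Output row order follows the patient table; the result is
    invariant to the ordering of ``facts``.
    """
    if facts.empty:
        return patients.iloc[0:0].copy()
    unknown = set(facts["patient_id"]) - set(patients["patient_id"])
    if unknown:
        raise IntegrityError(
            f"facts reference unknown patient(s): {sorted(unknown)[:5]}")
    preg = facts.loc[pregnancy_lexicon.match_frame(facts)]
    if preg.empty:
        return patients.iloc[0:0].copy()
    lo, hi = age_range
    birth = patients.set_index("patient_id")["birth_date"]
    merged = preg.merge(birth.rename("birth_date"), left_on="patient_id",
                        right_index=True)
    ages = [age_at(b, d) for b, d in zip(merged["birth_date"], merged["date"])]
    ok = merged.loc[[lo <= a <= hi for a in ages], "patient_id"].unique()
    return patients[patients["patient_id"].isin(set(ok))].copy()


def infer_episodes(patient_facts: pd.DataFrame,
                   pregnancy_lexicon: CodeLexicon,
                   gap_days: int = 90) -> list[PregnancyEpisode]:
    """Merge one patient's pregnancy-code facts into episodes.

    Consecutive pregnancy-code dates separated by <= ``gap_days`` belong to
    the same episode; the episode spans the first through last such date.
    Episodes are non-overlapping and chronologically ordered. Zero pregnancy
    facts give an empty list; a single fact gives a zero-length episode.
    """
    if patient_facts.empty:
        return []
    pids = patient_facts["patient_id"].unique()
    if len(pids) != 1:
        raise ValueError("infer_episodes expects facts for a single patient")
    preg = patient_facts.loc[pregnancy_lexicon.match_frame(patient_facts)]
    if preg.empty:
        return []
    dates = sorted(pd.to_datetime(preg["date"]))
    episodes: list[PregnancyEpisode] = []
    start = prev = dates[0]
    for d in dates[1:]:
        if (d - prev).days <= gap_days:
            prev = d
        else:
            episodes.append(PregnancyEpisode(pids[0], start, prev))
            start = prev = d
    episodes.append(PregnancyEpisode(pids[0], start, prev))
    return episodes


def infer_episodes_frame(facts: pd.DataFrame, pregnancy_lexicon: CodeLexicon,
                         gap_days: int = 90,
                         postpartum_days: int = POSTPARTUM_DAYS) -> pd.DataFrame:
    """Vectorised multi-patient episode inference.

    Returns a DataFrame (patient_id, start_date, end_date, window_end) with
    the same merge semantics as :func:`infer_episodes`.
    """
    preg = facts.loc[pregnancy_lexicon.match_frame(facts),
                     ["patient_id", "date"]].copy()
    if preg.empty:
        return pd.DataFrame(
            columns=["patient_id", "start_date", "end_date", "window_end"])
    preg["date"] = pd.to_datetime(preg["date"])
    preg = preg.sort_values(["patient_id", "date"], kind="mergesort")
    gap = preg.groupby("patient_id")["date"].diff().dt.days
    new_episode = gap.isna() | (gap > gap_days)
    preg["episode"] = new_episode.cumsum()
    out = preg.groupby(["patient_id", "episode"], sort=True).agg(
        start_date=("date", "first"), end_date=("date", "last")).reset_index()
    out["window_end"] = out["end_date"] + pd.Timedelta(days=postpartum_days)
    return out.drop(columns="episode")


def in_perinatal_window(date, episodes) -> bool:
    """True iff ``date`` falls inside any episode's perinatal window.

    The window is [start_date, end_date + 42 days], both ends inclusive
    ("during pregnancy, or within 42 days after abortion or delivery").
    ``episodes`` may be PregnancyEpisode objects or frame rows with
    start_date / window_end fields.
    """
    date = pd.Timestamp(date)
    for ep in episodes:
        start = ep.start_date if hasattr(ep, "start_date") else ep["start_date"]
        wend = ep.window_end if hasattr(ep, "window_end") else ep["window_end"]
        if pd.Timestamp(start) <= date <= pd.Timestamp(wend):
            return True
    return False
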