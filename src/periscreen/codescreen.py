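"""Structured-data arm: suicidality diagnostic codes in perinatal windows."""

from __future__ import annotations

import pandas as pd

from .lexicons import CodeLexicon

__all__ = ["screen_codes"]


def screen_codes(datamart: pd.DataFrame, facts: pd.DataFrame,
                 suicide_lexicon: CodeLexicon,
                 episodes: pd.DataFrame) -> pd.DataFrame:
    """Flag suicidality codes, ever and within a perinatal window.

    Returns one row per datamart patient with columns ``any_suicide_code``
    (>=1 matching fact at any time), ``in_window_suicide_code`` (>=1 matching
    fact inside some perinatal window) and ``first_event_date`` (earliest
    in-window event, NaT when none). ``in_window_suicide_code`` implies
    ``any_suicide_code``.
    """
    pids = datamart["patient_id"]
    out = pd.DataFrame({
        "patient_id": pids,
        "any_suicide_code": False,
        "in_window_suicide_code": False,
        "first_event_date": pd.NaT,
    }).set_index("patient_id")

    f = facts[facts["patient_id"].isin(set(pids))]
    if not f.empty:
        sui = f.loc[suicide_lexicon.match_frame(f), ["patient_id", "date"]].copy()
        if not sui.empty:
            sui["date"] = pd.to_datetime(sui["date"])
            out.loc[sui["patient_id"].unique(), "any_suicide_code"] = True
            if not episodes.empty:
                joined = sui.merge(episodes, on="patient_id")
                hit = joined[(joined["date"] >= joined["start_date"])
                             & (joined["date"] <= joined["window_end"])]
                if not hit.empty:
                    first = hit.groupby("patient_id")["date"].min()
                    out.loc[first.index, "in_window_suicide_code"] = True
                    out.loc[first.index, "first_event_date"] = first
    return out.reset_index()
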