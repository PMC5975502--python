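"""Per-woman relevance proportions and cascade group assignment.

Each sampled woman's screen statistic is the fraction of her suicide-concept
mentions inside a perinatal window that are relevant (affirmed, temporally
current, patient-experienced, not a section title). Women at or above the
threshold (default 0.25, boundary inclusive) screen positive on the notes
arm. Proportions are carried as exact rationals so the 0.25 boundary is
never a float artifact.

Cascade groups partition the population: a perinatal suicidality code wins
over everything (diagnostic_codes); otherwise sampled women with in-window
term mentions split into nlp_positive / nlp_not_relevant by the threshold;
sampled women with no mentions are no_term_mentions; everyone else is
outside_sample.
"""

from __future__ import annotations

from fractions import Fraction

import pandas as pd

__all__ = [
    "GROUPS",
    "relevance_proportion",
    "apply_threshold",
    "assign_cascade",
]

GROUPS = ("diagnostic_codes", "nlp_positive", "nlp_not_relevant",
          "no_term_mentions", "outside_sample")


def relevance_proportion(n_relevant: int, n_mentions: int) -> Fraction:
    """Exact n_relevant / n_mentions; undefined (ValueError) at 0 mentions."""
    if n_mentions < 1:
        raise ValueError("relevance proportion undefined with zero mentions")
    if not 0 <= n_relevant <= n_mentions:
        raise ValueError("n_relevant must lie in [0, n_mentions]")
    return Fraction(n_relevant, n_mentions)


def apply_threshold(proportion: Fraction | float, threshold=Fraction(1, 4)) -> bool:
    """Screen-positive iff proportion >= threshold (inclusive boundary)."""
    threshold = Fraction(threshold).limit_denominator(10**9) \
        if not isinstance(threshold, Fraction) else threshold
    if not 0 <= threshold <= 1:
        raise ValueError("threshold must lie in [0, 1]")
    return Fraction(proportion).limit_denominator(10**9) >= threshold \
        if not isinstance(proportion, Fraction) else proportion >= threshold


def assign_cascade(code_results: pd.DataFrame, sample_ids,
                   mention_counts: pd.DataFrame,
                   threshold=Fraction(1, 4)) -> pd.DataFrame:
    """Assign every woman her cascade group.

    Parameters
    ----------
    code_results : output of :func:`periscreen.codescreen.screen_codes`
        (patient_id, any_suicide_code, in_window_suicide_code, ...).
    sample_ids : iterable of patient_ids in the matched notes-arm sample.
    mention_counts : per-patient in-window mention tallies with columns
        (patient_id, n_mentions_window, n_relevant); patients absent from
        this table have zero in-window mentions.
    threshold : relevance-proportion cut, inclusive.

    Returns one row per code_results patient with columns patient_id,
    n_mentions_window, n_relevant, relevance_proportion (NaN when
    undefined) and group.
    """
    if not 0 <= Fraction(threshold) <= 1:
        raise ValueError("threshold must lie in [0, 1]")
    dup = mention_counts["patient_id"].duplicated()
    if dup.any():
        raise ValueError("duplicate patient in mention_counts: "
                         f"{mention_counts.loc[dup, 'patient_id'].iloc[0]}")
    sample = set(sample_ids)
    counts = mention_counts.set_index("patient_id")
    rows = []
    for rec in code_results.itertuples(index=False):
        pid = rec.patient_id
        n_m = int(counts["n_mentions_window"].get(pid, 0))
        n_r = int(counts["n_relevant"].get(pid, 0))
        prop = relevance_proportion(n_r, n_m) if n_m else None
        if rec.in_window_suicide_code:
            group = "diagnostic_codes"
        elif pid in sample:
            if n_m == 0:
                group = "no_term_mentions"
            elif apply_threshold(prop, threshold):
                group = "nlp_positive"
            else:
                group = "nlp_not_relevant"
        else:
            group = "outside_sample"
        rows.append((pid, n_m, n_r,
                     float(prop) if prop is not None else float("nan"), group))
    return pd.DataFrame(rows, columns=[
        "patient_id", "n_mentions_window", "n_relevant",
        "relevance_proportion", "group"])
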