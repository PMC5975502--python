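"""Matched sampling of screen-negative comparison groups.

The notes arm runs on a 1:30 sample of women without any suicidality code,
matched to the code-positive group on age (10-year bins), race and
comparative health; the reference group is a 1:100 sample matched on
comparative health only. Comparative health — the total count of structured
facts per patient — is a healthcare-utilization proxy, matched on quantile
bins of the pool distribution.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "MatchSpec",
    "comparative_health",
    "age_bin_10y",
    "ch_quantile_bin",
    "draw_matched_sample",
    "exclude_employees",
]


@dataclass
class MatchSpec:
    """Controls-per-case ratio and the ordered matching variables.

    ``variables`` may contain ``age_bin_10y``, ``race`` and
    ``comparative_health_bin``; comparative health is binned into
    ``ch_bins`` quantile bins of the pool distribution. Sampling is always
    without replacement.
    """
    ratio: int
    variables: tuple[str, ...] = ("age_bin_10y", "race", "comparative_health_bin")
    ch_bins: int = 10
    seed: int = 0
    without_replacement: bool = field(default=True, init=True)

    def __post_init__(self) -> None:
        if self.ratio < 1:
            raise ValueError("ratio must be >= 1")
        if self.ch_bins < 1:
            raise ValueError("ch_bins must be >= 1")
        if not self.without_replacement:
            raise ValueError("sampling is always without replacement")


def comparative_health(facts: pd.DataFrame,
                       patient_ids=None) -> pd.Series:
    """Per-patient total fact count (diagnoses, medications, test results).

    Patients in ``patient_ids`` with no facts get 0. The count equals the
    row count of each patient's facts table.
    """
    counts = (facts.groupby("patient_id").size() if not facts.empty
              else pd.Series(dtype=int))
    if patient_ids is not None:
        counts = counts.reindex(pd.Index(patient_ids, name="patient_id"),
                                fill_value=0)
    return counts.rename("fact_count").astype(int)


def age_bin_10y(age: int, lo: int = 10, hi: int = 64) -> str:
    """Decade bin label for an age within [lo, hi]: "[10,20)", ... "[60,65)"."""
    if not lo <= age <= hi:
        raise ValueError(f"age {age} outside [{lo}, {hi}]")
    start = lo + 10 * ((age - lo) // 10)
    end = min(start + 10, hi + 1)
    return f"[{start},{end})"


def ch_quantile_bin(values: pd.Series, pool_values: pd.Series,
                    n_bins: int) -> pd.Series:
    """Assign quantile-bin indices using edges from the pool distribution."""
    edges = np.unique(np.quantile(pool_values.to_numpy(dtype=float),
                                  np.linspace(0, 1, n_bins + 1)))
    if len(edges) < 2:
        return pd.Series(0, index=values.index)
    binned = np.clip(np.searchsorted(edges[1:-1], values.to_numpy(dtype=float),
                                     side="right"), 0, len(edges) - 2)
    return pd.Series(binned, index=values.index)


def draw_matched_sample(cases: pd.DataFrame, pool: pd.DataFrame,
                        spec: MatchSpec) -> tuple[pd.DataFrame, dict]:
    """Draw up to ``spec.ratio`` controls per case from the shared stratum.

    ``cases`` and ``pool`` must be disjoint on patient_id and carry the
    matching-variable columns named in ``spec.variables`` (with
    ``comparative_health`` as the raw count when ``comparative_health_bin``
    is requested). Controls are drawn uniformly without replacement within
    the joint stratum of all matching variables; cases are processed in
    randomized order under the seed so stratum exhaustion is not systematic.

    Returns (sampled controls, report). The report records per-case stratum
    shortfalls; an empty pool yields an empty sample plus a warning entry,
    not an exception.
    """
    overlap = set(cases["patient_id"]) & set(pool["patient_id"])
    if overlap:
        raise ValueError(f"cases and pool overlap: {sorted(overlap)[:5]}")
    report: dict = {"ratio": spec.ratio, "n_cases": len(cases),
                    "shortfalls": [], "warnings": []}
    if pool.empty:
        report["warnings"].append("empty control pool")
        return pool.iloc[0:0].copy(), report

    cases = cases.copy()
    pool = pool.copy()
    if "comparative_health_bin" in spec.variables:
        edges_src = pool["comparative_health"]
        pool["comparative_health_bin"] = ch_quantile_bin(
            pool["comparative_health"], edges_src, spec.ch_bins)
        cases["comparative_health_bin"] = ch_quantile_bin(
            cases["comparative_health"], edges_src, spec.ch_bins)

    rng = np.random.default_rng(spec.seed)
    key = list(spec.variables)
    strata = {(k if isinstance(k, tuple) else (k,)): sub["patient_id"].tolist()
              for k, sub in pool.groupby(key, sort=True)}
    taken: list[str] = []
    order = rng.permutation(len(cases))
    for idx in order:
        case = cases.iloc[idx]
        k = tuple(case[v] for v in key)
        avail = strata.get(k, [])
        n_take = min(spec.ratio, len(avail))
        if n_take < spec.ratio:
            report["shortfalls"].append(
                {"case": str(case["patient_id"]),
                 "stratum": [str(v) for v in (k if isinstance(k, tuple) else (k,))],
                 "available": len(avail), "requested": spec.ratio})
        if n_take:
            chosen = rng.choice(len(avail), size=n_take, replace=False)
            chosen_ids = [avail[i] for i in sorted(chosen)]
            taken.extend(chosen_ids)
            strata[k] = [pid for i, pid in enumerate(avail)
                         if i not in set(chosen)]
    sample = pool[pool["patient_id"].isin(set(taken))].copy()
    report["n_sampled"] = len(sample)
    return sample, report


def exclude_employees(sample: pd.DataFrame,
                      patients: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """Drop employee-flagged patients from a drawn sample.

    Returns (filtered sample, count report).
    """
    flags = patients.set_index("patient_id")["employee_flag"]
    is_emp = sample["patient_id"].map(flags).fillna(False).astype(bool)
    out = sample[~is_emp].copy()
    report = {"n_before": len(sample), "n_excluded": int(is_emp.sum()),
              "n_after": len(out)}
    return out, report
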