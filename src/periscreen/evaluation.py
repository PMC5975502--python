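"""Chart-review simulation and screening-performance estimation.

Real chart review assigns each sampled woman a binary label (completed
suicide, attempt, preparatory acts, or ideation = positive). On synthetic
cohorts the reviewer is replaced by a ground-truth lookup. From the review
sample the module estimates the positive predictive value (with a Wilson
95% interval), extrapolates the confirmed count in a screen-positive group
(round-half-up of N x PPV), and projects prevalence in a matched reference
population (100 x n_positive x PPV / denominator, 2 decimals).

Group contrasts use the Pearson chi-square test (no continuity correction)
for categorical variables and Student's two-sample t-test for continuous
ones.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.proportion import proportion_confint

from .cohort import IntegrityError  # noqa: F401  (re-exported for callers)
from .lexicons import CodeLexicon

__all__ = [
    "ReviewSample",
    "round_half_up",
    "proportion_pct",
    "simulate_chart_review",
    "estimate_ppv",
    "estimate_confirmed",
    "estimate_prevalence",
    "compare_groups",
    "flag_comorbidities",
]


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Decimal round-half-up (0.5 always rounds away from zero upward)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def proportion_pct(numerator: int, denominator: int, ndigits: int = 2) -> float:
    """100 * numerator / denominator, rounded half-up to ``ndigits``."""
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    return round_half_up(100.0 * numerator / denominator, ndigits)


@dataclass
class ReviewSample:
    """A reviewed subsample of one cascade group."""
    group: str
    sample_size: int
    labels: pd.Series            # index patient_id, bool (positive label)
    warnings: list

    @property
    def n_confirmed(self) -> int:
        return int(self.labels.sum())


def simulate_chart_review(members, ground_truth: pd.Series, sample_size: int,
                          seed: int, group: str = "") -> ReviewSample:
    """Uniform random review subsample with ground-truth labels.

    ``members`` is the group's patient_ids; ``ground_truth`` maps patient_id
    to the true phenotype label. If the group is smaller than
    ``sample_size`` the whole group is reviewed and a warning recorded; an
    empty group yields an empty sample with a warning.
    """
    members = list(members)
    warnings: list[str] = []
    rng = np.random.default_rng(seed)
    if not members:
        warnings.append(f"group {group!r} is empty")
        chosen: list = []
    elif sample_size >= len(members):
        if sample_size > len(members):
            warnings.append(
                f"group {group!r} has {len(members)} < {sample_size}; "
                "reviewing the whole group")
        chosen = members
    else:
        idx = rng.choice(len(members), size=sample_size, replace=False)
        chosen = [members[i] for i in sorted(idx)]
    labels = ground_truth.reindex(chosen).astype(bool)
    return ReviewSample(group=group, sample_size=len(chosen),
                        labels=labels, warnings=warnings)


def estimate_ppv(review: ReviewSample,
                 alpha: float = 0.05) -> tuple[float, tuple[float, float]]:
    """Point PPV (n_confirmed / sample_size) with a Wilson interval."""
    if review.sample_size < 1:
        raise ValueError("PPV undefined for an empty review sample")
    p = review.n_confirmed / review.sample_size
    lo, hi = proportion_confint(review.n_confirmed, review.sample_size,
                                alpha=alpha, method="wilson")
    return p, (float(lo), float(hi))


def estimate_confirmed(n_group: int, ppv: float) -> int:
    """Extrapolated confirmed count: round-half-up of N x PPV."""
    if not 0 <= ppv <= 1:
        raise ValueError("ppv must lie in [0, 1]")
    return int(round_half_up(n_group * ppv, 0))


def estimate_prevalence(n_positive: int, ppv: float, denom: int) -> float:
    """Projected prevalence (%) in the reference denominator, 2 decimals."""
    if denom < 1:
        raise ValueError("denominator must be >= 1")
    return round_half_up(100.0 * n_positive * ppv / denom, 2)


def compare_groups(group_a: pd.DataFrame, group_b: pd.DataFrame,
                   variables: dict[str, str]) -> pd.DataFrame:
    """Per-variable contrast between two groups.

    ``variables`` maps column name -> "categorical" | "continuous".
    Categorical: Pearson chi-square on the 2 x k contingency table, no
    continuity correction. Continuous: Student's two-sample t-test (pooled
    variance). Degenerate tables (a single category, or too few
    observations) are skipped with a note. P-values are returned both exact
    and rounded half-up to 2 decimals, the table's printed precision.
    """
    rows = []
    for var, kind in variables.items():
        note = ""
        stat = p = np.nan
        if kind == "categorical":
            a = group_a[var].value_counts()
            b = group_b[var].value_counts()
            cats = sorted(set(a.index) | set(b.index))
            table = np.array([[int(a.get(c, 0)) for c in cats],
                              [int(b.get(c, 0)) for c in cats]])
            table = table[:, table.sum(axis=0) > 0]
            if table.shape[1] < 2:
                note = "skipped: single category"
            else:
                stat, p, _, _ = stats.chi2_contingency(table, correction=False)
        elif kind == "continuous":
            a = group_a[var].dropna().to_numpy(dtype=float)
            b = group_b[var].dropna().to_numpy(dtype=float)
            if len(a) < 2 or len(b) < 2:
                note = "skipped: <2 observations in a group"
            else:
                stat, p = stats.ttest_ind(a, b, equal_var=True)
        else:
            raise ValueError(f"unknown variable kind {kind!r}")
        rows.append((var, kind, stat, p,
                     round_half_up(p, 2) if np.isfinite(p) else np.nan, note))
    return pd.DataFrame(rows, columns=[
        "variable", "kind", "statistic", "p_value", "p_value_2dp", "note"])


def flag_comorbidities(facts: pd.DataFrame,
                       comorbidity_lexicons: dict[str, CodeLexicon],
                       index_dates: pd.Series,
                       patient_ids=None) -> pd.DataFrame:
    """Per-patient comorbidity flags at or before the index date.

    ``index_dates`` maps patient_id to the date of the most recent
    suicidality evidence; a flag is set iff >=1 matching code is dated on or
    before that date. Patients with no index date are flagged over their
    full fact history and marked in the ``full_history`` provenance column.
    """
    if patient_ids is None:
        patient_ids = index_dates.index
    pids = pd.Index(patient_ids, name="patient_id")
    out = pd.DataFrame(index=pids)
    f = facts[facts["patient_id"].isin(set(pids))].copy()
    f["date"] = pd.to_datetime(f["date"])
    idx = pd.to_datetime(index_dates.reindex(pids))
    out["full_history"] = idx.isna().to_numpy()
    for name, lex in comorbidity_lexicons.items():
        if f.empty:
            out[name] = False
            continue
        hits = f.loc[lex.match_frame(f), ["patient_id", "date"]]
        cutoff = hits["patient_id"].map(idx)
        ok = hits[cutoff.isna() | (hits["date"] <= cutoff)]
        out[name] = out.index.isin(set(ok["patient_id"]))
    return out.reset_index()
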