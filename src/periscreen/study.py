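"""End-to-end screening study: model object, results object, pipeline.

:class:`ScreeningStudy` is built from the three EMR tables (patients,
facts, notes) plus lexicons; :meth:`ScreeningStudy.fit` executes the
cascade — datamart -> code screen -> matched sampling -> term/context
screen -> relevance scoring -> (simulated) chart review — and returns a
:class:`ScreeningResults` carrying the group assignments, PPV estimates
with Wilson intervals, extrapolated confirmed counts, projected reference
prevalence, recall diagnostics against planted ground truth, and
group-comparison tables. ``results.summary()`` prints the count cascade
and the estimates.

Every stage consuming randomness draws its seed deterministically from the
single study seed, so a refit with the same inputs is bit-identical.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from fractions import Fraction
from pathlib import Path

import numpy as np
import pandas as pd

from . import cohort as _cohort
from .codescreen import screen_codes
from .evaluation import (compare_groups, estimate_confirmed, estimate_ppv,
                         estimate_prevalence, flag_comorbidities,
                         proportion_pct, simulate_chart_review)
from .lexicons import (load_comorbidity_lexicons, load_pregnancy_lexicon,
                       load_suicide_lexicon, load_term_lexicon,
                       load_trigger_lexicon)
from .matching import (MatchSpec, age_bin_10y, comparative_health,
                       draw_matched_sample, exclude_employees)
from .nlp import annotate_note
from .scoring import assign_cascade
from .synthetic import CohortConfig, generate_cohort, read_notes, write_cohort

__all__ = ["PipelineConfig", "ScreeningStudy", "ScreeningResults",
           "run_pipeline"]


@dataclass
class PipelineConfig:
    """Tunable constants of the cascade; defaults reproduce the study design.

    window_days: postpartum perinatal-window length (days, inclusive).
    match_ratio / reference_ratio: controls per case for the notes-arm and
    reference samples. threshold: per-woman relevance-proportion cut,
    inclusive. review_sizes: chart-review sample sizes for the
    diagnostic-codes, notes-positive, notes-not-relevant and
    no-term-mention groups.
    """
    gap_days: int = 90
    window_days: int = 42
    match_ratio: int = 30
    reference_ratio: int = 100
    ch_bins: int = 10
    threshold: float = 0.25
    review_sizes: tuple[int, int, int, int] = (50, 100, 100, 100)
    age_range: tuple[int, int] = (10, 64)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.threshold <= 1.0:
            raise ValueError(f"threshold must lie in [0, 1], "
                             f"got {self.threshold}")
        for name in ("gap_days", "window_days", "match_ratio",
                     "reference_ratio", "ch_bins"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")

    def stage_seed(self, stage: str) -> int:
        """Deterministic per-stage seed derived from the study seed."""
        digest = hashlib.sha256(f"{self.seed}:{stage}".encode()).digest()
        return int.from_bytes(digest[:4], "big") % (2**31 - 1)


class ScreeningStudy:
    """Two-arm suicidality screen over one EMR cohort."""

    def __init__(self, patients: pd.DataFrame, facts: pd.DataFrame,
                 notes: pd.DataFrame, config: PipelineConfig | None = None,
                 *, pregnancy_lexicon=None, suicide_lexicon=None,
                 term_lexicon=None, triggers=None, comorbidity_lexicons=None):
        self.patients = patients.reset_index(drop=True)
        self.facts = facts.copy()
        self.facts["date"] = pd.to_datetime(self.facts["date"])
        self.notes = notes.reset_index(drop=True)
        self.config = config or PipelineConfig()
        self.pregnancy_lexicon = pregnancy_lexicon or load_pregnancy_lexicon()
        self.suicide_lexicon = suicide_lexicon or load_suicide_lexicon()
        self.term_lexicon = term_lexicon or load_term_lexicon()
        self.triggers = triggers or load_trigger_lexicon()
        self.comorbidity_lexicons = (comorbidity_lexicons
                                     or load_comorbidity_lexicons())
        self.cohort_config: CohortConfig | None = None

    # -- constructors ------------------------------------------------------
    @classmethod
    def from_synthetic(cls, cohort_config: CohortConfig | None = None,
                       config: PipelineConfig | None = None,
                       **kwargs) -> "ScreeningStudy":
        cohort_config = cohort_config or CohortConfig()
        patients, facts, notes = generate_cohort(cohort_config)
        study = cls(patients, facts, notes, config, **kwargs)
        study.cohort_config = cohort_config
        return study

    @classmethod
    def from_files(cls, patients_path, facts_path, notes_path,
                   config: PipelineConfig | None = None,
                   **kwargs) -> "ScreeningStudy":
        patients = pd.read_csv(patients_path, sep="\t",
                               parse_dates=["birth_date"])
        if "employee_flag" in patients.columns:
            patients["employee_flag"] = patients["employee_flag"].astype(bool)
        if "true_case" in patients.columns:
            patients["true_case"] = patients["true_case"].astype(bool)
        facts = pd.read_csv(facts_path, sep="\t", parse_dates=["date"],
                            dtype={"code": str})
        notes = read_notes(notes_path)
        return cls(patients, facts, notes, config, **kwargs)

    # -- the cascade -------------------------------------------------------
    def fit(self) -> "ScreeningResults":
        cfg = self.config
        manifest: dict = {"stages": {}, "seed": cfg.seed}

        def log(stage, **counts):
            manifest["stages"][stage] = counts

        # 1. pregnancy datamart
        datamart = _cohort.build_datamart(self.patients, self.facts,
                                          self.pregnancy_lexicon,
                                          cfg.age_range)
        log("datamart", n_input=len(self.patients), n_datamart=len(datamart))
        dm_ids = set(datamart["patient_id"])
        facts = self.facts[self.facts["patient_id"].isin(dm_ids)]

        # 2. perinatal windows
        episodes = _cohort.infer_episodes_frame(
            facts, self.pregnancy_lexicon, cfg.gap_days, cfg.window_days)
        log("episodes", n_episodes=len(episodes))

        # 3. diagnostic-code screen
        code_results = screen_codes(datamart, facts, self.suicide_lexicon,
                                    episodes)
        cases_ids = code_results.loc[code_results["in_window_suicide_code"],
                                     "patient_id"]
        any_code_ids = set(code_results.loc[code_results["any_suicide_code"],
                                            "patient_id"])
        log("code_screen", n_any_code=len(any_code_ids),
            n_in_window=len(cases_ids))

        # 4. matching variables
        ch = comparative_health(facts, datamart["patient_id"])
        first_preg = (episodes.groupby("patient_id")["start_date"].min()
                      if not episodes.empty else pd.Series(dtype="datetime64[ns]"))
        birth = datamart.set_index("patient_id")["birth_date"]
        mvars = datamart[["patient_id", "race"]].copy()
        mvars["comparative_health"] = ch.reindex(mvars["patient_id"]).to_numpy()
        ages = [
            _cohort.age_at(birth[pid], first_preg[pid]) for pid
            in mvars["patient_id"]]
        mvars["age_bin_10y"] = [age_bin_10y(a, *cfg.age_range) for a in ages]
        mvars["age_at_first_pregnancy"] = ages

        cases_df = mvars[mvars["patient_id"].isin(set(cases_ids))]
        # notes-arm pool: women without ANY suicidality code, ever
        pool_df = mvars[~mvars["patient_id"].isin(any_code_ids)]
        log("pools", n_cases=len(cases_df), n_pool=len(pool_df))

        # 5. 1:30 matched notes-arm sample, employees excluded afterwards
        spec = MatchSpec(cfg.match_ratio,
                         ("age_bin_10y", "race", "comparative_health_bin"),
                         ch_bins=cfg.ch_bins, seed=cfg.stage_seed("match"))
        sample_raw, match_report = draw_matched_sample(cases_df, pool_df, spec)
        sample, emp_report = exclude_employees(sample_raw, self.patients)
        log("matched_sample", n_drawn=len(sample_raw),
            n_employees_excluded=emp_report["n_excluded"],
            n_sample=len(sample))

        # 6. 1:100 reference sample (comparative health only)
        ref_spec = MatchSpec(cfg.reference_ratio, ("comparative_health_bin",),
                             ch_bins=cfg.ch_bins,
                             seed=cfg.stage_seed("reference"))
        ref_pool = mvars[~mvars["patient_id"].isin(set(cases_ids))]
        reference_raw, ref_report = draw_matched_sample(cases_df, ref_pool,
                                                        ref_spec)
        reference, ref_emp = exclude_employees(reference_raw, self.patients)
        log("reference_sample", n_drawn=len(reference_raw),
            n_employees_excluded=ref_emp["n_excluded"],
            n_reference=len(reference))

        # 7. term + context screen over the sampled women's notes
        sample_ids = set(sample["patient_id"])
        notes = self.notes[self.notes["patient_id"].isin(sample_ids)]
        mention_rows = []
        for rec in notes.to_dict("records"):
            for m in annotate_note(rec, self.term_lexicon, self.triggers):
                mention_rows.append(m.to_dict())
        mentions = pd.DataFrame(mention_rows, columns=[
            "note_id", "patient_id", "doc_date", "start", "end", "text",
            "concept_id", "polarity", "doc_time_rel", "experiencer",
            "section_title", "relevant"])
        log("nlp", n_notes=len(notes), n_mentions=len(mentions))

        # 8. in-window mention tallies and relevance scoring
        if mentions.empty:
            in_window = mentions
        else:
            m = mentions.copy()
            m["doc_date"] = pd.to_datetime(m["doc_date"])
            joined = m.merge(episodes, on="patient_id", how="left")
            ok = ((joined["doc_date"] >= joined["start_date"])
                  & (joined["doc_date"] <= joined["window_end"]))
            keys = joined.loc[ok, ["note_id", "start"]].drop_duplicates()
            in_window = m.merge(keys, on=["note_id", "start"])
        if in_window.empty:
            mention_counts = pd.DataFrame(
                columns=["patient_id", "n_mentions_window", "n_relevant"])
        else:
            mention_counts = (in_window.groupby("patient_id")
                              .agg(n_mentions_window=("relevant", "size"),
                                   n_relevant=("relevant", "sum"))
                              .reset_index())
        cascade = assign_cascade(
            code_results, sample_ids, mention_counts,
            Fraction(cfg.threshold).limit_denominator(10**6))
        group_sizes = cascade["group"].value_counts().to_dict()
        log("cascade", **{k: int(v) for k, v in group_sizes.items()})

        return ScreeningResults(self, datamart, episodes, code_results,
                                mvars, sample, reference, mentions,
                                in_window, cascade, manifest,
                                {"match": match_report, "employees": emp_report,
                                 "reference": ref_report,
                                 "reference_employees": ref_emp})


class ScreeningResults:
    """Fitted screen: group assignments, estimates and diagnostics."""

    def __init__(self, study, datamart, episodes, code_results, mvars,
                 sample, reference, mentions, mentions_in_window, cascade,
                 manifest, reports):
        self.study = study
        self.config = study.config
        self.datamart = datamart
        self.episodes = episodes
        self.code_results = code_results
        self.matching_vars = mvars
        self.sample = sample
        self.reference = reference
        self.mentions = mentions
        self.mentions_in_window = mentions_in_window
        self.cascade = cascade
        self.manifest = manifest
        self.reports = reports
        self._evaluate()

    # ------------------------------------------------------------------
    def group_members(self, group: str) -> list[str]:
        return self.cascade.loc[self.cascade["group"] == group,
                                "patient_id"].tolist()

    @property
    def group_sizes(self) -> dict[str, int]:
        return {g: int((self.cascade["group"] == g).sum())
                for g in ("diagnostic_codes", "nlp_positive",
                          "nlp_not_relevant", "no_term_mentions")}

    def _evaluate(self) -> None:
        cfg = self.config
        sizes = self.group_sizes
        self.review_samples = {}
        self.ppv = {}
        truth = None
        if "true_case" in self.study.patients.columns:
            truth = self.study.patients.set_index("patient_id")["true_case"]
        groups = ("diagnostic_codes", "nlp_positive", "nlp_not_relevant",
                  "no_term_mentions")
        if truth is not None:
            for group, size in zip(groups, cfg.review_sizes):
                rs = simulate_chart_review(
                    self.group_members(group), truth, size,
                    cfg.stage_seed(f"review:{group}"), group=group)
                self.review_samples[group] = rs
                if rs.sample_size:
                    self.ppv[group] = estimate_ppv(rs)

        est: dict = {"group_sizes": sizes,
                     "n_sample": len(self.sample),
                     "n_reference": len(self.reference)}
        n_codes, n_nlp = sizes["diagnostic_codes"], sizes["nlp_positive"]
        n_positive = n_codes + n_nlp
        est["n_screen_positive"] = n_positive
        if n_positive:
            est["codes_share_pct"] = proportion_pct(n_codes, n_positive)
            est["nlp_share_pct"] = proportion_pct(n_nlp, n_positive)
        n_term = n_nlp + sizes["nlp_not_relevant"]
        if len(self.sample):
            est["term_mention_rate_pct"] = proportion_pct(n_term,
                                                          len(self.sample))
        if "diagnostic_codes" in self.ppv:
            p = self.ppv["diagnostic_codes"][0]
            est["ppv_diagnostic_codes"] = p
            est["confirmed_diagnostic_codes"] = estimate_confirmed(n_codes, p)
        if "nlp_positive" in self.ppv:
            p = self.ppv["nlp_positive"][0]
            est["ppv_nlp"] = p
            est["confirmed_nlp"] = estimate_confirmed(n_nlp, p)
            if len(self.sample):
                est["reference_prevalence_pct"] = estimate_prevalence(
                    n_nlp, p, len(self.sample))

        # recall diagnostics against planted ground truth
        if truth is not None:
            dm_truth = truth.reindex(self.datamart["patient_id"])
            n_true = int(dm_truth.sum())
            est["n_true_cases"] = n_true
            if n_true:
                code_pos = set(self.group_members("diagnostic_codes"))
                nlp_pos = set(self.group_members("nlp_positive"))
                true_ids = set(dm_truth[dm_truth].index)
                est["code_arm_recall"] = len(code_pos & true_ids) / n_true
                est["combined_recall"] = (
                    len((code_pos | nlp_pos) & true_ids) / n_true)
        self.estimates = est
        self._truth = truth

        # demographic contrast between the two screen-positive groups
        pats = self.study.patients.set_index("patient_id")
        a = pats.reindex(self.group_members("diagnostic_codes")).reset_index()
        b = pats.reindex(self.group_members("nlp_positive")).reset_index()
        cat_vars = [v for v in ("race", "language", "marital_status",
                                "insurance", "vital_status")
                    if v in pats.columns]
        if len(a) and len(b):
            self.comparisons = compare_groups(
                a, b, {v: "categorical" for v in cat_vars})
        else:
            self.comparisons = pd.DataFrame()

        self.comorbidities = self._comorbidity_table()

    def _index_dates(self, ids) -> pd.Series:
        """Most recent in-window suicidality evidence per patient."""
        code_dates = (self.code_results.set_index("patient_id")
                      ["first_event_date"])
        rel = self.mentions_in_window
        rel_dates = (pd.to_datetime(rel.loc[rel["relevant"], "doc_date"])
                     .groupby(rel.loc[rel["relevant"], "patient_id"]).max()
                     if len(rel) else pd.Series(dtype="datetime64[ns]"))
        idx = pd.Series(pd.NaT, index=pd.Index(ids, name="patient_id"))
        for src in (code_dates, rel_dates):
            aligned = pd.to_datetime(src.reindex(idx.index))
            idx = pd.concat([idx, aligned], axis=1).max(axis=1)
        return idx

    def _comorbidity_table(self) -> pd.DataFrame:
        rows = []
        facts = self.study.facts
        for group in ("diagnostic_codes", "nlp_positive"):
            ids = self.group_members(group)
            if not ids:
                continue
            flags = flag_comorbidities(facts,
                                       self.study.comorbidity_lexicons,
                                       self._index_dates(ids), ids)
            for cond in self.study.comorbidity_lexicons:
                rows.append((group, cond, int(flags[cond].sum()),
                             proportion_pct(int(flags[cond].sum()),
                                            len(ids))))
        return pd.DataFrame(rows, columns=["group", "condition", "n", "pct"])

    # ------------------------------------------------------------------
    def summary(self) -> str:
        est = self.estimates
        lines = ["Two-arm suicidality screen", "=" * 44]
        st = self.manifest["stages"]
        lines.append(f"cohort women:            {st['datamart']['n_input']:>8}")
        lines.append(f"pregnancy datamart:      {st['datamart']['n_datamart']:>8}")
        lines.append(f"any suicidality code:    {st['code_screen']['n_any_code']:>8}")
        lines.append(f"perinatal code positive: {st['code_screen']['n_in_window']:>8}")
        lines.append(f"matched sample (1:{self.config.match_ratio}):   "
                     f"{est['n_sample']:>8}")
        sizes = est["group_sizes"]
        lines.append(f"  term mentions in window: {sizes['nlp_positive'] + sizes['nlp_not_relevant']:>6}")
        lines.append(f"  notes-screen positive:   {sizes['nlp_positive']:>6}")
        lines.append(f"  notes not relevant:      {sizes['nlp_not_relevant']:>6}")
        lines.append(f"  no term mentions:        {sizes['no_term_mentions']:>6}")
        lines.append(f"reference sample (1:{self.config.reference_ratio}): "
                     f"{est['n_reference']:>6}")
        lines.append("-" * 44)
        for group, (p, (lo, hi)) in self.ppv.items():
            rs = self.review_samples[group]
            lines.append(f"PPV {group:<18} {p:6.3f}  "
                         f"[{lo:.3f}, {hi:.3f}]  (n={rs.sample_size})")
        for key in ("confirmed_diagnostic_codes", "confirmed_nlp"):
            if key in est:
                lines.append(f"{key:<32} {est[key]}")
        for key in ("nlp_share_pct", "term_mention_rate_pct",
                    "reference_prevalence_pct"):
            if key in est:
                lines.append(f"{key:<32} {est[key]:.2f}")
        for key in ("code_arm_recall", "combined_recall"):
            if key in est:
                lines.append(f"{key:<32} {est[key]:.3f}")
        return "\n".join(lines)

    def report(self) -> dict:
        """JSON-serializable bundle of estimates and per-stage counts."""
        out = {"config": asdict(self.config), "manifest": self.manifest,
               "estimates": {}, "ppv": {}, "reports": {
                   k: v for k, v in self.reports.items()
                   if k in ("employees", "reference_employees")}}
        for k, v in self.estimates.items():
            out["estimates"][k] = (int(v) if isinstance(v, (int, np.integer))
                                   else v if isinstance(v, dict)
                                   else float(v))
        for group, (p, (lo, hi)) in self.ppv.items():
            rs = self.review_samples[group]
            out["ppv"][group] = {"estimate": float(p),
                                 "ci95": [float(lo), float(hi)],
                                 "n_reviewed": rs.sample_size,
                                 "n_confirmed": rs.n_confirmed}
        return out


def run_pipeline(cohort_config: CohortConfig | None = None,
                 config: PipelineConfig | None = None,
                 outdir: str | Path | None = None,
                 inputs: dict | None = None) -> ScreeningResults:
    """Execute the full cascade and (optionally) write every artifact.

    Either generates a synthetic cohort from ``cohort_config`` or reads the
    three tables from ``inputs`` (keys patients/facts/notes). When
    ``outdir`` is given, writes the input tables (synthetic runs), the
    per-woman screen outcomes, the mention annotations, the report JSON and
    a manifest with per-stage counts and the config hash.
    """
    config = config or PipelineConfig()
    if inputs:
        study = ScreeningStudy.from_files(inputs["patients"], inputs["facts"],
                                          inputs["notes"], config)
    else:
        study = ScreeningStudy.from_synthetic(cohort_config, config)
    results = study.fit()
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        if not inputs:
            write_cohort(study.patients, study.facts, study.notes, outdir,
                         study.cohort_config)
        results.cascade.to_csv(outdir / "screen_outcomes.tsv", sep="\t",
                               index=False)
        with open(outdir / "annotations.jsonl", "w") as fh:
            for rec in results.mentions.to_dict("records"):
                rec = dict(rec)
                rec["doc_date"] = str(pd.Timestamp(rec["doc_date"]).date())
                fh.write(json.dumps(rec) + "\n")
        report = results.report()
        cfg_text = json.dumps(asdict(config), sort_keys=True, default=str)
        report["config_sha256"] = hashlib.sha256(cfg_text.encode()).hexdigest()
        with open(outdir / "report.json", "w") as fh:
            json.dump(report, fh, indent=2, default=str)
    return results
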