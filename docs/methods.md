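# Methods

## The screening problem

Suicidal behavior (ideation, attempts, preparatory acts, completed
suicide) in the perinatal period is a rare phenotype — on the order of a
few percent of a pregnancy cohort — that is under-captured by billing
codes. The package implements a two-arm screen over an EMR warehouse:
arm 1 flags women with suicidality diagnostic codes inside a perinatal
window; arm 2 applies term matching and rule-based context extraction to
the clinical notes of a matched sample of women *without any* suicidality
code, then screens on a per-woman relevance proportion. Chart review of
subsamples yields positive predictive values, from which confirmed counts
and reference prevalence are extrapolated.

The screen is intentionally sensitivity-first: it builds a candidate pool
for downstream phenotyping, so a low notes-arm PPV is acceptable by
design, and the estimators quantify exactly how low.

## Perinatal windowing

Pregnancy episodes are inferred from pregnancy-code dates: consecutive
dates separated by at most `gap_days` (default 90) merge into one
episode, spanning first to last date. The perinatal window runs from
episode start through `window_days` (default 42) after the episode end,
both boundaries inclusive — "within 42 days" is read inclusively, and the
inclusive reading is asserted by boundary tests (end + 42 in, end + 43
out). Age eligibility (10–64) is computed as completed years at the
qualifying fact's date, both ends inclusive. Encounter dates, not coded
gestational ages, anchor both arms; nothing in the inputs identifies true
conception dates, so the episode model is an explicit stand-in.

The 90-day merge gap is a design choice with no external anchor: it must
exceed the longest plausible gap between prenatal encounters while
staying well under the shortest plausible inter-pregnancy interval. The
synthetic generator emits prenatal visit codes every 56–70 days and
separates successive pregnancies by 200–1,000 days, so inference
reconstructs the planted episodes exactly; real coding patterns are
sparser and less regular, and episode inference on real data would need
validation this package does not claim.

## Code matching

Diagnostic-code lexicons are editable TSVs with three pattern forms:
exact codes, trailing wildcards ("V22.*" matches "V22" and "V22.1" after
dot-stripping normalization), and numeric ranges compared on the leading
digit stem at the bounds' width ("640.*-679.*" covers stems 640–679;
"O0.*-O9.*" covers the first digit after the alpha prefix, i.e. the whole
obstetric chapter; DRG "370-384" is inclusive). Malformed patterns fail
at load time, never at match time. The suicidality lexicon covers
explicit ideation/attempt codes (ICD-9 E950–E958, V62.84; ICD-10 X60–X84,
R45.851, T14.91) plus the three poisoning categories (analgesics,
sedative-hypnotics, psychotropics); problem-list (LMR) entries are
site-specific and shipped as placeholders. Both lexicons are
approximations of unpublished appendix tables and are meant to be
replaced wholesale for any real deployment.

## The context engine

Arm 2 re-implements, as transparent rules, the attribute semantics that
clinical NLP systems (cTAKES-style) attach to concept mentions. All rules
are pure functions of (sentence, mention, lexicons).

**Segmentation.** Sentences end at `.`, `!`, `?` or a newline; a line
without terminal punctuation is its own sentence. This is load-bearing:
the colon-negation dialect ("suicidal behavior: none") appears on
unpunctuated lines, and isolating them keeps negation scope local.
Segmentation spans partition the non-whitespace text (property-tested).

**Term matching.** Case-insensitive word-boundary regex per lexicon
entry; overlapping matches resolve longest-first. Concept ids are flat
local identifiers standing in for UMLS CUIs.

**Polarity.** Negated iff (a) a pre-mention trigger (denies, no, not,
without, ...) lies within `scope_window` = 6 tokens before the mention —
the NegEx convention — with no adversative conjunction (but, however)
between; (b) the mention is followed, before any other colon or sentence
punctuation, by a colon and a negation word (none, denied, negative,
...); or (c) a post-phrase ("was ruled out") follows in scope. Rule (b)
exists precisely because trigger-window negation alone misses the colon
dialect, a documented major failure mode of off-the-shelf negation on
this phenotype.

**Temporality.** Historical cues ("history of", "hx of", "in 1996",
"when she was 14", ...) map to *before*; hypothetical/conditional/future
cues (if, would, will, "were to", ...) to *after*; durative cues (since,
ongoing, still, ...) to *before_overlap*; no cue means *overlap*.
Temporal cues scope the whole sentence — bidirectionally — because the
canonical historical markers ("when she was 14", "in 1996") *follow* the
mention. When several cues compete, the one nearest the mention in token
distance wins; ties prefer pre-mention cues, then the class order
historical > hypothetical > durative. Treating conditionals as *after*
follows the convention that the canonical "after" example is a
conditional; either way such mentions are temporally non-current and
excluded from relevance.

**Experiencer.** The nearest preceding subject cue decides: family terms
(mom, father, ...) give *family_member*, third-party terms (friend,
roommate, ...) give *other*, explicit patient references give *patient*.
With no resolvable subject the experiencer defaults to *patient* — the
standard default in clinical context systems; the engine therefore never
emits *null*, though the value remains legal in the data model.

**Section titles.** A sentence is a header iff it ends with ":" and
contains no finite-verb cue; "Assessment: patient endorses ..." has a
clause and is not a header.

**Relevance.** A mention is relevant iff affirmed ∧ (overlap ∨
before_overlap) ∧ patient ∧ ¬section-title. The conjunction is tested
exhaustively over the attribute lattice.

## Relevance scoring and the cascade

Per woman, the screen statistic is n_relevant / n_mentions over mentions
whose note date falls in a perinatal window; mentions outside every
window are excluded from numerator *and* denominator — the screen is
defined on the perinatal period. Proportions are exact `Fraction`s so the
inclusive ≥ 0.25 boundary can never be a float artifact. The cascade
assigns groups with code-arm precedence: perinatal code positive →
`diagnostic_codes`; else sampled with in-window mentions →
`nlp_positive` / `nlp_not_relevant` by threshold; else sampled →
`no_term_mentions`; else `outside_sample`. The notes-arm pool excludes
women with a suicidality code at *any* time, not only in-window — the
count cascade subtracts all code-carriers from the pool, so an
out-of-window code still removes a woman from arm 2.

## Matched sampling

Cases are the perinatal code positives. Controls are drawn without
replacement, up to `ratio` per case, from the case's joint stratum of age
bin ([10,20) ... [60,65), anchored at 10), race, and comparative-health
decile (bin edges from the pool distribution — the matching tolerance for
a count variable has to be chosen; quantile bins are the standard
choice). Cases are processed in randomized order under the stage seed so
stratum exhaustion is not systematic; shortfalls are recorded, not
fatal. Employee exclusion happens *after* the draw, matching the study
flow in which the drawn sample is trimmed for compliance reasons (the
package reproduces the 196 x 30 = 5880 → −598 → 5282 arithmetic in its
test suite). The reference group uses ratio 100 on comparative health
only. At the synthetic cohort's default size (5,000 women) many strata
cannot supply 30 controls, so the realized sample is smaller than ratio x
cases; the shortfall report makes this visible, and within-stratum
uniformity keeps the group-level PPV estimates unbiased.

## Chart review and estimators

On synthetic data the reviewer is a ground-truth lookup: the per-patient
`true_case` label plays the role of the binary classification (completed
suicide / attempt / preparatory acts / ideation collapsed to one flag).
Review samples default to 50 (codes group) and 100 (each notes-arm
group); groups smaller than the quota are reviewed in full with a
warning. PPV is the confirmed fraction with a Wilson 95% interval —
chosen over Wald because review samples are small and proportions can sit
near 0 or 1. Extrapolations use half-up rounding at the printed
precision: confirmed counts `round(N x PPV)` (e.g. 196 x 0.76 = 148.96 →
149; 486 x 0.30 = 145.8 → 146), prevalence to two decimals (486 x
0.30 / 5282 → 2.76%). One upstream published share (196/682 printed as
28.73%) is a truncation rather than a rounding; the package rounds
half-up (28.74) and documents the discrepancy here instead of chasing
it. Group contrasts use Pearson chi-square without continuity correction
(categorical) and Student's pooled-variance t-test (continuous), with
degenerate tables skipped and noted. Comorbidity flags fire on codes
dated on or before the index date, defined as the latest in-window
suicidality evidence (code date or relevant-mention note date) — "most
recent encounter" is otherwise undefined across arms; patients with no
index date fall back to full-history flagging with a provenance marker.

## The synthetic generator

The generator emulates the study's data-generating situation, not real
clinical prose. Each woman gets 1–3 pregnancy episodes of 182–301 days
inside a 1996–2016 observation window, prenatal codes as above,
background facts (Poisson, mean 20) and comorbidity codes (rate 0.5 for
true cases, 0.12 otherwise — psychiatric comorbidity is strongly
associated with the phenotype). Notes are template sentences plus neutral
filler; the template library is the single source of text truth, each
template coupling one sentence to fixed attribute ground truth, and
filler contains no lexicon terms (build-checked). Defaults encode the
study conditions: 5,000 women, 2% prevalence, code documentation
sensitivity 0.5 (codes miss roughly half of true cases, consistent with
the published range of code sensitivities), note documentation
sensitivity 0.9, planted chart-review PPVs 0.76 (codes arm) and 0.30
(notes arm), and an 18% rate of notes carrying only non-relevant
mentions, which together put the sample's term-mention rate near the
study's observed ~21%. False-positive documentation rates among
non-cases are derived in closed form from these knobs so the realized
group PPVs match the planted values in expectation; the derivation
conditions on code-carrier exclusion from the notes-arm pool.

What the generator does *not* emulate: realistic prose variety (the
engine's 100% attribute accuracy on synthetic notes shows rule/generator
consistency, not real-world NLP accuracy), coded gestational timing,
medication/lab semantics beyond counts, within-woman correlation of
documentation across episodes, and reviewer disagreement. Passing tests
therefore validate the pipeline's mechanics and estimator calibration,
not clinical performance on real notes.

## Numerical and reproducibility choices

Dates are day-resolution ISO-8601 throughout. Character spans are
0-based, half-open. Every stage that consumes randomness draws a 31-bit
seed deterministically (SHA-256) from the single study seed; identical
(inputs, config, seed) give bit-identical outputs, asserted in tests.
Test problem sizes: unit and property suites run on a shared 400-woman
cohort; calibration checks use 5,000-woman cohorts, with the PPV-coverage
suite running 100 seeded replicates.

## Known limitations

* Term, trigger, code and comorbidity lexicons are compact editable
  approximations, not validated clinical vocabularies.
* Episode inference is untested against real obstetric coding.
* The experiencer rule uses the nearest preceding cue only; discourse-level
  coreference ("her father ... He threatened suicide" across sentences) is
  out of scope.
* The notes arm requires a term mention to fire; concepts expressed only
  through paraphrase are invisible to both the screen and the generator.
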