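# Methods

## Model and assumptions

`dipscreen` grades drug-induced interstitial pneumonia (DIP) suspicion from
three EMR streams: free-text radiology reports, drug orders, and KL-6/SP-D
serum biomarkers. The pipeline has three stages — report-level IP calling,
exposure-period construction, and temporal grading — each with explicit,
independently testable contracts.

**Report scoring.** The findings-field classifier is naive Bayes expressed
in likelihood-ratio form. Writing sens(k) and spec(k) for keyword *k*'s
report-level operating characteristics against the radiologist label,

* LR+(k) = sens(k) / (1 − spec(k)) is multiplied in when *k* is
  effectively present,
* LR−(k) = (1 − sens(k)) / spec(k) when it is absent
  (`PRESENCE_ABSENCE` mode, the default),

under the assumption that keyword appearances are independent given the
IP status. The product is proportional to posterior odds (the prior is a
constant factor across reports of one corpus), so thresholding it orders
reports by posterior probability of IP. The independence assumption is
certainly violated by co-occurring radiological signs (ground-glass
opacity and reticulation co-occur in fibrosing disease); the score remains
a useful ranking statistic, which is all cutoff selection requires.

A second scoring mode, `PRESENT_ONLY`, multiplies LR+ over present
keywords only (empty product 1). It is retained because the two modes
differ only by the constant Π LR− when presence flags are fixed, but they
differ in how a *partially* matching report compares across reports with
different keyword subsets; the default mode uses the full 2×2 information
per keyword and makes sub-unity operating cutoffs meaningful.

**Effective presence.** A matched keyword is discounted when a negation
phrase starts within `negation_window` characters after it, or a non-lung
organ name lies within `organ_window` characters on either side; both
checks are confined to the keyword's sentence (sentences split on
`. ! ? 。 ．` and newlines). Windows are measured in characters, not
tokens, so the rule transfers across languages and tokenizers; matching is
case/whitespace-normalized substring search with a pluggable finder for
languages where that over-fires. Negation is searched only *after* the
keyword by default (`negation_direction=AFTER`), matching predicate-final
negation order in Japanese clinical prose, for which the window rule was
originally calibrated; `BIDIRECTIONAL` suits English reports, where
negators usually precede the finding ("no ground glass").

**Lexicon training.** Keywords are selected by report-level presence in
strictly more than `min_ip_report_count` IP-labeled reports, counted once
per report after mapping synonym/abbreviation surfaces onto canonicals via
a curated map (synonymy is an input, not learned). Presence counting at
training time is raw surface presence: negation and organ windows are
scoring-time rules and are not fed back into the contingency tables. This
keeps training a pure counting operation and matches a frequency-based
keyword workflow; if a training corpus were negation-heavy the LR−
estimates would be mildly attenuated, which the planted-corpus recovery
tests quantify (they plant no negations in training corpora).

**Zero cells.** A keyword absent from all non-IP reports has an infinite
LR+; one present in all IP reports has LR− = 0. When any of the four
contingency cells is zero, the configured `smoothing` (default 0.5, a
Haldane–Anscombe-style continuity correction) is added to *all four*
cells, keeping both ratios finite and strictly positive while leaving
clean tables untouched. A degenerate keyword absent everywhere smooths to
LR+ = LR− = 1 exactly — correctly conveying no information.

**Cutoff selection.** Candidate thresholds are the distinct observed
scores; prediction uses the `>=` convention (a score exactly at the cutoff
flags the report, the same convention as the candidate evaluation). The
selected cutoff minimizes the Euclidean distance to (FPR, TPR) = (0, 1).
Ties break toward higher specificity, then higher threshold: screening a
large exposed cohort favors fewer false positives, and the higher
threshold is the more conservative representative of an equivalent
operating point.

**Exposure periods.** Orders of one patient and drug merge into an episode
while the non-administration gap (days strictly between one order's end
and the next's start) is ≤ `order_merge_gap_days` (default 30). The
administration period runs from the episode start to `washout_days`
(default 30) past the last dose; the post period starts the next day and
is truncated at the censoring date and the day before any next episode,
keeping evidence attribution to episodes unambiguous. All arithmetic is
day-granularity with inclusive interval ends.

**Period status and grading.** Within one (period, source) cell, any
positive examination makes the cell positive — screening semantics: one
IP-positive CT among several is a finding, not an inconsistency. CT is
authoritative for a period whenever present. In CT-less periods, fallback
evidence is adopted in the order X-ray → KL-6 → SP-D (imaging before
biomarkers, X-ray being the standard radiological support for the
diagnosis), and only under a concordance rule: the examination must agree
with CT in at least one period of the same exposure where both exist, and
must show a different result in at least one other period. The second
clause discards examinations with no temporal signal — an always-negative
X-ray in a patient whose CT shows IP says nothing about *when* IP was
present. The rule can be disabled (`concordance_check=False`) to adopt any
available fallback. Biomarkers binarize strictly above their configured
upper limits of normal (`kl6_upper_limit` 500 U/mL, `spd_upper_limit`
110 ng/mL — site-configurable, as normal limits are assay-dependent); a
value exactly at the limit is normal.

The (pre, during, post) triple is graded by a hard-coded 27-row decision
table, total over {POS, NEG, NA}³. Its structure is dechallenge logic:
during-POS with post-NEG (IP resolving after withdrawal) earns the high
grades, pre-POS demotes to negative (IP predates the drug), during-NEG is
never suspected, and patterns dominated by NA are not determined. Patients
with several separated episodes of one drug are screened per episode and
reported at the most confident grade (definitive > strongly > weakly >
negative > not determined) — a screening tool should surface the episode
with the strongest causality signal.

**Cohort summaries.** Occurrence rate = (definitive + strongly + weakly) /
exposed patients. PPV = chart-review-confirmed DIP / all flagged patients;
reviews that end "not determined" stay in the denominator. Relative risk
is the ratio of *unrounded* occurrence rates against the reference drug;
percentages and ratios are rounded to one decimal only at presentation
(published tables that round before dividing can differ in the last
decimal; recomputation from the printed integer counts is authoritative
here). Chart-review adjudication takes three independent physician votes;
any 2-of-3 majority wins, three-way splits are "not determined".

## Synthetic data

`generate_corpus` plants per-keyword Bernoulli presence (separate
probabilities per class) into template English sentences, optionally
rendering a planted occurrence negated or in an other-organ context at
configured rates — placed *inside* the matching windows, so the discount
rules are actually exercised. `generate_cohort` draws a DIP grade per
patient from a planted distribution, realizes it through a canonical
period pattern (e.g. NEG/POS/NEG for definitive), and emits one CT report
per non-NA period whose template text deterministically clears or misses
the planted cutoff, plus log-normal biomarker values straddling the normal
limits and optionally gap-split orders. Defaults: 30-day merge gap and
washout, 15-character windows, a grade mixture dominated by negative
(64%) and not-determined (30%) patients with 2% in each suspected grade —
the order of magnitude seen when screening anticancer-drug cohorts.

What the generator does **not** emulate: realistic radiology prose
(paraphrase, anaphora, hedging), keyword correlation given disease status,
informative exam timing (real CTs cluster around clinical events),
biomarker autocorrelation, or X-ray/CT disagreement patterns. Passing
end-to-end tests therefore validates the period logic, decision table,
and bookkeeping exactly, and the text layer only against template-style
negation/confounding — not against clinical language in the wild.

## Numerical choices

* Scores are accumulated in log space and exponentiated once; agreement
  with the direct product is tested to 1e-9 relative tolerance.
* ROC tie comparisons use a 1e-12 absolute guard; candidate sets are small
  (distinct observed scores), so an exhaustive scan is exact and cheap.
* Window boundaries are inclusive: a term starting exactly
  `negation_window` characters after the keyword still negates it; the
  16th character does not.
* Degenerate inputs: empty findings yield the all-absent score; an empty
  lexicon scores every report 1.0; an empty post period (censoring inside
  the washout) is NA by construction.
* Problem sizes in the test-suite simulations — 2 × 2000 reports for
  likelihood-ratio recovery, 50 random score sets (≤ 500 reports) for the
  cutoff oracle, 500 patients for end-to-end grade recovery — are chosen
  so sampling error sits well inside the asserted tolerances while the
  whole suite stays interactive.

## Known limitations

* Substring matching over-fires on languages with heavy inflection and on
  nested terms; the term-finder hook exists for that reason, and diagnosis
  exclusion terms take precedence over inclusion terms to handle nesting
  ("lymphocytic interstitial pneumonia" contains "interstitial
  pneumonia").
* The temporal pattern is a necessary, not sufficient, condition for drug
  causality: mimics (carcinomatous lymphangiosis, edema, infection) that
  arise during exposure grade as suspected DIP. Chart review remains the
  adjudicator; the screen's value is the denominator-aware relative risk.
* Operating cutoffs are corpus properties. They transfer across hospitals
  only to the extent reporting vocabulary does; retraining the lexicon and
  cutoff per site is the intended workflow.
* The concordance rule implements one defensible reading of "agrees with
  CT somewhere, varies across periods"; it is config-gated because
  institutional data may warrant the permissive variant.
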