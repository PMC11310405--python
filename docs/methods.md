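# Methods

## The phenotyping model

The pipeline treats a patient's record as a bag of dated clinic letters.
Dictionary NER links surface forms (canonical names and synonyms matched
case-insensitively as token n-grams of length ≤ 6; abbreviations of ≤ 5
characters matched case-sensitively) to a 12-concept vocabulary. Scanning is
longest-match, left-to-right, non-overlapping, with ties broken leftmost —
the standard dictionary-NER convention, which keeps "portal vein thrombosis"
from being shadowed by the bare "thrombosis" synonym of the
not-otherwise-specified concept.

Every match receives three meta-annotations, NegEx-style:

* **negation** — a trigger token (`no, not, without, denies, denied, never,
  negative, excluded, unlikely`) within 6 tokens before or after the match,
  with the scope cut at sentence boundaries (`". "`, `"? "`, `"! "`,
  newline) and at the adversative `but`;
* **subject** — a family term (`family, mother, father, brother, sister`)
  within 5 preceding tokens marks the mention as *other*;
* **temporality** — `previous`, `prior`, or the bigram `history of` within 5
  preceding tokens marks it *historical*.

An *ambiguous* abbreviation (by default only "PE", which is also clinical
shorthand for physical examination and pleural effusion) links only when the
same document contains a non-ambiguous mention of the same concept —
within-document corroboration only, never across documents, favouring
precision.

Phenotype inference counts affirmative (`negated = False`), patient-subject
mentions per patient and concept; historical mentions are included because
the cohort statistics concern lifetime events. A phenotype is present iff
its count strictly exceeds the concept's threshold. "Threshold 2" therefore
means ≥ 3 mentions; the study's "threshold of 1 mention" for HC/CVA in PV is
read the same way (present iff > 1), the stricter of its two possible
readings. The threshold optimizer exhaustively searches t ∈ {0,…,10}
(counts above 10 add no discrimination at realistic per-patient document
counts) for the maximum patient-level F1 on a gold-labelled subsample, ties
broken by the smallest threshold; concepts missing from the gold set fall
back to the default threshold 2 with a warning.

Event timing: an event's date is the earliest document contributing a
non-negated patient-subject mention; strata are *pre/at diagnosis* (date ≤
diagnosis date), *during cytoreduction* (inside the interval), else *other*.

## Validation conventions

Document-level: a predicted mention is a true positive iff it overlaps a
gold span, links the same concept and carries the same negation flag; F1 is
0 when P + R = 0. Patient-level: sensitivity TP/(TP+FN), specificity
TN/(TN+FP), precision TP/(TP+FP), F1 = 2PR/(P+R); every 0/0 ratio is
reported as 0 with an explicit degenerate flag rather than omitted, so a
phenotype never observed in a cohort (the obesity case) stays visible in the
report. The two levels are computed independently and never collapsed: a
concept can be recognised perfectly per document while the patient-level
call is wrong, as with fluctuating smoking status.

## Statistics

* **Fisher's exact test** — two-sided p is the minimum-likelihood sum:
  hypergeometric point probabilities over the support of cell *a* at fixed
  margins that do not exceed the observed probability (relative slack
  1 + 1e-7), computed in log-gamma arithmetic. One-sided alternatives are
  exposed. Empty row/column margins return p = 1 with a degenerate flag.
  Note on the reference HTN–CVA figures: the ET table reproduces the
  reported value under the two-sided test, while the PV table reproduces it
  under the one-sided test — the source mixed sidedness conventions — so
  both values are always surfaced for exact-test comparisons.
* **Two-proportion test** — pooled-proportion z without continuity
  correction, two-sided normal p; this is the convention that reproduces
  the reported cohort-comparison p column. Degenerate when the pooled
  proportion is 0 or 1.
* **Odds ratio** — ad/bc with the Haldane–Anscombe 0.5 correction applied
  to all cells iff any cell is zero; Wald CI on the log scale.
* **Logistic regression** — IRLS (Fisher scoring), convergence when the max
  absolute coefficient change < 1e-8 within 100 iterations (flagged
  otherwise); Wald standard errors from the observed information X'WX;
  |coefficient| > 15 flags (quasi-)separation and suppresses the CIs.
  Wald (not profile-likelihood) intervals match the style of reported CIs.
* No multiplicity correction anywhere; every report labels its p-values
  unadjusted.

## The synthetic generator

The generator emulates the study conditions so that every stage is testable
without patient data. All randomness flows from one seed through named
`SeedSequence` spawn keys (phenotypes / events / dates / strata / rendering),
so cohort sampling and corpus rendering are independently reproducible.

* **Cohorts** — ET: 560 patients, PV: 360 (defaults; any n). Risk-factor
  prevalences and event-type prevalences are the cohort rates the pipeline
  is expected to recover (e.g. HTN 21.3% ET / 23.1% PV; obesity 0).
* **Comorbidity links** — conditional probabilities such as
  P(HTN | DM) = 0.692 (ET) are imposed by a no-interaction logistic link
  P(target | givens) whose parameters are root-solved against the target's
  marginal and all configured conditionals over the exact joint of the
  (independent) given concepts; the single-link case reduces to the
  closed-form complement rate. Infeasible specifications (a conditional
  implying P(target | ¬given) outside [0, 1]) are rejected with a
  diagnostic.
* **Thrombotic events** — an overall-TE indicator is drawn from
  `logit P(TE) = β₀ + Σ log(OR_j)·x_j` over the four risk factors, with β₀
  calibrated by root-finding so the cohort's expected TE rate is exactly the
  configured 20% (ET) / 35% (PV); the planted HTN odds ratios are 2.5 (ET)
  and 1.5 (PV), the values the multivariable model should recover. HC, DM
  and smoking carry mild planted effects (OR 1.1–1.3). Event-type vectors
  for TE-positive patients are independent Bernoullis conditioned on ≥ 1
  event, their rates fixed-point-solved so each event concept's marginal
  prevalence is exact and overall TE equals the union of event types by
  construction.
* **Dates** — diagnosis uniform over 2005–2017; 60% of patients get a
  cytoreduction interval starting 30–365 days after diagnosis and lasting
  1–5.5 years. Each positive patient-event is assigned a timing stratum
  (defaults 58/30/12% ET, 59/24/17% PV, the reference CVA proportions), and
  the renderer places that event's mentions only in documents consistent
  with the stratum, so timing recovery is exact on noise-free corpora.
* **Documents** — per-patient counts are a rounded log-normal with
  μ = ln(median) and σ = ln(q3/q1)/(2·z₀.₇₅) solved from the target median
  and IQR (right-skewed, as in the real corpora; the log-normal cannot also
  reproduce the IQR's asymmetry about the median, so the upper quartile runs
  somewhat high). Dates span one year before to seven years after
  diagnosis, with documents appended if a required timing stratum has no
  eligible date.
* **Mentions** — each true phenotype plants max(1, Poisson(rate)) affirmative
  sentences (default rate 4/patient; a condition a patient truly has is
  mentioned at least once, a +0.018 bias at rate 4 that is negligible
  against the generator's own sampling noise). Templates cover affirmative,
  historical, negated, family-history and colloquial forms ("The patient
  smokes 20 cigarettes a day"), each exercising a specific engine rule.
  Absent phenotypes plant Poisson-rate negated (default 0.5) and
  family-history (0.2) mentions; ambiguous-abbreviation sentences (rate 0.3)
  use the shorthand in an unrelated sense and carry no gold annotation.
  Every other planted mention is recorded as gold with its intended flags.

**What the generator does not emulate** — and hence what passing tests do
not show: real clinical prose (spelling variation, typos, free word order,
department-specific shorthand beyond the configured ambiguity), laboratory
values and driver mutations, documentation gaps, and NER *errors*: the
template language is deterministic, so the rule engine recognises it
perfectly, the aggregated counts are noise-free, and the threshold optimizer
legitimately settles on t = 0 with patient-level F1 = 1. The synthetic
corpora therefore validate the *filtering semantics* (negation, subject,
corroboration, aggregation, optimization machinery) and the statistical
layer's parameter recovery, not robustness to real-world language, which the
two-step validation design would quantify on real records via the
gold-standard chart review.

## Problem sizes used in the checks

Prevalence recovery at n = 10⁴ (3 binomial SEs); conditional-link recovery
vs a rejection-sampling oracle at n = 10⁴; odds-ratio recovery over 100
replicates of n = 5600 (ET) and n = 3600 (PV), requiring ≥ 90/100 CI
coverage of the planted value; document-count and zero-noise NER checks at
the cohort scale n = 560; end-to-end held-out phenotyping over 10 replicate
corpora of 560 patients with a 20% gold subsample. Exact-test equivalence
against brute-force hypergeometric enumeration covers every 2×2 table with
N ≤ 40 at 1e-12.

## Known limitations

* The context rules are fixed-window heuristics; long-range negation,
  uncertainty ("query DVT") and list constructions are out of scope.
* Surface forms shared between concepts are rejected at vocabulary load
  rather than disambiguated (only abbreviation ambiguity is modelled).
* The event-type assignment is independent of risk factors given TE, so
  per-event-type odds ratios are attenuated relative to the overall-TE one.
* The PV "threshold of 1 mention" phrasing is ambiguous in the reference
  material; the stricter strictly-greater reading is used throughout.
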