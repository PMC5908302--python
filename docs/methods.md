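# Methods

## Data model

A cohort contributes, per patient, a pre-treatment leukapheresis reference
sample and up to five treatment samples (before each of four vaccine doses,
and at the DTH evaluation a month after the last dose). Expression is a
gene × sample intensity matrix with optional per-probe detection p-values.
All downstream computation runs on the fold-change tensor
g<sub>i,p</sub>(t) = I(i, sample of p at t) / ref(i, p), t = 1..5, with a
per-(patient, timepoint) availability mask. Missing cells are *skipped* —
every score is a sum or mean over available cells only; no imputation is
performed inside the scores.

**Reference imputation.** ref(i, p) is patient p's leukapheresis intensity;
for patients lacking one, the unweighted per-gene mean of the reference
intensities of the patients that do have one. (This makes fold changes for
such patients comparable in level but not patient-anchored; they are treated
identically downstream.)

**Probe screening.** A gene is eliminated iff (a) its intensity is below the
cutoff (default 20) in *every* sample, or (b) it is never detected
(detection p > 0.01 in every sample), or (c) every available fold change
lies strictly inside the open window (0.5, 2.0) — i.e. the gene never moves
by at least two-fold in either direction. Boundary convention: a fold change
of exactly 0.5 or 2.0 rescues the gene (the window is open). The detection
and intensity screens default to the permissive "at least one sample
passes" reading; `detection_scope="all"` switches to requiring every sample
to pass. The screens are evaluated in the order intensity → detection →
fold-change window and the first failure is recorded as the drop reason.

**ΔΔCt.** Relative qPCR quantification uses the Livak convention:
fold change = 2^(−ΔΔCt), ΔΔCt = (Ct_target − Ct_housekeeping)_sample −
(Ct_target − Ct_housekeeping)_reference. Base 2 is the field standard for
cycle-threshold data (one cycle = one doubling).

## The nine scores

With R / N the responder / non-responder patient sets and ⟨·⟩ the mean over
*available* patients:

| score | definition | reads as |
|---|---|---|
| `sim` | abs(⟨g(1)⟩_R − ⟨g(1)⟩_N) | groups start alike |
| `diff26` | Euclidean distance of the two group-mean series over t = 1..5 | trajectories diverge |
| `tscoreR`, `tscoreN` | Σ sign(log g) over the group's cells at t ∈ {4, 5} | consistent late up/down |
| `SignifR`, `SignifN` | #{cells with g > 2 or g < 0.5} (strict) | significant moves |
| `absFCR`, `absFCN` | Σ abs(ln g) over the group's cells | regulation magnitude |
| `NumSigPos` | #{p ∈ R with g > 2 at some t} | breadth of up-regulation |
| `NumSigNeg` | −1 − #{p ∈ R with g < 0.5 at some t} | −1 ⇔ nobody goes down |

Numerical conventions:

* **Log base.** `tscore` only uses the sign of the logarithm, so its base is
  irrelevant; `absFC` is base-dependent and its stock thresholds (10.5 /
  2.5) are calibrated for the **natural** log, the default. The base is
  switchable (`log_base ∈ {e, 2, 10}`) and recorded in the score table's
  metadata, but the stock rule thresholds are only meaningful at base *e*.
* sign(log 1) = 0; the significance counts use strict inequalities, so a
  fold change of exactly 2 or 0.5 does not count.
* `NumSigNeg`'s −1 − count encoding is chosen so the selection rules' test
  "NumSigNeg = −1" literally means "no significant down-regulation in any
  responder"; it is the only encoding consistent with both that sentinel
  and the score being a (negated, offset) count.
* `diff26` spans all five post-reference time points. Including the
  reference point itself would add an identical 1 to both group series and
  contribute zero to the distance, so the restriction is immaterial under
  this reference convention; the time range is configurable.
* Genes whose data cannot support a score (a group with no available sample
  at a required time point) get NaN for that score — flagged, never a
  silent zero — and are excluded from any rule referencing it.

## Selection rules

Rules are conjunctions of `(field, comparator, threshold)` predicates over
the score table; the engine supports `<`, `>`, `≥`, `≤` and `=` (equality on
real-valued scores uses tolerance 1e−9; integer scores compare exactly). The
five stock searches are listed in the README. Two deliberate readings:

* The fifth rule's count predicate is **equality** (`NumSigPos = 5`):
  the "up in 5 of 7" archetype, and the only reading under which rules 4
  and 5 select disjoint gene sets. `rule5_ge=True` switches to ≥.
* Rule 3's `tscoreN = −1` requires an **odd** number of available
  non-responder cells at the last two time points (a sum of k nonzero ±1
  terms has the parity of k). With complete data (5 patients × 2 points =
  10 cells) the rule is unsatisfiable; it is meaningful precisely under the
  study-like availability pattern (2 + 1 = 3 cells). This is a property of
  the published thresholds, not of this implementation.

## Synthetic cohorts

`simulate_cohort` generates log fold changes as
log g = planted effect + ε, ε ~ N(0, noise_sd²) i.i.d. per cell, with
noise_sd = 0.2 (natural-log units) by default — multiplicative noise of
roughly ±20%, a realistic magnitude for bead-array fold changes in whole
blood. Defaults mirror the motivating study's conditions: 7 responders,
5 non-responders, and (optionally, `missing_pattern="study"`) the per-
timepoint sample counts 5,5,5,5,6 (responders) and 3,4,1,2,1
(non-responders).

Planted archetypes (defaults):

* **similar_start_diverging** — responders gain 6-fold at t ∈ {4, 5}.
  A 4-fold effect would put the group-mean distance at √18 ≈ 4.24, *below*
  the `diff26 > 5` threshold; 6-fold yields ≈ 7.1, clearing it at the
  default noise. This is why the divergence archetype has its own effect
  size (`divergence_fold`) while the other archetypes use `up_fold` = 4.
* **up_in_R_down_in_N** — responders ×4 at t ∈ {4, 5}, non-responders
  ×0.6 (a modest but sign-reliable down-regulation).
* **up_in_R_flat_in_N** — responders ×4 late; the available non-responder
  late cells get a small alternating wobble (±0.45 natural-log units), one
  more down than up, so the sign sum lands on the −1 sentinel when the
  number of those cells is odd.
* **up_in_6_of_7 / up_in_5_of_7** — exactly 6 (resp. 5) responders gain
  ×4 at their available late cells; the remaining responders stay flat.

Archetypes 1–3 additionally have their first-timepoint noise centered within
each group (the group means of the available log fold changes are exactly
zero). This expresses the archetypes' premise — both groups genuinely share
the baseline — rather than leaving the baseline-similarity score to the
sampling noise of a 7-vs-5 cohort, where `sim < 0.1` would fail ≈ 40% of the
time for reasons unrelated to the planted structure. Null genes are never
centered.

**What passing recovery tests shows — and what it does not.** The generator
produces independent log-normal cells with clean planted structure. It does
not emulate probe-level artifacts, within-patient correlation across time,
normalization residue, or baseline heterogeneity between patients. Recovery
results therefore validate the *pipeline logic* (scores, rules, masks,
thresholds) under the stated noise model, not the biological sensitivity of
the procedure on real arrays.

**Recovery metrics.** `evaluate_recovery` reports, per archetype, both
*union* sensitivity (planted gene appears anywhere in the selection union)
and *self* sensitivity (matches its own archetype's rule), plus the null
selection rate. The pipeline's headline sensitivity is the union reading:
archetypes overlap by construction (e.g. a strong rule-3 gene usually also
satisfies rule 2), and at noise sd 0.2 rule 3's own `absFCN < 2.5` budget —
2.5 natural-log units across 11 available non-responder cells whose noise
alone is expected to consume ≈ 1.28 — makes reliable self-matching
mathematically impossible to guarantee (the wobble needed for reliable signs
and the absFCN headroom are jointly infeasible); its planted genes are
nonetheless recovered through rule 2 essentially always. At noise sd 0.1
every archetype self-matches.

`simulate_survival` draws exponential event times with the stated group
medians (scale = median / ln 2); each patient is independently censored with
probability `censor_frac`, at a time uniform on (0, T).

## Survival analysis

* Groupings: immunological (DTH-positive vs negative/never-tested) and
  clinical (among array-profiled patients: DTH-positive, or DTH-negative
  surviving beyond a threshold defaulting to the 11-month historical median
  of comparable non-responders; the threshold is a parameter).
* Kaplan–Meier estimation and both log-rank variants are delegated to
  lifelines (Mantel–Cox, and `weightings="wilcoxon"` for the
  Gehan–Breslow–Wilcoxon at-risk weighting); p-values from χ² with 1 df.
  Ties between events and censorings at the same time follow the standard
  convention (events first).
* Two medians are reported, labeled: the **pooled** sample median of the
  follow-up column (censored and uncensored pooled — the naive summary
  printed in small-trial tables; on the packaged cohort 41.4 / 9.85 months)
  and the **KM** median, smallest t with S(t) ≤ 0.5 (35.1 months for the
  responders). They answer different questions and differ whenever
  censoring is informative about the tail.

## ROC evaluation

Positive class = responders, fixed direction "higher ⇒ responder" (the
screening targets genes overexpressed in responders; an auto-flip flag is
deliberately absent from the default path). AUC is computed by pair counting,
P(pos > neg) + ½ P(pos = neg), identical to the normalized Mann–Whitney U.
Cutoff candidates are the midpoints between adjacent pooled unique values
plus ±∞; the reported cutoff maximizes Youden's J = sensitivity +
specificity − 100 under "≥ cutoff ⇒ responder", ties broken toward the
smallest cutoff. Constant pooled input is flagged `degenerate` (AUC 0.5,
J = 0).

The Mann–Whitney p-value is two-sided, 2·min(tail) capped at 1. With both
groups ≤ 12 the exact null distribution is used: the closed-form recursion
for tie-free data, or full enumeration of all C(n₁+n₂, n₁) labelings when
ties are present (≤ 5·10⁵ labelings; beyond that, the tie-corrected normal
approximation).

## Connector networks

Per-seed neighbor lists from multiple interaction sources are merged by set
union after upper-casing symbols (no fuzzy matching — JUN and JUNB stay
distinct). A connector is a non-seed neighbor present in ≥ `min_degree`
(default 2) distinct seeds' merged lists; its degree is the number of such
seeds. A seed appearing in another seed's list becomes a direct seed–seed
edge and is never counted as a connector. Output is a deterministic edge
list plus a degree ranking; rendering is out of scope.

## Problem sizes used in the shipped checks

Oracle equivalence runs 100 random tensors of 5 genes × 7 patients against
a straight-loop reference at 1e−12; planted recovery averages 50 seeded
cohorts of 205 genes under the study-like availability pattern; survival
calibration runs 500 equal-hazard cohorts of 30 + 30 patients with 20%
censoring and checks the log-rank p-values against uniformity
(Kolmogorov–Smirnov). These sizes give stable Monte-Carlo estimates for the
thresholds being checked.

## Known limitations

* The stock `absFC` thresholds assume natural-log scoring; switching the
  log base without rescaling them changes the third rule's meaning.
* The clinical regrouping takes the survival threshold as given; it does
  not model the uncertainty of that historical median.
* The exact Mann–Whitney at the motivating study's group sizes (≤ 7 vs 5
  per time point) has limited resolution; perfect separation at n = 5 vs 1
  cannot reach p < 0.05, so "AUC = 1 with non-significant p" is an expected
  small-n outcome, not a contradiction.
* Reader support covers tab/comma-separated text exports; native binary
  array formats and repository download formats are out of scope.
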