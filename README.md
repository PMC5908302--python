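# vaccsig

Time-course gene-expression screening for treatment-response signatures in
small vaccinated cohorts.

## The problem

In early-phase cancer-vaccine trials (the motivating setting is a dendritic-
cell vaccine for advanced melanoma), a handful of patients give blood at a
pre-treatment leukapheresis and again before each vaccine dose and at the
final delayed-type-hypersensitivity (DTH) skin-test evaluation. The question
is which genes' expression *trajectories* separate patients who respond to
the therapy from those who do not — with a dozen patients, uneven sample
availability, and no replication, so standard differential-expression
machinery is a poor fit. `vaccsig` implements the screening procedure as a
tested, reusable pipeline:

1. **Fold changes.** For gene *i*, patient *p* and treatment time point
   *t* = 1..5, g<sub>i,p</sub>(t) = intensity at *t* divided by that
   patient's leukapheresis reference (patients without one fall back to the
   per-gene mean reference of the patients that have one). Probes are
   screened out when below 20 intensity everywhere, never detected at
   p ≤ 0.01, or with every fold change strictly inside (0.5, 2).
2. **Nine per-gene scores** over the responder (R) / non-responder (N)
   split: `sim` = |⟨g(1)⟩
   <sub>R</sub> − ⟨g(1)⟩<sub>N</sub>| (baseline similarity);
   `diff26` = Euclidean distance between the group-average series;
   `tscoreR`/`tscoreN` = Σ sign(log g) over the last two time points;
   `SignifR`/`SignifN` = number of fold changes > 2 or < 0.5;
   `absFCR`/`absFCN` = Σ |ln g|; `NumSigPos` = number of responders with
   g > 2 somewhere; `NumSigNeg` = −1 − (number of responders with g < 0.5
   somewhere), so −1 means "no responder ever goes down".
3. **Rule-based selection.** Five stock conjunctions of score thresholds
   (e.g. `sim < 0.6 & diff26 > 5`) pick candidate genes; arbitrary
   user-defined rules are supported.
4. **Biomarker evaluation.** Per-gene, per-timepoint ROC curves: AUC by
   cross-group pair counting, the Youden-optimal cutoff over midpoints of
   adjacent values, sensitivity/specificity at that cutoff, and an exact
   Mann–Whitney p-value for small groups.
5. **Survival comparison.** Kaplan–Meier curves, pooled and KM medians, and
   both the Mantel–Cox log-rank test and its Gehan–Breslow–Wilcoxon
   (at-risk-weighted) variant, via lifelines.
6. **Connector genes.** Per-seed interaction lists from multiple databases
   are merged by set union; neighbors appearing in ≥ 2 seed lists are
   reported as network connectors with their degree.

A seeded synthetic-cohort generator (`vaccsig.simulate`) produces expression
matrices and fold-change tensors with planted genes matching each selection
archetype, the study-like missing-sample pattern, and exponential survival
times — so every stage of the pipeline can be validated against known truth.

The package ships the 28-patient clinical table of the motivating cohort
(gender, AJCC stage, DTH result, overall survival, event flag, array-profiled
flag) as a fixture for the survival and reclassification computations.

## Worked example

Run the full simulate → preprocess → score → select → evaluate → survival
chain on the default configuration (7 responders + 5 non-responders,
study-like sample availability, 200 null genes, one planted gene per
archetype, log-normal noise sd 0.2):

```bash
vaccsig run --seed 1 --out demo/
```

`demo/summary.json` then reports (numbers printed by the run above):

```
"filter":    {"kept": 7, "dropped": 198}
"selection": {"union_size": 5, ...}
"recall":    1.0
"recovery":  {"null_selection_rate": 0.0,
              "union_sensitivity": {... all five archetypes: 1.0}}
```

All 205 simulated genes enter the filter; 198 (the pure-noise genes plus
nothing else) are eliminated as never leaving the 0.5–2-fold window, and the
5 planted genes plus 2 borderline nulls survive to scoring. Every planted
gene is recovered by the rule set (`recall` = 1.0) and no null gene is
selected. The survival block of the summary compares the two simulated
groups (pooled medians ≈ 62.2 vs 12.8 months for this seed).

On the packaged patient table:

```bash
vaccsig survival --out surv.json           # immunological grouping (DTH)
vaccsig survival --by clinical --out c.json
```

prints group sizes 12/16, pooled median survival 41.4 vs 9.85 months,
KM medians 35.1 vs 9.0 months, log-rank χ² = 5.47 (p = 0.019) and
Gehan–Breslow–Wilcoxon χ² = 7.59 (p = 0.0059): DTH-positive patients live
significantly longer. The clinical regrouping of the 12 array-profiled
patients yields 7 responders and 5 non-responders.

As a library:

```python
import vaccsig as v

tensor, groups, truth = v.simulate_cohort(
    v.SimulationConfig(seed=1, missing_pattern="study"))
scores = v.score_all(tensor, groups)          # nine scores per gene
result = v.select_genes(scores)               # five stock rules
roc = v.roc_timecourse(tensor, groups, result.union[0], timepoint=4)
print(roc.auc, roc.cutoff, roc.sensitivity, roc.specificity, roc.p_value)
```

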