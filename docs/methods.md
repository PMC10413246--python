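# Methods

## Problem setting

`dxpath` mines *ordered* disease-triplet pathways (A→B→C over incident
diagnosis dates) from longitudinal claims histories in a matched
case-control design, and uses them to predict case status — the motivating
application being incident dementia in older adults. The pipeline is
hypothesis-led rather than purely exploratory: the unit of analysis is the
ordered triple of distinct disease categories, which keeps temporal
precedence (a prerequisite for causal reasoning) while bounding the
combinatorial explosion of longer sequences.

## Incident validation and sequences

A (person, category) pair is accepted as a true incident condition iff some
365-day window holds ≥3 outpatient claims of the category, or the category
appears on ≥1 inpatient claim. The window check is exact: with outpatient
claim dates sorted, the pair is valid iff `d[i+2] − d[i] < 365` days for
some i. The incident date is the earliest claim of the category in *any*
setting once validity is established (the first-diagnosis date does not
restrict setting). Incidents on or after the person's index date are
dropped with a logged count, as are outcome-defining categories passed via
`exclude_categories` — keeping the outcome out of its own predictors.

**Ties.** Two diseases with the same incident date carry no order relation:
they never form an ordered pair with each other, but each still pairs with
strictly earlier/later diseases. This makes `enumerate_triplets` emit
exactly the ordered triples with strictly increasing dates; for n strictly
dated diseases that is n(n−1)(n−2)/6.

## Screening

Each triplet supported by ≥`min_case_support` (default 10) **case**
timelines is tested by univariable logistic regression of case status on
exposure. With a single binary covariate the MLE equals the 2×2
cross-product ratio, so the implementation is closed-form:
OR = (a·d)/(b·c), Wald z = log(OR)/√(1/a+1/b+1/c+1/d), two-sided normal
p. Any zero cell is logistic separation: the record is flagged
non-estimable and never selected — no continuity correction, matching the
no-adjustment screening design. Selection keeps OR > 1 and p < α
(default .05) with no multiplicity correction; under a null cohort the
expected selection rate is therefore ≈ α/2 (the OR>1 filter halves the
rejection region), which the test suite verifies empirically.

## Corresponding features

Each selected triplet expands into 15 binary features in 7 groups — group
sizes (1,2,2,3,3,3,1); groups 1–4 ordinal, 5–7 nonordinal (see the README
table). Group 2 contains only the *consecutive* doublets A→B and B→C — not
A→C — deliberately: the doublet features describe adjacency within the
triplet. Nonordinal tokens sort their categories lexicographically so
deduplication is deterministic. A person's feature is 1 iff some triplet in
the intersection of their enumerated triples with the *selected* set
generates the key (features are defined from pathways that survived
screening); `mode="all"` instead fires any vocabulary key generated by any
of the person's enumerated triples, for users who prefer
pattern-in-raw-sequence semantics. The default is monotone in the selected
set: enlarging the selection can only add 1s.

## Feature selection and classification

* **LASSO**: `LogisticRegressionCV` (liblinear, pure L1) over a 50-point
  log-spaced λ grid from 1e−4 to 1e4, choosing λ by minimum mean
  cross-validated deviance (not the 1-SE rule — the least-surprising
  default where no rule is prescribed) with stratified, seeded 3-fold
  folds; nonzero means |coef| > 1e−8. All-constant columns are dropped
  with a log entry. *by_group* runs seven independent fits (one per feature
  group) and unions the selections; *one_model* fits all columns at once.
* **Classifiers**: SVM with a linear kernel by default — the feature space
  is high-dimensional sparse binary, where linear margins are the standard
  choice (RBF available via the `kernel` argument) — tuned over
  C ∈ {0.01, 0.1, 1, 10}; random forest with 200 trees tuned over
  max_depth ∈ {None, 8} and min_samples_leaf ∈ {1, 5}. Tuning uses
  stratified seeded 3-fold CV with AUC as the criterion; the winner is
  refit on the full training split. No class weights: the cohort is 1:1
  matched by construction.
* **Evaluation**: confusion metrics at the classifier's native operating
  point (margin sign for SVM, majority vote for RF); metrics with zero
  denominators are reported as `nan`, never 0. AUC is the Mann-Whitney rank
  statistic with mid-rank tie correction, which equals trapezoidal ROC
  integration; the suite checks both routes agree to 1e−9.
* **Final model**: argmax of test sensitivity, ties broken by higher AUC
  then fewer features — sensitivity first because missing a future case is
  the costly error in a screening application.

## Disease trees and the temporal network

Final-model feature keys are mapped back through the vocabulary's
provenance to the screened triplets that generated them. Triplets sharing
the first disease merge under one parent; shared (first, second) prefixes
merge at level 2. A person covers a node iff the root-to-node ordered path
is a strictly dated subsequence of their sequence, so a child's covered
set is a subset of its parent's by construction. A node's *dementia
probability* is its covered-case fraction.

Parents are ordered greedily by incremental newly-covered case count
(ties: lexicographic). The **chosen parent count** is the number of
parents taken before the first whose marginal gain falls below
ε × (total cases), ε = 0.1% by default. The plateau criterion is a design
choice of this package — the underlying idea ("keep parents while they
still add covered cases") admits several formalisations — so the full
curve and marginal gains are always exported for users to apply their own
cut. Each retained parent keeps its top-5 children by dementia probability
(ties: higher case count, then lexicographic), recursively.

The temporal network adds, for every retained root→child→leaf path, the
count of case persons covering the *full* path to both of its edges
(d1→d2, d2→d3); weights aggregate across pathways sharing an edge **before**
the ≥50-case threshold is applied, since edge thickness is meant to show
total path traffic. Distinct-category triples make self-loops impossible.
Exports: GraphML (networkx), a minimal hand-written DOT (no pydot
dependency), JSON trees, CSV coverage curve and an optional matplotlib
curve plot.

## Synthetic cohort generator

The generator emulates the structure of an older-adult national claims
cohort; it is the package's test bed, not a patient-level simulator.

* **Registry**: cases get an index date uniform over the study window
  (2003–2013 by default) beyond a minimum lookback of 1095 days; each
  control copies its case's sex and birth year and draws a uniform day in
  the same calendar year (matching is on index *year*), clamped to honour
  the lookback. Ages are uniform in 55–90; sex is Bernoulli(sex_ratio).
* **Background diagnoses**: per person, Poisson(background_rate × years
  observed) distinct categories drawn uniformly without replacement from
  the vocabulary, with uniform incident dates — the simplest exchangeable
  null. Defaults: 2 incident diagnoses/person-year over a 40-category
  vocabulary.
* **Planted pathways**: with probability p_case (cases) / p_control
  (controls), the three ordered incident dates are placed before the index
  date with inter-diagnosis gaps uniform in [30, 365] days and a final gap
  to the index date uniform in [30, 180] days, and they *replace* any
  background incident date of those categories — so the configured
  probability really is the probability of the full ordered occurrence.
  Planting at p_case=0.5 vs p_control=0.1 implies a design odds ratio of
  (0.5/0.5)/(0.1/0.9) = 9; background chance occurrences add equally to
  both arms and slightly attenuate it, which is why the vocabulary default
  is 40 categories (at very small vocabularies the chance-pattern rate
  becomes non-negligible).
* **Claims emission**: each incident becomes one inpatient claim with
  probability 0.10, else three outpatient claims inside a 300-day window —
  every planted or background incident passes the validation rule by
  construction, so validation is exercised as a filter on window violations
  and sub-threshold repeats rather than as a lottery. An additional
  outpatient stream at 30 visits/person-year re-bills already-established
  categories (never moving a first-diagnosis date), reproducing the heavy
  utilisation volume of older-adult claims.
* **Determinism**: one global seed spawns four independent substreams
  (registry, background, planting, claims); identical configs give
  byte-identical CSVs.

What the generator does **not** emulate: comorbidity correlation structure
beyond the planted pathways, realistic ICD-9 code microstructure (category
labels are abstract), mortality/censoring, or secular trends in coding.
Passing tests therefore demonstrate that the pipeline recovers ordered
associations it was designed to detect under exchangeable background noise
— not that it would achieve any particular performance on real claims.

## Split, matching and problem sizes

Matched pairs are the unit of the 2/3–1/3 train/test split (both members
always co-assigned; train count = nearest integer, ties toward train).
`match_controls` performs exact matching on sex and index year with a
configurable age band (default 0 = exact year of age), sampling without
replacement; exhausted strata yield explicitly reported unmatched cases.

The test suite exercises the full pipeline at 500 matched pairs with three
planted pathways (p_case=0.4, p_control=0.1) over 10 seeds, and
null-calibration at 200 pairs over 20 replicates — sizes chosen so the
whole suite runs in a few minutes on one CPU while leaving Monte-Carlo
margins comfortably interpretable. Funnel counts at these sizes (≈10³
supported triplets, ≈10³ features) are three orders of magnitude below a
national cohort's, so headline counts from any particular claims database
are not reproduced, only the structural behaviour.

## Numerical and degenerate-input choices

* Zero-cell 2×2 tables: non-estimable, excluded (no Haldane correction).
* Metrics dividing by zero: `nan`, not 0 — degenerate test labels stay
  visible.
* LASSO nonzero threshold 1e−8 on |coef|; liblinear's internal shuffling
  is seeded for reproducibility.
* Coverage-curve ties in greedy parent selection break lexicographically;
  child-ranking ties break by case count then category.
* Empty screening selections stop the pipeline cleanly at the screening
  stage with the partial outputs retained.
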