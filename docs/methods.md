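# Methods

This note documents the models, numerical choices and known limitations
of the package; it is the reference for why the defaults are what they
are.

## The domain ontology

All structure flows from one declarative document (versioned YAML): a
list of entities with one-to-many relations (here `Patient` 1—N
`Aneurysm`, linked by a `patient_id` foreign key), typed attributes named
`Entity.Attribute` (numeric with unit and range, flat categorical with a
closed value list, hierarchical referencing a concept tree, boolean),
concept hierarchies as nested trees, validation rules, and derived
variables. Derived variables use a deliberately small declarative
language — arithmetic over attributes, `count(ChildEntity)` for related
records, `years_between(a, b)` for whole-year date differences — parsed
through a whitelisted AST walker, so an ontology document can never
execute arbitrary code. Validation rules are generated automatically
from the attribute declarations (range, membership, boolean parsability,
not-null) and can be extended with explicit cross-field `implies` rules;
violations are always reported per record and never silently dropped —
removing offending rows is a separate, explicit preprocessing decision.

The serialization format is this package's own design — there is no
established on-disk convention for this kind of ontology document — and
is carried by `schema_version` for future evolution.

## Preprocessing

`flatten` joins parent attributes onto each child record (patient age and
sex repeated on every aneurysm of that patient) after evaluating derived
variables; analysis runs at aneurysm grain, matching the unit of analysis
of the cohort the tool was designed for. Missing values are handled by
listwise deletion with a logged count — the most transparent default for
an expert-in-the-loop tool; no imputation is attempted. Numeric columns
are min-max scaled to [0, 1] for the distance pipeline (a constant column
maps to 0.5; it carries no pairwise information either way). For
classification, categorical and hierarchical attributes are one-hot
encoded at their declared leaf categories; the hierarchy informs only the
distance calculation, not the classifiers. The positive class is `True`
for boolean targets and is echoed in every report.

## Mixed-type distances

For two records the numeric block contributes
`d_num = sqrt(Σ_j (x_j − y_j)² / p_num)` over the `p_num` comparable
normalized attributes (the division bounds it in [0, 1]); the categorical
block contributes `d_cat = 1 − (Σ_k s_k)/p_cat`, where `s_k` is the
exact-match indicator for flat attributes and the Wu-Palmer similarity
`2·depth(LCA)/(depth(a)+depth(b))` for hierarchical ones (defined as 1
when `a = b`). The blocks are combined Gower-style as
`(p_num·d_num + p_cat·d_cat)/(p_num + p_cat)`, so every selected
attribute counts equally. Attributes missing in either record are
excluded from that pair's numerator and denominator; a pair with no
comparable attribute receives distance 1 with a logged warning.

Wu-Palmer was chosen as the canonical "relative position in the concept
hierarchy" similarity; it is isolated behind `concept_similarity` so an
alternative graded similarity can be swapped in without touching the
matrix assembly. Only pseudo-metric properties are claimed (symmetry,
zero self-distance, [0, 1] bounds): graded concept similarity does not
guarantee the triangle inequality. One subtlety of the Euclidean-mean
numeric block: because of the square root, appending a numeric attribute
on which two records agree can slightly *increase* their combined
distance when many agreeing categorical attributes are present (the
numeric block's effective weight grows faster than its value shrinks).
The monotonicity guarantee — adding an agreeing attribute never increases
distance — therefore holds for categorical attributes but not universally
for numeric ones; this is an accepted property of the chosen combination
rule.

## Sammon mapping

The stress is `E = [1/Σ_{i<j} d*_ij] · Σ_{i<j} (d*_ij − d_ij)²/d*_ij`
with `d*` the input and `d` the embedded Euclidean distances. Updates
follow the classical diagonal pseudo-Newton rule, each coordinate moving
by `magic_factor · (∂E/∂y) / |∂²E/∂y²|`. Defaults: `magic_factor` 0.3,
`max_iter` 500, relative tolerance 1e-9 — conventional values for this
algorithm family. Any step that would increase the stress is halved up
to 20 times, which enforces a non-increasing stress trace and guarantees
the final stress never exceeds the initialization's. Initialization is
the classical metric-scaling (principal-coordinate) solution by default,
making the map fully deterministic; seeded uniform-random initialization
is available. Zero input distances (duplicate records) are replaced by
`1e-6 × max(d*)` in the weights so duplicates co-locate without dividing
by zero; an all-zero matrix is rejected (no topology to preserve). A
non-finite update triggers one seeded jitter-and-retry, then an error.

## Meta-classification

Fold assignment is stratified (per-fold class counts within one record of
proportionality), with `k` reduced to the smaller class size when
necessary. Each configuration is fit on nine folds and scored on the
tenth; the pooled out-of-fold scores yield one AUC per configuration,
computed in the Mann-Whitney rank form with ties counted one half.
Pooling (rather than per-fold averaging) avoids degenerate small-fold
AUCs and is recorded in the report's provenance. Standardization for the
scale-sensitive families (SVM, MLP, logistic regression) is fit inside
each training fold, so no statistics leak across the fold boundary; tree
and naive-Bayes families take the raw encoded features.

Default grids: naive Bayes over two smoothing values; random forest with
100 trees, unbounded and depth-limited; logistic regression over
C ∈ {0.1, 1, 10}; RBF-SVM over the coarse exponential 3×3 grid
C ∈ {0.1, 1, 10} × γ ∈ {0.01, 0.1, 1}; an lbfgs-trained MLP with 16 or
32 hidden units (iteration-capped — a screening indicator does not need
fully converged networks). Grids are conventional and swappable; they
are configuration, not claims. Each configuration derives its random
state from a hash of (seed, family, configuration name), so results are
bit-for-bit reproducible and independent of execution order — parallel
execution is a contract, not a primitive. A failing configuration is
recorded and skipped; only a run in which everything fails errors out.

The verdict thresholds (best AUC < 0.60 → no measurable influence,
≥ 0.75 → strong indication, else weak) operationalize the qualitative
"close to 0.5" / "satisfying" reading of screening AUCs; they are
configurable and echoed in every report. The indicator deliberately
reports no statistical significance, no causal direction, no
feature-subset attribution and no inter-feature correlation.

## Synthetic registry generator

The generator emulates the registry cohort, not any individual patient:

| parameter | default | rationale |
| --- | --- | --- |
| patients | 774 | cohort size the tool was designed around |
| extra aneurysms | Poisson(1/3) per patient | 774·(4/3) = 1032 expected aneurysms |
| female probability | 2/3 | the 2:1 female:male ratio of aneurysm cohorts |
| age | normal(56, 12) truncated to [18, 90] years | peak incidence at 55–60 years |
| width | log-normal(μ=1.6, σ=0.55) mm, clipped to [0.5, 60] | median ≈ 5 mm with a realistic small-aneurysm bulk and rare giants; clipping keeps records inside the declared ontology range |
| locations | AComm .28, MCA .22, ICA .20, PComm .12, BasilarTip .06, Pericallosal .04, PICA .04, Vertebral .04 | plausible relative frequencies; the real catalog is unpublished |
| risk coefficients | width 0.9 (per log-mm), AComm 0.8, posterior 0.3, age −0.1 (per 12 y), multiplicity 0.25, sex 0.0 | moderate effects on the clinically recognized factors; sex intentionally zero so adding it changes screening AUCs only marginally |
| rupture rate target | 0.38 | the cohort's marginal rupture incidence |

The intercept is calibrated by bisection of the expected marginal rate
`E[expit(b0 + η)]` on one large fixed-seed covariate draw (deterministic,
monotone, bracket widened up to five times; tolerance 0.005). In
deterministic leakage mode presentation is `SAH` exactly when the
aneurysm ruptured, otherwise drawn as Coincidental .7 / Follow-up .2 /
Epilepsy .1 (an invented nuisance mix); noisy mode re-draws a fraction ε
of presentations at random. Everything is reproducible from the seed,
and every generated registry passes ontology validation with zero
violations.

What the generator does **not** emulate: real location catalogs and
their width/location dependence, longitudinal follow-ups, treatment
effects, correlated measurement error, informative missingness. Passing
tests on synthetic data therefore demonstrate that the pipeline detects
the structures it is pointed at (leakage, moderate risk signal, null
signal, group geometry) — not that any particular clinical AUC would be
reproduced on real data.

## Problem sizes in the test suite

The behavioral suites run at sizes chosen to make their statistics
stable: the leakage check on a full-size registry draw (774 patients,
~1032 aneurysms); the permutation-null suite on 20 replicate seeds at 500
records (mean best AUC required in [0.48, 0.58]); the paired
feature-set comparisons on 20 replicate seeds at 500 patients (~665
aneurysms) each; generator calibration checks on 50,000 patients. The
AUC implementation is checked against an exact all-pairs concordance
oracle, the distance matrix against hand-evaluated fixtures, and the
Sammon optimizer against a direct multi-restart stress minimization.

## Known limitations

- The graded hierarchical similarity is a design choice (Wu-Palmer); other
  graded similarities would produce different, equally defensible maps.
- Screening AUCs from pooled out-of-fold decision scores can differ
  slightly from per-fold-averaged AUCs for margin-based models whose
  score scales vary across folds.
- The SVM grid is searched on the same folds used for reporting; the
  consolidated best is an optimistic screening signal by construction,
  consistent with its role as an indicator rather than a performance
  estimate.
- Listwise deletion biases screening when missingness is informative;
  the dropped-row count is always logged and recorded in provenance.
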