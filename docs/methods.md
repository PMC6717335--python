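# Methods

This note documents the models and procedures implemented in `acutetox`,
the choices made where the design was genuinely open, and what the
synthetic-data suite does and does not demonstrate.

## Endpoints and units

All modeling operates on rat acute oral LD50 values in mg/kg body weight.
The continuous regression target is `log10(LD50 / MW)` — the dose in
log10 mmol/kg — so that equimolar toxicity is comparable across molecular
weights. The categorical endpoints are derived exactly at the regulatory
boundaries, with their stated inclusivities:

| endpoint | positive / bands |
| --- | --- |
| vT | positive iff LD50 < 50 (50 itself is negative) |
| nT | positive iff LD50 > 2000 (2000 itself is negative) |
| EPA | I ≤ 50 < II ≤ 500 < III ≤ 5000 < IV |
| GHS | I ≤ 5 < II ≤ 50 < III ≤ 300 < IV ≤ 2000 < V |

The EPA-I upper bound (≤ 50) and the vT positive bound (< 50) genuinely
disagree at 50 mg/kg; both are implemented as stated rather than
harmonized, and the boundary tests pin this down.

## Dataset preparation

Duplicates are recognized after desalting (keep the component with the
most heavy atoms, ties by molecular weight) and canonicalization.
Aggregation defaults to the geometric mean of the mg/kg values — the
arithmetic mean on the log scale the models operate on; median and
arithmetic mean are available. Structural outliers are flagged on the
first two principal components of a descriptor matrix when either
standardized score exceeds `z_cut` (default 6 SD — an extreme-tail rule;
configurable). The internal 80/20 split stratifies over K-means clusters
computed on fingerprint bits with the activity appended after scaling to
[0, 1], so training and validation are analogous both structurally and in
activity; `k_clusters` defaults to `max(2, n/50)`. Clusters with fewer
than two members go wholly to the training side, with a warning.

## Similarity and the integrated index

The integrated similarity index combines one binary-fingerprint similarity
with three structural-key similarities:

    SI = S(FP)^0.40 · S(CD)^0.35 · S(HE)^0.10 · S(FG)^0.15

S(FP) is the Maxwell–Pilliner index (clamped to [0, 1]: its raw range
admits negative values for anti-correlated fingerprints, while SI is
specified on [0, 1]); the key-block similarities are Bray–Curtis. The
combination is read as a weighted geometric product (exponents as above);
a weighted arithmetic mean is available via configuration, and the two
coincide whenever all components are equal because the weights sum to 1.
The geometric reading is the stricter of the two (any null component
annihilates SI), which suits an index that gates read-across predictions.

Fingerprint families are computed with RDKit: a pattern (substructure-key)
fingerprint folded to 881 bits for the PubChem-key family, a 1024-bit
Daylight-style path fingerprint for the Extended family and the same
family at 2048 bits. The structural-key blocks (35 constitutional counts,
11 heteroatom counts, 154 functional-group counts) are populated from an
openly computable catalog: RDKit molecular descriptors for the
constitutional block, element counts for the heteroatom block, and the
RDKit fragment catalog (85 patterns) extended with 69 curated SMARTS for
the functional-group block. Bit-exact parity with commercial descriptor
generators is a non-goal; the families, lengths and index definitions are
what the downstream machinery depends on.

Degenerate cases are defined rather than left to chance: Tanimoto and
Bray–Curtis of two all-zero objects are 1.0 (identical objects, logged); a
zero Maxwell–Pilliner denominator raises as a degenerate pair.

## Read-across with abstention

The thresholded kNN retains the k most similar training compounds with
SI strictly above `t_sim1`; with none it abstains (`NO_NEIGHBOR`); with
exactly one it predicts that neighbor's value only if its SI strictly
exceeds the stricter `t_sim2` (`SINGLE_BELOW_T2` otherwise); with two or
more it predicts only when the neighbors' value spread (max − min) is
strictly below `t_minmax` (`RANGE_EXCEEDED` otherwise). Predictions are
the SI^enhancement-weighted mean, normalized; the enhancement exponent
shifts weight toward the most similar neighbor, and at large exponents the
prediction converges to the single best neighbor's value (tested at
exponent 50 within 1e-6). SI ties during retention break stably by
(SI descending, id ascending).

Grid search spans k ∈ 2..5, `t_sim1` ∈ 0.70..0.90 (step 0.05),
`t_sim2` ∈ {0.85, 0.90} (constrained ≥ `t_sim1`), enhancement ∈ 1..3,
`t_minmax` ∈ {1.0, 1.5, 2.0} log units. Candidates are pre-selected as
the Pareto-nondominated set over (LOO RMSE, LOO coverage) on the training
pool — a formalization of "a good compromise of coverage and performance",
which is otherwise underdetermined — then the winner is the candidate with
the best validation RMSE subject to a validation coverage floor (default
0.85); if none reaches the floor, the best-coverage candidate is returned
with a warning. After selection the convention is to refit on the full
training pool (iTS + iVS) for external prediction.

## Structural alerts

Candidate fragments are every connected fragment obtainable by breaking up
to `max_breaks` (default 3) acyclic single bonds, with heavy-atom count in
[`min_atoms`, `max_atoms`] (defaults 2–18), canonicalized and
deduplicated. Ring bonds are never broken — this bounds the fragment space
and keeps aromaticity well-defined; it is exposed as a documented knob of
the design rather than a hidden constant. Each candidate is scored by the
likelihood ratio LR = (tp/n_target)/(fp/n_other) (+∞ when it never hits
the other class), and the ruleset is built greedily per class: admit the
best candidate meeting `min_lr` (default 2.0) and `min_tp` (default 4) —
highest LR, then highest support, then lexicographic SMARTS — remove the
molecules it matches, repeat. LR denominators stay at the full class
sizes while support is counted on uncovered molecules, so admitted
supports never overlap and every admitted alert re-checks against the full
set at ≥ its admitted support. Classification takes the label of the
matched alert with the highest LR; exact ties resolve to the more toxic
class (the conservative rule used throughout the package); no match means
the query is outside the ruleset's applicability domain.

## Forest pathways

The balanced random forest grows each tree on a balanced bootstrap: every
class contributes exactly `n_min` (minority-class size) indices drawn with
replacement. Within-class sampling is with replacement, the standard
balanced-forest practice. Plain forests use an ordinary n-of-n bootstrap.
Classification confidence is the agreeing-tree fraction (≥ 0.5 by
construction for binary problems); regression reports the tree-wise
standard deviation. Tree counts of 50/100/150 suit the plain/balanced
pathway; the hyperparameter-tuned pathway uses 500 trees and searches
mtry × splitrule (gini/variance vs extremely-randomized) × minimum node
size by bootstrap out-of-bag performance (RMSE for regression, balanced
accuracy for classification), ties broken by grid order.

Response outliers are flagged before the tuned refit when the
isolation-forest anomaly score exceeds its 0.99 quantile, or when both the
out-of-bag absolute error and the prediction variance across 100 bootstrap
refits exceed their 0.95 quantiles. All three quantiles are configurable;
for planted response outliers the error criterion does the work (a
corrupted point is predicted consistently wrong out-of-bag, so its
variance can be low), which the tests exercise by opening the variance
gate.

The error model is a forest regressor mapping per-compound AD metrics to
the cross-validated absolute error of the activity model; predictions are
clipped at zero. The metric vector is deliberately simple plumbing — mean
and maximum similarity (1/(1 + Manhattan distance)) to the five nearest
training compounds, plus the activity forest's tree-prediction SD — and is
configurable, since no canonical definition exists.

## Local models

For each target compound, neighbors with PubChem-family similarity ≥ 0.80
and Extended-family similarity ≥ 0.70 are selected; if fewer than 20
qualify the group is filled by best average rank across the two similarity
orderings (ties by index), and at most 50 are kept. A roster of base
learners — ridge/nearest-centroid, random forest, gradient-boosted trees,
kNN per task; pluggable — is fitted on the local group. Regression outputs
are averaged after discarding any more than 10% of the training-value span
outside the training range (the "10%" is read as a fraction of the span
beyond either bound, configurable); classification uses a majority vote
with ties resolved to the class least represented in the training set,
which for toxicity endpoints is the most toxic class. The ADM score (1–5)
comes from the mean PubChem/Extended similarities of the local group; the
in-AD anchor is score ≥ 2, i.e. mean similarities ≥ 0.60 and ≥ 0.30. The
upper tiers (3: 0.70/0.45, 4: 0.80/0.60, 5: 0.90/0.75) are a monotone
interpolation — only the score-2 anchor is externally fixed — and are
configurable.

## Applicability domains

* **Distance**: T_D is a percentile (100/97.5/95/90) of the training
  distribution of mean Manhattan distances to the k nearest *other*
  training compounds (k ∈ {1, 5}); a query is in AD iff its mean distance
  to its k nearest training compounds is ≤ T_D.
* **Confidence**: in AD iff forest confidence ≥ T_C; T_C sweeps
  0.60–0.75 (step 0.05) for binary and 0.30–0.70 (step 0.10) for
  multiclass models.
* **Error**: T_E is a percentile (100/90/75/65) of the training predicted
  errors from the error model; in AD iff the query's predicted error ≤ T_E.
* **Dummy matrix**: each training column is independently permuted across
  rows to build a mirror matrix that keeps marginals but destroys the
  joint structure; a 200-tree forest learns real vs dummy and queries
  classified "dummy" are out of AD.
* **Outlier similarity**: a query whose mean top-3 Tanimoto similarity to
  the flagged outliers exceeds that to the cleaned training set is out of
  AD.

All threshold comparisons are non-strict (a value exactly at the threshold
stays in AD) and percentiles use linear interpolation between order
statistics — both stated here because nothing external fixes them. The
threshold tuner computes the Pareto-nondominated set over (performance,
coverage) and returns the best performer with coverage ≥ a floor (default
0.70), falling back to best coverage with a warning; the result is
invariant to the input ordering of the combinations.

## Consensus integration and evaluation

Regression consensus is the unweighted mean of in-AD member predictions on
the log mmol/kg scale, with PF = (in-AD members)/(all members);
classification consensus is a majority vote over in-AD labels with
CS = agreeing − disagreeing votes, abstaining on exact ties (for ≥ 3
labels: votes-for-winner minus votes-against, same tie rule). Reliability
thresholds compare PF (or CS) with ≥; abstentions are always outside the
integrated AD. The PF-stratified error report computes R², MAE, RMSE, the
level count and share, and the fraction of samples with absolute error
≥ 1 log unit, per exact PF level.

R² is the coefficient of determination about the identity line (not a
squared correlation — conventions vary and the difference matters for
biased predictors). Binary classification reports the positive class's
sensitivity/specificity; multiclass reports one-vs-rest averages, with
BA the mean of the averaged sensitivity and specificity, skipping classes
with an empty truth row (with a warning). MCC uses the confusion-matrix
generalization

    MCC = (c·s − Σₖ pₖtₖ) / √(s² − Σₖ pₖ²) √(s² − Σₖ tₖ²)

which reduces to the familiar binary form on 2×2 matrices (unit-tested,
and cross-checked against scikit-learn's implementation as an independent
oracle). Pareto-front selection uses weak dominance — a model survives iff
no other is at least as good on both axes and strictly better on one —
with duplicates retained and stable output order.

A penalized logistic model (elastic net) for the nT endpoint is out of
scope for this package; for the record its penalty parameters in the
reference setting were α = 0.09 and λ = 0.02. It defines no applicability
domain and does not participate in the consensus.

## Synthetic data: what it emulates, and what it does not

The generators are pure functions of their parameters (identical reruns).

* **Descriptor matrices**: Gaussian descriptors with a linear response
  (optional interaction/threshold terms to exercise forests fairly) and
  controlled noise; classification thresholds the latent response at its
  own quantiles to realize the requested class proportions (calibrated to
  ±2% at n = 5000).
* **Fingerprint populations**: cluster centers at a set bit density, with
  member bits flipped at a probability solved (by root-finding on the
  closed-form expectation) so the expected within-cluster Tanimoto equals
  the target (realized within ±0.05 at n ≥ 200; reachable targets must
  exceed the random-overlap floor of ≈ 1/3).
* **Planted-toxicophore SMILES**: molecules are a rigid fused-ring
  scaffold (13+ heavy atoms, no acyclic single bonds; 26 tricyclic
  heteroaromatic templates) plus one benign decoration, with a nitrophenyl
  toxicophore attached to positives with probability `fidelity` and to
  negatives with probability `1 − fidelity`. Scaffolds and decorations are
  assigned round-robin within each class. The construction is deliberate:
  fragmentation only breaks acyclic single bonds, so any fragment touching
  a scaffold atom contains the whole ring system, a scaffold+toxicophore
  fragment always exceeds the default 18-atom fragment cap, and round-robin
  guarantees every scaffold and decoration occurs in both classes — hence
  the planted fragment is the only class-separating fragment family by
  construction, and alert recovery does not hinge on a lucky draw.
* **Model ledgers**: unbiased per-model predictions with multivariate
  normal errors (stated SDs, common pairwise correlation) and independent
  Bernoulli in-AD indicators at stated coverages (calibrated to ±2% at
  n = 5000). With four independent equal-σ models, the consensus error at
  full prediction fraction has SD σ/2, the reference point for the
  consensus-improvement checks.

What passing these suites shows: the decision rules, abstention logic,
integration arithmetic, AD monotonicity and mining machinery behave as
specified on data whose ground truth is known exactly. What they do not
show: performance on real chemistry — real descriptor distributions are
heavy-tailed and collinear in ways the Gaussian generator is not, real
toxicophores are neither single fragments nor carried at fixed fidelity,
and real model errors are correlated through shared descriptors. External
figures (RMSE ≈ 0.5, balanced accuracies above 0.8) belong to specific
curated datasets and commercial descriptor sets and are not reproduced
here.

## Problem sizes

The test suite runs its simulation-based checks at deliberately modest
sizes chosen as the package's own defaults for desk-scale verification:
200 ledger replicates of 50 samples for the consensus-error shape, 20
replicates of n = 2000 for the balanced-forest comparison, 100–200
molecules per class for alert recovery, and ≥ 5000 enumerated read-across
cases for oracle equivalence. These sizes put the statistical checks'
expected margins well clear of their thresholds (documented per test)
while keeping the whole suite in the tens of seconds.

## Known limitations

* Fingerprints and structural keys are open-implementation stand-ins for
  tool-specific families; models trained on one family do not transfer to
  another.
* The greedy ruleset reduction is order-deterministic but not globally
  optimal; alternative equal-LR alerts can be excluded by coverage
  removal.
* The dummy-matrix AD inherits the variance of its internal classifier;
  with few descriptors or few training rows its flags are noisy.
* The local-model engine refits learners per query; it is intended for
  moderate batch sizes, not high-throughput scoring.
* ADM tiers above the in-AD anchor are an interpolation, not an external
  standard; downstream users should treat scores 3–5 as ordinal only.
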