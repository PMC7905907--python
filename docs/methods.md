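# Methods

This note records the model, the parameter choices and the numerical
conventions implemented in `costvote`, and what the synthetic benchmark does
and does not demonstrate.

## Cost structure and the efficiency index

The cost matrix charges `cost_fn` for a missed patient (default 10),
`cost_fp` for a mislabeled healthy person (default 1), and 0 for correct
decisions. Misclassification cost is the average per-instance penalty
`MC = (FP·cost_fp + FN·cost_fn)/n`; it is a fraction internally and a percent
in reports, and it may exceed 100% because `cost_fn > 1`.

The efficiency index `E = (accuracy + 1 − MC/(cost_fn + cost_fp))/2` consumes
MC as the *fraction* form. With the default costs `MC/(cost_fn+cost_fp)` lies
in `[0, 10/11]`, so `E` ranges from ≈0.045 (everyone a missed patient) to 1
(perfect). `E` is strictly increasing in accuracy at fixed MC and strictly
decreasing in MC at fixed accuracy; both are covered by grid tests.

Member weights are `w_i = E_i/ΣE_j`. Because members of equal accuracy have
equal `FP+FN`, cost-neutral `(1,1)` weighting is exactly uniform, and the
asymmetric `(10,1)` matrix can only push a high-false-negative member *below*
uniform — the property asserted by the cost-sensitivity tests.

Weights are computed from the validation split by default
(`weight_source="validation"`). Training-set E is degenerate for
interpolating members (a forest or a wide ELM reproduces its training labels
almost exactly, collapsing all weights toward uniform), so training-phase
weighting is provided (`weight_source="train"`) but not the default.

## Ensemble vote

Each member emits a hard label; the positive score is the total weight voting
"patient". The label threshold is 0.5 and an exact 0.5 tie resolves to the
patient class, consistent with the cost asymmetry. The ensemble's AUC uses
this weighted vote share as the ranking score (a hard-voting ensemble has no
native probability); member AUCs use their native scores: vote fraction
(RF), sigmoid output (LR), decision-function value (SVM), hidden-layer
output `Hβ` (ELM), positive-neighbor fraction (KNN).

## Preprocessing

Features missing in more than `missing_threshold` (default 0.5) of instances
are removed. Remaining missing cells take the class-conditional mean
(continuous) or mode (categorical, ties to the smallest code); a feature
fully missing within one class falls back to the overall statistic with a
logged warning. Continuous features are z-scored with population
(divide-by-n) variance — the n vs n−1 choice is immaterial to the rank-based
downstream steps but is fixed for reproducibility; a zero-variance feature
maps to all zeros.

Group-mean imputation consults the instance's own label, which leaks label
information into held-out instances. Two modes are therefore provided:

* `group` (default): statistics fitted on the whole table and applied
  label-aware before splitting — the order given by the original protocol's
  flowchart, reproduced for fidelity;
* `strict`: the deployable variant — statistics fitted on the training part
  only; training cells filled label-aware, validation/test cells with the
  label-free overall statistics.

## Relief

Per-feature differences: 0/1 equality for categorical features, `|a−b|` for
continuous features, which are assumed z-normalized (normalization precedes
feature selection in the pipeline). The instance distance for the
near-hit/near-miss search is the sum of per-feature diffs; ties break toward
the smaller instance index. The weight update subtracts the squared hit diff
and adds the squared miss diff, divided by the number of sampled instances —
the original formulation; a linear-diff variant is available
(`squared=False`) since the printed algorithm leaves the update body's
exponent unstated. Defaults are `n_samples="all"` (one deterministic full
pass in index order) and `n_repeats=1`, because the sampling counts m and n
are not specified by the source protocol; sampled mode draws with
replacement from a seeded generator. Ranking ties break by schema order.
Equivalence with an independently coded brute-force implementation is tested
to 1e−12 on random mixed-type datasets.

The two-class formulation is intentional; multi-class ReliefF (k-neighbor
averaging, missing-value diffs) is out of scope.

## Members

* `rf` — scikit-learn random forest, 50 trees.
* `lr` — logistic regression with no regularization (`C=inf`) and the 0.5
  threshold.
* `svm` — RBF ("Gaussian") kernel, `C=1`, `gamma="scale"`; stand-in defaults
  where tuned values are unreported, overridable via config or the GA.
* `elm` — single hidden layer, width 50 by default; input weights and biases
  uniform on [−1,1] from the seed; sigmoid activation; output weights
  `β = pinv(H)·t` with targets ±1 (optional ridge term, default 0). The
  decision threshold on `Hβ` is 0, with 0 itself mapping to "patient".
  Note that one sigmoid hidden unit emits strictly positive activations, so
  a width-1 network can only predict a single class; width ≥ 2 is needed to
  separate anything, and width ≥ n interpolates the training labels (both
  tested).
* `knn` — k=5 under the heterogeneous distance
  `Σ_q w_q(a_q−b_q)² + Σ_c w_c·L_c(a_c,b_c)` (no square root, exactly as the
  formula is printed). Default `w_q = w_c = 1` and 0/1 penalty matrices —
  unspecified by the source, all configurable per feature. Distance ties
  prefer the smaller training index; split votes resolve to "patient".

## Protocol

Default protocol: `repeats` (10) independent stratified 80/10/10 splits.
Per-class part sizes use largest-remainder rounding (remainder ties toward
training); per-repeat seeds derive from the master seed through
`numpy.random.SeedSequence([master, index])`, so repeats are independent yet
reproducible, and two runs with the same configuration emit byte-identical
JSON. The source protocol also mentions ten-fold cross validation; the
80/10/10 reading is implemented because the validation fold is integral to
feature-subset selection and member weighting.

Subset selection evaluates every ranked prefix `k = 1..p`: members are
trained on the top-k training features, weighted from the configured split,
and the ensemble's validation E is recorded; the argmax wins, ties toward
the smaller k (parsimony). With a 27-instance validation fold the E curve is
quantized in steps of ≈1/30, so on noisy data the argmax can legitimately
land on a larger prefix; what is guaranteed (and tested) is that the chosen
prefix is never worse on validation than the full feature set, with the
small-prefix preference holding in median over seeded replicates.

Aggregation uses sample SD (n−1). Paired comparisons use the Wilcoxon
signed-rank test below. Feature pick counts tally how often each feature
enters the chosen subset across repeats.

## Wilcoxon signed-rank test

Zero differences are dropped (classical convention; Pratt's zero-rank method
is available by flag). Absolute differences receive midranks. The
standardized statistic is `Z = (W⁺ − m(m+1)/4)/√(m(m+1)(2m+1)/24 − Σ(t³−t)/48)`
with no continuity correction; the tie term vanishes for tie-free data. The
exact two-sided p-value enumerates all 2^m sign assignments via dynamic
programming over (doubled) rank sums for m ≤ 25, and the normal
approximation is reported alongside. Ten all-one-sign tie-free pairs give
`|Z| = 27.5/√96.25 = 2.803` and exact p = 2/1024 ≈ 0.002.

On approximation quality at m = 10: the exact tail of W⁺ matches the
continuity-corrected normal tail within 0.01 uniformly (worst gap 0.0084).
The *two-sided* exact p differs from the uncorrected normal p by up to
≈0.05 near |Z| ≈ 0.5 — an irreducible discreteness effect of the 1024-point
lattice, not an implementation artifact — so agreement claims are stated on
tails.

## Genetic-algorithm tuning

Generational GA with tournament selection (size 3), uniform crossover on a
0.8 fraction of offspring, per-gene mutation (rate 0.2; integer step or
log-normal multiplicative), and elitism (5% of a population of 50). The
fitness is the validation-set ensemble E on one fixed split. The desk-scale
default is 20 generations; the full-scale setting of 1000 generations is
configurable but not the default. Migration applies to multi-subpopulation
runs only and is not implemented for the single-population default, where
elitism plays that role. Search space: RF trees 10–200, SVM C and gamma
log-uniform over 4–5 decades, KNN k 1–15, ELM width 5–200.

## Synthetic generator

`generate` draws labels Bernoulli(prevalence), continuous features as
class-conditional Gaussians (patient mean shifted by `effect` SD units) and
categorical features as class-conditional multinomials; `inject_missing`
applies MCAR masks per cell with per-feature overrides (used to fabricate
>50%-missing columns for the filter). MCAR only: the group-mean imputation
treats missingness as ignorable, and MAR/MNAR mechanisms are out of scope.

The default fixture (`statlog_like`) has 270 instances at prevalence 0.444
with the 13-feature heart schema: three informative continuous features
(effects 1.5 SD on Thalach, 1.0 on Oldpeak, 0.7 on Age — a strong, a
moderate and a modest signal, signs chosen clinically: lower peak heart
rate and higher ST depression in patients) and uninformative remaining
features whose marginals roughly mimic published cohort frequencies.

What passing tests on this generator show: the pipeline's mechanics —
ranking recovers configured effect order, the weighted vote tracks the cost
structure, the protocol is reproducible. What they do not show: performance
on real heart-disease cohorts, whose features are correlated (e.g. age with
maximum heart rate), partly ordinal, and missing not at random; absolute
metric values on the synthetic fixture are not comparable to values
published for the UCI datasets. Simulation sizes in the tests (270-instance
protocol runs, 20 replicates of 500×8 for rank recovery) were chosen as the
smallest scales at which the distributional claims are stable.

## Known limitations

* Binary labels only; no multi-class, regression or sparse-matrix support.
* The `group` preprocessing mode leaks label information by construction;
  use `strict` for any deployment-like estimate.
* The repository ships no UCI data; readers for both UCI dialects are
  exercised on synthetic stand-ins written in those dialects.
* Hard-voting AUC depends on the vote-share score convention described
  above; with five members it takes at most 2⁵ distinct values per test set.
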