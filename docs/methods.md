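# Methods

## Model and assumptions

`mirpu` estimates, for every candidate miRNA:mRNA pair `x` with
per-algorithm score vector `p(x)`, the probability that the interaction
is real, `f′(p(x)) ≈ P(f(x)=1)`, using only validated positives (`L`) and
a large unlabeled pool (`U`). Three assumptions carry the method:

1. **Positivity of labels.** Every validated pair is a true interaction:
   `P(f=1 | l=1) = 1`. Validation databases are curated from functional
   experiments, so this is taken as exact.
2. **SCAR labeling.** Validated positives are selected completely at
   random from all positives, so `c = P(l=1 | f=1)` is a constant
   independent of `p(x)`. In reality pairs are chosen for validation for
   biological reasons; the assumption is the same one made implicitly
   whenever a training set is taken as representative of the deployment
   distribution.
3. **Score informativeness.** True interactions score systematically
   higher; the per-algorithm columns may be heavily collinear and partly
   missing, which is why a margin-based / regularised probabilistic
   classifier is used rather than a model requiring feature selection.

Given these, `P(f=1) = P(l=1)/c`, and both factors are estimated with a
*nontraditional* classifier `g` trained to separate labeled from
unlabeled rows.

## Bagging over the unlabeled pool

With `|L|/|U|` around 1/2000, a single classifier on `L ∪ U` collapses to
the majority class. Stage 1 therefore trains `K` members, each on all of
`L` (class 1) plus a with-replacement sample of `n` unlabeled rows
(class 0). The coverage identity

    P(x in union of samples) = 1 − (1 − 1/|U|)^(nK)

gives the member count for a target coverage γ:

    K = ceil( (1/n) · log(1−γ) / log(1 − 1/|U|) ),   floored at 1,

so realised coverage never undershoots γ (the ceiling is our stated
rounding rule). At `K = |U|/n` coverage tends to `1 − e⁻¹ ≈ 0.632` for
large `|U|`; γ → 1 requires unboundedly many samples, so γ trades
effectiveness against cost. Predictions for a row contained in several
samples average the members that saw it; rows outside every sample (and
all novel rows) average all members — the total-function extension the
per-sample definition needs at prediction time.

Duplicates inside a sample are kept (true bootstrap sampling). Per-member
sub-seeds are derived from the master seed and the member index only, so
enlarging K never perturbs earlier members.

### Default plan: n = |U|

The package defaults to full-size bootstrap samples (`n = |U|`,
γ = 0.9 ⇒ K = 3). The reason is the constant-`c` estimator below: `g`
trained on `L` versus a sample of `n` unlabeled rows estimates the
labeled-class probability *under the member's class ratio*
`|L| : n`. Only when each member sees the population ratio (`n = |U|`)
does `ĉ = mean of g over L` track the population labeling frequency; at
`n ≪ |U|` it is inflated toward the member prior (on uninformative data
it converges to `|L|/(|L|+n)` exactly, a behaviour the unit tests pin
down). The subsample-to-balance regime (`n` of the order of `|L|`)
remains fully supported through explicit `n`/γ and is the right choice
when a member cannot be trained on all of `U`; its `ĉ` should then be
read as a within-member calibration constant rather than an estimate of
the population labeling rate.

## The constant c and its bias

`ĉ = (1/|L|) Σ_{x∈L} g(p(x))`, clamped into (1e−6, 1], computed once
from the stage-1 ensemble and frozen (no iterative re-estimation).
Because `P(l=1|x) = c·P(f=1|x)`, the estimator's expectation is
`c · E[P(f=1|x) | f=1]`: it is **biased low by the average posterior of
true positives**, and is close to `c` only when positives are nearly
separable from negatives in score space. This is an inherent property of
the mean-of-g estimator, not of this implementation; it degrades
gracefully (multiplicatively) as class overlap grows. The synthetic
default regime (below) emulates the strongly informative panel the
estimator presumes; on weakly informative panels `ĉ` should be treated
as a lower bound.

## Stage 2: relabeling, weighting, cost-sensitive ensemble

For unlabeled rows the positive posterior is

    P(f=1 | l=0) = ((1−ĉ)/ĉ) · g/(1−g),

clamped to [0, 1] — the raw odds ratio exceeds 1 whenever `g > ĉ`, and
the quantity is used as a probability downstream, so clamping is the
only consistent treatment. Each row then gets exactly one training label
and weight: labeled rows `('+', 1.0)`; unlabeled rows `('+', posterior)`
when the posterior ≥ 1/2 (ties count as `+`), else `('−', 1−posterior)`.
Representing each unlabeled row once, rather than as both a weighted
positive and a weighted negative, avoids redundant duplicated rows that
can degrade the separating surface.

The `+`/`−` sets are themselves unbalanced, so the same bagging scheme is
reused: `K′` members, each trained on all `+` rows plus a bootstrap
sample of `−` rows, with the weights passed as per-example
misclassification costs. The stage-2 plan defaults to
`n = max(#'+' rows, 1000)` with the stage-1 γ. The membership-aware
average of the `K′` members is the final predictor `f′`.

## Base classifiers

The ensemble requires only `fit(X, y, sample_weight)` and
`predict_prob → [0,1]`. Defaults:

- `svc` (default): RBF-kernel SVM, `C = 1`, kernel width `1/s`
  (`s` = number of score columns), with 5-fold cross-validated sigmoid
  (Platt) calibration. Kernel, `C` and fold count are exposed; the values
  are conventional defaults, not tuned.
- `logistic`: L2-regularised logistic regression (`C = 1`). On roughly
  Gaussian score panels its linear log-odds are well specified; it is
  orders of magnitude faster and is used in the heavier statistical
  tests.

Calibration internals belong to the base classifier, not the ensemble.

## Data handling

- Scores are oriented so higher = stronger evidence; a per-column
  `invert` flag negates lower-is-better columns (e.g. energies) at load.
- Standardization z-scores each column over its *present* values
  (population SD); columns with fewer than two present values or zero
  spread pass through with a warning.
- Missing scores: default policy fills the column mean, i.e. exactly 0
  after standardization ("no evidence"); `min` and `zero-raw` policies
  are available. The choice is explicit because per-algorithm coverage in
  real integrated databases differs by two orders of magnitude and no
  single imputation is canonical.
- Identifiers are opaque case-sensitive strings; no alias resolution.
- Test sets drop pairs recorded as both positive and negative, and can
  exclude training positives.

## Synthetic benchmark

The generator emulates the statistical structure the learner faces, not
miRNA binding itself:

- informative columns: equicorrelated Gaussians (pairwise correlation
  `collinearity`, default 0.3) shifted by `effect` SD for true pairs;
- noise columns independent of truth;
- per-cell missingness at rate `missing_rate` (default 0.2), optionally
  biased toward negatives (predictors publish putative targets);
- SCAR labels: each true pair labeled with probability `label_freq`
  (default 0.5), independent of scores — so the true `c` is known;
- optional monotone per-column distortion to mimic heterogeneous score
  scales (AUC-invariant by construction).

Default sizes are 2,500 true positives vs 47,500 negatives with 6
informative + 4 noise columns, mirroring a 10-algorithm panel; the
`imbalanced` preset (250 expected labeled positives over ~500k unlabeled
rows) reproduces the 1/2000 labeled:unlabeled regime, and `tiny` (2,000
rows) runs end-to-end in seconds. The default `effect = 3` SD encodes
the near-separable operating regime the constant-`c` estimator assumes
(see above); real integrated panels are substantially noisier, so
passing tests demonstrate correct behaviour of the machinery under the
model's assumptions, not expected accuracy on real databases. Held-out
test pairs are unlabeled rows of the same table (the transductive
setting of real validation databases), never labeled ones.

## Evaluation

AUC with half-credit ties, computed from the trapezoidal ROC curve and
checked in the tests against an independent brute-force pairwise count.
Test pairs absent from the score table receive the method's minimum
score ("not predicted") and are counted. No multiple-testing correction
is applied anywhere.

## Bicluster statistics

Cohesiveness `q(C, A)` is the mean interaction score over all
miRNA × mRNA cross pairs of a bicluster (scores normalised to [0, 1];
unresolvable pairs score 0 and are counted); `μ_q` is the size-weighted
level average. Intra-bicluster functional similarity averages a
pluggable symmetric gene-similarity over distinct mRNA pairs;
inter-bicluster similarity averages, over bicluster pairs, the mean
similarity between their *exclusive* mRNA sets — pairs with an empty
exclusive set (nested biclusters) are skipped and counted rather than
scored 0, which would spuriously deflate the average. Both quantities
are defined over ordered pairs but computed over unordered pairs, which
is identical by symmetry. The intra-vs-inter comparison uses Welch's
two-sample t-test (the variance assumption is ours; the equal-variance
variant is a trivial switch), reporting two-sided and one-sided
(intra > inter) p-values. The intra sample is per-bicluster means by
default; a pooled gene-pair variant is exposed. A GO-based semantic
similarity is the intended real similarity source; the shipped
`SyntheticGeneSimilarity` is a deterministic module-structured synthetic
stand-in for development and testing.

## Numerical choices and degenerate inputs

- `ĉ` clamped to (1e−6, 1]; `g` clamped below 1 − 1e−12 before the odds
  ratio; posteriors clamped to [0, 1].
- `K` and `K′` use ceiling with floor 1.
- Fewer than two labeled positives, single-class stage-2 sets, empty
  sampling pools, single-class truth vectors and zero-variance t-test
  samples all raise typed errors rather than returning silent defaults.
- All randomness flows from one master seed through named substreams
  (stage, member index, replicate), so runs are bit-reproducible and
  extending an ensemble preserves its prefix.

## Problem sizes used in the shipped checks

The statistical test battery runs the c-recovery check at 1,000 true
positives vs 19,000 negatives (20 seeded replicates per labeling
frequency in {0.3, 0.5, 0.7}, logistic base, full-size bootstrap plan)
and the dominance check (ensemble > score averaging > median single
column, by held-out AUC) on the 50,000-row default regime — sizes chosen
so the whole suite exercises the full pipeline at meaningful scale while
staying fast on a single CPU.

## Known limitations

- `ĉ` is biased low under class overlap and inflated when `n ≪ |U|`;
  both effects are documented above and neither is corrected, matching
  the estimator's definition.
- SCAR is idealised: real validation sets are biologically biased, which
  shifts `ĉ` and, through it, the posterior scale (though not
  necessarily the ranking).
- The generator draws i.i.d. pairs; it does not model per-miRNA or
  per-gene structure, sequence features, or dependence between
  missingness patterns across algorithms beyond the optional
  truth-linked rate.
- Baseline weights for the weighted three-best combiner are
  user-supplied; no reliability estimation is performed.
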