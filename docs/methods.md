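# Methods

## The global test

For a pathway of *m* genes measured on *n* samples with binary outcome
*Y* (1 = disease, 0 = normal), the test statistic is the quadratic form

Q = (Y − μ)ᵀ R (Y − μ) / μ₂,  R = (1/m) X Xᵀ,

with μ = mean(Y). Q is motivated by a logistic random-effects model in
which each gene's regression coefficient is drawn with common variance
τ²; testing τ² = 0 yields a score statistic of this form, and Q grows
when samples with similar expression profiles share outcomes. Q is
computed as ‖Xᵀ(Y − μ)‖² / (m μ₂), which is algebraically identical to
the double sum Σᵢⱼ Rᵢⱼ (Yᵢ − μ)(Yⱼ − μ)/μ₂ but O(nm) instead of O(n²m).

**The μ₂ convention.** We take μ₂ = μ(1 − μ), the variance of a
Bernoulli(μ) outcome — the convention of the original global-test
literature. Some presentations are typographically ambiguous between
μ₂ and μ²; the choice only rescales Q by a constant for a fixed Y, so
permutation p-values are identical either way. Only Q's absolute scale
depends on it.

**Permutation p-values.** p = #{b : Q(permute_b(Y)) ≥ Q_obs}/B over B
uniform shuffles of Y (shuffling Y preserves class sizes by
construction). No +1 smoothing is applied, so p = 0 is attainable and
should be read as p < 1/B; the CLI notes this in its summary output.
Default B = 10,000, configurable. Because the permuted and observed Q
take slightly different floating-point paths, tie comparison allows a
relative slack of 1e-9 — ten orders of magnitude below any meaningful Q
difference — so that permutations realizing the observed arrangement
always count as ties. For n ≤ 10, `exact_permutation_p_value`
enumerates all C(n, n₁) distinct label arrangements; the observed
arrangement is among them, so p ≥ 1/C(n, n₁).

Q is scale-equivariant (Q(cX) = c²Q(X)), so permutation p-values are
invariant under uniform rescaling of X: assigning every gene the same
weight, whatever its value, is exactly the uniform-weight baseline.

Expression is assumed normalized upstream; no centering or
normalization is performed anywhere in the package.

## Weighting schemes

All schemes produce nonnegative weights applied multiplicatively to X
before scoring.

* **absT** — wⱼ ∝ |Tⱼ|, the absolute two-sample t statistic of gene j,
  normalized to sum to 1 within the pathway. The pooled-variance
  (classical equal-variance) form is the default; Welch's form is
  available via a flag. A gene with zero within-class variance but a
  nonzero mean difference has infinite |T|; it is capped at the largest
  finite |T| in the pathway so the normalization stays defined. If all
  |T| = 0 the weights fall back to uniform with a warning. |T| is a
  per-gene quantity, but the normalization makes weights
  pathway-relative.
* **Qdiff** — wⱼ ∝ |Q − Q₍₋ⱼ₎|, the change in Q when gene j is removed,
  normalized to sum to 1. For m = 1 the leave-one-out statistic is
  undefined and the single gene gets weight 1; an all-zero difference
  vector falls back to uniform.
* **RWV** — random search over per-gene weight vectors: each candidate
  draws m values uniformly in [0.1, 1.0], then resamples m of them with
  replacement, and the candidate minimizing the objective is kept. The
  two-step draw (which makes duplicated weights possible) is kept
  deliberately as the scheme's defining sampling protocol; a
  `simple_draw` flag collapses it to a single uniform draw.
* **RWM** — the same search over per-cell n×m weight matrices of
  uniform draws, applied elementwise. The n·m degrees of freedom let it
  reach lower objectives than RWV at equal budget, at higher
  computational cost.

Search defaults: range [0.1, 1.0], 25,000 iterations (the point past
which improvement was observed to flatten; see the iteration sweep
below). The uniform candidate is always evaluated first, so the best
objective can never exceed the uniform one, and the best-so-far trace
is non-increasing — properties the tests rely on. Ties in the p-value
objective (common at coarse permutation resolution) are broken in
favour of the larger observed Q; fully equal candidates keep the
first found.

**Fixed objective streams.** Inside a search, every candidate is scored
against the same pre-drawn permutation stream (or the same forest
seed), so candidate comparison is not corrupted by Monte-Carlo noise.
Re-randomizing per candidate would bias the minimum downward purely
through noise.

**Interpretation caveat.** absT, Qdiff, RWV and RWM all use the
observed labels (directly or through the objective) to construct
weights, so weighted p-values are optimized quantities, not calibrated
tail probabilities. Screens under different schemes are comparable to
each other; a weighted p-value alone is not evidence at its face value.

## Random-forest OOB scoring

A bagged classification forest (mtry = ⌊√m⌋, unlimited depth, bootstrap
size n — classical randomForest conventions) scores a pathway by its
out-of-bag error: each sample is predicted by majority vote of the
trees that did not see it in their bootstrap, and the error is the
misclassified fraction. Samples never out-of-bag (possible at very
small tree counts) are excluded from the denominator and counted in the
result. OOB error is reported as a proportion in [0, 1]. Defaults:
1,000 trees interactively, 50,000 behind `--full-fidelity`; tests use
≤ 500.

Per-gene (vector) weights rescale a column monotonically, which leaves
every tree's attainable split set unchanged — so absT/Qdiff/RWV cannot
change OOB error, and requesting them under the random forest raises
`UnsupportedCombinationError`. This invariance is also verified
empirically at a fixed seed in the tests. Only RWM, whose per-cell
weights reorder values within a column, is searchable under the OOB
objective.

## Simulator

A pathway is modeled as multivariate normal with a mean vector and full
covariance matrix (preserving the covariance implies preserving the
correlation structure — the stronger contract). `estimate_moments`
returns the sample mean and covariance (denominator n − 1), clipping
tiny negative eigenvalues to zero. `simulate_pathway` draws the normal
group from MVN(mean, cov) and the disease group from MVN(mean + shift,
cov), balanced when n is even. shift = 0 reproduces the
label-assignment design in which both groups come from one model and
the pathway is null — the configuration used for calibration checks;
a nonzero shift is the explicit extension for power studies.

`make_synthetic_study` builds a full screening fixture: 2,000 genes of
i.i.d. standard-normal background, 20 pathways of 10–30 genes sampled
without replacement within a pathway (overlap across pathways allowed,
as in real collections — the universe size keeps the gene-per-pathway-
slot ratio in the range of real collections), n = 50 balanced samples,
and 3 informative pathways in which half of the member genes get a
+2.0 mean shift in the disease group. Shifted genes are drawn from
members private to their pathway whenever enough exist, so pathways
outside the truth table really are null; if a pathway has too few
private members the shift spills onto shared genes with a warning.
All defaults are overridable.

What the simulator does **not** emulate: heavy-tailed or count-valued
expression, gene-gene correlation in the background (background genes
are independent), batch effects, and the covariance structure of any
particular real pathway. Tests passing on this generator demonstrate
the statistical machinery and the direction of the weighting effect
under a clean Gaussian signal; they do not certify performance on real
microarray or single-cell data.

## Screens, ranking and reports

A screen scores every pathway under one (scheme × method) combination.
Per-pathway randomness is derived from the screen seed and the
pathway's position, and the objective stream depends only on
(seed, pathway) — not the scheme — so scheme comparisons at a fixed
seed are paired: RWV/RWM screens can never score worse than the uniform
screen on any pathway. Pathways with no gene in the dataset are skipped
with a warning and excluded from ranking; missing genes within a
pathway are dropped with a logged count.

Ranks are competition ("1224") ranks of ascending score: rank = 1 +
number of strictly smaller scores; tied rows are displayed in input
order. Tie-inclusive top-k returns every row whose rank ≤ the k-th
row's rank, so a tie block is never split (a nominal top 20 can expand
to, say, 33 rows when the 20th rank sits inside a tie). Significance
counts use strict p < α with α = 0.05 and no multiple-testing
correction — a deliberate mirror of the screening practice this package
studies; corrected inference is out of scope and the raw counts should
be read accordingly.

`iteration_sweep` reports the mean best objective across pathways as a
function of the search budget by growing one candidate stream per
pathway and reading prefixes, making the curve deterministic per seed,
non-increasing by construction, and as cheap as a single maximal-budget
search. The average is taken over all screened pathways.

## Prediction evaluation

Selected pathways are evaluated by leave-one-out cross-validation with
LDA, linear-kernel SVM, polynomial-kernel SVM and KNN; the cell value
for a (classifier, scheme) pair is the unweighted mean of per-pathway
rates. Hyperparameters are conventions, not fitted values: KNN k = 3,
polynomial degree 3, SVM C = 1, LDA with its SVD solver (robust to
singular pooled covariance). A fold whose training labels are
single-class, or whose features are entirely constant, scores the
held-out sample by the training-fold majority class (ties to class 0).
Optional per-fold standardization is off by default.

Vector weights rescale columns uniformly across samples, so
scale-invariant classifiers (LDA) are provably unaffected by
absT/Qdiff/RWV weighting, and scale-sensitive ones (KNN, SVM) react
only through the metric, not through per-sample information. Only RWM
weighting genuinely changes the single-gene information the classifiers
see, so prediction evaluation mainly discriminates RWM from the rest.
We implement the evaluation faithfully for all schemes and surface this
caveat rather than forcing invariance.

## Problem sizes used in tests and the acceptance script

The test suite and `scripts/acceptance.py` run everything on synthetic
data generated at call time. Representative sizes, chosen as the
package's own desk-scale defaults: oracle equivalence on 100 instances
with n ≤ 12, m ≤ 6; Monte-Carlo-vs-exact comparison at 20,000
permutations on n = 6; null calibration over 200 regenerated n = 8
datasets with exact enumeration; search checks at counts ≤ 10,000 with
500–2,000 permutations; forest checks at ≤ 500 trees; moment recovery
at n = 10,000. The directional screen comparison uses the full
synthetic-study defaults (20 pathways, n = 50, 3 planted pathways,
shift 2.0) over 20 seeds with 500 permutations and 10,000 search
iterations per pathway.

## Known limitations

* Weighted p-values are optimized on the observed labels (see caveat
  above); the package reports them as screening scores, not calibrated
  significance.
* The permutation p-value has resolution 1/B; searches plateau once
  candidates hit the attainable floor, so comparisons between schemes
  at small B can tie.
* Gene identifiers are matched by exact, case-sensitive string
  equality; no probe collapsing, alias resolution or ortholog mapping.
* Continuous or survival outcomes, the analytic null of the global
  test, FDR/FWER control, and RF variable importance are out of scope.
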