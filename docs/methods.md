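# Methods

`mirank` infers candidate miRNA → mRNA regulatory relationships from
matched expression profiles (miRNA and mRNA abundance measured on the
same samples, log2 scale assumed) and validates the predictions against
confirmed-interaction and perturbation ground truths.  This note records
the models, the numerical choices, and what the synthetic benchmark does
and does not demonstrate.

## Score matrices and ranking conventions

Every method produces an mRNAs × miRNAs score matrix; cell (i, j) scores
the prediction that mRNA i is a target of miRNA j.  Because miRNAs
predominantly down-regulate their targets, sign-carrying methods
(Pearson, Spearman, Kendall, penalised-regression coefficients, IDA
effects) rank the most negative scores first (`ASC_SIGNED`).
Non-negative dependence measures (distance correlation, Hoeffding's D,
RDC, mutual information, pseudo-knockout Z-score) rank the largest
values first (`DESC_VALUE`), and aggregated rank matrices rank the
smallest mean rank first (`ASC_RANK`).  Whether a signed method should
rank by signed value or by magnitude-with-negativity-preference is a
genuinely open convention; we rank by signed value, and the ordering tag
travels with each matrix so the choice is explicit and overridable.

Undefined scores (zero-variance features, degenerate pairs) become 0
with a warning instead of aborting: a batch scoring run over thousands
of pairs should degrade gracefully, and 0 is the null score under every
ordering except `ASC_RANK` (where the null is the maximal rank).

## Pairwise measures

* **Pearson/Spearman/Kendall** — standard estimators; Spearman is
  Pearson on mid-ranks, Kendall is τ-b (tie-corrected).
* **Distance correlation** — biased V-statistic form via double-centred
  absolute-difference matrices; O(n²) per pair, with the centred matrix
  of each miRNA cached across the mRNA loop.
* **Hoeffding's D** — classical rank formula with mid-ranks and the
  ¼/½ tie convention for the bivariate rank; requires n ≥ 5.
* **RDC** — empirical copula per variable, intercept augmentation,
  20 random sinusoidal features sin(w·u + b) with w ~ N(0, scale²)
  (scale = 1/6, the original parameterisation of the method, where the
  projections are near-linear over the unit interval) and
  b ~ U(0, 2π); score = largest canonical correlation between the two
  feature blocks, ridge-regularised by 1e−8 because the sinusoidal
  features are near-collinear by construction.  Projections for pair
  (j, i) are drawn from `SeedSequence([seed, j, i])`, making the matrix
  reproducible across processes and invariant to row permutations.
* **Mutual information** — equal-frequency binning (default
  ceil(n^(1/3)) bins; ordinal ranks split ties by sample order) and the
  plug-in estimator in bits, no bias correction.  Simple and exactly
  checkable against the log2(B) diagonal identity.
* **Pseudo-knockout Z-score** — the sample where a miRNA is at its
  minimum (first occurrence on ties) stands in for a knockout; the score
  is |x_i(s*) − mean(x_i)| / sd(x_i).  The absolute value is used
  because knocking down a repressor can move a target either way.

## Penalised regression

Each mRNA is regressed on all miRNAs with the elastic net
(1/2n)‖y − β₀ − Xβ‖² + λ[α‖β‖₁ + (1−α)/2‖β‖₂²]; α = 1 is the Lasso and
α defaults to 0.5.  Predictors are standardised internally (unbiased
sd) and coefficients reported on that scale — the scores are used only
for ranking, so comparability across miRNAs matters more than original
units.  λ is chosen by 5-fold cross-validated minimum MSE over a
50-point log grid from the smallest all-zero λ down by 10³, with a
deterministic fold assignment (sample position mod k after a seeded
shuffle).  The solver is scikit-learn's coordinate descent; the
contract is fixed by closed forms (λ = 0 → OLS; orthogonal design →
soft-thresholding; λ ≥ λ_max → all-zero), not by the solver choice.

## Causal inference

The CPDAG over all features (miRNAs and mRNAs jointly — no tier
constraint by default, for fidelity to the underlying method; an
optional constraint forbidding mRNA → miRNA orientations is a possible
extension) is learned by **PC-stable**: at each level ℓ the neighbour
sets are frozen before any test, so output does not depend on column
order.  Conditional independence uses the Fisher-z partial-correlation
test, z = atanh(ρ)·sqrt(n − |S| − 3), with ρ from the inverse of the
corresponding correlation submatrix; default α = 0.01.  The default
conditioning-size cap is 3 (PC is exponential in conditioning size;
the cap keeps thousand-feature datasets tractable; `None` removes it).
V-structures are oriented by the sepset rule; conflicting v-structure
orientations leave the edge undirected (conservative), and Meek rules
1–4 are iterated to a fixed point (rule 4 cannot fire without
background knowledge but is kept for completeness).

**IDA** enumerates the candidate parent sets of a miRNA x: certain
parents plus every subset T of x's undirected neighbours whose
orientation toward x creates no new v-structure at x (every member of T
adjacent to every other chosen parent).  Each valid set P yields one
effect: the coefficient of x in the OLS regression of the mRNA on
{x} ∪ P (0 when the mRNA is itself in P; rank-deficient sets dropped
with a warning).  The tests verify this local enumeration against an
exhaustive oracle that enumerates all consistent DAG extensions of the
CPDAG (≤ 6 nodes) and dedupes by parent set.

The score matrix summarises each multiset by its minimum-absolute-value
element with sign preserved — the standard conservative bound.  On an
unoriented single edge the multiset contains 0 (the reverse orientation
cannot be excluded), so the summary is 0; this is the known
conservativeness of the equivalence-class view, not an estimation
failure — the multiset still contains the adjustment estimate.  Pairs
in different connected components of the skeleton score exactly 0:
every consistent extension d-separates them, so the effect is zero in
all extensions, and skipping the regression avoids reporting sampling
noise for structurally impossible effects.

## Differential expression

A moderated t-statistic with empirical-Bayes variance shrinkage: pooled
within-group variances s_g² (d_g df) are shrunk toward a prior
(d₀, s₀²) fitted by method of moments under s_g² ~ s₀²·F(d_g, d₀);
posterior s̃_g² = (d₀s₀² + d_g s_g²)/(d₀ + d_g), t̃ referred to a t
distribution on d₀ + d_g df, Benjamini–Hochberg adjustment.  When the
observed variances are under-dispersed the moment equations give
d₀ = ∞ and the statistic reduces to the ordinary pooled t with the
common variance — the correct limit.  A plain Welch t-test is available
as `method="welch"`.  Selection is by top-N smallest p (ties broken by
feature order, for determinism) or by an adjusted-p threshold.

## Pre-processing

`standardise` z-scores features (unbiased sd; zero-variance columns
become zero with a warning).  `impute_normalise` fills each missing
cell with the mean of that feature over the k = 10 samples nearest in
Euclidean distance on the complete features (feature median when no
complete feature exists; features > 50 % missing are dropped), then
quantile-normalises samples onto the mean order-statistic distribution,
ties receiving the mean of the reference values they span.  KNN +
quantile is our choice of a standard, fully specified pair of
algorithms for this utility; it preserves within-sample rank order and
is the identity when all samples already share a distribution.

## Ensembles, masking, validation

Borda aggregation averages per-method ranks (ties share the mean rank,
with mRNA name as a deterministic secondary sort key in listings); the
top-k variant first maps ranks strictly greater than k to the maximal
rank N (a gene exactly at rank k is kept — inclusive reading of "top
k").  Average rank and average rank-points (N − rank + 1) induce the
same ordering, so average rank is used.

The sequence-support mask nulls scores of pairs absent from a
binding-pair list (TargetScan-style export or CLIP-derived), applied
after scoring.  For signed matrices the null 0 places unsupported pairs
behind every negative score.

Validation counts, per miRNA, the top-k predictions present in the
ground truth.  Perturbation-derived truth uses strict |LFC| > threshold
(default 1.0); a gene at exactly the threshold is not a target.  Method
comparison retains the miRNAs with ≥ 1 confirmed target under *every*
method, ranks methods per miRNA by confirmed count (mean-rank ties) and
awards M − rank + 1 points; the per-miRNA "ranking score" formula is
our Borda-style choice — it is monotone in confirmed count and makes
the score sum over methods exactly retained × M(M+1)/2, a convenient
invariant.

## Synthetic generator

miRNA expressions are iid N(0, 1); `n_edges` regulations are sampled
uniformly over miRNA × mRNA pairs under a cap of 3 regulators per mRNA
(keeping regression recovery well-posed at desk-scale n); regulated
mRNAs follow y = Σ β_j x_j + ε with β ~ U(−1.0, −0.6) (negative-only by
default, matching the down-regulation emphasis; a flag admits positive
effects for stress-testing the signed ranking convention) and
ε ~ N(0, noise_sd), noise_sd = 1.  An optional fraction of regulated
mRNAs uses a monotone-decreasing cubic link, rescaled to the linear
predictor's spread so signal-to-noise is preserved.  The perturbation
table emulates a miRNA-inhibition assay: each planted edge records
lfc = −β·δ + N(0, 0.1) with δ = 2, so |β| ≥ 0.6 clears the |LFC| > 1
rule by construction; an equal number of decoy non-edges records
N(0, 0.3).

Benchmark conditions (300 samples, 20 miRNAs, 500 mRNAs, 100 edges)
put an intrinsic ceiling on fixed top-5-per-miRNA precision: the number
of true edges per miRNA is approximately Binomial(100, 1/20), so even a
perfect ranker averages E[min(edges, 5)]/5 ≈ 0.82.  Measured Pearson
and Lasso precisions sit just above 0.8 for exactly this reason.

What the generator does **not** emulate: count-based (RNA-seq) noise,
miRNA–miRNA correlation structure, batch effects, shared targets with
correlated regulators at realistic density, or the incompleteness and
bias of real interaction databases.  Passing the benchmark shows the
pipeline's machinery is correct and calibrated on its stated model; it
does not certify performance on real tumour profiles.

## Problem sizes and determinism

Test and acceptance runs use desk-scale problem sizes (hundreds of
samples, tens of miRNAs, hundreds of mRNAs; 10–20 replicate seeds),
chosen so the full suite completes in minutes while keeping the
Monte-Carlo assertions stable.  All randomness flows from explicit
integer seeds (`numpy.random.default_rng` / `SeedSequence`); repeated
runs with the same seed produce byte-identical CSV artefacts.

## Known limitations

* Kendall, Hoeffding, RDC and MI loop per pair in Python; fine at
  desk scale, slow for genome-wide matrices.
* The plug-in MI estimator is biased upward at small n; scores are
  used only for ranking, where the bias is monotone-comparable.
* PC-stable with a conditioning cap can retain edges a full PC run
  would remove; the cap is configurable.
* `ida_scores`' min-absolute summary is conservative by design; use
  `ida_effects` for the full multiset.
* Ordinal tie-splitting makes MI (only) depend on sample order in the
  presence of exact ties; expression data on a continuous scale is
  effectively tie-free.
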