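# Methods

## The question the framework answers

Transcriptomic classifiers are usually benchmarked by randomized
cross-validation (RCV) on data pooled from several studies. RCV estimates
prediction error under random sampling, i.e. assuming future samples are
drawn from the same distribution as the training data. Real deployments
violate that assumption: each study carries its own *study-effect* — the
joint technical (batch) and biological (cohort-composition) shift in
expression — so a classifier is, in practice, asked to transfer to studies
it never saw. Inter-study validation (ISV) measures exactly that: train on
all studies but one, test on the excluded study, repeat for every study.

Comparative cross-validation analysis (CCVA) contrasts the two estimates
per phenotype. For phenotype *p* with studies *s = 1..S*, ISV yields one
sensitivity per study (the fraction of the held-out study's *p*-samples
assigned label *p*); CCVA reports

* `mean_isv(p)` — the unweighted mean of the per-study ISV sensitivities
  (each study one vote, regardless of its size; a sample-weighted pooled
  ratio is also available),
* `rcv(p)` — the average per-fold sensitivity from ten-fold RCV (the
  pooled-count ratio is also available),
* `gap(p) = rcv(p) − mean_isv(p)` — the study-effect penalty, and
* `CoVar(p)` — sd/mean of the per-study ISV sensitivities, a consistency
  measure (undefined, never 0, with fewer than two studies or zero mean).

Cumulative CCVA traces `mean_isv` and `rcv` as functions of the number *n*
of the phenotype's studies included (all studies lacking the phenotype
always ride along). For each *n*, five distinct study subsets are drawn
uniformly (all of them when fewer than five exist; with replacement never);
each subset is a full CCVA run. At *n = N* this reduces to standard CCVA;
at *n = 1* ISV degenerates to train-on-one-study / test-on-the-rest.

A curve point's `covar` is computed from the per-study ISV sensitivities
pooled across the point's resamples: at *n = 2* a single resample holds
only two studies, and a standard deviation over two values is dominated by
its own sampling noise, so pooling (5 resamples × *n* studies) is the
smallest estimator that says anything about consistency.

## Validation engines

ISV builds one split per study, ordered by study id. If a phenotype loses
all (or all but one of) its training samples when a study is held out, the
split records it as untrainable; its (phenotype, study) cell is reported in
the `skipped` section of the report rather than silently dropped.

RCV deals each phenotype's pooled samples into ten folds: shuffle (seeded),
assign round-robin, so per-phenotype fold sizes differ by at most one.
Stratification is by phenotype only — never by study. Pooling across
studies is what makes RCV blind to study-effects, and that blindness is
the quantity being measured, so balancing studies within folds would be a
bug, not a refinement.

Both engines share a stratified training loop that mitigates sample-number
bias between phenotypes: each of `n_repeats` (default 11, odd to avoid
binary vote ties) repeats subsamples every phenotype without replacement
down to the smallest phenotype's training count, reruns feature selection
on the balanced subsample, trains a model, and the ensemble predicts by
per-sample majority vote (ties to the lexicographically smallest label).
On a class-balanced training set the subsample is the full training set
and all repeats coincide.

Feature selection, pair selection and classifier fitting happen strictly
inside each split's training side; the test side is touched only at
prediction time. `split_models` exposes the per-split training path so the
no-leakage property can be audited by recomputation.

## Classifiers

Two deliberately different schemes, to separate conclusions about
study-effects from conclusions about any one classifier:

**margin** — F-score feature selection followed by one-versus-one linear
maximal-margin discriminants (linear SVM, cost C, default 1). The F-score
of gene *g* between groups +/− is

    F = [(m⁺ − m)² + (m⁻ − m)²] / (s²⁺ + s²⁻)

with group means m±, pooled mean m, and unbiased within-group variances
s²± (a zero denominator scores +∞, ranked above all finite values; F is
invariant under affine rescaling of the gene). Multi-class selection
computes one-vs-rest F per phenotype and aggregates by the maximum, so
every phenotype contributes its most discriminative genes; the top
`n_features` (default 100) genes are kept, ties broken by gene id.
Prediction is pairwise majority vote, ties to the smallest label.

**rank_pair** — a top-scoring-pairs-family classifier. For phenotype *c*,
every ordered gene pair (i, j) among the selected genes is scored by

    Δ_c(i, j) = P̂(x_i < x_j | c) − P̂(x_i < x_j | not c)

with empirical fractions over training samples. Pairs are accepted
greedily in decreasing Δ (orientation chosen so Δ > 0, ties by
lexicographic (i, j)), skipping pairs that share a gene with an accepted
pair of the same phenotype, until `pairs_per_phenotype` (default 10) are
held. A sample scores each phenotype by the fraction of its pairs whose
ordering holds strictly; argmax wins, ties lexicographic. Decisions depend
only on within-sample orderings, hence are invariant under strictly
increasing per-sample transforms — the property that makes rank-pair
classifiers robust to monotone normalization differences, and, conversely,
directly sensitive to per-gene batch shifts.

The two schemes see study-effects very differently, and this matters when
interpreting the synthetic benchmarks: a per-study shift b_{g,s} that is
common to all of a study's samples projects onto a 100-gene hyperplane as
a single scalar offset and largely averages out when the class separation
is large, while each rank pair feels the shift difference of just two
genes. In the few-studies benchmark below the margin scheme's gap is
therefore small (~0.06) where the rank-pair gap is ~0.12; the study-effect
benchmarks use rank_pair for that reason.

## Synthetic data generator

Value for gene *g*, sample *j* (study *s*, phenotype *p*), log scale:

    x = μ_g + β_{g,p}·1[g ∈ S_p] + b_{g,s} + η_{g,s,p}·1[g ∈ S_p] + ε

with μ_g ~ N(m0, σ_μ²) per gene; signature S_p of size k drawn uniformly
without replacement per phenotype (signatures may overlap); β_{g,p} =
sign_g·(δ + N(0, σ_β²)) with sign_g = ±1 per gene, so the true signal
points the same way in every study; b_{g,s} ~ N(0, σ_study²) per
(gene, study) — the batch shift; η_{g,s,p} ~ N(0, σ_het²) per
(gene, study, phenotype) on signature genes — cohort heterogeneity; and
ε ~ N(0, σ_ε²) i.i.d. noise. Only b and η break transferability. A single
seeded stream with a fixed draw order (baselines, signs, signatures +
effects per phenotype, study effects, heterogeneity, noise column by
column) makes datasets bit-reproducible.

Defaults (log-expression units): 500 genes, phenotypes A/B, 6 studies of
20+20 samples, k = 30, m0 = 7, σ_μ = 1, δ = 1.5, σ_β = 0.3, σ_study = 1,
σ_het = 0.5, σ_ε = 1. m0/σ_μ mimic log2 microarray intensities; δ = 1.5σ_ε
is a clearly detectable but not trivial marker effect; σ_study = σ_ε and
σ_het = 0.5σ_ε are calibration choices — the study-effect literature gives
magnitudes only indirectly — flagged as such here. `study_design` accepts
arbitrary (study × phenotype) count tables, including zero cells and
unequal sizes, to mimic real compendia where rare phenotypes appear in a
handful of studies.

What the generator does *not* emulate: count-based RNA-seq noise
(negative binomial, dropout), probe-level artifacts, correlated gene
modules, platform mixtures, label noise. Benchmarks passing on this model
show the framework's estimators behave as designed when study-effects are
additive Gaussian shifts; they do not certify performance numbers on any
real compendium.

## Benchmark conditions (what the end-to-end tests run)

All sensitivities are fractions in [0, 1]; every condition uses σ_ε = 1,
30-gene signatures, 500 genes, two phenotypes, seeds 1–5, and the
class-balanced designs above (where the stratified loop is an identity, so
the benchmarks run with n_repeats = 1; the unbalanced path is unit-tested
separately).

* **Identical-distribution limit** — 6 studies × (20+20), δ = 1.5,
  σ_study = σ_het = 0: per phenotype, |mean ISV − RCV| ≤ 0.05 for both
  schemes. With no study component the held-out study is just another
  random sample, so the two estimates must coincide.
* **Few-studies gap** — 3 studies × (20+20), δ = 1.5, σ_study = 2,
  σ_het = 0, rank_pair: mean(RCV − mean ISV) ≥ 0.10.
* **Convergence and consistency** — 10 studies × (12+12), δ = 1.0,
  σ_study = 2, σ_het = 0.5, rank_pair; cumulative curves at
  n ∈ {2, 4, 6, 8}, 5 resamples, averaged over the two phenotypes. The
  smaller effect and studies keep single-study training below the
  sensitivity ceiling, which is where the convergence phenomenon lives:
  ISV rises from n = 2 to n = 8 (5/5 seeds), pooled Spearman
  ρ(n, mean ISV) > 0, CoVar falls from n = 2 to n = 8 in ≥ 4/5 seeds, and
  pooled ρ(CoVar, mean ISV) < 0.

`scripts/acceptance.py` reruns these conditions from scratch (seeds derived
from `--seed`) and writes the measured quantities as JSON.

## Numerical choices and degenerate inputs

* All tie-breaks (feature ranking, pair ranking, votes, argmax) are
  lexicographic; identical inputs and seeds give bit-identical outputs,
  which the CLI's checksum-stable reports rely on.
* Expression TSVs are written with shortest-round-trip float formatting,
  so write∘read is exact; readers reject duplicate ids, non-finite or
  non-numeric cells (with coordinates), and mismatched sample sets
  (listing the symmetric difference) rather than intersecting silently.
* Spearman p-values: exact permutation enumeration for n ≤ 9, t
  approximation (scipy) above; a constant vector returns an explicit
  undefined marker, never NaN. Rank-sum p-values: exact enumeration of all
  C(N, n₁) rank assignments (average ranks for ties) for N ≤ 20, normal
  approximation with tie correction above.
* Validation requires ≥ 2 training samples per phenotype per split;
  phenotypes below that are flagged untrainable and their test cells
  reported as skipped.
* Values are assumed log-scale and normalized upstream; the library never
  normalizes, and platform mixing is out of scope.

## Known limitations

* The study-effect model is additive and Gaussian; multiplicative or
  rank-distorting batch effects are representable only through their
  monotone part (to which rank_pair is blind by design).
* No nested hyperparameter tuning; cost, k and pairs-per-phenotype are
  fixed per run.
* Sensitivity is the only metric, matching the framework's focus;
  specificity/AUC would need a different report layer.
* Exact p-value enumeration is O(C(N, n₁)) and is capped at N = 20 by
  design.
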