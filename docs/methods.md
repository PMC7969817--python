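# Methods

This note documents the models, procedures and design choices behind
`autosig`, in the spirit of a methods appendix: what each stage assumes,
which parameters matter, and what the synthetic validation does and does
not establish.

## Synthetic cohorts

The generator emulates the *structure* of a multi-study case/control
gut-microbiome meta-analysis, not any particular dataset. Per sample:

1. a baseline composition is drawn log-normally — per-taxon mean
   μ_t ~ N(0, 1) fixed once per cohort, per-sample log-noise σ = 1 —
   giving the heavy-tailed, dominance-skewed profiles real genus tables
   show;
2. planted disease taxa are multiplied by `effect_fold` in diseased
   samples, and the study's batch taxa by `batch_fold` in all of that
   study's samples (multiplicative effects on relative abundance, before
   renormalisation, matching how fold changes are reported);
3. each taxon is structurally zeroed with probability `zero_inflation`
   (absence from the community, applied *before* read sampling, as
   opposed to undersampling zeros which the multinomial step produces on
   its own);
4. reads are drawn multinomially at a depth uniform in `depth_range`.

Key defaults and why: 3 studies × 50 samples per class per study
(150/class — the scale at which the recovery analyses are run), 200
genus-level taxa, a 15-taxon shared signature at 8-fold change, 5
disease-specific taxa per disease, 5 batch taxa per study at 10-fold,
depths 5,000–30,000 (so the rarefaction depth of 5,000 is attainable),
zero inflation 0.3, and a 150-metabolite layer with 10 planted links of
Spearman magnitude 0.6.

Planted (disease, batch, linked) taxa are drawn from the
above-median-μ half of the baseline. A fold change planted on a taxon
whose expected depth-5,000 count is below one read is unobservable in
principle; restricting the plant to detectable taxa makes "the pipeline
recovers what was planted" a meaningful statement about the pipeline
rather than about read depth. Disease and batch sets are disjoint by
construction so confound-flagging results are unambiguous.

The metabolite layer uses a Gaussian copula: the taxon's tie-averaged
ranks are mapped to normal scores z, and the metabolite is
exp(sign · r·z + √(1−r²)·ε) with the latent Pearson r = 2·sin(π·ρ/6)
chosen so the population Spearman correlation is the requested ρ. The
relation is exact for tie-free marginals; heavy zero-inflation introduces
rank ties and attenuates the realised |ρ| slightly.

What the generator does **not** emulate: phylogenetic correlation between
taxa, taxon–taxon ecological interactions, longitudinal dynamics,
platform-specific error profiles, or compositions whose class difference
is a *decrease* (planted folds are > 1; the consensus ranking is
direction-agnostic, so this loses no generality for recovery tests).
Passing recovery tests therefore shows the machinery is correct and
sensitive at the planted effect sizes, not that real effect sizes are
detectable.

## Preprocessing

Rarefaction subsamples each sample to exactly the target depth without
replacement (multivariate hypergeometric), the contract of the standard
feature-table rarefaction; samples below depth are dropped and logged.
The depth (default 5,000) is a configuration parameter, not derived
internally. Taxonomic collapse sums taxa sharing the lineage prefix at
the chosen rank; taxa *unnamed* at that rank (e.g. `g__`) are retained
under their deepest named ancestor rather than discarded, so family-level
mass survives a genus-level collapse and the matrix grand total is
conserved exactly. First-timepoint selection keeps the minimum
`time_index` per (study, subject), ties broken lexicographically by
sample ID for determinism. Adult-only cohorts (age ≥ 18) *exclude*
samples with missing age — the conservative reading, preventing children
from leaking into adult models. Class balancing subsamples the majority
class uniformly without replacement, seeded and logged.

## Batch diagnostics

Bray–Curtis, PCoA and PERMANOVA are implemented directly (and
cross-checked against scikit-bio in the tests). Bray–Curtis is not a
metric — the triangle inequality can fail — so no metric property is
asserted; a pair of all-zero samples gets distance 0 by convention. PCoA
reports the full eigenvalue spectrum, including negative eigenvalues
(non-Euclidean input); their axes are zero-filled rather than imaginary.
PERMANOVA permutes raw labels freely (no strata), one factor at a time;
the p-value uses the add-one estimator p = (1 + #{F* ≥ F}) / (1 + n_perm)
so it is never exactly 0. For small balanced designs an exhaustive mode
enumerates all distinct label arrangements and reports the exact
fraction.

## Classifiers and tuning

All four algorithms see the same NZV-filtered feature set and the same
stratified 90/10 split, so their importances are comparable per taxon.
The NZV rule is caret's: drop when frequency-ratio > 19 **and** unique
fraction < 10% (constants always drop). Tuning is grid search by mean CV
AUC over 7-fold × 3-repeat stratified folds; a single-point grid skips
the search (there is nothing to select) and fits directly. The built-in
grids are explicit stand-ins — published per-model tuning tables were not
available — and are overridable per run:

- random forest: 500 trees; features per split ∈ {√p, p/4, p/2};
- XGBoost: learning rate {0.05, 0.3} × depth {3, 6} × rounds {100, 300};
- ridge logistic: C over 10 log-spaced values in [10⁻³, 10³], features
  standardised first (importance = |coefficient| on the standardised
  scale);
- RBF-SVM: C ∈ {0.25, 1, 4}, kernel width around the median heuristic
  (×½, ×1, ×2).

An RBF-SVM has no native per-feature coefficients, so RFE scores features
by the univariate |AUC − 0.5| filter, the default importance for kernel
models in the reference modeling framework. Because that score does not
depend on the surviving set, elimination order is fixed once; the SVM is
retrained per surviving-set size only to score the elimination path,
using 3-fold CV AUC (the cheaper path CV is a deliberate choice — the
7×3 protocol is reserved for hyperparameter tuning). The best subset is
the path point with maximal CV AUC, ties resolved toward the smaller set;
final ranks are reverse elimination order (rank 1 = last survivor),
within-batch ties ordered by score. The reported SVM-RFE "importance" is
p − rank + 1, a non-negative score consistent with the other models'
higher-is-better convention.

Evaluation: AUC is the Mann–Whitney probability-ranking form (ties count
½); macro F1 averages the two per-class F1s at a fixed 0.5 threshold on
probability-like scores, and a never-predicted class contributes F1 = 0.

## Consensus and controls

Importances are converted to within-model ranks with tie-averaging (rank
sums always equal p(p+1)/2, a tested invariant), and taxa are ordered by
the arithmetic mean rank across models. "Top 30" means the 30 smallest
mean ranks, ties at the boundary broken lexicographically; the
alternative reading (union of per-model top-30s) was considered and
rejected because the visual the analysis mirrors shows exactly 30 rows
per disease. Fold change is log₂ of class means with a pseudocount of
half the smallest nonzero value (an absent-in-both taxon gets exactly 0).

The study-confound control fits one multiclass random forest predicting
study on all samples, disease ignored and unbalanced (the model must see
the batch signal exactly as the disease models do); per-taxon Gini
importances above the 99th percentile (linear interpolation) are flagged.
An absolute importance cutoff would be dataset-specific, so the
percentile is the parameter and the realised cutoff is reported. Whether
to fit one model per study or one multiclass model is ambiguous; the
multiclass model with per-taxon maximum importance is implemented.
Flagged taxa stay visible downstream (asterisked in the consensus table)
but are excluded from metabolite candidates and interpretation. The
random-label null permutes labels uniformly and reruns the full
NZV → split → fit → evaluate chain per repeat; its mean held-out AUC is
the pipeline's calibration check (~0.5).

## Contrasts and metabolites

Pairwise disease models balance the larger class down, then run the same
suite and consensus. Models touching MS or RA are adult-only by default.
"Consistently identified" means membership in ≥ 2 of the disease's 3
contrast top-30s; the full 3-way intersection is reported alongside.
Metabolite candidates are genus-level consistent taxa, present in the
correlation cohort, minus flagged taxa; taxa detected (strictly nonzero)
in < 10% of samples are dropped. Spearman ρ uses average-tied ranks;
two-sided p-values come from the t-approximation for n > 10 and from the
exact rank-permutation null for tie-free n ≤ 10 (both available). BH runs
once across the entire taxon × metabolite family by default (per-taxon
adjustment is an option, off by default), and significance is adjusted
p < alpha (default 0.05).

## Determinism and problem sizes

One master seed fans out to per-stage seeds through a splittable seed
sequence; every stochastic step (rarefaction draw, balancing, splits, CV
folds, learner internals, permutations) derives from it, and two runs
with the same seed write byte-identical files. The pipeline writes into a
caller-chosen directory with no timestamps inside the files, precisely so
that this byte-level reproducibility is checkable.

Simulation-backed tests run at deliberately chosen scales: recovery
analyses use 150 samples per class, 200 taxa and 15 planted taxa at
8-fold (with one-point tuning grids, since tuning breadth is orthogonal
to what those analyses measure); the null control uses 20 permutation
repeats; the determinism check uses a miniature cohort end to end. The
multi-point tuning path is exercised separately on small matrices.

## Known limitations

- Single-factor PERMANOVA only; no strata, no sequential (multi-term)
  models.
- The four classifiers are binary; multiclass disease prediction is out
  of scope.
- Batch effects are *detected and flagged*, never corrected.
- The SVM-RFE filter importance makes its ranking univariate at the
  elimination step; interactions influence only the best-subset choice.
- Spearman's exact permutation p-value is only used for tie-free small
  samples; zero-inflated taxa at small n fall back to the
  t-approximation.
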