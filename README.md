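# autosig

Consensus machine-learning signatures of autoimmune disease from
multi-study gut-microbiome abundance data.

Case/control microbiome studies of autoimmune diseases (IBD, MS, RA, ...)
disagree with each other: cohorts differ in geography, age, sequencing
platform and analysis pipeline, and single-study findings often fail to
replicate. One way through is a meta-analysis that re-processes many
studies into one abundance matrix and asks which taxa *predict* disease
across all of them. `autosig` implements that analysis as a tested,
reusable Python library, with a synthetic-cohort generator that plants
known disease, batch and metabolite structure so every stage can be
validated against ground truth.

## The method

Given per-study taxon count tables and sample metadata, the pipeline:

1. **Harmonises and preprocesses**: parses Greengenes-style
   (`k__...;g__...`) and MetaPhlAn-style (`k__...|g__...`) lineages,
   keeps each subject's first time point, rarefies every sample to a
   common depth *D* = 5,000 reads by without-replacement (multivariate
   hypergeometric) subsampling, drops shallower samples, collapses to
   genus or species, converts to relative abundance, and merges studies
   over the taxon union.
2. **Diagnoses batch structure**: Bray–Curtis dissimilarity
   BC(x, y) = Σ|xᵢ − yᵢ| / Σ(xᵢ + yᵢ), principal-coordinate analysis, and
   a one-factor PERMANOVA with pseudo-F
   F = [SS_B/(a−1)] / [SS_W/(n−a)] and a permutation p-value — all
   implemented from scratch.
3. **Fits four feature-ranking classifiers** on balanced,
   near-zero-variance-filtered data with a stratified 90/10 split and
   grid search under 7-fold, 3-times-repeated CV: random forest (Gini
   importance), XGBoost (total gain), ridge logistic regression
   (|standardised coefficient|) and an RBF-SVM with recursive feature
   elimination (step 2). Performance is held-out AUC and macro F1.
4. **Aggregates a consensus signature**: importances become within-model
   ranks (ties averaged), taxa are ordered by mean rank across the four
   models, and the top 30 form the signature, annotated with
   log₂(mean disease / mean healthy) fold change.
5. **Runs two controls**: a "mock" random-forest model predicting *study*
   rather than disease flags taxa in the top 1% of its Gini importances
   as batch-confounded; retraining on permuted labels must collapse the
   AUC to ~0.5.
6. **Contrasts diseases pairwise** and intersects top-30 sets to separate
   disease-specific taxa from the shared autoimmunity signature.
7. **Correlates candidate genera with metabolites**: taxa recurring in
   ≥ 2 of a disease's 3 contrast models, unflagged and present in ≥ 10%
   of samples, are tested pairwise against a metabolite matrix by
   Spearman correlation with one Benjamini–Hochberg adjustment across all
   pairs (significant at adjusted p < 0.05).

## Worked example

`examples/03_disease_models_and_consensus.py` generates a two-class
cohort (150 samples per class over 2 studies, 200 genera, a planted
15-taxon signature at 8-fold change), fits all four models and builds the
consensus:

```
NZV filter removed 0 of 200 taxa
random_forest      held-out AUC=1.000 macro-F1=1.000
gradient_boosting  held-out AUC=1.000 macro-F1=0.967
ridge_logistic     held-out AUC=0.996 macro-F1=0.933
svm_rfe            held-out AUC=1.000 macro-F1=1.000
planted taxa recovered in top-30 consensus: 15/15
```

Every planted taxon lands in the top-30 consensus and every model
separates the classes nearly perfectly — at an 8-fold effect this cohort
is deliberately easy, so anything less indicates a pipeline defect. The
confound-control example (`examples/04_confound_controls.py`) prints the
complementary checks: both taxa above the 99th-percentile study-model
cutoff are truly batch-planted, none of the disease-signature taxa are
flagged, and the random-label AUCs average 0.486.

The other examples cover simulation (`01`), preprocessing and batch
diagnostics (`02`), and contrasts plus metabolite correlation (`05`).
A thin CLI wraps the same library for end-to-end runs from a YAML config:

```bash
autosig run-all config.yaml --out runs/demo --seed 7
```

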