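# Methods

This note records the statistical model behind `tinvmark`, the conventions
and defaults that matter, and the choices made where the design was
genuinely open. Nothing here states an empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Problem and data model

The pipeline classifies chemicals as non-genotoxic hepatocarcinogens
(NGHC) vs non-hepatocarcinogens (NHC) from rat-liver expression responses
measured in several independent microarray datasets. Inputs are already
normalized, log2-scale expression matrices (probes/genes × samples) with
per-sample metadata: chemical, exposure style (treatment duration:
1-day, 3-day, 1-week = 5 or 7 days, 14-day, 28-day), dose group, replicate
index and a control flag. Dose and exposure grouping (e.g. mapping 5- and
7-day arms to "1w", the maximum tolerated dose to "high") is configuration,
not code; the analysis itself uses only the configured dose group, by
default "high".

The unit of replication throughout is the **chemical**, not the animal:
replicate animals are averaged into one per-chemical profile
(per gene: mean over treated replicates − mean over the applicable control
replicates) before any testing. Two control designs occur in the source
databases and both are supported: controls pooled per dataset × exposure
(default) and per-chemical matched controls. Under the pooled design the
control term is a constant offset shared by all chemicals of a dataset ×
exposure, so it cancels from the NGHC-vs-NHC contrast.

## Differential expression

Per gene, NGHC profiles are compared to NHC profiles with a two-sided
two-sample t-test. Welch's unequal-variance form is the default because
the class panels are strongly imbalanced (ratios such as 12:93 occur in
the emulated archives); the pooled-variance Student form is available for
sensitivity checks. A gene is a DEG when *p* < α (default 0.05, raw — no
multiple-testing correction at this stage, robustness comes from the
intersections that follow) **and** |Δ| ≥ log2(fold_threshold) with the
default threshold 1.5 (0.585 log2 units). Δ exactly at the threshold
passes. A gene with zero variance in both groups and Δ = 0 gets *p* = 1;
Δ = 0 can never be a DEG and its direction is recorded as "+" by inert
convention.

## Consensus and time-invariance

A consensus biomarker at one exposure style is a gene that is a DEG in at
least `min_datasets` datasets (default: all) with one direction wherever
it is a DEG. Each consensus set is then cross-checked at the other
exposure styles by per-gene **modulation calls** aggregated over datasets:

* "+" / "−" — every contributing dataset evidences that direction;
* "+/−" — datasets evidence conflicting directions, or no dataset
  evidences any direction;
* "absent" — the gene is not measured on any platform at that exposure
  (platform ID spaces genuinely differ; a gene missing from one platform
  is evaluated on the datasets where it exists).

A gene is **time-invariant** iff its call at every required exposure style
(default: the three short-term styles) is signed and identical. "Absent"
at a required exposure blocks the flag (logged).

**Direction-evidence rule.** At cross-check exposures significance is
never re-required, but a bare sign-of-Δ rule turned out to be too
permissive: for a transient gene with no true effect at one exposure, each
dataset's Δ is a small zero-centred noise term, so with three datasets the
sign-unanimity event has probability 1/4 and a spurious invariance flag
probability 1/8 per gene. The default rule (`direction_rule="fold"`)
therefore requires a dataset's |Δ| to reach the same log2(fold_threshold)
used in DEG calling before it evidences a direction; "no direction
evidenced" aggregates to "+/−", generalizing the natural Δ = 0 tie rule.
This makes the false-invariance probability of a no-effect exposure
essentially zero while leaving genuinely modulated genes (whose |Δ|
concentrates far above the threshold) untouched. The pure
sign-of-Δ-unanimity rule remains available as `direction_rule="sign"`.

The package bundles a reference table (`data/reference_modulation.tsv`) of
published per-exposure modulation calls and reported verdicts for six
rat-liver NGHC signatures; `evaluate_reference_modulation()` re-derives
all 57 verdicts from the encoded calls, which the acceptance suite
requires to agree exactly.

## Classifier evaluation

Feature tables are chemicals × biomarker-genes matrices of profile values,
restricted to the genes measured on the platform (absent genes dropped and
logged). Seven classifier families are exposed (decision tree, bagged
trees, boosted trees, kNN, naive Bayes, linear SVM, random forest), all as
scikit-learn estimators with library-default hyperparameters except the
random forest, which uses √(n_features) candidate features per split and a
tree count selected from the LOOCV grid 10..100 (step 10, ties toward the
smaller count). Tree-count selection runs on the same LOOCV used for
reporting; this is optimistically biased and is accepted as such — the
grid is tiny and the reported quantity of interest is stability across
dataset × exposure combinations rather than a single AUC.

LOOCV leaves out one chemical at a time; its probability-of-NGHC score
comes from a model trained on all the others, so no chemical influences
its own score. Margin classifiers without probabilities (SVM) are mapped
into [0, 1] by a rank-preserving min-max calibration of training decision
values, which cannot change the AUC. A degenerate single-class training
fold scores 0.5 with a warning. AUC follows the Mann–Whitney convention
(ties count one half); the test suite checks every AUC against an
exhaustive pair-counting oracle.

## Stability metrics

Given CvResults for all dataset × exposure combinations:

* median AUC and IQR = Q3 − Q1 over all entry AUCs, quartiles by linear
  interpolation between order statistics (the common "type 7" rule —
  conventions differ and this one is recorded in the report metadata);
* C.V.d = 100 · sd/mean over **per-dataset median** AUCs, C.V.e likewise
  over per-exposure medians. Medians (not means) per group mirror the
  median-AUC emphasis and are flagged in the metadata; standard deviations
  are sample (n−1). A grouping with a single group contributes C.V. = 0.
* stable ⇔ IQR ≤ 0.05 **and** C.V.d ≤ 5% **and** C.V.e ≤ 5%. The IQR rule
  compares an AUC-scale quantity to 0.05; comparisons tolerate float
  representation error so the verdict flips exactly at the printed
  boundary.

External validation fits once on all training-dataset chemicals and
computes the AUC on the test dataset, after intersecting gene columns —
the cross-platform restriction (a gene with no probe on the test
platform simply drops out) falls out of this intersection.

## Enrichment

One-sided hypergeometric over-representation of a query gene set against
a user-supplied term → gene catalog: per term,
P(overlap ≥ observed | |query|, |term|, |universe|), Bonferroni-corrected
over the tested terms, significant at corrected *p* < 0.05. The universe
defaults to all annotated genes and can be overridden to the platform's
measured genes; both are defensible backgrounds and the choice is the
caller's. Depletion is not tested. No specific annotation database is
assumed or reproduced.

## Synthetic data generator

`simulate()` emulates the joint structure of the real archives: several
datasets (default 3) on two platform tags, each platform randomly omitting
`missing_probe_fraction` of the gene universe (datasets sharing a platform
share the mask); an imbalanced chemical panel (default 26 NGHC : 62 NHC,
the most balanced of the emulated archives) shared across datasets with
dataset-global labels; exposure styles (default the five standard ones) in
biological triplicate with pooled or matched controls.

Values are baseline (per-gene N(8, 1.5²) log2 intensity) + per-dataset
per-gene offset (N(0, `dataset_shift_sd`²)) + i.i.d. N(0, `noise_sd`²)
noise, matching the log2-scale t-test framework. NGHC-treated samples add
±`effect_size` on planted genes; NHC-treated samples never carry signal.
Planted genes are either **invariant** (one direction at every exposure)
or **variant**, cycling three archetypes: sign-flip at the last exposure,
effect only at early exposures, effect only at late exposures — i.e. the
phenomena that produce "+/−" rows in real modulation tables. Identical
seeds give bit-identical output.

Defaults not pinned by the emulated designs were chosen once as plausible:
`noise_sd` = 0.4 log2 units (typical microarray replicate noise),
`dataset_shift_sd` = 0.2 (batch/platform offsets smaller than real
effects), `missing_probe_fraction` = 0.05, `effect_size` = 0.585
(the 1.5-fold convention), 10 + 10 invariant and 15 variant genes. The
inter-dataset technical variance of the real archives is not characterized
anywhere authoritative, so these are plausible rather than fitted.

What the generator deliberately does **not** model: probe-level physics
(hybridization, normalization artefacts), dose–response across arms,
per-animal covariates, correlated gene modules, and partial penetrance
(every NGHC modulates every planted gene). Passing parameter-recovery
tests therefore shows the pipeline's logic is correct under its own
assumptions, not that real archives would yield these precision/recall
levels — on real data, chemicals respond heterogeneously and AUCs are
well below 1.

## Problem sizes and numerical choices

The parameter-recovery benchmark uses 3 datasets × 3 exposures, 2,000
genes, 10 invariant + 10 variant planted genes, effect 1.0 log2 over noise
0.3, 30 NGHC vs 100 NHC, triplicates — large enough that the planted
contrast is detected with near-certainty per dataset while the null genes'
Δ (sd ≈ 0.04) essentially never crosses the 0.585 fold threshold. The
transient-exclusion rate is measured over 20 seeds. The full
modelling run in the acceptance script uses the same simulation with a
fixed 50-tree random forest across all 9 dataset × exposure combinations;
these sizes keep a complete from-scratch rerun to a couple of minutes on a
single CPU while leaving all conclusions unchanged at larger sizes.

Ties and degenerate cases are fixed deterministically throughout: RF
tree-count ties go to the smaller count, AUC ties contribute ½, Δ = 0
evidences no direction, single-class training folds score 0.5, and
enrichment output is sorted by (corrected p, raw p, term id) so results
are independent of term iteration order.

## Known limitations

* The pipeline consumes already-normalized log2 matrices; raw CEL/Codelink
  ingestion and normalization are out of scope.
* The t-test treats chemicals as exchangeable replicates; chemical-class
  structure (mechanism clusters) is ignored.
* LOOCV-based tree-count selection is optimistically biased (documented
  above).
* How the original multi-archive analyses aggregated direction calls when
  a gene was significant in some datasets and not others is not public;
  the fold-evidence rule is this package's own documented convention, with
  the sign rule available for comparison.
* Stability thresholds (0.05 / 5%) are conventions, not estimated
  quantities.
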