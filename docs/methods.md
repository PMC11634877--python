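# Methods

## Scope and data model

`ovuln` operates on three inputs: a genes x samples expression matrix
(raw counts plus gene lengths, TPM, or log2(TPM+1); all downstream
computation uses log2(TPM+1)), a per-sample genomic feature table (the
three genomic scar counts LOH/TAI/LST, mutational signature 3 and total
mutation counts, an HRR pathogenic-mutation flag, and an optional BRCA1
promoter methylation beta), and somatic variant tables with per-caller
support and tumor/normal variant allele frequencies. Gene identifiers are
HGNC symbols matched case-sensitively. Missing expression values are
rejected rather than imputed: ranks and means downstream are undefined on
missing data, and complete-case input keeps every score well defined.

TPM is computed as `(count_g/length_g) / sum_h(count_h/length_h) * 1e6`
per sample; the TPM layer is validated to sum to 1e6 per column (relative
tolerance 1e-6). Both entry points — counts plus lengths, or TPM supplied
directly — are supported, since quantifiers differ in whether they emit
length-corrected abundances.

## BRCAness ground truth

A sample is labeled BRCAness when at least one of four criteria holds:

| criterion | rule | boundary |
|---|---|---|
| HRR mutation | pathogenic (class V) or likely pathogenic (class IV) mutation in an HRR pathway gene | flag supplied per sample |
| HRD score | LOH + TAI + LST >= 63 | inclusive |
| signature 3 | sig3 mutations / all mutations > 0.25 | strict |
| methylation | BRCA1 promoter beta > 0.7 | strict |

The HRD score is the plain unweighted sum of the three scar counts and is
kept integer; no cross-assay rescaling is applied because a single
ovarian-specific cutoff is used. A sample with zero total mutations has an
undefined signature 3 ratio; undefined or missing assays count as
criterion-not-met. Because the rule is a disjunction, missingness can only
withhold a BRCAness call, which is the conservative direction for a
treatment-selection label. The HRR gene list is a configurable input
(default documented in `ovuln.truth.DEFAULT_HRR_GENES`, including
BRCA1/BRCA2); which genes count as "HRR pathway" varies across panels, so
the package does not hard-code a closed list into the rule itself.
Computing scar counts from segmentation and decomposing mutational
signatures are upstream of this package; their outputs are its inputs.

## Variant filters

The consensus filter keeps a variant when at least two of the four callers
(Mutect2, SomaticSniper, Varscan2, Strelka2) support it, tumor VAF
>= 0.05, and normal VAF < 0.05. "Two of four" is read as at-least-two:
a variant seen by three callers must not be rejected. TMB counts
nonsynonymous SNVs per megabase (indels and synonymous variants excluded).
Neoantigen counting applies the strict thresholds %rank < 2 (weak) and
%rank < 0.5 (strong) irrespective of peptide length and HLA allele; since
strict-< nesting makes every strong binder weak, the reported load is
weak_count per megabase with the strong count reported separately. The
exome denominator defaults to 30 Mb and is overridable — published
pipelines rarely print theirs, so the default is the conventional
whole-exome footprint.

## Signature selection and classifier

Feature selection runs recursive feature elimination independently under
three families — random forest, AdaBoost, gradient boosting — on a
class-balanced subsample (the majority class is randomly undersampled to
the minority size with the run's seed; the simplest balanced design, since
finer resampling schemes add variance without changing what the consensus
measures). Each RFE pass removes the 20% lowest-importance remaining
features per iteration (each family's native impurity-based importances)
until `top_k` (default 50) remain; a gene enters the consensus signature
when at least two of the three families retain it. Selection is fully
deterministic given the seed. Ensemble sizes default to 100 per family;
they are configurable, and the defaults keep a 500-gene x 200-sample
selection under ten seconds on one CPU.

The classifier is a random forest (default 200 trees) on the signature
genes. Performance is estimated by stratified 10-fold cross-validation;
the reported AUC is the per-fold mean +/- SD, and the decision cutoff is
chosen by maximizing the Youden index J = sensitivity + specificity - 1 on
the pooled out-of-fold probabilities (pooling uses every sample exactly
once; averaging per-fold cutoffs would estimate a different quantity from
ten times less data). Candidate thresholds are the observed scores;
classification is strict (`P > cutoff`), and J-ties break toward the
lowest threshold, the more sensitive operating point. Nested
cross-validation is deliberately not used — the ensembles' internal
bootstrapping already decouples fit from ranking — which is a documented
optimism risk for the CV AUC, not for the external validity of
predictions. Shipped operating points for applying a pre-trained model are
`P > 0.5266` (bulk) and `P > 0.45` per cell.

Single-cell classification labels each tumor cell at the cell cutoff and
calls the sample BRCAness when strictly more than half its cells are
positive; an exact half split is noBRCAness ("majority" read strictly —
conservative for treatment selection). Missing signature genes at
prediction time are a hard error; opt-in zero imputation
(`impute_missing="zero"`) warns, because silent imputation shifts
probabilities.

Only 8 of the 24 genes of the published expression signature are public
(CCDC90B, CRABP2, FZD4, GPAA1, PRCP, SNRP1, RAD17, LTA4H); they ship as a
documented partial fixture (`PUBLISHED_SIGNATURE_GENES`), and the package
reproduces the *procedure*, not the original fitted weights.

## Immune scoring

Signatures with at most 10 genes present in the matrix are scored as the
per-sample mean of log2(TPM+1); larger sets use a rank-sum single-sample
enrichment z-score: with G genes in the matrix and m set members,

    z = (mean within-sample rank of members - (G+1)/2)
        / sqrt((G-m)(G+1)/(12m))

This is the exact standardization of a mean of m ranks drawn without
replacement, so it has known null moments and is invariant to any strictly
monotone per-sample transform. It is a deliberate simplification with the
same ordering semantics as kernel-based single-sample enrichment
estimators, not a re-implementation of them. The size dispatch is
evaluated on *present* genes, since the score must be computable from
them. Cytolytic activity is `CYT = 0.5 * (GZMB + PRF1)` on log2(TPM+1).
The tumor-immune phenotype classifier is a multi-class random forest
restricted to a caller-supplied gene list (the published 157-gene
digital-pathology list is an input, not shipped).

## Vulnerability score

On log2(TPM+1) values, `ratio = 0.5*(GZMB+PRF1)/C1QA`; a sample with C1QA
exactly zero has an undefined ratio and propagates as missing with a
warning. The C2C transform is the two-parameter logistic
`1/(1+exp(-(ratio-location)/scale))` with shipped defaults location=0.301,
scale=0.0433 — the only reading of the published transform consistent with
a scalar sigmoid in one variable with those two constants and a midpoint
at 0.301. The score is the interceptless weighted sum
`2.597 * P(BRCAness) + 1.166 * C2C`, bounded by [0, 3.763] for the default
weights.

Refitting conventions (both opt-in; the printed constants remain the
defaults):

* `fit_c2c_params` sets location to the cohort midhinge `(q1+q3)/2` and
  scale to `IQR/(2 ln 3)`, which maps the cohort quartiles to C2C 0.25 and
  0.75 exactly (`expit(±ln 3) = 0.75/0.25`). How the shipped constants
  were originally derived is not published; this quartile-anchored
  convention is the package's own, chosen because it is closed-form,
  robust, and exactly testable. A zero-IQR cohort is rejected as
  degenerate.
* `fit_vulnerability_weights` fits a maximum-likelihood logistic
  regression of binary therapy response on a BRCAness proxy and C2C with
  an intercept, and returns the two slopes (the intercept is discarded,
  matching the interceptless score). The proxy is covariate-agnostic. On
  perfect or quasi-perfect separation the MLE diverges and the fit falls
  back to a ridge-penalized logistic regression with a warning.

The vulnerability map places samples at (x=C2C, y=BRCAness probability)
over a `grid_n x grid_n` lattice of the score for color-coding; the
lattice is monotone along both axes by construction.

## Synthetic data

The generators exist so every stage is testable without controlled-access
cohorts; their defaults are the study conditions of the test suite.

* **Bulk cohorts** (default n=200 samples, 500 genes, 20 informative,
  effect size 2.0 on the log2 scale, noise SD 1.0, class fraction 0.5):
  expression is Gaussian on the log2(TPM+1) scale floored at 0 (count-level
  realism is unnecessary for testing computations defined on log2(TPM+1));
  informative genes are shifted upward in the BRCAness class. Genomic
  profiles are drawn so the truth rule reproduces the drawn classes
  exactly — BRCAness samples receive scar counts summing >= 63 and/or a
  signature 3 ratio in (0.3, 0.6), noBRCAness samples stay below every
  threshold. Marker genes (GZMB, PRF1, C1QA and the 8 published signature
  genes) are always included so scoring runs without remapping.
* **Single-cell sets**: each sample has a noise-free latent profile
  (baseline + class shift); cells are drawn around it with the spec's
  noise SD, so one cell per sample matches the bulk distribution.
* **Variants**: caller flags iid Bernoulli(1/2), tumor VAF ~ U(0, 0.5),
  normal VAF ~ U(0, 0.1), consequence uniform over four tags, class
  uniform over 1–5; the closed-form consensus pass probability
  (11/16)·0.9·0.5 anchors a calibration test.
* **Response cohorts**: covariates uniform on [0,1], response Bernoulli
  with `logit = -2 + 2.597*proxy + 1.166*c2c` by default (the intercept
  keeps the response rate near 50% under the shipped weights).

What the synthetic data does **not** emulate: library-size and batch
effects, count overdispersion, single-cell dropout, gene–gene correlation,
and realistic class overlap in expression. Passing tests therefore
demonstrate the correctness and calibration of the computations, not
clinical performance; the published headline numbers (CV AUC 0.91 ± 0.04
and external-cohort accuracies) depend on controlled-access cohorts and
are out of scope.

## Numerical choices and degenerate inputs

* TPM column sums validated at relative tolerance 1e-6; TSV I/O uses
  round-trip float formatting so write-then-read is bit-exact.
* A sample with all-zero counts cannot be TPM-normalized and is rejected
  by name.
* Youden ties break toward the lowest threshold; a ROC over constant
  scores returns that score (J = 0 everywhere).
* C2C saturates to exactly 0/1 in double precision beyond roughly ±37
  scales from the location; monotonicity holds wherever it is
  representable.
* All estimators and generators are pure functions of their inputs and
  seed; reports serialize with sorted keys and no timestamps so identical
  runs are byte-identical.

## Problem sizes in the test suite

The suite exercises the pipeline at cohort sizes of 40–200 samples,
120–500 genes, 10-fold (or 5-fold for small cohorts) cross-validation, 20
label permutations for the null-AUC calibration, 5 seeds for planted-gene
recovery and 10 seeds for logistic weight recovery — sizes at which every
statistical check is stable while the full suite runs in well under five
minutes on one CPU.

## Known limitations

* The rank-sum enrichment score is not a GSVA/ssGSEA clone; absolute score
  values are not comparable with those tools, only orderings are similar.
* The published model's exact 24-gene signature and forest weights are not
  public; users reproduce the procedure on their own labeled cohorts.
* Whether the methylation criterion should also cover BRCA2 promoters is
  ambiguous in the source literature; the package exposes a single
  per-sample beta and leaves the assay choice to the caller.
* The ridge fallback of the weight fit shrinks slopes toward zero; its
  output is a stabilized estimate, not the MLE, and is flagged by a
  warning.
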