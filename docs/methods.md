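# Methods

This note documents the statistical model behind `vascsig`, the choices made
where the design was genuinely open, and what the synthetic-data tests do and
do not demonstrate about real data.

## Vascular group definition

Patients with an MRI perfusion value are grouped by the median relative
cerebral blood volume of the high-angiogenic tumor habitat (rCBV_HAT):
strictly greater than the threshold (default 7) is high vascularity (HV), at
or below is moderate (MV), and missing MRI data is unknown (-V). The
boundary case (exactly 7) is assigned to MV: HV is defined by *exceeding*
the threshold, and the strict rule resolves the ambiguity conservatively.
`assign_vascular_groups(..., inclusive=True)` exposes the `>=` alternative.
Missing values are an empty cell or `NA` token in the clinical table. When
several count columns map to one patient, the reader keeps the first and
warns — deterministic, in contrast to picking one at random.

## Gene selection

Selection is lexical: a gene is retained when any of 15 vascular-biology
terms (*vascular, vasculature, blood vessel, microvessel, angiogenesis,
hypoxia, necrosis, capillary, glomerulus, glomerular, vasculogenesis,
venous, artery, circulatory, coagulation*) occurs as a case-insensitive
substring of its free-text description. Substring semantics are deliberate —
broader words such as *neovascularization* must match — and the vocabulary
is overridable from a file. No ontology-graph traversal is attempted;
description matching is the portable stand-in for an ontology-term filter,
and the retained count will depend on the annotation source used.

CPM is computed against the **full-library** depth (sum over all genes
before any filtering), so per-sample CPM over the full gene set sums to
1e6 and later gene filtering cannot change the normalization. Genes are
excluded when their median CPM across all samples (unstratified) fails to
*strictly exceed* 0.2. The two plausible boundary readings (exclude `< 0.2`
vs `<= 0.2`) differ only at exact equality; the exclusive-retain rule
(`median > 0.2` retains) is the default and the floor is configurable.

## Differential expression

For one contrast (HV vs -V, or MV vs -V), samples of the third group are
dropped and a 0/1 group indicator is formed. The model for each gene is a
weighted linear regression of `log2CPM` on intercept, group, and (by
default) continuous age; the group coefficient is the log2 fold change,
positive meaning higher expression in the named group than in -V. Age can
be dropped with `include_age=False` (CLI `--no-age-covariate`).

* **log2CPM**: `log2((count + 0.5) / (library + 1) * 1e6)` — the 0.5 prior
  count avoids log of zero; the prior is configurable.
* **Precision weights**: per-gene unweighted fits give residual standard
  deviations; the quarter-root sd is regressed on average log2 count with a
  lowess smoother (span 0.5, 3 robustifying iterations). Each observation's
  weight is the fitted trend at its fitted log2 count, raised to the power
  -4. The fitted quarter-root sd is floored at 1e-3 so constant genes (zero
  residual variance) still receive finite positive weights. Span and prior
  count match the standard published defaults of the method.
* **Empirical-Bayes moderation**: prior degrees of freedom d0 and prior
  variance s0² are estimated by moment-matching a scaled F distribution on
  the log residual variances (digamma/trigamma moment equations, Newton
  inversion of the trigamma). Posterior variance
  `s̃g² = (d0·s0² + dg·sg²)/(d0+dg)`; moderated t = coef / (s̃g ·
  unscaled sd), referred to a t distribution with d0+dg df (normal in the
  d0 → ∞ limit). When the gene-wise variances carry no excess spread beyond
  chi-square sampling noise, the moment estimate of d0 diverges; the
  implementation then sets every posterior to the common mean variance —
  the documented full-shrinkage limit. Gene variances are floored at 1e-12
  to keep the log-moment equations finite.
* **FDR**: Benjamini-Hochberg step-up, two-sided p-values, significance at
  q < 0.01. The signature is the significant set with direction *over*
  (logFC > 0) or *under*.

The whole chain is implemented directly (no calls into an existing
differential-expression package); one test cross-checks it against the
Bioconductor limma-voom implementation on a shared fixture, requiring
log-fold-changes within 0.02, moderated-t correlation above 0.995, and an
identical set of called genes. The small residual discrepancy comes from
the two lowess implementations, which differ in interpolation details.

## Score system

For each signature gene a center (median by default; the mean is available
because informal descriptions of such scores often say "average") is taken
across **all** samples, including the one being scored. A sample gets +1
when its expression is strictly above the center for an *over* gene, or
strictly below for an *under* gene; exact ties earn nothing. Scores are
computed on the same log2CPM matrix the DE stage used. Scoring is monotone
in over-gene expression, invariant to per-gene translations (the center
shifts equally), and invariant to sample/gene ordering.

Stratification: for an HV-derived signature, score > cutoff ⇒ EHV (expected
high vascularity), else EMV; for an MV-derived signature the labels are
reversed, since there a high score means concordance with the *moderate*
pattern.

## Survival analysis

Kaplan-Meier curves use the product-limit estimator with deaths processed
before censorings at tied times; the median is the smallest observed time
with S(t) ≤ 0.5 (undefined if never reached). The two-group log-rank test
accumulates observed-minus-hypergeometric-expected deaths at each distinct
event time, with the usual variance term, against chi-square with 1 df.
Records missing time or event flag are excluded from estimation only —
they remain in the cohort for expression analysis and scoring.

The cutoff search evaluates every integer cutoff whose two groups each hold
at least `min_group_frac` (default 0.1) of the valid records and returns the
one with the smallest log-rank p (ties toward the smaller cutoff). The
minimum-size rule is this package's own guard against degenerate splits.
Because the search selects the best of many correlated tests, its minimum
p-value is optimistic; `null_calibration` permutes survival records against
scores, re-runs the search per permutation, and reports the add-one
permutation fraction of null minima at or below the observed minimum. The
chi-square approximation (not an exact test) is used inside the search, as
is common practice.

Both estimators are written in numpy rather than delegated: the spec of the
estimators is part of the package's contract, and the cutoff search plus
permutation calibration re-run the log-rank test thousands of times, where
per-call overhead dominates. The `lifelines` implementations serve as
independent oracles in the test suite.

## Synthetic cohort generator

The generator emulates the study conditions the analysis was designed for,
with known ground truth:

| parameter | default | meaning |
|---|---|---|
| `n_samples` | 147 | RNA-seq cohort size |
| `n_mri` | 15 | samples with an rCBV_HAT value |
| `frac_hv` | 7/15 | mixture weight of the high-vascularity rCBV component |
| `rcbv_mv_mean`, `rcbv_hv_mean` | 4.17, 8.31 | component means (rCBV units) |
| `rcbv_sd` | 0.8 | component sd, consistent with the observed group ranges |
| `n_genes` | 2000 | transcriptome scale after keyword-level selection |
| `n_signature_genes` | 21 | planted over-expressed genes |
| `signature_logfc_range` | (1.1, 3.6) | planted log2 fold changes |
| `nb_dispersion` | 0.2 | shared negative-binomial dispersion |
| `libsize_log_mean/sd` | log(1.5e7), 0.35 | log-normal library sizes |
| `baseline_hazard` | ln2/350 /day | ~350-day median survival at mean score |
| `log_hazard_per_score_point` | 0.08 | prognostic strength of concordance |
| `censor_rate` | 1/1500 /day | independent exponential censoring |
| `censor_cap_days` | 2000 | administrative follow-up cap |
| `keyword_frac` | 0.08 | background genes given a vascular keyword |

Counts are negative-binomial with a single dispersion shared across genes —
the simplest model exhibiting the mean-variance trend the precision weights
must learn. Baseline abundances are log-normal on the log2-CPM scale;
signature genes are drawn well expressed (as the real signature genes were,
all surviving the CPM filter) and their means are multiplied by 2^logFC in
HV samples only. The true group label is defined by thresholding the drawn
rCBV at 7 — the mixture components shape the rCBV distribution, but truth
and the threshold rule can never disagree. rCBV components are truncated at
zero; exact threshold collisions have probability zero under the continuous
draws.

Survival is exponential with log hazard linear in the sample's *realized*
concordance — its score against the planted all-over signature computed
from the generated log2-CPM matrix — centered at the cohort mean, so the
end-to-end pipeline has a coherent ground truth: samples that genuinely
express the signature die earlier. Event flag 1 = death; censoring is the
minimum of an exponential time and the 2000-day cap.

Each artifact (gene baselines, library sizes, rCBV, counts, ages, survival,
keywords) uses its own child stream spawned from the master seed, so
changing one configuration parameter leaves unrelated draws untouched, and
identical configurations are bit-identical.

What the generator does **not** emulate: gene-gene correlation, per-gene
dispersion variation, batch effects, subtype structure, non-proportional
hazards, or covariate-dependent censoring. Passing tests therefore
demonstrate correctness of the estimators and the pipeline's operating
characteristics under a clean generative model, not performance on real
TCGA data; in particular the planted-recovery sensitivity is an upper bound
on what heterogeneous real cohorts would give.

## Problem sizes used in tests

The simulation-based tests run deliberately small versions of the study
conditions chosen to keep the whole suite fast while leaving the Monte-Carlo
error well inside the asserted margins: recovery and null-FDR checks use
300-gene cohorts at the study's 7-vs-132 group sizes over 20 replicates
each; cutoff recovery uses 100 replicates of 140 patients; the permutation
calibration uses 100–200 permutations.

## Known limitations

* Equal gene weighting in the score; no per-gene prognostic weighting.
* Lexical keyword matching cannot reproduce ontology-release-specific gene
  counts.
* Chi-square log-rank p-values are asymptotic; with very small groups an
  exact or permutation p would be preferable (the calibration utility
  covers the cutoff-search case).
* The moment estimator of d0 assumes a common residual df across genes
  (true here, where all genes share one design).
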