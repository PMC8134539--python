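# Methods

## Overview

`fcstrat` stratifies high-functioning autistic individuals (full IQ >= 70)
into severe and mild subgroups from resting-state functional connectivity
(FC), and predicts symptom severity measured by the Autism Diagnostic
Observation Schedule (ADOS). The pipeline is:

1. **Connectome construction.** Per subject, ROI time series give a Pearson
   correlation matrix; the upper triangle (R(R-1)/2 edges; 4,371 for the
   94-region AAL-2 parcellation) is Fisher z-transformed (arctanh) and
   standardized to z-scores within subject. Nuisance covariates — age, sex,
   full IQ, mean framewise displacement (FD, mm), and site (drop-first
   indicator coding) — are regressed out of every edge by OLS.
2. **Screening.** Each edge's Spearman rank correlation with the three ADOS
   subscales (Communication, Social Interaction, Restricted/Stereotyped
   Behaviors) is computed in the discovery group; edges whose smallest
   two-sided p (t-approximation on df = n-2) is below 0.005 are kept.
3. **CCA.** Canonical correlation analysis between the k screened edges and
   the three subscales yields canonical correlations R1 >= R2 >= R3, Wilks'
   Lambda = prod(1 - R_i^2), and eta^2 = 1 - Lambda.
4. **Selection-aware permutation.** Because screening and CCA are fit on the
   same sample, eta^2 is grossly optimistic. At each of B iterations the
   subscale rows (and the totals that travel with them) are permuted
   jointly, the **top-k** screen (k = observed selection size, preserving
   the feature-to-sample ratio) is re-run, the CCA re-fit, and the
   clustering re-done. Empirical p-values use the add-one rule
   p = (1 + #{null >= obs}) / (1 + B). The shrunken effect size is
   adj-eta^2 = (eta^2 - mean(eta^2_null)) / (1 - mean(eta^2_null)).
5. **Clustering.** Ward agglomerative clustering (Euclidean distance) of the
   n x 3 edge-side canonical variates; the two-cluster cut is the default,
   checked against k = 2..10 by mean silhouette width. The cluster with the
   higher mean ADOS total is labeled *severe*; the pooled two-sample t of
   totals between clusters is referred to the whole-pipeline permutation
   null of the same statistic.
6. **Agreement.** The FC partition is compared with ADOS-total cutoff
   partitions (severe iff total >= cutoff; sweep 9-17) via percentage of
   agreement (PoA), sensitivity (severe called severe) and specificity
   (mild called mild), under either partition as reference.
7. **Biomarkers.** Each subgroup is compared against controls on all edges
   (covariate-controlled pooled t, Benjamini-Hochberg FDR at q = 0.05 over
   the full edge universe). Significant edges are aligned by the sign of
   their defining t (edges weaker in patients are negated) and summed per
   subject; severe-vs-mild and mild-vs-control contrasts on this composite
   test the graded-change hypothesis (a monotone increase control -> mild
   -> severe). Age-band (6-12, (12,18], (18,30]; boundary ages to the
   younger band), sex, and stricter-FD (<= 0.2 mm) re-runs check stability.
8. **Prediction.** The edges most different between the subgroups (BH-FDR
   over the screened set, capped at the 20 smallest p) feed an RBF-kernel
   SVM with fixed default hyperparameters (cost C = 1, kernel width
   gamma = 1/n_features). Ten-fold cross-validation with a seeded shuffle
   (260 subjects -> 234 train / 26 test per fold) pools one prediction per
   subject; Pearson r between predicted and observed totals is tested via
   t = r sqrt(n-2)/sqrt(1-r^2). The model fit on the full discovery group is
   then applied unchanged to the held-out validation group.

## Statistical kernels

All two-sample tests are pooled-variance (Student) t-tests: this is the form
under which Cohen's D obeys D = t sqrt(1/n1 + 1/n2), used throughout to
convert between t and D. Covariate control residualizes both groups jointly
on [intercept + covariates] and reduces the degrees of freedom by the number
of covariate columns (df = n1 + n2 - 2 - q); the one-tailed p is reported in
the direction of the observed effect.

## Inclusion filters

Subjects are excluded for age outside 6-30 years, full IQ < 70, or mean FD
> 0.5 mm. ADOS totals are recomputed as Communication + Social Interaction
(never the RRB subscale); patients require total > 7 (strict: 8 and above
kept). Individual-level rules run first; then autistic subjects at sites
with fewer than 3 surviving autistic subjects are excluded. Surviving
patients with all three subscales form the discovery group; those with a
total but an incomplete subscale record form the validation group, which by
default must come from sites disjoint from the discovery sites
(`validation_site_disjoint`, default on). Controls are kept only from sites
contributing discovery subjects. A filter report counts removals per rule.

## Key parameters (PipelineConfig)

| parameter | default | meaning |
|---|---|---|
| `screening_p_threshold` | 0.005 | min-p screen threshold (observed run) |
| `screening_k` | 100 | top-k size for permutation re-screens |
| `n_permutations` | 10,000 | whole-pipeline permutation count |
| `fdr_q` | 0.05 | BH-FDR level |
| `cutoff_range` | (9, 17) | ADOS-total cutoffs for the agreement sweep |
| `n_folds` | 10 | CV folds |
| `prediction_feature_cap` | 20 | max severity-discriminating edges |
| `fd_threshold` / `age_range` / `iq_min` | 0.5 mm / (6, 30) y / 70 | inclusion bounds |
| `ados_min_exclusive` | 7 | patients need total > this |
| `min_asd_per_site` | 3 | site rule |
| `svm_mode` | classification | integer totals as classes; `regression` available |
| `standardize_mode` | within_subject | or `per_edge` (z-score per edge across subjects) |
| `cca_on_residualized` | true | CCA inputs are covariate-residualized |
| `min_screened_edges` | 3 | floor on the screened set (CCA needs >= 3 columns) |

The screened-edge floor exists because a null dataset can select fewer than
three edges at P < 0.005, which would make the 3-component CCA (and hence a
permutation iteration) undefined; the floor takes the top-3 by min-p.

## Synthetic cohort generator

The generator is the pipeline's acceptance surface: every downstream claim
is tested as recovery of structure the generator planted.

* **Latent clinical trait.** z in R^3; subscale j is a rounded, clipped
  (Communication 0-10, Social Interaction 0-14, RRB 0-8) linear map of
  rho_j z_j + sqrt(1-rho_j^2) eps, so `canonical_strength` rho = (0.8, 0.8,
  0.7) is the implied population canonical correlation when the edges
  measure z well. Patient totals are forced > 7 by redrawing (the
  inclusion rule made generative).
* **Planted subgroups are a latent mixture, not a threshold.** A random
  `severe_frac` (0.3) of patients carries an additive shift along the
  severity direction (z1 + z2)/sqrt(2) — the combination that drives the
  total — of `latent_subgroup_shift` (default 16) within-subgroup SDs, with
  each dimension renormalized to unit variance. The mixture is anchored at
  the mild group: mild patients sit at the control level of the trait, so
  signal edges carry severe > mild ~ control. Thresholding a continuous
  trait was rejected as a labeling rule because it plants no separable
  cluster structure: whatever the labels, the data remain unimodal, and no
  clustering method can be expected to recover them. A further geometric
  constraint informs the strong default: canonical variates are
  variance-normalized, so the between-subgroup gap along any single whitened
  direction cannot exceed 1/sqrt(f(1-f)) (~2.1 at f = 0.3) no matter how
  large the planted shift; Ward's greedy merges need the gap near that cap,
  with small within-subgroup spread, to find the planted split reliably.
  The planted separation is therefore deliberately extreme — severe
  patients average ~8 ADOS points above mild, far beyond real cohorts —
  and passing recovery tests demonstrates correctness of the machinery,
  not sensitivity at clinical effect sizes.
* **Edges.** value = baseline + latent loadings on 60 signal edges
  (loading 0.9, round-robin over dimensions, random sign) + marker shifts
  + site offset (per site x edge, SD 0.2) + covariate loadings (age, IQ,
  sex, FD) + N(0, noise_sd^2), noise_sd = 0.5. Severe-marker edges (25)
  shift severe subjects by `subgroup_separation` (2) noise-SDs and mild
  subjects by 0.4 of that (graded severe > mild > control); mild-marker
  edges (15) realize mild > severe > control with shifts (1.0, 0.5)
  noise-SDs. The three planted sets are disjoint.
* **Covariates** are drawn inside the inclusion bounds (age ~ N(15, 5.5^2)
  clipped to 6-30; IQ clipped at 70; FD clipped at 0.5 mm; male fraction
  0.9 in patients, 0.7 in controls). Site offsets act on edges only, never
  on ADOS — the simplest structure that makes residualization
  consequential.
* **Validation group** subjects have totals and one missing subscale, and
  live on sites of their own.
* **Time-series emission** maps each subject's edge vector to a correlation
  matrix via tanh(v/3) with a nearest-PSD projection, then draws Gaussian
  series; the implied (T -> infinity) edge values are returned alongside so
  estimation error can be isolated. FC-level emission is the default test
  path (no estimation noise).

What the generator does **not** emulate: temporal autocorrelation and
scanner-specific spectra, non-Gaussian motion artifacts, realistic
(clinical-scale) effect sizes, site-by-diagnosis confounding, missing-data
patterns beyond the validation group's single absent subscale, and any ADOS
measurement model beyond a monotone link. Passing tests therefore show the
machinery is correct and calibrated, not that real cohorts of this size
would yield stable subgroups.

## Numerical choices

* Within-subject standardization uses the population SD (divisor n).
* CCA is solved by SVD of the product of orthonormal bases of centered X
  and Y, with pseudo-inverse rank truncation (no ridge); an independent
  eigendecomposition oracle checks it to 1e-8 in the tests.
* Top-k screening breaks min-p ties by edge position (ascending).
* Ward clustering via SciPy linkage is deterministic given input order;
  silhouette of singleton clusters is 0 (scikit-learn convention);
  silhouette ties choose the smaller k.
* Permutation iterations that fail (degenerate permuted data) are resampled,
  capped at 1% of B. If the null saturates at eta^2 = 1 (screened k >= n),
  adj-eta^2 is undefined and reported as NaN with a warning.
* Equal cluster means of the ADOS total (a tie) label the smaller cluster
  severe with a warning; totals constant within both clusters yield no
  contrast.
* The t-approximation for Spearman p-values slightly under-rejects on
  heavily tied integer subscales; the null screening rate runs ~10% below
  the nominal 1-(1-0.005)^3 per edge.

## Problem sizes in tests and analyses

The bundled analyses and the acceptance checks run on a 30-ROI edge space
(435 edges) with the study-sized cohort (260/574/29) and B = 999
permutations; calibration experiments use 200 replicate null cohorts
(n = 120, 528 edges, B = 199). These sizes were chosen so the whole suite
re-runs in minutes while keeping every feature-to-sample ratio and rule of
the full-scale design.

## Known limitations

* Cross-validated r is negatively biased under the null (the training set
  excludes the test subject), about -0.03 at n = 260; the sanity tests
  account for this.
* Feature selection for prediction uses subgroup labels derived from the
  full discovery sample, so the pooled CV correlation is optimistic; this
  reproduces the published design faithfully, and the held-out validation
  group is the honest check.
* Ward's greedy agglomeration can miss the planted split when the
  whitened-space gap is near its geometric cap; k-means with restarts is
  more robust but is not the published procedure, so it is not used.
* The discovery-sample correlation test uses df = n - 2 throughout
  (r = 0.30, n = 260 gives t ~ 5.05); no attempt is made to reproduce any
  alternative effective df.
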