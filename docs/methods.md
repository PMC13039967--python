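# Methods

`metabotyper` implements a two-step framework for characterizing metabolic
heterogeneity in a clinical cohort: unsupervised phenotyping ("metabotyping")
of routine clinical chemistry, followed by untargeted LC-MS metabolomics
analysis of the resulting subgroups. This note documents the models,
parameters, numerical choices and limitations; all empirical statements here
are computed by the test suite or by `scripts/acceptance.py`.

## Step 1 — clinical metabotyping

**Variables.** Ten routinely available variables form the clustering space:
age (years), ALT (U/L), AST (U/L), waist circumference (cm), VLDL (mg/dL,
derived as TG/5), LDL (mg/dL), triglycerides (mg/dL), HOMA2-IR
(dimensionless, consumed as an input), uric acid (mg/dL), and systolic blood
pressure (mm Hg).

**Preparation.** Sparse missingness is imputed with the per-variable cohort
median. A single-pass extreme-value screen excludes any subject with a raw
clustering variable strictly more than 5 sample SDs from the mean (mean/SD
computed once, post-imputation; zero-variance variables are skipped with a
warning). The screen runs on raw, not scaled, variables. Surviving columns
are z-scaled to mean 0 and sample SD 1 (denominator n−1).

**Clustering.** k-means (Lloyd iterations, k-means++ seeding, 25 restarts,
up to 1000 iterations, best restart by within-cluster sum of squares) is
deterministic given a seed. The number of clusters is chosen by majority vote
over a reduced index panel: mean silhouette width (maximize),
Calinski–Harabasz (maximize), Davies–Bouldin (minimize), the gap statistic
(50 uniform reference sets over the data bounding box, first-rise rule), and
the WSS elbow located at the maximum second difference of WSS over k
(anchored at k=1). Ties go to the smallest k and are flagged. This replaces a
larger multi-index panel with the indices that carry most of its signal.

**Stability.** The permutation null destroys row structure while preserving
marginals: each of B=100 randomized datasets permutes every column
independently; k-means is refit at every k in 2..10 and the mean silhouette
recorded. The add-one-smoothed empirical p at k is
(1 + #{permuted ≥ observed}) / (B + 1), so p is never exactly zero. The
comparison is reported across the whole grid, not only at the chosen k.

**Profiling.** Continuous variables are summarized as median (IQR) per
cluster with tie-corrected Kruskal–Wallis omnibus tests (chi-squared
approximation, df = g−1) and pairwise Mann–Whitney U tests (exact enumeration
when both groups have ≤ 8 observations, tie- and continuity-corrected normal
approximation otherwise). Categorical variables are counts (percent) with
chi-squared tests; when any expected count is below 5, 2×2 tables use
Fisher's exact test (hypergeometric) and larger tables a Monte-Carlo
chi-squared p over 10,000 fixed-margin tables (Patefield sampler, fixed
seed). Pairwise p-values are reported unadjusted and flagged as such in the
report metadata.

## Step 2 — metabolomics

**Preprocessing order.** Per mode (HILIC+ / C18−) and instrument source:
replicate summarization → replicate-CV filter → within-source batch
adjustment → cross-source match/merge → across-source standardization →
quantile normalization → log2 transform → Hotelling-T² outlier screen.

* *Replicates.* Triplicate injections are checked by pairwise Pearson
  correlation (median pairwise r must exceed 0.7, else the sample is flagged)
  and collapsed to per-feature medians.
* *CV filter.* Feature CV = SD/mean across technical replicates within each
  sample on the raw intensity scale, median-aggregated across samples;
  features are kept iff CV < 0.75 (strict).
* *Batch adjustment.* Parametric empirical-Bayes location/scale adjustment
  on the log2 scale: features standardized by the batch-size-weighted grand
  mean and pooled residual SD; per-batch location (γ) and scale (δ²)
  estimates shrunk toward moment-matched normal / inverse-gamma priors by the
  standard iterative solver (relative tolerance 1e-4); effects removed and
  the matrix back-transformed. Per-batch scale uses denominator n_i (matching
  the pooled denominator) so identical batches are an exact fixed point.
  Exact batch-mean equalization holds only in the no-shrinkage limit
  (`eb=False`); the EB path equalizes within shrinkage tolerance. The
  ambiguous "standardized across the studies" step is implemented as this
  same adjustment with instrument source as the batch factor, applied after
  merging; this choice is recorded in the run-report notes.
* *Matching.* Cross-source feature pairs must satisfy ppm difference ≤ 5
  (computed against the mean of the two masses, symmetric and
  order-independent) and RT difference ≤ 30 s, both inclusive; one-to-one
  assignment is greedy by ascending ppm, tie-broken by RT difference then
  feature ids. Unmatched features are dropped; consensus m/z is the mean.
* *Normalization.* Classical quantile normalization across samples (rank
  values within each sample, replace by the mean of each order statistic
  across samples; ties receive the mean of their rank-range targets),
  followed by log2 with per-feature half-minimum replacement of zeros.
* *Outlier screen.* PCA by SVD of the column-centered matrix (component sign
  fixed so the largest-magnitude loading is positive); per-sample
  T² = Σ_{h≤5} t_h²/λ_h against the 99% control limit
  5(n−1)/(n−5) · F₀.₉₉(5, n−5). Flagged samples are removed from all
  downstream stages (the union across modes).

**Differential analysis.** Classical one-way ANOVA per feature
(F = MSB/MSW, p from F with (g−1, n−g) df; features with no variance at all
get p = 1), Benjamini–Hochberg step-up FDR per ionization mode, and
Tukey–Kramer post-hoc comparisons (studentized-range distribution, k groups,
n−g error df) restricted to features with q < 0.05. PLS-DA (PLS against a
one-hot class matrix) and PCA score exports support ordination; PLS-DA
X-scores are mutually orthogonal by construction.

**Pathway enrichment.** Features are annotated by accurate-mass matching to
common ESI adducts (positive: M+H primary, M+Na, M+NH4, M+H−H2O; negative:
M−H primary, M+Cl, M−H−H2O; proton 1.007276 Da, Na 22.989218, NH4 18.033823,
Cl 34.969402, H2O 18.010565) within ±5 ppm. Library-confirmed identities are
level 1 on the five-level confidence scale, mass-match-only hits level 5.
Enrichment counts distinct compounds (not features, avoiding double counting
of multiple adducts) reached through primary ions only; the null redraws
feature sets of the same size from the quality-filtered background B=1000
times; empirical p uses add-one smoothing (replacing a fitted-Gamma
smoothing of the same permutation statistic). Pathways are reported when at
least 3 significant compounds overlap. Retention time is carried through but
unused in matching: the packaged toy reference has no RT library.

**Association networks.** Per metabotype, the clinical block (natural log of
ALT, AST, TG, VLDL, LDL, HOMA2-IR; square root of fibrosis stage, which
handles stage 0; remaining variables untransformed; all columns z-scaled —
the log base is irrelevant after scaling) is related to the significant
features of both modes by two-block PLS in canonical mode (3 components by
default; symmetric deflation, each block on its own scores). The association
score is r_ij = Σ_h cor(X_i, z_h)·cor(Y_j, z_h) with z_h the average of the
two block variates, clipped to [−1, 1], with a two-sided Student-t p on n−2
df. Edges require |r| > 0.3 (strict) and p < 0.05 (strict); isolated nodes
are dropped. Communities come from multilevel (Louvain) modularity
maximization on |r| weights (resolution 1, best of 10 seeded restarts);
centrality from power iteration on the |r|-weighted adjacency. Because the
clinical–metabolite graph is bipartite, the iteration runs on A + I (same
dominant eigenvector, aperiodic, hence convergent; tolerance 1e-10) and the
result is scaled so the maximum is 1. On disconnected graphs the mass
concentrates on the dominant component, which is flagged. Metabolite nodes
whose centrality changes by ≥ 0.025 (inclusive; absent nodes count as 0)
between two metabotype networks feed the pairwise pathway enrichment.

**Fibrosis screen.** Spearman correlation of every feature with the
square-root-transformed fibrosis stage (monotone, so ρ itself is unchanged;
the transform matters only for any downstream linear use), average ranks for
ties, two-sided p from the t approximation with n−2 df; features are ranked
by p and the top 20 exported.

## Synthetic data

The generator emulates the study conditions so every stage is testable
without the controlled-access cohort data.

* **Cohort.** Defaults: 514 subjects in three latent metabotypes with
  proportions 254/189/71 of 514, drawn i.i.d. categorical (a fixed-count
  option exists). Right-skewed positive variables are log-normal with
  location = configured median (log-normal median = exp(μ)) and log-SD set
  from the configured IQR (σ = ln(q3/q1)/(2·0.6745)); age and blood
  pressures are normal. Per-cluster locations/IQRs default to the published
  per-metabotype medians. VLDL is emitted as TG/5 before rounding. Histology
  scores (steatosis 0–3, lobular inflammation 0–3, ballooning 0–2, fibrosis
  0–4) and the four-level steatohepatitis category are cluster-conditional
  categorical draws with default probabilities taken from the published
  frequencies. Missingness is 0.34% per continuous cell; optional extreme
  subjects get one clustering variable pushed 6–8 SD from the mean.
  Within-cluster variables are independent by default (no published
  correlations); an optional correlation matrix is accepted.
* **Feature tables.** Two modes (HILIC+, C18−) across two instrument
  sources (one covering two studies, one the third, mirroring the cohort's
  acquisition). Every reference compound is rendered as its primary adduct
  (plus a random subset of secondary adducts) with Gaussian ppm mass noise
  (default SD 2 ppm); background features are unassigned (paper-scale
  defaults 3758/3520; tests use smaller counts). Intensities are log-normal
  on the raw scale: per-feature base abundance (log2 ≈ N(17, 1.5)),
  between-subject noise (log2 SD 0.7), planted per-cluster log2 shifts on
  pathway compounds, planted within-cluster clinical–metabolite association
  slopes, per-study batch location/scale shifts on the log2 scale,
  triplicate injections with multiplicative replicate noise at the
  configured CV (default 0.10), and a 24/514 fraction of samples with
  inflated independent noise (multivariate outliers), drawn once per cohort.
  Default planted effects mirror the cohort findings: tryptophan-pathway
  compounds up 1.0 log2 units in the inflammatory-fibrotic metabotype (with
  an ALT-coupled association block), purine-pathway compounds up in the
  cardiometabolic metabotype.
* **Toy pathway reference.** Six pathways (tryptophan metabolism,
  branched-chain amino acid degradation, butanoate, propanoate, pantothenate
  and CoA biosynthesis, purine metabolism) with 7–10 real monoisotopic
  compound masses each, computed from elemental formulas and cross-checked
  against an independent cheminformatics implementation.
* **What it does not model.** Raw spectra, peak shapes, isotope envelopes,
  chromatographic drift, realistic between-variable covariance beyond the
  configured marginals, missing features, or correlated background
  structure. Passing recovery tests therefore demonstrates that the
  *pipeline machinery* behaves as specified under known ground truth, not
  that the biological findings of any particular cohort would replicate.

## Problem sizes and determinism

Tests and the acceptance script run scaled-down configurations chosen to
exercise every stage comfortably on a single CPU: cohorts of 90–500 subjects,
150–400 background features per mode, B = 19–199 permutations for stability
and enrichment (20,000 where a permutation null is compared against its
exact hypergeometric limit). Every random stage derives its seed from one
root seed by hashing the stage name (SHA-256, reduced below 2³¹); identical
configurations reproduce byte-identical outputs.

## Known limitations and design notes

* Cluster recovery on default-separation synthetic cohorts is bounded by the
  overlap of the early-mild and cardiometabolic component distributions: a
  supervised oracle on the generative labels reaches ~95% accuracy, so ARI
  near 0.75–0.85 is the attainable ceiling and k-means sits close to it.
  The index-panel vote for k is correspondingly tenting between 2 and 3 at
  moderate cohort sizes and stabilizes at 3 for well-separated or larger
  cohorts.
* The EB batch adjustment deliberately leaves a shrinkage-sized residual of
  observed batch-mean differences; exact equalization is available via
  `eb=False`.
* One-feature inputs skip EB shrinkage entirely (priors cannot be estimated
  across a single feature).
* The association-score formula is a declared reconstruction pinned by this
  package's own tests; upstream integration tools do not print theirs.
* Eigenvector centrality on disconnected association graphs concentrates on
  the dominant component; comparisons involving such graphs carry a flag.
* The source analysis reports both 248 and 284 significant positive-mode
  features in different places; the run report notes this discrepancy and
  leaves it unresolved.
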