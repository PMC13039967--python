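# metabotyper

Clinical metabotyping with untargeted-metabolomics integration, for cohort
studies of metabolic liver disease (pediatric MASLD and similar settings)
where routine clinical chemistry and serum LC-MS metabolomics are available
on the same subjects.

The package implements a two-step framework:

1. **Metabotyping.** k-means clustering of ten routine clinical variables —
   age, ALT, AST, waist circumference, VLDL (= TG/5), LDL, triglycerides,
   HOMA2-IR, uric acid, systolic blood pressure — after median imputation, a
   5-SD extreme-value screen and z-scaling. The number of clusters k is
   chosen by majority vote of a clustering-index panel (silhouette,
   Calinski–Harabasz, Davies–Bouldin, gap statistic, WSS elbow), and cluster
   stability is tested against a permutation null: B randomized datasets,
   each permuting every variable independently, refit at every k ∈ 2..10,
   with empirical p = (1 + #{permuted silhouette ≥ observed}) / (B + 1).
   Metabotypes are profiled Table-1-style (median/IQR, Kruskal–Wallis,
   Mann–Whitney, chi-squared/Fisher).

2. **Metabolomics.** Per-mode (HILIC+ / C18−) feature tables go through
   triplicate summarization (Pearson r > 0.7), a CV < 75% filter,
   empirical-Bayes batch adjustment, cross-study matching (≤ 5 ppm, ≤ 30 s),
   quantile normalization, log2 transform and a Hotelling-T² outlier screen
   (99% limit over 5 PCs). Per-feature one-way ANOVA with BH-FDR and Tukey
   HSD finds metabotype-discriminating features; m/z pathway enrichment
   (accurate-mass adduct annotation, permutation null over the
   quality-filtered background, ≥ 3-compound overlap, primary ions enforced)
   interprets them; per-metabotype clinical–metabolite association networks
   (two-block PLS, canonical mode; edges |r| > 0.3, p < 0.05; Louvain
   communities; eigenvector centrality) are compared pairwise by
   Δ centrality ≥ 0.025 to select features for pairwise enrichment; and all
   features are screened against √(fibrosis stage) by Spearman correlation.

A fully seeded synthetic-data module (`metabotyper.simulate`) generates
cohorts with known latent metabotypes, planted pathway effects, batch
structure, triplicates and multivariate outliers, so the entire pipeline is
testable without access to controlled study data. See `docs/methods.md` for
the modelling details.

## Worked example

Run the whole workflow on a synthetic cohort of 500 subjects (300 background
features per mode, stability B = 20):

```bash
metabotyper run-all --seed 0 --n-subjects 500 --features-per-mode 300 \
    --perm-b 20 --out out/
```

Key lines from the emitted stage log (`out/run_report.json`):

```
clinical_qc        subjects_in=500  excluded=4  subjects_out=496
select_k           recommendation=3  votes={silhouette: 3, calinski_harabasz: 2,
                                            davies_bouldin: 4, gap: 4, wss_elbow: 3}
kmeans             k=3  sizes=[67, 242, 187]  mean_silhouette=0.206
permutation_stability  B=20  empirical_p_at_k=0.0476
hotelling[hilic_pos]   flagged=29  limit=15.4
differential[hilic_pos] samples=467 features=336 significant=41
```

The index panel recommends k = 3 and the observed silhouette beats all 20
permuted datasets (p = 1/21 ≈ 0.048). The recovered metabotypes reproduce the
planted clinical pattern — per-cluster ALT medians 258.9 / 81.8 / 72.5 U/L,
i.e. one inflammatory-fibrotic-like group far above two similar groups — and
the ~5% planted multivariate outliers are flagged by the T² screen. Both
planted pathways are recovered by enrichment (`out/enrichment_hilic_pos.csv`):

```
pathway                 hits  detected  ratio  empirical_p     B
purine metabolism          8         8    8/8     0.000999  1000
tryptophan metabolism     10        10  10/10     0.000999  1000
```

with networks, Δ-centrality tables, Tukey results and the fibrosis Spearman
screen written alongside. Individual stages are also available as
subcommands (`simulate`, `cluster`, `preprocess`, `differential`, `enrich`,
`network`, `fibrosis`) and as plain library functions.

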