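# imd — longitudinal immunometabolic tumor profiling

Tumors treated with neoadjuvant chemotherapy (NAC) change on several layers
at once: the fraction of tumor cells in each biopsy falls, the immune
microenvironment warms or cools, tumor-cell metabolic programs shift, and
clones are extinguished or persist. `imd` implements the computational
pipeline that quantifies those layers from bulk expression and paired exome
data and tests how they associate:

1. **Purity deconvolution** — each bulk profile is a convex linear-space
   mixture `B = p·t + (1−p)·s` of a tumor-cell profile `t` and a
   combination `s` of tumor-free reference profiles; a block-coordinate
   constrained least-squares solver (with an exact linear-programming
   tie-break in the noiseless regime) estimates the purity `p` and extracts
   tumor-cell expression.
2. **Immune states** — immune-cell fractions (constrained least squares
   against a cell-type signature matrix) and ssGSEA signature scores are
   jointly clustered (PCA + Gaussian mixture, model size by BIC) into
   cold/warm/hot states ordered by immune activation score; per-patient
   change is negative iff the tumor stays cold or moves colder.
3. **Metabolic phenotypes** — per sample and per pathway, genes are ranked
   by cohort z-score and scored by pre-ranked GSEA with gene-set permutation
   p-values; a sample is up/down iff FDR < 0.1 with a positive/negative
   pathway Z, neutral otherwise; change is positive iff the later state is
   downregulated. Immune × metabolic changes integrate into groups G1–G4.
4. **Clonal dynamics** — somatic calls pass a multi-clause filter (caller
   concordance × VAF, depth, normal support, population frequency); the
   cancer cell fraction `CCF = VAF·(1/p)·[p·CN_t + CN_n(1−p)]` gets an
   exact binomial confidence interval (clonal iff the interval overlaps 1);
   a patient shows clonal extinction iff >90% of baseline mutations
   disappear or <10 remain post-treatment; immune change × evolution is
   tested on a 2×2 table (Yates chi-squared, Fisher exact, odds ratio).
5. **Association statistics** — linear mixed models with per-patient random
   intercepts (longitudinal score ~ purity + subtype + time with a
   likelihood-ratio test for time; immune ~ metabolic + subtype for the
   interaction), two-way ANOVA with interaction, Spearman matrices, and an
   |r| ≥ 0.3 Pearson correlation network pruned to its 2-core.

A first-class synthetic-data module generates cohorts with the full
statistical structure the pipeline assumes — known purities, immune classes,
pathway states, transitions, and clonal architecture — so every stage is
validated against ground truth without downloading anything. See
`docs/methods.md` for the models, defaults and their rationale.

## Worked example

The numbered scripts under `analysis/` run the whole study on a synthetic
cohort (each writes tables under `results/`):

```bash
python analysis/01_simulate_cohort.py         # cohort + truth
python analysis/02_deconvolve_purity.py       # purity + tumor expression
python analysis/03_immune_states.py           # cold/warm/hot + change
python analysis/04_metabolic_phenotypes.py    # pathway states + groups
python analysis/05_clonal_dynamics.py         # CCF, extinction, association
python analysis/06_association_stats.py       # LMEMs, ANOVA, network
```

A run at the default seed prints, among others:

```
bulk cohort: 2000 genes x 120 samples ({'warm': 47, 'hot': 39, 'cold': 34})
purity MAE vs truth: 0.0474 (max 0.1730)
BIC-selected k = 3; state sizes {'warm': 47, 'hot': 39, 'cold': 34}
ARI vs simulated classes: 1.000
state accuracy vs truth per pathway:
  tca_cycle: 0.992
cohort co-evolution: table [[7, 2], [0, 11]], Yates p = 0.0016, Fisher p = 0.00046, OR = 69.0
```

Reading: purity is recovered to ~0.05 mean absolute error on noisy bulk
data; the Bayesian-information-criterion scan selects exactly three immune
states and they match the simulated classes perfectly (adjusted Rand
index 1.0); per-pathway metabolic states are ≥97% correct through the full
deconvolve-then-classify chain; and in the simulated co-evolution design
(7/9 positive-immune-change patients with clonal extinction, 11/11
negative-change patients persisting) the Yates-corrected chi-squared gives
p ≈ 0.002 — the association between immune warming and clonal extinction.

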