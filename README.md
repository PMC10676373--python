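# bloodtrace

Whole-blood gene expression changes accompany solid tumours, but separating
robust disease markers from the noise of count heteroscedasticity, immune
cell-composition shifts and smoking exposure takes a specific analytical
chain. `bloodtrace` implements that chain as a tested, seeded Python
pipeline for transcriptomic biomarker studies that pair a **diagnostic**
case–control cohort (blood drawn at clinical work-up) with **prospective**
cohorts (blood banked years before diagnosis):

1. **Moderated differential expression** — gene-wise weighted linear models
   on log2 reads-per-million with mean–variance precision weights
   (weight = fitted sqrt-sd⁻⁴) and empirical-Bayes variance shrinkage
   toward a scaled-inverse-χ² prior (d₀, s₀²), giving moderated
   *t*-statistics on df + d₀ degrees of freedom; eight stage/histology
   subcomparisons as contrasts on one joint adjusted model.
2. **Expression-dependent candidate filter** — a loess curve of |log₂FC| on
   average expression defines a local cut-off, so lowly expressed genes
   with noise-inflated fold changes are excluded where a flat |log₂FC|
   threshold would keep them.
3. **Survival** — per-stage Cox proportional-hazards models of
   median-dichotomized candidate expression (Newton–Raphson partial
   likelihood, Efron or Breslow ties) with Kaplan–Meier summaries.
4. **Prospective validation** — logistic case–control models with a
   study-level random intercept (Laplace ML), a two-year
   time-to-diagnosis restriction that keeps all controls, and an exact
   binomial test of effect-direction concordance between cohorts.
5. **Time-to-diagnosis trends** — mixed-model residuals smoothed by
   natural cubic splines (df = 2) against years to diagnosis, with a
   formal window-elevation flag.
6. **Cell composition** — reference-based deconvolution by Huber robust
   regression, cross-platform calibration on overlap samples, and
   cell-type/disease association models.
7. **Discrimination** — ROC/AUC (Mann–Whitney rank formulation) for the
   nested ladder of smoking, cell-type and gene models.

A first-class synthetic-data module generates diagnostic and prospective
cohorts, cell mixtures and survival outcomes with planted ground truth, so
every stage is testable end to end without restricted data. See
`docs/methods.md` for models, defaults and limitations.

## Worked example

Discovery on a simulated diagnostic cohort (2,000 genes, 60 cases / 60
controls, 20 planted marker genes at |log₂FC| = 1):

```python
import bloodtrace as bt
from bloodtrace.pipeline import RunConfig, run_discovery

cfg = RunConfig(sim=bt.SimConfig(n_genes=2000, n_samples_per_group=60,
                                 frac_de=0.01), seed=7)
disc = run_discovery(cfg)
print(len(disc["truth"].de_gene_ids))          # 20 planted genes
print(len(disc["candidates"]))                 # 19 candidates selected
hits = set(disc["candidates"].genes) & disc["truth"].de_gene_ids
print(len(hits))                               # 18 of them planted
```

The candidate set recovers 18 of the 20 planted genes with one false
selection — the FDR, fold-change and loess-curve criteria acting together.

Prospective validation of two genes planted to rise within two years of
diagnosis (amplitude 1 log₂ unit) in two simulated studies (251 + 96
samples, times to diagnosis up to 8 years):

```python
from bloodtrace.pipeline import run_validation

sim = bt.SimConfig(n_genes=2000, seed=7)
intensity, counts, ann, truth = bt.simulate_prospective_cohorts(sim)
val = run_validation(cfg, sorted(truth.trend_gene_ids),
                     intensity, counts, ann)
print(val["or_table"].head(3))
print(val["restricted_or_table"].head(3))
```

One planted gene survives the platform-detectability filter. Its
unrestricted odds ratios are weak (1.23–1.44 per standardized log₂ unit,
e.g. all-cases OR = 1.32, 95% CI 1.05–1.65), its time-trend is flagged as
elevated inside the two-year window for late-stage and all cases, and the
window-restricted models sharpen markedly: all-cases OR = 2.74 (95% CI
1.67–4.47), late-stage OR = 6.91 (95% CI 2.59–18.44) — the signature of a
marker that is informative only close to diagnosis.

The same run is available from a shell:

```bash
bloodtrace all --seed 7 --out runs/demo/
```

which writes DE tables, the candidate table, the survival screen, OR
tables, trend flags and a manifest (seed, thresholds, config hash) under
`runs/demo/`.

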