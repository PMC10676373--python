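# Methods

bloodtrace implements a discovery-to-validation workflow for whole-blood
transcriptomic cancer markers: moderated differential expression on RNA-seq
counts, an expression-dependent fold-change filter for candidate selection,
survival and discrimination analyses of the candidates, and their
evaluation in prospective (pre-diagnostic) cohorts. This note records the
models, the numerical choices, and what the synthetic cohorts do and do not
emulate.

## Differential expression

Counts are transformed to log2 reads per million,
`log2((count + 0.5) / (libsize + 1) * 1e6)`, and fit gene-wise by weighted
least squares on one joint additive design: intercept, case indicator,
stage (middle/late vs early) and histology (vs adenocarcinoma) dummies
nested within cases, smoking status (never/ever), scaled age, sex, and a
batch factor for technical variation.

Precision weights follow the count-aware recipe: per-gene linear fits on
log2-RPM, a lowess curve (span 0.5, plain — no robustness iterations) of
sqrt(residual sd) against mean log2 count, linear interpolation with
boundary clamping, and per-observation weights equal to the interpolated
sqrt-sd at the fitted log2 count raised to the power −4.

Gene-wise residual variances s² with df residual degrees of freedom are
shrunk toward a scaled-inverse-chi-square prior (d0, s0²) estimated by
moment matching of log s²: with e = log s² − digamma(df/2) + log(df/2), the
excess spread of e over its chi-square sampling floor determines d0 through
the trigamma equation (Newton iteration, tolerance 1e−8); when the observed
spread is at or below the floor the prior is infinite and every posterior
variance equals s0². For exactly identical s² the sampling-noise correction
does not apply and s0² is returned as that value. Moderated t statistics
use posterior variance (d0·s0² + df·s²)/(d0 + df) on df + d0 degrees of
freedom.

Eight subcomparisons are expressed as contrast vectors on the joint model:
all cases, NSCLC cases and late-stage cases versus the cancer-free
("FalsePos") group; the histology pairs AD/SQ, AD/other-NSCLC,
SQ/other-NSCLC; SCLC versus NSCLC; and early versus late stage. Because
stage and histology are coded nested within cases, group contrasts average
the nested dummies over the observed composition of the cases entering the
comparison (a population-averaged group difference). Contrasts with an
empty group are skipped with a warning. p-values are Benjamini–Hochberg
adjusted within each contrast.

## Candidate selection

A gene is a candidate when, in at least one of the three case–control
comparisons, it satisfies (i) an absolute fold change above `min_fc`
(natural scale; the default 1.0 demands any up- or down-regulation, which
is the criterion as printed — set `min_fc = 2` for a two-fold rule),
(ii) FDR < 0.05, and (iii) |logFC| strictly above a loess curve of |logFC|
on average log2 expression. The curve (tricube local-linear, span 0.75,
fitted values floored at 0, predictions clamped outside the fitted range)
estimates the expression-dependent background |logFC| level that count
heteroscedasticity induces at low expression.

The curve is fit on the pooled significant genes of the three comparisons
when they supply at least 100 (gene, contrast) rows. Below that the
significant set is dominated by true effects at a common size — a curve
through it would sit at the true-effect level and filter the very genes
the pipeline is meant to find — so the pool falls back to all tested rows,
which profiles the null envelope directly. When more than `max_n`
(default 30) genes qualify, the `max_n` with the largest margin above the
curve are kept, ties broken by gene id.

Candidate co-expression is summarized by single-linkage components of the
Pearson-correlation graph at r ≥ 0.8; constant genes are reported as
singletons.

## Survival

Expression is dichotomized at the gene's median (ties to "low"), and one
Cox proportional-hazards model is fit per (gene, stage group) with scaled
age, sex and smoking as covariates, Benjamini–Hochberg adjustment across
the screen. The partial likelihood is maximized by Newton–Raphson with
step halving; ties use the Efron correction by default (Breslow
available); the score-equation residual at convergence is below 1e−8 in
well-posed problems. A coefficient drifting beyond 10 on a vanishing
gradient is reported as monotone-likelihood separation with unbounded
confidence limits. Stage stratification is implemented as separate models
per stage group, matching per-stage hazard-ratio reporting. Kaplan–Meier
summaries come from lifelines (Greenwood variance).

## Prospective validation

For each candidate, a logistic model of case status on expression (by
default standardized within study, since the two platforms differ in
location and scale) adjusted for scaled age, sex and a seven-category
smoking variable, with the study as a Gaussian random intercept fit by
Laplace-approximated maximum likelihood (per-cluster Newton mode finding;
BFGS over fixed effects and log sigma). With a single study, or when the
random-intercept standard deviation collapses below 1e−3, the model falls
back to fixed study indicators and records the path taken. Three
comparisons are run: all cases, NSCLC cases and late-stage cases, each
versus all controls.

The seven smoking categories combine status (never/former/current) with
pack-years bins (≤ 10.0, 10.1–20.0, ≥ 20.1); pack-years are rounded to one
decimal before binning because the bins are decimal-gapped; ever-smokers
with missing pack-years are "unknown".

The two-year restriction keeps cases diagnosed within `window_years` of
sampling (boundary inclusive) and all controls. Direction concordance
between two cohorts' per-gene effect signs is tested by the exact
symmetric binomial tail P(X ≥ k) + P(X ≤ n − k) at null probability ½;
13 of 14 concordant signs gives p = 0.00183, printed as 0.002.

## Time-to-diagnosis trends

Case expression is residualized by a linear mixed model with study random
intercept. REML estimation is a profiled one-dimensional optimization in
the log variance ratio (the per-cluster covariance I + λ11' inverts in
closed form), which is robust at two clusters where general-purpose mixed
solvers tend to collapse to the zero boundary; conditional residuals
subtract the BLUP study effects. Residuals are then smoothed against years
to diagnosis (0 = diagnosis, increasing into the past) by an unpenalized
natural cubic spline of basis dimension 2 (one interior knot at the median
time; dimension 1 degrades to a straight line), with pointwise standard
errors from the hat matrix.

The elevation flag compares the mean fitted value on [0, window] with the
mean on (window, max], and fires when the difference exceeds
`k_se` (default 2) times the pooled pointwise standard error
(root-mean-square over the grid). The comparison is one-sided for
elevation; the sign is reported either way. Trends are fit per stage group
and overall.

## Cell composition

Cell-type fractions are estimated by robust regression of each bulk
profile on a marker-by-cell-type reference: Huber IRLS (c = 1.345, up to
50 iterations, coefficient tolerance 1e−8) with an intercept, negative
coefficients truncated at zero, renormalized to the simplex. On noiseless
mixtures the estimate is exact to 1e−6. Both expression and
methylation-like modalities share this engine.

Cross-platform calibration fits, per cell type, a least-squares line from
modality-B to modality-A estimates on overlap samples (at least 10
required), applies it to B-only samples, clips to [0, 1] and renormalizes
rows; the Spearman rank correlation on the overlap is reported per cell
type. A value-scale line was chosen over a rank-scale one so that an exact
affine distortion is inverted exactly on held-out samples; a negative
correlation produces a warning but a defined map. Case–control association
of each cell type uses logistic regression adjusted for sex, scaled age
and smoking, BH-adjusted across cell types.

## Discrimination

AUC is computed by the Mann–Whitney rank formulation (ties get half
credit), which equals the trapezoidal area under the empirical ROC; curves
come from fitted probabilities of IRLS logistic models. The model ladder
fits, on one sample set: smoking alone; gene alone; smoking + gene;
smoking + neutrophils; smoking + neutrophils + CD4 T; smoking +
neutrophils + CD4 T + NK + gene; and the cell-types-only seventh model,
reported in the table. AUCs are apparent (in-sample) by design; no
cross-validation is applied.

## Synthetic cohorts

The generator is the package's definition of the study conditions:

- **Diagnostic cohort.** Negative-binomial counts with variance
  mu + phi(mu)·mu², dispersion trend phi(mu) = 0.05 + 2/mu, gene means
  log-normal (ln-mean 3.0, ln-sd 1.2), library-size factors log-normal
  (ln-sd 0.25), 60 samples per group by default. Planted DE genes (0.4% of
  genes, |log2FC| = 1, balanced up/down) deviate ±half the logFC in each
  group so that the compositional library inflation from planted genes is
  equal in both groups and cancels in the contrast; RPM analyses on such
  data control the false discovery proportion without a normalization
  step. A 0.3-log2 batch effect on 5% of genes, with sex, age, smoking and
  stage/histology structure resembling a diagnostic lung-cancer series, is
  recorded in the truth object.
- **Prospective cohorts.** Two studies — one Gaussian log2-intensity
  (125 cases/126 controls) and one count-based (38/58) — with case
  times-to-diagnosis uniform on (0, 8] years. Trend genes gain a
  piecewise-linear ramp: 0 at the two-year window edge rising to
  `trend_amplitude` log2 units at diagnosis; controls carry no elevation
  and no time-to-diagnosis. Controls are matched on study and sex with age
  jittered within ±2 years.
- **Cell mixtures.** Dirichlet proportions around a typical blood
  composition (concentration 60); cases get +0.05 added to the neutrophil
  fraction with the remainder rescaled, so the mean case–control
  difference equals the shift exactly. Bulk = reference × proportions +
  Gaussian noise; a paired methylation-like modality in [0, 1] derives
  from the same proportions.
- **Survival.** Exponential event times with log-hazard log 2 for the
  high-expression half of a designated marker gene; independent
  exponential censoring tuned to a 30% censoring fraction.

All randomness flows through `numpy.random.default_rng` (PCG64) seeded
from the config; a fixed seed reproduces every matrix bit for bit.

What the generator does not emulate: read-level sequencing artifacts,
array normalization effects, registry linkage, matched-set sampling,
longitudinal repeat specimens, and correlated co-expression modules beyond
the planted genes. Passing recovery tests therefore demonstrates that the
estimators find what was planted under this noise model, not that the
thresholds transfer to any particular real cohort.

## Problem sizes

Simulation studies in the test suite and acceptance script use 2,000–10,000
genes, 40–120 samples, and 10–200 replicates per study — sizes chosen so
each statistical property is measured with useful precision while a full
run of the suite stays interactive on a laptop-class single core.

## Known limitations

- The union of three per-contrast BH-0.05 candidate lists has a union-level
  false fraction near 0.10–0.12 when only ~20 true positives exist; a
  pooled adjustment across contrasts would lower it but per-contrast
  adjustment is the convention followed here.
- With two studies the random-intercept variance (logistic and linear) is
  weakly identified; the fallback to fixed study indicators is reported in
  the result objects rather than hidden.
- The elevation flag's pooled-SE rule treats grid points as exchangeable
  and ignores their correlation; `k_se` is a calibration knob, defaulting
  to 2, not a formal test level.
- Deconvolution assumes the reference spans the bulk signal; unmodeled
  cell types bias fractions toward the nearest signature.
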