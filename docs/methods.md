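# Methods note

This note documents the statistical model behind `pharmtx`, the assumptions
it makes, the default parameters and why they were chosen, what the synthetic
data generator does and does not emulate, the numerical choices, and the known
limitations. All quantitative statements about behaviour are the ones computed
by `tests/test_acceptance.py` and `scripts/acceptance.py`; nothing here claims
more than those checks verify.

## 1. Data model

The unit of analysis is a probes × samples matrix of bead-array-style
intensities with per-cell detection p-values, a per-sample annotation table
(sex, age, lymphocyte and monocyte fractions, smoking status, BMI, batch
label, optional chip-control QC features), a binary medication intake matrix
(samples × ATC-coded substances), and a probe → gene annotation.

After preprocessing, the expression of probe *g* in sample *i* is modelled as

```
y_gi = alpha_g + beta_g * drug_i + x_i' * gamma_g + e_gi,   e_gi ~ N(0, s_g^2)
```

where `drug_i` is the 0/1 intake of the tested substance and `x_i` collects
the base covariates plus the selected adjustment substances. The parameter of
interest is `beta_g`, the additive effect on log2 expression.

## 2. Preprocessing

| Step | Rule | Default | Rationale |
|---|---|---|---|
| Detection filter | keep probe iff detected at p ≤ `detection_alpha` in ≥ `detection_min_fraction` of samples | 0.05 / 0.05 | standard expression call for bead arrays; inclusive boundary, so a probe detected in exactly 5% of samples is kept |
| Quantile normalization | map each sample's order statistics to the mean order-statistic profile, averaging ties | — | removes sample-level intensity distribution differences before log transform |
| Log transform | log2 of normalized intensities | offset 0 | effects become additive; intensities are positive after normalization |
| Sample QC | squared Mahalanobis distance over QC features; remove above `median + k·IQR` | k = 4 | one-sided fence; robust to the outliers being screened; under multivariate normality the squared distance is approximately chi-square, checked by test |
| Batch adjustment | parametric empirical-Bayes location/scale model (ComBat) | tol 1e-4, ≤ 100 iterations | shrinks per-batch, per-probe location and scale estimates toward cross-probe priors; stable for small batches |
| Batch diagnostic | per-probe one-way ANOVA across batches before/after | report fraction p ≤ 0.05 | adjustment success indicator; after adjustment the fraction falls to (or below) the nominal level |
| Expression outliers | Euclidean distance to the 10%-trimmed mean profile, `median + 4·IQR` fence | trim 0.10 | catches samples with globally aberrant profiles that pass chip QC |

Batches with a single sample are rejected (a location/scale model is not
identifiable there); the pipeline drops singleton batches with a note in the
run manifest.

## 3. Adjustment-substance selection

Base covariates are always included: sex, age, lymphocyte fraction, monocyte
fraction, smoking, log BMI (logged because BMI is right-skewed and its
expression associations are closer to linear on the log scale).

Candidate substances must have prevalence strictly greater than
`min_prevalence` (default 0.05): below that, a binary regressor has too few
users for a stable transcriptome-wide estimate. A candidate becomes an
adjustment substance iff, in a moderated-t scan adjusted for the base
covariates, it has at least one probe with BH q ≤ 0.05 — substances without
any transcriptome signal cannot confound the expression analysis and only
cost degrees of freedom.

Per tested substance, each adjustment drug is screened against the tested
substance with a 2×2 intake odds ratio (Haldane–Anscombe +0.5 correction on
zero cells). Drugs with OR outside [1/8, 8] (default `or_lo`/`or_hi`) are
dropped from that model only: such collinear intake patterns make the design
nearly singular and the estimate of `beta_g` unstable. The tested substance
itself is always removed from the adjustment set first. Variance inflation
factors of the final design are reported and flagged above 5 but never cause
automatic removal — the OR screen is the acting rule, the VIF is a
diagnostic.

## 4. Moderated differential expression

Per-probe OLS is computed jointly for all probes (shared design matrix, one
solve). Residual variances `s_g^2` with `d` degrees of freedom are shrunk
toward a scaled-inverse-chi-square prior `(d0, s0^2)` estimated by moment
matching on `e_g = log s_g^2 − digamma(d/2) + log(d/2)`:

- excess variance of `e_g` over `trigamma(d/2)` identifies `d0` through the
  inverse trigamma function (Newton iteration);
- zero or negative excess variance gives `d0 = ∞` (all variances equal the
  prior point, normal reference distribution).

The moderated t-statistic uses posterior variance
`(d0·s0^2 + d·s_g^2)/(d0 + d)` with `d0 + d` degrees of freedom. P-values are
adjusted per substance with Benjamini–Hochberg (implemented in-house, checked
against `statsmodels` and a brute-force definition). A substance is analysed
only with at least `min_users` (default 20) exposed samples.

Gene-level summaries take the minimum q over a gene's probes; the reported
best probe breaks ties by larger |t|, then lexicographic probe id, so output
is deterministic.

## 5. Hierarchical replication

Given discovery results and an independent cohort, each substance with
discovery-significant probes that exist on the replication platform forms a
*family*. In the replication cohort:

1. the moderated-t model is fitted per substance on the full probe matrix
   (so variance moderation borrows strength from all probes), then restricted
   to the family;
2. BH is applied within each family; the family statistic is its minimum
   q-value;
3. BH across the M family minima at level 0.05 selects S families;
4. probes in selected families are called significant at the adjusted level
   `0.05 · S / M` (default `replication_method="selective"`; the alternative
   `"minq_adjust"` thresholds the within-family q-values at the BH-adjusted
   family level instead);
5. a probe *replicates* iff significant and concordant in direction with
   discovery; a gene replicates iff at least one of its probes does.

This two-stage scheme controls the expected average false discovery
proportion over selected families. Under a global null the probability that
any family produces a falsely replicated probe stays near the nominal 5%
level — checked by Monte Carlo in the acceptance tests.

Sensitivity analyses: nominal replication (p ≤ 0.05, same direction) and an
exact two-sided sign test (binomial, success probability 0.5) on the
direction concordance of family probes.

## 6. Gene-set over-representation

For a hit list H and background B (the analysed genes of the replication
run), each gene set G is intersected with B first, then
`P(X ≥ |H∩G|)` is computed for `X ~ Hypergeometric(|B|, |G∩B|, |H|)`, with
the odds ratio from the +0.5-corrected 2×2 table. BH runs across all sets
within a substance. Sets whose significant hits are an identical gene list
are deduplicated, keeping the set with the largest odds ratio (ties: smaller
p, then lexicographic set name), because identical hit lists carry no
independent evidence.

## 7. The simulator

The generator emulates, with known ground truth:

- log2 baseline expression per probe (expressed fraction 0.8, baseline mean
  7), with unexpressed probes at low intensity and uniform detection
  p-values (expressed probes get Beta(0.5, 20) detection p-values);
- covariate effects on a random 30% of probes;
- planted drug effects: per substance, a chosen number of affected probes
  with explicit effect values cycled over probes (e.g. `[0.45, -0.45]` for
  balanced up/down effects) or draws from a configurable distribution;
- batch structure: per-batch location shifts N(0, 0.3) and inverse-gamma
  distributed scale factors;
- correlated comedication: pairwise joint intake via a Plackett copula
  matching a target log odds ratio, with marginal prevalences preserved;
- a never-user control fraction (default 0.19) with intake probability
  rescaled to `p/(1 − control_fraction)` among the rest, so marginal
  prevalences are preserved — configurations where this rescaled probability
  reaches 1 are rejected as infeasible;
- planted multivariate QC outliers (6–10 marginal SDs on 1–3 features).

Seeding uses `numpy.random.SeedSequence`. The structural seed fixes probe
baselines, expressed flags and planted effects; an optional `sample_seed`
redraws participants, intakes, batches and noise. Two cohorts with the same
structural seed and different sample seeds share their true effects — the
replication setting.

Not emulated: probe-level cross-hybridisation, intensity-dependent
(mean–variance) noise, within-person repeated measures, dose or duration of
intake, population stratification, and platform-specific probe failure
patterns. Effects are purely additive on log2 intensity.

## 8. Numerical choices

- Quantile normalization uses a stable argsort and averages the mean order
  statistics over ties, making it a fixed point on already-normalized data.
- Mahalanobis distances use a Cholesky factorization of the covariance
  (optionally ridge-regularized); distances are affine-invariant to 1e-8,
  which is tested.
- ComBat iterates the standard parametric fixed-point update to tolerance
  1e-4 (max 100 iterations) and matches Bioconductor `sva::ComBat` to 1e-4
  in tests (observed agreement is far tighter). A single batch is a no-op.
- BH is computed by the step-up minimum over the sorted p-value sequence;
  exact agreement with `statsmodels` is tested.
- The inverse trigamma uses Newton's method on 1/x (monotone, quadratic
  convergence), as in the standard limma implementation.
- Tables are written with `%.10g` formatting, which round-trips the reported
  statistics and makes repeated runs byte-identical.

## 9. Limitations

- FDR control is verified for the simulator's generative model; real data
  with correlated probes and heavier-tailed noise may behave worse. Effects
  planted all in one direction for a prevalent substance measurably distort
  quantile normalization (the user group shifts the pooled reference
  distribution), inflating false positives on null probes; the acceptance
  checks use direction-balanced effects, which is what is observed for
  medication signatures, but strongly one-sided real signatures would need a
  normalization scheme robust to that.
- The empirical-Bayes batch model assumes additive location and
  multiplicative scale batch effects only.
- The OR screen is pairwise; sets of three or more jointly collinear drugs
  can pass it while still producing an unstable design (the VIF flag is the
  safety net).
- Family selection treats substances as exchangeable; no weighting by family
  size or discovery strength is applied.
- The sign test and nominal replication are descriptive sensitivity analyses
  and are not error-controlled at the study level.
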