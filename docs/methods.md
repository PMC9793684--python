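# Methods

This note documents the models and procedures the package implements, the
choices made where the design was genuinely open, and what the synthetic
cohorts do and do not establish.

## Connectivity and task potency

Each subject/condition time-series matrix (T x R, T >= 30) is reduced to a
connectivity matrix in four steps.

1. **Shrinkage covariance.**  Ledoit-Wolf shrinkage toward the scaled
   identity guarantees a well-conditioned, positive-definite estimate even
   when T is not much larger than R; the data-driven shrinkage intensity
   is recorded per subject for audit.
2. **Partial correlations.**  p_ij = -Theta_ij / sqrt(Theta_ii Theta_jj)
   with Theta the inverse covariance; the diagonal is forced to 0.
3. **Fisher-Z.**  Elementwise arctanh variance-stabilizes the
   correlations; the diagonal is kept at exactly 0 (arctanh(1) is
   undefined).
4. **Mixture normalization.**  A three-component mixture is fit to the
   matrix's own edge distribution by EM: a central Gaussian for the null
   bulk, a gamma on the excursions above the Gaussian mean and a mirrored
   gamma below it.  Edges are normalized to (v - mu0)/sigma0 using the
   main-Gaussian location and scale.  Every matrix (rest and each task)
   fits its own mixture; whether a shared fit should be used instead is
   not determinable from the method description, and per-matrix fits make
   the normalization self-calibrating.

Task potency is the elementwise difference normalized-task minus
normalized-rest for the same subject.  Edge tables use a frozen
vectorization: upper triangle, i < j, row-major in atlas region order,
labels "i_j".

### Mixture EM details

Initialization: Gaussian at (median, 1.4826 MAD); gammas by method of
moments on the tails beyond +-2 MAD.  M-steps: weighted ML for the
Gaussian, responsibility-weighted ML (Newton on the digamma equation) for
the gamma shapes.  Tail components with weight below 1e-3 are pruned so
EM can terminate cleanly.  Convergence is declared when the log-likelihood
changes by less than 1e-6 (cap 1000 iterations).  Degenerate fits -- a
main Gaussian that fails to stay dominant (weight <= 0.5) or non-finite
parameters -- fall back to robust location/scale (median, 1.4826 MAD) and
are flagged converged=False.  A fit that merely hits the iteration cap
with a healthy dominant Gaussian keeps its EM estimates (flagged), because
the parameter estimates stabilize one to two orders of magnitude earlier
than the strict likelihood tolerance; discarding them for a MAD estimate
would be strictly worse.

## Site harmonization

Parametric empirical-Bayes ComBat, applied per task to the potency edge
table (one harmonization per analyzed feature set, after potency, before
normative modelling).  Age, sex and diagnostic group are protected
covariates: their effects are estimated jointly with site, removed before
the EB step and re-added after, so case-control differences cannot be
absorbed as site effects.  Priors are the original normal
(locations) / inverse-gamma (scales) pair with moment-matched
hyperparameters and the standard iterative posterior solve.  The
implementation reproduces the Bioconductor reference on fixtures to ~1e-5.
Note that EB ComBat is not exactly idempotent: shrunk estimates leave
residuals a second pass would shrink again; re-application changes the
data an order of magnitude less than the first pass (tested), which is the
meaningful convergence property.

## Normative deviation model

Per edge, a Bayesian linear regression of potency on
[1, age_c, age_c^2, sex] (age centered on the training mean; quadratic
term captures mild nonlinearity across the 6-30 y range; a [1, age, sex]
basis is available by configuration).  With a flat prior the posterior
coefficient covariance is sigma^2 (X'X)^-1, giving the predictive variance
sigma^2 (1 + x*'(X'X)^-1 x*) used in the deviation Z-score.  A predictive
variance floor of 1e-6 guards degenerate synthetic edges.  Rank-deficient
design columns (e.g. a single-sex training set) are dropped with a
warning.

Controls are scored strictly out-of-sample through 10-fold
cross-validation within the control group (each subject scored once, by
the model fit on the other folds); clinical subjects are scored by the
model trained on all controls.  The per-subject atypicality score is
100 * #{|Z| > threshold} / E with threshold 2.571 -- the printed two-tailed
1% constant, kept verbatim (the conventional quantile would be 2.576);
it is configurable.  Group comparison uses the pooled-variance Student t
(matching the pooled-SD Cohen's d; Welch by configuration), and p-values
are Benjamini-Hochberg corrected across the five task conditions.

Calibration note: on null data the mean flagged fraction sits slightly
above the analytic 2(1-Phi(2.571)) ~ 1.01% (about 1.06-1.08% at 270
training subjects per fold) because the predictive distribution has
Student-t tails at finite training size.  This is a property of the
procedure, not an implementation artifact.

## Cross-task similarity

The group-level pattern of a task is the per-edge mean |Z| over the
group's subjects (absolute deviation, consistent with the region-level
aggregation; signed means available by configuration).  Task-pair Pearson
correlations form a T x T similarity matrix per group; the group
difference is tested on the T(T-1)/2 unique pairs with the Wilcoxon
signed-rank test, exact for <= 25 pairs.  With five tasks the exact
two-sided floor is 2/2^10 ~ 0.00195.

## Brain-behavior CCA

Run on clinical-group subjects only, per task.  Missing behavior cells are
imputed once, up front, by chained random-forest regression
(missForest-style: median initialization, per-column RF regressions on the
other six scales, up to 10 sweeps or max cell change < 1e-3); observed
cells are never altered.  Imputing before cross-validation follows the
analyzed procedure and is a known, deliberate leakage caveat (7 columns;
the brain side is untouched).

The brain matrix is PCA-reduced to the top 10 components.  By default the
reduction and all standardization are re-fit inside every training fold so
held-out subjects never influence the training transform; a `global_pca`
flag reproduces the simpler one-global-reduction variant.  CCA is solved
by SVD of the whitened cross-covariance; the sign of every fit is fixed so
the SRS weight is non-negative, making weights comparable across folds.
The test distribution holds one value per split: held-out canonical
variates are pooled over the 10 folds and correlated once (pooling is
stable where per-fold correlations at ~n/10 subjects are not).  Weight
stability is the mean correlation of fold-level behavior weight vectors
with the all-data weights (behavior weights, because fold-specific PCA
bases make brain component weights incommensurable across folds).  The
permutation null shuffles behavior rows within scanner site -- preserving
site structure, destroying coupling -- and scores one full tenfold pass
per permutation (1000 permutations by default, not 1000 x 1000).
Significance: mean(test) > 95th percentile(null).  Loadings are structure
correlations (variable vs first canonical variate), and brain weights are
mapped back to edge space through the PCA basis for region-level
reporting (mean |weight| of the edges incident to a region; top 10% of
regions = ceil(0.10 R), ties broken by region index).

## Synthetic cohorts

The generator produces exactly the statistical structure the analysis
consumes and nothing more.  Time-series rows are i.i.d. draws from
N(0, Theta^-1): no hemodynamics, autocorrelation, motion or drift,
because every downstream stage consumes only covariance structure.  The
rest precision is block-structured (stronger within-network partial
correlations, networks of contiguous regions); the base partial-
correlation pattern is rescaled so its spectral radius is at most 0.6,
leaving a wide positive-definiteness margin for subject-level effects.
Task, age, sex, site and group-deviation effects enter as symmetric
perturbations of the *task* precision matrices only (rest stays at
baseline) -- effects applied equally to both states would cancel in
potency, and potency is where the analysis looks.  If a perturbation
would break positive-definiteness it is halved until it does not (logged);
with default scales this is rare.  The clinical deviation lives on one
edge subset shared by all tasks, scaled per subject by (1 + severity),
where severity is a unit-variance latent impairment axis centered 1.5
higher in the clinical group; the seven behavior scales are
loading * severity + noise with impairment-direction signs
(SRS/RBS/SSP/ADHD up, Vineland/IQ down), and cells go missing completely
at random.  Controls receive no structured deviation by default; a weak
shared control pattern can be injected via `td_pattern_amplitude` for
sensitivity analyses.

`simulate_potency_edges` additionally provides an edge-level cohort that
starts downstream of the time-series stage (per-edge intercept/age/sex
structure, unit noise, and a shared-support group deviation with
gamma-distributed per-subject gain).  The deviation amplitude 0.85 used in
the effect-size recovery tests was calibrated once against the
generating-model oracle to produce an empirical Cohen's d of ~0.6 in the
percent-atypical statistic and then frozen.

What passing tests show -- and what they do not: the pipeline recovers the
structures this generator plants (group deviation effects, shared
cross-task support, latent brain-behavior modes) and stays calibrated in
their absence.  They do not show robustness to hemodynamic confounds,
motion artifacts, non-Gaussian noise, scanner drift or site-by-covariate
interactions, none of which the generator emulates.

## Problem sizes and numerical choices

Test and demo scale is R=40 regions / 4 networks / T=300 timepoints and
cohorts of tens of subjects per group; statistical acceptance checks use
edge-level cohorts of 150-300 subjects with 250-5000 edges, 200-split
CCA distributions, and 20-50 seeded replicates per property.  These sizes
were chosen so that every documented property is testable at desk scale
with comfortable statistical margins.  Other numerical details: edge
vectorization order is frozen into every file header; partial-correlation
output is clipped to [-1, 1]; the Wilcoxon test drops zero differences
(warning and p=1 if all differences vanish); percentile computations use
numpy's default linear interpolation.

## Known limitations

- The behavior imputation leaks across CV folds by design (see above).
- The mixture model is identifiability-limited when the true edge
  distribution is exactly Gaussian: a gamma component can absorb a few
  percent of a flank, biasing sigma0 down by up to ~5%.  The normalization
  self-consistency property still holds.
- The normative model is linear-Gaussian; heavy-tailed or heteroscedastic
  edge noise would miscalibrate the deviation rate.
- Site effects are modelled (and removed) as linear location/scale only.
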