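# Methods

## Model

`compoda` tests whether the composition of cell types in a single-cell
experiment changes with a covariate (typically a binary condition). The unit
of analysis is the aggregated count table: N samples × K cell types, with an
N × M covariate matrix X. Because each sample's counts are constrained by
its sequencing budget, the parts carry only relative information; the model
is therefore compositional and every statement is relative to a reference
cell type.

Counts are modelled hierarchically:

    Y_n        ~ DirMult(phi_n, ybar_n)
    log(phi)   = alpha + X beta
    alpha_k    ~ Normal(0, 5)
    beta_mk    = tau_mk * beta~_mk          tau_mk = logistic(t_mk)
    t_mk / 50  ~ Normal(0, 1)
    beta~_mk   = sigma2_m * gamma_mk
    sigma2_m   ~ HalfCauchy(1)
    gamma_mk   ~ Normal(0, 1)

The Dirichlet-Multinomial captures overdispersion relative to a plain
multinomial and the negative correlation between parts. The logit-normal
factor tau is a continuous relaxation of a spike-and-slab indicator: when t
drifts strongly negative, tau ≈ 0 pins the effect to (numerically) zero;
when t is strongly positive the effect follows the slab sigma2 * gamma. The
near-flat prior on t (scale 50) gives inclusion and exclusion equal prior
weight, so selection is driven by the likelihood. Normal scale parameters
are standard deviations throughout; this reading of the intercept prior
Normal(0, 5) is recorded in the run manifest so it can be revisited by
configuration if a variance reading is ever preferred.

One cell type is the reference: its column of beta is zeroed after the
tau * sigma2 * gamma product, making the remaining K−1 effects identifiable.
Effects must be interpreted as changes relative to the reference. The
automatic reference choice picks, among cell types with a nonzero count in
at least 95% of samples, the one whose per-sample relative abundance has the
smallest sample variance (coefficient of variation available via
`dispersion="cv"`); ties break to the lowest column index. The presence
constraint exists because very rare types have unstable proportions; if no
type satisfies it the error message suggests lowering the threshold.

Zero counts are replaced by a 0.5 pseudocount before fitting (the DM
likelihood needs positive support); pseudocounting is applied before
reference selection, and the ordering is recorded in the run manifest.
Continuous covariates enter the same linear term unchanged; no automatic
standardization is applied — explicit preprocessing beats silent rescaling.

## Inference

Inference is Hamiltonian Monte Carlo on the unconstrained vector
[alpha, gamma, log sigma2, t], with the log-Jacobian of the sigma2 log
transform included in the target. Default chains: 20 000 iterations, the
first 5 000 discarded, ten leapfrog steps per transition. Step size is
adapted by Nesterov dual averaging toward 0.75 acceptance during burn-in and
frozen at its running average afterwards. alpha and gamma initialize from
standard normal draws; t starts at 0 (tau = 1/2, an unbiased selection
start) and sigma2 at 1. Gradients are analytic (digamma identities for the
DM likelihood) and are pinned against Richardson-extrapolated central
finite differences at relative tolerance 1e-5.

The kinetic energy uses a diagonal mass matrix in prior-standardized units:
the t block gets inverse mass 50² (the hierarchy itself states
t/50 ~ N(0,1)), all other coordinates 1. This matters: with an identity
mass, dual averaging tunes the step size to the sharp alpha/gamma directions
(around 0.04 on typical data), and t — whose posterior is prior-dominated
whenever an effect is excluded — then mixes an order of magnitude too
slowly. Since the inclusion indicator |beta| ≥ 1e-3 is driven by tau
crossing between its saturated regimes, slow t mixing inflates inclusion
probabilities of null effects. The scale was validated by checking that
short chains (2000/500) reproduce the inclusion probabilities of converged
20 000-iteration chains to ~0.13, where weaker scalings deviate by ~0.35.
`run_hmc` itself stays generic with identity mass by default.

Proposals with non-finite Hamiltonians are rejected and counted; more than
50% divergent proposals over any 500-iteration window aborts with a
diagnostic. A fixed seed gives a bit-identical chain. Acceptance below 0.3
triggers a warning, not a failure.

## Decisions

For each effect, the inclusion probability is the fraction of post-burn-in
draws with |beta| ≥ 1e-3. Credible effects are selected by direct posterior
probability: rank effects by type-I error 1 − P ascending and keep the
longest prefix whose running mean stays ≤ the nominal FDR level. Because the
running mean of sorted values is nondecreasing, this prefix equals the
largest admissible threshold set; the brute-force threshold scan is kept as
a test oracle. Effects tied at the boundary error value enter all-or-none,
and effects with zero inclusion probability are never admissible (the
threshold ranges over (0,1)). The reported estimated FDR is the running mean
over the selected set, hence always ≤ the nominal level.

Effect sizes are conditional on inclusion: the mean of beta over draws with
|beta| ≥ 1e-3 (0 if never included), and the highest-density interval over
those same draws. Restricting the HDI avoids the zero-inflation bias the
spike component would otherwise introduce. The interval is the narrowest
window containing at least ceil(mass · n) of the restricted draws; an empty
restricted set yields [0, 0] and constant draws a degenerate [v, v]. The
"included" event operationalizes the condition tau > 0, which is vacuous for
a strictly positive logistic tau; using the same |beta| ≥ 1e-3 event keeps
one inclusion definition throughout.

## Synthetic data

The generator emulates case-control cell-count tables: each sample is
Multinomial(ybar, softmax(z)) with z ~ MVN(mu_group, 0.05 I_K). The diagonal
covariance 0.05 mimics the between-sample variability of published
intestinal-epithelium counts while assuming no correlation between types
beyond compositional closure. Two mean layouts are built from a base count
mu0 and additive case effects: a single-effect layout (first type mu0,
others share the remainder of ybar equally) and a two-effect layout (all
types at the base count, cases add (e1, e2) to the first two). Ground truth
marks exactly the types with nonzero additive effect. The heterogeneous
variant draws only round(f · n_case) case samples from the case
distribution, keeping the case label on all of them.

The benchmark grid reproduces the published comparison settings:
K ∈ {5, 10, 15}, balanced groups of 1–5 samples, ybar = 1000 K, six effect
pairs (0,500)…(1000,2000), with a configurable replicate count. The grid
cell K = 5 with effects (1000, 2000) is degenerate — the unaffected types'
mean count is exactly zero — and is flagged as failed at generation and
excluded from aggregates. Per-dataset seeds derive from (master seed,
combination index, replicate index) through `numpy` SeedSequence, so the
assignment is independent of execution order.

What the generator does not emulate: real annotation noise, between-type
covariance, varying per-sample totals, batch structure, or cluster-level
uncertainty from upstream processing. Passing benchmarks therefore
demonstrate correctness of the method under its own generative assumptions,
not robustness to misannotation or batch effects.

## Benchmarks and power analysis

Decisions against ground truth are summarized by MCC (0 when a
confusion-matrix marginal vanishes), TPR (0 without positives) and realized
FDR (0 when nothing is called). Datasets with one sample per group are kept
for decision metrics but excluded from pooled ROC/PR curves, where each
(dataset, cell type) pair contributes one scored instance — inclusion
probability for the Bayesian model, 1 − p for the comparator. The comparator
is the additive log-ratio t-test: Welch tests on log(count_k / count_ref)
after pseudocounting, Benjamini–Hochberg corrected; with fewer than two
samples in a group it reports no discoveries.

The power model regresses per-grid-cell mean TPR on a quasibinomial GLM with
log link and exactly five terms: intercept, log total sample size x_ss,
log2 fold change x_fc, and the interactions x_fc·x_cc and x_ss·x_cc with
the log absolute count change x_cc. Inverting the linear predictor at
y = log(target power) gives the required log sample size in closed form;
the target power enters through the link because the fitted model predicts
on the link scale. Dispersion is estimated by Pearson chi-squared, which
affects standard errors only, not the coefficients used in the inversion.

## Scale of the shipped checks

The acceptance script and the end-to-end tests run the comparison grid with
2 replicates per cell and 2000-iteration chains (500 burn-in), and a
20-seed power batch — about 380 chains, chosen so a full desk-scale
reproduction completes in minutes on one core while leaving the Monte-Carlo
error of the aggregate metrics in the few-percent range. Production
analyses should keep the 20 000 / 5 000 defaults.

## Known limitations

- Single-chain inference by default; R-hat style diagnostics require
  running `fit` with several seeds manually.
- The reference choice can matter. Types with genuinely changing abundance
  make poor references; the automatic rule only screens for low dispersion.
- The FDR calibration is the posterior-probability approximation; it is
  accurate insofar as inclusion probabilities are well calibrated, which
  degrades for very short chains.
- The power inversion extrapolates a GLM fitted on simulated TPR values;
  outside the fitted covariate ranges it is an extrapolation like any other.
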