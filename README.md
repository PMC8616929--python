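# compoda

Bayesian compositional differential-abundance analysis for cell-type counts.

Single-cell experiments yield, per sample, a vector of cell-type counts that
is constrained by the number of cells captured: if one population expands,
every other proportion must shrink. Naive per-type tests on such
compositional data inflate false discoveries, and typical studies have very
few biological replicates. `compoda` addresses both problems with a
hierarchical Bayesian model for the K-part composition of N samples against
M covariates:

    Y ~ DirMult(phi, ybar),   log(phi) = alpha + X beta,
    beta_mk = tau_mk * sigma2_m * gamma_mk,   tau_mk = logistic(t_mk),
    alpha_k ~ N(0, 5),  t_mk/50 ~ N(0, 1),  sigma2_m ~ HalfCauchy(1),
    gamma_mk ~ N(0, 1)

The Dirichlet-Multinomial likelihood models all cell types jointly (capturing
overdispersion and the negative correlation induced by the fixed total), and
the logit-normal factor `tau` acts as a continuous spike-and-slab: each
(covariate, cell type) effect gets a posterior *inclusion probability*
P(beta_mk) = (1/H) Σ_h 1(|beta_mk,h| ≥ 1e-3) over H Hamiltonian Monte Carlo
draws. One cell type serves as the reference (beta pinned to 0), chosen
explicitly or automatically as the least-dispersed sufficiently-present
type; all effects are relative to it. Credible effects are selected by a
direct posterior-probability FDR rule: rank effects by 1 − P and keep the
longest prefix whose running mean stays below the nominal FDR level.

The package also ships the machinery to validate the method end to end: a
synthetic generator (Multinomial counts with softmax-of-MVN compositions and
known ground truth, including heterogeneous-response groups), an additive
log-ratio t-test comparator, benchmark metrics (MCC, TPR, FDR, pooled
ROC/PR), and a quasibinomial power model with closed-form sample-size
inversion. See `docs/methods.md` for the full model account.

## Worked example

Simulate a 5-type dataset with five samples per group (5000 cells each) in
which the first cell type doubles from 1000 to 2000 expected cells in the
case group, then fit it:

```python
import numpy as np
from compoda import (SimulationConfig, generate_dataset, apply_zero_pseudocount,
                     ModelConfig, HMCConfig, fit, summarize_effects)

cfg = SimulationConfig(n_cell_types=5, n_control=5, n_case=5, total=5000,
                       base_count=1000.0, effect=1000.0, seed=12)
ds, truth = generate_dataset(cfg)          # truth == [True, False, False, False, False]
ds = apply_zero_pseudocount(ds)
chain = fit(ds,
            ModelConfig(n_cell_types=5, n_covariates=1, reference_index=4),
            HMCConfig(num_iterations=2000, burn_in=500, seed=12))
summary = summarize_effects(chain, ds, fdr_level=0.05)
print(summary.table[["cell_type", "inclusion_probability", "credible",
                     "effect", "hdi_low", "hdi_high"]].round(3).to_string(index=False))
```

```
  cell_type  inclusion_probability  credible  effect  hdi_low  hdi_high
cell_type_0                  1.000      True   1.037    0.734     1.312
cell_type_1                  0.233     False   0.164   -0.135     0.506
cell_type_2                  0.223     False  -0.064   -0.333     0.217
cell_type_3                  0.258     False  -0.087   -0.426     0.193
cell_type_4                  0.000     False   0.000    0.000     0.000
```

Only the truly affected type is credible. Its effect 1.04 is the change in
log concentration relative to the reference (`cell_type_4`): the simulated
shift is log(2000/750) − log(1000/1000) ≈ 0.98, and the 95% conditional HDI
[0.73, 1.31] covers it. The unaffected types keep inclusion probabilities
near the no-signal level, and the reference row is pinned to zero by
construction.

The same analysis runs from the shell on TSV tables:

```sh
compoda run --counts counts.tsv --meta meta.tsv --covariate condition \
    --case case --reference auto --fdr 0.05 --seed 12 --out results/
```

writing `effects.tsv` (the table above) and `manifest.json` (settings, seed,
selection threshold, estimated FDR, acceptance rate). `compoda simulate`,
`compoda benchmark` and `compoda power` expose the generator, the benchmark
harness and the power model; all flags mirror a YAML config file, with flags
taking precedence.

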