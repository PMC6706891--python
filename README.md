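# beem — biomass estimation and gLV inference from microbiome time series

16S/metagenomic sequencing of a microbial community yields *relative*
abundances: per-sample proportions that sum to one. Community dynamics,
however, play out in *absolute* densities — a species can grow while its
proportion shrinks. Fitting dynamical models to proportions alone therefore
misleads, and experimental total-biomass measurements (16S qPCR, flow
cytometry) are often missing or too noisy to help.

`beem` jointly infers the per-sample total biomass and the parameters of a
generalized Lotka–Volterra model (gLVM) directly from longitudinal
relative-abundance data, using an expectation–maximization algorithm. It is
aimed at microbiome researchers with dense time series (ideally several
replicates recovering from perturbations) who want growth rates, a directed
interaction network, and a biomass trajectory without extra experiments.

## The model and algorithm

The gLVM couples absolute densities `x_i(t)` of `p` species:

    dx_i/dt = mu_i x_i + sum_j beta_ij x_i x_j

with intrinsic growth rates `mu_i` and interactions `beta_ij`
(`beta_ii < 0`: self-limitation). Writing `x_i = m(t) * x~_i` with biomass
`m(t)` and proportions `x~_i`, the additive log-ratio (ALR) transform
against a reference species `r`, `y_i = ln(x~_i / x~_r)`, removes the
shared biomass term from the log-derivatives:

    dy_i/dt = a_i + m(t) * sum_j b_ij x~_j ,   a_i = mu_i - mu_r ,
                                               b_ij = beta_ij - beta_rj .

Spline-smoothed gradients `Y_it` of the ALR series make this a regression
problem that is *conditionally linear* in each block of unknowns, so the
algorithm alternates:

* **E-step** — per sample, the biomass is the no-intercept slope of
  `U_ti = Y_it − a_i` on `V_ti = sum_j b_ij x~_jt` across species, after
  boxplot-outlier and sign-concordance filtering;
* **M-step** — per species, sparse gradient matching (lasso path +
  extended-BIC selection, OLS refit) of `Y_i` on the scaled abundances
  `m_t x~_jt`.

Biomass is initialized from cumulative-sum-scaling (CSS) factors; estimates
are medians over post-burn-in iterations whose E-step MSE is within 5% of
the minimum. `beta` is recovered from `b` by the sparse median-column rule,
growth rates by solving the gLVM point-wise, and each interaction gets a
confidence score `s_ij = |beta_ij / sigma_j|`. Biomass (and `beta`) are
identified only up to a global constant; one absolutely quantified sample
fixes the scale.

The package also ships the full synthetic benchmark: a stable sparse gLV
community sampler, post-perturbation replicate simulation, Poisson
sequencing noise at fixed depth, log-normal qPCR/flow-cytometry biomass
noise (CV 51% / 5%), and the evaluation metrics (median relative error and
interaction AUC-ROC).

## Worked example

`examples/simulate_and_fit.py` simulates a 10-species community (20
replicates recovering from random perturbations, 30 time points, Poisson
sequencing at depth 5×10⁴) and runs the EM on counts alone:

```
simulated 10 species x 20 replicates x 30 time points
EM: 100 iterations, converged = False
biomass median relative error: 2.9%   (how closely the inferred total-abundance profile tracks the truth)
growth-rate MRE: 52.2%
interaction MRE: 39.1%   (median error over the nonzero true parameters)
```

The biomass trajectory is recovered to within a few percent with *no*
biomass measurements; parameter errors are larger (they always are at this
data size — compare the noise-free-biomass ceiling in
`examples/benchmark_conditions.py`). The other examples print the
scaling-condition comparison table and a ranked interaction edge list.

## Command line

```bash
beem simulate --species 10 --replicates 20 --timepoints 30 --outdir sim/
beem fit --counts sim/counts.tsv --meta sim/metadata.tsv --outdir fit/
beem eval --params fit/params_glv.tsv --truth sim/truth.tsv
beem benchmark --replicates 15 --sims 5 --out bench.tsv
```

`fit` writes `biomass.tsv`, `params_glv.tsv` (mu and beta), `params_ab.tsv`
(ALR-transformed parameters), `network.tsv` (confident edges), `trace.tsv`
(per-iteration MSE), `run.log` and a `config.json` echoing every tunable.
Counts are tab-delimited with species on rows and samples on columns;
metadata maps each sample to a replicate and a numeric time.

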