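# Methods

## Model

The community follows a generalized Lotka–Volterra model (gLVM) in absolute
densities `x_i(t)`, `i = 1..p`:

    dx_i/dt = x_i (mu_i + sum_j beta_ij x_j)

`mu_i > 0` is the intrinsic growth rate (per unit time); `beta_ij` (per unit
time per unit density) is the effect of species `j` on `i`; `beta_ii < 0`
encodes self-limitation and is required for bounded trajectories. The model
has no external forcing: data are assumed to come from communities relaxing
toward an attractor after perturbations.

Sequencing observes proportions `x~_i(t) = x_i / m(t)` with total biomass
`m(t) = sum_i x_i(t)`. In log-derivatives,

    d ln x_i/dt = d ln m/dt + d ln x~_i/dt = mu_i + m(t) sum_j beta_ij x~_j ,

the unknown `d ln m/dt` is shared by all species, so subtracting the
equation of a reference species `r` (lowest pooled coefficient of variation
of relative abundance, by default; ties broken by species order) removes it:

    dy_i/dt = a_i + m(t) sum_j b_ij x~_j ,  y_i = ln(x~_i/x~_r),
    a_i = mu_i - mu_r ,  b_ij = beta_ij - beta_rj .

With spline-estimated gradients `Y_it` and Gaussian residuals this is a
likelihood in `(a, b, m)` that is linear in `m` given `(a, b)` and vice
versa — the basis of the EM alternation.

### Identifiability

Only the products `m_t * b_ij` are identified: rescaling all biomass by a
constant `c` and all `b` by `1/c` leaves the likelihood unchanged (the same
degeneracy appears in the ODE itself: `(mu, beta/c)` from `c x0` traces `c`
times the `(mu, beta)` trajectory). The implementation therefore (i)
normalizes every stored iteration to the gauge `median(m) = 1` before
aggregation — element-wise medians across iterations are meaningless if the
gauge drifts — and (ii) reports biomass with median 1. Growth rates and the
confidence ranking are gauge-invariant; reported `beta` carries the gauge,
and comparisons against known truth rescale it by the truth's median
biomass (the same convention used to compare estimated biomass to
measurements). In practice one absolutely quantified sample fixes the scale.

## Preprocessing

* **Closure and zeros.** Counts are divided by their column sums. Zeros are
  preserved until log-transform time, then replaced by half the smallest
  positive relative abundance in the dataset and the column renormalized — a
  standard pseudo-fraction that preserves ordering. Configurable.
* **Gradients.** Per species per replicate (replicates have independent
  initial states, so a shared spline would be meaningless), `dy/dt` is the
  analytic derivative of an order-5 smoothing spline whose penalty is
  chosen by 5-fold cross-validation over a log-spaced grid (series shorter
  than 9 points fall back to a cubic GCV spline; shorter than 6, to finite
  differences with a warning). A quintic spline follows the sharp
  post-perturbation transient that dominates the information content of
  these series; an over-smoothed fit biases exactly the gradients that
  identify the parameters, and that bias propagates into a systematic
  displacement of the EM's fixed point.
* **Abundance outliers.** Points are flagged by robust z-scores of absolute
  spline residuals, `(e - median e)/MAD e > tau` (`tau = 5`, MAD with
  normal consistency as in R), using *sequential deletion* against the
  cross-validated spline: fit, flag the single worst point above `tau`,
  refit, repeat (capped at 20% of the series). Scoring against a rigid
  "heavily over-smoothed" trend instead would mistake the fast transient
  itself for outliers — on clean data it flags the most informative points
  and measurably destroys interaction recovery — while the flexible fit
  flags only points the surrounding data cannot explain. A constant
  residual series (MAD = 0) flags nothing.
* **Gradient outliers.** Estimated-gradient series are de-trended with a
  robust LOESS smoother (statsmodels `lowess`, bisquare iterations, span
  0.75; locally linear — the installed LOESS does not expose degree 2) and
  the same robust-z rule is applied to residuals *studentized by a local
  scale estimate* (robust LOESS of |residuals|, floored at 0.3× their
  median): gradient series are strongly heteroscedastic — transient
  variability dwarfs plateau variability — and a global MAD would flag the
  transient wholesale. A flag additionally requires the residual to exceed
  30% of the series' own robust scale, so smoother boundary misfit on
  noiseless series does not register.
* **Equilibrium filter.** A time point is dropped when more than 80% of the
  detected species changed by less than 5% in relative abundance since the
  previous point (forward differences; first point always kept; a species
  appearing from zero counts as changed). Near-static samples carry no
  gradient signal, only noise. The exclusion applies to the
  *gradient-matching* regressions; the per-sample biomass regression keeps
  all samples, because its signal is the spread across species at fixed
  time, not time differences — excluding equilibrium samples there would
  leave most of the series with no biomass estimate at all in
  plateau-dominated datasets.
* **CSS initialization.** Per sample, the factor is the sum of counts at or
  below the median of its positive-count distribution, normalized to median
  1; a sample with a single positive species falls back to its total count
  with a warning. Used only as `m^(0)`.

## EM engine

* **E-step.** Per sample: `U_i = Y_it - a_i`, `V_i = sum_j b_ij x~_jt` over
  `i != r`; pairs deviating from the median by more than 1.5× IQR in either
  coordinate, or with discordant signs (which would force negative
  biomass), are removed; the slope of the no-intercept regression is
  `m_t`. Samples with fewer than 3 surviving pairs inherit the previous
  estimate with a warning. Reliable estimation needs more than 6 species
  (warned otherwise). The E-step regression has no intercept because the
  model `U = m V` has none.
* **M-step.** Per species, `Y_i` is regressed on an intercept plus the `p`
  scaled abundances. Sparsity: a lasso coordinate-descent path generates
  candidate supports, extended BIC (`gamma = 0.5`) selects one, and OLS on
  the selected support gives de-biased coefficients (relaxed lasso). The
  estimator is fully deterministic, which makes entire EM runs
  bit-reproducible. The RSS in the criterion is floored relative to the
  response scale so exactly-fitting models are compared by parsimony rather
  than by `log(0)`. A non-sparse mode (plain OLS) is available.
* **Inter-iteration biomass repair.** Outliers in the estimated biomass
  series (per replicate, log scale) are flagged by the same sequential
  spline rule and replaced with spline-interpolated values.
* **Termination.** The E-step MSE (mean squared residual over fitted pairs),
  smoothed by a moving median of window 3, must change by less than 0.1%
  (relative) for 3 consecutive iterations; otherwise the loop stops at
  `max_iter` (default 100, minimum 5) with a warning. A warning is also
  emitted when the biomass-normalized MSE — mean squared E-step residual
  divided by the squared median biomass — exceeds 1e-5 (poor fit).
* **Aggregation.** Final `(a, b, m)` are element-wise medians over the
  iterations after burn-in (30; shrunk to half the trace for shorter runs)
  whose MSE is within 5% of the post-burn-in minimum.

## Recovering gLVM parameters

Because `beta` is sparse, most entries of each column are zero, so the
median of column `j` of `b` estimates `-beta_rj`; adding it back recovers
all rows (`beta_ij = b_ij + beta_rj`). Confidence scores are
`s_ij = |beta_ij / sigma_j|` with `sigma_j` the standard deviation of
column `j`'s off-diagonal entries (self-interactions are systematically
large and would inflate it). Growth rates are not sparse; they are
recovered by solving the gLVM point-wise,
`mu_i(t) = d ln x_i/dt - sum_j beta_ij m_t x~_jt` with
`d ln x_i/dt = d ln m/dt + d ln x~_i/dt` from splines, taking the median of
strictly positive per-time estimates (species with none are reported
missing with a warning). Network export keeps directed edges `j -> i` with
`s_ij` above a threshold (default 1), and a consensus helper keeps edges
passing in a majority of repeated runs.

## Synthetic benchmark

The simulator emulates the statistical structure of a
post-perturbation 16S time-series experiment:

* **Parameter prior** (the fitted real-data parameters behind the original
  benchmark are not published, so a documented stand-in is used):
  `mu_i ~ U(0.1, 1)` per unit time; `beta_ii ~ -U(1, 5)` so single-species
  equilibria are O(0.02–1) density units; off-diagonal `beta_ij` nonzero
  with probability 0.2, magnitudes `Normal(0, 0.25 |mean beta_ii|)`, both
  signs. Draws are rejection-sampled until the community has an
  all-positive, locally stable coexistence equilibrium and bounded
  trajectories (error after 100 rejections).
* **Replicates** start from the equilibrium multiplied element-wise by
  `U(0.1, 1)` factors — recovery after a random perturbation toward a known
  attractor — and are integrated with an adaptive Dormand–Prince solver
  (rtol 1e-8, atol 1e-10; densities clipped at zero after output, since the
  exact dynamics preserve non-negativity). Default grid: 30 unit-spaced
  time points; irregular grids are supported.
* **Counts**: per sample, densities are rescaled to sum to the expected
  depth (5×10⁴) and each species' count is Poisson with that mean.
* **Biomass measurements**: independent log-normal draws with mean equal to
  the true biomass and a requested CV via
  `sigma_log = sqrt(ln(1+cv^2))`, `mu_log = ln m − sigma_log²/2`;
  CV 0.51 emulates 16S qPCR (optionally averaging 3 technical replicates),
  CV 0.05 flow cytometry.

**Benchmark conditions** share one estimator — gradient matching in
absolute-abundance space (`d ln x_i/dt` on `[1, x_1..x_p]`) with the same
sparse selector — so differences isolate the scaling factors: exact
biomass, none (RA), noisy qPCR (1 or 3 technical replicates), flow, CSS,
or the full EM. The fixed-scaling baseline applies neither the
equilibrium exclusion nor the outlier layers (those are the EM method's own
refinements); both are available as flags. Metrics: median relative error
over nonzero true parameters, and AUC-ROC (Mann–Whitney with averaged tie
ranks) for classifying nonzero off-diagonal interactions by confidence
score. Desk-scale designs (5 simulations of 15 replicates for the
condition comparison; 3 of 20 replicates for the biomass check) keep the
full benchmark and test suite in the minutes range; medians across
simulations are reported.

### What the synthetic data do and do not show

The generator reproduces compositional observation, Poisson sampling noise
and measurement-noise magnitudes, but not: taxonomic copy-number bias,
overdispersion beyond Poisson, external perturbations or environmental
drift, sequencing batch effects, or model misspecification (real dynamics
are not exactly gLV). Passing benchmarks therefore demonstrates correctness
and the *relative* value of scaling strategies, not field performance.

Two regime effects are worth knowing. First, the prior puts total biomass
near ~1.5 simulator units, so the "no scaling" condition (m = 1) is
accidentally almost correctly *scaled* and its measured degradation
(~45% parameter MRE here) reflects only biomass shape variation; with
real-world units (e.g. 16S copies, ≫10⁹) the same condition is off by
orders of magnitude and degrades much further. Second, datasets whose
dynamics relax within a few sampling intervals leave few usable transient
points; parameter recovery (and, mildly, interaction ranking) suffers
there even with exact biomass — the equilibrium filter exists precisely to
keep such samples from polluting the regressions.

## Defaults

| parameter | default | meaning |
|---|---|---|
| `tau` | 5 | robust-z outlier threshold (all MAD rules) |
| LOESS span | 0.75 | de-trending window for gradient outliers |
| eq. fraction / change | 0.8 / 0.05 | equilibrium-filter thresholds |
| `tol` | 0.1% | relative smoothed-MSE convergence tolerance |
| `max_iter` | 100 | EM iteration cap |
| burn-in | 30 | iterations excluded from aggregation |
| MSE band | 5% | qualifying-iteration band above minimum |
| EBIC `gamma` | 0.5 | sparsity weight of the model selector |
| depth | 5×10⁴ | expected reads per sample |
| edge threshold | 1.0 | minimum confidence score for export |

## Known limitations

* No external perturbation terms in the gLVM (post-perturbation relaxation
  only) and no cross-sectional equilibrium mode.
* The EM is a local optimizer: on datasets dominated by equilibrium
  samples it can wander along weakly identified directions; the reported
  medians over qualifying iterations damp but do not remove this.
* Growth-rate estimates inherit errors from `beta` and `m`; at desk-scale
  data sizes their error is typically several times the noise-free-biomass
  ceiling.
* BIOM parsing, TMM normalization and external reference baselines are out
  of scope; the TSV dialect documented in the README is the only format.
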