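# Methods

## Problem setting

Time-stamped snapshot (TSS) experiments (CyTOF, single-cell RNA-seq) measure
protein abundances in thousands of individual cells, but destroy the cells
they measure: the population observed at time *t* is disjoint from the
population observed at time 0. When abundances are large, single-cell
signalling kinetics are well approximated by deterministic mass-action ODEs,
with cell-to-cell variability entering through random initial conditions
(extrinsic noise). Given several candidate ODE models — here three nested
variants of a minimal NK-cell signalling network — the task is to decide
which candidate best explains the time-*t* snapshot.

The selection criterion is cross-entropy. Writing *f* for the (unknown)
density of the observed abundances *y* at time *t* and *h_i* for candidate
*i*'s predictive density at time *t*,

    CE(f ‖ h_i) = −E_f[ log h_i(y) ] = KL(f ‖ h_i) + H(f).

The entropy H(f) is the same for every candidate, so minimizing
cross-entropy over candidates is equivalent to minimizing Kullback–Leibler
divergence — without ever evaluating *f*. Cross-entropy only needs samples
from *f* plus an estimate of each *h_i*, both of which TSS data provide.

## Pipeline

For each candidate model *i*:

1. **Moment targets.** Sample means, variances and pairwise covariances of a
   20% estimation split of the observed time-*t* cells (27 conditions for 6
   proteins).
2. **GMM estimation.** The candidate's free rates θ̃_i minimize a weighted
   sum of squared differences between those targets and the same moments of
   the candidate pool (an independent population of time-0 cells) evolved to
   *t* under the trial rates.
3. **Predictive density.** The candidate pool evolved under θ̃_i is
   summarized by ĥ_i: Gaussian-kernel marginals on the log scale composed
   with a Gaussian copula through Sklar's theorem.
4. **Scoring.** The approximate cross-entropy is the sample average
   ACE_i = (1/N) Σ_j −log ĥ_i(y_j) over the held-out 80% evaluation split.

The candidate minimizing ACE is selected; exact ties break toward fewer
free parameters, then lower candidate id. An approximate AICc on the vector
of observed-minus-predicted mean abundances (modelled as independent
zero-mean normals) provides an independent cross-check, and bootstrap
resampling of the evaluation cells yields model-selection probabilities.

## The synthetic-data generator

The generator reproduces the study conditions end to end. 8,000 cells draw
initial abundances from independent lognormal coordinates with log-scale
location μ = (5.25, 7.60, 5.25, 7.60, 5.25, 5.25) and variance
σ² = (0.15, 0.06, 0.15, 0.06, 0.15, 0.15) over the species
(Syk, Vav1, Syk:Vav1, pVav1, SHP1, SHP1:pVav1) — typical copy numbers
e^5.25 ≈ 190 and e^7.6 ≈ 2000. "Uncorrelated lognormal" is implemented as
independent coordinates (a diagonal log-scale covariance); no copula is
implied for the initial state. The first half of the cells is evolved to
t = 1.5 s under the scenario's ground-truth model to form the observed
sample; the second half is reserved at time 0 as the candidate pool. One
master seed drives every sub-draw (initial conditions, 20/80 split,
bootstrap) through deterministically derived child seeds.

The generator emulates extrinsic noise only. It does not emulate intrinsic
(reaction) noise, measurement error, instrument effects (spillover,
debarcoding), or correlated pre-stimulus states, so a passing suite shows
that the method ranks deterministic-dynamics models under initial-condition
variability — not that it is robust to those other features of real data.

### Network topology

The published figure of the minimal NK-cell model is not machine-readable,
so the default topology is this package's reconstruction from the named
species: the kinase Syk binds Vav1 (θ₁) and phosphorylates it (θ₂), the
complex can dissociate (0.12 1/s); the phosphatase SHP1 binds pVav1 (θ₃),
the complex dissociates (0.14 1/s) or releases dephosphorylated Vav1
(0.05 1/s). The assignment of the three fixed rate values to the three
back/catalytic reactions is likewise a reconstruction. Both are fully
configurable: `load_network` reads an alternative topology and fixed-rate
placement from a YAML file without code changes, and the conserved-moiety
checks on load catch inconsistent edits.

### Ground-truth rates

The true rate values behind the published selection experiments are not
available, so this package ships documented defaults, chosen once on two
principles and then frozen:

- the bimolecular association rates put the complexation relaxation
  timescales at order *t* = 1.5 s (for the SMALL constraints,
  θ₁·E[Vav1] ≈ 0.3 1/s, so roughly a third of total Syk shifts into the
  complex by *t*), which keeps both the equilibrium level and the approach
  timescale informative about the rates — dynamics neither saturated nor
  negligible;
- the freed rates in MEDIUM (θ₃) and LARGE (θ₂, θ₃) sit several-fold off
  the nested constraint manifolds θ₃ = 2θ₁ and θ₂ = 9θ₁, so the three
  scenarios are dynamically distinct and the constrained candidates are
  genuinely misspecified under richer truths.

Defaults (1/(abundance·s) for θ₁, θ₃; 1/s for θ₂):

| scenario | θ₁      | θ₂       | θ₃      | constraints active |
|----------|---------|----------|---------|--------------------|
| SMALL    | 1.5e-4  | 1.35e-3  | 3.0e-4  | θ₂=9θ₁, θ₃=2θ₁     |
| MEDIUM   | 1.5e-4  | 1.35e-3  | 8.0e-4  | θ₂=9θ₁             |
| LARGE    | 1.5e-4  | 3.0e-1   | 8.0e-4  | none               |

Because the selection probabilities depend on these implementation choices,
the MEDIUM/SMALL probabilities are expectations with generous stochastic
tolerance, not exact reproductions.

## Numerical choices

**Integration.** Cells are independent 6-dimensional ODE systems, so a
population is integrated as one flattened batch with the high-order explicit
Runge–Kutta method DOP853 at rtol 1e-8 / atol 1e-10. At realistic rates the
system is non-stiff (relaxation rates ≲ 2 1/s over t = 1.5 s) and the batch
path is two to three orders of magnitude faster than per-cell integration; a
per-cell LSODA path (`method="stiff"`) serves as fallback and cross-check.
Negative undershoots within 100·atol of zero are clipped to zero with a
warning; anything larger is an error naming the offending cell row.
Conserved moieties (total Syk, total SHP1, total Vav1 moiety), derived at
network construction by exact rational elimination, are verified to 1e-6
relative drift in the tests.

**GMM.** Optimization runs in log-parameter space (rates are positive, span
decades), bounds 1e-8..1e2 per free rate, with a seeded Latin-hypercube
screen (8 points by default, plus a warm start embedded from the nested
sub-model's solution) followed by L-BFGS-B polishing of the best two
screening points. The finite-difference step is 1e-4 in log space — safely
above the integrator noise floor, small relative to the smooth moment
surface. The embedded warm start guarantees that the achieved objective is
monotone non-increasing along the nesting chain. Trial rates that make the
batch integrator exceed a fixed evaluation budget (absurdly stiff corners of
the search box) receive a large finite penalty instead of stalling the
search. The default weighting is diagonal scale-relative, 1/scale² per
condition: the scale of a mean or variance condition is the target itself;
the scale of a covariance condition is √(var_j·var_k), i.e. covariance
errors are measured on the correlation scale. (Weighting a covariance by its
own inverse square would be ill-posed — a covariance target can be
legitimately near zero — and would let pure sampling noise dominate the
objective.) Two alternatives sit behind `weights_mode`: "inverse_variance",
the first-step efficient diagonal choice that weights each condition by the
inverse of its plug-in sampling variance from the estimation cells
(Var(mean) = var/N, Var(s²) ≈ (m₄ − var²)/N,
Var(cov) ≈ (var_j·var_k + cov²)/N) — it recovers rates several-fold more
precisely and is recommended when parameter estimates themselves are the
goal — and "unit". The scale-relative default reflects the regime the
selection experiments characterize: moderate estimation noise whose
propagation into the predictive densities is what the bootstrap
probabilities quantify. A means+variances-only mode is available
(`include_covariances=False`).

**Density estimation.** Marginals use Gaussian-kernel KDE on log abundances
with the change-of-variables Jacobian (positive data; avoids boundary bias
at zero) and Silverman's bandwidth 0.9·min(sd, IQR/1.34)·N^(−1/5). Kernel
sums are evaluated with logsumexp so log-densities stay finite arbitrarily
far into the tails. The copula is Gaussian, fitted on normal scores of rank
pseudo-observations rank/(N+1), with a ridge-to-identity repair (smallest
ridge on a fixed grid) if the correlation matrix is numerically singular.
Copula arguments use the KDE-smoothed CDF (same bandwidth as the pdf, so pdf
and CDF in Sklar's formula are mutually consistent), clipped into
[ε, 1−ε] with ε = 1e-6 so evaluation points in the far tails incur a
bounded penalty rather than −∞. All of these estimator choices stand in for
unavailable published appendix detail and are isolated behind keyword
switches.

**AICc.** The per-protein variance of the mean difference is the sum of the
two squared standard errors (`variance_mode="sem"`; a pooled-variance
variant is available). The small-sample correction uses n = number of
proteins and k = number of free parameters, so the criterion is undefined
for k ≥ n−1 and raises a documented error — the stated limitation of this
approximation. ACE has no such limitation. Natural logarithms throughout;
ACE is reported in nats.

**Bootstrap.** Default `reestimate=False`: θ̃ and ĥ stay fixed and only the
evaluation cells are resampled, which makes each resample a cheap average of
precomputed pointwise log-densities. Full re-estimation per resample is
implemented (`reestimate=True`) but costly; the flag is recorded in the
report. The observed split membership is kept fixed under resampling.

## Problem sizes and runtime

The tests and the acceptance script run the three full-size scenarios
(8,000 cells) once each and share the results; bootstrap uses B = 200
resamples with `reestimate=False`, which preserves the bootstrap
distribution's shape at a fraction of the published B = 1000 cost. Parameter
recovery uses five independent seeds per generating model. Unit tests use
small populations (200–5,000 cells) sized so each closed-form oracle's
sampling error is well below its assertion tolerance.

## Known limitations

- Intrinsic (reaction) noise is out of scope; the method as implemented
  assumes deterministic dynamics between snapshots.
- Only the Gaussian copula is provided; the `CopulaModel`/`JointDensityModel`
  split is the extension point for t- or vine copulas.
- The approximate AICc penalty calibration is inherited as-is; with
  thousands of cells informing 6 mean differences its absolute scale is
  heuristic, which is why it serves as a concordance check rather than the
  primary criterion.
- Published ACE/AICc magnitudes cannot be reproduced exactly because they
  depend on the unprinted ground-truth rates; only selection outcomes and
  bootstrap probabilities are comparable.
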