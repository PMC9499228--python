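# Methods

## The canonical model and its exact solution

The core object is a two-species reaction network per gene,

    0 --alpha(t)--> U --beta--> S --gamma--> 0,

with a piecewise-constant transcription rate alpha(t) (rates alpha_k on
intervals separated by switch times tau_k over a horizon T), a constant
splicing rate beta and degradation rate gamma. Its probability law obeys the
chemical master equation; for this linear network, a system started in a
Poisson (or deterministic zero) state remains product-Poisson at every time,
with means solving

    d mu_u/dt = alpha(t) - beta mu_u,
    d mu_s/dt = beta mu_u - gamma mu_s.

`models.mean_trajectory` evaluates the per-interval closed forms and
propagates the endpoint of each interval as the next interval's initial
condition, so the trajectory is exact and continuous. By default the system
starts at the steady state of the first interval (u0 = alpha_1/beta,
s0 = alpha_1/gamma) — the convention under which the generating-function
solution holds without an initial-condition correction.

**Degenerate rates.** The spliced closed form divides by (gamma - beta); when
|beta - gamma| < 1e-9 beta the removable singularity is evaluated through its
limit (e^{-beta t} - e^{-gamma t})/(gamma - beta) -> t e^{-beta t}. The
switch point is far above double-precision cancellation error and far below
any biologically distinguishable rate difference.

## Occupation measures

Sequencing has no access to the process clock: cells are sampled at latent
process times drawn from a sampling measure f. The observable law is the
occupation measure P(x) = E_f[P(x; t)]. Three measures are supported, each
motivated by an idealized reactor configuration: uniform on [0, T]
(plug-flow/batch — the default, and the assumption under which order
statistics of sampled times are Beta-distributed), exponential with rate 1/T
(stirred tank), and a Dirac point mass at T (synchronized endpoint, the
fluorescence-experiment analogue). All converge to the ergodic stationary
law as T grows.

Occupation PMFs are computed by averaging the instantaneous product-Poisson
law under f with a fixed composite-Simpson panel rule (768 panels, split at
schedule switch times where the means have kinks). A half-resolution
evaluation provides a Richardson-style error estimate; if it exceeds 1e-5
the computation aborts with the achieved tolerance rather than returning a
silently inaccurate PMF. The exponential measure is truncated at 30 T
(residual mass < 1e-13), extending the final interval's rate beyond T.

For the one-species birth-death process the occupation PGF has the closed
form H(z) = e^{u alpha/beta}/(beta T) [Ei(u c) - Ei(u c e^{-beta T})] with
u = z - 1 and c = y0 - alpha/beta. The real (principal-value) exponential
integral is used, which the formula requires for z < 1; when e^{-beta T}
underflows, Ei near zero is replaced by its logarithmic asymptote so the
ergodic limit e^{(z-1) alpha/beta} is still recovered. c = 0 is handled as
the constant-mean limit.

## Bursty transcription

Stationary bursty expression is modeled with geometric bursts (PGF
M(z) = 1/(1 + b(1 - z)), mean b molecules per event) arriving at frequency
alpha. The log-PGF of the stationary joint law is

    phi(g) = alpha * Int_0^inf [M(1 + U1(g; s)) - 1] ds,

with the downstream characteristic U1(g; s) = g_u e^{-beta s} +
g_s beta/(beta-gamma)(e^{-gamma s} - e^{-beta s}). The integral is mapped to
[0, 1] by x = e^{-min(beta,gamma) s} and evaluated with 96-point
Gauss-Legendre; the PGF is then evaluated on the 2-D unit-circle grid and
inverted by FFT. The geometric family is a standard, maximally dispersed
choice for burst sizes; the moment identities used for truncation and
validation are Fano_u = 1 + b and Fano_s = 1 + b beta/(beta + gamma).

**Truncation.** All joint PMFs are truncated at mu + 5 sigma per species,
floored at 10 states. For heavy bursts this can leave up to a few parts per
thousand of mass beyond the grid (which the FFT aliases back); the
boundary-row mass is reported as `truncated_mass` and logged when it exceeds
1e-4. Sampling in the bursty simulator draws directly from this truncated
histogram, which is the intended construction, so the report is suppressed
there.

## Simulators: what they emulate, and what they do not

All three generators draw counts from the exact laws above rather than from
a stochastic simulation algorithm — legitimate because the laws are known in
closed form; the Gillespie SSA is retained in the test suite purely as an
independent oracle. One seed sequence is sub-streamed per gene, so any gene
subset is reproducible independently of the total gene count.

- **Perturbation/reversion (ABA).** 2000 cells, 100 genes; horizon T = 10
  with synchronized switches at tau_1 = 3, tau_2 = 7; per-gene rates
  alpha_1, alpha_2 ~ LogNormal(0, 1), beta ~ LogNormal(1, 0.5),
  gamma ~ LogNormal(0.5, 0.25) (splicing somewhat faster than degradation);
  sampling times Uniform[0, T]; counts Poisson at the exact means. An empty
  switch list degenerates to the stationary (constant-rate) control.
- **Multipotent AB(C/D/E).** Identical conditions; after tau_2 each cell
  follows one of three equiprobable terminal fates with fate-specific
  terminal transcription rates, drawn independently per fate from the same
  lognormal law (the branch correlation is not pinned by the study
  conditions; independence is this package's choice). Two fate
  probabilities give the bifurcation variant.
- **Stationary bursty.** 100 genes; 10 cell types x 300 cells; burst sizes
  b ~ LogNormal(0.3, 0.8) clipped to [0.05, 25], shared across cell types;
  beta = 1 without loss of generality; per-gene log-degradation centers
  ~ Normal(-0.3, 0.3) with per-type gamma ~ LogNormal(center, 0.1) clipped
  to [0.08, 4]; burst frequencies ~ LogNormal(-1, 0.5) clipped to
  [0.005, 1]. Parameter sets with truncation area
  (mu_u + 5 sigma_u)(mu_s + 5 sigma_s) > 1.5e4 are redrawn, capped at 1000
  attempts per (gene, type) — the cap is a package choice to bound the
  rejection loop. Ground-truth velocity is identically zero.

The simulators deliberately omit technical noise (capture/sequencing
models), cell-size extrinsic noise, normalization-inducing compositional
effects, doublets, and cell-cycle structure. Passing tests therefore
establish the behavior of the estimation chain in its *best case* — matched
model, no technical artifacts; distortions measured here are lower bounds on
what real data would incur, and agreement here does not imply correctness on
real data.

## The estimation chain

Defaults follow the standard velocyto-style analysis: discard cells in the
bottom 0.5th percentile of total unspliced counts; discard genes with fewer
than 40 spliced counts or expressed in fewer than 30 cells; keep the top
2000 genes by coefficient-of-variation-vs-mean among genes with mean
expression <= 35. The CV score is the residual of log CV above a least-
squares power-law fit of CV on mean in log-log space (the reference
implementation's exact scoring formula is not published; this is the natural
reading). An optional gate on spliced-unspliced correlation > 0.05 is
available but off by default. Filtering and normalization are both skipped
for simulated data — simulated genes all have valid dynamics by
construction, and omitting normalization keeps the PCA space, the pooling
space, and the extrapolation space identical.

Normalization (when on) rescales each cell's per-species total to the
dataset mean total, separately for spliced and unspliced. PCA is computed
from log1p-transformed spliced counts (the pseudocount makes the transform
zero-safe; plain log is undefined at zero counts) with 25 components;
component signs are fixed so each component's largest-magnitude loading is
positive, making results machine-independent. Pooling replaces each cell's
value by the mean over the cell itself plus its k = 50 nearest neighbors in
PC space (self-inclusion makes k = 0 the identity and the pool a proper
local mean); neighbor ties are broken by ascending cell index via a stable
sort, so the chain is bit-deterministic.

The extremal fit regresses pooled u on pooled s with an intercept over cells
whose pooled s lies at or below the 5th or at or above the 95th percentile
for that gene (the reference extremal-percentile defaults are not printed;
these are configurable). Genes with constant s among the extrema are flagged
and excluded rather than fit. Velocity is v_ij = u_ij - (slope_j s_ij + q_j).

**Extrapolation.** dt* = min_{ij} s_ij/|v_ij| over entries with
v_ij < -1e-6, which is the largest time for which every extrapolated spliced
value stays non-negative. Entries with s_ij < 1e-6 and v_ij < -1e-6 have
their displacement zeroed and are excluded from the minimum (they would
otherwise pin it at zero, making the zeroing rule vacuous); residual
negatives below the numeric floor are clipped at zero so non-negativity is
exact. If no velocity is appreciably negative, the conventional dt = 1 is
used.

## Velocity embeddings

The linear embedding projects s and s + v dt* through the same PCA basis and
takes the difference of the top-two coordinates. The nonlinear embedding
finds k = 150 nearest neighbors in the 2-D embedding, computes the Pearson
correlation between each high-dimensional neighbor displacement and the
cell's velocity displacement after a variance-stabilizing transform (signed
square root by default — the signed variant handles negative displacement
coordinates, which an unsigned root cannot), and weights neighbor directions
by a softmax with kernel width sigma = 0.05. The Boolean mode replaces the
correlation by the fraction of sign-concordant coordinates (Kronecker match
on signs in {-1, 0, 1}).

The density correction subtracts the uniform-weight mean neighbor direction.
The reference implementation's exact correction formula is not published;
this contract was chosen so that a cell whose weights carry no information
(all concordances equal) gets exactly a zero arrow. Neighbor displacements
with zero variance, or a zero velocity displacement, yield a neutral
(zero) concordance; cells with an all-zero displacement get zero arrows.
Grid aggregation averages the 100 nearest cell arrows per node of a 20 x 20
grid under a Gaussian kernel with bandwidth 0.5 x the mean grid spacing.

## Diagnostics

Neighborhood degradation uses k = 150 neighbor sets (anchor excluded, set
semantics) per representation and the Jaccard distance
(|A u B| - |A n B|)/|A u B| between stages. Angle deviations are reported in
degrees on [0, 180]; pairs where either arrow has zero norm are excluded
rather than scored as zero. The upregulated fraction counts cells strictly
above the fitted line. Moment recovery compares pooled means (and pooled
variances over each cell's pool) with the true instantaneous Poisson
moments, as fold deviations max(a/b, b/a) restricted to entries with true
moment >= 0.1 — the floor is an analysis constant of this package, chosen to
avoid ratio blow-up at near-zero means.

## Inference from occupation-measure data

Given M cells sampled uniformly on a unit horizon and a known rank ordering
sigma, the i-th cell's latent time is a uniform order statistic with law
Beta(sigma_i, M + 1 - sigma_i) and variance
sigma_i(M+1-sigma_i)/((M+1)^2(M+2)) = O(1/M); the plug-in estimate
t_i = sigma_i/(M+1) therefore concentrates, and the likelihood conditioned
on sigma separates across genes. `fit_conditional_mle` grid-searches global
switch times (default step 0.05 — a grid rather than continuous optimization,
for reproducibility) and, for each candidate, fits every gene's
(alpha_k, beta, gamma) independently by L-BFGS-B in log-parameter space
(bounds e^{-12}..e^{8}, ftol 1e-10) from moment-based starts: beta = 1,
gamma from the ratio of species means, alpha_k from per-interval unspliced
means. Zero probabilities are guarded with a 1e-300 log-floor.

Inference of the ordering itself is a combinatorial (TSP-like) problem and
is out of scope by design; orderings are supplied — the true ordering for
simulated data, reversals and random permutations as controls, or an
external pseudotime. The permutation control refits each candidate ordering
and reports where the fitted ordering ranks: a transient fit that does not
beat random permutations is overfit.

Two special-case scoring functions connect this framework to existing
methods: the isotropic bivariate Gaussian kernel pseudo-log-likelihood
-M ln(2 pi s_j^2) - (1/2 s_j^2) sum ||D_ij - mu(t_i)||^2 (the dynamical-
model objective; its optimum is invariant under positive rescaling), and the
stationary product-Poisson mixture likelihood with an EM fitting helper (the
clustering limit; Poisson components are the coherent choice for the count
models here, with lognormal clustering deliberately not the default).

## Problem sizes and runtime

The headline statistics (imputation fold deviation, gamma/beta recovery,
k-sweep stability, Jaccard degradation, angle deviations) are computed on
the full study conditions: 2000 cells x 100 genes for the transient
simulations, 3000 cells x 100 genes for the bursty population. Oracle
cross-checks run at sizes where exact enumeration or 1e5-sample stochastic
simulation is comfortable: SSA comparisons use 1e5 trajectories (total
variation threshold 0.02), order-statistic Monte Carlo uses 1e5 replicates,
and the conditional-MLE recovery uses 300 cells x 8 genes over the full
switch-time grid — enough for the +-0.1 recovery check while keeping the
whole suite within a few minutes on one CPU.

## Known limitations

- The occupation-measure machinery covers the PGF-tractable model class:
  piecewise-constant (or deterministic) transcription, linear splicing
  networks, geometric-burst stationary models, finite fate mixtures.
  Telegraph (promoter-switching) transients, time-dependent burst laws,
  gene-gene coupling, cell cycle, and elongation models are out of scope.
- The kNN machinery materializes full pairwise distance matrices (O(n^2)
  memory) for exact, reproducible tie-breaking; this is comfortable to
  ~20k cells but not beyond.
- t-SNE/UMAP coordinates are accepted as embedding inputs but not computed
  internally; their internals (and seeds) are the caller's responsibility.
- The conditional MLE assumes synchronized switch times shared by all genes
  and a uniform sampling measure on a unit horizon; per-gene switch times
  would make the global parameters vacuous.
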