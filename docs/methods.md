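# Methods

## Growth laws and their parameterization

The three single-species growth equations are the Zwietering forms, in
which every parameter is biologically interpretable: the asymptote *A*, the
maximum specific growth rate *r* (the slope of the tangent at the
inflection point), and the lag time *λ* (the tangent's x-intercept).
Richards adds a shape parameter *v* > 0 and reduces exactly to the logistic
at *v* = 1; the model-selection code treats logistic-in-Richards as a
nested pair (df = 1).  Gompertz is *not* nested in Richards (it is a
*v* → 0 limit); the F test is nevertheless offered for the Gompertz-vs-
Richards comparison with a one-df convention, a pragmatic choice the user
should read as approximate.

These sigmoids describe growth *relative to the inoculum*: functional
mapping and the monoculture generator work on y = log10(N/N₀), which rises
from ~0 through the lag and exponential phases to A = log10(K/N₀).  The
co-culture side models absolute log10 abundance, because the LV dynamics
carry the inoculum explicitly.

Growth phases follow a tangent-line convention: the lag phase is [0, λ] and
the exponential phase ends where the inflection tangent reaches the
asymptote, at λ + A/r.  Published phase boundaries derived from other
heterochronic formulas will differ; ours is an internal convention, not a
reproduction target.

## Lotka–Volterra dynamics, decomposition and classification

The LV system uses carrying-capacity-normalized interaction terms,
(N_e + α_e|s N_s)/K_e for species e and symmetrically for s (the same K in
both terms of each equation).  Solving is fixed-step fourth-order
Runge–Kutta; the library-level solver defaults to step 0.01 h with linear
interpolation onto observation times, which matches the decoupled logistic
closed form to better than 1e-6 relative error.

Each species' growth rate splits into an independent term r N (1 − N/K) and
an interactive term −r N α N_partner / K, integrated along the solved path
with cumulative Simpson on the RK4 grid so that
overall = independent + interactive pointwise to integration tolerance.
The interaction type is the cell of the 3×3 strategy matrix indexed by the
signs of the two time-integrated interactive components; integrals smaller
than 1% of the species' integrated overall growth count as zero.

## Mixture likelihoods and estimation

**Static model (one time point).**  A four-component bivariate-normal
mixture over the interspecific genotype combinations, with shared 2×2
covariance (σ²_A, σ²_B, ρ) and fixed per-pair component weights.  Default
weights are one-hot marker-as-QTL; an LD-based soft-weight mode accepts any
valid weight matrix.  EM with a variance floor of 1e-8 × the phenotype
variance; convergence at relative log-likelihood change < 1e-8.  With
one-hot weights the EM fixed point coincides with the closed-form group
means and pooled covariance, which the scan exploits directly.

**Dynamic models.**  The residual covariance of the stacked trajectory
pair (2T × 2T) is generated by structuring parameters Ψ: per-species
variances, temporal correlations, and one cross-species correlation.  The
default structure is AR(1) on the actual (possibly unequal) time spacings,
corr(t_j, t_k) = ρ^|t_j − t_k| with ρ the per-hour correlation restricted
to [0, 1); antedependence-1 and ARMA(1,1) (on index lags) are selectable,
and AIC can arbitrate.  The cross block couples the species with
correlation ρ_c times the geometric mean of the two within-species
correlation profiles — exactly separable (Kronecker) when the species share
temporal parameters, positive-definiteness checked by Cholesky (one 1e-10
jitter retry) otherwise.  Ψ is estimated by Nelder–Mead simplex over
transformed parameters (log variances, atanh correlations), with one
restart from a perturbed point.

`systems_mapping_fit` alternates (E) posterior combo memberships, (M1)
per-combo LV parameters by RK4-embedded weighted Gaussian maximum
likelihood, and (M2) Ψ by simplex, to relative tolerance 1e-6 (max 200
outer iterations).  With one-hot weights the E step is trivial and the
log-likelihood ascends monotonically.  Initial abundances are fixed at the
design inoculum (5 × 10³ copies/mL per species by default) rather than
estimated.

**Scan computation.**  Genome scans and permutation thresholds profile the
residual covariance at its estimate under the shared-curve null.  With Σ
fixed, the LRT of genotype-specific versus shared mean curves reduces
exactly to 2(ℓ₁ − ℓ₀) = Σ_g n_g [d(ȳ_g, μ̂₀) − d(ȳ_g, μ̂_g)], where d is
the Σ-weighted squared distance and ȳ_g the genotype-group mean trajectory
— so each marker (pair) costs a handful of weighted curve fits, not n
per-strain fits.  Because permuting phenotype blocks leaves the pooled data
unchanged, μ̂₀ and Σ̂ are permutation-invariant and the identical statistic
is recomputed in every permutation.  The inner fits are damped Gauss–Newton
(Levenberg–Marquardt) steps warm-started from the null fit (numba-compiled;
scan-level RK4 step 1.0 h, single-pair estimation 0.25 h, at most 12–15 LM
iterations per group fit — the statistic is defined by this procedure and
is applied identically to observed and permuted data).  The LV fit box
(r ∈ [0.01, 10]/h, K within 10³ of the observed maximum, |α| ≤ 5) enters as
a smooth quadratic penalty.

**Why a profile estimator for α.**  In the free six-parameter combo fit,
partner-induced saturation (α N_partner/K) can mimic self-limitation
(N/K): the profile likelihood has a nearly flat (K, α) ridge
(information correlation ≈ 0.99 under realistic designs), so per-combo α
point estimates are wildly variable at realistic noise even though the LRT
is unaffected.  Reported interaction coefficients therefore come from a
conditional estimator: (r, K) of both species held at the shared-curve
estimates, (α_e|s, α_s|e) refit per combo (`profile_combo_alphas`,
`systems_mapping_fit(shared_growth=True)`).  Under the generator's
architecture — combo-specific α with shared growth parameters — this is
consistent and reduces the α sampling error by an order of magnitude.

**Permutation thresholds.**  Phenotype pair-blocks (both species'
trajectories of a pair kept together) are permuted against genotype pairs;
the genome-wide threshold is the k-th largest null maximum with
k = ⌊α(n_perm + 1)⌋, which makes "observed maximum exceeds threshold" an
exact level-α permutation test.  Thresholds are seeded and bit-reproducible;
χ² p-values in static outputs are descriptive only.

**Effect tests.**  After a significant pair, direct, indirect and epistatic
effect curves are tested by their time-integrated squares (trapezoid),
against a null ensemble of the same statistics computed on permuted fits;
p = (1 + #{null ≥ obs}) / (1 + K).

## Synthetic data and validation harness

The generator reproduces the paired-community design: n pairs (default 45),
genotypes i.i.d. Bernoulli at allele frequency 0.5 (markers unlinked),
abundance at 0, 2, …, 24, 28, 32, 36 h with 3 replicates.  Monoculture mean
curves are genotype-specific Richards curves (direct effects only; default
asymptote shift 0.3 log10).  Co-culture mean curves solve genotype-
combination-specific LV systems built from a base antagonistic
parameterization (r_e = 1.0/h, K_e = 8×10⁸; r_s = 0.8/h, K_s = 5×10⁸;
ᾱ_e|s = 0.4, ᾱ_s|e = 0.3 — growth from 5×10³ to ~10⁹ copies/mL with
species e saturating earlier, qPCR-like dynamics) with combo shifts
α_e|s + d₁x_A + d₃x_Ax_B and α_s|e + d₂x_B + d₃x_Ax_B (x = ±1,
d = 0.12 each): the minimal architecture that carries direct, indirect and
epistatic effects for both species simultaneously.  Residuals are
multivariate normal from the AR(1) structure (base log10 variance 0.04,
per-hour correlation 0.85, cross-species correlation 0.2) plus per-replicate
measurement noise (sd 0.08 log10).

Heritability is defined at a reference time — by default the observation
time of maximum between-combo variance — as between-combo variance over
total (combo + residual + replicate-averaged measurement) variance; the
residual scale is calibrated per species so the realized value matches the
target.  The generator does not emulate linkage disequilibrium, population
structure, qPCR calibration error, or non-Gaussian outliers, so passing
simulations demonstrate correctness of the statistical machinery under the
stated model, not robustness to those real-data features.

The power/FPR harness (`estimate_power_fpr`) reports, over seeded
replicates, the fraction in which the causal marker (pair) exceeds its
genome-wide threshold (power) or any marker does on null data
(replicate-level FPR), plus bias/RMSE of the profile α estimates for
detected pairs.

### Problem sizes

The validation studies run at desk scale: 200 markers (mono) or 20 markers
per species (co), 45 pairs, 50 replicates, 50-permutation 5% thresholds —
about one minute for the monoculture study and ten for the co-culture
study on one CPU.  The acceptance script uses exactly these sizes;
paper-scale settings (1000 markers, 1000 permutations) are available via
the scenario and CLI flags.

## Numerical choices and edge cases

* Overflow-guarded closed forms (exponents clipped at ±700; ±60 in the
  compiled kernels); LV integration reports blow-up with the offending time.
* Degenerate inputs: constant trajectories are rejected as unfittable;
  monomorphic markers (after missing-data removal) are skipped with NaN;
  mixture covariance degeneracy triggers the variance floor and a flag.
* Missing genotypes drop the pair for that marker (no imputation); marker
  filters default to MAF ≥ 0.1 and missingness ≤ 0.2.
* Population structure is handled by a covariate-adjustment hook
  (`adjust_structure`): per-time regression on subpopulation indicators,
  residuals recentred on the grand mean; subpopulations with < 2 strains
  are merged with a warning.
* AIC ties break toward fewer parameters; allele codes are assigned
  alphabetically per marker in TSV input; marker positions are 1-based.

## Known limitations

* The F test for non-nested Gompertz-vs-Richards is approximate (see above).
* Multi-locus heritability sums per-pair variances without a
  linkage-disequilibrium correction — an upper bound under linkage
  equilibrium.
* Under unequal combo frequencies the three effect contrasts are
  correlated; reported variance shares are normalized component shares
  (the equal-frequency orthogonal decomposition is the exactly additive
  reference).
* The scan statistic profiles Σ at the null estimate rather than refitting
  Ψ per marker pair under H₁; `systems_mapping_fit` provides the full
  alternating estimation for pairs of interest.
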