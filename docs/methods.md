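# Methods

## Generative model

One kidney, one measurement condition (SV volume v, Gaussian post-filter
sigma f): the true absorbed dose D (Gy) is observed through

    D_WKP  = D (1 + ε_WKP),
    D_SV,i = D · b (1 + ε_i),   i = 1..m,

with (ε_1..ε_m, ε_WKP) jointly zero-mean Gaussian. The covariance is
compound-symmetric among SVs plus a uniform SV–WKP cross-correlation:

| parameter | meaning | unit | default |
|---|---|---|---|
| `sigma_sv` | relative noise of one SV estimate | fraction | calibrated per condition (≈ 0.093–0.112) |
| `sigma_wkp` | relative noise of the WKP estimate | fraction | calibrated (≈ 0.069–0.073) |
| `rho_sv_wkp` | Corr(ε_i, ε_WKP) | — | 0 |
| `rho_sv_sv` | Corr(ε_i, ε_j), i≠j | — | 0 |
| `bias` | multiplicative SV bias b | — | per-condition NF (0.91–1.23) |

The cross-correlation captures the shared spatial origin of SV and WKP
noise: disjoint voxel sets give ρ = 0, overlap on a spatially
autocorrelated field gives 0 < ρ < 1, and ρ = 1 makes a single SV
coincide with the reference so the relative difference vanishes. The
joint correlation matrix is positive semi-definite only when
m·ρ_sv_wkp² ≤ 1 + (m−1)·ρ_sv_sv; construction-time validation rejects
violations. `rho_sv_sv` is an extension knob (default 0): SV–SV spatial
autocorrelation is plausible but unparameterised by any reported value.

Draws use an eigendecomposition square root of the covariance (it may be
singular at |ρ| = 1). A draw yielding any factor 1 + ε ≤ 0 (a
non-positive dose) has its whole noise vector redrawn, preserving the
joint structure; per-component truncation would distort the
correlations. At the realistic noise levels here (σ ≤ 0.15) the
rejection probability is ~1e-11 per kidney, so the induced truncation is
far below every tolerance used. A configurable cap on redraws turns
absurd noise settings into an error instead of a spin loop.

The bias multiplies SV doses only: the WKP is the reference against which
the normalization factor is defined, so a common factor on both would be
unidentifiable from dose ratios.

All stochastic functions take an explicit `numpy.random.Generator`; a
cohort is bit-reproducible from its config seed.

## Estimators

**Normalization factor.** NF = mean of the pooled per-SV ratios
D_SV,i/D_WKP within a (volume, filter) stratum; SEM = sd(ratios, ddof=1)/√n.
Note NF is a ratio estimator: E[NF] = b·E[1/(1+ε_WKP)] ≈ b(1+σ_WKP²),
a ≈ +0.5% second-order inflation at σ_WKP ≈ 0.07. This is invisible at
the 36-kidney scale (SEM ≈ 1%) but detectable on 50× cohorts; the test
suite checks NF against this exact expectation there.

**Relative differences.** RD(k) is computed per kidney for SV subsets of
size k. All C(m, k) subsets are enumerated (deterministic, lexicographic;
a seeded uniform subsample is available for large m) and the per-subset
RDs are *pooled* across kidneys before taking sd(ddof=1). Pooling rather
than per-kidney averaging is deliberate: averaging all size-k subset
means reproduces the full-m mean and would destroy the k-dependence.
Pooled subsets within a kidney are dependent, so `n_samples` overstates
the effective sample size; U(k) is still a valid dispersion estimate, but
no confidence intervals are derived from `n_samples`.

**Normalization before precision analysis.** Each stratum's SV doses are
divided by that stratum's own NF. This forces mean RD(k=1) = 0 exactly
(mean(ratio)/NF − 1 = 0), which is why observed biases are at
floating-point level; the un-normalized second-order bias is
σ_WKP² − ρ·σ_SV·σ_WKP (in fraction units), exposed as a closed-form
oracle.

**Group comparison.** Two groups of precision estimates (e.g. per-filter
U values of the two SV volumes) are compared with a two-sided Wilcoxon
rank-sum test: exact enumeration when both groups are tie-free and below
20 observations, otherwise the midrank normal approximation
(`scipy.stats.mannwhitneyu`).

## Power-law fit

U(k) = α·k^(−β) + γ is fitted by bounded least squares
(`scipy.optimize.least_squares`, trust-region reflective) with α ≥ 0,
β ∈ (0, 2], γ ≥ 0, so the fitted curve is non-increasing.
Initialization: γ₀ = min(u), α₀ = u(smallest k) − γ₀, β₀ = 0.5. If the
gradient path fails, a grid over β (step 0.05) with a non-negative
linear solve (NNLS) for (α, γ) selects the best candidate and is refined;
`method_` records which path produced the result. The β upper bound 2.0
is a generous envelope around the theoretical ½ and is configurable.
Unweighted by default (weighting by `n_samples` is available but off,
since pooled counts overstate information). R² = 1 − SSR/SST with SST
about the mean of the observed u; the degenerate SST = 0 case is defined
as 1 when SSR = 0 and 0 otherwise, so flat curves report rather than
crash. Parameter standard errors come from the Jacobian curvature when
the degrees of freedom allow.

On data generated by this model with σ_WKP > 0, the *true* curve is
100·sqrt(σ_SV²/k + σ_WKP²), which is not a power law; the fit is a
deliberate flexible approximation. The mismatch study in the tests shows
the 5-point fit still attains R² ≥ 0.99 and extrapolates U(100) within
10% of the analytic value — the tolerance used wherever γ or U(100) from
a fit is compared to the sqrt-form truth.

## Analytic oracles and their accuracy

`analytic_rd_sd` is the first-order (delta-method) sd of RD(k):
100·sqrt(σ_SV²[1/k + (1−1/k)ρ_sv_sv] + σ_WKP² − 2ρ_sv_wkp σ_SV σ_WKP).
The noisy denominator 1 + ε_WKP makes the exact sd slightly larger, by
≈ (3/2)σ_WKP² relative (~1% at σ_WKP = 0.07) — more than 3 sampling
standard errors once n ≳ 5·10⁴, so simulation checks at that scale
compare against the *exact* RD moments, computed independently by
Gauss–Hermite quadrature over ε_WKP with closed-form conditional
Gaussian moments, and separately verify the first-order formula within
an a-priori 4σ_WKP² truncation envelope. `analytic_rd_bias` is the
second-order mean, 100(σ_WKP² − ρσ_SVσ_WKP), guarded to σ_WKP < 0.3.

## Synthetic cohort calibration

The generator emulates the observed study design: 18 patients × 2
kidneys; 5 SVs per kidney; SV volumes 2 and 0.6 ml; filters 0/3/4/5/6 mm
(filters enter only through their noise parameters — no filter physics is
modelled). True doses are log-normal, median 3.76 Gy, log-sd 0.33, chosen
so the central 95% interval (≈ 2.0–7.2 Gy) matches the reported dose
range; one dose per kidney, shared across conditions, with noise drawn
independently per condition (the real cross-filter noise correlation is
unknown — a documented limitation).

Per-condition σ values invert the first-order formula from the observed
per-filter single-SV precisions (2 ml: 11.82/11.41/11.38/11.29/11.40%;
0.6 ml: 13.13/12.30/12.11/12.07/12.24%) and plateaus (7.27% and 6.92%):
σ_SV = sqrt(U(1)² − U(∞)²) for any ρ, with σ_WKP the positive root of
the plateau quadratic. ρ defaults to 0 as an *assumption*, not an
estimate: partial correlation is argued qualitatively but no value is
reported, and ρ = 0 is the conservative (worst-precision) choice with a
closed-form calibration. Per-condition biases are the observed per-filter
normalization factors (2 ml: 1.12/1.05/1.01/0.96/0.91; 0.6 ml:
1.23/1.14/1.09/1.02/0.96); the smoothing mechanism behind their filter
dependence is not modelled, only its magnitude.

What passing tests on these cohorts show — and what they do not: they
verify the estimators and the fitting machinery against a model whose
assumptions (Gaussian noise, compound symmetry, condition-independent
draws, no outliers, no segmentation failures) are idealisations. They do
not validate those assumptions on real images; on real data β and γ
absorb spatial heterogeneity and partial-volume effects that this
generator does not emulate.

## Problem sizes

Simulation-backed checks use cohorts chosen to make sampling error small
relative to each tolerance: 10⁵–2·10⁶ draws for oracle agreement, 50×
cohorts (1800 kidneys) for end-to-end parameter recovery, 2·10⁴ kidneys
for monotonicity, and 20 replicate study-scale cohorts (36 kidneys) for
the R² and bias levels. The whole suite runs in well under a minute.

## Known limitations

- The power law is an empirical approximation to a sqrt-form truth under
  this model; fitted (α, β) are descriptive, not physical constants.
- γ estimates the WKP imprecision only insofar as SV and WKP noise are
  uncorrelated; with ρ > 0 the plateau is sqrt(σ_WKP² − 2ρσ_SVσ_WKP),
  which the calibration handles but single-condition fits cannot
  disentangle.
- The ratio-estimator inflation of NF (≈ b·σ_WKP²) is not corrected, only
  documented; at study scale it is an order of magnitude below the SEM.
- File formats carry doses in Gy as plain CSV; no imaging formats are
  read — the package starts from dose tables.
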