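# Methods

`dcovnet` estimates directed functional connectivity (FC) from
haemodynamic time series and validates the whole chain on synthetic data
with known ground truth.  This note documents the models, the numerical
choices, and what the synthetic experiments do and do not establish.

## Differential covariance

Neural measurements are viewed as a linear stochastic dynamical system
`dV/dt = W V + noise`.  The derivative of a node's trace reflects its
*inputs* (sinks), its value reflects its *outputs* (sources), so the
covariance between one node's derivative and another node's signal carries
directed information:

* **Δc** (`differential_covariance`): `Δc[i,j] = cov(dz_i, z_j)` with a
  central-difference derivative and the signal trimmed to the derivative's
  support.  Entry `(i, j)` is the influence of source `j` on sink `i`
  (row = sink everywhere in this package).  For stationary data Δc is
  antisymmetric up to sampling error; the realised ratio
  `||Δc + Δcᵀ||_F / ||Δc||_F` is recorded in the matrix metadata rather
  than asserted, since it is a diagnostic, not an identity.
* **Δp** (`partial_differential_covariance`): for each ordered pair the
  contribution of all remaining nodes `K` is regressed out,
  `Δp_ij = Δc_ij − Cov_jK Cov_KK⁻¹ Δc_iKᵀ`, removing chain and common-input
  effects.  With two nodes the conditioning set is empty and Δp = Δc;
  diagonal entries condition on all other nodes.  `Cov_KK` systems are
  solved directly; a ridge jitter of `1e-8 × mean(diag)` is added only when
  the block's condition number exceeds 1e12 (collinear components).  The
  matrix form is cross-checked against an explicit per-pair
  residual-regression implementation to 1e-8.
* **Δs** (`sparse_latent_split`): Δp is split into a sparse coupling
  matrix and a low-rank remainder capturing shared input from unobserved
  sources, by solving `min α‖Δs‖₁ + ‖L‖_*` subject to `Δs + L = Δp` with
  inexact augmented-Lagrange multipliers (singular-value shrinkage for L,
  soft-thresholding for Δs).  The nuclear norm is used as the low-rank
  penalty because Δp is not symmetric; on positive-semidefinite arguments
  it reduces to the trace.  The weight α defaults to `1/√N` (the
  exact-recovery scaling for this convex program); note that α must
  multiply the *sparse* term — if the ℓ₁ term has unit weight and the
  nuclear term weight is below 1, the optimum is always `Δs = 0` because
  `‖M‖_* ≤ ‖M‖₁` for every matrix.  Solver defaults: tolerance 1e-7 on the
  relative constraint residual, 500 iterations, penalty growth 1.5.

Benchmarks implemented alongside: sample covariance (divisor T−1),
precision matrix (pseudo-inverse with a warning when rank-deficient),
graphical-lasso and ridge precision (ridge: `(Cov + ρ·mean(diag)·I)⁻¹`,
default ρ = 0.1; lasso default λ = 10 applied on the per-sample likelihood
scale λ/T), and conditional Granger causality (VAR order by AIC over
1..10 with ties to the smaller order, OLS full/reduced fits, log
residual-variance ratio referred to χ² with the selected order as degrees
of freedom, uncorrected p-values).

## Haemodynamics and backward reconstruction

The forward map from neural activity to BOLD is the four-state
Balloon–Windkessel model (vasodilatory signal s, inflow f, venous volume
v, deoxyhaemoglobin q) with readout
`y = V0 (k1(1−q) + k2(1−q/v) + k3(1−v))`,
`k1 = 4.3·ϑ0·ρ·TE`, `k2 = ε·r0·ρ·TE`, `k3 = 1−ε`.  It is integrated with
fixed-step RK4 (dt ≤ 0.01 s recommended) from the resting fixed point,
either in full nonlinear form or linearised about rest.

Linearised, the cascade from neural drive u to BOLD is LTI, and applying

    P(D) = (τD + 1/α)(D + 1/τ)(D² + κD + γ)
         = p4 D⁴ + p3 D³ + p2 D² + p1 D + p0

to y collapses it to `z = P(D) y = q1 u̇ + q0 u` with

    q1 = −V0 η [(k1+k2) c_f + (k3−k2)]
    q0 = −(V0 η/τ) [(k1+k2)((c_f−1)/α + 1) + (k3−k2)]
    c_f = 1 + (1−ρ) ln(1−ρ)/ρ,

where `c_f` is the linearised slope of the flow–extraction product
`f·E(f)/ρ` at rest.  The p coefficients are exactly the expansion of the
factored operator above; the q coefficients are derived from the same
linearisation, so the round-trip property (reconstruct z from forward-model
BOLD, correlate with `q1 V̇ + q0 V`) holds by construction of consistency
and is verified numerically per node (r > 0.95; still > 0.9 with every
biophysical parameter independently perturbed by ±20%, since in the slow
signal band a coefficient error mostly rescales z, which correlation
ignores).

Defaults (overridable, recorded in output sidecars): κ = 0.65 s⁻¹,
γ = 0.41 s⁻¹, τ = 0.98 s, α = 0.32, ρ = 0.34, V0 = 0.02, ε = 0.5,
r0 = 25 s⁻¹, η = 0.02, ϑ0 = 40.3·(B/1.5) s⁻¹.  TE and B are acquisition
properties with no defaults; presets: `BalloonParams.hcp()` (3 T,
TE = 33.1 ms) and `BalloonParams.mouse()` (9.4 T, TE = 12 ms).

Derivatives are central differences, exact on low-order polynomials, with
symmetric trimming by the derivative order (no filtering by default; an
optional Savitzky–Golay pre-filter is exposed).  A float64 caveat: a
4th-order stencil has cancellation noise ~eps/h⁴, so at h = 1 ms the
4th derivative of an O(1) signal carries ~1e-3 absolute noise; at
h = 10 ms both truncation (~h²/6) and roundoff are below 1e-4.

## Edge significance

The null hypothesis for every edge is that all node traces arose
independently.  Per node, an AR model is fitted to the centred trace by
conditional least squares, with all candidate orders scored on a common
sample so BICs are comparable; order q+1 replaces q only when it lowers
BIC by more than 2, and the search stops at the first rejection (a
deliberately conservative rule: white noise selects order 0 ≈ 99% of the
time).  Nonstationary fits fall back to lower orders.  Surrogates draw
every node independently from its own fitted AR model (500-sample
burn-in), preserving node spectra while destroying cross-dependencies;
1000 surrogates by default.  Each edge's null is summarised by a Gaussian
fit and the two-sided p-value `2Φ(−|x−μ|/σ)` is reported uncorrected;
binarization thresholds {0.05, 0.01, 0.005, 0.001} stand in for multiple-
comparison control.  Two-sided tests are used because FC estimates are
signed.  The Gaussian summary follows the procedure this package
implements; an empirical-quantile alternative can be obtained from the
stored null moments only in the Gaussian family, so heavy-tailed nulls are
a known approximation (type-I error is verified to stay in [0.02, 0.10]
at nominal 0.05 for the partial dCov).  `match_sparsity` equalises edge
counts across methods (smallest p, ties by larger |empirical value|, then
row-major position).

## Structure match and topology

Significant FC edges form a boolean mask on the structural matrix; masked
strengths pooled over subjects are the SCS set and their mean the ASCS.
The diagonal is always excluded.  Directed masks are looked up at the same
(sink, source) positions; undirected masks contribute both orientations
once each.  Surrogate SC comes from the generating weights either as
seven equal-mass ordinal bins of |W| with the diagonal fixed at 7
(tracing-database convention; rank-based quantisation is the
least-assumption emulation of an ordinal literature-derived scale) or as
the symmetrised `|W| + |Wᵀ|` with zero diagonal (diffusion convention).

Topology measures (degrees, BFS shortest paths, triangles, global and
local efficiency, clustering, transitivity, modularity) are implemented
for binary directed and undirected graphs, the directed forms summing both
edge orientations so the undirected formulas are exact special cases
(verified numerically against brute-force enumeration).  Infinite
distances contribute zero to efficiency sums.  Directed FC adjacencies are
transposed to the `a_ij = edge i→j` orientation before graph analysis.
Modularity uses the standard Newman form `Q = Σ_u (e_uu − a_u^out a_u^in)`;
a variant that squares the whole bracket is available behind
`printed_form=True` for auditing against sources that print it that way.
The module search is a seeded greedy agglomeration from singletons,
merging the best positive-gain pair until none remains and never returning
a partition worse than the single-module Q = 0.

## Behavior linkage

Confounding measures (age, weight, height, systolic and diastolic blood
pressure, total brain volume — six names are carried although such
confound sets are sometimes counted as five) are regressed out of the
per-subject efficiency values; residuals are correlated with every
non-confound measure on pairwise-complete subjects, measures with more
than 200 missing entries are excluded, and results are ranked by raw
p-value.  Because residuals are exactly orthogonal to the confounds
in-sample, confound loadings inside a measure can only attenuate the
recovered correlation (by inflating the measure's variance), never inject
a spurious one; the attenuation matches `r → c/√(c² + Σβ² + σ²)`.

## Synthetic data: what it emulates and what it does not

`generate_network` draws sparse directed couplings with random sign,
magnitudes ~U(0.5, 1.5) scaled by `0.75·decay/√(N·density)` — roughly half
the self-decay rate per edge.  This scale was chosen from an asymptotic
analysis of the linear system: much weaker coupling leaves the covariance
essentially uncontaminated by propagation (chain/confounder) effects, so
all estimators trivially tie and the conditions no longer probe what the
directed estimators are for; much stronger coupling requires aggressive
rescaling for stability.  Dynamics are Euler–Maruyama with a 10% burn-in
prepended; runs abort if any trajectory exceeds 10× the theoretical
stationary standard deviation (Lyapunov solution).

Edge-recovery experiments use N = 10, density 0.2, T = 20 000 samples at
dt = 0.05 s (20 samples per intrinsic time constant, a record of 1000
correlation times).  At much finer sampling the same wall-clock record
shrinks and every estimator's ranking becomes variance-dominated; the
derivative's white-noise amplification (variance ~σ²/2dt) also grows.
Recovery is scored as ROC-AUC against the *symmetrized* support — an edge
in either direction marks a node pair as connected — because the
structural matrices this mirrors do not resolve direction; with a strictly
directed target, reversed-orientation entries of the partial dCov
(inherent to the linear model: `Δp_ij` contains a `−W_ii·pcov_ij` term)
dominate the comparison instead.

The behavior generator plants one reaction-time-like measure
`coupling·efficiency + confound mix + noise` in a battery of six confounds
and eight pure-noise measures (a deliberately scaled-down battery; with
hundreds of noise measures a true effect of r ≈ 0.2 cannot rank first
reliably at n = 400, which is a fact about multiplicity, not about the
procedure).

Not emulated: scanner noise, motion, physiological confounds, ICA
component mixing, nonlinear neural dynamics.  Passing these experiments
shows the chain is correct and well-calibrated under its own linear
assumptions; it does not certify performance on real recordings, where
component mixing and haemodynamic variability add error sources the
generator does not model.

## Problem sizes used by the validation suite

Oracle agreement uses 200 random instances (≤6 nodes, T = 500);
antisymmetry one 10-node OU run of T = 100 000 at dt = 0.01; sparse-latent
recovery N = 30 with a 5%-dense sparse part and a rank-1 sheet of 10×
smaller entries; AR-bootstrap calibration 20 repeats × 500 surrogates at
T = 2000; Granger calibration/power 20 and 50 runs at T = 5000 on 3
nodes (the minimal genuinely conditional setting); ASCS ordering 20
subjects at T = 5000, 200 surrogates; behavior recovery 100 seeds at
n = 400.  All scenarios are deterministic given their seed.
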