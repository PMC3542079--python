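# Methods

## Model

A membrane-bound molecule occupies one of `n` binding states.  State `j`
has a lateral diffusion coefficient `D_j` (µm²/s) and a dissociation
rate constant `λ_j` (1/s); fluorophore photobleaching at rate `λ_b`
terminates observation indistinguishably from dissociation, so all
observable decays carry the apparent rates `λ'_j = λ_j + λ_b`.  Bound
states interconvert with first-order rates `k_ij` (from `i` to `j`).  A
molecule binds at the origin at `t = 0` in state `j` with probability
`q_j`.

The state-occupancy vector obeys `dQ/dt = K Q` with
`K[j,i] = k_ij (i≠j)` and `K[i,i] = −(λ'_i + Σ_j k_ij)`; the negative
column sums of `K` equal the per-state exit rates to the cytosol, which
is the mass-balance invariant the unit tests assert.  The residence
(survival) probability is `R(t) = Σ_j Q_j(t)`, and `Q_j` / `R` are
evaluated by scaling-and-squaring matrix exponentials, with an
eigendecomposition fast path (`SpectralDecomposition`) used where the
eigenvector matrix is well conditioned (condition number < 1e10;
defective or near-defective rate matrices, which arise at parameter
ties, fall back to the matrix exponential).  The two routes agree to
1e-10 in the tests.  All survival and subpopulation functions are
therefore generic in the number of states rather than written as
explicit bi- or tri-exponential formulas; the two-state closed form
(hand-diagonalized 2×2) serves as an independent oracle in the test
suite, and setting all `k = 0` or `n = 1` reduces the machinery to the
static-mixture and single-exponential special cases exactly.

The position density solves the reaction–diffusion system in transform
space, where the radially symmetric solution is
`Q̂(κ,t) = exp[(K − κ² diag(D)) t] q`, multiplied by `exp(−ε²κ²)` for the
Gaussian localization error of SD `ε` (equivalent to convolving the
real-space density with the error kernel).  The zeroth-order Hankel
inversion `P_j(r,t) = (1/2π)∫ Q̂_j e^{−ε²κ²} J₀(κr) κ dκ` uses
Gauss–Legendre quadrature on `[0, κ_max]` with
`κ_max = sqrt(41 / (min_j D_j·t + ε²))` (the integrand is then below
~1e-18 at the cut-off); the node count is doubled until successive
evaluations agree to 1e-6, and non-convergence raises a diagnostic
error.  `D·t + ε² = 0` is a delta mass and is rejected.  The planar
integral of the density equals `R(t)` to 1e-4, checked per call in the
tests.

The one-lag displacement density is the mixture
`f(Δr) = Σ_j p_j Δr/(2σ_j²) exp(−Δr²/(4σ_j²))` with
`σ_j² = D_j Δt + ε²` (so `E[Δr²] = 4σ_j²` per component); `σ² = 0`
components are point masses handled explicitly.  Mean binding lifetimes
come from first-step analysis, `τ = Σ_j m_j` with `K m = −q`, which
equals `∫R dt` (quadrature-checked to 1e-8).

## Simulator

Trajectories are generated by sampling the exact continuous-time Markov
chain of state switches and dissociation (event-time sampling, valid for
all rate magnitudes), then adding Brownian increments of per-axis
variance `2 D(state) δt` on a fine grid `δt = 1/300 s`.  A fine step
containing a switch uses the state at the step start — an `O(δt)`
approximation equivalent to a discrete-step protocol at 1/300 s; the
simulated conditional position moments agree with the PDE solution
within Monte-Carlo error, and the χ² position-consistency test is
calibrated (uniform p-values across independent seeds).  Positions are
recorded every `Δt = 1/30 s` with i.i.d. Gaussian error of SD
`ε = 0.04 µm` on each coordinate; tracks end at dissociation (or
photobleaching, off by default since the reference protocol bleaches
nothing) or at the 60 s horizon, where they are flagged as censored.
The standard ensemble size is 1000–3000 tracks.

What the generator does *not* emulate: detection/linking failures,
blinking, spot-overlap losses, drift, non-Brownian (confined or
directed) motion, and frame-integration blur.  Pipeline results on real
data therefore depend on tracking quality in ways the tests cannot
probe; the tests establish correctness of the estimators under the
model's own assumptions.

## Inference pipeline

1. **Dissociation test.**  Durations are defined as (frames − 1)·Δt, so
   the fraction of tracks with duration ≥ mΔt estimates `R(mΔt)`
   without discretization bias.  Survival is estimated by the
   Kaplan–Meier product-limit (lifelines), with horizon-censored tracks
   right-censored; single-frame tracks count for survival but
   contribute no displacements (configurable).  A log-linear fit gives
   an overall decay rate; membrane dissociation is reported when its
   95% lower bound exceeds `λ_b` (default 0.1 1/s, the value measured
   on immobilized molecules in fixed cells).
2. **Localization error.**  `ε` is estimated beforehand by fitting
   `MSD(Δt) = 4D*Δt + 4ε²` through the MSD at the first two lags;
   negative intercepts clip to `ε = 0` with a warning.  `ε` is then
   frozen in all mixture likelihoods.
3. **State counting.**  For each candidate `N = 1..N_max` the Rayleigh
   mixture is maximized by EM on the squared displacements (M-step
   `σ_j² = Σγr²/4Σγ`, constrained `σ_j² ≥ ε²`).  Initialization is
   deterministic — component scales at the `N` quantiles of `Δr²/4`
   plus 10 multiplicative perturbation restarts from a fixed policy
   seed — and components are sorted by ascending `D` for
   identifiability.  Samples above 3000 displacements are histogrammed
   onto 4000 equal-width bins and fitted by weighted EM; the
   quantization (sub-nm bin widths) is orders of magnitude below the
   statistical error and leaves the AIC ranking unchanged.
   `AIC = −2 logL + 2(2N−1)` counts `N` diffusion coefficients and
   `N−1` fractions (`ε` is pre-measured, not a fitted parameter); the
   minimum over converged fits sets the state number.  Optional
   confidence intervals for `D` are Wald intervals from the observed
   information matrix; non-identifiable fits (e.g. duplicated
   components) surface as infinite-width intervals.
4. **Decay profiles and transition test.**  Fractions `p_j(t)` are
   re-estimated by EM over the fractions only (diffusion coefficients
   and `ε` frozen) in windows of width `τ` advanced by one frame.  The
   default is `τ = Δt` — single-lag windows — because wider windows
   average the fast early kinetics over the window and visibly bias the
   fast-state rate estimates; `τ` remains configurable.  Each window
   also yields a Fisher-information standard error for `p̂` (component
   overlap, not just counts, limits the precision), which propagates to
   the profiles as `Var(Q) = R²Var(p̂) + p²Var(R̂)`.  Windows with fewer
   than 50 displacements are dropped.  The transition test fits
   weighted log-slopes per state: transitions are reported when early
   slopes differ significantly, all states with usable late data share
   a common late slope (the slowest eigenmode), and at least one
   profile visibly bends between the two regimes.  The late-region
   onset is auto-detected by scanning candidate onsets
   (0.5–5 s); points whose relative profile error exceeds 50% carry no
   slope information and are excluded, so states too sparse to test
   (e.g. a rare fast-dissociating state) simply drop out of the
   comparison.  The test operates at roughly the 5% level; with
   marginal data (two-state switching at 1000 tracks) both false
   positives and false negatives occur at the ~15% level, which matches
   its role as a model-selection heuristic rather than a proof.
5. **Kinetic fit.**  All decay profiles are fitted simultaneously to the
   model `Q_j(t)` by trust-region least squares weighted by the profile
   standard errors, over `λ'_j ≥ 0`, the transition rates on the chosen
   topology (chain by default; the three-state chain 1–2–3 has no
   direct 1↔3 transitions), and `q` in stick-breaking coordinates.
   Initial values come from per-profile log-slopes and the first-window
   fractions.  On noise-free profiles the fit recovers the generating
   parameters to 1e-4 relative.  True rates are reported as
   `λ_j = λ'_j − λ_b`, flagged "not determined" when `λ'_j ≤ λ_b`; the
   transition rates are independent of `λ_b` by construction, which the
   bleaching-enabled recovery test confirms.
6. **Consistency check.**  Radial position histograms (relative to the
   first observed position) at chosen times are compared by χ² with the
   conditional model density `2πr P(r,t)/R(t)`, with tail bins merged to
   keep expected counts ≥ 5.

Single-run sampling spread under the standard two-state protocol
(1000 tracks) is ±5–10% for `D` and up to ±25% for rates and initial
probabilities; three-state fits add two practically non-identifiable
parameters (a dissociation rate far below `λ_b`'s scale and a near-zero
return rate), which are bounded rather than estimated in the tests.
The displacement autocorrelation (mean-removed, per-track normalized,
fitted with `a·exp(−Kt)+b` from lag 1, since lag 0 is dominated by
within-state noise) provides an independent read-out of mobility
switching; for a two-state chain `K` estimates `k_12 + k_21`.

## Membrane-density model

Association frequencies follow from a single bulk measurement: at steady
state `bound/cytosol = μ_total · τ`, so `μ_total = ratio/τ` and
`μ_j = q_j μ_total`.  The lifetime `τ` uses the *apparent* rates by
default — the bundled PTEN parameter sets carry the apparent
(bleaching-uncorrected) per-state decay constants exactly as estimated,
and state 1 of the three-state sets dissociates more slowly than the
fluorophore bleaches, so its true rate is undetermined and only the
apparent-rate lifetime is well defined.  With the non-polarized
three-state set and ratio 0.76 this yields `μ = (0.541, 1.377, 0.357)`
1/s.

A `CompartmentSystem` is a spherical cell (radius 5 µm by default) whose
membrane regions (each with its own kinetic model, `μ` vector and area
fraction) share one cytosolic pool; fluxes are
`dn_r/dt = K_r n_r + μ_r f_r N_cyt` with the dissociation flux returned
to the pool, conserving total molecule number to integrator precision
(LSODA, rtol = atol = 1e-9).  Steady states solve `K n = −μ c` directly;
region density ratios are per unit area and therefore independent of
both the shared cytosol level and the (unreported) anterior area
fraction, for which 0.2 is the configurable default.  Ramped or stepped
perturbations of `μ` enter as piecewise-linear schedules.  An exact
Gillespie mode on the aggregated counts cross-checks the ODE solution
(agreement within Monte-Carlo error at a few thousand molecules); the
ODE mode is the default.

For the uniform reference cell (20000 cytosolic molecules) the bound
total is `0.76 × 20000 = 15200` exactly, i.e. 48.4 molecules/µm² on a
5 µm sphere; the polarized tail/pseudopod parameter sets with the
region-resolved `μ` vectors give a posterior/anterior density ratio of
2.47.

## Numerical and design choices

* Coordinates in µm, times in s, frame indices 0-based; displacements
  are between consecutive recorded frames.
* EM convergence: relative log-likelihood change < 1e-9, ≤ 5000
  iterations; fraction-only EM < 1e-10.
* Kaplan–Meier evaluation at `t − Δt/2` turns the right-continuous step
  estimate into the left-continuous `P(duration ≥ t)` needed on the
  frame grid.
* Initial probabilities are reported from the kinetic fit (step 5), not
  from the first window, so that early dissociation is modeled rather
  than averaged over.
* The stochastic density mode and the windowed-fraction warm starts are
  deterministic given their seeds; all CLI runs with fixed seeds are
  byte-reproducible.

## Problem sizes used in the tests

Simulation-based tests use 1000–3000 tracks (the standard ensemble
sizes); state-count discrimination uses 10 replicates of 2000 tracks,
and three-state parameter recovery averages 3 replicates of 3000
tracks, matching the replicate structure the method is normally
assessed with.
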