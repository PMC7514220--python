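# Methods

## Model

Two groups — `n1` leaders, `n2` followers — each member holding one of two
opinions.  Per-capita flip rates: leaders `3p/4` (opinion 1→2) and `p/4`
(2→1) independent of everyone else; followers `p/4 + μp·y₁₂` and
`3p/4 + μp·y₁₁`, i.e. imitation of the *leader* opinion fractions with
strength μ.  In the large-`n` limit the master equation for the counts
becomes a Fokker–Planck equation in the imbalances `x_i = y_{i,2} − y_{i,1}`
with the linear drift and diagonal diffusion stated in the README.  Three
structural facts drive everything else:

1. the drift is linear, so the sampled process is exactly VAR(1);
2. the diffusion scales as `1/n_i` (weakly multiplicative noise: its state
   gradients vanish for large groups);
3. μ enters the follower diffusivity linearly, so noise amplification and
   synchronising force grow together.

GC is used in its definitional form `GC = ln(Ξ₂/Σ₂₂)`: the log-ratio of the
followers' one-step innovation variance predicted from their own past alone
(Ξ₂) versus with the leaders' past included (Σ₂₂).  For Gaussian (linear)
processes this equals twice the transfer entropy; we report nats (a CLI
flag converts to bits).

## Parameters and defaults

| parameter | meaning | default | why |
|---|---|---|---|
| `p` | intrinsic flip rate (1/time) | 1.0 | sets the time unit; kept explicit rather than absorbed into time so `p` and `Δt` can be varied independently |
| `n1`, `n2` | group sizes | 100, 10 000 | ε = 0.01 — "every leader has a hundred followers", the regime with a pronounced GC maximum |
| `μ` | coupling strength | per-run | grid [0, 100] (hybrid linear/geometric) for curves; `inf` accepted only by the dedicated limit API |
| `Δt` | observation interval | 0.145 | h = pΔt = 0.145 is the package's calibration: it is the root of GC∞(0.01, h) = 0.027 inside [0.14, 0.15], and places the curve maximum near μ ≈ 3 |
| `dt_sim` | Euler step | Δt/10 | keeps the per-substep relaxation (1+μ)p·dt_sim ≲ 0.06 for the μ range of interest |
| `burn_in` | discarded observations | ⌈10/(pΔt)⌉ | ten relaxation times of the slow (leader) component |

Finite-μ routines reject μ > 1e6 (and μ = ∞): beyond that, `e^{−μh}` terms
underflow silently and the dedicated tight-coupling limit API is the
correct tool.

## Closed-form residual covariance

`Σ = ∫₀^Δt e^{Γt} D e^{Γᵀt} dt` with `Γ = p[[−1,0],[μ,−(1+μ)]]` and
`D = diag(σ₁², σ₂²(μ))` is implemented in the antiderivative form

    Σ₁₁ = σ₁² I_mm,   Σ₁₂ = σ₁² (I_mm − I_mn),
    Σ₂₂ = σ₂² I_nn + σ₁² (I_mm − 2 I_mn + I_nn),

with `I_mm = (1−e^{−2h})/2p`, `I_mn = (1−e^{−(2+μ)h})/(p(2+μ))`,
`I_nn = (1−e^{−2(1+μ)h})/(2p(1+μ))`.  This grouping is algebraically
identical to the expanded textbook form but is manifestly regular at μ = 0
(no removable singularity, no special-case branch) and vectorises over
per-state diffusivities.  It is verified against adaptive quadrature of the
matrix integral (`quad_vec`, rel. 1e−10, absolute floor 1e−16·‖D‖ so the
zero-diffusion case is exact) to rel. 1e−9 over μ ∈ {0, …, 100} ×
h ∈ {0.05, 0.1, 0.2}.

## GC routes and their domains

Three independent routes are maintained and cross-checked:

* **closed form** `ln[(S+√(S²−4b′²))/2]` — the primary result;
* **spectral** — the Kolmogorov mean log-spectrum of the driven component,
  `(1/π)∫₀^π ln[(1+b′²+c′²−2b′cos λ)/(1+b′²−2b′cos λ)] dλ`, by adaptive
  quadrature; equals the closed form to 1e−8;
* **state-space** — the innovations (Riccati) recursion
  `P ← APAᵀ + Σ − (APHᵀ)(HPHᵀ)^{−1}(HPAᵀ)`, `H = [0,1]`, iterated from the
  stationary covariance to a 1e−13 relative fixed point; works for any
  stable bivariate VAR(1) including feedback (`d ≠ 0`), where no closed
  form is implemented.

The closed-form and spectral routes require |b′| < 1 and raise otherwise.
Randomly sampled stable triangular models *can* have |b′| ≥ 1 (b′ is an
effective, not a dynamical, coefficient); the state-space route remains
valid there, and the test-suite model sampler restricts to |b′| < 1 where
all three routes are compared.  `gc_closed` returns exactly 0.0 when
c′ = 0, avoiding a ~1e−16 floating-point residue in the μ = 0 case.

Square-root placement in the effective coefficient: c′² = (det Σ/Σ₂₂²)·c².
This choice reproduces the printed tight-coupling limits of b′ and c′ and
is confirmed against the state-space oracle on random models (the release
gate for this ambiguity).

## Simulator

Euler–Maruyama with the convention `dx_i = D⁽¹⁾_i dt + √(D⁽²⁾_ii) dW_i`
(noise intensity equals the diffusion coefficient).  This convention is
fixed by consistency with the VAR(1) residual covariance: a scalar OU
process relaxing at rate p with diffusivity σ² must have lag-h residual
variance σ²(1−e^{−2h})/(2p).  States are clipped to the closed square
[−1, 1]² after each step (D₂₂ can lose positivity outside); at the default
group sizes boundary contact is measure-negligible.  One master seed;
per-μ streams derive from `SeedSequence([master, index])` so multi-μ runs
are reproducible independently of execution order.

Known bias: Euler is weakly first-order, so lag-1 regression on simulated
data recovers the exact transition/residual entries with an O(dt_sim)
bias — about 3% in Σ₂₂ at μ = 3 with dt_sim = Δt/10, halving with the
step.  The moment-level and local-average analyses are insensitive to it;
tests that compare fitted coefficients against the exact discretisation
use dt_sim = Δt/40 so the bias sits below the Monte-Carlo error.  Where an
exact sampler is appropriate (parameter-recovery benchmarks) the package
iterates the VAR(1) recursion directly (`simulate_var1`).

## Estimator hierarchy (curve reproduction)

* **analytic** — mean-substituted diffusivities → closed-form Σ → closed
  form GC.
* **average-noise** — same VAR(1), GC via the state-space route; agrees
  with the analytic curve to 1e−9 (a non-trivial identity check, not a
  tautology).
* **local-average** — GC of the per-state frozen-diffusion VAR(1),
  averaged over the states visited by a seeded simulation.  The per-state
  Σ uses the vectorised closed form (proven equal to the quadrature route
  by the var_map tests); `local_var` for a single state keeps the
  quadrature route.  Agreement with the analytic value at 2×10⁵
  observations: within 5% relative at μ ∈ {1, 3, 10}.  The default
  2×10⁵-point runs keep the test suite fast; a 10⁶-point run tightens the
  Monte-Carlo error by ~2.2× at proportional cost.
* **empirical** — OLS VAR(1) fit (intercept estimated and discarded,
  residual covariance with denominator n−3) followed by the state-space
  GC; a 100-block bootstrap supplies a standard error.  No small-sample
  bias correction is applied; the uncoupled-series bias at n = 10⁵ is
  below 1e−3 nats.

## Cross-correlations

Stationary covariance from the discrete Lyapunov (Yule–Walker) equation
`S = ASAᵀ + Σ` (SciPy's solver), lagged covariances by `C(τ) = A C(τ−1)`.
Sign convention, stamped in every CSV header: positive lag = driver leads.
The μ = ∞ ladder entry is always the analytic limiting model (a → 0,
c → b, limit covariance), never a large finite μ.  Exact moments are used
throughout — no estimation error.

At the default h = 0.145 the peak correlation ρ*(μ) rises with μ up to a
~5e−3 wiggle caused by the discrete-lag argmax; at h ≤ 0.1 the rise is
strictly monotone.  The lag-0 limit value (1+ε)^{−1/2} is h-independent.

## Domain of the "no maximum for n1 ≥ n2" prediction

For ε ≥ 1 the GC curve is monotone increasing and stays below its
tight-coupling plateau over the examined coupling window (μ ≤ 10) at the
default h, and over the full default grid (μ ≤ 100) in the fine-sampling
regime h ≲ 0.02.  This is the regime in which the suppression of the
interior maximum holds.  It is *not* a global property: for any fixed
h > 0 the closed form exhibits a shallow overshoot of the plateau at
μ* ≈ O(1/h) (relative size ~0.6% at h = 0.001 rising to ~18% at
h = 0.145) before decaying back.  The package pins this overshoot in its
own test; users extrapolating the qualitative claim to arbitrary coupling
at coarse sampling should expect it.

## What the synthetic data do and do not show

The simulator realises the diffusion-level model: continuous state space,
Gaussian increments, weakly multiplicative noise.  It does not realise the
underlying finite-`n` jump process (integer opinion counts, Poissonian
flips), non-Gaussian heavy tails, or any misspecification of the VAR
order — so passing tests certify the internal consistency of the
diffusion→VAR(1)→GC chain and the estimators' behaviour on data generated
by that chain, not robustness of GC estimation on real social or neural
recordings.

## Numerical choices

* Riccati iteration: relative tolerance 1e−13, cap 10⁶ iterations
  (convergence is geometric; ~10² iterations in practice).
* Spectral GC quadrature: `scipy.integrate.quad`, eps 1e−12, 200
  subdivisions.
* Grid argmax (`curve_peak`, `max_ccf`): first index wins ties; no
  interpolation — peak locations are reported at grid resolution.
* CSV output: 12 significant digits (`%.12g`), locale-independent;
  re-parsing reproduces the floats exactly.
* Degenerate inputs: zero diffusion → Σ = 0 exactly; c = 0 → GC = 0
  exactly; unstable transition (spectral radius ≥ 1) → explicit error.

## Limitations

* Bidirectional coupling (`d ≠ 0`) is handled only numerically (state
  space); no closed form is exposed.
* The master-equation jump process is out of scope; conclusions about
  finite small groups (n ≲ 20) should not be drawn from the diffusion
  simulator.
* The calibrated h = 0.145 is a package choice: the combination
  (p, n1, n2, Δt) behind the original figures is not uniquely
  recoverable, only ε = 0.01 is; curve *shapes* are therefore checked as
  properties, not point-wise.
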