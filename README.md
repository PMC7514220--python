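# resgc — residual Granger causality in the tight-coupling limit

`resgc` analyses directed predictive information flow in a two-group
stochastic opinion model — `n1` *leaders* who flip opinion intrinsically and
`n2` *followers* who imitate them with coupling strength `μ` — and shows,
analytically and numerically, that the Granger causality (GC) from leaders
to followers does **not** vanish when the coupling becomes infinitely
strong: a residual predictive information flow survives complete
synchronisation pressure whenever ε = n1/n2 > 0.

It is aimed at researchers studying coupling-strength dependence of
directionality measures (GC, transfer entropy) in stochastic population,
network, or neural models, where the folk expectation is a unimodal
GC-vs-coupling curve that decays to zero under synchronisation.

## Model and statistic

At the diffusion (Fokker–Planck) level the opinion imbalances
`x_i = y_{i,2} − y_{i,1} ∈ [−1, 1]` obey a linear drift

    D⁽¹⁾₁ = −p (x₁ − 1/2),
    D⁽¹⁾₂ = −p (x₂ + 1/2 + μ (x₂ − x₁)),

with diagonal demographic noise

    D⁽²⁾₁₁ = (p/n₁)(2 − x₁),
    D⁽²⁾₂₂ = (p/n₂)(2 + x₂ + 2μ(1 − x₁x₂)).

Crucially, the coupling μ enters **both** the synchronising drift and the
follower diffusivity (asymptotically σ₂²(μ) ∼ (3/2)(p/n₂)·μ).

Sampling at interval Δt (h = pΔt) maps the process exactly onto a
triangular VAR(1), `X_t = [[b,0],[c,a]] X_{t−1} + θ_t`, with
`b = e^{−h}`, `a = e^{−(1+μ)h}`, `c = b − a`, and residual covariance Σ
given in closed form by the matrix integral
`Σ = ∫₀^Δt e^{Γt} D e^{Γᵀt} dt`.  For correlated residuals the GC
(leaders → followers, in nats) is

    GC = ln[(S + √(S² − 4b′²))/2],   S = 1 + b′² + c′²,
    b′ = b − (Σ₁₂/Σ₂₂) c,            c′² = (det Σ / Σ₂₂²) c².

As μ → ∞ the residual covariance keeps a second finite semi-axis of order
η = ε / (2(1 − e^{−2h})), so b′ and c′ stay finite and the GC tends to a
strictly positive plateau; at ε = 0.01 and h = 0.145 this residual GC is
≈ 0.027 nats, the lag-0 cross-correlation ceiling is (1+ε)^{−1/2} ≈ 0.995,
and the follower residual variance blows up by a leading-order factor
1/ε = 100.

## Worked example

GC at coupling μ = 3 (close to the curve's maximum), default conditions
ε = 0.01, p = 1, h = 0.145:

```bash
$ resgc gc --mu 3 --method analytic
{
  "gc": 0.5341484098475425,
  "units": "nats",
  "method": "closed_form",
  "b_eff": 0.1501470625696505,
  "c_eff": 0.8346648034297536
}
```

The value 0.534 nats says the followers' one-step prediction error shrinks
by a factor e^{0.534} ≈ 1.71 when the leaders' past is included.  The full
curve shows the unimodal shape with the positive tight-coupling plateau:

```bash
$ resgc curve --mu-grid 0,1,3,10,100 --out out
...
  "gc_at_mu0": 0.0,
  "peak": { "mu": 3.0, "gc": 0.5341484098475425, "interior": true },
  "asymptote": 0.027153422961173016

$ head -4 out/curve.csv
# GC (nats) vs coupling; eps=0.01 h=0.145 seed=20191017
mu,gc_closed,gc_average_noise
0,0,0
1,0.419986662742,0.419986662742
```

GC is exactly zero at μ = 0 (no coupling, `c = 0`), peaks at μ ≈ 3, and
decays to the residual plateau 0.0272 nats instead of zero.  The analytic
closed form and the state-space (average-noise) route agree to 1e−9.
Cross-correlations, including the analytic μ = ∞ ladder entry, come from
`resgc ccf --mu-list 0,1,inf`; the μ = ∞ row at lag 0 reads 0.995037 —
tight coupling never synchronises the groups completely.

Simulation-backed estimators (`--method local_average` or `empirical`) use
a seeded Euler–Maruyama integrator; identical seeds give bit-identical
trajectories.

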