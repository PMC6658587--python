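# Methods

## Models and notation

All three models describe p items answered by one person, with accuracy
x_i ∈ {0, 1} and response time t_i > 0.  "Marginal" distributions condition
on the latent traits with the other observable integrated out; "manifest"
distributions integrate the latents out entirely.

**HM.** Accuracy follows the two-parameter logistic model
p(x_i = 1 | θ) = logistic(α_i(θ + β_i)) with discrimination α_i > 0 and
easiness β_i; log response time is normal, ln t_i | η ~ N(ξ_i − η, 1/φ_i),
with time intensity ξ_i (log-seconds) and precision φ_i > 0.  Accuracies and
times are conditionally independent given (θ, η).  Identification fixes the
latent means at 0 and the ability variance at 1, leaving the speed variance
v_η² and the ability–speed correlation ρ.

**SM.** Items carry deadlines d_i (seconds); the joint density given ability
is an exponential family whose sufficient statistic is the signed residual
score s_i = (2x_i − 1)(d_i − t_i): residual time is gained when correct and
lost when incorrect.  The accuracy marginal is a 2PL with discrimination
d_i; the pseudo-time transform t*_i = t_i (correct) / d_i − t_i (incorrect)
makes accuracies and pseudo-times conditionally independent, the latter
truncated-exponential on (0, d_i) with rate θ + β_i.

**DM.** Unbiased Wiener accumulation: drift θ + β_i, unit volatility,
boundary separation α_i, start at α_i/2, non-decision time T_er (a per-item
field; a shared value is the common special case and the default reading).
The joint density uses the large-time series of the first-passage density;
the accuracy marginal is a 2PL with discrimination α_i.  The model is a
curved exponential family: s_i1 = α_i x_i − β_i t_i is sufficient for θ and
s_i2 = t_i for −½θ².

## Manifest construction

Writing each model as p(x_i, t_i | ζ) = b_i exp(s_iᵀζ)/Z_i(ζ) and giving ζ
the Kac-type density g(ζ) ∝ ∏ Z_i(ζ) k(ζ) with a normal kernel k(m, V),
the normalizers cancel and

    p(x, t) ∝ ∏ b_i · E_k[exp(Sᵀζ)] = ∏ b_i · exp(Sᵀm + ½SᵀVS),

with S = Σ s_i; the posterior of ζ is N(m + VS, V) exactly.  For the curved
DM the scalar moment identity

    E[exp(r₁θ − ½r₂θ²)] = (r₂v² + 1)^{−1/2}
        · exp((r₁²v² + 2r₁m − r₂m²)/(2r₂v² + 2)),   θ ~ N(m, v²),

replaces the MGF.  The derivative-free prefactor (r₂v² + 1)^{−1/2} is the
one the 1-D quadrature oracle confirms; it reduces to the plain normal MGF
at r₂ = 0 and is valid on r₂v² + 1 > 0, outside which the expectation
diverges and a structured error is raised.

Resulting quadratic manifest laws p(q) ∝ exp(qᵀμ + h(q)·qᵀΣq)·ω(q):

| model | q | μ | Σ | h | ω |
|---|---|---|---|---|---|
| HM | (x, ln t) | (α⊙β, φ⊙ξ) | ½(α,vφ)·[[1,−ρ],[−ρ,1]]·(α,vφ)ᵀ, rank 2 | 1 | ∏exp(−½φ_i u_i²) |
| SM (residual) | y⊙r | β | ½·11ᵀ, rank 1 | 1 | 1 |
| SM (pseudo) | (x, t*) | (d⊙β, −β) | ½(d,−1)(d,−1)ᵀ, rank 1 | 1 | 1 |
| DM | (x, t) | (α⊙β, −½β⊙β) | ½(α,−β)(α,−β)ᵀ, rank 1 | 1/(t₊+1) | (t₊+1)^{−1/2}∏series_i |

The SM quadratic term is ½(Σ_i y_i r_i)² — cross products and self terms
included — as the closed form requires; the per-item full conditional
therefore carries a ½r_i² self-interaction term, which `sm_full_conditional`
reports explicitly alongside the corresponding display without it.  The HM
statistic uses s_i2 = −φ_i ln t_i; this is the convention under which the
stated Z_i, the pointwise reconstruction of 2PL × lognormal, and the
manifest Σ above are all mutually consistent (verified numerically to
1e-10).  The DM first-passage series is taken with the weight
n·sin(½πn) on the n-th term; this is the representation under which the
joint density integrates to one and the accuracy marginal is exactly the
2PL, both of which the suite checks by quadrature.

## Normalizability of the HM manifest

The normal base measure ω(u) restricts the admissible speed variance.  The
per-item statement v_η² < min_i(1/φ_i) is necessary; the operative test
implemented as the gate is positive definiteness of diag(φ) − v_η²φφᵀ,
equivalent to v_η²·Σφ_i < 1 (Sherman–Morrison), which is strictly stronger
for p > 1.  `hm_normalizability` reports both, and
`hm_manifest_u_normalization_trace` exhibits the divergence: the
accuracy-summed manifest integral over u ∈ [−L, L]^p stabilizes under L →
2L exactly when the eigenvalue test passes.  Under the restriction, speed
explains v_η²/(1/φ_i + v_η²) of Var(ln t_i), with supremum ½ attained only
in the limit at the highest-precision item.

## Numerics

- **Latent quadrature.**  All oracles use Gauss–Hermite product rules
  centered at the Laplace mode of the log-integrand (numeric mode +
  inverse-Hessian scaling), starting at 61 nodes per dimension and doubling
  until the integral changes by less than 1e-8 relatively.  Everything is
  computed in log space; ratios are log differences.  Improperness is
  detected — mode runaway past 1e3, a non-negative-definite Hessian, or
  log-integrand growth at mode ± 8 SD — and raised as a structured error
  carrying the violated finiteness condition, never clipped.
- **Removable singularities.**  The SM normalizer (e^{dλ} − e^{−dλ})/λ and
  the truncated-exponential normalizer (1 − e^{−dλ})/λ switch to fourth-order
  series inside |λ| < 1e-4 (relative error below 1e-12 at the switch
  radius).
- **DM series.**  Alternating sum truncated when the next term drops below
  tolerance (default 1e-12) in the decreasing regime, so the alternating
  bound applies; the truncation bound is reported on request.  When the
  scaled decision time π²(t − T_er)/(2α²) falls below 0.0171 the true value
  is ~e^{−36} of the leading term and lies under the cancellation floor of
  double precision; the density is then reported as exactly zero.  A term
  budget (default 800) guards the slow-convergence band and raises with
  guidance when exhausted.
- **Normalizing constants.**  Manifest densities are unnormalized by
  default; the joint constant is only ever computed on demand for toy
  p ≤ 3 by summing the 2^p accuracy patterns against time quadrature.  All
  equivalence tests compare log densities up to one shared additive
  constant (spread over ≥ 20 points).

## Samplers and what the synthetic data covers

Latents come from the kernel or from g; g-draws use inverse-CDF on a
2048-node grid spanning the Laplace mode ± 8 SD (one dimension), and in two
dimensions a marginal-then-conditional inverse-CDF on the tensor grid —
exact on the grid, chosen over Gibbs sweeps to avoid any burn-in question.
Observables: HM by direct Bernoulli/lognormal draws; SM by 2PL accuracy and
truncated-exponential pseudo-time inversion (uniform inside |θ + β| < 1e-4)
mapped back through the pseudo-time involution; DM by Bernoulli accuracy
and inverse-CDF of the conditional decision-time law on a 4096-point
cumulative-trapezoid grid (the inversion solves the interpolated CDF
exactly; grids are cached per (θ, item)).  The DM grid starts at
τ = 2e-4·α², below which the remaining mass is of order e^{−625}.

The generator reproduces the models exactly (KS tests at n = 1e5 pass at
the 1% level for all three conditional samplers, and the full chain
g-latents + conditional draws matches manifest expectations).  It emulates
the models' own idealizations only: no person covariates, no trial-level DM
variability, no misfit, no missingness.  Passing tests therefore certify
the internal consistency of the formulas and code, not the adequacy of any
model for empirical response data.

## Problem sizes

Oracle-equivalence tests run on p ≤ 3 item toys with ≥ 20 evaluation
points; sampler fidelity uses n = 1e5 draws per sampler and moment checks
at n = 2e4; the normalizability traces use p ≤ 2 grids up to extent 32.
These sizes put every quadrature comparison at or below 1e-6 while keeping
the whole suite at desk scale.

## Design choices and limitations

- Closed forms require a normal kernel; `manifest_theorem1_log` accepts any
  kernel through its density contract and remains the general oracle.
- No parameter estimation anywhere: item parameters and kernel moments are
  inputs.  Extensions out of scope: biased DM starting points (z ≠ α/2),
  item-specific SM discriminations beyond α_i = d_i, Box–Cox or
  linear-factor time models.
- The posterior under g is normal only for the plain (non-curved) families;
  for the DM the posterior of θ is available through quadrature only.
- |ρ| = 1 in the HM kernel is accepted as a degenerate diagnostic case
  (interaction rank drops to one); the latent decomposition itself requires
  |ρ| < 1 for a positive-definite kernel.
- JSON parameter files round-trip bit-exactly; CSV outputs are written with
  nine decimal digits and are byte-identical under a fixed seed.
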