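# Methods

This note records the mathematical model, the numerical schemes, the
concrete algorithmic choices made in this implementation, and its known
limitations. Empirical statements below are limited to what the test suite
(`tests/`) and the acceptance script (`scripts/acceptance.py`) actually
compute.

## Model

A well-stirred reaction network with N species and M channels is a Markov
jump process on copy-number vectors X ∈ ℕᴺ. Channel j has a mass-action
propensity

  a_j(x) = c_j · Π_i C(x_i, r_ij) · r_ij!

(falling-factorial combinatorics: the number of distinct reactant
multisets), stoichiometric change ν_j, and fires at rate a_j(x). Species can
be flagged *fixed* (chemostatted); their rows of ν are zeroed so reservoir
populations never move (used by the Schlögl system). For deterministic
stages the propensities are evaluated on real-valued states with the same
falling-factorial polynomials.

Two auxiliary objects feed the solvers:

* the drift f(x) = Σ_j ν_j a_j(x) of the reaction-rate equations (RRE), and
* the reaction-coupling matrix f_{jj'} = Σ_i (∂a_j/∂x_i) ν_{ij'}, the
  sensitivity of channel j's rate to firings of channel j' (computed from
  analytic falling-factorial derivatives).

## Reference solvers

**SSA.** Exact Gillespie direct method: exponential waiting time with rate
a₀ = Σ a_j, channel chosen with probability a_j/a₀, frozen at absorbing
states until the horizon.

**Euler τ-leap.** K_j ~ Poisson(a_j(x) τ) with the leap-condition stepsize
bound: for every non-fixed species,

  τ ≤ max(ε x_i / g_i, 1) / |μ_i|  and  τ ≤ max(ε x_i / g_i, 1)² / σ_i²,

where μ_i = Σ_j ν_ij a_j, σ_i² = Σ_j ν_ij² a_j and g_i accounts for the
highest reaction order consuming species i (with the small-population copy
corrections, e.g. g = 2 + 1/(x−1) for a channel consuming two copies). A
step producing a negative population is rejected and retried with τ/2.

## The Stochastic Bulirsch–Stoer step

One SBS macro step of size τ from state X:

1. **Stages.** For q = 1, 2, … the RRE are integrated across [0, τ] with the
   modified midpoint (Gragg) method at n_q = 2q substeps:
   z₀ = X, z₁ = z₀ + h f(z₀), z_{m+1} = z_{m−1} + 2h f(z_m), h = τ/n_q.
   Gragg's smoothed endpoint is computed for diagnostics; the integral below
   uses the raw stages. Cost: n_q + 1 drift evaluations.
2. **Propensity integrals.** Each channel's expected firing count is the
   integral Δa_j = ∫₀^τ a_j(z(s)) ds, approximated by the composite
   trapezoid over the raw stages. Because the stages have an even-power
   error expansion in h, so does this integral.
3. **Extrapolation.** The vectors Δa(n_q) enter a Neville table in h²:
   Y_{q−r,q} = Y_{q−r+1,q} + (Y_{q−r+1,q} − Y_{q−r,q−1}) /
   ((n_q/n_{q−r})² − 1). The scaled column error
   err_q = ‖Y_diag − Y_subdiag‖₂ / (atol + rtol ‖Y_diag‖₂)
   gates convergence: the step accepts at the first window column with
   err_q ≤ 1.
4. **Update.** K_j ~ Poisson(Δa_j^extr) (clamped at 0), X′ = X + Σ ν_j K_j.
   A negative population, a stage leaving the admissible region, or no
   convergence inside the window rejects the step and halves τ.

**Order and stepsize control.** Following the deterministic Bulirsch–Stoer
controller, each tested column proposes

  τ_k = τ · S1 · (S2 / err_k)^{1/(2(k−1)+1)},

and the column minimising the work per unit time W = A_k/τ_k wins, where
A₁ = 3, A_{q+1} = A_q + n_{q+1} counts cumulative drift evaluations. The
next step's window is {k*−1, k*, k*+1} ∩ [2, k_max] (first step: 2…k_max,
k_max = 8). Two implementation choices matter here:

* the growth cap in the general branch is τ·max_growth (default 4); the cap
  τ·S1·max_growth applies only when err vanishes. Capping the general
  branch at τ·S1·max_growth would forbid growth entirely whenever
  S1·max_growth < 1 and deadlock the controller.
* after acceptance one extra first-column row (column k+1) is computed
  purely so an order *increase* can compete in the W-minimisation; the
  state update still uses the accepted column. Without it the controller
  can never leave a low-order regime once entered.

The initial stepsize is τ₀ if given, else a multiple (default 10) of the
expected SSA waiting time 1/a₀(X₀). Both stepsize regimes reported for this
method — few large high-column steps vs. many small column-2 steps — are
reachable depending on τ₀ and the tolerances; the canonical fixture
settings land in the fast high-column regime.

## Degree-of-advancement variant (SBS-DA)

Instead of Δa_j, SBS-DA extrapolates the per-channel firing-count moments
from the frozen-coefficient ODEs

  dμ_j/ds = Σ_{j'} f_{jj'}(X) μ_{j'} + a_j(X),  μ_j(0) = 0,
  dV_j/ds = 2 f_{jj}(X) V_j + dμ_j/ds,       V_j(0) = 0,

integrated with the same modified-midpoint/Neville machinery (two tables;
convergence gated on μ). Sampling is hybrid: K_j ~ Poisson(μ_j) when
μ_j < 10, otherwise round(Normal(μ_j, V_j)) clamped at zero. The corrected
variance removes the Poisson update's O(τ) variance inflation on
self-limiting channels; the price is the frozen-coefficient closure, which
is exact only for linear propensities.

**UBTL.** The unbiased τ-leap comparator uses the leap-condition stepsize
(as the Euler τ-leap) but draws its per-step (μ, V) from the same moment
ODEs at fixed high resolution (n = 8 with one Richardson extrapolation
against n = 16), with the hybrid sampler. It removes the Euler mean bias at
matched stepsizes while doing no order/stepsize adaptation.

## Analysis toolbox and oracles

* **Histograms** live on a global integer grid (origin + m·w per species,
  canonical widths per fixture), so ensembles computed separately are
  comparable. The distributional error is the L¹ distance Σ|p₁ − p₂| ∈
  [0, 2]; the efficiency score is η = (Σ errors)⁻¹ / (Σ runtimes).
* **Weak-order slopes** are least-squares fits of log error against log τ.
* **Yule oracle.** X → 2X has closed-form mean x₀e^{cT} and variance
  x₀e^{cT}(e^{cT} − 1); the chain mean of any fixed-step method with a
  state-linear step parameter obeys an exact recursion
  E[X_{n+1}] = (1 + g)E[X_n], so mean errors are computed without any
  sampling.
* **Truncated CME oracle.** States reachable with all non-fixed counts ≤ a
  cap are enumerated breadth-first; the generator is assembled sparse and
  the distribution advanced with a sparse matrix exponential
  (`expm_multiply`). Outflow past the cap is absorbing; leaked mass above
  10⁻⁸ raises rather than silently biasing the reference.
* **Exact chain propagation.** For effectively one-dimensional systems the
  *full distribution* of a fixed-step numerical chain is propagated: at
  each support point the step's per-channel count law (Poisson with
  deterministic parameter; rounded Gaussian for SBS-DA's large channels) is
  convolved through the support, with boundary mass lumped at the edges.
  Weak errors measured this way against the CME oracle carry zero
  Monte-Carlo noise, which is what makes the order measurements in
  `scripts/acceptance.py` deterministic.

## Measured behaviour

The quantities below are computed by the tests and the acceptance script —
see `results/acceptance.json` for the values on this machine:

* Linear (Yule) mean weak orders: SBS column 1 ≈ 2, column 2 ≈ 4; SBS-DA
  matches (its moment mean coincides with the propensity integral for
  linear systems); Euler τ-leap ≈ 1.
* Nonlinear (binary annihilation) mean weak orders: SBS column 2 stays
  high (> 2.6 at small scale; ≈ 4–5 in the large-population, large-step
  regime), SBS-DA column 2 is capped ≈ 2 by its closure, τ-leap ≈ 1.
* Chain-decay ensembles at canonical settings: the SBS variants and UBTL
  all achieve materially lower L¹ histogram error than the Euler τ-leap
  against the analytic final-time law.

## Limitations

* The per-step *variance* of plain SBS's update is that of a Poisson draw,
  so the weak order of the variance (and of the full distribution) stays
  at 1 even when the mean converges at high order; SBS-DA repairs the
  variance but sacrifices mean order on nonlinear networks.
* The moment closure in SBS-DA and UBTL freezes coefficients at the step
  start; very large UBTL stepsizes (ε ≳ 4 on the decay chain) reintroduce
  a small mean bias through negativity rejections.
* Stages are deterministic RRE solves, so stiff systems are limited by the
  explicit modified midpoint method's stability, not by the extrapolation
  order; no implicit variant is provided.
* The exact chain-propagation oracle requires an effectively
  one-dimensional state space; multi-dimensional weak-order measurements
  fall back to Monte-Carlo.
* The CME oracle scales with the enumerated state count and is practical
  only for small truncations (≈ 10³–10⁴ states).
* Propensities are strictly mass-action; arbitrary rate laws are not
  supported.
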