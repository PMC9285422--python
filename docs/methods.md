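# Methods

## Model

An environment offers a large number of options. Option *i* carries a latent
drift μ_i drawn i.i.d. from a prior p(μ) with mean μ0 and variance σ0²;
evidence about μ_i accumulates as a drift–diffusion process
dx_i = μ_i dt + σ dW_i. The agent must split a total sampling budget T over
the options **before** observing anything — only the endpoints x_i of the
diffusions are seen, never the running paths — and then chooses the option
with the highest posterior-mean drift μ̂_i = E[μ_i | x_i, t_i]. The value of
an allocation t = (t_1, …) is its expected utility

    U(t) = E[ max_i μ̂_i(x_i, t_i) ],

the expected drift of the chosen option averaged over drifts and endpoints.
Unsampled options (t_i = 0) cannot be chosen; an optional "default" variant
adds a fallback worth μ0.

Because the likelihood of μ given (x, t) is Gaussian with variance σ²/t, the
only combination of budget and noise that matters is the dimensionless
**capacity**

    C = σ0² T / σ²,      c_i = σ0² t_i / σ²  per option.

Dividing time at fixed noise and dividing precision 1/σ_i² at fixed common
time are equivalent whenever the c_i match (`duality_convert` /
`duality_invert` realize the bijection).

## Prior families and inference

Three families are supported (all with configurable μ0, σ0):

* **gaussian** — conjugate; μ̂ = (μ0/σ0² + x/σ²) / (1/σ0² + t/σ²); endpoint
  marginal N(μ0 t, σ0² t² + σ² t).
* **uniform** — support [μ0 − √3 σ0, μ0 + √3 σ0] so the variance is σ0²; the
  posterior is a truncated normal whose mean is computed with an
  erfcx-scaled formula that stays accurate ten-plus standard deviations into
  either tail; the marginal CDF has a closed form through the antiderivative
  of Φ, with an asymptotic branch for the deep lower tail.
* **bimodal** — equal-weight mixture of two Gaussians at μ0 ± Δ/2 with
  per-mode SD s. Defaults Δ = 2σ0 and s = σ0; these shape parameters are not
  pinned down by the problem (only the per-mode variance is), so they are
  exposed in the API and CLI. The *overall* variance s² + Δ²/4 — not the σ0
  hyperparameter — enters the capacity, and `CapacityParams.for_prior`
  always uses the prior's actual overall SD.

All marginal CDFs are evaluated in log space so that F^(M−1) =
exp((M−1) log F) remains usable for M ≥ 10⁴.

## Expected utility

**Even allocations** (t_i = T/M on M options): since μ̂ is monotone in x and
the M estimate maps coincide, the choice is equivalent to picking the largest
endpoint, and

    U(M) = M ∫ F(y|t)^{M−1} p(y|t) μ̂(y, t) dy .

For the Gaussian prior this collapses to the closed form
U = μ0 + σ0 (1 + M/C)^{−1/2} E_M, with E_M the expected maximum of M standard
normals (itself a one-dimensional integral). M = 1 and C = 0 return μ0
exactly rather than as quadrature limits.

**Uneven allocations**: with unequal t_i the estimate maps differ and the
correct choice variable is the estimate itself. Writing F_{μ̂_i}(u) =
F_x(μ̂_i^{-1}(u) | t_i) for the CDF of option i's posterior mean,

    U(t) = ∫ u d/du [ Π_i F_{μ̂_i}(u) ] du
         = Σ_i ∫ p(x|t_i) Π_{j≠i} F_x(μ̂_j^{-1}(μ̂_i(x)) | t_j) μ̂_i(x) dx ,

evaluated term by term (product rule) — no numerical differentiation. The
inverse maps are exact for the Gaussian prior (μ̂ is affine in x) and are
monotone-interpolated from dense tables otherwise; equal times share the
identity inverse, so the uneven integral reduces *exactly* to the even one
at even inputs. An alternative reading that picks the option with the
largest raw endpoint rather than the largest estimate defines a slightly
inferior policy when times are uneven; we computed both during development
and implement the estimate-space (optimal-policy) version.

**Quadrature.** Gauss–Legendre with 600 points (800 for uneven) on the
standardized evidence range [−9, 8 + √(2 log M)] marginal SDs; the upper
edge widens with M because the maximum drifts into the tail. Inverse-map
tables use 4001 points over ±15 SDs. Accuracy checks (normalization of the
max density, MC cross-validation, reduction of uneven to even) hold at
1e−6 or better.

## Asymptotics

* **Small capacity.** U = μ0 + σ0 √C · h(M) + O(C) with h(M) = E_M/√M for
  *any* prior — the prior enters only through μ0 and σ0, so the optimal
  breadth is capacity- and prior-independent there. h peaks at M = 5
  (h(5) ≈ 0.5201). For the Gaussian prior the truncation error is actually
  O(C^{3/2}).
* **Large capacity.** Replacing E_M by its extreme-value scale
  b_M = (2 log M − log log M − log 4π)^{1/2} and maximizing the continuous
  relaxation gives, to leading order, M* log M* = C, inverted as
  M* = C/W(C) (principal Lambert branch, via `scipy.special.lambertw`).
  b_M's radicand is negative for very small M; the function refuses there
  instead of clipping — use the exact E_M.
* **Quality of the inversion.** The leading-order inversion sets the scale
  but converges slowly: b_M underestimates E_M by ≈ γ/b_M, and the exact
  integer argmax at C = 10³ is ~51% above C/W(C) (the utility peak is so
  flat that the two differ by < 0.5% in utility). The gap decays only
  logarithmically in C. The same slow convergence makes b_M/E_M reach the
  2%-agreement band only around M ≈ 10⁸.

## Optimization

* `optimal_m`: integer argmax of the even utility; dense scan for M ≤ 32, a
  40-point geometric grid beyond, then full integer refinement in a ±35%
  window around the coarse argmax. Ties break to the smallest M (the
  small-capacity landscape is flat); a flag warns when the utility is still
  rising at `m_max`.
* `simplex_path_utilities`: straight segments from the even point over M
  options (zero-padded) to the even point over M+1 — the segment lies in the
  (M+1)-simplex and is orthogonal to its symmetric subspace. Every even
  point is a critical point by permutation symmetry. The reported optimum is
  the best *symmetric* point. A genuine model feature shows up here: U is
  discontinuous at the simplex boundary, because an option given
  infinitesimal time immediately becomes a choosable fallback with a
  near-prior estimate. Grid points just inside a segment can therefore
  exceed the adjacent even point by a few 1e−4 in utility (the value jumps
  toward the default-option variant as t → 0⁺). The profile records this in
  `interior_exceeds_symmetric`; it does not move the optimal breadth.
* `project_to_simplex`: exact Euclidean projection (sort-and-threshold).
* `stochastic_gradient_ascent`: pathwise (reparametrized) gradient — with
  x_i = μ_i t_i + σ√t_i z_i and a fixed (μ, z) batch per step, only the
  winning option of each trial contributes dμ̂/dt_i through the endpoint and
  the explicit time dependence; analytic for the Gaussian prior, central
  differences otherwise. Step size η_k = 0.1 T/(1 + k/100), batch 10⁴,
  simplex projection after every step. The run stops when *both* the
  full-vector CV and the active-support CV move less than 1e−4 over 200
  steps — the small-capacity landscape is nearly flat, so shorter plateau
  windows stop the run long before the active allocation has equalized.
  Both CVs are recorded: the full-vector CV stays O(1) whenever the
  converged support is smaller than `dims` (e.g. 5 active of 20), while the
  active-support CV going to zero is what expresses "the allocation in use
  is even".

## Monte-Carlo oracle

`simulate_batch` draws drifts from the prior and endpoints from their exact
law N(μ t, σ² t) — the endpoint is the sufficient statistic, so no Euler
paths enter any estimate (a path simulator exists for illustration only).
`mc_expected_utility` returns both the mean chosen posterior mean and the
mean chosen *true* drift; the tower property makes them equal in
expectation, and the pair is the package's central cross-validation against
every quadrature and closed form. All stochastic routines take explicit
seeds and are bit-reproducible.

## Problem sizes and defaults

Defaults mirror the conditions the results are stated under: μ0 = 0.5
throughout; σ0² = 1 for breadth-depth curves and the allocation-landscape
study (T = 0.1, σ = 1, hence C = 0.1); σ0² = 1/12 for prior-family
comparisons so the Gaussian matches the uniform on [0, 1]. The MC
cross-validation grid uses 3 priors × M ∈ {1,2,3,5,8,13} × C ∈ {0.01, 0.1,
1, 10} at 10⁶ trials; the gradient study uses 10 starts × dims = 20 × C ∈
{0.1, 1, 10} with 10³ steps. The power-law fit for the uniform prior uses 15
log-spaced capacities in [10, 10⁴], giving exponent ≈ 0.35 (the C-range is
finite; the asymptotic exponent is 1/3).

## What the synthetic data do and do not show

The generator implements the model itself (i.i.d. drifts, independent
Gaussian endpoint noise, known prior), so passing tests demonstrate internal
correctness and the model's own claims — not that human or animal deciders
face i.i.d. options, know their priors, or observe nothing until the end of
sampling. Sequential stopping, correlated options, and unknown
hyperparameters are outside the model.

## Known limitations

* The bimodal mode separation is a modeling choice (Δ = 2σ0); conclusions
  that depend on it (e.g. the exact M*(C) curve between the Gaussian and
  uniform cases) should be read as one member of a family.
* `optimal_m` assumes a unimodal utility-vs-M profile when refining around
  the coarse argmax; all profiles inspected are unimodal.
* The Lambert-W optimum is a leading-order statement; see above for how far
  the finite-C argmax sits from it.
* The SGA explores a fixed `dims`-simplex; it cannot add options beyond
  `dims`, and multi-start evidence is not a global-optimality proof.
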