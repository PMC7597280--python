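# Methods

## Model

The generative tree model `M(k, γ)` has a binary root `Y ~ Bern(1/2)`,
`k+1` active predictors `X_i = γ^(i−1) Y + ε_i` (`i = 1..k+1`) and one
child `X1^(1) = X_1 + ε_{k+2}`, with i.i.d. standard normal noise. The
actives are conditionally independent given `Y` and form its Markov
blanket; the child is conditionally independent of `Y` given `X_1`. The
decay parameter `γ ∈ (0, 1]` controls how quickly the actives' relevance
falls off: at `γ = 1` they are exchangeable, and as `γ → 0` only `X_1`
matters.

Any subset `X_S` of predictors satisfies `X_S | Y = y ~ N(y·μ_S, Σ_S)`:
`μ_S` has entry `γ^(i−1)` for an active `X_i` and `1` for the child;
`Σ_S` is the identity on actives, with diagonal `2` for the child and a
single unit covariance between `X_1` and the child. Marginally each subset
is therefore an equal-weight two-component Gaussian mixture with shared
covariance.

## Information measures

All information quantities are in nats. The building block is the entropy
of the one-dimensional standardized mixture,

    h(a) = −∫ f log f,   f(x) = [φ(x) + φ(x−a)] / 2,

which is strictly increasing in `a ≥ 0` and bounded between `½log(2πe)`
(coincident components) and `½log(2πe) + log 2` (disjoint components, one
extra bit for the component identity). For a `d`-variate mixture with
mean difference `μ` and shared covariance `Σ`, a rotation plus whitening
argument gives

    H(X)   = h(s) + (d−1)/2·log(2πe) + ½·log det Σ,
    I(X,Y) = h(s) − ½·log(2πe),       s = ‖Σ^(−1/2)μ‖,

so every criterion value in the model reduces to differences of `h` at
explicit arguments. Interaction information is computed from subset
entropies by the alternating Möbius sum (supported to four variables,
which covers the three-way terms the criteria need plus one conditional
level); total correlation uses the same reduction for standardized
mixtures.

## Numerics

`h` is computed with `scipy.integrate.quad` on the truncated interval
`[min(0,a) − T, max(0,a) + T]`, `T = 12` standard deviations, where the
neglected Gaussian tails contribute < 1e-30; default absolute/relative
tolerances are 1e-10, and a quadrature whose error estimate exceeds 100×
the tolerance raises with diagnostics rather than returning silently. The
integrand evaluates `f log f` as 0 when `f < 1e-300`. `h` values are
cached per `(a, tolerance)` key — greedy selection and the crossover scans
revisit the same arguments heavily, and the quadrature dominates cost.
`Σ^(−1/2)` uses the symmetric eigendecomposition, rejecting matrices with
`λ_min < 1e-12·λ_max`; only the scalar `‖Σ^(−1/2)μ‖` enters the results.

`h` accepts `a ≥ 0` only (entropy is reflection-invariant; callers pass
magnitudes). Criterion values within 1e-9 of zero are clamped to exactly
0.0: the child's CMI given `X_1` is identically zero and quadrature noise
should not mask that, and the printed tables use the same convention.
Mixtures must have exactly equal weights; the closed forms above do not
hold otherwise, so unequal weights are rejected rather than approximated.

## Criteria and selection

CMI is evaluated as the chain-rule increment `I(X_{S∪j};Y) − I(X_S;Y)`,
each term an exact subset MI. JMI averages pairwise CMIs over the selected
set; CIFE adds the unweighted interaction sum; mRMR drops the
class-conditional redundancy terms. With an empty conditioning set all
four return the marginal MI `I(X_j;Y)` (JMI's `1/|S|` is undefined at
`|S| = 0`, and the first greedy step is relevance ranking for every
criterion). The only nonzero class-conditional pair dependence is
`I(X_1; X1^(1) | Y) = ½ log 2` (within-class correlation `1/√2`).

Greedy selection breaks ties (within 1e-12) toward the canonical order —
actives by index, child last — which at `γ = 1` makes the exchangeable
actives enter in index order. The optional stopping rule halts before
appending a winner with score ≤ 0 and applies to any criterion (default
off).

Closed per-candidate forms for `X_{k+1}` and `X1^(1)` given `{X_1..X_k}`
are re-derived from the pairwise mixture MIs and exposed alongside the
generic subset computation; tests verify the two routes agree to 1e-9.
For the child's CIFE score the re-derived form is

    (1−k)[h(1/√2) − ½log(2πe)] + Σ_{i=2..k} [h(√(γ^{2(i−1)} + ½)) − h(γ^{i−1})],

whose `γ = 1` slope is `−[h(1) + h(1/√2) − h(√(3/2)) − ½log(2πe)] ≈
−0.0117`; the reference table values (−0.0057 and −0.0083 at `γ = 2/3`)
confirm this grouping. The active's `γ = 1` slope is steeper,
`−[2h(1) − h(√2) − ½log(2πe)] ≈ −0.0215`, so both scores fall linearly and
the child eventually outscores the last active (crossover at `k = 11`).

The JMI crossover finder scans `k` upward with the closed forms; its bound
`10·⌈−log 2 / (2 log γ)⌉ + 50` multiplies the threshold beyond which
`γ^{2k} < ½` makes every summand of the crossover inequality positive, so
the scan terminates with a clear error if the finiteness argument were
ever violated numerically. The boundary at which the `k = 2` crossover
flips lies at `γ ≈ 0.7116`: for `γ ≤ 0.7` the child is admitted by greedy
JMI at step 3, while at `γ = 0.8` the crossover is `k = 3` (step 4). The
crossover is not computed at `γ ≥ 1` (no crossover exists there).

## Simulator and oracles

`sample_gtm` draws from the noise representation with one
`numpy.random.Generator` per call (no global state); identical seeds give
bit-identical batches. The Monte-Carlo entropy oracle averages `−log p`
over draws from the mixture using the exact density via `logsumexp`; it
shares no code with the quadrature path and reports the standard error of
the mean, so quadrature-versus-oracle agreement is asserted within 3 SE.
`mc_mi_with_label` subtracts the *exact* conditional entropy (Gaussian, so
`d/2·log(2πe) + ½·log det Σ`), leaving only the marginal-entropy term
estimated. Oracle sample sizes are 10⁶ for entropy checks (SE ≈ 7e-4,
enough to detect errors at the third decimal) and 10⁵ for moment checks of
sampled batches.

The simulator emulates exactly the model's idealized conditions —
perfectly Gaussian noise, exact Bernoulli(1/2) class balance, known γ. It
does not emulate features of real data (heavy tails, estimated densities,
finite-sample MI estimators), so passing tests validate the theoretical
criterion values and their implementation, not the behavior of empirical
criterion estimators on data.

## Problem sizes and test design

The dual-route identity tests run on `k ≤ 12` (chain rule) and `k ≤ 8`
(JMI/CIFE closed forms) over `γ ∈ {0.3, 0.5, 2/3, 0.8, 1}`; the `γ = 1`
affine-in-`k` checks use `k = 2..30`; the JMI limit at `γ = 1` is checked
at `k = 500`, where the `(k−1)/k` deficiency (≈ 9e-5) sits inside the 1e-4
tolerance; crossover scans in tests stop at `γ = 0.95` (`k* = 9`), since
the scan cost grows roughly quadratically as `γ → 1`. Monte-Carlo
validation uses 20 random mixtures (`d ≤ 3`) plus 10 random model subsets
at `n = 10⁶` with fixed seeds.

## Known limitations

- Only equal-weight, shared-covariance, two-component mixtures; no ≥3
  component mixtures, no closed-form entropy approximations.
- Interaction information limited to p ≤ 4 variables.
- One child variable attached to `X_1`; multi-child or multi-level trees
  are out of scope.
- No finite-sample MI/CMI estimators: the package studies the criteria's
  theoretical values.
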