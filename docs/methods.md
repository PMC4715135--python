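# Methods

## Model and notation

A binary target Y and binary predictor vector **X** ∈ {0,1}^d have joint
law parameterized by θ = (c, **p**, **q**): c = P(Y=0),
pᵢ = P(**X** = xⁱ | Y=0), qᵢ = P(**X** = xⁱ | Y=1), over the cell
enumeration xⁱ = binary expansion of i−1 with X₁ as the most-significant
bit (indices 1..2^d; every module shares this convention). The discrete
coefficient of determination is CoD = (ε₀ − ε)/ε₀ with
ε₀ = min{c, 1−c} and ε = Σᵢ min{c pᵢ, (1−c) qᵢ}; CoD = 0 when ε₀ = 0
(degenerate target, flagged in debug logs).

The Bayesian treatment places independent conjugate priors
c ~ Beta(α, β), **p** ~ Dirichlet(α₁..α_b), **q** ~ Dirichlet(β₁..β_b)
(b = 2^d). Each prior is summarized by a concentration (Δ_c = α+β,
Δ_p = Σαⱼ, Δ_q = Σβⱼ) and a base measure (c₀ = α/Δ_c, p₀ = α⃗/Δ_p,
q₀ = β⃗/Δ_q); larger concentrations peak the prior at the base measure,
with Var(Xᵢ) = a′ᵢ(1−a′ᵢ)/(Δ+1) for a Dirichlet marginal. The posterior
adds the observed counts (n₀, n₁, Uᵢ, Vᵢ) to the hyperparameters.

## The MMSE CoD estimator and its numerics

The minimum-mean-square-error estimator is the posterior mean
E[CoD | Sₙ]. Writing the CoD as a sum over cells of four indicator terms
(split by c < 1/2 vs c ≥ 1/2 and by which class attains the per-cell
minimum) and using the independence of the posteriors, each term is a
nested expectation over three independent Beta variables:
pᵢ ~ Beta(aᵢ, āᵢ), qᵢ ~ Beta(bᵢ, b̄ᵢ), c ~ Beta(α˒, β˒) with
aᵢ = Uᵢ+αᵢ, āᵢ = n₀−Uᵢ+Δ_p−αᵢ, etc.

The evaluation strategy, re-derived from first principles:

1. The inner expectation over pᵢ is a truncated Beta moment,
   E[pᵢ I_{pᵢ<t}] = IB(min(t,1); aᵢ+1, āᵢ)/B(aᵢ, āᵢ), expanded in the
   incomplete-Beta power series IB(x;a,b) = Σⱼ rⱼ(a,b) x^{a+j} with
   rⱼ(a,b) = (−1)ʲ C(b−1,j)/(a+j) (finite polynomial when b is a positive
   integer).
2. The middle expectation over qᵢ expands the resulting powers of qᵢ the
   same way.
3. The outer expectation over c reduces to quantities of the form
   E[(c/(1−c))^m I_{c<1/2}] = IB(1/2; α˒+m, β˒−m)/B(α˒, β˒), which are
   evaluated **directly** through the regularized incomplete Beta function
   rather than a third series level — collapsing the innermost alternating
   sum analytically is a significant stability gain.
4. Only two of the four terms are coded; the other two follow from the
   exact label symmetry (p-shapes ↔ q-shapes, c ↔ 1−c).

The closed form requires α > Δ_p − 1 and β > Δ_q − 1 (on the prior, read
literally); otherwise the c-expectations above would need shapes ≤ 0.

**Precision.** The j,k double sums are alternating with binomial-sized
terms scaled by 1/B(aᵢ, āᵢ) ~ C(n₀+Δ_p, ·); in double precision this
loses roughly one decimal digit per two samples (measured: absolute error
3e−8 at n = 24, 1e−5 at n = 32, 0.04 at n = 40 for the d=1 flat prior).
Because every quantity in the integer-hyperparameter closed form is
rational — rational coefficients, rational Beta functions, exact powers of
1/2 — the default exact path evaluates the sums in exact rational
arithmetic (`fractions.Fraction`), which is immune to cancellation and
costs O(n²) per cell (≈2 ms at n=20, d=1; <0.5 s at n=100, d=3). The
floating-point series path is retained for non-integer hyperparameters,
with lazy term-by-term accumulation: the raw coefficients decay only like
a power law, but each term carries Beta moments that decay geometrically,
so accumulation stops once three consecutive terms fall below 1e−11 of the
running sum (cap 2000 per level). Out-of-domain c-integrals (shape ≤ 0,
reachable only on this path) are computed by log-space quadrature.

`mmse_cod(method="auto")` chooses: exact rational when the prior is valid,
integer, and n + Δ_c ≤ 256; otherwise posterior-sampling Monte Carlo
(default 20 000 draws, standard error reported in the diagnostics).
Non-integer priors always take the Monte-Carlo route under "auto": their
truncated series is verified accurate but orders of magnitude slower per
estimate. Each closed-form term is clamped to [0,1]; a deviation beyond
1e−8 raises a runtime warning.

The standalone `inc_beta` evaluates the series with a reflection
IB(x;a,b) = B(a,b) − IB(1−x;b,a) past the mass split point x = a/(a+b),
keeping the alternating sum on the small tail; this holds its error below
~1e−11 for shapes up to 20. Non-integer series truncation targets a 1e−12
relative tail at x = 1 using a power-law tail estimate (|next| · i/b),
capped at 10 000 terms; at the cap the x=1 sum is good to ~1e−9 absolute.

## The OBP CoD estimator and its exact accuracy

The optimal Bayesian predictor labels cell i by comparing the
posterior-expected joint masses E[c pᵢ] and E[(1−c) qᵢ]; ties go to
label 0 (strict inequality for label 1). Its posterior-expected error
ratio gives ĈoD_OBP = 1 − ε̂/ε̂₀ ∈ [0,1] in O(2^d).

For fixed θ, ε̂/ε̂₀ is a function of the multinomial sufficient statistics
only, so its sampling moments are exact finite sums: condition on
n₀ ~ Binomial(n, c), note ε̂₀ = min(n₀+α, n₁+β)/(n+Δ_c) — ties between the
two normalizers are assigned to the first branch, which is exactly the
indicator that removes double counting in the two-sided decomposition —
and sum the per-cell min-terms against Binomial(Uᵢ | n₀) weights for the
first moment and joint multinomial (Uᵢ, Uⱼ | n₀) weights for the second.
The second-moment pair terms are computed by tensor contraction of the
min-matrices against the joint count pmfs (O(n³) per pair per n₀,
vectorized); `obp_fixed_accuracy(method="auto")` uses the exact path below
a 5e8-flop budget and a seeded Monte-Carlo path with reported standard
errors beyond it. Bias, variance, RMS follow from the two moments with
RMS² = variance + bias² by construction. An exhaustive enumeration oracle
over all count outcomes (budget 1e6 outcomes) verifies the exact formulas
to 1e−10 in the test suite.

## Classical baselines

All four nonparametric estimators plug the histogram (majority-vote)
predictor into 1 − ε̂/ε̂₀ with ε̂₀ = min(n₀, n₁)/n computed on the full
sample (the alternative — re-estimating ε̂₀ within each resampling scheme —
was considered and not adopted; using one ε̂₀ isolates differences to the
conditional-error estimate). Tie rules, fixed and documented: unseen cells
and within-cell ties predict the training majority class; an overall tie
predicts 0. Resubstitution CoD is automatically in [0,1]; leave-one-out,
0.632 bootstrap (B = 100 resamples by default, conventional for this
estimator) and 10-repeated twofold CV (class-stratified halving) can come
out negative and are clipped to 0, with the raw value kept in the
diagnostics. All resampling is driven by an explicit seeded generator.

## Simulation designs

*Global accuracy*: θ is drawn fresh from the prior in every replicate, a
sample of size n is drawn from θ, and every estimator is evaluated on the
same replicate (paired errors, enabling paired standard errors for
ordering comparisons). The standard flat design uses α = β = 2^d + 1 with
uniform Dirichlet weights. Default M = 2000 replicates per sample size and
an n-grid of {10,…,60}; both are configurable, and the grid ceiling
reflects that the study's conclusions stabilize well below n = 100 while
the auto MMSE path switches to Monte Carlo above n + Δ_c = 256.

*Fixed-parameter accuracy*: one benchmark model per d ∈ {1,2,3} with
c* = 0.5 (e.g. p* = (0.6, 0.4) and q* = p* reversed for d = 1), and three
nonflat base measures — matched (= p*), poorly matched (flattened), and
mismatched (reversed) — at three concentration levels
Δ_c/2 = Δ_p = Δ_q ∈ {5, 25, 50} for d=1 ({10,50,100} for d=2,
{20,100,200} for d=3). Base-measure × concentration products are kept
exact even when non-integer; rounding them would change the prior being
studied. OBP rows are computed exactly; all other estimators by Monte
Carlo over samples from the fixed model (default 1000 replicates). On this
design the exact OBP RMS falls by 49–76% across the d=1 grid when the
matched prior is tightened from Δ_p = 5 to Δ_p = 50 — the
prior-informativeness effect the estimators are designed to exploit.

## Boolean network inference

A target gene follows Y = f(**X**) ⊕ N with f = g(X_{i₁},…,X_{i_k}) a
Boolean function of k essential inputs (the wiring {i₁<…<i_k}) and N
Bernoulli noise with P(N=0) = p (the predictive power). Candidate
functions are all truth tables with every input essential (2, 10, 218 for
k = 1, 2, 3 — verified against a brute-force essentiality filter). Truth
tables are stored in logic-table order, lowest wired gene index as the
most-significant bit (AND = 00000001).

Hyperparameters are set empirically per candidate (g, wiring): p is
estimated by the agreement frequency p̂ = n⁻¹ Σ I{f(Xⱼ)=Yⱼ}; with a flat
predictor distribution (sample-frequency estimates of P(**X**) are
unreliable at n ≈ 31 and d = 6) the model implies cell masses
p̂ᵢ ∝ p̂(1−gᵢ) + (1−p̂)gᵢ and q̂ᵢ ∝ p̂gᵢ + (1−p̂)(1−gᵢ), normalized over
cells, and ĉ = mean of the unnormalized p-masses. Hyperparameters are the
ceilings ⌈base × Δ⌉, floored at 1 so the prior stays proper when p̂ is
exactly 0 or 1 (the ceiling of a zero mass would otherwise produce an
improper Dirichlet). At the default Δ = 1 every hyperparameter is 1 — a
flat prior that violates the MMSE closed-form constraint, so the MMSE
variant runs on its seeded Monte-Carlo fallback (20 000 draws per
candidate by default); the OBP variant is closed-form and fast and is the
default estimator.

Selection is two-step: per function g, keep the wiring with the largest
CoD estimate (ties broken uniformly at random from the run's seed); among
the per-function winners, keep the largest p̂ (recomputed on the selected
wiring; again random ties). With the resubstitution estimator the standard
procedure applies: best wiring by resubstitution CoD, logic = plug-in
majority table. k is fixed per run; input order within a wiring is
ascending gene index. The whole selection is a pure function of (data,
seed).

*Synthetic fixtures.* `synth_expression` draws an n × g binary matrix by
ancestral sampling from an acyclic network spec (roots Bernoulli(1/2),
regulated genes apply their table and flip with probability 1−p); cyclic
specs are rejected with a configuration error. `random_network_spec`
emulates the scale of a small binarized tumor-expression panel — 7 genes,
31 samples, k = 3, p = 0.95 by default. What these fixtures do *not*
emulate: real binarization noise structure, correlated roots, genes
regulated by more or fewer than k inputs, and feedback loops — so passing
recovery tests demonstrates correctness of the search procedure under the
generative model, not performance on real expression data.

## Known limitations

- The exact MMSE path is practical to roughly n + Δ_c ≈ 256 (rational
  arithmetic cost grows ~n² per cell with growing integer sizes); beyond
  that the estimator is Monte Carlo with reported SE.
- The exact OBP second moment is O(4^d n⁴) worst case and is gated by a
  flop budget; d = 3 with n ≥ ~60 falls back to Monte Carlo.
- The non-integer-hyperparameter closed form converges slowly when the
  posterior of c concentrates near 1/2 (power-law boundary decay); it is
  provided for verification, not for production loops.
- Priors are independent across c, **p**, **q**; dependent priors are out
  of scope.
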