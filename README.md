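# discod

Bayesian and classical estimation of the **discrete coefficient of
determination (CoD)** between binary predictors and a binary target, with
exact small-sample accuracy analysis and Boolean gene-regulatory-network
inference from binarized expression data.

## The problem

In genomic signal processing, regulatory relationships are often modeled on
binarized expression states: a target gene Y ∈ {0,1} and a vector of
candidate predictor genes **X** ∈ {0,1}^d. The strength of the relationship
is measured by the discrete CoD,

    CoD = (ε₀ − ε) / ε₀,

where ε₀ = min{c, 1−c} is the error of the best constant prediction of Y
(c = P(Y=0)) and ε = Σᵢ min{c pᵢ, (1−c) qᵢ} is the Bayes error of predicting
Y from **X** (pᵢ = P(**X**=xⁱ | Y=0), qᵢ = P(**X**=xⁱ | Y=1)). The CoD lives
in [0,1]; by convention it is 0 when ε₀ = 0. In practice (c, **p**, **q**)
are unknown and the CoD must be estimated from a small i.i.d. sample — the
regime where naive plug-in estimates are badly biased.

`discod` implements a conjugate Bayesian treatment: a Beta prior on c and
Dirichlet priors on **p**, **q** give, after observing class counts n₀, n₁
and per-cell counts Uᵢ, Vᵢ, two estimators:

- **MMSE CoD** — the posterior expectation E[CoD | Sₙ], optimal in mean
  square over the joint law of parameters and samples. Evaluated in closed
  form through the incomplete-Beta power series
  IB(x; a, b) = Σᵢ rᵢ(a,b) x^(a+i), rᵢ(a,b) = (−1)ⁱ C(b−1, i)/(a+i);
  for integer hyperparameters every term is rational and the package
  computes the estimate in exact rational arithmetic (the alternating sums
  are hopeless in floating point beyond n ≈ 30). A posterior-sampling
  Monte-Carlo fallback covers priors outside the closed form's validity
  region (α > Δ_p − 1, β > Δ_q − 1) and large samples.
- **OBP CoD** — the plug-in error ratio of the *optimal Bayesian predictor*,
  ĈoD = 1 − (1/min{n₀+α, n₁+β}) Σᵢ min{(n₀+α)(Uᵢ+αᵢ)/(n₀+Δ_p),
  (n₁+β)(Vᵢ+βᵢ)/(n₁+Δ_q)} — an O(2^d) formula whose fixed-parameter bias,
  variance and RMS this package computes **exactly** by summing the
  estimator over the multinomial sampling distribution of the counts.

Four classical baselines (resubstitution, leave-one-out, 0.632 bootstrap,
10-repeated twofold CV) and the full simulation benchmarks are included, as
is a two-step empirical-Bayes procedure that infers a Boolean regulatory
network (function truth tables + wirings + CoD per target gene) from a
binarized expression matrix.

## Worked example

```python
import numpy as np
from discod import (DiscreteJointModel, PriorSpec, count, mmse_cod,
                    obp_cod, sample, true_cod)
from discod.classical_estimators import resub_cod

# ground truth: a strongly predictive single gene, CoD = 0.6
model = DiscreteJointModel(d=1, c=0.5, p=[0.8, 0.2], q=[0.2, 0.8])
print(true_cod(model))                      # 0.6

cells, y = sample(model, n=20, rng=np.random.default_rng(3))
counts = count(cells, y, d=1)
prior = PriorSpec.flat(1)                   # alpha = beta = 3, flat Dirichlets

print(round(mmse_cod(prior, counts).value, 4))   # 0.4924
print(round(obp_cod(prior, counts).value, 4))    # 0.549
print(round(resub_cod(cells, y, 1).value, 4))    # 0.6667
```

The two Bayesian estimates sit closer to the true value 0.6 than the
optimistic resubstitution estimate (0.667 here; on average resubstitution
overshoots much more strongly — see the benchmarks below).

The same estimators are available from the shell:

```console
$ discod estimate-cod samples.tsv --estimator obp
estimator	cod
obp	0.500000
```

Other subcommands: `exact-obp-accuracy` (exact bias/variance/RMS tables),
`simulate-global` / `simulate-fixed` (the benchmark studies),
`infer-network` / `synth-expression` (Boolean network inference and
synthetic fixtures). All accept `--help` and write plain TSV.

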