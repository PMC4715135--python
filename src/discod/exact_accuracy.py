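"""Exact fixed-parameter accuracy of the OBP CoD estimator, plus Monte-Carlo
machinery for global (prior-averaged) accuracy of any CoD estimator.

For a fixed parameter vector theta = (c, p, q) and sample size n, the OBP
error ratio eps_hat/eps0_hat is a function of the sufficient statistics
(n0, {U_i}, {V_i}) only, so its first two sampling moments can be computed
exactly: condition on n0 ~ Binomial(n, c), note that the constant-predictor
error takes the value min(n0+alpha, n1+beta)/(n+Delta_c), and sum the
per-cell min-terms against exact binomial (first moment) and joint
multinomial (second moment) weights.  Bias, variance and RMS follow from
the two moments; RMS^2 = variance + bias^2 by construction.

An exhaustive enumeration oracle over all multinomial outcomes provides an
independent check for small n, and a Monte-Carlo path covers sizes where
the exact second moment (O(4^d n^4) worst case) is not worth its cost.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats

from .bayes_estimators import (
    CoDEstimate,
    mmse_cod,
    obp_cod,
    obp_errors,
)
from .classical_estimators import b632_cod, cv10x2_cod, loo_cod, resub_cod
from .discrete_model import DiscreteJointModel, sample, true_cod
from .sample_stats import PriorSpec, SampleCounts, count

__all__ = [
    "AccuracyReport",
    "obp_first_moment",
    "obp_second_moment",
    "obp_fixed_accuracy",
    "enumerate_outcomes_oracle",
    "global_accuracy",
    "GlobalAccuracyResult",
    "make_estimator",
    "ESTIMATOR_NAMES",
]

#: flop budget above which obp_fixed_accuracy(method="auto") switches to MC
EXACT_FLOP_BUDGET = 5e8
ENUMERATION_BUDGET = 1_000_000


@dataclass
class AccuracyReport:
    """Bias/variance/RMS of an estimator at one sample size."""

    estimator: str
    n: int
    bias: float
    variance: float
    rms: float
    method: str  # exact | enumerated | monte-carlo
    reps: int | None = None
    se_bias: float | None = None
    se_rms: float | None = None


# ---------------------------------------------------------------------------
# exact sampling moments of the OBP error ratio
# ---------------------------------------------------------------------------

def _cell_terms(prior: PriorSpec, n0: int, n1: int):
    """Per-cell OBP mass terms A_i(k), B_i(l) on the count grids.

    A_i(k) = (n0+a)(k+a_i) / ((n0+Dp)(n+Dc)) for k = 0..n0, and the
    V-analogue; the OBP error given counts is sum_i min{A_i(U_i), B_i(V_i)}.
    """
    n = n0 + n1
    dc = prior.delta_c
    k = np.arange(n0 + 1)
    l = np.arange(n1 + 1)
    A = (n0 + prior.alpha) * (k[None, :] + prior.alpha_vec[:, None]) / (
        (n0 + prior.delta_p) * (n + dc)
    )
    B = (n1 + prior.beta) * (l[None, :] + prior.beta_vec[:, None]) / (
        (n1 + prior.delta_q) * (n + dc)
    )
    return A, B  # shapes (ncells, n0+1), (ncells, n1+1)


def _joint_multinomial(n: int, pi: float, pj: float) -> np.ndarray:
    """P(U_i = k, U_j = r) for (U_i, U_j) marginals of Multinomial(n; pi, pj, rest).

    Returns an (n+1, n+1) matrix, zero where k + r > n.
    """
    rest = max(1.0 - pi - pj, 0.0)
    k = np.arange(n + 1)
    logfact = special.gammaln(k + 1.0)
    K, R = np.meshgrid(k, k, indexing="ij")
    S = n - K - R
    valid = S >= 0
    Sc = np.where(valid, S, 0)
    logp = (
        special.gammaln(n + 1.0)
        - logfact[K]
        - logfact[R]
        - special.gammaln(Sc + 1.0)
        + special.xlogy(K, pi)
        + special.xlogy(R, pj)
        + special.xlogy(Sc, rest)
    )
    out = np.where(valid, np.exp(logp), 0.0)
    return out


def _moments_given_n0(model, prior, n0: int, n1: int, want_second: bool):
    """(E[eps_hat | n0], E[eps_hat^2 | n0]) with exact count weights."""
    A, B = _cell_terms(prior, n0, n1)
    ncells = len(model.p)
    pmf_u = [stats.binom.pmf(np.arange(n0 + 1), n0, model.p[i]) for i in range(ncells)]
    pmf_v = [stats.binom.pmf(np.arange(n1 + 1), n1, model.q[i]) for i in range(ncells)]
    mins = [np.minimum(A[i][:, None], B[i][None, :]) for i in range(ncells)]
    first = sum(float(pmf_u[i] @ mins[i] @ pmf_v[i]) for i in range(ncells))
    if not want_second:
        return first, None
    second = sum(
        float(pmf_u[i] @ (mins[i] ** 2) @ pmf_v[i]) for i in range(ncells)
    )
    for i in range(ncells):
        for j in range(i + 1, ncells):
            PU = _joint_multinomial(n0, model.p[i], model.p[j])
            PV = _joint_multinomial(n1, model.q[i], model.q[j])
            # E[m_i m_j] = sum_{k,l,r,s} M_i[k,l] M_j[r,s] PU[k,r] PV[l,s]
            X = PU.T @ mins[i]          # (r, l)
            Y = X @ PV                  # (r, s)
            second += 2.0 * float(np.sum(mins[j] * Y))
    return first, second


def _ratio_moments(model: DiscreteJointModel, prior: PriorSpec, n: int,
                   want_second: bool):
    dc = prior.delta_c
    first = 0.0
    second = 0.0
    weights = stats.binom.pmf(np.arange(n + 1), n, model.c)
    for n0 in range(n + 1):
        w = weights[n0]
        if w == 0.0:
            continue
        n1 = n - n0
        # eps0_hat = min(n0+alpha, n1+beta)/(n+Delta_c); ties fall in the
        # first branch, which removes the double counting of the event
        # n0+alpha = n1+beta in the two-sided decomposition
        norm = min(n0 + prior.alpha, n1 + prior.beta) / (n + dc)
        m1, m2 = _moments_given_n0(model, prior, n0, n1, want_second)
        first += w * m1 / norm
        if want_second:
            second += w * m2 / norm**2
    return first, (second if want_second else None)


def obp_first_moment(model: DiscreteJointModel, prior: PriorSpec, n: int) -> float:
    """Exact E_{S_n|theta}[eps_hat_OBP / eps0_hat_OBP]."""
    if n < 1:
        raise ValueError("n must be >= 1")
    return _ratio_moments(model, prior, n, want_second=False)[0]


def obp_second_moment(model: DiscreteJointModel, prior: PriorSpec, n: int) -> float:
    """Exact E_{S_n|theta}[(eps_hat_OBP / eps0_hat_OBP)^2]."""
    if n < 1:
        raise ValueError("n must be >= 1")
    return _ratio_moments(model, prior, n, want_second=True)[1]


def _exact_flops(d: int, n: int) -> float:
    ncells = 2**d
    pairs = ncells * (ncells - 1) / 2
    return (n + 1) * pairs * (n / 2 + 1) ** 3


def obp_fixed_accuracy(
    model: DiscreteJointModel,
    prior: PriorSpec,
    n: int,
    method: str = "auto",
    reps: int = 5000,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
) -> AccuracyReport:
    """Fixed-parameter bias, variance and RMS of the OBP CoD estimator.

    method="exact" uses the closed-form sampling moments; "mc" simulates
    ``reps`` datasets; "auto" picks exact while the second-moment cost is
    below ``EXACT_FLOP_BUDGET`` flops.
    """
    cod = true_cod(model)
    if method == "auto":
        method = "exact" if _exact_flops(model.d, n) <= EXACT_FLOP_BUDGET else "mc"
    if method == "exact":
        m1, m2 = _ratio_moments(model, prior, n, want_second=True)
        bias = (1.0 - m1) - cod
        variance = max(m2 - m1**2, 0.0)
        rms = float(np.sqrt(variance + bias**2))
        return AccuracyReport("obp", n, float(bias), float(variance), rms, "exact")
    if method != "mc":
        raise ValueError(f"unknown method {method!r}")
    if rng is None:
        rng = np.random.default_rng(seed)
    errs = np.empty(reps)
    for r in range(reps):
        cells, y = sample(model, n, rng)
        counts = count(cells, y, model.d)
        errs[r] = obp_cod(prior, counts).value - cod
    bias = float(errs.mean())
    variance = float(errs.var(ddof=1))
    rms = float(np.sqrt(np.mean(errs**2)))
    return AccuracyReport(
        "obp", n, bias, variance, rms, "monte-carlo", reps=reps,
        se_bias=float(errs.std(ddof=1) / np.sqrt(reps)),
        se_rms=float((errs**2).std(ddof=1) / np.sqrt(reps) / max(2 * rms, 1e-12)),
    )


# ---------------------------------------------------------------------------
# exhaustive enumeration oracle
# ---------------------------------------------------------------------------

def _compositions(total: int, parts: int):
    """All nonnegative integer vectors of length ``parts`` summing to ``total``."""
    if parts == 1:
        yield (total,)
        return
    for first in range(total + 1):
        for rest in _compositions(total - first, parts - 1):
            yield (first,) + rest


def enumerate_outcomes_oracle(
    model: DiscreteJointModel, prior: PriorSpec, n: int
) -> pd.DataFrame:
    """Exact distribution of the OBP CoD estimate over all samples of size n.

    Returns a DataFrame with one row per sufficient-statistic outcome
    (n0, U, V): its probability, the OBP error ratio and the CoD estimate.
    Probabilities sum to 1 (to ~1e-12); intended as a verification oracle
    for small n and d.
    """
    ncells = 2**model.d
    total_outcomes = sum(
        special.comb(n0 + ncells - 1, ncells - 1, exact=True)
        * special.comb(n - n0 + ncells - 1, ncells - 1, exact=True)
        for n0 in range(n + 1)
    )
    if total_outcomes > ENUMERATION_BUDGET:
        raise ValueError(
            f"enumeration would visit {total_outcomes} outcomes "
            f"(budget {ENUMERATION_BUDGET})"
        )
    rows = []
    logp = np.log(np.where(model.p > 0, model.p, 1.0))
    logq = np.log(np.where(model.q > 0, model.q, 1.0))
    logfact = special.gammaln(np.arange(n + 2) + 1.0)

    def _multinomial_pmf(counts_vec, total, probs, logprobs):
        counts_vec = np.asarray(counts_vec)
        if ((counts_vec > 0) & (probs == 0)).any():
            return 0.0
        return float(
            np.exp(
                logfact[total]
                - logfact[counts_vec].sum()
                + (counts_vec * logprobs).sum()
            )
        )

    for n0 in range(n + 1):
        n1 = n - n0
        w = float(stats.binom.pmf(n0, n, model.c))
        for U in _compositions(n0, ncells):
            pu = _multinomial_pmf(U, n0, model.p, logp)
            for V in _compositions(n1, ncells):
                pv = _multinomial_pmf(V, n1, model.q, logq)
                prob = w * pu * pv
                counts = SampleCounts(model.d, np.array(U), np.array(V))
                eps, eps0 = obp_errors(prior, counts)
                ratio = eps / eps0
                rows.append(
                    {"n0": n0, "U": U, "V": V, "prob": prob,
                     "ratio": ratio, "cod": 1.0 - ratio}
                )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# global (prior-averaged) Monte-Carlo accuracy
# ---------------------------------------------------------------------------

ESTIMATOR_NAMES = ("mmse", "obp", "resub", "loo", "b632", "cv10x2")


def make_estimator(
    name: str,
    prior: PriorSpec,
    d: int,
    rng: np.random.Generator,
    mmse_method: str = "auto",
    mmse_mc_reps: int = 20_000,
    b632_B: int = 100,
):
    """A uniform callable (cells, y) -> CoD value for a named estimator."""
    if name == "mmse":
        def est(cells, y):
            return mmse_cod(
                prior, count(cells, y, d), method=mmse_method,
                mc_reps=mmse_mc_reps, rng=rng,
            ).value
    elif name == "obp":
        def est(cells, y):
            return obp_cod(prior, count(cells, y, d)).value
    elif name == "resub":
        def est(cells, y):
            return resub_cod(cells, y, d).value
    elif name == "loo":
        def est(cells, y):
            return loo_cod(cells, y, d).value
    elif name == "b632":
        def est(cells, y):
            return b632_cod(cells, y, d, B=b632_B, rng=rng).value
    elif name == "cv10x2":
        def est(cells, y):
            return cv10x2_cod(cells, y, d, rng=rng).value
    else:
        raise ValueError(f"unknown estimator {name!r}")
    return est


@dataclass
class GlobalAccuracyResult:
    """Monte-Carlo global accuracy: summary table plus per-replicate errors.

    ``errors[name]`` holds estimate - true CoD per replicate, enabling
    paired comparisons between estimators on the shared replicates.
    """

    table: pd.DataFrame
    errors: dict

    def report(self, name: str) -> AccuracyReport:
        row = self.table.set_index("estimator").loc[name]
        return AccuracyReport(
            name, int(row["n"]), row["bias"], row["variance"], row["rms"],
            "monte-carlo", reps=int(row["reps"]),
            se_bias=row["se_bias"], se_rms=row["se_rms"],
        )


def global_accuracy(
    prior: PriorSpec,
    d: int,
    n: int,
    M: int,
    estimators=ESTIMATOR_NAMES,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
    mmse_method: str = "auto",
) -> GlobalAccuracyResult:
    """Global bias/variance/RMS: theta ~ prior, then S_n | theta, M replicates.

    Every estimator sees the same replicate datasets, so their per-replicate
    errors are paired.
    """
    if M < 1:
        raise ValueError("M must be >= 1")
    if rng is None:
        rng = np.random.default_rng(seed)
    fns = {name: make_estimator(name, prior, d, rng, mmse_method=mmse_method)
           for name in estimators}
    errors = {name: np.empty(M) for name in estimators}
    for m in range(M):
        c = rng.beta(prior.alpha, prior.beta)
        p = rng.dirichlet(prior.alpha_vec)
        q = rng.dirichlet(prior.beta_vec)
        model = DiscreteJointModel(d, c, p, q)
        cod = true_cod(model)
        cells, y = sample(model, n, rng)
        for name, fn in fns.items():
            errors[name][m] = fn(cells, y) - cod
    rows = []
    for name in estimators:
        e = errors[name]
        rms = float(np.sqrt(np.mean(e**2)))
        rows.append({
            "estimator": name, "n": n, "reps": M,
            "bias": float(e.mean()),
            "variance": float(e.var(ddof=1)),
            "rms": rms,
            "se_bias": float(e.std(ddof=1) / np.sqrt(M)),
            "se_rms": float((e**2).std(ddof=1) / np.sqrt(M) / max(2 * rms, 1e-12)),
        })
    return GlobalAccuracyResult(pd.DataFrame(rows), errors)
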