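"""Bayesian CoD estimators: the posterior-mean (MMSE) estimator and the
optimal-Bayesian-predictor (OBP) estimator.

MMSE estimator
--------------
The minimum mean-square error estimator is the posterior expectation
E[CoD | S_n].  Under the Beta-Dirichlet model the CoD decomposes, per
predictor cell i, into four terms of the form

    E[ p_i I_{p_i < ((1-c)/c) q_i} I_{c < 1/2} ],     (and the three
    symmetric companions with c >= 1/2 and the roles of p and q swapped)

where c, p_i, q_i are independent posterior Beta variables.  Each term is
reduced to nested incomplete-Beta series: the innermost expectation over p_i
is a truncated Beta moment, the expectation over q_i expands the resulting
incomplete-Beta into its power series, and the final expectation over c is
an incomplete-Beta evaluation at 1/2 which is computed directly through the
regularized incomplete Beta function (this collapses the last alternating
sum analytically, which matters for numerical stability).  For integer
hyperparameters all series are finite polynomials and the result is exact up
to floating-point cancellation; for non-integer hyperparameters the series
are truncated adaptively.

The closed form exists only when alpha > Delta_p - 1 and beta > Delta_q - 1;
otherwise the estimator falls back to posterior-sampling Monte Carlo.  For
integer hyperparameters every quantity in the closed form is rational
(finite alternating sums of rationals and powers of 1/2), so the default
closed-form path evaluates them in exact rational arithmetic -- the
alternating sums cancel catastrophically in floating point beyond n ~ 30,
while exact arithmetic is immune and still costs only O(n^2) per cell.

OBP estimator
-------------
The optimal Bayesian predictor assigns to cell i the label with the larger
posterior-expected joint mass; its posterior-expected errors give the simple
closed form

    CoD_OBP = 1 - (1/min{n0+a, n1+b}) *
              sum_i min{ (n0+a)(U_i+a_i)/(n0+Dp), (n1+b)(V_i+b_i)/(n1+Dq) },

which lies in [0, 1] and costs O(2^d).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from fractions import Fraction
from math import comb

import numpy as np
from scipy import special

from .beta_dirichlet import log_beta_fn
from .discrete_model import true_cod_batch
from .sample_stats import PriorSpec, SampleCounts, check_mmse_validity, posterior

__all__ = [
    "CoDEstimate",
    "mmse_cod",
    "mmse_cod_mc",
    "obp_predict",
    "obp_errors",
    "obp_cod",
]

logger = logging.getLogger(__name__)

#: rational path: largest n + Delta_c for which the exact arithmetic stays
#: comfortably sub-second (runtime guard, not a precision limit)
RATIONAL_SIZE_CAP = 256
#: default replicate count for the Monte-Carlo fallback
DEFAULT_MC_REPS = 20_000
_CLAMP_WARN = 1e-8
_INT_TOL = 1e-9


def _all_integer(prior: PriorSpec) -> bool:
    vals = np.concatenate(
        ([prior.alpha, prior.beta], prior.alpha_vec, prior.beta_vec)
    )
    return bool(np.all(np.abs(vals - np.round(vals)) < _INT_TOL))


@dataclass
class CoDEstimate:
    """A CoD estimate with its estimator tag and optional diagnostics."""

    value: float
    estimator: str
    diagnostics: dict = field(default_factory=dict)

    def __float__(self) -> float:
        return float(self.value)


# ---------------------------------------------------------------------------
# OBP estimator
# ---------------------------------------------------------------------------

def _obp_masses(prior: PriorSpec, counts: SampleCounts):
    """Posterior-expected joint masses E[c p_i] and E[(1-c) q_i] per cell."""
    n = counts.n
    denom = n + prior.alpha + prior.beta
    m0 = (counts.n0 + prior.alpha) / denom * (counts.U + prior.alpha_vec) / (
        counts.n0 + prior.delta_p
    )
    m1 = (counts.n1 + prior.beta) / denom * (counts.V + prior.beta_vec) / (
        counts.n1 + prior.delta_q
    )
    return m0, m1


def obp_predict(prior: PriorSpec, counts: SampleCounts, i: int) -> int:
    """OBP label for cell i (1-based): 1 iff the Y=1 posterior mass is
    strictly larger; ties map to 0."""
    m0, m1 = _obp_masses(prior, counts)
    return int(m0[i - 1] < m1[i - 1])

def obp_errors(prior: PriorSpec, counts: SampleCounts) -> tuple[float, float]:
    """(eps_hat_OBP, eps0_hat_OBP): posterior-expected errors of the OBP and
    of the best constant predictor."""
    m0, m1 = _obp_masses(prior, counts)
    eps = float(np.minimum(m0, m1).sum())
    denom = counts.n + prior.alpha + prior.beta
    eps0 = min(counts.n0 + prior.alpha, counts.n1 + prior.beta) / denom
    return eps, eps0


def obp_cod(prior: PriorSpec, counts: SampleCounts) -> CoDEstimate:
    """The OBP CoD estimate 1 - eps_hat/eps0_hat, guaranteed to lie in [0, 1]."""
    eps, eps0 = obp_errors(prior, counts)
    value = 1.0 - eps / eps0
    return CoDEstimate(float(np.clip(value, 0.0, 1.0)), "obp")


# ---------------------------------------------------------------------------
# MMSE estimator: closed form
# ---------------------------------------------------------------------------

#: per-level cap and consecutive-small-term count for the lazy series
_SERIES_LEVEL_CAP = 2000
_SERIES_PATIENCE = 3


def _log_quad(lo: float, hi: float, e1: float, e2: float, offset: float) -> float:
    """int_lo^hi exp(e1*ln(u) + e2*ln(1-u) - offset) du, kept in log space."""
    from scipy import integrate

    def f(u):
        return np.exp(e1 * np.log(u) + e2 * np.log1p(-u) - offset)

    val, _ = integrate.quad(f, lo, hi, limit=200)
    return float(val)


def _g_lt(m: float, A: float, B: float, lab: float) -> float:
    """E[(c/(1-c))^m I_{c<1/2}] for c ~ Beta(A, B); lab = log B(A, B)."""
    if B - m > 0:
        return float(
            np.exp(log_beta_fn(A + m, B - m) - lab) * special.betainc(A + m, B - m, 0.5)
        )
    # shape B - m <= 0: the integral over [0, 1/2] still converges
    return _log_quad(0.0, 0.5, A + m - 1.0, B - m - 1.0, lab)


def _g_ge(m: float, A: float, B: float, lab: float) -> float:
    """E[((1-c)/c)^m I_{c>=1/2}] for c ~ Beta(A, B); lab = log B(A, B)."""
    if A - m > 0:
        return float(
            np.exp(log_beta_fn(B + m, A - m) - lab) * special.betainc(B + m, A - m, 0.5)
        )
    return _log_quad(0.5, 1.0, A - m - 1.0, B + m - 1.0, lab)


def _coeff_iter(a: float, b: float):
    """Series coefficients r_i(a, b) by recurrence, lazily (finite for
    integer b, else until the caller stops)."""
    int_b = abs(b - round(b)) < _INT_TOL
    nmax = round(b) if int_b else _SERIES_LEVEL_CAP
    r = 1.0 / a
    for i in range(nmax):
        yield i, r
        r *= -(b - 1.0 - i) / (i + 1.0) * (a + i) / (a + i + 1.0)


def _lazy_sum(term_iter) -> tuple[float, int]:
    """Accumulate terms until several consecutive ones are negligible.

    The individual terms carry Beta moments that decay geometrically, even
    when the raw binomial coefficients decay only like a power law, so a
    contribution-based stop is both safe and fast.
    """
    acc = 0.0
    small = 0
    used = 0
    for term in term_iter:
        acc += term
        used += 1
        if abs(term) < 1e-11 * max(abs(acc), 1e-300):
            small += 1
            if small >= _SERIES_PATIENCE:
                break
        else:
            small = 0
    return acc, used


def _term_lt(a, abar, b, bbar, A, B, tol) -> tuple[float, int]:
    """E[p I_{p < ((1-c)/c) q} I_{c<1/2}] for independent p ~ Beta(a, abar),
    q ~ Beta(b, bbar), c ~ Beta(A, B).  Returns (value, series terms used)."""
    lab_c = log_beta_fn(A, B)
    lab_p = log_beta_fn(a, abar)
    lab_q = log_beta_fn(b, bbar)

    # cache of E[(c/(1-c))^(b+k) I_{c<1/2}], grown lazily
    gvals: list[float] = []

    def _g(k: int) -> float:
        while len(gvals) <= k:
            gvals.append(_g_lt(b + len(gvals), A, B, lab_c))
        return gvals[k]

    nterms = 0

    def _outer():
        nonlocal nterms
        for j, r1j in _coeff_iter(a + 1.0, abar):
            inner, used = _lazy_sum(
                r2k * _g(k) for k, r2k in _coeff_iter(a + b + j + 1.0, bbar)
            )
            nterms += used + 1
            yield r1j * inner

    acc, _ = _lazy_sum(_outer())
    t1a = acc * np.exp(-lab_p - lab_q)

    ep = a / (a + abar)                              # E[p]
    t1b = ep * float(special.betainc(A, B, 0.5))     # E[p] P(c < 1/2)

    acc3, used3 = _lazy_sum(
        r3j * _g(j) for j, r3j in _coeff_iter(b, bbar)
    )
    nterms += used3
    t1c = ep * acc3 * np.exp(-lab_q)

    return t1a + t1b - t1c, nterms


def _term_ge(a, abar, b, bbar, A, B, tol) -> tuple[float, int]:
    """E[(c/(1-c)) p I_{p < ((1-c)/c) q} I_{c>=1/2}] for the same model.

    With c >= 1/2 the threshold ((1-c)/c) q is always < 1, so no indicator
    split is needed.
    """
    lab_c = log_beta_fn(A, B)
    lab_p = log_beta_fn(a, abar)
    lab_q = log_beta_fn(b, bbar)

    def _terms():
        for j, r1j in _coeff_iter(a + 1.0, abar):
            # E[q^(a+1+j)] = B(a+b+j+1, bbar)/B(b, bbar)
            lmom = special.betaln(a + b + j + 1.0, bbar) - lab_q
            yield r1j * np.exp(lmom) * _g_ge(a + j, A, B, lab_c)

    acc, used = _lazy_sum(_terms())
    return acc * np.exp(-lab_p), used


def _mmse_closed_form(prior: PriorSpec, counts: SampleCounts, tol: float):
    post = posterior(prior, counts)
    A, B = post.alpha_s, post.beta_s
    total = 0.0
    nterms = 0
    for a, abar, b, bbar in zip(
        post.alpha_s_vec, post.alpha_bar_s_vec, post.beta_s_vec, post.beta_bar_s_vec
    ):
        t1, n1_ = _term_lt(a, abar, b, bbar, A, B, tol)
        t2, n2_ = _term_ge(a, abar, b, bbar, A, B, tol)
        # label symmetry: swap (p-shapes <-> q-shapes, c <-> 1-c)
        t4, n4_ = _term_lt(b, bbar, a, abar, B, A, tol)
        t3, n3_ = _term_ge(b, bbar, a, abar, B, A, tol)
        nterms += n1_ + n2_ + n3_ + n4_
        for t in (t1, t2, t3, t4):
            if t < -_CLAMP_WARN or t > 1.0 + _CLAMP_WARN:
                warnings.warn(
                    f"MMSE closed-form term {t:.3e} outside [0,1]; "
                    "alternating-series cancellation is degrading precision",
                    RuntimeWarning,
                    stacklevel=3,
                )
            total += min(max(t, 0.0), 1.0)
    return 1.0 - total, nterms


# ---------------------------------------------------------------------------
# MMSE estimator: exact rational arithmetic (integer hyperparameters)
# ---------------------------------------------------------------------------

def _rbeta(a: int, b: int) -> Fraction:
    """B(a, b) = (a-1)!(b-1)!/(a+b-1)! as an exact rational."""
    return Fraction(1, (a + b - 1) * comb(a + b - 2, a - 1))


def _rcoeffs(a: int, b: int) -> list[Fraction]:
    """Exact series coefficients r_j(a, b) = (-1)^j C(b-1, j)/(a+j)."""
    return [Fraction((-1) ** j * comb(b - 1, j), a + j) for j in range(b)]


def _rg_lt(m: int, A: int, B: int) -> Fraction:
    """E[(c/(1-c))^m I_{c<1/2}] = IB(1/2; A+m, B-m)/B(A, B), exactly."""
    half = Fraction(1, 2)
    s = sum(r * half ** (A + m + l) for l, r in enumerate(_rcoeffs(A + m, B - m)))
    return s / _rbeta(A, B)


def _rg_ge(m: int, A: int, B: int) -> Fraction:
    """E[((1-c)/c)^m I_{c>=1/2}] = IB(1/2; B+m, A-m)/B(A, B), exactly."""
    half = Fraction(1, 2)
    s = sum(r * half ** (B + m + l) for l, r in enumerate(_rcoeffs(B + m, A - m)))
    return s / _rbeta(A, B)


def _rterm_lt(a: int, abar: int, b: int, bbar: int, A: int, B: int) -> Fraction:
    """Rational E[p I_{p < ((1-c)/c) q} I_{c<1/2}]."""
    bq = _rbeta(b, bbar)
    g = [_rg_lt(b + k, A, B) for k in range(bbar)]
    t1a = Fraction(0)
    for j, r1j in enumerate(_rcoeffs(a + 1, abar)):
        r2 = _rcoeffs(a + b + j + 1, bbar)
        t1a += r1j * sum(rk * g[k] for k, rk in enumerate(r2))
    t1a /= _rbeta(a, abar) * bq
    ep = Fraction(a, a + abar)
    p_half = sum(
        r * Fraction(1, 2) ** (A + l) for l, r in enumerate(_rcoeffs(A, B))
    ) / _rbeta(A, B)
    t1c = ep * sum(rj * g[j] for j, rj in enumerate(_rcoeffs(b, bbar))) / bq
    return t1a + ep * p_half - t1c


def _rterm_ge(a: int, abar: int, b: int, bbar: int, A: int, B: int) -> Fraction:
    """Rational E[(c/(1-c)) p I_{p < ((1-c)/c) q} I_{c>=1/2}]."""
    acc = Fraction(0)
    for j, r1j in enumerate(_rcoeffs(a + 1, abar)):
        acc += r1j * _rbeta(a + b + j + 1, bbar) * _rg_ge(a + j, A, B)
    return acc / (_rbeta(a, abar) * _rbeta(b, bbar))


def mmse_cod_rational(prior: PriorSpec, counts: SampleCounts) -> Fraction:
    """Exact rational value of the closed-form MMSE CoD estimate.

    Requires integer hyperparameters satisfying the validity constraint;
    the float paths are checked against this in the test suite.
    """
    valid, msg = check_mmse_validity(prior)
    if not valid:
        raise ValueError(f"closed-form MMSE not applicable: {msg}")
    if not _all_integer(prior):
        raise ValueError("rational closed form requires integer hyperparameters")
    alpha, beta = round(prior.alpha), round(prior.beta)
    av = [round(x) for x in prior.alpha_vec]
    bv = [round(x) for x in prior.beta_vec]
    U = [int(x) for x in counts.U]
    V = [int(x) for x in counts.V]
    n0, n1 = sum(U), sum(V)
    A, B = n0 + alpha, n1 + beta
    dp, dq = sum(av), sum(bv)
    total = Fraction(0)
    for i in range(len(av)):
        a, abar = U[i] + av[i], n0 - U[i] + dp - av[i]
        b, bbar = V[i] + bv[i], n1 - V[i] + dq - bv[i]
        total += _rterm_lt(a, abar, b, bbar, A, B)
        total += _rterm_ge(a, abar, b, bbar, A, B)
        total += _rterm_lt(b, bbar, a, abar, B, A)
        total += _rterm_ge(b, bbar, a, abar, B, A)
    return 1 - total


# ---------------------------------------------------------------------------
# MMSE estimator: Monte-Carlo posterior expectation
# ---------------------------------------------------------------------------

def mmse_cod_mc(
    prior: PriorSpec,
    counts: SampleCounts,
    reps: int = DEFAULT_MC_REPS,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
) -> CoDEstimate:
    """E[CoD | S_n] by averaging the true CoD over posterior draws of theta."""
    if reps < 1:
        raise ValueError("reps must be >= 1")
    if rng is None:
        rng = np.random.default_rng(seed)
    post = posterior(prior, counts)
    c = rng.beta(post.alpha_s, post.beta_s, size=reps)
    p = rng.dirichlet(post.alpha_s_vec, size=reps)
    q = rng.dirichlet(post.beta_s_vec, size=reps)
    cods = true_cod_batch(c, p, q)
    se = float(cods.std(ddof=1) / np.sqrt(reps)) if reps > 1 else float("nan")
    return CoDEstimate(
        float(cods.mean()),
        "mmse",
        {"method": "monte-carlo", "reps": reps, "se": se},
    )


def mmse_cod(
    prior: PriorSpec,
    counts: SampleCounts,
    method: str = "auto",
    series_tol: float = 1e-12,
    mc_reps: int = DEFAULT_MC_REPS,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
) -> CoDEstimate:
    """The Bayesian MMSE CoD estimate E[CoD | S_n].

    Parameters
    ----------
    method:
        "exact" forces the closed form (raises if the prior violates the
        validity constraint): exact rational arithmetic for integer
        hyperparameters, adaptively truncated float series otherwise.
        "mc" forces posterior sampling.  "auto" uses the closed form when it
        is valid and numerically trustworthy and falls back to Monte Carlo
        otherwise (reporting why in the diagnostics).
    """
    valid, msg = check_mmse_validity(prior)
    if method not in ("auto", "exact", "mc"):
        raise ValueError(f"unknown method {method!r}")
    if method == "exact" and not valid:
        raise ValueError(f"closed-form MMSE not applicable: {msg}")
    integer = _all_integer(prior)
    if method == "auto":
        # non-integer priors are routed to Monte Carlo: their truncated
        # series is accurate but orders of magnitude slower per estimate
        if valid and integer and counts.n + prior.delta_c <= RATIONAL_SIZE_CAP:
            method = "exact"
        else:
            logger.debug("MMSE auto path -> Monte Carlo (valid=%s)", valid)
            method = "mc"
    if method == "mc":
        est = mmse_cod_mc(prior, counts, reps=mc_reps, rng=rng, seed=seed)
        est.diagnostics["fallback_reason"] = None if valid else msg
        return est
    if integer:
        value = float(mmse_cod_rational(prior, counts))
        return CoDEstimate(value, "mmse", {"method": "closed-form-rational"})
    value, nterms = _mmse_closed_form(prior, counts, series_tol)
    value = float(np.clip(value, 0.0, 1.0))
    return CoDEstimate(
        value, "mmse", {"method": "closed-form-series", "series_terms": nterms}
    )
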