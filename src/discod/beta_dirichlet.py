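"""Beta and Dirichlet numerics used throughout the package.

The central primitive is the power-series representation of the incomplete
Beta function,

    IB(x; a, b) = int_0^x u^(a-1) (1-u)^(b-1) du = sum_i r_i(a, b) x^(a+i),

with coefficients r_i(a, b) = (-1)^i C(b-1, i) / (a + i).  When b is a
positive integer the series is a finite polynomial with exactly b terms;
otherwise it is an infinite series (convergent for x in [0, 1]) that is
truncated adaptively.  The posterior-expectation formulas for the MMSE CoD
estimator are assembled from these coefficients, so they live here together
with Beta/Dirichlet moments, truncated moments, and seeded sampling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import special

__all__ = [
    "BetaParams",
    "DirichletParams",
    "beta_fn",
    "log_beta_fn",
    "series_coeffs",
    "inc_beta",
    "truncated_moment",
    "dirichlet_marginal",
    "sample_beta",
    "sample_dirichlet",
]

#: relative tail tolerance for truncating the non-integer-shape series
DEFAULT_SERIES_TOL = 1e-12
#: hard cap on the number of series terms
MAX_SERIES_TERMS = 10_000

_INT_TOL = 1e-9


def _is_int(x: float) -> bool:
    return abs(x - round(x)) < _INT_TOL


@dataclass(frozen=True)
class BetaParams:
    """Shape parameters of a Beta(a, b) distribution."""

    a: float
    b: float

    def __post_init__(self) -> None:
        if not (self.a > 0 and self.b > 0):
            raise ValueError(f"Beta shapes must be positive, got ({self.a}, {self.b})")

    @property
    def mean(self) -> float:
        return self.a / (self.a + self.b)


@dataclass(frozen=True)
class DirichletParams:
    """Shape vector of a Dirichlet distribution (K >= 2 components)."""

    a: tuple

    def __post_init__(self) -> None:
        a = tuple(float(x) for x in self.a)
        if len(a) < 2:
            raise ValueError("Dirichlet needs at least 2 components")
        if any(x <= 0 for x in a):
            raise ValueError("Dirichlet shapes must be positive")
        object.__setattr__(self, "a", a)

    @property
    def concentration(self) -> float:
        return float(sum(self.a))

    @property
    def base_measure(self) -> np.ndarray:
        return np.asarray(self.a) / self.concentration


def beta_fn(a: float, b: float) -> float:
    """Beta function B(a, b) = Gamma(a)Gamma(b)/Gamma(a+b); symmetric in (a, b)."""
    if a <= 0 or b <= 0:
        raise ValueError(f"beta_fn requires positive shapes, got ({a}, {b})")
    return float(special.beta(a, b))


def log_beta_fn(a: float, b: float) -> float:
    """log B(a, b); carried in log space to survive posterior shapes ~1e3."""
    if a <= 0 or b <= 0:
        raise ValueError(f"log_beta_fn requires positive shapes, got ({a}, {b})")
    return float(special.betaln(a, b))


def series_coeffs(a: float, b: float, tol: float = DEFAULT_SERIES_TOL) -> np.ndarray:
    """Coefficients r_i(a, b) of the incomplete-Beta power series.

    For integer b returns exactly b coefficients (the series is a polynomial);
    otherwise the infinite series is truncated when the next term's absolute
    contribution at x = 1 falls below ``tol`` times the running sum of
    absolute contributions, with a hard cap of ``MAX_SERIES_TERMS``.

    The coefficients are built by the term-ratio recurrence
    r_{i+1} = -r_i (b-1-i)/(i+1) * (a+i)/(a+i+1), never by factorials.
    """
    if a <= 0 or b <= 0:
        raise ValueError(f"series_coeffs requires positive shapes, got ({a}, {b})")
    if _is_int(b):
        nb = round(b)
        out = np.empty(nb)
        r = 1.0 / a
        for i in range(nb):
            out[i] = r
            r *= -(nb - 1 - i) / (i + 1) * (a + i) / (a + i + 1)
        return out
    coeffs = []
    r = 1.0 / a
    tail_scale = abs(r)
    for i in range(MAX_SERIES_TERMS):
        coeffs.append(r)
        nxt = r * -(b - 1 - i) / (i + 1) * (a + i) / (a + i + 1)
        # the coefficients eventually decay like i^-(b+1) with one sign, so
        # the remaining tail at x = 1 is roughly |next| * i/b, not |next|
        tail = abs(nxt) * max((i + 1) / b, 1.0)
        if tail < tol * tail_scale:
            break
        tail_scale += abs(nxt)
        r = nxt
    return np.asarray(coeffs)


def _series_eval(x: float, a: float, b: float, tol: float) -> float:
    r = series_coeffs(a, b, tol=tol)
    i = np.arange(len(r))
    return float(np.sum(r * x ** (a + i)))


def inc_beta(x: float, a: float, b: float, tol: float = DEFAULT_SERIES_TOL) -> float:
    """Incomplete Beta function IB(x; a, b) via the power series.

    IB(1; a, b) = B(a, b); monotone nondecreasing in x on [0, 1].  Past the
    mass split point x = a/(a+b) the series is evaluated through the
    reflection IB(x; a, b) = B(a, b) - IB(1-x; b, a), which keeps the
    alternating sum on the small tail and bounds its cancellation.
    """
    if not (0.0 <= x <= 1.0):
        raise ValueError(f"inc_beta requires x in [0, 1], got {x}")
    if x == 0.0:
        # touch the domain check for shapes
        beta_fn(a, b)
        return 0.0
    if x > a / (a + b):
        return beta_fn(a, b) - _series_eval(1.0 - x, b, a, tol)
    return _series_eval(x, a, b, tol)


def truncated_moment(a: float, b: float, k: float, l: float, x: float) -> float:
    """E[X^k (1-X)^l I_{X<=x}] for X ~ Beta(a, b).

    Equals IB(x; a+k, b+l)/B(a, b) for x < 1 and B(a+k, b+l)/B(a, b) for
    x >= 1.  Requires k > -a and l > -b for the moment to exist.
    """
    if not (k > -a):
        raise ValueError(f"moment requires k > -a (k={k}, a={a})")
    if not (l > -b):
        raise ValueError(f"moment requires l > -b (l={l}, b={b})")
    if not (0.0 <= x):
        raise ValueError(f"truncated_moment requires x >= 0, got {x}")
    lb = log_beta_fn(a, b)
    if x >= 1.0:
        return float(np.exp(log_beta_fn(a + k, b + l) - lb))
    # regularized incomplete beta is numerically preferable to the raw series
    lab = log_beta_fn(a + k, b + l)
    return float(special.betainc(a + k, b + l, x) * np.exp(lab - lb))


def dirichlet_marginal(params: DirichletParams, i: int) -> BetaParams:
    """Marginal of component i (1-based) of a Dirichlet: Beta(a_i, Delta - a_i)."""
    a = params.a
    if not (1 <= i <= len(a)):
        raise IndexError(f"component index {i} out of range 1..{len(a)}")
    ai = a[i - 1]
    return BetaParams(ai, params.concentration - ai)


def sample_beta(params: BetaParams, rng: np.random.Generator, size: int = 1) -> np.ndarray:
    return rng.beta(params.a, params.b, size=size)


def sample_dirichlet(
    params: DirichletParams, rng: np.random.Generator, size: int = 1
) -> np.ndarray:
    return rng.dirichlet(params.a, size=size)


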