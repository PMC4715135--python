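"""Sufficient statistics, conjugate Beta-Dirichlet priors, and posteriors.

The prior places c ~ Beta(alpha, beta), p ~ Dirichlet(alpha_1..alpha_b),
q ~ Dirichlet(beta_1..beta_b) with b = 2^d cells, assuming independence
f(theta) = f(c) f(p) f(q).  Conjugacy gives the posterior by adding the
observed counts to the hyperparameters.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .beta_dirichlet import BetaParams, DirichletParams

__all__ = [
    "SampleCounts",
    "PriorSpec",
    "PosteriorSpec",
    "count",
    "posterior",
    "check_mmse_validity",
]


@dataclass(frozen=True)
class SampleCounts:
    """Per-cell counts (U_i, V_i) of (X = x^i, Y = 0/1) in an i.i.d. sample.

    n0 = sum U_i and n1 = sum V_i are derived, so the bookkeeping invariant
    holds by construction.
    """

    d: int
    U: np.ndarray
    V: np.ndarray

    def __post_init__(self):
        U = np.asarray(self.U, dtype=np.int64)
        V = np.asarray(self.V, dtype=np.int64)
        if U.shape != (2**self.d,) or V.shape != (2**self.d,):
            raise ValueError(f"U and V must have length 2^{self.d}")
        if (U < 0).any() or (V < 0).any():
            raise ValueError("counts must be nonnegative")
        object.__setattr__(self, "U", U)
        object.__setattr__(self, "V", V)

    @property
    def n0(self) -> int:
        return int(self.U.sum())

    @property
    def n1(self) -> int:
        return int(self.V.sum())

    @property
    def n(self) -> int:
        return self.n0 + self.n1


@dataclass(frozen=True)
class PriorSpec:
    """Hyperparameters (alpha, beta, alpha_vec, beta_vec) of the conjugate prior."""

    alpha: float
    beta: float
    alpha_vec: np.ndarray
    beta_vec: np.ndarray

    def __post_init__(self):
        av = np.asarray(self.alpha_vec, dtype=float)
        bv = np.asarray(self.beta_vec, dtype=float)
        if self.alpha <= 0 or self.beta <= 0:
            raise ValueError("alpha, beta must be positive")
        if av.ndim != 1 or bv.shape != av.shape:
            raise ValueError("alpha_vec and beta_vec must be 1-d with equal length")
        if (av <= 0).any() or (bv <= 0).any():
            raise ValueError("Dirichlet hyperparameters must be positive")
        k = len(av)
        if k < 2 or k & (k - 1):
            raise ValueError("hyperparameter vectors must have length 2^d")
        object.__setattr__(self, "alpha_vec", av)
        object.__setattr__(self, "beta_vec", bv)

    @property
    def d(self) -> int:
        return int(np.log2(len(self.alpha_vec)))

    # concentrations
    @property
    def delta_c(self) -> float:
        return self.alpha + self.beta

    @property
    def delta_p(self) -> float:
        return float(self.alpha_vec.sum())

    @property
    def delta_q(self) -> float:
        return float(self.beta_vec.sum())

    # base measures
    @property
    def c0(self) -> float:
        return self.alpha / self.delta_c

    @property
    def p0(self) -> np.ndarray:
        return self.alpha_vec / self.delta_p

    @property
    def q0(self) -> np.ndarray:
        return self.beta_vec / self.delta_q

    def c_params(self) -> BetaParams:
        return BetaParams(self.alpha, self.beta)

    def p_params(self) -> DirichletParams:
        return DirichletParams(tuple(self.alpha_vec))

    def q_params(self) -> DirichletParams:
        return DirichletParams(tuple(self.beta_vec))

    @classmethod
    def flat(cls, d: int) -> "PriorSpec":
        """The standard non-informative choice: alpha = beta = 2^d + 1 and
        uniform Dirichlet weights (flat p, q priors, c peaked at 1/2)."""
        k = 2**d
        return cls(k + 1.0, k + 1.0, np.ones(k), np.ones(k))


@dataclass(frozen=True)
class PosteriorSpec:
    """Posterior shapes after a conjugate update.

    c | S ~ Beta(alpha_s, beta_s); the Dirichlet posteriors are summarized by
    their per-cell marginal Beta shapes:
    p_i | S ~ Beta(alpha_s_i, alpha_bar_s_i), q_i | S ~ Beta(beta_s_i, beta_bar_s_i).
    """

    alpha_s: float
    beta_s: float
    alpha_s_vec: np.ndarray      # u_i + alpha_i
    alpha_bar_s_vec: np.ndarray  # n0 - u_i + Delta_p - alpha_i
    beta_s_vec: np.ndarray       # v_i + beta_i
    beta_bar_s_vec: np.ndarray   # n1 - v_i + Delta_q - beta_i

    def c_posterior(self) -> BetaParams:
        return BetaParams(self.alpha_s, self.beta_s)

    def p_posterior(self) -> DirichletParams:
        return DirichletParams(tuple(self.alpha_s_vec))

    def q_posterior(self) -> DirichletParams:
        return DirichletParams(tuple(self.beta_s_vec))


def count(cells, y, d: int) -> SampleCounts:
    """Tally a sample given as (cell indices in 1..2^d, binary labels)."""
    cells = np.asarray(cells, dtype=np.int64)
    y = np.asarray(y, dtype=np.int64)
    if cells.shape != y.shape or cells.ndim != 1:
        raise ValueError("cells and y must be 1-d arrays of equal length")
    ncells = 2**d
    if cells.size and (cells.min() < 1 or cells.max() > ncells):
        raise ValueError(f"cell indices must lie in 1..{ncells}")
    if not np.isin(y, (0, 1)).all():
        raise ValueError("labels must be binary")
    U = np.bincount(cells[y == 0] - 1, minlength=ncells)
    V = np.bincount(cells[y == 1] - 1, minlength=ncells)
    return SampleCounts(d, U, V)


def posterior(prior: PriorSpec, counts: SampleCounts) -> PosteriorSpec:
    """Conjugate update: add counts to the hyperparameters."""
    if prior.d != counts.d:
        raise ValueError(f"dimension mismatch: prior d={prior.d}, counts d={counts.d}")
    n0, n1 = counts.n0, counts.n1
    return PosteriorSpec(
        alpha_s=n0 + prior.alpha,
        beta_s=n1 + prior.beta,
        alpha_s_vec=counts.U + prior.alpha_vec,
        alpha_bar_s_vec=n0 - counts.U + prior.delta_p - prior.alpha_vec,
        beta_s_vec=counts.V + prior.beta_vec,
        beta_bar_s_vec=n1 - counts.V + prior.delta_q - prior.beta_vec,
    )


def check_mmse_validity(prior: PriorSpec) -> tuple[bool, str]:
    """Whether the closed-form MMSE CoD expressions are applicable.

    They require alpha > Delta_p - 1 and beta > Delta_q - 1 (strictly, on the
    prior hyperparameters).  When violated, the MMSE estimator falls back to
    posterior-sampling Monte Carlo downstream.
    """
    ok_p = prior.alpha > prior.delta_p - 1.0
    ok_q = prior.beta > prior.delta_q - 1.0
    if ok_p and ok_q:
        return True, "closed form valid"
    parts = []
    if not ok_p:
        parts.append(
            f"alpha={prior.alpha} must exceed Delta_p - 1 = {prior.delta_p - 1.0}"
        )
    if not ok_q:
        parts.append(
            f"beta={prior.beta} must exceed Delta_q - 1 = {prior.delta_q - 1.0}"
        )
    return False, "; ".join(parts)
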