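"""Parametric joint model of binary predictors X and a binary target Y.

The joint law of (X, Y) with X in {0,1}^d and Y in {0,1} is parameterized by
theta = (c, p, q): c = P(Y=0), p_i = P(X = x^i | Y=0) and
q_i = P(X = x^i | Y=1) over an enumeration x^1, ..., x^(2^d) of the
predictor states.  The enumeration convention, shared by every module, is
that x^i is the binary expansion of i-1 with the most-significant bit
carrying X_1; e.g. for d=2: x^1=(0,0), x^2=(0,1), x^3=(1,0), x^4=(1,1).

The discrete coefficient of determination is
CoD = (eps0 - eps)/eps0, where eps0 = min{c, 1-c} is the best constant-
predictor error and eps = sum_i min{c p_i, (1-c) q_i} is the Bayes error of
predicting Y from X.  CoD = 0 by convention when eps0 = 0.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

__all__ = [
    "DiscreteJointModel",
    "cell_index",
    "cell_vector",
    "optimal_error",
    "prior_error",
    "true_cod",
    "sample",
]

logger = logging.getLogger(__name__)

_PROB_TOL = 1e-12


def cell_index(x) -> int:
    """Map a binary predictor vector to its cell index in 1..2^d.

    The index is 1 + the integer whose binary expansion is x, with x[0]
    (i.e. X_1) as the most-significant bit.
    """
    x = np.asarray(x)
    if x.ndim != 1 or not np.isin(x, (0, 1)).all():
        raise ValueError(f"predictor vector must be binary, got {x!r}")
    idx = 0
    for bit in x:
        idx = (idx << 1) | int(bit)
    return idx + 1


def cell_vector(i: int, d: int) -> np.ndarray:
    """Inverse of :func:`cell_index`: the binary vector x^i of length d."""
    if not (1 <= i <= 2**d):
        raise ValueError(f"cell index {i} out of range 1..{2**d}")
    bits = np.array([(i - 1) >> (d - 1 - j) & 1 for j in range(d)], dtype=np.int64)
    return bits


@dataclass(frozen=True)
class DiscreteJointModel:
    """theta = (c, p, q) for d binary predictors and a binary target."""

    d: int
    c: float
    p: np.ndarray
    q: np.ndarray

    def __post_init__(self):
        d, c = self.d, self.c
        p = np.asarray(self.p, dtype=float)
        q = np.asarray(self.q, dtype=float)
        if d < 1:
            raise ValueError("d must be >= 1")
        if p.shape != (2**d,) or q.shape != (2**d,):
            raise ValueError(f"p and q must have length 2^{d}={2**d}")
        if not (0.0 <= c <= 1.0):
            raise ValueError(f"c must lie in [0, 1], got {c}")
        for name, vec in (("p", p), ("q", q)):
            if (vec < -_PROB_TOL).any() or (vec > 1 + _PROB_TOL).any():
                raise ValueError(f"{name} entries must lie in [0, 1]")
            if abs(vec.sum() - 1.0) > 1e-10:
                raise ValueError(f"{name} must sum to 1, got {vec.sum()}")
        object.__setattr__(self, "d", int(d))
        object.__setattr__(self, "c", float(c))
        object.__setattr__(self, "p", p)
        object.__setattr__(self, "q", q)

    # -- flat-config (de)serialization ------------------------------------
    def to_config(self) -> dict:
        return {"d": self.d, "c": self.c, "p": list(map(float, self.p)),
                "q": list(map(float, self.q))}

    @classmethod
    def from_config(cls, cfg: dict) -> "DiscreteJointModel":
        return cls(int(cfg["d"]), float(cfg["c"]), cfg["p"], cfg["q"])


def optimal_error(model: DiscreteJointModel) -> float:
    """Bayes error eps = sum_i min{c p_i, (1-c) q_i} of predicting Y from X."""
    return float(np.minimum(model.c * model.p, (1.0 - model.c) * model.q).sum())


def prior_error(model: DiscreteJointModel) -> float:
    """Best constant-predictor error eps0 = min{c, 1-c}."""
    return float(min(model.c, 1.0 - model.c))


def true_cod(model: DiscreteJointModel) -> float:
    """CoD = (eps0 - eps)/eps0, with CoD = 0 when eps0 = 0 (degenerate target)."""
    eps0 = prior_error(model)
    if eps0 == 0.0:
        logger.debug("degenerate model (eps0 = 0); CoD set to 0 by convention")
        return 0.0
    # rounding can push eps a few ulp past eps0; the CoD lives in [0, 1]
    return float(np.clip((eps0 - optimal_error(model)) / eps0, 0.0, 1.0))


def true_cod_batch(c: np.ndarray, p: np.ndarray, q: np.ndarray) -> np.ndarray:
    """Vectorized CoD over a batch of parameter draws.

    ``c`` has shape (m,); ``p`` and ``q`` have shape (m, 2^d).
    """
    c = np.asarray(c, dtype=float)
    eps = np.minimum(c[:, None] * p, (1.0 - c)[:, None] * q).sum(axis=1)
    eps0 = np.minimum(c, 1.0 - c)
    out = np.zeros_like(eps)
    ok = eps0 > 0
    out[ok] = (eps0[ok] - eps[ok]) / eps0[ok]
    return np.clip(out, 0.0, 1.0)


def sample(
    model: DiscreteJointModel, n: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Draw n i.i.d. pairs; returns (cells, y) with cells in 1..2^d.

    Y = 0 with probability c, then the predictor cell is drawn from p or q
    accordingly.
    """
    if n < 0:
        raise ValueError("sample size must be nonnegative")
    ncells = 2**model.d
    y = (rng.random(n) >= model.c).astype(np.int64)  # 0 w.p. c
    cells = np.empty(n, dtype=np.int64)
    mask0 = y == 0
    n0 = int(mask0.sum())
    if n0:
        cells[mask0] = rng.choice(ncells, size=n0, p=model.p) + 1
    if n - n0:
        cells[~mask0] = rng.choice(ncells, size=n - n0, p=model.q) + 1
    return cells, y
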