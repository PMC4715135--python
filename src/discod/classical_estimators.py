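"""Nonparametric CoD estimators used as baselines: resubstitution,
leave-one-out, 0.632 bootstrap, and 10-repeated twofold cross-validation.

All four plug the discrete histogram (plug-in) predictor into
CoD = 1 - eps_hat/eps0_hat, where eps0_hat = min(n0, n1)/n is the
resubstitution estimate of the constant-predictor error, computed on the
full sample for every scheme.  The plug-in predictor assigns each predictor
cell the majority label among the training points that fell in it, with
fixed tie rules: unseen cells and within-cell ties predict the training-set
majority class, and an overall tie predicts 0.

Resubstitution CoD is always in [0, 1]; the resampling-based estimates can
come out negative, in which case the primary value is clipped to 0 and the
raw value is kept in the diagnostics.
"""

from __future__ import annotations

import numpy as np

from .bayes_estimators import CoDEstimate

__all__ = ["resub_cod", "loo_cod", "b632_cod", "cv10x2_cod"]

DEFAULT_BOOTSTRAP_REPS = 100


def _check(cells: np.ndarray, y: np.ndarray, min_n: int) -> int:
    cells = np.asarray(cells)
    y = np.asarray(y)
    if cells.ndim != 1 or cells.shape != y.shape:
        raise ValueError("cells and y must be 1-d arrays of equal length")
    n = len(y)
    if n < min_n:
        raise ValueError(f"need at least {min_n} sample points, got {n}")
    return n


def _plugin_predict(U: np.ndarray, V: np.ndarray, cells: np.ndarray) -> np.ndarray:
    """Labels of the plug-in predictor (trained on counts U, V) at ``cells``.

    U[c], V[c] are training counts of (cell c+1, Y=0/1).
    """
    n0, n1 = U.sum(), V.sum()
    majority = 0 if n0 >= n1 else 1  # overall tie -> 0
    per_cell = np.where(U > V, 0, np.where(V > U, 1, majority))
    return per_cell[np.asarray(cells) - 1]


def _counts(cells, y, ncells):
    U = np.bincount(cells[y == 0] - 1, minlength=ncells)
    V = np.bincount(cells[y == 1] - 1, minlength=ncells)
    return U, V


def _cod_from_errors(eps: float, eps0: float, name: str, clip: bool) -> CoDEstimate:
    if eps0 == 0.0:
        return CoDEstimate(0.0, name, {"raw": 0.0, "eps": eps, "eps0": eps0})
    raw = 1.0 - eps / eps0
    value = float(np.clip(raw, 0.0, 1.0)) if clip else float(raw)
    return CoDEstimate(value, name, {"raw": float(raw), "eps": eps, "eps0": eps0})


def resub_cod(cells, y, d: int) -> CoDEstimate:
    """Resubstitution (plug-in sample-frequency) CoD estimate."""
    n = _check(cells, y, 1)
    cells = np.asarray(cells, dtype=np.int64)
    y = np.asarray(y, dtype=np.int64)
    ncells = 2**d
    U, V = _counts(cells, y, ncells)
    pred = _plugin_predict(U, V, cells)
    eps = float((pred != y).mean())
    eps0 = min(U.sum(), V.sum()) / n
    return _cod_from_errors(eps, eps0, "resub", clip=False)


def loo_cod(cells, y, d: int) -> CoDEstimate:
    """Leave-one-out CoD estimate (plug-in rule trained on the other n-1)."""
    n = _check(cells, y, 2)
    cells = np.asarray(cells, dtype=np.int64)
    y = np.asarray(y, dtype=np.int64)
    ncells = 2**d
    U, V = _counts(cells, y, ncells)
    errors = 0
    for c, lab in zip(cells, y):
        u = U.copy()
        v = V.copy()
        (u if lab == 0 else v)[c - 1] -= 1
        pred = _plugin_predict(u, v, np.array([c]))[0]
        errors += int(pred != lab)
    eps = errors / n
    eps0 = min(U.sum(), V.sum()) / n
    return _cod_from_errors(eps, eps0, "loo", clip=True)


def b632_cod(
    cells,
    y,
    d: int,
    B: int = DEFAULT_BOOTSTRAP_REPS,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
) -> CoDEstimate:
    """0.632 bootstrap CoD: eps = 0.632 * eps_oob + 0.368 * eps_resub."""
    n = _check(cells, y, 2)
    if B < 1:
        raise ValueError("B must be >= 1")
    if rng is None:
        rng = np.random.default_rng(seed)
    cells = np.asarray(cells, dtype=np.int64)
    y = np.asarray(y, dtype=np.int64)
    ncells = 2**d
    oob_errors = []
    for _ in range(B):
        idx = rng.integers(0, n, size=n)
        oob = np.setdiff1d(np.arange(n), idx, assume_unique=False)
        if oob.size == 0:
            continue
        U, V = _counts(cells[idx], y[idx], ncells)
        pred = _plugin_predict(U, V, cells[oob])
        oob_errors.append(float((pred != y[oob]).mean()))
    eps_boot = float(np.mean(oob_errors)) if oob_errors else float("nan")
    eps_resub = resub_cod(cells, y, d).diagnostics["eps"]
    eps = 0.632 * eps_boot + 0.368 * eps_resub
    U, V = _counts(cells, y, ncells)
    eps0 = min(U.sum(), V.sum()) / n
    est = _cod_from_errors(eps, eps0, "b632", clip=True)
    est.diagnostics["B_effective"] = len(oob_errors)
    return est


def cv10x2_cod(
    cells,
    y,
    d: int,
    repeats: int = 10,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
) -> CoDEstimate:
    """10-repeated twofold cross-validation CoD.

    Each repetition splits the sample into random halves, stratified by
    class when both classes are present, and tests the plug-in rule trained
    on each half against the other.
    """
    n = _check(cells, y, 2)
    if rng is None:
        rng = np.random.default_rng(seed)
    cells = np.asarray(cells, dtype=np.int64)
    y = np.asarray(y, dtype=np.int64)
    ncells = 2**d
    idx_by_class = [np.flatnonzero(y == k) for k in (0, 1)]
    fold_errors = []
    for _ in range(repeats):
        half_a = []
        for idx in idx_by_class:
            if idx.size == 0:
                continue
            perm = rng.permutation(idx)
            half_a.append(perm[: idx.size // 2 + (idx.size % 2) * int(rng.random() < 0.5)])
        half_a = np.concatenate(half_a) if half_a else np.array([], dtype=np.int64)
        mask = np.zeros(n, dtype=bool)
        mask[half_a] = True
        for train_mask in (mask, ~mask):
            tr, te = np.flatnonzero(train_mask), np.flatnonzero(~train_mask)
            if tr.size == 0 or te.size == 0:
                continue
            U, V = _counts(cells[tr], y[tr], ncells)
            pred = _plugin_predict(U, V, cells[te])
            fold_errors.append(float((pred != y[te]).mean()))
    eps = float(np.mean(fold_errors)) if fold_errors else float("nan")
    U, V = _counts(cells, y, ncells)
    eps0 = min(U.sum(), V.sum()) / n
    return _cod_from_errors(eps, eps0, "cv10x2", clip=True)
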