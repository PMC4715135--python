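"""Boolean gene-regulatory-network inference from binarized expression.

The regulation model for a target gene Y with predictor states X is
Y = f(X) XOR N, where f = g(X_{i1}, ..., X_{ik}) is a Boolean function of k
essential inputs chosen from the d candidate predictors (the index set
{i1 < ... < ik} is the *wiring*), and N is Bernoulli noise with
P(N = 0) = p, the *predictive power*.

Model selection is a two-step empirical-Bayes search: for each candidate
function g over all C(d, k) wirings, hyperparameters are built from the
sample-frequency estimate of p and a flat predictor distribution, a
Bayesian CoD estimate is computed, and the best wiring per g is kept
(step 1); among the per-function winners the pair with the largest
predictive-power estimate is selected (step 2).  Ties are broken randomly.
With the resubstitution estimator the standard procedure applies instead:
the wiring with the largest resubstitution CoD is selected and the logic is
the plug-in majority table.

Truth tables are stored in logic-table order with the first (lowest-index)
wired gene as the most-significant bit; e.g. the 3-input AND is 00000001.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd

from .bayes_estimators import mmse_cod, obp_cod
from .classical_estimators import resub_cod
from .sample_stats import PriorSpec, SampleCounts, count

__all__ = [
    "BooleanRegulation",
    "InferredNetwork",
    "enumerate_essential",
    "predictive_power",
    "empirical_hyperparams",
    "select_model",
    "infer_network",
    "NetworkSpec",
    "synth_expression",
    "random_network_spec",
]

DEFAULT_DELTA = 1.0
DEFAULT_MMSE_REPS = 20_000
_TIE_RTOL = 1e-12


@dataclass(frozen=True)
class BooleanRegulation:
    """A Boolean function g, its wiring, and its predictive power estimate.

    ``wiring`` holds 0-based predictor column indices in ascending order;
    ``table`` is the length-2^k truth table of g in logic-table order.
    """

    k: int
    table: tuple
    wiring: tuple
    p_hat: float = float("nan")
    wiring_names: tuple | None = None

    def __post_init__(self):
        if len(self.table) != 2**self.k:
            raise ValueError("truth table length must be 2^k")
        if any(b not in (0, 1) for b in self.table):
            raise ValueError("truth table must be binary")
        if len(set(self.wiring)) != len(self.wiring):
            raise ValueError("wiring indices must be distinct")

    @property
    def bitstring(self) -> str:
        return "".join(map(str, self.table))


def _essential_mask(table: np.ndarray, k: int) -> bool:
    """True iff every one of the k inputs is essential for this table."""
    idx = np.arange(2**k)
    for v in range(k):
        partner = idx ^ (1 << (k - 1 - v))
        if np.array_equal(table, table[partner]):
            return False
    return True


@lru_cache(maxsize=None)
def enumerate_essential(k: int) -> tuple:
    """All truth tables of k-input Boolean functions with every input
    essential, as tuples in logic-table order.

    Counts: k=1 -> 2, k=2 -> 10, k=3 -> 218 (matching inclusion-exclusion
    over reducible functions).
    """
    if not (1 <= k <= 4):
        raise ValueError("k must be between 1 and 4")
    ncells = 2**k
    out = []
    for code in range(2**ncells):
        table = np.array([(code >> (ncells - 1 - i)) & 1 for i in range(ncells)])
        if _essential_mask(table, k):
            out.append(tuple(int(b) for b in table))
    return tuple(out)


def _project_cells(X: np.ndarray, wiring) -> np.ndarray:
    """Cell codes in 0..2^k-1 of the wired predictor columns (MSB first)."""
    cols = X[:, list(wiring)]
    weights = 1 << np.arange(len(wiring) - 1, -1, -1)
    return cols @ weights


def predictive_power(X: np.ndarray, y: np.ndarray, reg: BooleanRegulation) -> float:
    """Sample-frequency estimate of p: the fraction of points with f(X) = Y."""
    X = np.asarray(X)
    y = np.asarray(y)
    if len(y) < 1:
        raise ValueError("need at least one sample point")
    cells = _project_cells(X, reg.wiring)
    f_vals = np.asarray(reg.table)[cells]
    return float((f_vals == y).mean())


def empirical_hyperparams(
    p_hat: float, table, delta: float = DEFAULT_DELTA
) -> PriorSpec:
    """Empirical-Bayes hyperparameters from the predictive power and g.

    With a flat predictor distribution, the model implies cell masses
    p_i ∝ p(1-g_i) + (1-p) g_i  (target 0) and q_i ∝ p g_i + (1-p)(1-g_i)
    (target 1), and c = mean_i(p(1-g_i) + (1-p) g_i).  These normalized
    masses are the prior base measures; hyperparameters are their products
    with the concentration, rounded up (and floored at 1 so the prior stays
    proper when a cell mass is exactly zero).
    """
    if not (0.0 <= p_hat <= 1.0):
        raise ValueError("p_hat must lie in [0, 1]")
    if delta <= 0:
        raise ValueError("delta must be positive")
    g = np.asarray(table, dtype=float)
    ncells = len(g)
    mass0 = p_hat * (1.0 - g) + (1.0 - p_hat) * g
    mass1 = p_hat * g + (1.0 - p_hat) * (1.0 - g)
    c_hat = mass0.sum() / ncells
    p_base = mass0 / mass0.sum() if mass0.sum() > 0 else np.full(ncells, 1.0 / ncells)
    q_base = mass1 / mass1.sum() if mass1.sum() > 0 else np.full(ncells, 1.0 / ncells)
    ceil = lambda x: np.maximum(np.ceil(x - 1e-12), 1.0)
    return PriorSpec(
        float(ceil(c_hat * delta)),
        float(ceil((1.0 - c_hat) * delta)),
        ceil(p_base * delta),
        ceil(q_base * delta),
    )


def _tie_argmax(values: np.ndarray, rng: np.random.Generator) -> int:
    top = values.max()
    ties = np.flatnonzero(values >= top - _TIE_RTOL * max(abs(top), 1.0))
    return int(ties[0] if len(ties) == 1 else rng.choice(ties))


def _plugin_table(cells: np.ndarray, y: np.ndarray, k: int) -> tuple:
    """Majority-vote truth table (unseen cells / ties -> training majority)."""
    ncells = 2**k
    U = np.bincount(cells[y == 0], minlength=ncells)
    V = np.bincount(cells[y == 1], minlength=ncells)
    majority = 0 if U.sum() >= V.sum() else 1
    table = np.where(U > V, 0, np.where(V > U, 1, majority))
    return tuple(int(b) for b in table)


def _obp_scores(counts: SampleCounts, p_hats: np.ndarray, tables: np.ndarray,
                delta: float) -> np.ndarray:
    """Vectorized OBP CoD over candidate functions sharing one wiring."""
    out = np.empty(len(p_hats))
    for g in range(len(p_hats)):
        prior = empirical_hyperparams(p_hats[g], tables[g], delta)
        out[g] = obp_cod(prior, counts).value
    return out


def select_model(
    X,
    y,
    k: int = 3,
    delta: float = DEFAULT_DELTA,
    estimator: str = "obp",
    rng: np.random.Generator | None = None,
    seed: int | None = None,
    mmse_reps: int = DEFAULT_MMSE_REPS,
) -> tuple[BooleanRegulation, float]:
    """Two-step Bayesian model selection for one target.

    Returns (BooleanRegulation, CoD estimate value).  ``X`` is the n x d
    binary predictor matrix, ``y`` the binary target vector.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    X = np.asarray(X, dtype=np.int64)
    y = np.asarray(y, dtype=np.int64)
    n, d = X.shape
    if k > d:
        raise ValueError(f"k={k} exceeds the predictor pool size d={d}")
    wirings = list(itertools.combinations(range(d), k))

    if estimator == "resub":
        scores = np.empty(len(wirings))
        for w, wiring in enumerate(wirings):
            cells = _project_cells(X, wiring)
            scores[w] = resub_cod(cells + 1, y, k).value
        w_best = _tie_argmax(scores, rng)
        wiring = wirings[w_best]
        cells = _project_cells(X, wiring)
        table = _plugin_table(cells, y, k)
        reg = BooleanRegulation(k, table, wiring)
        reg = BooleanRegulation(k, table, wiring, predictive_power(X, y, reg))
        return reg, float(scores[w_best])

    if estimator not in ("obp", "mmse"):
        raise ValueError(f"unknown estimator {estimator!r}")

    tables = np.array(enumerate_essential(k))
    n_g = len(tables)
    scores = np.empty((n_g, len(wirings)))
    p_hats = np.empty((n_g, len(wirings)))
    for w, wiring in enumerate(wirings):
        cells = _project_cells(X, wiring)
        counts = count(cells + 1, y, k)
        f_vals = tables[:, cells]                      # (n_g, n)
        p_hats[:, w] = (f_vals == y).mean(axis=1)
        if estimator == "obp":
            scores[:, w] = _obp_scores(counts, p_hats[:, w], tables, delta)
        else:
            for g in range(n_g):
                prior = empirical_hyperparams(p_hats[g, w], tables[g], delta)
                scores[g, w] = mmse_cod(
                    prior, counts, mc_reps=mmse_reps, rng=rng
                ).value
    # step 1: best wiring per function
    best_w = np.array([_tie_argmax(scores[g], rng) for g in range(n_g)])
    # step 2: among per-function winners, largest predictive power
    winner_p = p_hats[np.arange(n_g), best_w]
    g_best = _tie_argmax(winner_p, rng)
    w_best = best_w[g_best]
    reg = BooleanRegulation(
        k, tuple(int(b) for b in tables[g_best]), wirings[w_best],
        float(p_hats[g_best, w_best]),
    )
    return reg, float(scores[g_best, w_best])


@dataclass
class InferredNetwork:
    """Per-target selected regulations with their CoD estimates."""

    genes: tuple
    regulations: dict  # target gene name -> (BooleanRegulation, cod)
    estimator: str
    k: int
    delta: float

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for target, (reg, cod) in self.regulations.items():
            names = reg.wiring_names or tuple(map(str, reg.wiring))
            rows.append({
                "target": target,
                "predictors": ",".join(names),
                "table": reg.bitstring,
                "cod": cod,
                "p_hat": reg.p_hat,
                "estimator": self.estimator,
            })
        return pd.DataFrame(rows)

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    def to_dot(self, path) -> None:
        lines = ["digraph regulatory_network {"]
        for target, (reg, cod) in self.regulations.items():
            for pred in (reg.wiring_names or tuple(map(str, reg.wiring))):
                lines.append(f'  "{pred}" -> "{target}" [label="{cod:.3f}"];')
        lines.append("}")
        with open(path, "w") as fh:
            fh.write("\n".join(lines) + "\n")


def infer_network(
    matrix: pd.DataFrame,
    k: int = 3,
    delta: float = DEFAULT_DELTA,
    estimator: str = "obp",
    seed: int | None = 0,
    mmse_reps: int = DEFAULT_MMSE_REPS,
) -> InferredNetwork:
    """Infer one regulation per gene, using the other genes as predictors.

    ``matrix`` is a samples x genes 0/1 DataFrame with gene-name columns.
    A gene is never in its own predictor pool.
    """
    data = matrix.to_numpy()
    if not np.isin(data, (0, 1)).all():
        raise ValueError("expression matrix must be binarized to {0, 1}")
    genes = tuple(matrix.columns)
    if len(genes) < k + 1:
        raise ValueError(f"need at least k+1={k + 1} genes")
    rng = np.random.default_rng(seed)
    regulations = {}
    for t, target in enumerate(genes):
        pool = [g for g in range(len(genes)) if g != t]
        X = data[:, pool]
        y = data[:, t]
        reg, cod = select_model(
            X, y, k=k, delta=delta, estimator=estimator, rng=rng,
            mmse_reps=mmse_reps,
        )
        names = tuple(genes[pool[i]] for i in reg.wiring)
        reg = BooleanRegulation(reg.k, reg.table, reg.wiring, reg.p_hat, names)
        regulations[target] = (reg, cod)
    return InferredNetwork(genes, regulations, estimator, k, delta)


# ---------------------------------------------------------------------------
# synthetic expression fixtures
# ---------------------------------------------------------------------------

@dataclass
class NetworkSpec:
    """Generative spec: per gene either a root Bernoulli or a regulation.

    ``nodes`` maps gene name -> {"kind": "root", "p1": float} or
    {"kind": "regulation", "wiring": [names], "table": tuple, "p": float}.
    The wiring graph must be acyclic (generation is by ancestral sampling).
    """

    nodes: dict

    def topological_order(self) -> list:
        order, seen, visiting = [], set(), set()

        def visit(name):
            if name in seen:
                return
            if name in visiting:
                raise ValueError(
                    f"cyclic wiring at gene {name!r}: ancestral sampling "
                    "needs an acyclic spec"
                )
            visiting.add(name)
            node = self.nodes[name]
            if node["kind"] == "regulation":
                for parent in node["wiring"]:
                    visit(parent)
            visiting.discard(name)
            seen.add(name)
            order.append(name)

        for name in self.nodes:
            visit(name)
        return order


def synth_expression(
    spec: NetworkSpec, n: int = 31, rng: np.random.Generator | None = None,
    seed: int | None = None,
) -> pd.DataFrame:
    """Draw an n x genes binarized expression matrix from the noisy-Boolean
    regulation model (roots are Bernoulli; regulated genes apply their truth
    table to the wired parents and flip the output with probability 1-p).

    Defaults emulate the scale of a small binarized tumor-expression panel
    (n = 31 samples, 7 genes).
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    order = spec.topological_order()
    columns = {}
    for name in order:
        node = spec.nodes[name]
        if node["kind"] == "root":
            columns[name] = (rng.random(n) < node["p1"]).astype(np.int64)
        else:
            parents = np.column_stack([columns[p] for p in node["wiring"]])
            weights = 1 << np.arange(parents.shape[1] - 1, -1, -1)
            f_vals = np.asarray(node["table"])[parents @ weights]
            noise = (rng.random(n) >= node["p"]).astype(np.int64)
            columns[name] = f_vals ^ noise
    return pd.DataFrame({name: columns[name] for name in spec.nodes})


def random_network_spec(
    genes: int = 7, k: int = 3, p: float = 0.95,
    rng: np.random.Generator | None = None, seed: int | None = None,
) -> NetworkSpec:
    """A random acyclic spec: the first k genes are Bernoulli(1/2) roots and
    each later gene is a random essential-k function of k earlier genes."""
    if rng is None:
        rng = np.random.default_rng(seed)
    if genes < k + 1:
        raise ValueError("need at least k+1 genes")
    tables = enumerate_essential(k)
    names = [f"G{i + 1}" for i in range(genes)]
    nodes = {}
    for i, name in enumerate(names):
        if i < k:
            nodes[name] = {"kind": "root", "p1": 0.5}
        else:
            wiring = sorted(rng.choice(i, size=k, replace=False).tolist())
            nodes[name] = {
                "kind": "regulation",
                "wiring": [names[w] for w in wiring],
                "table": tables[rng.integers(len(tables))],
                "p": p,
            }
    return NetworkSpec(nodes)
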