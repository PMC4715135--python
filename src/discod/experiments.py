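"""Simulation study designs: global accuracy versus sample size, and
fixed-parameter accuracy under flat/matched/poorly-matched/mismatched priors
at three prior-concentration levels.

The fixed-parameter designs use one fixed model per dimensionality d with
c* = 0.5 and the p* vectors below (q* is p* flipped left-to-right), and
three nonflat base measures per d: "matched" equals the true p*, "poor" is
a flatter compromise, and "mismatched" flips the true vector.  Priors are
assembled from a base measure and a concentration: alpha = c0 * Delta_c,
alpha_i = p0_i * Delta_p, etc.  The concentration triples per d follow the
convention Delta_c/2 = Delta_p = Delta_q with levels (high, medium, low
variance) = (5, 25, 50) for d=1, (10, 50, 100) for d=2, (20, 100, 200) for
d=3.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .discrete_model import DiscreteJointModel
from .exact_accuracy import (
    ESTIMATOR_NAMES,
    global_accuracy,
    make_estimator,
    obp_fixed_accuracy,
)
from .discrete_model import sample, true_cod
from .sample_stats import PriorSpec

__all__ = [
    "ExperimentConfig",
    "table1_models",
    "build_prior",
    "concentration_levels",
    "run_global",
    "run_fixed",
    "plot_accuracy",
]

SCENARIOS = ("flat", "matched", "poor", "mismatched")
LEVELS = ("high", "medium", "low")

#: Delta_p (= Delta_q = Delta_c/2) per dimension and variance level
_CONCENTRATIONS = {
    1: {"high": 5.0, "medium": 25.0, "low": 50.0},
    2: {"high": 10.0, "medium": 50.0, "low": 100.0},
    3: {"high": 20.0, "medium": 100.0, "low": 200.0},
}

_PSTAR = {
    1: (0.6, 0.4),
    2: (0.2, 0.3, 0.1, 0.4),
    3: (0.1, 0.15, 0.05, 0.2, 0.15, 0.1, 0.1, 0.15),
}

_BASE_MEASURES = {
    1: {
        "matched": (0.6, 0.4),
        "poor": (0.5, 0.5),
        "mismatched": (0.4, 0.6),
    },
    2: {
        "matched": (0.2, 0.3, 0.1, 0.4),
        "poor": (0.3, 0.2, 0.2, 0.3),
        "mismatched": (0.4, 0.1, 0.3, 0.2),
    },
    3: {
        "matched": (0.1, 0.15, 0.05, 0.2, 0.15, 0.1, 0.1, 0.15),
        "poor": (0.15, 0.1, 0.1, 0.15, 0.1, 0.05, 0.15, 0.2),
        "mismatched": (0.2, 0.05, 0.15, 0.1, 0.05, 0.2, 0.2, 0.05),
    },
}


def table1_models() -> dict:
    """The fixed true models and nonflat base measures, per d in {1, 2, 3}.

    Returns {d: {"model": DiscreteJointModel, "base_measures":
    {scenario: (c0, p0, q0)}}}; q-vectors are the p-vectors flipped
    left-to-right, and c* = c0 = 0.5 throughout.
    """
    out = {}
    for d in (1, 2, 3):
        pstar = np.asarray(_PSTAR[d])
        model = DiscreteJointModel(d, 0.5, pstar, pstar[::-1].copy())
        bases = {}
        for scen, p0 in _BASE_MEASURES[d].items():
            p0 = np.asarray(p0)
            bases[scen] = (0.5, p0, p0[::-1].copy())
        out[d] = {"model": model, "base_measures": bases}
    return out


def concentration_levels(d: int) -> dict:
    """(Delta_c, Delta_p, Delta_q) per variance level for dimension d."""
    return {
        level: (2.0 * dp, dp, dp) for level, dp in _CONCENTRATIONS[d].items()
    }


def build_prior(c0: float, p0, q0, delta_c: float, delta_p: float,
                delta_q: float) -> PriorSpec:
    """Assemble hyperparameters from base measures and concentrations.

    alpha = c0 Delta_c, beta = (1-c0) Delta_c, alpha_i = p0_i Delta_p,
    beta_i = q0_i Delta_q.  Products are kept exact (possibly non-integer);
    non-integer hyperparameters route the MMSE estimator through its
    truncated-series or Monte-Carlo path downstream.
    """
    p0 = np.asarray(p0, dtype=float)
    q0 = np.asarray(q0, dtype=float)
    return PriorSpec(c0 * delta_c, (1.0 - c0) * delta_c, p0 * delta_p, q0 * delta_q)


def scenario_prior(d: int, scenario: str, level: str = "medium") -> PriorSpec:
    """The prior of a named scenario ("flat" ignores the level)."""
    if scenario == "flat":
        return PriorSpec.flat(d)
    c0, p0, q0 = table1_models()[d]["base_measures"][scenario]
    dc, dp, dq = concentration_levels(d)[level]
    return build_prior(c0, p0, q0, dc, dp, dq)


@dataclass
class ExperimentConfig:
    """Configuration shared by the global and fixed simulation designs."""

    d: int = 1
    n_grid: tuple = (10, 20, 30, 40, 50, 60)
    estimators: tuple = ESTIMATOR_NAMES
    scenario: str = "flat"
    level: str = "medium"
    reps: int = 2000
    seed: int = 0

    def __post_init__(self):
        if self.d not in (1, 2, 3):
            raise ValueError("d must be 1, 2 or 3")
        if self.scenario not in SCENARIOS:
            raise ValueError(f"scenario must be one of {SCENARIOS}")
        if self.level not in LEVELS:
            raise ValueError(f"level must be one of {LEVELS}")
        unknown = set(self.estimators) - set(ESTIMATOR_NAMES)
        if unknown:
            raise ValueError(f"unknown estimators: {sorted(unknown)}")


def run_global(config: ExperimentConfig) -> pd.DataFrame:
    """Global accuracy versus sample size under the flat prior design.

    For each n in the grid, theta is drawn fresh from the prior in each of
    ``config.reps`` replicates; every estimator is evaluated on the same
    replicate samples.  Returns a tidy table (n, estimator, bias, variance,
    rms, se_bias, se_rms, reps).
    """
    prior = scenario_prior(config.d, config.scenario, config.level)
    frames = []
    for i, n in enumerate(config.n_grid):
        rng = np.random.default_rng((config.seed, i))
        res = global_accuracy(
            prior, config.d, n, config.reps, estimators=config.estimators,
            rng=rng,
        )
        frames.append(res.table)
    return pd.concat(frames, ignore_index=True)


def run_fixed(config: ExperimentConfig) -> pd.DataFrame:
    """Fixed-parameter accuracy for the Table-1 model of dimension d.

    OBP rows are computed exactly from the closed-form sampling moments;
    all other estimators are averaged over ``config.reps`` Monte-Carlo
    samples drawn from the fixed distribution.
    """
    model = table1_models()[config.d]["model"]
    prior = scenario_prior(config.d, config.scenario, config.level)
    cod = true_cod(model)
    rows = []
    for i, n in enumerate(config.n_grid):
        rng = np.random.default_rng((config.seed, 1, i))
        # exact OBP
        rep = obp_fixed_accuracy(model, prior, n, method="auto", rng=rng)
        rows.append({
            "n": n, "estimator": "obp", "scenario": config.scenario,
            "level": config.level, "bias": rep.bias, "variance": rep.variance,
            "rms": rep.rms, "method": rep.method,
            "se_bias": rep.se_bias, "se_rms": rep.se_rms, "reps": rep.reps,
        })
        others = [name for name in config.estimators if name != "obp"]
        if not others:
            continue
        fns = {name: make_estimator(name, prior, config.d, rng)
               for name in others}
        errs = {name: np.empty(config.reps) for name in others}
        for m in range(config.reps):
            cells, y = sample(model, n, rng)
            for name, fn in fns.items():
                errs[name][m] = fn(cells, y) - cod
        for name in others:
            e = errs[name]
            rms = float(np.sqrt(np.mean(e**2)))
            rows.append({
                "n": n, "estimator": name, "scenario": config.scenario,
                "level": config.level,
                "bias": float(e.mean()), "variance": float(e.var(ddof=1)),
                "rms": rms, "method": "monte-carlo",
                "se_bias": float(e.std(ddof=1) / np.sqrt(config.reps)),
                "se_rms": float(
                    (e**2).std(ddof=1) / np.sqrt(config.reps) / max(2 * rms, 1e-12)
                ),
                "reps": config.reps,
            })
    return pd.DataFrame(rows)


def plot_accuracy(table: pd.DataFrame, out_path: str, title: str = "") -> None:
    """Bias/variance/RMS panels versus sample size, one line per estimator."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 3, figsize=(12, 3.5), sharex=True)
    for metric, ax in zip(("bias", "variance", "rms"), axes):
        for name, grp in table.groupby("estimator"):
            grp = grp.sort_values("n")
            ax.plot(grp["n"], grp[metric], marker="o", label=name)
        ax.set_xlabel("sample size n")
        ax.set_ylabel(metric)
        if metric == "bias":
            ax.axhline(0.0, color="gray", lw=0.5)
    axes[0].legend(fontsize=8)
    if title:
        fig.suptitle(title)
    fig.tight_layout()
    fig.savefig(out_path, dpi=120)
    plt.close(fig)
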