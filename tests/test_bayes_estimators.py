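"""MMSE and OBP CoD estimators: worked values, oracles, invariants."""

import time
from fractions import Fraction

import numpy as np
import pytest

from discod import (
    DiscreteJointModel,
    PriorSpec,
    SampleCounts,
    count,
    mmse_cod,
    mmse_cod_mc,
    obp_cod,
    obp_predict,
    sample,
    true_cod,
)
from discod.bayes_estimators import mmse_cod_rational, obp_errors


def _random_instance(rng, d_max=2, n_max=10):
    """Random integer-hyperparameter (prior, counts) with a valid prior."""
    d = int(rng.integers(1, d_max + 1))
    k = 2**d
    av = rng.integers(1, 3, size=k).astype(float)
    bv = rng.integers(1, 3, size=k).astype(float)
    alpha = float(av.sum() + rng.integers(0, 3))
    beta = float(bv.sum() + rng.integers(0, 3))
    prior = PriorSpec(alpha, beta, av, bv)
    n = int(rng.integers(0, n_max + 1))
    n0 = int(rng.integers(0, n + 1))
    U = rng.multinomial(n0, np.ones(k) / k)
    V = rng.multinomial(n - n0, np.ones(k) / k)
    return prior, SampleCounts(d, U, V)


class TestObp:
    def test_worked_example(self, toy_prior, toy_counts):
        # 1 - (1/5)(min{15/4, 5/4} + min{5/4, 15/4}) = 0.5
        assert obp_cod(toy_prior, toy_counts).value == pytest.approx(0.5)

    def test_predict_worked_cells(self, toy_prior, toy_counts):
        assert obp_predict(toy_prior, toy_counts, 1) == 0  # 0.375 vs 0.125
        assert obp_predict(toy_prior, toy_counts, 2) == 1  # 0.125 vs 0.375

    def test_tie_maps_to_zero(self):
        prior = PriorSpec(2.0, 2.0, [1, 1], [1, 1])
        counts = SampleCounts(1, [1, 1], [1, 1])
        for i in (1, 2):
            assert obp_predict(prior, counts, i) == 0

    def test_symmetric_counts_give_zero(self):
        prior = PriorSpec(3.0, 3.0, [1, 1], [1, 1])
        counts = SampleCounts(1, [2, 1], [2, 1])
        assert obp_cod(prior, counts).value == 0.0

    def test_error_decomposition(self, rng):
        # CoD_OBP == 1 - eps_hat/eps0_hat assembled from the two errors
        for _ in range(20):
            prior, counts = _random_instance(rng)
            eps, eps0 = obp_errors(prior, counts)
            assert obp_cod(prior, counts).value == pytest.approx(
                1.0 - eps / eps0, abs=1e-12
            )

    def test_bounds_random(self, rng):
        for _ in range(50):
            prior, counts = _random_instance(rng, d_max=3, n_max=30)
            assert 0.0 <= obp_cod(prior, counts).value <= 1.0

    def test_label_swap_symmetry(self, rng):
        # swapping (U, alpha_vec, alpha) <-> (V, beta_vec, beta) exchanges
        # the roles of the classes and leaves the CoD unchanged
        for _ in range(10):
            prior, counts = _random_instance(rng)
            sw_prior = PriorSpec(prior.beta, prior.alpha, prior.beta_vec,
                                 prior.alpha_vec)
            sw_counts = SampleCounts(counts.d, counts.V, counts.U)
            assert obp_cod(prior, counts).value == pytest.approx(
                obp_cod(sw_prior, sw_counts).value, abs=1e-12
            )


class TestMmseClosedForm:
    def test_worked_example_exact_rational(self, toy_prior, toy_counts):
        # exact posterior expectation for the toy sample is 395/1024
        assert mmse_cod_rational(toy_prior, toy_counts) == Fraction(395, 1024)

    def test_matches_mc_oracle(self, toy_prior, toy_counts):
        est = mmse_cod(toy_prior, toy_counts, method="exact")
        mc = mmse_cod_mc(toy_prior, toy_counts, reps=400_000, seed=3)
        assert abs(est.value - mc.value) <= 3 * mc.diagnostics["se"]

    def test_matches_mc_oracle_random_instances(self, rng):
        for trial in range(8):
            prior, counts = _random_instance(rng)
            est = mmse_cod(prior, counts, method="exact")
            mc = mmse_cod_mc(prior, counts, reps=200_000, seed=trial)
            assert abs(est.value - mc.value) <= 3 * mc.diagnostics["se"]

    def test_noninteger_series_matches_mc(self):
        prior = PriorSpec(5.0, 5.0, [2.5, 2.5], [2.5, 2.5])
        counts = SampleCounts(1, [3, 1], [1, 2])
        est = mmse_cod(prior, counts, method="exact")
        assert est.diagnostics["method"] == "closed-form-series"
        mc = mmse_cod_mc(prior, counts, reps=400_000, seed=8)
        assert abs(est.value - mc.value) <= 3 * mc.diagnostics["se"]

    def test_label_swap_symmetry(self, toy_prior, toy_counts):
        swapped = mmse_cod(
            PriorSpec(3.0, 3.0, [1, 1], [1, 1]),
            SampleCounts(1, toy_counts.V, toy_counts.U),
            method="exact",
        )
        ref = mmse_cod(toy_prior, toy_counts, method="exact")
        assert swapped.value == pytest.approx(ref.value, abs=1e-12)

    def test_value_in_unit_interval(self, rng):
        for _ in range(10):
            prior, counts = _random_instance(rng)
            assert 0.0 <= mmse_cod(prior, counts, method="exact").value <= 1.0

    def test_invalid_prior_raises_for_exact(self):
        prior = PriorSpec(1.0, 1.0, [1, 1], [1, 1])
        with pytest.raises(ValueError):
            mmse_cod(prior, SampleCounts(1, [1, 0], [0, 1]), method="exact")

    def test_runtime_desk_scale(self, rng):
        # closed form stays sub-second up to n = 60, d = 3
        prior = PriorSpec.flat(3)
        U = rng.multinomial(30, np.ones(8) / 8)
        V = rng.multinomial(30, np.ones(8) / 8)
        counts = SampleCounts(3, U, V)
        start = time.perf_counter()
        mmse_cod(prior, counts, method="exact")
        assert time.perf_counter() - start < 1.0


class TestMmseMcFallback:
    def test_reproducible_by_seed(self, toy_prior, toy_counts):
        a = mmse_cod_mc(toy_prior, toy_counts, reps=1000, seed=4)
        b = mmse_cod_mc(toy_prior, toy_counts, reps=1000, seed=4)
        assert a.value == b.value

    def test_single_rep(self, toy_prior, toy_counts):
        est = mmse_cod_mc(toy_prior, toy_counts, reps=1, seed=0)
        assert 0.0 <= est.value <= 1.0

    def test_invalid_prior_auto_falls_back(self, toy_counts):
        prior = PriorSpec(1.0, 1.0, [1, 1], [1, 1])
        est = mmse_cod(prior, toy_counts, seed=0)
        assert est.diagnostics["method"] == "monte-carlo"
        assert est.diagnostics["fallback_reason"]

    def test_prior_expectation_with_no_data(self):
        # with no data the posterior is the prior, so the estimate must match
        # an independent prior-expectation Monte Carlo
        prior = PriorSpec(3.0, 3.0, [1, 1], [1, 1])
        counts = SampleCounts(1, [0, 0], [0, 0])
        est = mmse_cod(prior, counts, method="exact")
        rng = np.random.default_rng(12)
        reps = 400_000
        from discod.discrete_model import true_cod_batch

        cods = true_cod_batch(
            rng.beta(3.0, 3.0, reps),
            rng.dirichlet([1.0, 1.0], reps),
            rng.dirichlet([1.0, 1.0], reps),
        )
        se = cods.std(ddof=1) / np.sqrt(reps)
        assert abs(est.value - cods.mean()) <= 3 * se


class TestLargeSampleConsistency:
    def test_estimates_approach_true_cod(self, weak_model):
        rng = np.random.default_rng(99)
        cells, y = sample(weak_model, 10_000, rng)
        counts = count(cells, y, 1)
        prior = PriorSpec.flat(1)
        cod = true_cod(weak_model)
        obp = obp_cod(prior, counts).value
        mmse = mmse_cod(prior, counts, rng=rng).value  # auto -> MC at this n
        assert abs(obp - cod) < 0.02
        assert abs(mmse - cod) < 0.02
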