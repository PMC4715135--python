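"""Boolean network inference: essential functions, empirical Bayes, model
selection, and the synthetic expression generator."""

import itertools

import numpy as np
import pandas as pd
import pytest

from discod.network_inference import (
    BooleanRegulation,
    NetworkSpec,
    empirical_hyperparams,
    enumerate_essential,
    infer_network,
    predictive_power,
    random_network_spec,
    select_model,
    synth_expression,
)


def _apply(table, X, wiring):
    w = 1 << np.arange(len(wiring) - 1, -1, -1)
    return np.asarray(table)[X[:, list(wiring)] @ w]


class TestEnumerateEssential:
    @pytest.mark.parametrize("k, expected", [(1, 2), (2, 10), (3, 218)])
    def test_counts(self, k, expected):
        assert len(enumerate_essential(k)) == expected

    def test_k1_is_identity_and_negation(self):
        assert set(enumerate_essential(1)) == {(0, 1), (1, 0)}

    @pytest.mark.parametrize("k", [1, 2, 3])
    def test_agrees_with_brute_force_filter(self, k):
        # independent essentiality test: evaluate g on all input vectors and
        # check each variable flips the output somewhere
        ncells = 2**k
        inputs = np.array(list(itertools.product((0, 1), repeat=k)))
        survivors = set()
        for code in range(2**ncells):
            table = tuple((code >> (ncells - 1 - i)) & 1 for i in range(ncells))
            ok = True
            for v in range(k):
                flipped = inputs.copy()
                flipped[:, v] ^= 1
                orig = _apply(table, inputs, range(k))
                flip = _apply(table, flipped, range(k))
                if (orig == flip).all():
                    ok = False
                    break
            if ok:
                survivors.add(table)
        assert survivors == set(enumerate_essential(k))

    def test_rejects_bad_k(self):
        with pytest.raises(ValueError):
            enumerate_essential(0)


class TestPredictivePower:
    def test_noiseless_data(self, rng):
        table = enumerate_essential(3)[7]
        X = rng.integers(0, 2, size=(40, 5))
        reg = BooleanRegulation(3, table, (0, 2, 4))
        y = _apply(table, X, (0, 2, 4))
        assert predictive_power(X, y, reg) == 1.0
        assert predictive_power(X, 1 - y, reg) == 0.0

    def test_partial_agreement(self, rng):
        table = (0, 1)
        X = rng.integers(0, 2, size=(31, 2))
        reg = BooleanRegulation(1, table, (0,))
        y = _apply(table, X, (0,))
        y[:3] ^= 1  # 28 of 31 agree
        assert predictive_power(X, y, reg) == pytest.approx(28 / 31)


class TestEmpiricalHyperparams:
    def test_and_function_delta_one(self):
        # AND, p_hat = 0.9: c_hat = (7*0.9 + 0.1)/8 = 0.8; with Delta = 1
        # every ceiling lands at 1 (flat prior)
        prior = empirical_hyperparams(0.9, (0, 0, 0, 0, 0, 0, 0, 1), 1.0)
        assert prior.alpha == prior.beta == 1.0
        np.testing.assert_allclose(prior.alpha_vec, np.ones(8))
        np.testing.assert_allclose(prior.beta_vec, np.ones(8))
        assert prior.c0 == pytest.approx(0.5)

    def test_and_function_delta_64(self):
        # normalized p-masses are 0.9/6.4 = 0.140625 (f=0 cells) and
        # 0.1/6.4 = 0.015625 (f=1 cell): ceilings 9 and 1
        prior = empirical_hyperparams(0.9, (0, 0, 0, 0, 0, 0, 0, 1), 64.0)
        np.testing.assert_allclose(prior.alpha_vec, [9] * 7 + [1])

    def test_pure_noise_gives_flat_base(self):
        prior = empirical_hyperparams(0.5, (0, 0, 0, 1), 4.0)
        np.testing.assert_allclose(prior.p0, np.full(4, 0.25))
        np.testing.assert_allclose(prior.q0, np.full(4, 0.25))

    def test_noiseless_edge_stays_proper(self):
        # p_hat = 1 zeroes some cell masses; hyperparameters stay >= 1
        prior = empirical_hyperparams(1.0, (0, 1), 8.0)
        assert (prior.alpha_vec >= 1).all() and (prior.beta_vec >= 1).all()


class TestSelectModel:
    def test_candidate_space_size(self):
        import math
        assert math.comb(6, 3) == 20
        assert len(enumerate_essential(3)) == 218

    def test_deterministic_given_seed(self, rng):
        X = rng.integers(0, 2, size=(31, 5))
        y = rng.integers(0, 2, size=31)
        a = select_model(X, y, k=2, estimator="obp", seed=9)
        b = select_model(X, y, k=2, estimator="obp", seed=9)
        assert a == b

    def test_noiseless_recovery_small(self, rng):
        table = enumerate_essential(2)[3]
        wiring = (1, 3)
        X = rng.integers(0, 2, size=(120, 4))
        y = _apply(table, X, wiring)
        reg, cod = select_model(X, y, k=2, estimator="obp", seed=1)
        assert reg.wiring == wiring
        assert reg.table == table
        assert cod > 0.8

    def test_k_larger_than_pool_raises(self, rng):
        X = rng.integers(0, 2, size=(10, 2))
        with pytest.raises(ValueError):
            select_model(X, X[:, 0], k=3)


@pytest.fixture(scope="module")
def matrix():
    spec = random_network_spec(6, 2, 0.95, seed=21)
    return synth_expression(spec, n=31, seed=22)


class TestInferNetwork:
    def test_no_self_regulation(self, matrix):
        net = infer_network(matrix, k=2, estimator="obp", seed=1)
        for target, (reg, _) in net.regulations.items():
            assert target not in reg.wiring_names

    def test_row_permutation_invariance(self, matrix):
        net_a = infer_network(matrix, k=2, estimator="obp", seed=1)
        shuffled = matrix.sample(frac=1.0, random_state=0).reset_index(drop=True)
        net_b = infer_network(shuffled, k=2, estimator="obp", seed=1)
        assert net_a.to_frame().equals(net_b.to_frame())

    def test_constant_target_gets_zero_cod(self, matrix):
        mat = matrix.copy()
        mat["G1"] = 0
        net = infer_network(mat, k=2, estimator="obp", seed=1)
        assert net.to_frame().set_index("target").loc["G1", "cod"] == 0.0

    def test_rejects_nonbinary(self):
        bad = pd.DataFrame(np.full((5, 4), 2))
        with pytest.raises(ValueError):
            infer_network(bad, k=2)

    def test_edge_list_and_dot_output(self, matrix, tmp_path):
        net = infer_network(matrix, k=2, estimator="obp", seed=1)
        net.to_tsv(tmp_path / "edges.tsv")
        net.to_dot(tmp_path / "net.dot")
        edges = pd.read_csv(tmp_path / "edges.tsv", sep="\t")
        assert set(edges.columns) >= {"target", "predictors", "table", "cod", "p_hat"}
        assert len(edges) == matrix.shape[1]
        dot = (tmp_path / "net.dot").read_text()
        assert dot.startswith("digraph") and "->" in dot


class TestSynthExpression:
    def test_default_shape(self):
        mat = synth_expression(random_network_spec(seed=0), seed=1)
        assert mat.shape == (31, 7)
        assert set(np.unique(mat.to_numpy())) <= {0, 1}

    def test_noiseless_targets_are_deterministic(self, rng):
        spec = random_network_spec(5, 2, p=1.0, seed=3)
        mat = synth_expression(spec, n=200, seed=4)
        for name, node in spec.nodes.items():
            if node["kind"] != "regulation":
                continue
            parents = mat[node["wiring"]].to_numpy()
            f_vals = _apply(node["table"], parents, range(len(node["wiring"])))
            np.testing.assert_array_equal(f_vals, mat[name].to_numpy())

    def test_pure_noise_target_has_low_cod(self):
        spec = random_network_spec(5, 2, p=0.5, seed=5)
        mat = synth_expression(spec, n=31, seed=6)
        net = infer_network(mat, k=2, estimator="obp", seed=7)
        frame = net.to_frame().set_index("target")
        regulated = [n for n, v in spec.nodes.items() if v["kind"] == "regulation"]
        assert frame.loc[regulated, "cod"].mean() < 0.5

    def test_cyclic_spec_rejected(self):
        nodes = {
            "A": {"kind": "regulation", "wiring": ["B"], "table": (0, 1), "p": 1.0},
            "B": {"kind": "regulation", "wiring": ["A"], "table": (0, 1), "p": 1.0},
        }
        with pytest.raises(ValueError):
            synth_expression(NetworkSpec(nodes), n=5, seed=0)

    def test_reproducible(self):
        spec = random_network_spec(seed=8)
        a = synth_expression(spec, seed=9)
        b = synth_expression(spec, seed=9)
        assert a.equals(b)


class TestCrossModuleConsistency:
    def test_regulation_model_implies_consistent_cod(self, rng):
        # build the exact joint model implied by (f, p) with flat P(X) and
        # check the analytic CoD against direct simulation
        from discod import DiscreteJointModel, cell_index, true_cod

        table = enumerate_essential(2)[4]
        p_power = 0.9
        g = np.asarray(table)
        mass0 = p_power * (1 - g) + (1 - p_power) * g
        mass1 = p_power * g + (1 - p_power) * (1 - g)
        c = mass0.sum() / 4
        model = DiscreteJointModel(2, c, mass0 / mass0.sum(), mass1 / mass1.sum())
        cod = true_cod(model)

        n = 200_000
        X = rng.integers(0, 2, size=(n, 2))
        y = _apply(table, X, (0, 1)) ^ (rng.random(n) >= p_power).astype(int)
        # empirical CoD of the optimal predictor on this stream
        cells = np.array([cell_index(row) for row in X])
        eps_emp = 0.0
        for cell in range(1, 5):
            mask = cells == cell
            p1 = y[mask].mean()
            eps_emp += mask.mean() * min(p1, 1 - p1)
        eps0_emp = min(y.mean(), 1 - y.mean())
        cod_emp = 1 - eps_emp / eps0_emp
        assert cod == pytest.approx(cod_emp, abs=0.01)
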