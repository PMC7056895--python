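"""Objective, gradients and AdaGrad training of the latent model.

The primary oracle for this module is agreement between analytic gradients
and central finite differences of the objective on random small instances.
"""

import numpy as np
import pytest

from dsplmf import lmf
from dsplmf.datasets import binarize_response
from dsplmf.evaluation import auc_score
from dsplmf.similarity import (
    aggregate_cell_similarity,
    jaccard_similarity,
    knn_adjacency,
    pearson_similarity,
)
from dsplmf.synthetic import FixtureSpec, fixture_hyperparams, generate


def random_instance(seed):
    """Random (model, Q, Hc, Hd, hp) with n<=6, m<=5, L<=4."""
    rng = np.random.default_rng(seed)
    n, m, L = int(rng.integers(2, 7)), int(rng.integers(2, 6)), int(rng.integers(1, 5))
    model = lmf.init_model(n, m, L, seed=seed)
    q = (rng.random((n, m)) < 0.5).astype(float)

    def reg(size):
        a = np.zeros((size, size))
        for i in range(size):
            others = [j for j in range(size) if j != i]
            picks = rng.choice(others, size=min(2, len(others)), replace=False)
            a[i, picks] = rng.random(len(picks))
        row, col = np.diag(a.sum(1)), np.diag(a.sum(0))
        return (row + col) - (a + a.T)

    hp = lmf.LMFHyperparams(
        L=L,
        lambda_c=float(rng.random()),
        lambda_d=float(rng.random()),
        alpha=float(rng.random()),
        beta=float(rng.random()),
        r=float(1 + rng.integers(0, 2)),
        seed=seed,
    )
    return model, q, reg(n), reg(m), hp


def numeric_gradients(model, q, hc, hd, hp, h=1e-5):
    """Central finite differences of the objective over every parameter."""
    def obj(m):
        return lmf.objective(m, q, hc, hd, hp)

    out = {}
    for name in ("U", "V", "bias_c", "bias_d"):
        arr = getattr(model, name)
        grad = np.zeros_like(arr)
        it = np.nditer(arr, flags=["multi_index"])
        for _ in it:
            idx = it.multi_index
            m2 = model.copy()
            getattr(m2, name)[idx] += h
            plus = obj(m2)
            getattr(m2, name)[idx] -= 2 * h
            minus = obj(m2)
            grad[idx] = (plus - minus) / (2 * h)
        out[name] = grad
    return out


def fixture_training_inputs(seed):
    """Q, Hc, Hd and the cell adjacency for one planted cohort."""
    ds, _ = generate(FixtureSpec(seed=seed))
    hp = fixture_hyperparams(seed=seed)
    q = binarize_response(ds.ic50).q
    s_total = aggregate_cell_similarity(
        pearson_similarity(ds.expression),
        pearson_similarity(ds.cnv),
        jaccard_similarity(ds.mutation),
        pearson_similarity(ds.ic50),
        *hp.similarity_weights(),
    )
    cell_graph = knn_adjacency(s_total, hp.k)
    drug_graph = knn_adjacency(
        jaccard_similarity(ds.fingerprints), min(hp.k, ds.m - 1)
    )
    return q, cell_graph, drug_graph, hp


class TestInit:
    def test_shapes_and_determinism(self):
        m1 = lmf.init_model(3, 2, 4, seed=1)
        m2 = lmf.init_model(3, 2, 4, seed=1)
        assert m1.U.shape == (3, 4) and m1.V.shape == (2, 4)
        np.testing.assert_array_equal(m1.U, m2.U)
        np.testing.assert_array_equal(m1.bias_c, np.zeros(3))

    def test_degenerate_dimension(self):
        m = lmf.init_model(3, 2, 1, seed=0)
        assert m.U.shape == (3, 1)

    def test_entries_centered_at_zero(self):
        m = lmf.init_model(100, 100, 1, seed=0)
        entries = np.concatenate([m.U.ravel(), m.V.ravel()])
        se = entries.std() / np.sqrt(entries.size)
        assert abs(entries.mean()) < 3 * se


class TestPredictor:
    def test_zero_model(self):
        m = lmf.LatentModel(np.zeros((2, 2)), np.zeros((3, 2)), np.zeros(2), np.zeros(3))
        assert lmf.linear_predictor(m, 0, 0) == 0.0
        assert lmf.probability(m, 0, 0) == 0.5

    def test_hand_dot_product(self):
        m = lmf.LatentModel(
            np.array([[1.0, 2.0]]), np.array([[3.0, 4.0]]),
            np.array([0.5]), np.array([-0.5]),
        )
        assert lmf.linear_predictor(m, 0, 0) == pytest.approx(11.0)

    def test_bias_shift_linearity(self):
        m = lmf.init_model(3, 2, 2, seed=0)
        base = lmf.linear_predictor(m, 1, 1)
        m.bias_c[1] += 2.5
        assert lmf.linear_predictor(m, 1, 1) == pytest.approx(base + 2.5)

    def test_probability_saturates_without_overflow(self):
        m = lmf.LatentModel(
            np.array([[1000.0]]), np.array([[1.0]]), np.zeros(1), np.zeros(1)
        )
        p = lmf.probability(m, 0, 0)
        assert 0 < p < 1 and p > 1 - 1e-9

    def test_logistic_symmetry(self):
        rng = np.random.default_rng(0)
        for z in rng.normal(scale=3, size=10):
            mp = lmf.LatentModel(np.array([[z]]), np.array([[1.0]]), np.zeros(1), np.zeros(1))
            mn = lmf.LatentModel(np.array([[-z]]), np.array([[1.0]]), np.zeros(1), np.zeros(1))
            assert lmf.probability(mp, 0, 0) + lmf.probability(mn, 0, 0) == pytest.approx(1.0)


class TestObjective:
    def test_zero_model_gives_nm_log2(self):
        n, m = 4, 3
        model = lmf.LatentModel(np.zeros((n, 2)), np.zeros((m, 2)), np.zeros(n), np.zeros(m))
        q = (np.random.default_rng(0).random((n, m)) < 0.5).astype(float)
        hp = lmf.LMFHyperparams(L=2, lambda_c=0, lambda_d=0, alpha=0, beta=0, r=1)
        assert lmf.objective(model, q, None, None, hp) == pytest.approx(n * m * np.log(2))

    def test_unregularized_equals_cross_entropy(self):
        model, q, _, _, _ = random_instance(7)
        hp = lmf.LMFHyperparams(L=model.L, lambda_c=0, lambda_d=0, alpha=0, beta=0, r=1)
        p = model.probability_matrix()
        oracle = -np.sum(q * np.log(p) + (1 - q) * np.log(1 - p))
        assert lmf.objective(model, q, None, None, hp) == pytest.approx(oracle)

    def test_linear_in_alpha(self):
        model, q, hc, hd, hp = random_instance(11)
        base = lmf.objective(model, q, hc, hd, hp)
        hp2 = lmf.LMFHyperparams(**{**hp.to_dict(), "alpha": 2 * hp.alpha})
        delta = 0.5 * hp.alpha * float(np.trace(model.U.T @ hc @ model.U))
        assert lmf.objective(model, q, hc, hd, hp2) == pytest.approx(base + delta)


class TestGradients:
    @pytest.mark.parametrize("seed", range(20))
    def test_matches_finite_differences(self, seed):
        model, q, hc, hd, hp = random_instance(seed)
        g = lmf.gradients(model, q, hc, hd, hp)
        num = numeric_gradients(model, q, hc, hd, hp)
        for name, analytic in (
            ("U", g.dU), ("V", g.dV), ("bias_c", g.dbias_c), ("bias_d", g.dbias_d)
        ):
            np.testing.assert_allclose(
                analytic, num[name], rtol=1e-5, atol=1e-7,
                err_msg=f"gradient mismatch in {name} (seed {seed})",
            )

    def test_balanced_q_zero_model_bias_gradient_sums_to_zero(self):
        n, m = 4, 4
        model = lmf.LatentModel(np.zeros((n, 2)), np.zeros((m, 2)), np.zeros(n), np.zeros(m))
        q = np.kron(np.eye(2), np.ones((2, 2)))  # two 1s and two 0s per row/col
        hp = lmf.LMFHyperparams(L=2, lambda_c=0, lambda_d=0, alpha=0, beta=0, r=1)
        g = lmf.gradients(model, q, None, None, hp)
        assert g.dbias_c.sum() == pytest.approx(0.0)

    def test_data_term_hand_expansion(self):
        # with no regularization, dU rows are sum_j [(sigma(z)-q) v_j]
        model = lmf.LatentModel(
            np.array([[0.5, -1.0], [2.0, 0.0]]),
            np.array([[1.0, 1.0], [0.0, -1.0]]),
            np.zeros(2), np.zeros(2),
        )
        q = np.array([[1.0, 0.0], [0.0, 1.0]])
        hp = lmf.LMFHyperparams(L=2, lambda_c=0, lambda_d=0, alpha=0, beta=0, r=1)
        g = lmf.gradients(model, q, None, None, hp)
        p = model.probability_matrix()
        expected = (p - q) @ model.V
        np.testing.assert_allclose(g.dU, expected)

    def test_r_upweights_positive_entries(self):
        model, q, _, _, _ = random_instance(13)
        hp1 = lmf.LMFHyperparams(L=model.L, lambda_c=0, lambda_d=0, alpha=0, beta=0, r=1)
        hp2 = lmf.LMFHyperparams(**{**hp1.to_dict(), "r": 2.0})
        g1 = lmf.gradients(model, q, None, None, hp1)
        g2 = lmf.gradients(model, q, None, None, hp2)
        # the extra gradient mass comes only from q=1 entries
        p = model.probability_matrix()
        extra = ((p - 1.0) * q).sum(axis=1)
        np.testing.assert_allclose(g2.dbias_c - g1.dbias_c, extra)


class TestFit:
    def test_objective_descends_on_planted_fixture(self):
        q, cg, dg, hp = fixture_training_inputs(seed=1)
        _, traj = lmf.fit(q, cg.reg_matrix, dg.reg_matrix, hp)
        assert traj[-1] < traj[0]
        # near-monotone after the AdaGrad warm-up
        diffs = np.diff(traj[5:])
        assert (diffs <= 1e-6).all()

    def test_zero_epochs_returns_initial_model(self):
        q, cg, dg, hp = fixture_training_inputs(seed=1)
        hp0 = lmf.LMFHyperparams(**{**hp.to_dict(), "n_iters": 0})
        model, traj = lmf.fit(q, cg.reg_matrix, dg.reg_matrix, hp0)
        init = lmf.init_model(q.shape[0], q.shape[1], hp0.L, hp0.seed)
        np.testing.assert_array_equal(model.U, init.U)
        assert len(traj) == 1

    def test_same_seed_bitwise_identical(self):
        q, cg, dg, hp = fixture_training_inputs(seed=2)
        m1, t1 = lmf.fit(q, cg.reg_matrix, dg.reg_matrix, hp)
        m2, t2 = lmf.fit(q, cg.reg_matrix, dg.reg_matrix, hp)
        np.testing.assert_array_equal(m1.U, m2.U)
        np.testing.assert_array_equal(m1.V, m2.V)
        assert t1 == t2

    def test_neighborhood_penalty_pulls_linked_latents_together(self):
        q, cell_graph, drug_graph, hp = fixture_training_inputs(seed=1)
        i, j = np.nonzero(cell_graph.adjacency)

        def mean_linked_distance(alpha):
            hpa = lmf.LMFHyperparams(**{**hp.to_dict(), "alpha": alpha})
            model, _ = lmf.fit(q, cell_graph.reg_matrix, drug_graph.reg_matrix, hpa)
            return np.linalg.norm(model.U[i] - model.U[j], axis=1).mean()

        assert mean_linked_distance(4.0) < mean_linked_distance(0.0)

    def test_held_out_entries_are_predicted(self):
        """Masked-entry AUC: the model generalizes within the matrix."""
        aucs = []
        for seed in (1, 2, 3):
            q, cg, dg, hp = fixture_training_inputs(seed=seed)
            rng = np.random.default_rng(seed)
            mask = (rng.random(q.shape) > 0.2).astype(float)
            model, _ = lmf.fit(q, cg.reg_matrix, dg.reg_matrix, hp, mask=mask)
            held = mask == 0
            aucs.append(auc_score(q[held], model.probability_matrix()[held]))
        assert np.median(aucs) >= 0.85

    def test_save_load_roundtrip(self, tmp_path):
        q, cg, dg, hp = fixture_training_inputs(seed=3)
        model, traj = lmf.fit(q, cg.reg_matrix, dg.reg_matrix, hp)
        path = tmp_path / "model.npz"
        lmf.save_model(model, path, hp, traj)
        loaded, hp2, traj2 = lmf.load_model(path)
        np.testing.assert_array_equal(loaded.U, model.U)
        assert hp2.to_dict() == hp.to_dict()
        assert traj2 == pytest.approx(traj)
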