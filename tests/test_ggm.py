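"""EBIC-glasso: solver oracles, scoring arithmetic, selection behaviour."""

import numpy as np
import pytest
from sklearn.covariance import graphical_lasso as sk_glasso

import ordnet
from ordnet.ggm import (
    NetworkModel,
    default_lambda_grid,
    ebic_score,
    edge_density,
    glasso_path,
    select_network,
)
from ordnet.polycor import CorrelationMatrix


def _corr(values, n=500):
    values = np.asarray(values, dtype=float)
    p = values.shape[0]
    return CorrelationMatrix(
        values=values,
        pairwise_n=np.full((p, p), n),
        item_labels=[f"V{i + 1}" for i in range(p)],
    )


def _random_corr(p, seed, strength=0.5):
    rng = np.random.default_rng(seed)
    a = rng.normal(size=(p, 4 * p)) * strength
    s = a @ a.T / (4 * p) + np.eye(p)
    d = np.sqrt(np.diag(s))
    return s / np.outer(d, d)


class TestGlassoPath:
    def test_huge_penalty_gives_diagonal_precision(self):
        R = _random_corr(6, 0)
        (K,) = glasso_path(R, np.array([10.0]))
        off = K - np.diag(np.diag(K))
        assert np.max(np.abs(off)) < 1e-10

    def test_equicorrelated_triple_partials_one_third(self):
        R = _corr([[1, 0.5, 0.5], [0.5, 1, 0.5], [0.5, 0.5, 1]])
        (K,) = glasso_path(R, np.array([1e-6]))
        d = np.sqrt(np.diag(K))
        w = -K / np.outer(d, d)
        # closed form: (r12 - r13 r23)/sqrt((1-r13^2)(1-r23^2)) = 1/3
        iu = np.triu_indices(3, 1)
        assert np.allclose(w[iu], 1.0 / 3.0, atol=1e-4)

    def test_edge_count_monotone_along_path(self):
        R = _random_corr(8, 1)
        lams = default_lambda_grid(R, n_lambda=30)
        path = glasso_path(R, lams)
        counts = [
            (np.abs(K[np.triu_indices(8, 1)]) > 1e-8).sum() for K in path
        ]
        assert all(b >= a for a, b in zip(counts, counts[1:]))

    @pytest.mark.parametrize("p,seed", [(4, 2), (5, 3), (6, 4)])
    def test_unpenalised_limit_matches_matrix_inversion(self, p, seed):
        R = _random_corr(p, seed)
        (K,) = glasso_path(R, np.array([1e-7]))
        d = np.sqrt(np.diag(K))
        w = -K / np.outer(d, d)
        Kinv = np.linalg.inv(R)
        di = np.sqrt(np.diag(Kinv))
        wi = -Kinv / np.outer(di, di)
        np.fill_diagonal(w, 0)
        np.fill_diagonal(wi, 0)
        assert np.max(np.abs(w - wi)) < 1e-4

    @pytest.mark.parametrize("lam", [0.3, 0.1, 0.03])
    def test_agrees_with_sklearn_solver(self, lam):
        """Independent solver cross-check on the same convex problem."""
        R = _random_corr(9, 5)
        (K,) = glasso_path(R, np.array([lam]))
        _, K_sk = sk_glasso(R, alpha=lam, max_iter=500, tol=1e-6)
        assert np.array_equal(np.abs(K) > 1e-7, np.abs(K_sk) > 1e-7)
        assert np.max(np.abs(K - K_sk)) < 5e-3

    def test_bad_lambda_sequence_rejected(self):
        R = _random_corr(4, 6)
        with pytest.raises(ValueError):
            glasso_path(R, np.array([0.1, 0.2]))
        with pytest.raises(ValueError):
            glasso_path(R, np.array([-0.1]))


class TestEbicScore:
    def test_penalty_difference_arithmetic(self):
        """Two models of equal likelihood differing by 2 edges at n=367,
        p=17, gamma=0.5 differ by 2 log 367 + 8*0.5*log 17 ~ 23.14."""
        n, p, gamma = 367, 17, 0.5
        def penalty(E):
            return E * np.log(n) + 4 * E * gamma * np.log(p)
        assert penalty(12) - penalty(10) == pytest.approx(23.144, abs=0.01)

        # same thing through ebic_score: identical K scored at gamma vs 0
        R = _corr(_random_corr(p, 7), n=n)
        (K,) = glasso_path(R.values, np.array([0.1]))
        E = (np.abs(K[np.triu_indices(p, 1)]) > 1e-8).sum()
        diff = ebic_score(K, R, n, gamma) - ebic_score(K, R, n, 0.0)
        assert diff == pytest.approx(4 * E * gamma * np.log(p), rel=1e-10)

    def test_gamma_zero_is_plain_bic(self):
        R = _corr(_random_corr(5, 8))
        (K,) = glasso_path(R.values, np.array([0.05]))
        E = (np.abs(K[np.triu_indices(5, 1)]) > 1e-8).sum()
        sign, logdet = np.linalg.slogdet(K)
        ll = 0.5 * 500 * (logdet - np.trace(R.values @ K))
        assert ebic_score(K, R, 500, 0.0) == pytest.approx(-2 * ll + E * np.log(500))

    def test_diagonal_precision_brute_force_likelihood(self):
        K = np.diag([1.3, 0.8, 2.1])
        R = _corr(np.eye(3), n=100)
        expected = -2 * (100 / 2) * (np.log(np.linalg.det(K)) - np.trace(R.values @ K))
        assert ebic_score(K, R, 100, 0.5) == pytest.approx(expected)

    def test_non_pd_rejected(self):
        R = _corr(np.eye(3))
        with pytest.raises(ValueError):
            ebic_score(np.diag([1.0, -0.5, 1.0]), R, 100)


class TestSelectNetwork:
    def test_identity_correlations_give_empty_network(self):
        for gamma in (0.0, 0.5):
            net = select_network(_corr(np.eye(6)), gamma=gamma)
            assert net.n_edges() == 0

    def test_heavier_gamma_never_denser(self, model17):
        d = ordnet.sample_ordinal(model17, 400, seed=21)
        R = ordnet.correlation_matrix(d)
        e_half = select_network(R, gamma=0.5).n_edges()
        e_zero = select_network(R, gamma=0.0).n_edges()
        assert e_half <= e_zero

    def test_sparser_than_saturated_inverse_and_recovers(self, model17):
        d = ordnet.sample_ordinal(model17, 2000, seed=22)
        R = ordnet.correlation_matrix(d)
        net = select_network(R)
        assert net.n_edges() < 17 * 16 / 2
        assert ordnet.sensitivity(model17, net) >= 0.6

    def test_label_equivariance_under_permutation(self):
        Rv = _random_corr(6, 9)
        perm = np.array([3, 0, 5, 1, 4, 2])
        net = select_network(_corr(Rv))
        net_p = select_network(_corr(Rv[np.ix_(perm, perm)]))
        assert np.allclose(net_p.weights, net.weights[np.ix_(perm, perm)], atol=1e-6)

    def test_n_effective_defaults_to_mean_pairwise_n(self, model17):
        d = ordnet.sample_ordinal(model17, 300, seed=23)
        d = ordnet.inject_missing(d, 0.02, seed=24)
        R = ordnet.correlation_matrix(d)
        net = select_network(R)
        assert net.n_effective == pytest.approx(R.mean_pairwise_n)


class TestEdgeDensity:
    def test_hand_cases(self):
        w = np.zeros((3, 3))
        net = NetworkModel(w, ["a", "b", "c"], 0.1, 0.5, 100)
        assert edge_density(net) == 0.0
        w = np.full((3, 3), 0.2)
        np.fill_diagonal(w, 0.0)
        net = NetworkModel(w, ["a", "b", "c"], 0.1, 0.5, 100)
        assert edge_density(net) == 1.0

    def test_seventeen_node_arithmetic(self):
        w = np.zeros((17, 17))
        iu = np.triu_indices(17, 1)
        idx = np.random.default_rng(0).choice(136, size=72, replace=False)
        w[iu[0][idx], iu[1][idx]] = 0.1
        w = w + w.T
        net = NetworkModel(w, [f"V{i}" for i in range(17)], 0.1, 0.5, 367)
        assert edge_density(net) == pytest.approx(72 / 136)
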