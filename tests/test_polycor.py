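"""Polychoric estimation: oracles, invariances, pairwise deletion."""

import numpy as np
import pytest
from scipy.special import ndtri
from scipy.stats import multivariate_normal

import ordnet
from ordnet.polycor import (
    DegenerateMarginError,
    _clip_to_psd,
    correlation_matrix,
    polychoric_pair,
)
from ordnet.synth import OrdinalDataset


def _simulate_pair(rho, n, seed, cuts=(-0.84, -0.25, 0.25, 0.84)):
    rng = np.random.default_rng(seed)
    z = rng.multivariate_normal([0, 0], [[1, rho], [rho, 1]], size=n)
    cuts = np.asarray(cuts)
    return np.digitize(z[:, 0], cuts) + 1.0, np.digitize(z[:, 1], cuts) + 1.0


def test_perfect_concordance_hits_upper_bound():
    x = np.array([1, 2, 3, 4, 5] * 4, dtype=float)
    assert polychoric_pair(x, x) >= 0.99


def test_recovers_latent_rho_half():
    x, y = _simulate_pair(0.5, 10_000, seed=1)
    assert polychoric_pair(x, y) == pytest.approx(0.5, abs=0.03)


def test_tetrachoric_matches_brute_force_grid():
    """Binary data: the bounded search must agree with an exhaustive
    likelihood grid evaluated with scipy's bivariate normal CDF."""
    x, y = _simulate_pair(0.35, 2000, seed=4, cuts=(0.2,))
    est = polychoric_pair(x, y, max_categories=2)

    table = np.zeros((2, 2))
    np.add.at(table, (x.astype(int) - 1, y.astype(int) - 1), 1.0)
    tx = ndtri(np.cumsum(table.sum(1))[0] / table.sum())
    ty = ndtri(np.cumsum(table.sum(0))[0] / table.sum())

    def loglik(r):
        cov = [[1, r], [r, 1]]
        p11 = multivariate_normal.cdf([tx, ty], mean=[0, 0], cov=cov)
        px = multivariate_normal.cdf([tx, np.inf], mean=[0, 0], cov=cov)
        py = multivariate_normal.cdf([np.inf, ty], mean=[0, 0], cov=cov)
        probs = np.array(
            [[p11, px - p11], [py - p11, 1 - px - py + p11]]
        ).clip(1e-12)
        return (table * np.log(probs)).sum()

    grid = np.arange(-0.998, 0.999, 1e-3)
    best = grid[np.argmax([loglik(r) for r in grid])]
    assert est == pytest.approx(best, abs=1.5e-3)


def test_symmetry_in_arguments():
    x, y = _simulate_pair(-0.4, 3000, seed=7)
    assert polychoric_pair(x, y) == pytest.approx(polychoric_pair(y, x), abs=1e-8)


def test_invariant_to_monotone_relabelling():
    x, y = _simulate_pair(0.45, 3000, seed=8)
    relabel = {1: 1, 2: 3, 3: 4, 4: 6, 5: 9}
    xr = np.vectorize(relabel.get)(x.astype(int)).astype(float)
    yr = np.vectorize(relabel.get)(y.astype(int)).astype(float)
    a = polychoric_pair(x, y, max_categories=5)
    b = polychoric_pair(xr, yr, max_categories=9)
    assert a == pytest.approx(b, abs=1e-6)


def test_corrects_discretisation_attenuation():
    """At latent rho = 0.6 with 5 balanced bins, Pearson on the categories is
    attenuated; the polychoric estimate recovers the latent value."""
    cuts = ndtri([0.2, 0.4, 0.6, 0.8])
    x, y = _simulate_pair(0.6, 10_000, seed=9, cuts=cuts)
    pearson = np.corrcoef(x, y)[0, 1]
    poly = polychoric_pair(x, y)
    assert poly > pearson
    assert poly == pytest.approx(0.6, abs=0.03)


def test_degenerate_margin_raises():
    x = np.ones(50)
    y = np.array([1, 2] * 25, dtype=float)
    with pytest.raises(DegenerateMarginError):
        polychoric_pair(x, y)


class TestCorrelationMatrix:
    def test_complete_data_pairwise_n_constant(self, model17):
        d = ordnet.sample_ordinal(model17, 200, seed=3)
        R = correlation_matrix(d)
        iu = np.triu_indices(R.p, 1)
        assert np.all(R.pairwise_n[iu] == 200)

    def test_pairwise_counts_after_missingness(self, model17):
        d = ordnet.sample_ordinal(model17, 400, seed=4)
        d = ordnet.inject_missing(d, 0.05, seed=5)
        R = correlation_matrix(d)
        iu = np.triu_indices(R.p, 1)
        assert np.all(R.pairwise_n[iu] <= 400)
        assert R.mean_pairwise_n < 400
        obs = ~np.isnan(d.values)
        i, j = 0, 1
        assert R.pairwise_n[i, j] == int((obs[:, i] & obs[:, j]).sum())

    def test_adversarial_pairwise_deletion_triggers_repair(self):
        """Three items observed on disjoint row blocks so the pairwise
        estimates are mutually inconsistent (r12, r13 ~ +1, r23 ~ -1):
        assembly is non-PD and must be clipped back to PSD."""
        n = 150
        rng = np.random.default_rng(0)
        base = rng.integers(1, 6, size=n).astype(float)
        vals = np.full((n, 3), np.nan)
        g = np.repeat([0, 1, 2], n // 3)
        b0, b1, b2 = (g == 0), (g == 1), (g == 2)
        vals[b0, 0] = base[b0]; vals[b0, 1] = base[b0]          # r12 ~ +1
        vals[b1, 0] = base[b1]; vals[b1, 2] = base[b1]          # r13 ~ +1
        vals[b2, 1] = base[b2]; vals[b2, 2] = 6 - base[b2]      # r23 ~ -1
        data = OrdinalDataset(values=vals, item_labels=["a", "b", "c"])
        R = correlation_matrix(data)
        assert R.repaired
        assert np.linalg.eigvalsh(R.values).min() >= 1e-8
        assert np.all(np.diag(R.values) == 1.0)

    def test_too_few_complete_pairs_names_the_pair(self, model17):
        d = ordnet.sample_ordinal(model17, 60, seed=6)
        vals = d.values.copy()
        vals[: 55, 0] = np.nan
        vals[55:, 1] = np.nan
        bad = OrdinalDataset(vals, list(d.item_labels))
        with pytest.raises(ValueError, match="complete cases"):
            correlation_matrix(bad)


def test_clip_to_psd_restores_unit_diagonal_psd():
    m = np.array([[1.0, 0.99, 0.99], [0.99, 1.0, -0.99], [0.99, -0.99, 1.0]])
    assert np.linalg.eigvalsh(m).min() < 0
    fixed = _clip_to_psd(m)
    assert np.linalg.eigvalsh(fixed).min() >= 1e-8
    assert np.all(np.diag(fixed) == 1.0)
    assert np.allclose(fixed, fixed.T)
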