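"""Centrality measures and weighted clustering: hand oracles + properties."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import ordnet
from ordnet.centrality import (
    bridge_strength,
    eigencentrality,
    global_clustering,
    standardize,
    strength,
)
from conftest import make_network


def _random_weights(p, seed, density=0.5):
    rng = np.random.default_rng(seed)
    w = np.zeros((p, p))
    iu = np.triu_indices(p, 1)
    mask = rng.random(len(iu[0])) < density
    w[iu[0][mask], iu[1][mask]] = rng.uniform(-0.5, 0.5, mask.sum())
    return w + w.T


def test_strength_hand_sum():
    w = np.array([[0, 0.3, -0.2], [0.3, 0, 0], [-0.2, 0, 0]])
    assert np.allclose(strength(make_network(w)), [0.5, 0.3, 0.2])


def test_strength_empty_network_is_zero():
    assert np.all(strength(make_network(np.zeros((4, 4)))) == 0)


@given(st.integers(min_value=0, max_value=10_000))
@settings(max_examples=25, deadline=None, derandomize=True)
def test_strength_handshake_identity(seed):
    w = _random_weights(7, seed)
    s = strength(make_network(w))
    iu = np.triu_indices(7, 1)
    assert np.sum(s) == pytest.approx(2 * np.sum(np.abs(w[iu])))


def test_eigencentrality_star_closed_form():
    w = np.zeros((4, 4))
    w[0, 1:] = w[1:, 0] = 0.3
    e = eigencentrality(make_network(w))
    assert e[0] == pytest.approx(1.0)
    assert np.allclose(e[1:], 1 / np.sqrt(3), atol=1e-10)


def test_eigencentrality_scale_invariant_and_constant_on_equicorrelation():
    w = np.full((5, 5), 0.2)
    np.fill_diagonal(w, 0.0)
    e = eigencentrality(make_network(w))
    assert np.allclose(e, 1.0)
    e2 = eigencentrality(make_network(2 * w))
    assert np.allclose(e, e2)


def test_eigencentrality_empty_network_undefined():
    with pytest.raises(ValueError):
        eigencentrality(make_network(np.zeros((3, 3))))


def test_bridge_strength_hand_sum_and_single_community():
    w = np.array([[0, 0.3, -0.2], [0.3, 0, 0], [-0.2, 0, 0]])
    net = make_network(w)
    b = bridge_strength(net, np.array([1, 1, 2]))
    assert np.allclose(b, [0.2, 0.0, 0.2])
    assert np.all(bridge_strength(net, np.ones(3)) == 0)


@given(st.integers(min_value=0, max_value=10_000))
@settings(max_examples=25, deadline=None, derandomize=True)
def test_bridge_strength_bounded_by_strength(seed):
    w = _random_weights(8, seed)
    net = make_network(w)
    labels = np.random.default_rng(seed).integers(1, 4, size=8)
    assert np.all(bridge_strength(net, labels) <= strength(net) + 1e-12)


class TestGlobalClustering:
    def test_triangle_is_one(self):
        w = np.full((3, 3), 0.4)
        np.fill_diagonal(w, 0.0)
        assert global_clustering(make_network(w)) == pytest.approx(1.0)

    def test_open_path_is_zero(self):
        w = np.zeros((3, 3))
        w[0, 1] = w[1, 0] = 0.3
        w[1, 2] = w[2, 1] = 0.2
        assert global_clustering(make_network(w)) == 0.0

    @pytest.mark.parametrize("scale", [0.05, 0.3, 0.9])
    def test_clique_is_one_at_any_uniform_weight(self, scale):
        w = np.full((5, 5), scale)
        np.fill_diagonal(w, 0.0)
        assert global_clustering(make_network(w)) == pytest.approx(1.0)

    @pytest.mark.parametrize("variant", ["zhang", "onnela", "barrat"])
    def test_variants_bounded_and_agree_on_uniform_clique(self, variant):
        w = np.full((4, 4), 0.5)
        np.fill_diagonal(w, 0.0)
        assert global_clustering(make_network(w), variant) == pytest.approx(1.0)
        rand = make_network(_random_weights(7, 3))
        assert 0.0 <= global_clustering(rand, variant) <= 1.0

    def test_unknown_variant_rejected(self):
        with pytest.raises(ValueError):
            global_clustering(make_network(np.zeros((3, 3))), "watts")


class TestStandardize:
    def test_hand_case(self):
        assert np.allclose(standardize(np.array([1.0, 2.0, 3.0])), [-1, 0, 1])

    def test_moments_and_rank_preservation(self):
        rng = np.random.default_rng(4)
        x = rng.uniform(0, 5, size=20)
        z = standardize(x)
        assert z.mean() == pytest.approx(0.0, abs=1e-10)
        assert z.std(ddof=1) == pytest.approx(1.0, abs=1e-10)
        assert np.array_equal(np.argsort(z), np.argsort(x))

    def test_zero_sd_rejected(self):
        with pytest.raises(ValueError):
            standardize(np.array([2.0, 2.0, 2.0]))


def test_highest_total_weight_node_tops_strength_z(model17):
    net = make_network(model17.partial_corr, labels=list(model17.item_labels))
    tbl = ordnet.centrality_table(net, model17.communities)
    top = tbl["strength_z"].idxmax()
    assert tbl.loc[top, "strength"] == tbl["strength"].max()
    # z-columns standardised
    for col in ("strength_z", "eigencentrality_z", "bridge_strength_z"):
        assert tbl[col].mean() == pytest.approx(0.0, abs=1e-10)
        assert tbl[col].std(ddof=1) == pytest.approx(1.0, abs=1e-10)


def test_centralities_invariant_under_relabelling(model17):
    w = model17.partial_corr
    perm = np.random.default_rng(1).permutation(w.shape[0])
    net, net_p = make_network(w), make_network(w[np.ix_(perm, perm)])
    assert np.allclose(strength(net)[perm], strength(net_p))
    assert np.allclose(eigencentrality(net)[perm], eigencentrality(net_p))
    labels = model17.communities
    assert np.allclose(
        bridge_strength(net, labels)[perm], bridge_strength(net_p, labels[perm])
    )
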