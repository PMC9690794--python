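"""Node centrality and weighted clustering for partial-correlation networks.

Conventions follow the signed-network practice in psychometrics: strength,
eigencentrality and clustering operate on absolute edge weights (a strong
negative partial correlation is as structurally important as a positive
one). Betweenness and closeness are deliberately absent — they interpret
conditional associations as distances, which is not meaningful here.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .ggm import NetworkModel

__all__ = [
    "strength",
    "eigencentrality",
    "bridge_strength",
    "global_clustering",
    "standardize",
    "centrality_table",
]


def strength(network: NetworkModel) -> np.ndarray:
    """Sum of absolute edge weights incident to each node."""
    return np.abs(network.weights).sum(axis=1)


def eigencentrality(network: NetworkModel) -> np.ndarray:
    """Leading-eigenvector centrality of |W|, scaled to maximum 1.

    Computed as the Perron vector of the largest connected component (by
    node count, ties by total weight); nodes outside it get 0. Undefined on
    an empty network.
    """
    A = np.abs(network.weights)
    if not np.any(A > 0):
        raise ValueError("eigencentrality is undefined on an empty network")
    # connected components of the nonzero-edge graph
    p = network.p
    comp = -np.ones(p, dtype=int)
    c = 0
    for s in range(p):
        if comp[s] >= 0:
            continue
        stack = [s]
        comp[s] = c
        while stack:
            u = stack.pop()
            for v in np.nonzero(A[u] > 0)[0]:
                if comp[v] < 0:
                    comp[v] = c
                    stack.append(v)
        c += 1
    sizes = np.bincount(comp)
    weightsum = np.array([A[comp == k].sum() for k in range(c)])
    main = max(range(c), key=lambda k: (sizes[k], weightsum[k]))
    idx = np.nonzero(comp == main)[0]
    sub = A[np.ix_(idx, idx)]
    eigval, eigvec = np.linalg.eigh(sub)
    v = eigvec[:, -1]
    v = np.abs(v)  # Perron vector is sign-definite; fix orientation
    out = np.zeros(p)
    out[idx] = v / v.max()
    return out


def bridge_strength(network: NetworkModel, communities: np.ndarray) -> np.ndarray:
    """Per node, the summed absolute weight of edges to other communities."""
    labels = np.asarray(communities)
    if labels.shape[0] != network.p or np.any(pd.isna(labels)):
        raise ValueError("every node must carry a community label")
    A = np.abs(network.weights)
    other = labels[:, None] != labels[None, :]
    return (A * other).sum(axis=1)


def _zhang_clustering(A: np.ndarray) -> float:
    """Zhang–Horvath weighted clustering on max-normalised weights, averaged
    over nodes with at least two neighbours."""
    m = A.max()
    if m == 0:
        return 0.0
    W = A / m
    num = np.diag(W @ W @ W)
    s = W.sum(axis=1)
    den = s**2 - (W**2).sum(axis=1)
    degree = (A > 0).sum(axis=1)
    eligible = degree >= 2
    if not np.any(eligible):
        return 0.0
    ci = np.zeros(A.shape[0])
    ok = eligible & (den > 0)
    ci[ok] = num[ok] / den[ok]
    return float(ci[eligible].mean())


def _onnela_clustering(A: np.ndarray) -> float:
    m = A.max()
    if m == 0:
        return 0.0
    W = (A / m) ** (1.0 / 3.0)
    num = np.diag(W @ W @ W)
    degree = (A > 0).sum(axis=1)
    eligible = degree >= 2
    if not np.any(eligible):
        return 0.0
    ci = np.zeros(A.shape[0])
    denom = degree * (degree - 1)
    ci[eligible] = num[eligible] / denom[eligible]
    return float(ci[eligible].mean())


def _barrat_clustering(A: np.ndarray) -> float:
    adj = (A > 0).astype(float)
    s = A.sum(axis=1)
    degree = adj.sum(axis=1)
    eligible = degree >= 2
    if not np.any(eligible):
        return 0.0
    ci = np.zeros(A.shape[0])
    for i in np.nonzero(eligible)[0]:
        nbrs = np.nonzero(adj[i])[0]
        tot = 0.0
        for a in range(len(nbrs)):
            for b in range(a + 1, len(nbrs)):
                j, k = nbrs[a], nbrs[b]
                if adj[j, k]:
                    tot += (A[i, j] + A[i, k]) / 2.0
        ci[i] = tot / (s[i] * (degree[i] - 1) / 2) if s[i] > 0 else 0.0
    return float(ci[eligible].mean())


_CLUSTERING = {
    "zhang": _zhang_clustering,
    "onnela": _onnela_clustering,
    "barrat": _barrat_clustering,
}


def global_clustering(network: NetworkModel, variant: str = "zhang") -> float:
    """Weighted global clustering coefficient on absolute weights.

    The default is the Zhang–Horvath coefficient on max-normalised absolute
    weights; ``variant`` may also be ``"onnela"`` or ``"barrat"``.
    """
    try:
        fn = _CLUSTERING[variant]
    except KeyError:
        raise ValueError(f"unknown clustering variant {variant!r}") from None
    return fn(np.abs(network.weights))


def standardize(values: np.ndarray) -> np.ndarray:
    """z-scores with the sample (ddof=1) standard deviation."""
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ValueError("need at least 2 values to standardise")
    sd = values.std(ddof=1)
    if sd == 0:
        raise ValueError("cannot standardise values with zero standard deviation")
    return (values - values.mean()) / sd


def centrality_table(
    network: NetworkModel, communities: np.ndarray
) -> pd.DataFrame:
    """Raw and z-standardised strength, eigencentrality and bridge strength
    per node (columns mirroring the usual centrality-table layout)."""
    s = strength(network)
    e = eigencentrality(network)
    b = bridge_strength(network, communities)
    return pd.DataFrame(
        {
            "variable": network.node_labels,
            "strength": s,
            "eigencentrality": e,
            "bridge_strength": b,
            "strength_z": standardize(s),
            "eigencentrality_z": standardize(e),
            "bridge_strength_z": standardize(b),
        }
    )
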