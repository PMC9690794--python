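"""Community structure: walktrap detection, parametric bootstrap of the
community count, and within/between-community RMSEW connectivity.

Walktrap (Pons & Latapy) measures node similarity by short random walks on
the absolute-weight graph and agglomerates, cutting the dendrogram at the
partition of maximum weighted Newman modularity. Detection runs per
connected component; isolated nodes become singleton communities.

The parametric bootstrap quantifies uncertainty in the *number* of
communities: ordinal datasets are re-simulated from the Gaussian model
implied by the estimated network, and the full estimation pipeline
(polychoric matrix, EBIC-glasso, walktrap) is re-run on each replicate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import igraph as ig
import numpy as np
import pandas as pd

from .ggm import NetworkModel, select_network
from .polycor import correlation_matrix
from .synth import OrdinalDataset

__all__ = [
    "CommunityAssignment",
    "CommunityBootstrap",
    "walktrap",
    "modularity",
    "bootstrap_communities",
    "rmsew",
]

logger = logging.getLogger(__name__)


@dataclass
class CommunityAssignment:
    """Node -> community labels (contiguous ids 1..C) with modularity."""

    labels: np.ndarray
    modularity: float
    node_labels: list[str] = field(default_factory=list)

    @property
    def n_communities(self) -> int:
        return int(self.labels.max()) if self.labels.size else 0

    def to_frame(self) -> pd.DataFrame:
        names = self.node_labels or [f"V{i + 1}" for i in range(len(self.labels))]
        return pd.DataFrame({"node": names, "community": self.labels})


@dataclass
class CommunityBootstrap:
    """Distribution of the community count over bootstrap replicates."""

    counts: np.ndarray
    median: float
    ci_low: float  # percentile 2.5
    ci_high: float  # percentile 97.5
    mean: float
    ci_norm_low: float  # normal-approximation CI around the mean count
    ci_norm_high: float
    n_boot: int
    n_failed: int = 0


def modularity(weights: np.ndarray, labels: np.ndarray) -> float:
    """Weighted Newman modularity of a partition on |weights|."""
    A = np.abs(np.asarray(weights, dtype=float))
    m2 = A.sum()  # = 2m
    if m2 == 0:
        return 0.0
    k = A.sum(axis=1)
    same = np.asarray(labels)[:, None] == np.asarray(labels)[None, :]
    return float(((A - np.outer(k, k) / m2) * same).sum() / m2)


def _components(A: np.ndarray) -> list[np.ndarray]:
    p = A.shape[0]
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
    return [np.nonzero(comp == k)[0] for k in range(c)]


def walktrap(network: NetworkModel, steps: int = 4) -> CommunityAssignment:
    """Walktrap communities of the absolute-weight graph.

    Each connected component is processed independently; the component
    dendrogram is cut at maximum modularity; isolated nodes are singletons.
    An empty network therefore yields p singleton communities.
    """
    if steps < 1:
        raise ValueError("steps must be >= 1")
    A = np.abs(network.weights)
    labels = np.zeros(network.p, dtype=int)
    next_id = 1
    for idx in _components(A):
        if idx.size == 1:
            labels[idx[0]] = next_id
            next_id += 1
            continue
        sub = A[np.ix_(idx, idx)]
        g = ig.Graph.Weighted_Adjacency(sub.tolist(), mode="undirected", attr="weight")
        dendro = g.community_walktrap(weights="weight", steps=steps)
        member = np.asarray(dendro.as_clustering().membership)
        for local in range(member.max() + 1):
            labels[idx[member == local]] = next_id
            next_id += 1
    # relabel contiguously in order of first appearance
    seen: dict[int, int] = {}
    out = np.empty_like(labels)
    for i, lab in enumerate(labels):
        if lab not in seen:
            seen[lab] = len(seen) + 1
        out[i] = seen[lab]
    return CommunityAssignment(
        labels=out,
        modularity=modularity(network.weights, out),
        node_labels=list(network.node_labels),
    )


def implied_latent_correlation(network: NetworkModel) -> np.ndarray:
    """Correlation matrix implied by the network's partial correlations
    (precision with unit diagonal and -w off-diagonal, inverted, rescaled)."""
    p = network.p
    K = -network.weights.copy()
    np.fill_diagonal(K, 1.0)
    eigval, eigvec = np.linalg.eigh(K)
    if eigval.min() <= 1e-10:  # clip: LASSO networks are PD in practice
        eigval = np.maximum(eigval, 1e-6)
        K = (eigvec * eigval) @ eigvec.T
    sigma = np.linalg.inv(K)
    d = np.sqrt(np.diag(sigma))
    sigma = sigma / np.outer(d, d)
    return (sigma + sigma.T) / 2


def bootstrap_communities(
    network: NetworkModel,
    thresholds: np.ndarray,
    n: int,
    n_boot: int = 2500,
    steps: int = 4,
    seed: int = 0,
    gamma: float | None = None,
    n_lambda: int = 100,
    lambda_min_ratio: float = 0.01,
    max_failure_rate: float = 0.05,
) -> CommunityBootstrap:
    """Parametric bootstrap 95% CI for the number of communities.

    Each replicate simulates ``n`` ordinal respondents from the estimated
    network (latent Gaussian thresholded at ``thresholds``), re-estimates
    the polychoric matrix and the EBIC-glasso network, and re-runs walktrap.
    Failed replicates (degenerate margins, solver failures) are skipped and
    counted; more than ``max_failure_rate`` of them is an error.

    Reports the replicate counts, their median, the 2.5/97.5 percentile CI,
    and a normal-approximation CI around the mean count (mean +/- 1.96
    SD/sqrt(B)) — the latter is the convention that can produce intervals
    tighter than one integer.
    """
    if n < 50:
        raise ValueError("parametric bootstrap needs n >= 50")
    gamma = network.gamma if gamma is None else gamma
    sigma = implied_latent_correlation(network)
    rng = np.random.default_rng(seed)
    counts: list[int] = []
    n_failed = 0
    for b in range(n_boot):
        z = rng.multivariate_normal(np.zeros(network.p), sigma, size=n, method="cholesky")
        values = np.empty_like(z)
        for j in range(network.p):
            values[:, j] = np.digitize(z[:, j], thresholds[j]) + 1
        data = OrdinalDataset(
            values=values,
            item_labels=list(network.node_labels),
            n_categories=thresholds.shape[1] + 1,
        )
        try:
            R = correlation_matrix(data)
            net_b = select_network(
                R, gamma=gamma, n_lambda=n_lambda, lambda_min_ratio=lambda_min_ratio
            )
            counts.append(walktrap(net_b, steps=steps).n_communities)
        except Exception as err:  # noqa: BLE001 — any replicate failure is skipped
            logger.warning("bootstrap replicate %d failed: %s", b, err)
            n_failed += 1
    if n_failed > max_failure_rate * n_boot:
        raise RuntimeError(
            f"{n_failed}/{n_boot} parametric bootstrap replicates failed"
        )
    arr = np.asarray(counts, dtype=float)
    mean = float(arr.mean())
    half = 1.96 * float(arr.std(ddof=1)) / np.sqrt(arr.size) if arr.size > 1 else 0.0
    return CommunityBootstrap(
        counts=arr.astype(int),
        median=float(np.median(arr)),
        ci_low=float(np.percentile(arr, 2.5)),
        ci_high=float(np.percentile(arr, 97.5)),
        mean=mean,
        ci_norm_low=mean - half,
        ci_norm_high=mean + half,
        n_boot=n_boot,
        n_failed=n_failed,
    )


def rmsew(network: NetworkModel, communities: CommunityAssignment) -> pd.DataFrame:
    """Root mean squared edge weight per community block pair.

    For each unordered pair of communities (including a community with
    itself): RMSEW = sqrt(mean of w^2 over *all* node pairs in the block,
    zero edges included), plus the mean and SD of |w| over the same pairs.
    """
    labels = communities.labels
    if labels.shape[0] != network.p:
        raise ValueError("assignment does not match network size")
    W = network.weights
    rows = []
    ids = np.unique(labels)
    for a_i, a in enumerate(ids):
        for b in ids[a_i:]:
            ia = np.nonzero(labels == a)[0]
            ib = np.nonzero(labels == b)[0]
            if a == b:
                if ia.size < 2:
                    continue
                iu = np.triu_indices(ia.size, 1)
                w = W[np.ix_(ia, ia)][iu]
            else:
                w = W[np.ix_(ia, ib)].ravel()
            absw = np.abs(w)
            rows.append(
                {
                    "community_a": int(a),
                    "community_b": int(b),
                    "n_pairs": w.size,
                    "rmsew": float(np.sqrt(np.mean(w**2))),
                    "mean_abs": float(absw.mean()),
                    "sd_abs": float(absw.std(ddof=1)) if absw.size > 1 else 0.0,
                }
            )
    return pd.DataFrame(rows)
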