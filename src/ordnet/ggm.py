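"""Sparse Gaussian graphical model estimation: glasso path + EBIC selection.

The network is the partial-correlation matrix obtained from the penalised
precision matrix ``K``: ``w_ij = -K_ij / sqrt(K_ii * K_jj)``. The L1 penalty
is selected by minimising the Extended Bayesian Information Criterion

    EBIC = -2 * L(K) + E log(n) + 4 E gamma log(p)

where ``L = n/2 (log det K - tr(R K))`` is the Gaussian log-likelihood at
the sample correlation matrix ``R``, ``E`` counts nonzero upper-triangle
off-diagonals and ``gamma`` (default 0.5) is the extra-penalty hyperparameter;
``gamma = 0`` recovers ordinary BIC.

The convex solver behind each path point is the compiled block coordinate
descent in :mod:`ordnet._glasso`, warm-started along the decreasing penalty
sequence; the path, EBIC scoring and model selection live here.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from ._glasso import glasso_warm

from .polycor import CorrelationMatrix

__all__ = [
    "NetworkModel",
    "default_lambda_grid",
    "glasso_path",
    "ebic_score",
    "select_network",
    "edge_density",
]

logger = logging.getLogger(__name__)

#: |weight| below this is an exact zero (numeric noise floor).
EDGE_TOL = 1e-8


class GlassoError(RuntimeError):
    pass


@dataclass
class NetworkModel:
    """Estimated GGM: symmetric partial-correlation weights, zero diagonal."""

    weights: np.ndarray
    node_labels: list[str]
    lambda_selected: float
    gamma: float
    n_effective: float
    precision: np.ndarray | None = None
    selection_trace: pd.DataFrame | None = field(default=None, repr=False)

    @property
    def p(self) -> int:
        return self.weights.shape[0]

    def n_edges(self) -> int:
        iu = np.triu_indices(self.p, 1)
        return int((np.abs(self.weights[iu]) > 0).sum())

    def edge_list(self) -> pd.DataFrame:
        rows = []
        for i in range(self.p):
            for j in range(i + 1, self.p):
                if abs(self.weights[i, j]) > 0:
                    rows.append(
                        (self.node_labels[i], self.node_labels[j], self.weights[i, j])
                    )
        return pd.DataFrame(rows, columns=["node_i", "node_j", "weight"])

    def to_networkx(self):
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(self.node_labels)
        for i in range(self.p):
            for j in range(i + 1, self.p):
                if abs(self.weights[i, j]) > 0:
                    g.add_edge(
                        self.node_labels[i],
                        self.node_labels[j],
                        weight=float(self.weights[i, j]),
                    )
        return g

    def to_graphml(self, path: str | Path) -> None:
        import networkx as nx

        nx.write_graphml(self.to_networkx(), path)

    def validate(self) -> None:
        w = self.weights
        if not np.allclose(w, w.T, atol=1e-10):
            raise ValueError("weights not symmetric")
        if np.any(np.diag(w) != 0.0):
            raise ValueError("diagonal must be exactly 0")
        if np.any(np.abs(w) >= 1):
            raise ValueError("partial correlations must have magnitude < 1")


def default_lambda_grid(
    R: np.ndarray, n_lambda: int = 100, lambda_min_ratio: float = 0.01
) -> np.ndarray:
    """Log-spaced decreasing penalty grid from the largest absolute
    off-diagonal correlation down to ``lambda_min_ratio`` times it."""
    p = R.shape[0]
    lam_max = float(np.max(np.abs(R - np.diag(np.diag(R)))))
    lam_max = max(lam_max, 1e-4)
    return np.geomspace(lam_max, lam_max * lambda_min_ratio, n_lambda)


MAX_ITER = 200
#: outer stopping rule: mean absolute covariance change below
#: GLASSO_TOL * mean|off-diagonal of R| per sweep (reference-implementation
#: convention)
GLASSO_TOL = 1e-5


def glasso_path(
    R: CorrelationMatrix | np.ndarray,
    lambdas: np.ndarray,
    max_iter: int = MAX_ITER,
) -> list[np.ndarray | None]:
    """Penalised precision matrices along a decreasing penalty sequence.

    Entries are ``None`` where the solver failed (possible at tiny penalties
    on near-singular input); failures are logged. Raises
    :class:`GlassoError` if every penalty fails.
    """
    Rv = R.values if isinstance(R, CorrelationMatrix) else np.asarray(R, dtype=float)
    lambdas = np.asarray(lambdas, dtype=float)
    if np.any(lambdas <= 0) or np.any(np.diff(lambdas) >= 0):
        raise ValueError("lambdas must be positive and strictly decreasing")
    out: list[np.ndarray | None] = []
    n_fail = 0
    W_prev: np.ndarray | None = None
    for lam in lambdas:
        try:
            with np.errstate(over="raise", invalid="raise"):
                prec, W_prev, _ = glasso_warm(
                    Rv, lam, W_init=W_prev, max_iter=max_iter, tol=GLASSO_TOL
                )
            if not np.all(np.isfinite(prec)) or np.any(np.diag(prec) <= 0):
                raise FloatingPointError("non-finite or non-PD precision")
            out.append(prec)
        except (FloatingPointError, np.linalg.LinAlgError, ValueError) as err:
            logger.warning("glasso failed at lambda=%.5g: %s", lam, err)
            out.append(None)
            W_prev = None
            n_fail += 1
    if n_fail == len(lambdas):
        raise GlassoError(
            f"graphical lasso failed at every penalty (last lambda {lambdas[-1]:.4g})"
        )
    return out


def _count_edges(K: np.ndarray) -> int:
    iu = np.triu_indices(K.shape[0], 1)
    return int((np.abs(K[iu]) > EDGE_TOL).sum())


def ebic_score(
    K: np.ndarray, R: CorrelationMatrix | np.ndarray, n: float, gamma: float = 0.5
) -> float:
    """Extended BIC of a precision matrix against sample correlations."""
    Rv = R.values if isinstance(R, CorrelationMatrix) else np.asarray(R, dtype=float)
    sign, logdet = np.linalg.slogdet(K)
    if sign <= 0:
        raise ValueError("precision matrix must be positive definite")
    p = K.shape[0]
    loglik = 0.5 * n * (logdet - float(np.trace(Rv @ K)))
    E = _count_edges(K)
    return -2.0 * loglik + E * np.log(n) + 4.0 * E * gamma * np.log(p)


def _partials(K: np.ndarray) -> np.ndarray:
    d = np.sqrt(np.diag(K))
    w = -K / np.outer(d, d)
    np.fill_diagonal(w, 0.0)
    w[np.abs(w) < EDGE_TOL] = 0.0
    return (w + w.T) / 2


def select_network(
    R: CorrelationMatrix,
    n: float | None = None,
    gamma: float = 0.5,
    n_lambda: int = 100,
    lambda_min_ratio: float = 0.01,
    node_labels: list[str] | None = None,
) -> NetworkModel:
    """EBIC-glasso: fit the penalty path and return the EBIC-minimising
    partial-correlation network.

    ``n`` defaults to the mean of the pairwise complete-case counts, the
    effective sample size under pairwise deletion.
    """
    if n is None:
        n = R.mean_pairwise_n
    lambdas = default_lambda_grid(R.values, n_lambda, lambda_min_ratio)
    path = glasso_path(R, lambdas)
    rows = []
    best: tuple[float, float, np.ndarray] | None = None
    for lam, K in zip(lambdas, path):
        if K is None:
            continue
        score = ebic_score(K, R, n, gamma)
        rows.append((lam, _count_edges(K), score))
        if best is None or score < best[0]:
            best = (score, lam, K)
    assert best is not None  # glasso_path raised if everything failed
    _, lam_sel, K_sel = best
    labels = node_labels or R.item_labels or [f"V{i + 1}" for i in range(R.p)]
    model = NetworkModel(
        weights=_partials(K_sel),
        node_labels=list(labels),
        lambda_selected=float(lam_sel),
        gamma=gamma,
        n_effective=float(n),
        precision=K_sel,
        selection_trace=pd.DataFrame(rows, columns=["lambda", "n_edges", "ebic"]),
    )
    model.validate()
    return model


def edge_density(network: NetworkModel) -> float:
    """Fraction of possible node pairs carrying a nonzero edge."""
    p = network.p
    if p < 2:
        raise ValueError("edge density needs at least 2 nodes")
    return network.n_edges() / (p * (p - 1) / 2)
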