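"""Bootstrap precision and stability diagnostics for estimated networks.

Two resampling schemes:

* **Nonparametric edge bootstrap** — resample respondents with replacement,
  re-estimate the network, and summarise each edge's bootstrap distribution
  (mean and percentile 95% CI).
* **Case-dropping bootstrap** — repeatedly drop a fixed proportion of
  respondents, re-estimate, and correlate the subsample statistic (edge
  weights or node strengths) with the full-sample one. The correlation
  stability (CS) coefficient is the largest drop proportion at which that
  correlation stays >= 0.7 with 95% probability; values below 0.25 signal
  an unstable statistic and values above 0.50 a comfortably stable one.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .centrality import strength
from .ggm import NetworkModel, select_network
from .polycor import correlation_matrix
from .synth import OrdinalDataset

__all__ = [
    "EdgeBootstrap",
    "CaseDropResult",
    "BootstrapSummary",
    "bootstrap_edges",
    "case_dropping_bootstrap",
    "cs_from_result",
    "cs_coefficient",
    "DEFAULT_DROP_GRID",
]

logger = logging.getLogger(__name__)

#: Case-drop proportions 0.05, 0.10, ..., 0.75.
DEFAULT_DROP_GRID: tuple[float, ...] = tuple(np.round(np.arange(0.05, 0.76, 0.05), 2))


def _fit(data: OrdinalDataset, gamma, n_lambda, lambda_min_ratio) -> NetworkModel:
    R = correlation_matrix(data)
    return select_network(
        R, gamma=gamma, n_lambda=n_lambda, lambda_min_ratio=lambda_min_ratio
    )


def _edge_vector(net: NetworkModel) -> np.ndarray:
    iu = np.triu_indices(net.p, 1)
    return net.weights[iu]


@dataclass
class EdgeBootstrap:
    """Per-edge bootstrap distribution summary."""

    table: pd.DataFrame  # node_i, node_j, estimate, boot_mean, ci_low, ci_high
    samples: np.ndarray = field(repr=False)  # n_boot x n_pairs edge draws
    n_boot: int = 0
    n_failed: int = 0

    def mean_estimate_correlation(self) -> float:
        """Pearson correlation between sample estimates and bootstrap means
        across edges nonzero in the sample network."""
        t = self.table
        nz = t["estimate"].abs() > 0
        return float(np.corrcoef(t.loc[nz, "estimate"], t.loc[nz, "boot_mean"])[0, 1])


@dataclass
class CaseDropResult:
    """Per-level distributions of subsample-vs-original correlations."""

    statistic: str
    drop_grid: np.ndarray
    correlations: dict[float, np.ndarray]
    n_per_level: int
    n_failed: int = 0

    def mean_correlations(self) -> pd.Series:
        return pd.Series(
            {q: float(np.mean(c)) for q, c in self.correlations.items()},
            name="mean_correlation",
        )


@dataclass
class BootstrapSummary:
    """Combined precision/stability report for one dataset."""

    edges: EdgeBootstrap | None = None
    drop_edges: CaseDropResult | None = None
    drop_strength: CaseDropResult | None = None
    cs_edges: float | None = None
    cs_strength: float | None = None


def bootstrap_edges(
    data: OrdinalDataset,
    n_boot: int = 2500,
    seed: int = 0,
    gamma: float = 0.5,
    n_lambda: int = 100,
    lambda_min_ratio: float = 0.01,
    max_failure_rate: float = 0.05,
) -> EdgeBootstrap:
    """Nonparametric (row-resampling) bootstrap of edge weights."""
    if data.n < 50:
        raise ValueError("edge bootstrap needs n >= 50")
    net0 = _fit(data, gamma, n_lambda, lambda_min_ratio)
    est = _edge_vector(net0)
    rng = np.random.default_rng(seed)
    draws = []
    n_failed = 0
    for b in range(n_boot):
        rows = rng.integers(0, data.n, size=data.n)
        boot = OrdinalDataset(
            values=data.values[rows],
            item_labels=list(data.item_labels),
            n_categories=data.n_categories,
        )
        try:
            draws.append(_edge_vector(_fit(boot, gamma, n_lambda, lambda_min_ratio)))
        except Exception as err:  # noqa: BLE001
            logger.warning("edge bootstrap replicate %d failed: %s", b, err)
            n_failed += 1
    if n_failed > max_failure_rate * n_boot:
        raise RuntimeError(f"{n_failed}/{n_boot} bootstrap replicates failed")
    samples = np.asarray(draws)
    iu = np.triu_indices(net0.p, 1)
    table = pd.DataFrame(
        {
            "node_i": [net0.node_labels[i] for i in iu[0]],
            "node_j": [net0.node_labels[j] for j in iu[1]],
            "estimate": est,
            "boot_mean": samples.mean(axis=0),
            "ci_low": np.percentile(samples, 2.5, axis=0),
            "ci_high": np.percentile(samples, 97.5, axis=0),
        }
    )
    return EdgeBootstrap(table=table, samples=samples, n_boot=n_boot, n_failed=n_failed)


def _statistic_vector(net: NetworkModel, statistic: str) -> np.ndarray:
    if statistic == "edges":
        return _edge_vector(net)
    if statistic == "strength":
        return strength(net)
    raise ValueError("statistic must be 'edges' or 'strength'")


def case_dropping_bootstrap(
    data: OrdinalDataset,
    statistic: str = "strength",
    drop_grid: tuple[float, ...] = DEFAULT_DROP_GRID,
    n_per_level: int = 250,
    seed: int = 0,
    gamma: float = 0.5,
    n_lambda: int = 100,
    lambda_min_ratio: float = 0.01,
    max_failure_rate: float = 0.05,
) -> CaseDropResult:
    """Subsample the data at each drop proportion and correlate the
    re-estimated statistic with the full-sample one.

    The correlation is Pearson, computed over the entries that are nonzero
    in the original network (for edges) or over all nodes (for strength).
    Seeds for the levels are spawned independently from ``seed``.
    """
    grid = np.asarray(sorted(drop_grid), dtype=float)
    if np.any(grid <= 0) or np.any(grid >= 0.95):
        raise ValueError("drop proportions must lie in (0, 0.95)")
    net0 = _fit(data, gamma, n_lambda, lambda_min_ratio)
    ref = _statistic_vector(net0, statistic)
    if statistic == "edges":
        keep = np.abs(ref) > 0
        if keep.sum() < 3:
            raise ValueError("too few nonzero edges to correlate")
    else:
        keep = np.ones_like(ref, dtype=bool)
    ref = ref[keep]

    child_seeds = np.random.SeedSequence(seed).spawn(len(grid))
    corrs: dict[float, np.ndarray] = {}
    total_failed = 0
    for q, ss in zip(grid, child_seeds):
        rng = np.random.default_rng(ss)
        m = int(round((1.0 - q) * data.n))
        level = []
        for _ in range(n_per_level):
            rows = rng.choice(data.n, size=m, replace=False)
            sub = OrdinalDataset(
                values=data.values[rows],
                item_labels=list(data.item_labels),
                n_categories=data.n_categories,
            )
            try:
                stat = _statistic_vector(
                    _fit(sub, gamma, n_lambda, lambda_min_ratio), statistic
                )[keep]
            except Exception as err:  # noqa: BLE001
                logger.warning("case-drop replicate (q=%.2f) failed: %s", q, err)
                total_failed += 1
                continue
            if np.std(stat) == 0 or np.std(ref) == 0:
                level.append(0.0)  # degenerate subsample network
            else:
                level.append(float(np.corrcoef(ref, stat)[0, 1]))
        corrs[float(q)] = np.asarray(level)
    if total_failed > max_failure_rate * len(grid) * n_per_level:
        raise RuntimeError(f"{total_failed} case-dropping replicates failed")
    return CaseDropResult(
        statistic=statistic,
        drop_grid=grid,
        correlations=corrs,
        n_per_level=n_per_level,
        n_failed=total_failed,
    )


def cs_from_result(
    result: CaseDropResult, cor_threshold: float = 0.7, prob: float = 0.95
) -> float:
    """CS coefficient: largest drop proportion whose correlation
    distribution stays >= ``cor_threshold`` with probability ``prob``;
    0.0 if no level qualifies."""
    qualifying = [
        q
        for q, c in result.correlations.items()
        if c.size and np.mean(c >= cor_threshold) >= prob
    ]
    return max(qualifying) if qualifying else 0.0


def cs_coefficient(
    data: OrdinalDataset,
    statistic: str = "strength",
    drop_grid: tuple[float, ...] = DEFAULT_DROP_GRID,
    n_per_level: int = 250,
    cor_threshold: float = 0.7,
    prob: float = 0.95,
    seed: int = 0,
    **estimator_kwargs,
) -> float:
    """Convenience wrapper: run the case-dropping bootstrap and return CS."""
    result = case_dropping_bootstrap(
        data,
        statistic=statistic,
        drop_grid=drop_grid,
        n_per_level=n_per_level,
        seed=seed,
        **estimator_kwargs,
    )
    return cs_from_result(result, cor_threshold=cor_threshold, prob=prob)
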