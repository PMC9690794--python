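"""Synthetic ordinal questionnaire data from ground-truth sparse GGMs.

The study data this package was written around (17 five-point items on
perceived stress, coping and social support, n = 367 pregnant women) is
confidential, so every downstream stage is exercised against data drawn from
a known Gaussian graphical model instead. Two generators are provided:

* :func:`generate_true_ggm` — planted-community networks (default: three
  blocks of 7 stress, 6 coping and 4 support items; positive edges within
  blocks, negative stress--coping and stress--support edges, positive
  coping--support edges), for recovery and community-detection tests.
* :func:`generate_random_ggm` — the uniformly-weak-edge construction used by
  Monte-Carlo sample-size tools for psychological networks (edge weights
  U(0.5, 1) before scaling, 90% positive, precision diagonal set to a
  multiple of the maximum absolute column sum), for power analysis.

Ordinal responses arise by thresholding latent Gaussian vectors, the same
assumption under which polychoric correlations are consistent.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import ndtri

__all__ = [
    "TrueModel",
    "OrdinalDataset",
    "DEFAULT_BLOCKS",
    "DEFAULT_BLOCK_SIGNS",
    "default_thresholds",
    "generate_true_ggm",
    "generate_random_ggm",
    "sample_ordinal",
    "inject_missing",
]

#: Default synthetic instrument: 7 stress + 6 coping + 4 support items.
DEFAULT_BLOCKS: tuple[int, ...] = (7, 6, 4)

#: Sign of the partial correlations per (unordered) block pair, 0-indexed
#: blocks in the order stress, coping, support.
DEFAULT_BLOCK_SIGNS: dict[tuple[int, int], int] = {
    (0, 0): +1,
    (1, 1): +1,
    (2, 2): +1,
    (0, 1): -1,  # stress–coping
    (0, 2): -1,  # stress–support
    (1, 2): +1,  # coping–support
}

#: Default edge-magnitude intervals: strong within blocks, weak between
#: (~3:1, the within/between contrast reported for questionnaire networks).
DEFAULT_WITHIN_RANGE: tuple[float, float] = (0.2, 0.4)
DEFAULT_BETWEEN_RANGE: tuple[float, float] = (0.03, 0.10)


class ParameterError(ValueError):
    """Infeasible generator configuration."""


@dataclass
class TrueModel:
    """Ground-truth GGM: standardised precision matrix and its network.

    ``partial_corr[i, j] = -precision[i, j] / sqrt(precision[i, i] *
    precision[j, j])`` off the diagonal, zero on it; this is the edge-weight
    convention of the Gaussian graphical model (standardise the precision
    matrix and reverse the sign).
    """

    precision: np.ndarray
    partial_corr: np.ndarray
    communities: np.ndarray  # int labels, 1..C
    thresholds: np.ndarray  # p x (K-1), strictly increasing per row
    seed: int
    item_labels: list[str] = field(default_factory=list)

    @property
    def p(self) -> int:
        return self.precision.shape[0]

    @property
    def n_categories(self) -> int:
        return self.thresholds.shape[1] + 1

    def latent_correlation(self) -> np.ndarray:
        """Model-implied correlation of the latent Gaussian (inverse of the
        precision matrix rescaled to unit diagonal)."""
        sigma = np.linalg.inv(self.precision)
        d = np.sqrt(np.diag(sigma))
        return sigma / np.outer(d, d)

    def validate(self) -> None:
        k = self.precision
        if not np.allclose(k, k.T, atol=1e-12):
            raise ValueError("precision matrix is not symmetric")
        if np.linalg.eigvalsh(k).min() <= 0:
            raise ValueError("precision matrix is not positive definite")
        d = np.sqrt(np.diag(k))
        w = -k / np.outer(d, d)
        np.fill_diagonal(w, 0.0)
        if not np.allclose(w, self.partial_corr, atol=1e-12):
            raise ValueError("partial_corr inconsistent with precision")
        if np.any(np.diff(self.thresholds, axis=1) <= 0):
            raise ValueError("thresholds must be strictly increasing per item")

    def to_files(self, edge_csv: str | Path, sidecar_json: str | Path) -> None:
        """Write nonzero edges as CSV plus a JSON sidecar with thresholds,
        community labels and the seed."""
        p = self.p
        rows = []
        labels = self.item_labels or [f"V{i + 1}" for i in range(p)]
        for i in range(p):
            for j in range(i + 1, p):
                if self.partial_corr[i, j] != 0.0:
                    rows.append((labels[i], labels[j], self.partial_corr[i, j]))
        pd.DataFrame(rows, columns=["node_i", "node_j", "weight"]).to_csv(
            edge_csv, index=False
        )
        meta = {
            "thresholds": self.thresholds.tolist(),
            "communities": self.communities.tolist(),
            "seed": self.seed,
            "item_labels": labels,
        }
        Path(sidecar_json).write_text(json.dumps(meta, indent=1))


@dataclass
class OrdinalDataset:
    """Respondent x item matrix of ordinal scores in 1..K, NaN = missing."""

    values: np.ndarray  # float array, NaN marks missing
    item_labels: list[str]
    n_categories: int = 5

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def p(self) -> int:
        return self.values.shape[1]

    def validate(self) -> None:
        if self.p < 3:
            raise ValueError("need at least 3 items")
        obs = self.values[~np.isnan(self.values)]
        if obs.size and (
            np.any(obs != np.round(obs)) or obs.min() < 1 or obs.max() > self.n_categories
        ):
            raise ValueError(f"scores must be integers in 1..{self.n_categories}")
        for j in range(self.p):
            col = self.values[:, j]
            if np.unique(col[~np.isnan(col)]).size < 2:
                raise ValueError(
                    f"item {self.item_labels[j]!r} has fewer than 2 observed categories"
                )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, columns=self.item_labels)

    def to_csv(self, path: str | Path) -> None:
        df = self.to_dataframe().astype("Int64")
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, n_categories: int = 5) -> "OrdinalDataset":
        df = pd.read_csv(path)
        return cls(
            values=df.to_numpy(dtype=float),
            item_labels=[str(c) for c in df.columns],
            n_categories=n_categories,
        )


def default_thresholds(p: int, n_categories: int = 5) -> np.ndarray:
    """Equal-probability category thresholds on the standard-normal scale."""
    cuts = ndtri(np.arange(1, n_categories) / n_categories)
    return np.tile(cuts, (p, 1))


def _default_labels(blocks: tuple[int, ...] | list[int]) -> list[str]:
    names = ["stress", "coping", "support"]
    labels: list[str] = []
    for b, size in enumerate(blocks):
        stem = names[b] if b < len(names) else f"block{b + 1}"
        labels += [f"{stem}{i + 1}" for i in range(size)]
    return labels


def _allocate_edges(
    m: int,
    pair_counts: dict[tuple[int, int], int],
    within_tilt: float = 1.0,
) -> dict[tuple[int, int], int]:
    """Largest-remainder allocation of m edges across block pairs.

    Allocation weight is the number of node pairs in the block pair, times
    ``within_tilt`` for within-block pairs — a tilt > 1 concentrates edges
    inside blocks the way questionnaire subscales do."""
    share = {
        k: c * (within_tilt if k[0] == k[1] else 1.0) for k, c in pair_counts.items()
    }
    total = sum(share.values())
    exact = {k: m * s / total for k, s in share.items()}
    base = {k: int(np.floor(v)) for k, v in exact.items()}
    for k, c in pair_counts.items():
        base[k] = min(base[k], c)
    short = m - sum(base.values())
    order = sorted(exact, key=lambda k: exact[k] - base[k], reverse=True)
    while short > 0:
        placed = 0
        for k in order:
            if short > 0 and base[k] < pair_counts[k]:
                base[k] += 1
                short -= 1
                placed += 1
        if placed == 0:  # no capacity anywhere
            raise ParameterError("edge count exceeds available node pairs")
    return base


def _standardise_precision(omega: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    d = np.sqrt(np.diag(omega))
    k = omega / np.outer(d, d)
    w = -k.copy()
    np.fill_diagonal(w, 0.0)
    np.fill_diagonal(k, 1.0)
    return k, w


def generate_true_ggm(
    p: int = 17,
    density: float = 0.4,
    communities: tuple[int, ...] | list[int] = DEFAULT_BLOCKS,
    weight_ranges: dict[tuple[int, int], tuple[float, float, int]] | None = None,
    seed: int = 0,
    n_categories: int = 5,
    thresholds: np.ndarray | None = None,
    ridge: float = 0.1,
    within_tilt: float = 3.5,
) -> TrueModel:
    """Generate a sparse GGM with planted block (community) structure.

    Exactly ``round(density * p*(p-1)/2)`` edges are placed across block
    pairs by largest-remainder allocation with within-block pairs carrying
    ``within_tilt`` times the weight of between-block pairs (default 3.5,
    emulating the dense-subscale / sparse-bridge structure of questionnaire
    networks; 1.0 gives allocation proportional to pair counts).
    Edge magnitudes are uniform on the configured interval per block pair
    (default 0.2–0.4 within blocks, 0.03–0.10 between, mirroring the strong
    within/between contrast of questionnaire networks) with the configured
    sign per block pair; positive definiteness is then
    enforced by setting the precision diagonal to the absolute row sum plus
    ``ridge`` (diagonal dominance) and standardising.

    Parameters
    ----------
    weight_ranges
        Optional map ``(block_a, block_b) -> (lo, hi, sign)`` with
        ``block_a <= block_b`` 0-indexed and sign in ``{-1, +1}``; defaults
        to magnitudes 0.1–0.4 and the stress/coping/support sign pattern.
    """
    communities = tuple(int(b) for b in communities)
    if sum(communities) != p:
        raise ParameterError(f"block sizes {communities} do not sum to p={p}")
    if not 0.0 <= density <= 1.0:
        raise ParameterError("density must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    labels = np.repeat(np.arange(len(communities)), communities)

    n_pairs = p * (p - 1) // 2
    m = int(round(density * n_pairs))
    block_pairs: dict[tuple[int, int], list[tuple[int, int]]] = {}
    for i in range(p):
        for j in range(i + 1, p):
            key = (int(labels[i]), int(labels[j]))
            block_pairs.setdefault(key, []).append((i, j))

    def cfg(key: tuple[int, int]) -> tuple[float, float, int]:
        if weight_ranges is not None and key in weight_ranges:
            lo, hi, sign = weight_ranges[key]
        else:
            within = key[0] == key[1]
            lo, hi = DEFAULT_WITHIN_RANGE if within else DEFAULT_BETWEEN_RANGE
            sign = DEFAULT_BLOCK_SIGNS.get(key, +1)
        if not (0 <= lo <= hi < 1):
            raise ParameterError(f"weight magnitudes for {key} must satisfy 0<=lo<=hi<1")
        if sign not in (-1, +1):
            raise ParameterError(f"sign for {key} must be -1 or +1")
        return lo, hi, sign

    alloc = _allocate_edges(
        m, {k: len(v) for k, v in block_pairs.items()}, within_tilt=within_tilt
    )
    omega = np.zeros((p, p))
    for key, pairs in block_pairs.items():
        lo, hi, sign = cfg(key)
        take = alloc.get(key, 0)
        idx = rng.choice(len(pairs), size=take, replace=False)
        for t in idx:
            i, j = pairs[t]
            w = sign * rng.uniform(lo, hi)
            omega[i, j] = omega[j, i] = -w  # precision sign is opposite the edge
    np.fill_diagonal(omega, np.abs(omega).sum(axis=1) + ridge)

    eig_min = np.linalg.eigvalsh(omega).min()
    if eig_min <= 0:
        raise ParameterError(
            f"positive-definiteness repair failed (smallest eigenvalue {eig_min:.3e})"
        )
    precision, partial = _standardise_precision(omega)
    model = TrueModel(
        precision=precision,
        partial_corr=partial,
        communities=labels + 1,
        thresholds=(
            thresholds if thresholds is not None else default_thresholds(p, n_categories)
        ),
        seed=seed,
        item_labels=_default_labels(communities),
    )
    model.validate()
    return model


def generate_random_ggm(
    p: int = 17,
    density: float = 0.4,
    weight_range: tuple[float, float] = (0.5, 1.0),
    positive_prob: float = 0.9,
    constant: float = 1.5,
    seed: int = 0,
    n_categories: int = 5,
) -> TrueModel:
    """Random GGM in the weak-uniform-edge regime of network sample-size
    simulators.

    Edge support is uniform over node pairs (exactly ``round(density *
    p*(p-1)/2)`` edges); raw weights are uniform on ``weight_range`` with
    probability ``positive_prob`` of a positive sign; the precision diagonal
    is set to ``constant`` times the maximum absolute column sum before
    standardising, which shrinks every partial correlation by the same
    factor (typical resulting magnitudes ~0.05–0.11 at the defaults). All
    nodes are assigned to a single community.
    """
    if not 0.0 <= density <= 1.0:
        raise ParameterError("density must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    n_pairs = p * (p - 1) // 2
    m = int(round(density * n_pairs))
    iu = np.triu_indices(p, 1)
    idx = rng.choice(n_pairs, size=m, replace=False)
    w = rng.uniform(*weight_range, size=m)
    w *= np.where(rng.random(m) < positive_prob, 1.0, -1.0)
    omega = np.zeros((p, p))
    omega[iu[0][idx], iu[1][idx]] = -w
    omega += omega.T
    np.fill_diagonal(omega, constant * np.abs(omega).sum(axis=0).max())
    precision, partial = _standardise_precision(omega)
    model = TrueModel(
        precision=precision,
        partial_corr=partial,
        communities=np.ones(p, dtype=int),
        thresholds=default_thresholds(p, n_categories),
        seed=seed,
        item_labels=[f"V{i + 1}" for i in range(p)],
    )
    model.validate()
    return model


def sample_ordinal(model: TrueModel, n: int, seed: int = 0) -> OrdinalDataset:
    """Draw n respondents: latent multivariate normal with the model-implied
    correlation matrix, thresholded to ordinal categories 1..K."""
    if n < 1:
        raise ValueError("sample size must be at least 1")
    rng = np.random.default_rng(seed)
    sigma = model.latent_correlation()
    z = rng.multivariate_normal(np.zeros(model.p), sigma, size=n, method="cholesky")
    values = np.empty_like(z)
    for j in range(model.p):
        values[:, j] = np.digitize(z[:, j], model.thresholds[j]) + 1
    return OrdinalDataset(
        values=values,
        item_labels=list(model.item_labels) or [f"V{j + 1}" for j in range(model.p)],
        n_categories=model.n_categories,
    )


def inject_missing(data: OrdinalDataset, rate: float, seed: int = 0) -> OrdinalDataset:
    """Set each cell to missing independently with probability ``rate`` (MCAR)."""
    if not 0.0 <= rate < 0.5:
        raise ValueError("missingness rate must lie in [0, 0.5)")
    rng = np.random.default_rng(seed)
    values = data.values.copy()
    if rate > 0:
        mask = rng.random(values.shape) < rate
        values[mask] = np.nan
        if np.any(np.all(np.isnan(values), axis=0)):
            raise ValueError("missingness left an item with no observed values")
    return OrdinalDataset(
        values=values, item_labels=list(data.item_labels), n_categories=data.n_categories
    )
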