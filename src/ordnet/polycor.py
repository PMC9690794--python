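"""Polychoric correlation matrices from ordinal data under pairwise deletion.

A polychoric correlation treats two ordinal items as discretised views of a
latent bivariate normal and estimates the latent correlation from their
contingency table. Estimation here is the classic two-step procedure:
thresholds are fixed at standard-normal quantiles of the marginal cumulative
proportions, then the correlation maximises the bivariate-normal likelihood
of the table by bounded one-dimensional search.

Pairwise deletion (each pair estimated from rows complete for that pair) can
yield an assembled matrix that is not positive semi-definite; the repair is
eigenvalue clipping followed by rescaling to unit diagonal, with the
``repaired`` flag set so downstream consumers can tell.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.special import ndtri

from ._bvn import bvn_cdf
from .synth import OrdinalDataset

__all__ = [
    "CorrelationMatrix",
    "polychoric_pair",
    "correlation_matrix",
    "DegenerateMarginError",
]

RHO_BOUND = 0.999
MIN_COMPLETE_PAIRS = 10
_PROB_FLOOR = 1e-12


class DegenerateMarginError(ValueError):
    """An item has fewer than two observed categories after deletion."""


@dataclass
class CorrelationMatrix:
    """Polychoric correlation matrix with pairwise complete-case counts."""

    values: np.ndarray
    pairwise_n: np.ndarray
    item_labels: list[str] = field(default_factory=list)
    repaired: bool = False

    @property
    def p(self) -> int:
        return self.values.shape[0]

    @property
    def mean_pairwise_n(self) -> float:
        iu = np.triu_indices(self.p, 1)
        return float(np.mean(self.pairwise_n[iu]))

    def validate(self) -> None:
        v = self.values
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("correlation matrix not symmetric")
        if not np.all(np.diag(v) == 1.0):
            raise ValueError("diagonal must be exactly 1")
        if np.any(np.abs(v) > 1 + 1e-12):
            raise ValueError("entries must lie in [-1, 1]")

    def to_csv(self, path: str | Path, counts_path: str | Path | None = None) -> None:
        labels = self.item_labels or [f"V{i + 1}" for i in range(self.p)]
        pd.DataFrame(self.values, index=labels, columns=labels).to_csv(path)
        if counts_path is not None:
            pd.DataFrame(self.pairwise_n, index=labels, columns=labels).to_csv(
                counts_path
            )


def _thresholds_from_margin(codes: np.ndarray, k: int) -> np.ndarray:
    """Cut-points (length k+1, with -inf/+inf ends) from observed category
    proportions of integer codes 0..k-1."""
    counts = np.bincount(codes, minlength=k).astype(float)
    cum = np.cumsum(counts) / counts.sum()
    inner = ndtri(np.clip(cum[:-1], 1e-10, 1 - 1e-10))
    return np.concatenate(([-np.inf], inner, [np.inf]))


def _table_loglik(table: np.ndarray, ta: np.ndarray, tb: np.ndarray, rho: float) -> float:
    cdf = bvn_cdf(ta[:, None], tb[None, :], rho)
    probs = np.diff(np.diff(cdf, axis=0), axis=1)
    probs = np.clip(probs, _PROB_FLOOR, 1.0)
    return float((table * np.log(probs)).sum())


def polychoric_pair(
    x: np.ndarray, y: np.ndarray, max_categories: int = 5
) -> float:
    """Two-step polychoric correlation of two ordinal vectors.

    Rows where either value is missing (NaN) are dropped. Categories are the
    integers ``1..max_categories``; unobserved categories collapse to
    zero-probability cells and do not perturb the estimate.

    Returns the latent correlation in ``(-RHO_BOUND, RHO_BOUND)``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    if x.size < MIN_COMPLETE_PAIRS:
        raise ValueError(
            f"only {x.size} complete pairs; at least {MIN_COMPLETE_PAIRS} required"
        )
    cx = x.astype(int) - 1
    cy = y.astype(int) - 1
    if np.unique(cx).size < 2:
        raise DegenerateMarginError("first item has a single observed category")
    if np.unique(cy).size < 2:
        raise DegenerateMarginError("second item has a single observed category")

    k = max_categories
    table = np.zeros((k, k))
    np.add.at(table, (cx, cy), 1.0)
    ta = _thresholds_from_margin(cx, k)
    tb = _thresholds_from_margin(cy, k)

    res = minimize_scalar(
        lambda r: -_table_loglik(table, ta, tb, r),
        bounds=(-RHO_BOUND, RHO_BOUND),
        method="bounded",
        options={"xatol": 1e-5},
    )
    if not res.success:
        raise RuntimeError(
            f"polychoric search failed on bracket (-{RHO_BOUND}, {RHO_BOUND}): "
            f"{res.message}"
        )
    return float(res.x)


def _clip_to_psd(values: np.ndarray, floor: float = 1e-6) -> np.ndarray:
    """Eigenvalue clipping with rescale to unit diagonal."""
    eigval, eigvec = np.linalg.eigh(values)
    eigval = np.maximum(eigval, floor)
    fixed = (eigvec * eigval) @ eigvec.T
    d = np.sqrt(np.diag(fixed))
    fixed = fixed / np.outer(d, d)
    fixed = (fixed + fixed.T) / 2
    np.fill_diagonal(fixed, 1.0)
    return fixed


def correlation_matrix(
    data: OrdinalDataset, min_pairs: int = MIN_COMPLETE_PAIRS
) -> CorrelationMatrix:
    """Assemble the full polychoric matrix under pairwise deletion.

    Element (i, j) uses the rows where both items are observed;
    ``pairwise_n`` records those counts. If the assembled matrix is not
    positive semi-definite it is repaired by eigenvalue clipping (smallest
    eigenvalue floored at 1e-6, rescaled to unit diagonal) and the
    ``repaired`` flag is set.
    """
    data.validate()
    p = data.p
    vals = np.eye(p)
    counts = np.zeros((p, p), dtype=int)
    observed = ~np.isnan(data.values)
    np.fill_diagonal(counts, observed.sum(axis=0))
    for i in range(p):
        for j in range(i + 1, p):
            both = observed[:, i] & observed[:, j]
            n_ij = int(both.sum())
            if n_ij < min_pairs:
                raise ValueError(
                    f"items {data.item_labels[i]!r} and {data.item_labels[j]!r} share "
                    f"only {n_ij} complete cases (minimum {min_pairs})"
                )
            counts[i, j] = counts[j, i] = n_ij
            try:
                r = polychoric_pair(
                    data.values[both, i], data.values[both, j], data.n_categories
                )
            except DegenerateMarginError as err:
                raise DegenerateMarginError(
                    f"pair ({data.item_labels[i]!r}, {data.item_labels[j]!r}): {err}"
                ) from err
            vals[i, j] = vals[j, i] = r

    repaired = False
    if np.linalg.eigvalsh(vals).min() < 1e-8:
        vals = _clip_to_psd(vals)
        repaired = True
    out = CorrelationMatrix(
        values=vals,
        pairwise_n=counts,
        item_labels=list(data.item_labels),
        repaired=repaired,
    )
    out.validate()
    return out
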