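"""Monte-Carlo sample-size estimation for GGM edge recovery.

The question answered: how many respondents are needed so that an
EBIC-glasso network of ``p`` nodes and true edge density ``d`` recovers at
least a target fraction of the true edges (sensitivity) in at least a
target fraction of replications (power)?

Sensitivity is TP / (TP + FN): true edges estimated nonzero over all true
edges. False positives do not enter.

True networks come from :func:`ordnet.synth.generate_random_ggm`, the
uniformly-weak-edge construction used by network sample-size simulators
(all partial correlations ~0.05–0.11 at the defaults); this regime — not
the strong planted-community generator used elsewhere in the package — is
what makes the required sample sizes land in the thousands.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.isotonic import IsotonicRegression

from .ggm import NetworkModel, select_network
from .polycor import CorrelationMatrix, correlation_matrix
from .synth import TrueModel, generate_random_ggm, sample_ordinal

__all__ = ["PowerResult", "sensitivity", "estimate_sample_size"]


def sensitivity(true_model: TrueModel, estimated: NetworkModel) -> float:
    """Edge-recovery sensitivity TP / (TP + FN) of an estimated network."""
    if true_model.p != estimated.p:
        raise ValueError("true and estimated networks differ in size")
    iu = np.triu_indices(true_model.p, 1)
    truth = np.abs(true_model.partial_corr[iu]) > 1e-12
    if not truth.any():
        raise ValueError("sensitivity is undefined for an empty true network")
    est = np.abs(estimated.weights[iu]) > 0
    tp = int((truth & est).sum())
    return tp / int(truth.sum())


@dataclass
class PowerResult:
    """Outcome of the sample-size search."""

    candidate_ns: np.ndarray
    curve: pd.DataFrame  # n, fraction_meeting, smoothed_fraction, sens quantiles
    selected_n: int
    attained: bool
    sens_target: float
    power_target: float
    reps: int
    seed: int


def _gaussian_corr(model: TrueModel, n: int, rng: np.random.Generator) -> np.ndarray:
    sigma = model.latent_correlation()
    x = rng.multivariate_normal(np.zeros(model.p), sigma, size=n, method="cholesky")
    return np.corrcoef(x, rowvar=False)


def estimate_sample_size(
    p: int = 17,
    density: float = 0.4,
    sens_target: float = 0.6,
    power_target: float = 0.8,
    candidate_ns: tuple[int, ...] = tuple(range(250, 3001, 250)),
    reps: int = 100,
    mode: str = "ordinal",
    gamma: float = 0.5,
    n_lambda: int = 100,
    lambda_min_ratio: float = 0.01,
    seed: int = 0,
) -> PowerResult:
    """Smallest candidate n meeting the sensitivity/power criterion.

    For every candidate n and replicate: draw a fresh true network, simulate
    data (``mode="ordinal"``: 5-category items + polychoric matrix, the full
    analysis pipeline; ``mode="gaussian"``: continuous latent data + Pearson
    matrix, much faster and nearly equivalent since the items carry balanced
    categories), fit EBIC-glasso, and record sensitivity. The per-n fraction
    of replicates with sensitivity >= ``sens_target`` is smoothed by
    isotonic (monotone non-decreasing) regression before selection, which
    de-noises the grid without interpolating off it.

    If no candidate reaches ``power_target`` the result is flagged
    (``attained=False``) and the largest candidate is reported.
    """
    if mode not in ("ordinal", "gaussian"):
        raise ValueError("mode must be 'ordinal' or 'gaussian'")
    grid = np.asarray(sorted(candidate_ns), dtype=int)
    if reps < 1:
        raise ValueError("reps must be positive")
    master = np.random.SeedSequence(seed)
    rows = []
    for n, ss in zip(grid, master.spawn(len(grid))):
        rng = np.random.default_rng(ss)
        sens = []
        for r in range(reps):
            model_seed = int(rng.integers(0, 2**31 - 1))
            model = generate_random_ggm(p=p, density=density, seed=model_seed)
            if mode == "gaussian":
                Rv = _gaussian_corr(model, int(n), rng)
                R = CorrelationMatrix(
                    values=Rv,
                    pairwise_n=np.full((p, p), int(n)),
                    item_labels=list(model.item_labels),
                )
            else:
                data = sample_ordinal(model, int(n), seed=int(rng.integers(0, 2**31 - 1)))
                R = correlation_matrix(data)
            net = select_network(
                R, n=int(n), gamma=gamma, n_lambda=n_lambda,
                lambda_min_ratio=lambda_min_ratio,
            )
            sens.append(sensitivity(model, net))
        sens = np.asarray(sens)
        rows.append(
            {
                "n": int(n),
                "fraction_meeting": float(np.mean(sens >= sens_target)),
                "sens_q25": float(np.percentile(sens, 25)),
                "sens_median": float(np.median(sens)),
                "sens_q75": float(np.percentile(sens, 75)),
            }
        )
    curve = pd.DataFrame(rows)
    iso = IsotonicRegression(increasing=True, out_of_bounds="clip")
    curve["smoothed_fraction"] = iso.fit_transform(
        curve["n"].to_numpy(float), curve["fraction_meeting"].to_numpy(float)
    )
    meets = curve["smoothed_fraction"] >= power_target
    if meets.any():
        selected = int(curve.loc[meets, "n"].iloc[0])
        attained = True
    else:
        selected = int(grid[-1])
        attained = False
    return PowerResult(
        candidate_ns=grid,
        curve=curve,
        selected_n=selected,
        attained=attained,
        sens_target=sens_target,
        power_target=power_target,
        reps=reps,
        seed=seed,
    )
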