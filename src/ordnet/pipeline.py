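"""End-to-end analysis pipeline: data file in, full network report out.

Stage order mirrors the analysis the package implements: polychoric
correlation matrix (pairwise deletion) → EBIC-glasso network → global
characteristics (edge density, weighted clustering) → walktrap communities
(+ parametric bootstrap of the community count, RMSEW block connectivity)
→ centrality table → MST backbone → nonparametric edge bootstrap and
case-dropping CS coefficients.

A single master seed fans out to per-stage seeds through
``numpy.random.SeedSequence.spawn``, so stages are independently
reproducible and the whole report is deterministic given (config, seed).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .centrality import centrality_table, global_clustering
from .community import (
    CommunityAssignment,
    CommunityBootstrap,
    bootstrap_communities,
    rmsew,
    walktrap,
)
from .ggm import NetworkModel, edge_density, select_network
from .mst import mst_backbone
from .polycor import correlation_matrix
from .stability import (
    BootstrapSummary,
    bootstrap_edges,
    case_dropping_bootstrap,
    cs_from_result,
)
from .synth import OrdinalDataset

__all__ = ["PipelineConfig", "AnalysisReport", "run_pipeline"]

logger = logging.getLogger(__name__)

SCHEMA_VERSION = 1


@dataclass
class PipelineConfig:
    """All analysis settings in one place (citable defaults)."""

    n_categories: int = 5
    gamma: float = 0.5
    n_lambda: int = 100
    lambda_min_ratio: float = 0.01
    walktrap_steps: int = 4
    clustering_variant: str = "zhang"
    n_boot_communities: int = 2500
    n_boot_edges: int = 2500
    drop_grid: tuple[float, ...] = tuple(np.round(np.arange(0.05, 0.76, 0.05), 2))
    n_per_level: int = 250
    cor_threshold: float = 0.7
    cs_prob: float = 0.95
    mst_absolute: bool = False

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "drop_grid" in raw:
            raw["drop_grid"] = tuple(float(q) for q in raw["drop_grid"])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["drop_grid"] = list(self.drop_grid)
        return d

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]


@dataclass
class AnalysisReport:
    """Everything the pipeline computes, JSON-serialisable."""

    network: NetworkModel
    edge_density: float
    global_clustering: float
    communities: CommunityAssignment
    community_bootstrap: CommunityBootstrap | None
    rmsew_blocks: "object"  # DataFrame
    centrality: "object"  # DataFrame
    mst: "object"  # SpanningTree
    stability: BootstrapSummary
    provenance: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        cb = self.community_bootstrap
        stab = self.stability
        return {
            "schema_version": SCHEMA_VERSION,
            "network": {
                "nodes": self.network.node_labels,
                "edges": self.network.edge_list().to_dict(orient="records"),
                "lambda_selected": self.network.lambda_selected,
                "gamma": self.network.gamma,
                "n_effective": self.network.n_effective,
            },
            "edge_density": self.edge_density,
            "global_clustering": self.global_clustering,
            "communities": {
                "labels": self.communities.labels.tolist(),
                "n_communities": self.communities.n_communities,
                "modularity": self.communities.modularity,
                "bootstrap": None
                if cb is None
                else {
                    "median": cb.median,
                    "ci_percentile": [cb.ci_low, cb.ci_high],
                    "mean": cb.mean,
                    "ci_normal": [cb.ci_norm_low, cb.ci_norm_high],
                    "n_boot": cb.n_boot,
                    "n_failed": cb.n_failed,
                },
            },
            "rmsew": self.rmsew_blocks.to_dict(orient="records"),
            "centrality": self.centrality.to_dict(orient="records"),
            "mst": self.mst.edge_frame().to_dict(orient="records"),
            "stability": {
                "cs_edges": stab.cs_edges,
                "cs_strength": stab.cs_strength,
                "edge_bootstrap_n": None if stab.edges is None else stab.edges.n_boot,
                "mean_estimate_correlation": None
                if stab.edges is None
                else stab.edges.mean_estimate_correlation(),
            },
            "provenance": self.provenance,
        }


def _estimate_thresholds(data: OrdinalDataset) -> np.ndarray:
    """Per-item standard-normal cut-points from observed category
    proportions (for the parametric community bootstrap)."""
    from scipy.special import ndtri

    k = data.n_categories
    out = np.empty((data.p, k - 1))
    for j in range(data.p):
        col = data.values[:, j]
        col = col[~np.isnan(col)]
        counts = np.bincount(col.astype(int) - 1, minlength=k).astype(float)
        cum = np.cumsum(counts) / counts.sum()
        out[j] = ndtri(np.clip(cum[:-1], 1e-6, 1 - 1e-6))
    return out


def run_pipeline(
    data: OrdinalDataset | str | Path,
    config: PipelineConfig | None = None,
    outdir: str | Path | None = None,
    seed: int = 1,
) -> AnalysisReport:
    """Run the full analysis; optionally write all artifacts to ``outdir``.

    Outputs (when ``outdir`` is given): edges.csv, network.graphml,
    selection_trace.csv, centrality.csv, communities.csv, rmsew.csv,
    mst.csv, bootstrap_edges.csv, case_drop_edges.csv,
    case_drop_strength.csv, community_boot_counts.csv, report.json,
    run.log.
    """
    config = config or PipelineConfig()
    if not isinstance(data, OrdinalDataset):
        data = OrdinalDataset.from_csv(data, n_categories=config.n_categories)
    data.validate()

    handler = None
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        handler = logging.FileHandler(outdir / "run.log", mode="w")
        handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
        logging.getLogger("ordnet").addHandler(handler)
        logging.getLogger("ordnet").setLevel(logging.INFO)

    seeds = np.random.SeedSequence(seed).spawn(4)
    stage_seed = [int(s.generate_state(1)[0] % (2**31 - 1)) for s in seeds]

    try:
        logger.info("polychoric correlation matrix (n=%d, p=%d)", data.n, data.p)
        R = correlation_matrix(data)
        logger.info("EBIC-glasso selection (gamma=%.2f)", config.gamma)
        net = select_network(
            R,
            gamma=config.gamma,
            n_lambda=config.n_lambda,
            lambda_min_ratio=config.lambda_min_ratio,
        )
        dens = edge_density(net)
        clus = global_clustering(net, variant=config.clustering_variant)

        comm = walktrap(net, steps=config.walktrap_steps)
        thresholds = _estimate_thresholds(data)
        cb = None
        if config.n_boot_communities > 0:
            logger.info(
                "parametric community bootstrap (%d replicates)",
                config.n_boot_communities,
            )
            cb = bootstrap_communities(
                net,
                thresholds,
                n=data.n,
                n_boot=config.n_boot_communities,
                steps=config.walktrap_steps,
                seed=stage_seed[0],
                n_lambda=config.n_lambda,
                lambda_min_ratio=config.lambda_min_ratio,
            )
        blocks = rmsew(net, comm)
        cent = centrality_table(net, comm.labels)
        tree = mst_backbone(net, absolute=config.mst_absolute)

        stab = BootstrapSummary()
        estimator = dict(
            gamma=config.gamma,
            n_lambda=config.n_lambda,
            lambda_min_ratio=config.lambda_min_ratio,
        )
        if config.n_boot_edges > 0:
            logger.info("nonparametric edge bootstrap (%d)", config.n_boot_edges)
            stab.edges = bootstrap_edges(
                data, n_boot=config.n_boot_edges, seed=stage_seed[1], **estimator
            )
        if config.n_per_level > 0:
            logger.info("case-dropping bootstrap (edges, strength)")
            stab.drop_edges = case_dropping_bootstrap(
                data,
                statistic="edges",
                drop_grid=config.drop_grid,
                n_per_level=config.n_per_level,
                seed=stage_seed[2],
                **estimator,
            )
            stab.drop_strength = case_dropping_bootstrap(
                data,
                statistic="strength",
                drop_grid=config.drop_grid,
                n_per_level=config.n_per_level,
                seed=stage_seed[3],
                **estimator,
            )
            stab.cs_edges = cs_from_result(
                stab.drop_edges, config.cor_threshold, config.cs_prob
            )
            stab.cs_strength = cs_from_result(
                stab.drop_strength, config.cor_threshold, config.cs_prob
            )

        report = AnalysisReport(
            network=net,
            edge_density=dens,
            global_clustering=clus,
            communities=comm,
            community_bootstrap=cb,
            rmsew_blocks=blocks,
            centrality=cent,
            mst=tree,
            stability=stab,
            provenance={
                "seed": seed,
                "stage_seeds": stage_seed,
                "config": config.to_dict(),
                "config_digest": config.digest(),
                "ordnet_version": __version__,
                "n": data.n,
                "p": data.p,
            },
        )

        if outdir is not None:
            net.edge_list().to_csv(outdir / "edges.csv", index=False)
            net.to_graphml(outdir / "network.graphml")
            if net.selection_trace is not None:
                net.selection_trace.to_csv(outdir / "selection_trace.csv", index=False)
            cent.to_csv(outdir / "centrality.csv", index=False)
            comm.to_frame().to_csv(outdir / "communities.csv", index=False)
            blocks.to_csv(outdir / "rmsew.csv", index=False)
            tree.edge_frame().to_csv(outdir / "mst.csv", index=False)
            if stab.edges is not None:
                stab.edges.table.to_csv(outdir / "bootstrap_edges.csv", index=False)
            for res, name in (
                (stab.drop_edges, "case_drop_edges.csv"),
                (stab.drop_strength, "case_drop_strength.csv"),
            ):
                if res is not None:
                    pd.DataFrame(
                        {f"drop_{q:.2f}": pd.Series(c) for q, c in res.correlations.items()}
                    ).to_csv(outdir / name, index=False)
            if cb is not None:
                np.savetxt(
                    outdir / "community_boot_counts.csv",
                    cb.counts,
                    fmt="%d",
                    header="n_communities",
                    comments="",
                )
            (outdir / "report.json").write_text(
                json.dumps(report.to_dict(), indent=1, default=float)
            )
        return report
    except Exception:
        if outdir is not None:
            for f in (
                "edges.csv", "network.graphml", "selection_trace.csv",
                "centrality.csv", "communities.csv", "rmsew.csv", "mst.csv",
                "bootstrap_edges.csv", "case_drop_edges.csv",
                "case_drop_strength.csv", "community_boot_counts.csv", "report.json",
            ):
                (outdir / f).unlink(missing_ok=True)
        raise
    finally:
        if handler is not None:
            logging.getLogger("ordnet").removeHandler(handler)
            handler.close()
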