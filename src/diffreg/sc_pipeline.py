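"""Single-cell (pseudo-bulk, per-cluster) pipeline.

Each cell cluster is analysed separately: per-sample spliced/unspliced/
ambiguous gene counts are summed across the cluster's cells (pseudo-bulk),
lowly abundant genes are filtered, and the Dirichlet-multinomial model is
fitted independently per group.  Allocation concerns multi-GENE ECs only,
with member probability proportional to rho(g) * pi_version(g) and no
length normalisation; ambiguous reads form their own category and are never
re-split between s and u at the allocation level (the probability that an
ambiguous read is spliced cannot be computed reliably).  The comparison
parameter assigns half of the ambiguous mass to unspliced:
pi_tilde_U = pi_bar_U + 0.5 * pi_bar_A.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .bulk_pipeline import estimate_eb_prior, subseed
from .differential import build_results, rank_results
from .ec_data import (
    CellAssignment,
    CellLevelData,
    aggregate_pseudobulk,
    filter_min_counts,
    split_by_group,
)
from .mcmc_engine import GroupPosterior, McmcConfig, run_chain


@dataclass
class ClusterResultSet:
    """Per-cluster posteriors and differential tables."""

    results: dict[str, tuple[GroupPosterior, GroupPosterior, pd.DataFrame]] = field(
        default_factory=dict)
    skipped: dict[str, str] = field(default_factory=dict)

    def table(self) -> pd.DataFrame:
        """All clusters' differential results, probability-ranked within
        cluster, concatenated."""
        if not self.results:
            raise ValueError("no cluster produced results")
        return pd.concat(
            [rank_results(res, "probability") for _, _, res in self.results.values()],
            ignore_index=True,
        )


def pi_tilde_sc(pi_bar_u: np.ndarray, pi_bar_a: np.ndarray) -> np.ndarray:
    """pi_tilde_U chain: pi_bar_U + 0.5 * pi_bar_A, elementwise in [0, 1]."""
    out = np.asarray(pi_bar_u) + 0.5 * np.asarray(pi_bar_a)
    return np.clip(out, 0.0, 1.0)


def fit_sc(
    cell_data: CellLevelData,
    assign: CellAssignment,
    group_of: dict[str, str],
    config: McmcConfig,
    min_count: int = 10,
    clusters: list[str] | None = None,
) -> ClusterResultSet:
    """Run the per-cluster pseudo-bulk analysis.

    Clusters with fewer than 2 samples per group, or with no gene passing
    the >= `min_count`-per-group filter, are skipped with a warning and
    recorded in the result's `skipped` mapping.  Each cluster's chains use
    a seed derived from the master seed by a stable hash, so results do not
    depend on the order clusters are processed in.
    """
    out = ClusterResultSet()
    for cluster in clusters or assign.clusters:
        try:
            ds = aggregate_pseudobulk(cell_data, assign, cluster, group_of)
            per_group = {}
            for s in ds.samples:
                per_group.setdefault(group_of[s], []).append(s)
            if len(per_group) != 2 or any(len(v) < 2 for v in per_group.values()):
                raise ValueError(
                    f"cluster {cluster!r} needs >= 2 samples in each of two groups, "
                    f"got {[(g, len(v)) for g, v in per_group.items()]}")
            ds = filter_min_counts(ds, min_count)
            if ds.catalog.n_features == 0:
                raise ValueError(f"cluster {cluster!r}: no gene passes the "
                                 f">= {min_count}-per-group filter")
        except ValueError as e:
            warnings.warn(f"skipping cluster {cluster!r}: {e}", stacklevel=2)
            out.skipped[cluster] = str(e)
            continue

        eb = estimate_eb_prior(ds, seed=subseed(config.seed, "eb", cluster))
        prior = eb.to_delta_prior()
        posts = {}
        for g, sub in split_by_group(ds).items():
            cfg_g = McmcConfig(
                n_iter=config.n_iter, burn_in=config.burn_in,
                latent_update_every=config.latent_update_every,
                seed=subseed(config.seed, cluster, *sub.samples),
                hw_alpha=config.hw_alpha, max_restarts=config.max_restarts,
                store_pi=config.store_pi,
            )
            posts[g] = run_chain(sub, cfg_g, model="sc", prior=prior, group=g)
        ga, gb = sorted(posts)
        res = build_results(posts[ga], posts[gb], cluster=cluster)
        out.results[cluster] = (posts[ga], posts[gb], res)
    return out
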