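"""Bulk transcript-level pipeline.

Per group of samples, transcript totals follow a multinomial over
transcripts and the spliced/unspliced split a hierarchical beta-binomial.
Multi-mapping reads are allocated with length-normalised weights
pi_S / l_S and pi_U / l_U, so allocation probabilities do not depend on how
long transcripts are.

Hyper-parameter priors are set empirically: a random selection of up to
1000 features is fitted with a per-feature Dirichlet-multinomial maximum-
likelihood precision (on naive equal-split counts), and the mean/sd of the
log precisions define a log-normal prior on delta_plus.  Each feature
contributes only a tiny fraction to this prior, which keeps it mild.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .ec_data import ECDataset, split_by_group
from .mcmc_engine import DeltaPrior, ECArrays, GroupPosterior, McmcConfig, run_chain

PRECISION_BOUNDS = (1e-2, 1e6)
SD_LOG_PRECISION_FLOOR = 0.5


def subseed(master_seed: int, *tokens: str) -> int:
    """Derive a stage seed < 2**31 from the master seed and string tokens
    (stable hash, so stages and groups can be rerun in isolation)."""
    import zlib

    h = zlib.crc32(("|".join(map(str, tokens))).encode())
    return int((master_seed * 2654435761 + h) % (2**31))


@dataclass
class EBPrior:
    """Empirical-Bayes prior summary: log delta_plus ~ Normal(mean, sd),
    pi_bar flat on the simplex, symmetric Dirichlet(rho_prior_conc) on rho."""

    mean_log_precision: float
    sd_log_precision: float
    rho_prior_conc: float = 1.0

    def to_delta_prior(self) -> DeltaPrior:
        return DeltaPrior(self.mean_log_precision, self.sd_log_precision,
                          self.rho_prior_conc)


def length_normalized_weights(pi: np.ndarray, catalog) -> np.ndarray:
    """Allocation weights pi / effective length, per sample and feature.

    pi has shape (n_samples, n_features, 2); the returned weights have the
    same shape.  Rescaling all effective lengths by a common factor leaves
    the normalised allocation probabilities unchanged.
    """
    if catalog.eff_len is None:
        raise ValueError("catalog has no effective lengths")
    return pi / catalog.eff_len[None, :, :]


def fit_dm_precision(x: np.ndarray) -> float:
    """Beta-binomial / Dirichlet-multinomial precision of per-sample counts
    x (N, K) via a Kleinman-type weighted moment estimator.

    Per category, the intra-class correlation rho = 1/(delta_plus + 1) is
    estimated from the count-weighted dispersion of the sample proportions
    around the pooled proportion, with the (N - 1) degrees-of-freedom
    correction; category estimates are combined weighted by p(1-p).  Result
    bounded to [1e-2, 1e6].  (Few-sample maximum likelihood systematically
    underestimates the overdispersion here, hence the moment estimator.)
    """
    x = np.asarray(x, dtype=float)
    N, K = x.shape
    w = x.sum(axis=1)
    used = w > 0
    x, w = x[used], w[used]
    N = len(w)
    if N < 2:
        raise ValueError("need counts in at least 2 samples")
    W = w.sum()
    p = x.sum(axis=0) / W
    num = den = 0.0
    denom_w = W - (w**2).sum() / W
    for k in range(K):
        pk = p[k]
        if pk <= 0 or pk >= 1:
            continue
        s = np.sum(w * (x[:, k] / w - pk) ** 2)
        rho_k = (s / (pk * (1 - pk)) - (N - 1)) / denom_w
        num += pk * (1 - pk) * rho_k
        den += pk * (1 - pk)
    if den == 0:
        return PRECISION_BOUNDS[1]
    rho = num / den
    rho = min(max(rho, 1.0 / (PRECISION_BOUNDS[1] + 1)), 1.0 / (PRECISION_BOUNDS[0] + 1))
    return float(1.0 / rho - 1.0)


def estimate_eb_prior(ds: ECDataset, n_features: int = 1000, seed: int = 0) -> EBPrior:
    """Estimate the prior on log delta_plus from a random feature selection.

    Multi-mapping EC counts are split equally among members (initialisation
    only); each selected feature with positive counts in >= 2 samples gets a
    Dirichlet-multinomial moment precision; the prior location and scale are
    the median and 1.4826*MAD of the log precisions (robust to the boundary
    pile-up of features showing no overdispersion; sd floored at 0.5).  With
    < 10 usable features a weakly informative default (mean = log 10,
    sd = 2) is returned with a warning.
    """
    arrays = ECArrays(ds)
    X = arrays.equal_split()  # (N, F, K)
    rng = np.random.default_rng(seed)
    F = arrays.n_features
    chosen = rng.choice(F, size=min(n_features, F), replace=False)
    log_precs = []
    for f in chosen:
        x = X[:, f, :]
        if (x.sum(axis=1) > 0).sum() < 2:
            continue
        log_precs.append(np.log(fit_dm_precision(x)))
    if len(log_precs) < 10:
        warnings.warn(
            f"only {len(log_precs)} usable features for the empirical-Bayes "
            "prior; falling back to the weakly informative default",
            stacklevel=2,
        )
        return EBPrior(mean_log_precision=float(np.log(10.0)), sd_log_precision=2.0)
    log_precs = np.asarray(log_precs)
    mad = float(np.median(np.abs(log_precs - np.median(log_precs))))
    sd = max(1.4826 * mad, SD_LOG_PRECISION_FLOOR)
    return EBPrior(mean_log_precision=float(np.median(log_precs)), sd_log_precision=sd)


def fit_bulk(
    dsA: ECDataset,
    dsB: ECDataset,
    config: McmcConfig,
    eb_prior: EBPrior | None = None,
) -> tuple[GroupPosterior, GroupPosterior]:
    """Fit the bulk model independently in each group of samples.

    The empirical-Bayes prior is estimated once on the pooled samples; each
    group then runs its own chain (with a group-specific sub-seed) and
    returns post-burn-in chains of delta, from which pi_bar and the
    comparison parameter pi_tilde_U (= pi_bar_U in bulk) derive.
    """
    if tuple(dsA.catalog.feature_ids) != tuple(dsB.catalog.feature_ids):
        raise ValueError("groups must share one (already filtered) catalog")
    if eb_prior is None:
        pooled = _pool_for_prior(dsA, dsB)
        eb_prior = estimate_eb_prior(pooled, seed=config.seed)
    prior = eb_prior.to_delta_prior()
    posts = []
    for ds, name in ((dsA, "A"), (dsB, "B")):
        cfg_g = McmcConfig(
            n_iter=config.n_iter, burn_in=config.burn_in,
            latent_update_every=config.latent_update_every,
            seed=subseed(config.seed, *ds.samples),
            hw_alpha=config.hw_alpha, max_restarts=config.max_restarts,
            store_pi=config.store_pi,
        )
        posts.append(run_chain(ds, cfg_g, model="bulk", prior=prior, group=name))
    return posts[0], posts[1]


def fit_bulk_two_group(ds: ECDataset, config: McmcConfig,
                       eb_prior: EBPrior | None = None):
    """Convenience wrapper: split a two-group dataset and fit both groups."""
    groups = split_by_group(ds)
    if len(groups) != 2:
        raise ValueError(f"expected exactly two groups, found {list(groups)}")
    (ga, dsA), (gb, dsB) = groups.items()
    postA, postB = fit_bulk(dsA, dsB, config, eb_prior=eb_prior)
    postA.group, postB.group = ga, gb
    return postA, postB


def _pool_for_prior(dsA: ECDataset, dsB: ECDataset) -> ECDataset:
    """Concatenate the two groups' samples (shared catalog) for prior
    estimation."""
    from .ec_data import EquivalenceClass

    samples = tuple(dsA.samples) + tuple(dsB.samples)
    merged: dict[tuple, np.ndarray] = {}
    for off, ds in ((0, dsA), (dsA.n_samples, dsB)):
        for ec in ds.ecs:
            key = tuple(sorted(ec.members))
            row = merged.setdefault(key, np.zeros(len(samples), dtype=np.int64))
            row[off : off + ds.n_samples] += ec.counts
    group_of = {**{s: "A" for s in dsA.samples}, **{s: "B" for s in dsB.samples}}
    return ECDataset(catalog=dsA.catalog, samples=samples, group_of=group_of,
                     ecs=[EquivalenceClass(k, v) for k, v in merged.items()])
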