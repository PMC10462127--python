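"""Metropolis-within-Gibbs sampler with latent read allocation.

The model, per experimental group: sample totals across features follow a
multinomial with per-sample relative abundances rho; within each feature the
split across splice versions follows a hierarchical beta-binomial (bulk,
versions S/U) or Dirichlet-multinomial (single-cell, versions S/U/A) with
hyper-parameters delta.  Reads are only observed at the equivalence-class
level, so the per-(feature, version) counts X are latent and sampled by data
augmentation: multi-mapping reads are allocated with probability
proportional to rho(feature) * weight(feature, version), where the weight is
the per-sample splice proportion pi (divided by the effective length in the
bulk model).

One sweep updates, in order: delta | pi (adaptive-random-walk Metropolis,
vectorised over features), pi | X, delta (conjugate Beta/Dirichlet draw),
rho | X (conjugate Dirichlet draw), and X | Z, pi (multinomial allocation).
The allocation step is the expensive one and is under-sampled: it runs every
`latent_update_every`-th iteration (default 10) while the other blocks run
every iteration.

Convergence is checked with a Heidelberger-Welch stationarity test on the
trace of the marginal log-posterior of delta given pi; on failure the
burn-in is escalated up to half the chain, then the chain is rerun once with
doubled length.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln, kv
from scipy.special import gamma as gamma_fn

PI_EPS = 1e-12  # clamp for simplex draws before log-density evaluation


# ---------------------------------------------------------------------------
# configuration and chain containers
# ---------------------------------------------------------------------------


@dataclass
class McmcConfig:
    """Sampler settings.

    n_iter / burn_in default to 2000 / 500; latent allocations refresh every
    10 iterations; hw_alpha is the stationarity-test level; max_restarts
    bounds the doubled-chain reruns after a failed test.
    """

    n_iter: int = 2000
    burn_in: int = 500
    latent_update_every: int = 10
    seed: int = 0
    hw_alpha: float = 0.05
    max_restarts: int = 1
    store_pi: bool = False

    def __post_init__(self) -> None:
        if not self.burn_in < self.n_iter:
            raise ValueError("burn_in must be < n_iter")
        if self.latent_update_every < 1:
            raise ValueError("latent_update_every must be >= 1")


@dataclass
class DeltaPrior:
    """Empirical-Bayes prior on the hyper-parameters of one feature:
    log-normal on the precision delta_plus, uniform on the group-level
    proportions pi_bar."""

    mean_log_precision: float
    sd_log_precision: float
    rho_prior_conc: float = 1.0

    def logpdf(self, delta: np.ndarray) -> np.ndarray:
        """Log prior density of delta rows (natural scale), shape (F,).

        The density over delta in R+^K corresponding to delta_plus being
        log-normal and pi_bar uniform: the change of variables
        d(delta) = delta_plus^(K-1) d(delta_plus) d(pi_bar) contributes a
        -K*log(delta_plus) term on top of the normal density in
        log(delta_plus).
        """
        delta = np.atleast_2d(delta)
        K = delta.shape[1]
        dp = delta.sum(axis=1)
        z = (np.log(dp) - self.mean_log_precision) / self.sd_log_precision
        return (-0.5 * z**2 - np.log(self.sd_log_precision)
                - 0.5 * np.log(2 * np.pi) - K * np.log(dp))


@dataclass
class LatentCounts:
    """Latent allocation X (sample, feature, version) and totals Y."""

    X: np.ndarray
    Y: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.Y = self.X.sum(axis=2)


# ---------------------------------------------------------------------------
# equivalence classes in array form
# ---------------------------------------------------------------------------


class ECArrays:
    """Array view of an ECDataset for fast allocation.

    Single-member ECs are resolved once into a fixed count array; multi-
    member ECs are grouped by member count so each group allocates with a
    vectorised conditional-binomial scheme.
    """

    def __init__(self, ds) -> None:
        cat = ds.catalog
        fidx = cat.index
        F, K, N = cat.n_features, cat.n_versions, ds.n_samples
        self.n_samples, self.n_features, self.n_versions = N, F, K
        self.X_fixed = np.zeros((N, F, K), dtype=np.int64)
        by_size: dict[int, list] = {}
        for ec in ds.ecs:
            if len(ec.members) == 1:
                (f, v), = ec.members
                self.X_fixed[:, fidx[f], cat.version_index(v)] += ec.counts
            else:
                by_size.setdefault(len(ec.members), []).append(ec)
        self.groups = []
        for k, ecs in sorted(by_size.items()):
            feat = np.array([[fidx[f] for f, _ in ec.members] for ec in ecs])
            ver = np.array([[cat.version_index(v) for _, v in ec.members] for ec in ecs])
            counts = np.array([ec.counts for ec in ecs])  # (M, N)
            labels = [ec.members for ec in ecs]
            self.groups.append((k, feat, ver, counts, labels))
        self.total = self.X_fixed.sum(axis=(1, 2)) + sum(
            g[3].sum(axis=0) for g in self.groups
        ) if self.groups else self.X_fixed.sum(axis=(1, 2))

    def equal_split(self) -> np.ndarray:
        """Initial X: every multi-member EC count split equally among members."""
        X = self.X_fixed.astype(float).copy()
        for k, feat, ver, counts, _ in self.groups:
            share = counts / k  # (M, N)
            for j in range(k):
                np.add.at(X, (slice(None), feat[:, j], ver[:, j]), share.T)
        return X


def allocate_reads(arrays: ECArrays, rho: np.ndarray, weights: np.ndarray,
                   rng: np.random.Generator) -> LatentCounts:
    """Sample X | Z, pi: allocate every EC's reads among its members.

    Member probabilities are proportional to rho[i, feature] *
    weights[i, feature, version].  Single-member ECs are deterministic;
    multi-member ECs are partitioned with one multinomial draw implemented
    as a chain of conditional binomials (vectorised over ECs of equal size).
    Total reads per sample are conserved exactly.
    """
    X = arrays.X_fixed.astype(np.int64).copy()
    for k, feat, ver, counts, labels in arrays.groups:
        for i in range(arrays.n_samples):
            P = rho[i, feat] * weights[i, feat, ver]  # (M, k)
            psum = P.sum(axis=1)
            bad = (psum <= 0) & (counts[:, i] > 0)
            if np.any(bad):
                raise ValueError(
                    f"all member probabilities are zero for EC {labels[int(np.argmax(bad))]}"
                )
            remaining = counts[:, i].copy()
            prem = np.where(psum > 0, psum, 1.0)
            for j in range(k - 1):
                ratio = np.clip(np.where(prem > 0, P[:, j] / prem, 0.0), 0.0, 1.0)
                draw = rng.binomial(remaining, ratio)
                np.add.at(X[i], (feat[:, j], ver[:, j]), draw)
                remaining -= draw
                prem -= P[:, j]
            np.add.at(X[i], (feat[:, k - 1], ver[:, k - 1]), remaining)
    return LatentCounts(X)


# ---------------------------------------------------------------------------
# conjugate Gibbs blocks
# ---------------------------------------------------------------------------


def sample_rho(Y: np.ndarray, prior_conc: float, rng: np.random.Generator) -> np.ndarray:
    """Draw rho | X for every sample: Dirichlet(prior_conc + Y_i)."""
    if prior_conc <= 0:
        raise ValueError("prior_conc must be > 0")
    g = rng.gamma(prior_conc + Y)
    g = np.clip(g, 1e-300, None)
    return g / g.sum(axis=1, keepdims=True)


def sample_pi(X: np.ndarray, delta: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Draw pi | X, delta: Beta/Dirichlet(delta + X) per sample and feature.

    Draws are clamped slightly inside the simplex so downstream allocation
    weights and log-densities stay finite.
    """
    g = rng.gamma(delta[None, :, :] + X)
    g = np.clip(g, 1e-300, None)
    pi = g / g.sum(axis=2, keepdims=True)
    pi = np.clip(pi, PI_EPS, 1 - PI_EPS)
    return pi / pi.sum(axis=2, keepdims=True)


def log_posterior_delta(delta: np.ndarray, pi: np.ndarray, prior: DeltaPrior) -> np.ndarray:
    """Marginal log-posterior of delta given pi, per feature.

    Sum over samples of the Beta/Dirichlet log-density of pi_i at delta,
    plus the log prior.  pi is clamped away from the simplex boundary.
    """
    delta = np.atleast_2d(delta)  # (F, K)
    if np.any(delta <= 0):
        raise ValueError("delta must be positive")
    pi = np.clip(pi, PI_EPS, 1 - PI_EPS)
    N = pi.shape[0]
    sumlog = np.log(pi).sum(axis=0)  # (F, K)
    ll = N * (gammaln(delta.sum(axis=1)) - gammaln(delta).sum(axis=1))
    ll += ((delta - 1.0) * sumlog).sum(axis=1)
    return ll + prior.logpdf(delta)


# ---------------------------------------------------------------------------
# adaptive random-walk Metropolis for delta
# ---------------------------------------------------------------------------


class AdaptiveRWSampler:
    """Gaussian random-walk Metropolis with Haario-style adaptation, run in
    parallel over independent chains (one per feature).

    Proposal covariance: (2.38^2 / d) * running empirical covariance +
    1e-6 * I, using Welford updates; until 2d history points are seen, an
    isotropic 0.1^2/d starting scale is used.  Adaptation is meant to be
    frozen after burn-in (the caller stops calling :meth:`adapt`).
    """

    def __init__(self, n_chains: int, dim: int) -> None:
        self.n_chains, self.dim = n_chains, dim
        self.count = 0
        self.mean = np.zeros((n_chains, dim))
        self.m2 = np.zeros((n_chains, dim, dim))
        self.accepts = np.zeros(n_chains, dtype=np.int64)
        self.proposals = 0
        self._chol = np.tile((0.1 / np.sqrt(dim)) * np.eye(dim), (n_chains, 1, 1))

    def adapt(self, eta: np.ndarray) -> None:
        self.count += 1
        d = eta - self.mean
        self.mean += d / self.count
        self.m2 += d[:, :, None] * (eta - self.mean)[:, None, :]
        if self.count > 2 * self.dim:
            cov = self.m2 / (self.count - 1)
            prop = (2.38**2 / self.dim) * cov + 1e-6 * np.eye(self.dim)
            self._chol = np.linalg.cholesky(prop)

    def propose(self, eta: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        z = rng.standard_normal((self.n_chains, self.dim))
        return eta + np.einsum("fij,fj->fi", self._chol, z)

    def accept_step(self, log_alpha: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        """Vector of accept decisions; non-finite log-ratios auto-reject."""
        u = np.log(rng.uniform(size=self.n_chains))
        ok = np.isfinite(log_alpha) & (u < log_alpha)
        self.accepts += ok
        self.proposals += 1
        return ok

    @property
    def acceptance_rate(self) -> np.ndarray:
        return self.accepts / max(self.proposals, 1)


def delta_to_eta(delta: np.ndarray) -> np.ndarray:
    """(F, K) positive delta -> (F, K) unconstrained (log delta_plus, alr(pi_bar))."""
    dp = delta.sum(axis=1)
    pbar = delta / dp[:, None]
    alr = np.log(pbar[:, :-1]) - np.log(pbar[:, -1:])
    return np.column_stack([np.log(dp), alr])


def eta_to_delta(eta: np.ndarray) -> np.ndarray:
    dp = np.exp(eta[:, 0])
    e = np.exp(np.column_stack([eta[:, 1:], np.zeros(len(eta))]))
    pbar = e / e.sum(axis=1, keepdims=True)
    return dp[:, None] * pbar


def _eta_log_target(eta: np.ndarray, pi: np.ndarray, prior: DeltaPrior) -> tuple[np.ndarray, np.ndarray]:
    """Target density on the unconstrained scale = natural-scale posterior
    plus the log-Jacobian K*log(delta_plus) + sum_k log(pi_bar_k).

    Rows whose back-transformed delta under/overflows get -inf (so the
    Metropolis step auto-rejects them).
    """
    with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
        delta = eta_to_delta(eta)
        valid = np.all(np.isfinite(delta) & (delta > 0), axis=1)
        safe = np.where(valid[:, None], delta, 1.0)
        lp = log_posterior_delta(safe, pi, prior)
        dp = safe.sum(axis=1)
        K = safe.shape[1]
        logjac = K * np.log(dp) + np.sum(np.log(safe / dp[:, None]), axis=1)
        lp = np.where(valid, lp, -np.inf)
        target = np.where(valid, lp + logjac, -np.inf)
    return lp, target


def sample_delta_mh(
    delta: np.ndarray,
    pi: np.ndarray,
    prior: DeltaPrior,
    sampler: AdaptiveRWSampler,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """One Metropolis step for delta | pi, vectorised over features.

    Returns (new delta, natural-scale log-posterior per feature, accept
    mask).
    """
    eta = delta_to_eta(delta)
    lp_cur, target_cur = _eta_log_target(eta, pi, prior)
    prop = sampler.propose(eta, rng)
    lp_prop, target_prop = _eta_log_target(prop, pi, prior)
    accept = sampler.accept_step(target_prop - target_cur, rng)
    eta_new = np.where(accept[:, None], prop, eta)
    lp_new = np.where(accept, lp_prop, lp_cur)
    return eta_to_delta(eta_new), lp_new, accept


# ---------------------------------------------------------------------------
# Heidelberger-Welch stationarity diagnostic
# ---------------------------------------------------------------------------


def _pcramer(q: float, eps: float = 1e-5) -> float:
    """CDF of the asymptotic Cramer-von Mises distribution.

    Four-term Bessel series; it loses accuracy deep in the upper tail, so
    for q > 1 the (monotone) CDF is floored at its value at 1, which is
    already > 0.997.
    """
    if q <= 0:
        return 0.0
    if q > 1.0:
        return max(_pcramer(1.0, eps), _series_pcramer(q, eps))
    return _series_pcramer(q, eps)


def _series_pcramer(q: float, eps: float) -> float:
    total = 0.0
    for k in range(4):
        z = gamma_fn(k + 0.5) * np.sqrt(4 * k + 1) / (gamma_fn(k + 1) * np.pi**1.5 * np.sqrt(q))
        u = (4 * k + 1) ** 2 / (16 * q)
        if u <= -np.log(eps):
            total += z * np.exp(-u) * kv(0.25, u)
    return float(min(max(total, 0.0), 1.0))


def _spectrum0_ar(x: np.ndarray, detrend: bool = True) -> float:
    """Spectral density at frequency zero via an AIC-selected AR fit
    (Yule-Walker).

    The series is linearly detrended first: under stationarity this barely
    changes the estimate, while for a drifting chain it stops the AR fit
    from absorbing the drift as a near-unit root (which would inflate the
    variance estimate enough to mask the non-stationarity the test is
    meant to detect).
    """
    x = np.asarray(x, dtype=float)
    n = len(x)
    if detrend:
        t = np.arange(n)
        slope, intercept = np.polyfit(t, x, 1)
        v = x - (slope * t + intercept)
    else:
        v = x - x.mean()
    var = float(np.mean(v**2))
    if var == 0:
        return 0.0
    max_order = int(min(n - 1, 10 * np.log10(n)))
    acov = np.correlate(v, v, "full")[n - 1 : n + max_order] / n
    best_aic, best = np.inf, (0, np.array([]), var)
    for order in range(max_order + 1):
        if order == 0:
            sigma2 = acov[0]
            phi = np.array([])
        else:
            from scipy.linalg import solve_toeplitz
            try:
                phi = solve_toeplitz(acov[:order], acov[1 : order + 1])
            except np.linalg.LinAlgError:
                continue
            sigma2 = acov[0] - phi @ acov[1 : order + 1]
        if sigma2 <= 0:
            continue
        aic = n * np.log(sigma2) + 2 * order
        if aic < best_aic:
            best_aic, best = aic, (order, phi, sigma2)
    order, phi, sigma2 = best
    denom = (1.0 - phi.sum()) ** 2 if order else 1.0
    if denom <= 0:
        denom = 1e-12
    return float(sigma2 / denom)


@dataclass
class HWResult:
    passed: bool
    start_index: int | None
    pvalue: float | None


def heidelberger_welch(trace, alpha: float = 0.05) -> HWResult:
    """Heidelberger-Welch stationarity test.

    Cramer-von Mises statistic of the Brownian-bridge functional of the
    cumulative sums, with the long-run variance estimated by the spectral
    density at zero of the last half of the trace.  The test is retried
    discarding 10%-prefixes up to 50%; the first passing window's start
    index is returned.  Zero-variance traces pass by definition.
    """
    x = np.asarray(trace, dtype=float)
    n = len(x)
    if n < 50:
        raise ValueError(f"trace too short for stationarity test (n={n} < 50)")
    if np.ptp(x) < 1e-12 * max(1.0, abs(float(x[0]))):
        return HWResult(True, 0, 1.0)
    s0 = _spectrum0_ar(x[n // 2 :])
    if s0 <= 0:
        return HWResult(True, 0, 1.0)
    last_p = 0.0
    for frac in (0.0, 0.1, 0.2, 0.3, 0.4, 0.5):
        start = int(frac * n)
        y = x[start:]
        nw = len(y)
        b = np.cumsum(y) - y.mean() * np.arange(1, nw + 1)
        stat = float(np.sum(b * b) / (nw * nw * s0))
        last_p = 1.0 - _pcramer(stat)
        if last_p > alpha:
            return HWResult(True, start, last_p)
    return HWResult(False, None, last_p)


# ---------------------------------------------------------------------------
# posterior container and chain driver
# ---------------------------------------------------------------------------


@dataclass
class GroupPosterior:
    """Post-burn-in chains for one group of samples."""

    feature_ids: tuple[str, ...]
    versions: tuple[str, ...]
    delta: np.ndarray              # (n_stored, F, K)
    log_post: np.ndarray           # (n_stored,) total log p(delta | pi)
    converged: bool
    hw: HWResult
    config: McmcConfig
    acceptance_rate: np.ndarray    # (F,)
    group: str = "NA"
    pi: np.ndarray | None = None   # optional (n_stored, N, F, K)

    @property
    def delta_plus(self) -> np.ndarray:
        return self.delta.sum(axis=2)

    @property
    def pi_bar(self) -> np.ndarray:
        """(n_stored, F, K) group-level proportions delta / delta_plus."""
        return self.delta / self.delta_plus[:, :, None]

    def pi_tilde_u(self) -> np.ndarray:
        """(n_stored, F) chain of the comparison parameter: pi_bar_U in the
        bulk model, pi_bar_U + 0.5 * pi_bar_A in the single-cell model."""
        pb = self.pi_bar
        iu = self.versions.index("U")
        out = pb[:, :, iu]
        if "A" in self.versions:
            out = out + 0.5 * pb[:, :, self.versions.index("A")]
        return out

    # -- serialisation -----------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        """Long/columnar layout: feature, iteration, parameter, value."""
        S, F, K = self.delta.shape
        rows = []
        for k, v in enumerate(self.versions):
            rows.append(pd.DataFrame({
                "feature": np.repeat(self.feature_ids, S),
                "iteration": np.tile(np.arange(S), F),
                "parameter": f"delta_{v}",
                "value": self.delta[:, :, k].T.ravel(),
            }))
        return pd.concat(rows, ignore_index=True)

    def save(self, path) -> None:
        path = str(path)
        self.to_frame().to_parquet(path)
        meta = {
            "feature_ids": list(self.feature_ids),
            "versions": list(self.versions),
            "group": self.group,
            "converged": bool(self.converged),
            "hw": {"passed": self.hw.passed, "start_index": self.hw.start_index,
                   "pvalue": self.hw.pvalue},
            "config": {k: getattr(self.config, k) for k in
                       ("n_iter", "burn_in", "latent_update_every", "seed",
                        "hw_alpha", "max_restarts")},
        }
        with open(path + ".json", "w") as fh:
            json.dump(meta, fh, indent=1)

    @classmethod
    def load(cls, path) -> "GroupPosterior":
        path = str(path)
        df = pd.read_parquet(path)
        with open(path + ".json") as fh:
            meta = json.load(fh)
        feats = meta["feature_ids"]
        versions = meta["versions"]
        S = int(df["iteration"].max()) + 1
        delta = np.empty((S, len(feats), len(versions)))
        for k, v in enumerate(versions):
            sub = df[df["parameter"] == f"delta_{v}"]
            delta[:, :, k] = sub["value"].to_numpy().reshape(len(feats), S).T
        cfg = McmcConfig(**{k: v for k, v in meta["config"].items()})
        hw = HWResult(**meta["hw"])
        return cls(tuple(feats), tuple(versions), delta, np.zeros(S),
                   meta["converged"], hw, cfg, np.zeros(len(feats)),
                   group=meta["group"])


def _initial_state(arrays: ECArrays, prior: DeltaPrior):
    X = arrays.equal_split()
    Y = X.sum(axis=2)
    K = arrays.n_versions
    pi = (X + 1.0) / (Y[:, :, None] + K)  # posterior mean under delta = 1
    rho = (Y + 0.5) / (Y + 0.5).sum(axis=1, keepdims=True)
    pooled = X.sum(axis=0)
    tot = pooled.sum(axis=1, keepdims=True)
    pbar = np.where(tot > 0, pooled / np.where(tot > 0, tot, 1.0), 1.0 / K)
    pbar = np.clip(pbar, 1e-3, 1 - 1e-3)
    pbar /= pbar.sum(axis=1, keepdims=True)
    delta = np.exp(prior.mean_log_precision) * pbar
    return LatentCounts(X), pi, rho, delta


def run_chain(ds, config: McmcConfig, model: str | None = None,
              prior: DeltaPrior | None = None, group: str | None = None) -> GroupPosterior:
    """Run the full Metropolis-within-Gibbs chain on one group of samples.

    `model` defaults to the catalog mode ("bulk" uses length-normalised
    allocation weights pi / effective length; "sc" uses pi directly).
    Returns post-burn-in chains; if the stationarity test fails even after
    burn-in escalation and a doubled-chain restart, the result is returned
    flagged non-converged.
    """
    cat = ds.catalog
    if model is None:
        model = "bulk" if cat.mode == "bulk-transcript" else "sc"
    if model == "bulk" and cat.eff_len is None:
        raise ValueError("bulk model requires effective lengths in the catalog")
    if prior is None:
        prior = DeltaPrior(mean_log_precision=np.log(10.0), sd_log_precision=2.0)

    inv_len = None
    if model == "bulk":
        inv_len = 1.0 / cat.eff_len  # (F, 2)

    cfg = config
    for attempt in range(config.max_restarts + 1):
        post = _run_single(ds, cfg, model, prior, inv_len, seed_offset=attempt)
        if post.converged:
            break
        if attempt < config.max_restarts:
            cfg = McmcConfig(
                n_iter=cfg.n_iter * 2, burn_in=cfg.burn_in * 2,
                latent_update_every=cfg.latent_update_every, seed=cfg.seed,
                hw_alpha=cfg.hw_alpha, max_restarts=cfg.max_restarts,
                store_pi=cfg.store_pi,
            )
    post.group = group if group is not None else (ds.groups[0] if ds.groups else "NA")
    return post


def _run_single(ds, config: McmcConfig, model: str, prior: DeltaPrior,
                inv_len, seed_offset: int) -> GroupPosterior:
    rng = np.random.default_rng((config.seed, seed_offset))
    arrays = ECArrays(ds)
    F, K, N = arrays.n_features, arrays.n_versions, arrays.n_samples
    latent, pi, rho, delta = _initial_state(arrays, prior)
    sampler = AdaptiveRWSampler(F, K)

    n_store = config.n_iter - config.burn_in
    delta_chain = np.empty((n_store, F, K))
    lp_chain = np.empty(n_store)
    pi_chain = np.empty((n_store, N, F, K)) if config.store_pi else None

    for it in range(config.n_iter):
        delta, lp, _ = sample_delta_mh(delta, pi, prior, sampler, rng)
        pi = sample_pi(latent.X, delta, rng)
        rho = sample_rho(latent.Y, prior.rho_prior_conc, rng)
        if (it + 1) % config.latent_update_every == 0:
            weights = pi * inv_len[None, :, :] if model == "bulk" else pi
            latent = allocate_reads(arrays, rho, weights, rng)
        if it < config.burn_in:
            sampler.adapt(delta_to_eta(delta))
        else:
            s = it - config.burn_in
            delta_chain[s] = delta
            lp_chain[s] = log_posterior_delta(delta, pi, prior).sum()
            if pi_chain is not None:
                pi_chain[s] = pi

    hw = heidelberger_welch(lp_chain, alpha=config.hw_alpha)
    start = hw.start_index if (hw.passed and hw.start_index) else 0
    return GroupPosterior(
        feature_ids=tuple(ds.catalog.feature_ids), versions=ds.catalog.versions,
        delta=delta_chain[start:], log_post=lp_chain[start:],
        converged=hw.passed, hw=hw, config=config,
        acceptance_rate=sampler.acceptance_rate,
        pi=None if pi_chain is None else pi_chain[start:],
    )
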