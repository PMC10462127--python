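"""Between-group comparison of the unspliced fraction.

The key quantity is pi_tilde_U, the group-level relative abundance of
unspliced reads (plus half the ambiguous fraction in single-cell data).
Two rankings are produced:

* probability mode: p = Pr(pi_tilde_U in group B > in group A), estimated
  from the posterior chains; features are ranked by max(p, 1 - p), so
  results with p near 0 or 1 come first and p near 0.5 last;
* Wald mode: the posterior of (pi_bar_S, pi_bar_U) is approximated by a
  bivariate normal and a two-group Wald test with a chi-square(2) reference
  is run (pi_bar_A is excluded since it is determined by the other two).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .mcmc_engine import GroupPosterior


def prob_up_regulated(chain_a: np.ndarray, chain_b: np.ndarray,
                      method: str = "matched") -> float:
    """Estimate p = Pr(pi_tilde_U_B > pi_tilde_U_A) from posterior chains.

    "matched" compares the chains iteration by iteration (truncated to the
    shorter length); "all-pairs" uses every cross pair.  Ties count 1/2, so
    identical chains give exactly 0.5 and p(A,B) = 1 - p(B,A).
    """
    a = np.asarray(chain_a, dtype=float)
    b = np.asarray(chain_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("empty posterior chain")
    if method == "matched":
        n = min(len(a), len(b))
        a, b = a[:n], b[:n]
        return float(np.mean((b > a) + 0.5 * (b == a)))
    if method == "all-pairs":
        order = np.sort(a)
        gt = np.searchsorted(order, b, side="left")
        ge = np.searchsorted(order, b, side="right")
        return float(np.mean((gt + ge) / 2) / len(a))
    raise ValueError(f"unknown method {method!r}")


def wald_test(chains_a: np.ndarray, chains_b: np.ndarray) -> tuple[float, float]:
    """Wald test on posterior clouds of the free splice proportions.

    T = (m_A - m_B)' (S_A + S_B)^-1 (m_A - m_B) with posterior means m_g and
    sample covariances S_g; p-value from the upper chi-square tail with as
    many degrees of freedom as free coordinates.  Single-cell data passes
    the bivariate (pi_bar_S, pi_bar_U) cloud (pi_bar_A is excluded as it is
    determined by the other two); bulk data has only one free coordinate
    (pi_bar_U) and uses the 1-d version.  A singular pooled covariance is
    ridge-regularised (1e-8 * trace).
    """
    a = np.atleast_2d(np.asarray(chains_a, dtype=float).T).T
    b = np.atleast_2d(np.asarray(chains_b, dtype=float).T).T
    if a.shape[0] < 100 or b.shape[0] < 100:
        raise ValueError("need at least 100 post-burn-in draws per group")
    m = a.mean(axis=0) - b.mean(axis=0)
    s = np.atleast_2d(np.cov(a, rowvar=False)) + np.atleast_2d(np.cov(b, rowvar=False))
    if np.linalg.cond(s) > 1e12:
        warnings.warn("singular posterior covariance; applying ridge", stacklevel=2)
        s = s + 1e-8 * np.trace(s) * np.eye(s.shape[0])
    stat = float(m @ np.linalg.solve(s, m))
    pval = float(stats.chi2.sf(stat, df=m.size))
    return stat, max(pval, np.finfo(float).tiny)


def build_results(post_a: GroupPosterior, post_b: GroupPosterior,
                  cluster: str | None = None) -> pd.DataFrame:
    """Per-feature differential table from two group posteriors."""
    if post_a.feature_ids != post_b.feature_ids:
        raise ValueError("posteriors cover different feature sets")
    pt_a, pt_b = post_a.pi_tilde_u(), post_b.pi_tilde_u()
    pb_a, pb_b = post_a.pi_bar, post_b.pi_bar
    bulk = len(post_a.versions) == 2  # pi_S determined by pi_U: 1 free coordinate
    if bulk:
        keep = [post_a.versions.index("U")]
    else:
        keep = [post_a.versions.index("S"), post_a.versions.index("U")]
    rows = []
    for j, fid in enumerate(post_a.feature_ids):
        p = prob_up_regulated(pt_a[:, j], pt_b[:, j])
        w, wp = wald_test(pb_a[:, j, keep], pb_b[:, j, keep])
        rows.append({
            "feature_id": fid,
            "p": p,
            "rank_score": max(p, 1 - p),
            "wald_stat": w,
            "wald_pvalue": wp,
            "mean_piU_A": float(pt_a[:, j].mean()),
            "mean_piU_B": float(pt_b[:, j].mean()),
            "converged": bool(post_a.converged and post_b.converged),
        })
    df = pd.DataFrame(rows)
    if cluster is not None:
        df.insert(1, "cluster_id", cluster)
    df["bh_pvalue"] = multipletests(df["wald_pvalue"], method="fdr_bh")[1]
    return df


def rank_results(results: pd.DataFrame, mode: str = "probability") -> pd.DataFrame:
    """Order the results table: probability mode by rank_score descending,
    Wald mode by wald_pvalue ascending; stable lexicographic tie-break on
    feature_id."""
    if len(results) == 0:
        raise ValueError("empty results table")
    df = results.sort_values("feature_id", kind="stable")
    if mode == "probability":
        df = df.sort_values("rank_score", ascending=False, kind="stable")
    elif mode == "wald":
        df = df.sort_values("wald_pvalue", ascending=True, kind="stable")
    else:
        raise ValueError(f"unknown ranking mode {mode!r}")
    return df.reset_index(drop=True)


def plot_traceplot(posteriors: dict[str, GroupPosterior], feature: str, path) -> None:
    """Write a traceplot plus marginal density of pi_tilde_U per group."""
    import difflib

    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, (ax_tr, ax_de) = plt.subplots(1, 2, figsize=(9, 3.2))
    for name, post in posteriors.items():
        if feature not in post.feature_ids:
            near = difflib.get_close_matches(feature, post.feature_ids, n=3)
            raise ValueError(f"feature {feature!r} not found; near matches: {near}")
        j = post.feature_ids.index(feature)
        chain = post.pi_tilde_u()[:, j]
        ax_tr.plot(chain, lw=0.6, label=f"group {name}")
        if np.ptp(chain) > 0:
            grid = np.linspace(chain.min(), chain.max(), 200)
            ax_de.plot(grid, stats.gaussian_kde(chain)(grid), label=f"group {name}")
        else:
            ax_de.axvline(chain[0], label=f"group {name}")
    ax_tr.set_xlabel("iteration")
    ax_tr.set_ylabel(r"$\tilde{\pi}_U$")
    ax_tr.set_title(feature)
    ax_de.set_xlabel(r"$\tilde{\pi}_U$")
    ax_de.set_ylabel("posterior density")
    ax_tr.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
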