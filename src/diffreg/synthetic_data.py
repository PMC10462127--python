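"""Count-level benchmark generator with known ground truth.

Emulates the benchmark conditions the method is evaluated under:

* negative-binomial count variability across biological replicates, with
  per-feature dispersions and log-normal baseline relative abundances;
* differential regulation (DR): spliced/unspliced proportions inverted in
  one (randomly chosen) group — 2000 transcripts in the default bulk
  configuration, 20% of genes per cell cluster in single-cell mode;
* differential gene expression (DGE) as a nuisance: group means scaled by
  fold changes averaging 3, 6 or 9;
* differential alternative splicing (DAS, bulk only) as a nuisance:
  within-gene transcript proportions permuted in one group, leaving gene
  totals and per-transcript splice proportions untouched;
* null data, 2-batch designs, and single-cell zero fractions of 90/95/99%
  at fixed pseudo-bulk totals;
* equivalence-class multi-mapping ambiguity: a configurable fraction of
  reads is placed into ECs joining 2..max_members (feature, version)
  partners, replacing read-level simulation while conserving totals
  exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ec_data import (
    SC_VERSIONS,
    CellAssignment,
    CellECData,
    CellLevelData,
    ECDataset,
    EquivalenceClass,
    FeatureCatalog,
)


# ---------------------------------------------------------------------------
# scenario description and truth bookkeeping
# ---------------------------------------------------------------------------


@dataclass
class SimScenario:
    """Generator settings; defaults reproduce the benchmark conditions.

    Bulk mode: `n_features` transcripts, `n_dr` of them differentially
    regulated (s/u inverted in one group), 3+3 samples.  Single-cell mode:
    genes across `n_clusters` cell clusters with `dr_fraction` of genes DR
    per cluster (distinct genes in each cluster), counts spread over cells
    at `zero_fraction` zeros while keeping pseudo-bulk totals fixed.
    """

    mode: str = "bulk"                      # "bulk" | "sc"
    n_features: int = 10_000
    n_samples_per_group: int = 3
    n_dr: int | None = None                 # bulk; defaults to 2000 (capped at n_features)
    dr_fraction: float = 0.20               # sc
    dge_fraction: float = 0.0               # fraction of features with a DGE effect
    mean_fc: float = 3.0                    # average DGE fold change (3, 6 or 9)
    das: bool = False                       # bulk only
    das_fraction: float = 0.10
    batch: bool = False
    zero_fraction: float = 0.90             # sc only
    seed: int = 0
    reads_per_feature: float = 200.0        # mean sequencing depth per feature
    disp_log_mean: float = -2.0             # NB dispersion ~ log-normal
    disp_log_sd: float = 0.5
    pi_u_beta: tuple[float, float] = (2.0, 6.0)  # baseline unspliced fraction
    dr_pi_u: float | None = None            # force DR features' baseline pi_U
    delta_plus: float = 30.0                # sample-to-sample precision of the splice split
    pi_a_beta: tuple[float, float] = (2.0, 18.0)  # sc ambiguous fraction
    n_clusters: int = 3                     # sc
    n_cells: int = 100                      # sc: cells per sample per cluster

    def __post_init__(self) -> None:
        if self.mode not in ("bulk", "sc"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.n_dr is None:
            self.n_dr = min(2000, self.n_features) if self.mode == "bulk" else None
        if self.mode == "bulk" and self.n_dr > self.n_features:
            raise ValueError("n_dr cannot exceed n_features")
        for frac in (self.dr_fraction, self.dge_fraction, self.zero_fraction):
            if not 0 <= frac <= 1:
                raise ValueError("fractions must lie in [0, 1]")


@dataclass
class BulkCounts:
    """True per-sample spliced/unspliced counts (no EC ambiguity yet)."""

    catalog: FeatureCatalog
    samples: tuple[str, ...]
    group_of: dict[str, str]
    counts: np.ndarray                      # (N, F, 2) ints, versions (S, U)
    batch_of: dict[str, int] | None = None


@dataclass
class ScCounts:
    """Single-cell simulation output: cell-level data plus assignments."""

    cell_data: CellLevelData
    assignment: CellAssignment
    group_of: dict[str, str]
    pseudobulk: dict[str, np.ndarray] = field(default_factory=dict)  # cluster -> (N, G, 3)


# ---------------------------------------------------------------------------
# count simulation
# ---------------------------------------------------------------------------


def _nb_draw(rng, mu: np.ndarray, phi: np.ndarray) -> np.ndarray:
    """Negative binomial with mean mu and dispersion phi (var = mu + phi mu^2)."""
    size = 1.0 / np.maximum(phi, 1e-12)
    p = size / (size + mu)
    return rng.negative_binomial(size, p)


def _split_counts(rng, total: np.ndarray, pi: np.ndarray, delta_plus: float) -> np.ndarray:
    """Hierarchical split of totals (N, F) into versions via per-sample
    Dirichlet(delta_plus * pi[F, K]) proportions and conditional binomials."""
    N, F = total.shape
    K = pi.shape[1]
    conc = np.clip(delta_plus * pi, 1e-3, None)
    g = rng.gamma(np.broadcast_to(conc, (N, F, K)))
    g = np.clip(g, 1e-300, None)
    p = g / g.sum(axis=2, keepdims=True)
    out = np.zeros((N, F, K), dtype=np.int64)
    remaining = total.astype(np.int64).copy()
    prem = np.ones((N, F))
    for k in range(K - 1):
        ratio = np.clip(np.where(prem > 0, p[:, :, k] / prem, 0.0), 0, 1)
        draw = rng.binomial(remaining, ratio)
        out[:, :, k] = draw
        remaining -= draw
        prem -= p[:, :, k]
    out[:, :, K - 1] = remaining
    return out


def _assign_genes(rng, n_features: int) -> np.ndarray:
    """Group transcripts into genes of size 1-3 (for DAS simulation)."""
    gene = np.empty(n_features, dtype=np.int64)
    g = 0
    i = 0
    while i < n_features:
        size = int(rng.integers(1, 4))
        gene[i : i + size] = g
        i += size
        g += 1
    return gene


def simulate_counts(scenario: SimScenario):
    """Simulate count tables and ground truth for one scenario.

    Returns ``(BulkCounts, truth)`` in bulk mode or ``(ScCounts, truth)`` in
    single-cell mode; `truth` is a per-feature DataFrame recording DR, DGE,
    DAS flags, the affected group, the generating unspliced fractions per
    group and the true fold change.
    """
    rng = np.random.default_rng(scenario.seed)
    if scenario.mode == "bulk":
        return _simulate_bulk(scenario, rng)
    return _simulate_sc(scenario, rng)


def _simulate_bulk(sc: SimScenario, rng):
    F = sc.n_features
    N = sc.n_samples_per_group
    feature_ids = tuple(f"tx{i:05d}" for i in range(F))
    len_s = rng.lognormal(np.log(1500.0), 0.4, size=F)
    eff_len = np.column_stack([len_s, len_s * rng.uniform(1.5, 3.5, size=F)])
    catalog = FeatureCatalog(feature_ids, mode="bulk-transcript", eff_len=eff_len)
    samples = tuple(f"A{i+1}" for i in range(N)) + tuple(f"B{i+1}" for i in range(N))
    group_of = {s: s[0] for s in samples}

    base_rho = rng.lognormal(0.0, 1.0, size=F)
    base_rho /= base_rho.sum()
    pi_u = rng.beta(*sc.pi_u_beta, size=F)
    phi = rng.lognormal(sc.disp_log_mean, sc.disp_log_sd, size=F)
    gene_of = _assign_genes(rng, F)

    dr = np.zeros(F, dtype=bool)
    dr[rng.choice(F, size=sc.n_dr, replace=False)] = True
    if sc.dr_pi_u is not None:
        pi_u[dr] = sc.dr_pi_u
    affected = np.where(rng.uniform(size=F) < 0.5, "A", "B")

    dge = np.zeros(F, dtype=bool)
    fc = np.ones(F)
    if sc.dge_fraction > 0:
        # selected independently of the DR labels (overlap allowed)
        n_dge = int(round(sc.dge_fraction * F))
        dge[rng.choice(F, size=n_dge, replace=False)] = True
        fc[dge] = 1.0 + rng.exponential(sc.mean_fc - 1.0, size=dge.sum())

    # group-level relative abundances; DGE scales the affected group's mean
    mu = {g: base_rho * sc.reads_per_feature * F for g in ("A", "B")}
    mu = {g: m.copy() for g, m in mu.items()}
    for g in ("A", "B"):
        mask = dge & (affected == g)
        mu[g][mask] *= fc[mask]

    das = np.zeros(F, dtype=bool)
    if sc.das:
        sizes = np.bincount(gene_of)
        eligible = np.flatnonzero(sizes[gene_of] >= 2)
        genes = np.unique(gene_of[eligible])
        chosen = rng.choice(genes, size=max(1, int(round(sc.das_fraction * len(genes)))),
                            replace=False)
        if len(chosen) == 0:
            raise ValueError("DAS requested but no multi-transcript genes available")
        for g in chosen:
            idx = np.flatnonzero(gene_of == g)
            das[idx] = True
            grp = affected[idx[0]]
            affected[idx] = grp
            # cyclic permutation of transcript abundances; gene total preserved
            mu[grp][idx] = np.roll(mu[grp][idx], 1)

    pi_u_group = {"A": pi_u.copy(), "B": pi_u.copy()}
    for g in ("A", "B"):
        mask = dr & (affected == g)
        pi_u_group[g][mask] = 1.0 - pi_u_group[g][mask]

    counts = np.zeros((2 * N, F, 2), dtype=np.int64)
    for j, s in enumerate(samples):
        g = group_of[s]
        total = _nb_draw(rng, mu[g], phi)
        pi_sv = np.column_stack([1.0 - pi_u_group[g], pi_u_group[g]])
        counts[j] = _split_counts(rng, total[None, :], pi_sv, sc.delta_plus)[0]

    truth = pd.DataFrame({
        "feature_id": feature_ids,
        "gene_id": [f"g{g:05d}" for g in gene_of],
        "is_dr": dr, "is_dge": dge, "is_das": das,
        "affected_group": np.where(dr | dge | das, affected, ""),
        "pi_u_A": pi_u_group["A"], "pi_u_B": pi_u_group["B"],
        "fold_change": fc,
    })
    return BulkCounts(catalog, samples, group_of, counts), truth


def _simulate_sc(sc: SimScenario, rng):
    G = sc.n_features
    N = sc.n_samples_per_group
    gene_ids = tuple(f"gene{i:05d}" for i in range(G))
    samples = tuple(f"A{i+1}" for i in range(N)) + tuple(f"B{i+1}" for i in range(N))
    group_of = {s: s[0] for s in samples}
    clusters = tuple(f"cluster{c+1}" for c in range(sc.n_clusters))

    base_rho = rng.lognormal(0.0, 1.0, size=(sc.n_clusters, G))
    base_rho /= base_rho.sum(axis=1, keepdims=True)
    pi_u = rng.beta(*sc.pi_u_beta, size=(sc.n_clusters, G))
    pi_a = rng.beta(*sc.pi_a_beta, size=(sc.n_clusters, G))
    phi = rng.lognormal(sc.disp_log_mean, sc.disp_log_sd, size=(sc.n_clusters, G))

    # distinct DR genes per cluster
    n_dr = int(round(sc.dr_fraction * G))
    perm = rng.permutation(G)
    dr = np.zeros((sc.n_clusters, G), dtype=bool)
    for c in range(sc.n_clusters):
        take = perm[(c * n_dr) % G : (c * n_dr) % G + n_dr]
        dr[c, take] = True
    affected = np.where(rng.uniform(size=(sc.n_clusters, G)) < 0.5, "A", "B")

    dge = np.zeros((sc.n_clusters, G), dtype=bool)
    fc = np.ones((sc.n_clusters, G))
    if sc.dge_fraction > 0:
        for c in range(sc.n_clusters):
            n_dge = int(round(sc.dge_fraction * G))
            sel = rng.choice(G, size=n_dge, replace=False)
            dge[c, sel] = True
            fc[c, sel] = 1.0 + rng.exponential(sc.mean_fc - 1.0, size=n_dge)

    cell_ids, cell_rows = [], []
    counts = {v: [] for v in SC_VERSIONS}
    ec_members: list[tuple[tuple[str, str], ...]] = []
    ec_counts: list[dict[str, int]] = []
    pseudobulk: dict[str, np.ndarray] = {}
    truth_rows = []

    for c, cl in enumerate(clusters):
        pb = np.zeros((2 * N, G, 3), dtype=np.int64)
        piU = {"A": pi_u[c].copy(), "B": pi_u[c].copy()}
        for g in ("A", "B"):
            mask = dr[c] & (affected[c] == g)
            piU[g][mask] = 1.0 - piU[g][mask]
        for j, s in enumerate(samples):
            g = group_of[s]
            mu = base_rho[c] * sc.reads_per_feature * G
            mask = dge[c] & (affected[c] == g)
            mu = np.where(mask, mu * fc[c], mu)
            total = _nb_draw(rng, mu, phi[c])
            pA = pi_a[c]
            pi_sva = np.column_stack([(1 - pA) * (1 - piU[g]), (1 - pA) * piU[g], pA])
            pb[j] = _split_counts(rng, total[None, :], pi_sva, sc.delta_plus)[0]
        pseudobulk[cl] = pb
        # spread pseudo-bulk counts over cells at the requested zero fraction
        n_nonzero = max(1, int(round((1.0 - sc.zero_fraction) * sc.n_cells)))
        for j, s in enumerate(samples):
            ids = [f"{cl}_{s}_c{k}" for k in range(sc.n_cells)]
            cell_ids.extend(ids)
            cell_rows.extend((cid, s, cl) for cid in ids)
            block = {v: np.zeros((G, sc.n_cells), dtype=np.int64) for v in SC_VERSIONS}
            for gi in range(G):
                # one expressed-cell subset per gene, shared by s/u/a
                cols = rng.choice(sc.n_cells, size=min(n_nonzero, sc.n_cells),
                                  replace=False)
                share = np.full(len(cols), 1.0 / len(cols))
                for k, v in enumerate(SC_VERSIONS):
                    n = int(pb[j, gi, k])
                    if n:
                        block[v][gi, cols] += rng.multinomial(n, share)
            for v in SC_VERSIONS:
                counts[v].append(block[v])
        for gi in range(G):
            truth_rows.append({
                "cluster_id": cl, "feature_id": gene_ids[gi],
                "is_dr": bool(dr[c, gi]), "is_dge": bool(dge[c, gi]), "is_das": False,
                "affected_group": affected[c, gi] if (dr[c, gi] or dge[c, gi]) else "",
                "pi_u_A": piU["A"][gi], "pi_u_B": piU["B"][gi],
                "fold_change": fc[c, gi],
            })

    full = {v: np.concatenate(counts[v], axis=1) for v in SC_VERSIONS}
    cell_data = CellLevelData(gene_ids, tuple(cell_ids), full,
                              ecs=CellECData(ec_members, ec_counts))
    assignment = CellAssignment(pd.DataFrame(cell_rows,
                                             columns=["cell_id", "sample_id", "cluster_id"]))
    out = ScCounts(cell_data, assignment, group_of, pseudobulk)
    return out, pd.DataFrame(truth_rows)


# ---------------------------------------------------------------------------
# EC-level multi-mapping emulation
# ---------------------------------------------------------------------------


def emulate_multimapping_ecs(
    counts: BulkCounts,
    p_multi: float = 0.3,
    max_members: int = 4,
    seed: int = 0,
) -> ECDataset:
    """Convert true (feature, version) counts into equivalence classes.

    For every feature-version, a Binomial(count, p_multi) share of its reads
    joins a multi-member EC with 1..max_members-1 randomly chosen partner
    (feature, version) pairs — same-feature s/u pairs included — while the
    remainder stays uniquely assigned.  Totals are conserved exactly per
    sample.
    """
    if not 0 <= p_multi <= 1:
        raise ValueError("p_multi must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    cat = counts.catalog
    F, K = cat.n_features, 2
    N = len(counts.samples)
    flat = counts.counts.reshape(N, F * K)
    multi = rng.binomial(flat, p_multi) if p_multi > 0 else np.zeros_like(flat)
    unique = flat - multi

    merged: dict[tuple, np.ndarray] = {}

    def add(members: tuple, row: np.ndarray) -> None:
        key = tuple(sorted(members))
        merged.setdefault(key, np.zeros(N, dtype=np.int64))
        merged[key] += row

    versions = cat.versions
    for fk in range(F * K):
        f, k = divmod(fk, K)
        me = (cat.feature_ids[f], versions[k])
        if unique[:, fk].sum() > 0:
            add((me,), unique[:, fk])
        if multi[:, fk].sum() > 0:
            n_partners = int(rng.integers(1, max_members))
            partners = set()
            while len(partners) < n_partners:
                pf, pk = divmod(int(rng.integers(F * K)), K)
                cand = (cat.feature_ids[pf], versions[pk])
                if cand != me:
                    partners.add(cand)
            add((me, *partners), multi[:, fk])
    ecs = [EquivalenceClass(m, c) for m, c in merged.items()]
    return ECDataset(catalog=cat, samples=counts.samples,
                     group_of=dict(counts.group_of), ecs=ecs)


def emulate_multimapping_ecs_sc(
    sc_counts: ScCounts,
    p_multi: float = 0.3,
    max_members: int = 4,
    seed: int = 0,
) -> ScCounts:
    """Move a p_multi share of single-cell reads into multi-gene ECs.

    Reads removed from the per-cell count matrices are placed, cell by
    cell, into ECs joining the donor (gene, version) with randomly chosen
    partners (shared across cells).  Totals are conserved exactly.
    """
    rng = np.random.default_rng(seed)
    cd = sc_counts.cell_data
    G = len(cd.gene_ids)
    new_counts = {v: m.copy() for v, m in cd.counts.items()}
    members: dict[tuple, int] = {}
    ec_members: list[tuple[tuple[str, str], ...]] = []
    ec_counts: list[dict[str, int]] = []

    for v in SC_VERSIONS:
        m = new_counts[v]
        take = rng.binomial(m.astype(np.int64), p_multi)
        new_counts[v] = m - take
        for gi in np.flatnonzero(take.sum(axis=1)):
            me = (cd.gene_ids[gi], v)
            n_partners = int(rng.integers(1, max_members))
            partners = set()
            while len(partners) < n_partners:
                pg = int(rng.integers(G))
                pv = SC_VERSIONS[int(rng.integers(3))]
                if (cd.gene_ids[pg], pv) != me:
                    partners.add((cd.gene_ids[pg], pv))
            key = tuple(sorted((me, *partners)))
            if key not in members:
                members[key] = len(ec_members)
                ec_members.append(key)
                ec_counts.append({})
            slot = ec_counts[members[key]]
            for ci in np.flatnonzero(take[gi]):
                cell = cd.cell_ids[ci]
                slot[cell] = slot.get(cell, 0) + int(take[gi, ci])
    cell_data = CellLevelData(cd.gene_ids, cd.cell_ids, new_counts,
                              ecs=CellECData(ec_members, ec_counts))
    return ScCounts(cell_data, sc_counts.assignment, sc_counts.group_of,
                    sc_counts.pseudobulk)


# ---------------------------------------------------------------------------
# batch design
# ---------------------------------------------------------------------------


def apply_batch_design(
    counts: BulkCounts,
    truth: pd.DataFrame,
    effect_abundance: float = 1.5,
    effect_logit: float = 1.0,
    frac_affected: float = 0.2,
    seed: int = 0,
) -> tuple[BulkCounts, pd.DataFrame]:
    """Introduce a 2-batch effect balanced across the two groups.

    Samples alternate between batches within each group; in batch 2, a
    random feature subset (orthogonal to the DR labels) gets a
    multiplicative shift of overall abundance and an additive logit shift
    of the unspliced proportion.  Batch assignments and affected features
    are recorded in the returned truth table.
    """
    groups: dict[str, list[str]] = {}
    for s in counts.samples:
        groups.setdefault(counts.group_of[s], []).append(s)
    if any(len(v) < 2 for v in groups.values()):
        raise ValueError("batch design needs at least 2 samples per group")
    batch_of = {}
    for ss in groups.values():
        for i, s in enumerate(ss):
            batch_of[s] = 1 + (i % 2)

    rng = np.random.default_rng(seed)
    F = counts.catalog.n_features
    affected = np.zeros(F, dtype=bool)
    affected[rng.choice(F, size=int(round(frac_affected * F)), replace=False)] = True

    new = counts.counts.copy()
    if effect_abundance != 1.0 or effect_logit != 0.0:
        for j, s in enumerate(counts.samples):
            if batch_of[s] != 2:
                continue
            sub = new[j][affected]
            total = sub.sum(axis=1)
            scaled = np.round(total * effect_abundance).astype(np.int64)
            old_pu = np.where(total > 0, sub[:, 1] / np.maximum(total, 1), 0.5)
            logit = np.log(np.clip(old_pu, 1e-6, 1 - 1e-6) /
                           np.clip(1 - old_pu, 1e-6, 1 - 1e-6)) + effect_logit
            new_pu = 1.0 / (1.0 + np.exp(-logit))
            xu = rng.binomial(scaled, new_pu)
            new[j][affected, 0] = scaled - xu
            new[j][affected, 1] = xu

    truth = truth.copy()
    truth["batch_affected"] = affected
    out = BulkCounts(counts.catalog, counts.samples, dict(counts.group_of),
                     new, batch_of=batch_of)
    return out, truth


# ---------------------------------------------------------------------------
# scoring
# ---------------------------------------------------------------------------


def score_methods(
    results: pd.DataFrame,
    truth: pd.DataFrame,
    score_col: str = "rank_score",
    top_n: tuple[int, ...] = (20, 50, 100, 200),
) -> dict:
    """ROC/AUROC, false positives among top-N, and false discovery
    proportion at rank cutoffs, for a ranking against the DR ground truth.

    `results` must carry `feature_id` and a score column (higher = stronger
    evidence); `truth` carries `feature_id` and `is_dr`.  Features missing
    from `results` are ignored (they were filtered before testing).
    """
    from sklearn.metrics import roc_auc_score, roc_curve

    key = ["feature_id"] + (["cluster_id"] if "cluster_id" in results.columns
                            and "cluster_id" in truth.columns else [])
    merged = results.merge(truth[key + ["is_dr"]], on=key, how="inner")
    y = merged["is_dr"].to_numpy(dtype=int)
    s = merged[score_col].to_numpy(dtype=float)
    if y.sum() == 0 or y.sum() == len(y):
        raise ValueError("scoring needs both DR and non-DR features")
    fpr, tpr, _ = roc_curve(y, s)
    order = np.argsort(-s, kind="stable")
    sorted_y = y[order]
    fp_top = {int(n): int((1 - sorted_y[:n]).sum()) for n in top_n if n <= len(y)}
    fdp = {int(n): float((1 - sorted_y[:n]).mean()) for n in top_n if n <= len(y)}
    return {
        "auroc": float(roc_auc_score(y, s)),
        "roc": {"fpr": fpr.tolist(), "tpr": tpr.tolist()},
        "fp_top": fp_top,
        "fdp": fdp,
        "n_features": int(len(y)),
        "n_true": int(y.sum()),
    }
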