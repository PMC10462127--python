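"""Equivalence-class count data model and I/O.

An *equivalence class* (EC) is the set of (feature, splice-version)
references that a sequencing read is compatible with; all reads sharing a
class are interchangeable for inference.  Features are transcripts (bulk
data, versions S/U with effective lengths) or genes (single-cell data,
versions S/U/A following the USA convention of spliced / unspliced /
ambiguous counts).

Supported on-disk formats:

* salmon ``eq_classes.txt`` dialect (plain or gzip), with splice versions
  encoded by an identifier suffix (default ``-U`` unspliced, ``-A``
  ambiguous);
* an internal, versioned JSON schema that round-trips an :class:`ECDataset`
  losslessly;
* MatrixMarket MTX triplets plus barcode/feature TSVs for single-cell
  spliced/unspliced/ambiguous count matrices;
* plain TSVs for effective lengths and cell->cluster assignments.
"""

from __future__ import annotations

import gzip
import json
import re
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

EC_JSON_SCHEMA_VERSION = 1

BULK_VERSIONS = ("S", "U")
SC_VERSIONS = ("S", "U", "A")

#: default regex mapping an identifier to its (feature, version) pair:
#: trailing ``-U`` marks unspliced, ``-A`` ambiguous, anything else spliced.
DEFAULT_SUFFIX_PATTERN = r"^(?P<feature>.+?)(?:-(?P<version>[UA]))?$"


def split_versioned_id(name: str, pattern: str = DEFAULT_SUFFIX_PATTERN) -> tuple[str, str]:
    """Split a suffixed identifier like ``tx1-U`` into ``("tx1", "U")``."""
    m = re.match(pattern, name)
    if m is None:
        raise ValueError(f"identifier {name!r} does not match version pattern {pattern!r}")
    return m.group("feature"), m.group("version") or "S"


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FeatureCatalog:
    """Ordered feature universe with splice versions and effective lengths.

    Parameters
    ----------
    feature_ids
        Unique transcript or gene identifiers, in model order.
    mode
        ``"bulk-transcript"`` (versions S/U, effective lengths required for
        length-normalised read allocation) or ``"sc-gene"`` (versions S/U/A,
        no length normalisation).
    eff_len
        Array of shape ``(n_features, 2)`` with the effective lengths of the
        spliced and unspliced version of each transcript; ``None`` for
        single-cell catalogs.
    """

    feature_ids: tuple[str, ...]
    mode: str = "bulk-transcript"
    eff_len: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("bulk-transcript", "sc-gene"):
            raise ValueError(f"unknown catalog mode {self.mode!r}")
        if len(set(self.feature_ids)) != len(self.feature_ids):
            raise ValueError("feature_ids must be unique")
        if self.eff_len is not None:
            el = np.asarray(self.eff_len, dtype=float)
            if el.shape != (len(self.feature_ids), 2):
                raise ValueError("eff_len must have shape (n_features, 2)")
            if not np.all(el > 0):
                raise ValueError("all effective lengths must be > 0")
            object.__setattr__(self, "eff_len", el)

    @property
    def versions(self) -> tuple[str, ...]:
        return BULK_VERSIONS if self.mode == "bulk-transcript" else SC_VERSIONS

    @property
    def n_features(self) -> int:
        return len(self.feature_ids)

    @property
    def n_versions(self) -> int:
        return len(self.versions)

    @property
    def index(self) -> dict[str, int]:
        return {f: i for i, f in enumerate(self.feature_ids)}

    def version_index(self, version: str) -> int:
        try:
            return self.versions.index(version)
        except ValueError:
            raise ValueError(
                f"version {version!r} not available in mode {self.mode!r}"
            ) from None


@dataclass(frozen=True)
class EquivalenceClass:
    """One EC: its member (feature, version) pairs and per-sample counts."""

    members: tuple[tuple[str, str], ...]
    counts: np.ndarray  # (n_samples,) non-negative ints

    def __post_init__(self) -> None:
        if len(self.members) == 0:
            raise ValueError("equivalence class must have at least one member")
        if len(set(self.members)) != len(self.members):
            raise ValueError(f"duplicate members in EC {self.members}")
        c = np.asarray(self.counts, dtype=np.int64)
        if np.any(c < 0):
            raise ValueError("EC counts must be non-negative")
        object.__setattr__(self, "counts", c)


@dataclass
class ECDataset:
    """Equivalence-class counts for a set of samples over one catalog."""

    catalog: FeatureCatalog
    samples: tuple[str, ...]
    group_of: dict[str, str]
    ecs: list[EquivalenceClass] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.samples = tuple(self.samples)
        idx = self.catalog.index
        versions = set(self.catalog.versions)
        for ec in self.ecs:
            if ec.counts.shape != (len(self.samples),):
                raise ValueError("EC counts length must equal number of samples")
            for f, v in ec.members:
                if f not in idx:
                    raise ValueError(f"EC member feature {f!r} not in catalog")
                if v not in versions:
                    raise ValueError(f"EC member version {v!r} not in catalog versions")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def groups(self) -> tuple[str, ...]:
        seen: list[str] = []
        for s in self.samples:
            g = self.group_of[s]
            if g not in seen:
                seen.append(g)
        return tuple(seen)

    def total_counts(self) -> np.ndarray:
        """Total EC reads per sample."""
        if not self.ecs:
            return np.zeros(self.n_samples, dtype=np.int64)
        return np.sum([ec.counts for ec in self.ecs], axis=0)

    def feature_group_totals(self) -> pd.DataFrame:
        """Per (feature, group) sum of counts of every EC containing any
        version of the feature (the abundance measure used for filtering)."""
        totals = np.zeros((self.catalog.n_features, len(self.groups)), dtype=np.int64)
        gidx = {g: j for j, g in enumerate(self.groups)}
        sample_g = np.array([gidx[self.group_of[s]] for s in self.samples])
        fidx = self.catalog.index
        for ec in self.ecs:
            by_group = np.bincount(sample_g, weights=ec.counts, minlength=len(self.groups))
            for f in {f for f, _ in ec.members}:
                totals[fidx[f]] += by_group.astype(np.int64)
        return pd.DataFrame(totals, index=list(self.catalog.feature_ids), columns=list(self.groups))

    def subset_samples(self, keep: list[str]) -> "ECDataset":
        pos = [self.samples.index(s) for s in keep]
        ecs = []
        for ec in self.ecs:
            c = ec.counts[pos]
            if c.sum() > 0:
                ecs.append(EquivalenceClass(ec.members, c))
        return ECDataset(
            catalog=self.catalog,
            samples=tuple(keep),
            group_of={s: self.group_of[s] for s in keep},
            ecs=ecs,
        )


def split_by_group(ds: ECDataset) -> dict[str, ECDataset]:
    """Split a two-group dataset into per-group datasets (shared catalog)."""
    out = {}
    for g in ds.groups:
        keep = [s for s in ds.samples if ds.group_of[s] == g]
        out[g] = ds.subset_samples(keep)
    return out


@dataclass
class CellAssignment:
    """Mapping cell -> (sample, cluster), backed by a DataFrame."""

    table: pd.DataFrame  # columns: cell_id, sample_id, cluster_id

    def __post_init__(self) -> None:
        required = {"cell_id", "sample_id", "cluster_id"}
        if not required.issubset(self.table.columns):
            raise ValueError(f"assignment table needs columns {sorted(required)}")
        if self.table["cell_id"].duplicated().any():
            dup = self.table.loc[self.table["cell_id"].duplicated(), "cell_id"].iloc[0]
            raise ValueError(f"cell {dup!r} assigned more than once")

    @property
    def clusters(self) -> tuple[str, ...]:
        return tuple(pd.unique(self.table["cluster_id"]))

    @property
    def samples(self) -> tuple[str, ...]:
        return tuple(pd.unique(self.table["sample_id"]))

    def cells_in(self, cluster: str) -> pd.DataFrame:
        return self.table[self.table["cluster_id"] == cluster]


@dataclass
class CellECData:
    """Multi-gene equivalence classes with per-cell counts.

    ``counts[j]`` holds (cell_id, count) pairs for EC ``members[j]``; unique
    (single-gene) reads live in the per-cell count matrices instead.
    """

    members: list[tuple[tuple[str, str], ...]]
    counts: list[dict[str, int]]


@dataclass
class CellLevelData:
    """Per-cell spliced/unspliced/ambiguous gene counts plus multi-gene ECs."""

    gene_ids: tuple[str, ...]
    cell_ids: tuple[str, ...]
    counts: dict[str, np.ndarray]  # version -> (n_genes, n_cells)
    ecs: CellECData | None = None

    def __post_init__(self) -> None:
        for v, m in self.counts.items():
            if m.shape != (len(self.gene_ids), len(self.cell_ids)):
                raise ValueError(f"count matrix {v!r} has shape {m.shape}, expected "
                                 f"({len(self.gene_ids)}, {len(self.cell_ids)})")


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def _open_text(path, mode="rt"):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


def read_salmon_eq_classes(
    path,
    catalog: FeatureCatalog | None = None,
    sample_id: str = "sample1",
    suffix_pattern: str = DEFAULT_SUFFIX_PATTERN,
    mode: str = "bulk-transcript",
) -> ECDataset:
    """Parse a salmon ``eq_classes.txt`` file into a one-sample dataset.

    Layout: number of transcripts, number of ECs, one transcript name per
    line, then per-EC lines ``k idx_1 ... idx_k count``.  Splice versions are
    recovered from the identifier suffix (default ``-U`` / ``-A``).
    """
    with _open_text(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    if len(lines) < 2:
        raise ValueError(f"{path}: truncated eq_classes file")
    try:
        n_tx = int(lines[0])
        n_ec = int(lines[1])
    except ValueError as e:
        raise ValueError(f"{path}: malformed header: {e}") from None
    names = lines[2 : 2 + n_tx]
    if len(names) != n_tx:
        raise ValueError(f"{path}: expected {n_tx} transcript names, found {len(names)}")

    pairs = [split_versioned_id(nm, suffix_pattern) for nm in names]
    if catalog is None:
        feature_ids = list(dict.fromkeys(f for f, _ in pairs))
        catalog = FeatureCatalog(tuple(feature_ids), mode=mode)
    known = catalog.index
    for lineno, (f, v) in enumerate(pairs, start=3):
        if f not in known:
            raise ValueError(f"{path}:{lineno}: unknown transcript {f!r}")
        catalog.version_index(v)

    ecs = []
    for lineno, ln in enumerate(lines[2 + n_tx : 2 + n_tx + n_ec], start=3 + n_tx):
        toks = ln.split()
        try:
            k = int(toks[0])
            idxs = [int(t) for t in toks[1 : 1 + k]]
            count = int(toks[1 + k])
        except (ValueError, IndexError):
            raise ValueError(f"{path}:{lineno}: malformed EC line {ln!r}") from None
        if count < 0:
            raise ValueError(f"{path}:{lineno}: negative count")
        members = tuple(pairs[i] for i in idxs)
        ecs.append(EquivalenceClass(members, np.array([count])))
    if len(ecs) != n_ec:
        raise ValueError(f"{path}: expected {n_ec} EC lines, found {len(ecs)}")
    return ECDataset(catalog=catalog, samples=(sample_id,), group_of={sample_id: "NA"}, ecs=ecs)


def write_salmon_eq_classes(ds: ECDataset, path, sample: str | None = None) -> None:
    """Write one sample of a dataset in salmon ``eq_classes.txt`` layout."""
    sample = sample or ds.samples[0]
    si = ds.samples.index(sample)
    names = []
    name_idx: dict[tuple[str, str], int] = {}
    for ec in ds.ecs:
        for f, v in ec.members:
            if (f, v) not in name_idx:
                name_idx[(f, v)] = len(names)
                names.append(f if v == "S" else f"{f}-{v}")
    with _open_text(path, "wt") as fh:
        fh.write(f"{len(names)}\n{len(ds.ecs)}\n")
        for nm in names:
            fh.write(nm + "\n")
        for ec in ds.ecs:
            idxs = [name_idx[m] for m in ec.members]
            fh.write("\t".join(map(str, [len(idxs), *idxs, int(ec.counts[si])])) + "\n")


def combine_samples(datasets: list[ECDataset], group_of: dict[str, str]) -> ECDataset:
    """Merge one-sample datasets (same catalog) into a multi-sample dataset,
    merging ECs with identical member sets."""
    cat = datasets[0].catalog
    samples = []
    for ds in datasets:
        if tuple(ds.catalog.feature_ids) != tuple(cat.feature_ids):
            raise ValueError("all datasets must share one catalog")
        samples.extend(ds.samples)
    merged: dict[tuple, np.ndarray] = {}
    for j, ds in enumerate(datasets):
        for ec in ds.ecs:
            key = tuple(sorted(ec.members))
            row = merged.setdefault(key, np.zeros(len(samples), dtype=np.int64))
            off = sum(d.n_samples for d in datasets[:j])
            row[off : off + ds.n_samples] += ec.counts
    ecs = [EquivalenceClass(k, v) for k, v in merged.items()]
    return ECDataset(catalog=cat, samples=tuple(samples), group_of=dict(group_of), ecs=ecs)


def write_ec_json(ds: ECDataset, path) -> None:
    """Serialise a dataset to the internal JSON schema (lossless)."""
    doc = {
        "schema_version": EC_JSON_SCHEMA_VERSION,
        "catalog": {
            "feature_ids": list(ds.catalog.feature_ids),
            "mode": ds.catalog.mode,
            "eff_len": None if ds.catalog.eff_len is None else ds.catalog.eff_len.tolist(),
        },
        "samples": list(ds.samples),
        "group_of": dict(ds.group_of),
        "ecs": [
            {"members": [[f, v] for f, v in ec.members], "counts": ec.counts.tolist()}
            for ec in ds.ecs
        ],
    }
    with _open_text(path, "wt") as fh:
        json.dump(doc, fh)


def read_ec_json(path) -> ECDataset:
    """Read the internal JSON schema; schema violations raise with a pointer."""
    with _open_text(path) as fh:
        doc = json.load(fh)

    def need(obj, key, ptr):
        if not isinstance(obj, dict) or key not in obj:
            raise ValueError(f"EC JSON schema violation at {ptr}: missing {key!r}")
        return obj[key]

    if need(doc, "schema_version", "/") != EC_JSON_SCHEMA_VERSION:
        raise ValueError(f"EC JSON schema violation at /schema_version: "
                         f"unsupported version {doc.get('schema_version')!r}")
    cat = need(doc, "catalog", "/")
    eff = need(cat, "eff_len", "/catalog")
    catalog = FeatureCatalog(
        feature_ids=tuple(need(cat, "feature_ids", "/catalog")),
        mode=need(cat, "mode", "/catalog"),
        eff_len=None if eff is None else np.asarray(eff, dtype=float),
    )
    samples = tuple(need(doc, "samples", "/"))
    ecs = []
    for i, rec in enumerate(need(doc, "ecs", "/")):
        members = tuple((f, v) for f, v in need(rec, "members", f"/ecs/{i}"))
        counts = np.asarray(need(rec, "counts", f"/ecs/{i}"), dtype=np.int64)
        ecs.append(EquivalenceClass(members, counts))
    return ECDataset(catalog=catalog, samples=samples,
                     group_of=dict(need(doc, "group_of", "/")), ecs=ecs)


def read_effective_lengths(path, feature_ids: list[str]) -> np.ndarray:
    """Read a TSV ``feature_id  eff_len_S  eff_len_U`` into catalog order."""
    df = pd.read_csv(path, sep="\t")
    df = df.set_index(df.columns[0])
    missing = [f for f in feature_ids if f not in df.index]
    if missing:
        raise ValueError(f"effective lengths missing for features: {missing[:5]}")
    return df.loc[list(feature_ids)].iloc[:, :2].to_numpy(dtype=float)


def read_cluster_assignment(path) -> CellAssignment:
    """Read a TSV with columns cell_id, sample_id, cluster_id."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    return CellAssignment(df)


def read_usa_mtx(mtx_paths: dict[str, str], features_path, barcodes_path) -> CellLevelData:
    """Read genes x cells MTX matrices (one per version S/U/A) plus feature
    and barcode TSVs.  A single matrix with ``-U``/``-A``-suffixed gene rows
    is also accepted by passing it under the key ``"USA"``."""
    from scipy.io import mmread

    genes = pd.read_csv(features_path, sep="\t", header=None)[0].tolist()
    cells = pd.read_csv(barcodes_path, sep="\t", header=None)[0].tolist()
    if set(mtx_paths) == {"USA"}:
        m = np.asarray(mmread(mtx_paths["USA"]).todense())
        pairs = [split_versioned_id(g) for g in genes]
        base = list(dict.fromkeys(f for f, _ in pairs))
        counts = {v: np.zeros((len(base), len(cells))) for v in SC_VERSIONS}
        bidx = {g: i for i, g in enumerate(base)}
        for row, (f, v) in enumerate(pairs):
            counts[v][bidx[f]] += m[row]
        return CellLevelData(tuple(base), tuple(cells), counts)
    counts = {}
    for v, p in mtx_paths.items():
        m = np.asarray(mmread(p).todense())
        if m.shape != (len(genes), len(cells)):
            raise ValueError(f"MTX {v!r} shape {m.shape} does not match "
                             f"{len(genes)} genes x {len(cells)} cells")
        counts[v] = m
    for v in SC_VERSIONS:
        counts.setdefault(v, np.zeros((len(genes), len(cells))))
    return CellLevelData(tuple(genes), tuple(cells), counts)


# ---------------------------------------------------------------------------
# pseudo-bulk aggregation and filtering
# ---------------------------------------------------------------------------


def aggregate_pseudobulk(
    cell_data: CellLevelData,
    assign: CellAssignment,
    cluster: str,
    group_of: dict[str, str] | None = None,
) -> ECDataset:
    """Sum single-cell s/u/a counts over each sample's cells in `cluster`.

    Unique (single-gene) reads from the count matrices become single-member
    ECs; multi-gene ECs are summed per sample and merged by member set.
    Total reads are conserved exactly.
    """
    sub = assign.cells_in(cluster)
    if len(sub) == 0:
        raise ValueError(f"cluster {cluster!r} has zero assigned cells")
    missing = set(sub["cell_id"]) - set(cell_data.cell_ids)
    if missing:
        raise ValueError(f"cells assigned but absent from count matrix: {sorted(missing)[:5]}")

    samples = tuple(pd.unique(sub["sample_id"]))
    cell_pos = {c: i for i, c in enumerate(cell_data.cell_ids)}
    catalog = FeatureCatalog(tuple(cell_data.gene_ids), mode="sc-gene")

    merged: dict[tuple, np.ndarray] = {}
    for si, s in enumerate(samples):
        cols = [cell_pos[c] for c in sub.loc[sub["sample_id"] == s, "cell_id"]]
        for v in SC_VERSIONS:
            tot = cell_data.counts[v][:, cols].sum(axis=1)
            for gi in np.nonzero(tot)[0]:
                key = ((cell_data.gene_ids[gi], v),)
                row = merged.setdefault(key, np.zeros(len(samples), dtype=np.int64))
                row[si] += int(round(tot[gi]))
    if cell_data.ecs is not None:
        cluster_cells = set(sub["cell_id"])
        sample_of_cell = dict(zip(sub["cell_id"], sub["sample_id"]))
        for members, per_cell in zip(cell_data.ecs.members, cell_data.ecs.counts):
            key = tuple(sorted(members))
            for cell, n in per_cell.items():
                if cell in cluster_cells:
                    row = merged.setdefault(key, np.zeros(len(samples), dtype=np.int64))
                    row[samples.index(sample_of_cell[cell])] += n
    ecs = [EquivalenceClass(k, v) for k, v in merged.items()]
    if group_of is None:
        group_of = {s: "NA" for s in samples}
    return ECDataset(catalog=catalog, samples=samples, group_of=dict(group_of), ecs=ecs)


def filter_min_counts(ds: ECDataset, min_count: int = 10) -> ECDataset:
    """Keep features with >= `min_count` EC-compatible reads in *each* group.

    A feature's abundance is the summed count of every EC containing any
    version of it.  Mixed-membership ECs retain their surviving members;
    ECs left with no surviving member are dropped.  Idempotent.
    """
    if len(ds.groups) < 2:
        raise ValueError("filtering requires two groups")
    totals = ds.feature_group_totals()
    keep = set(totals.index[(totals >= min_count).all(axis=1)])
    new_ids = tuple(f for f in ds.catalog.feature_ids if f in keep)
    if ds.catalog.eff_len is not None:
        pos = [ds.catalog.index[f] for f in new_ids]
        catalog = replace(ds.catalog, feature_ids=new_ids, eff_len=ds.catalog.eff_len[pos])
    else:
        catalog = replace(ds.catalog, feature_ids=new_ids)
    ecs = []
    for ec in ds.ecs:
        members = tuple(m for m in ec.members if m[0] in keep)
        if members:
            ecs.append(EquivalenceClass(members, ec.counts))
    return ECDataset(catalog=catalog, samples=ds.samples, group_of=dict(ds.group_of), ecs=ecs)
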