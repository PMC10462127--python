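import numpy as np
import pytest

from diffreg.ec_data import ECDataset, EquivalenceClass, FeatureCatalog


def make_conjugate_dataset(n_features=5, n_samples=3, seed=0, mode="bulk-transcript",
                           delta_plus=20.0, pbar_u=None, depth=(50, 200)):
    """Dataset with only single-member ECs, generated from the hierarchical
    model itself — the uniquely-mapping limit where the posterior is
    available in closed conjugate form."""
    rng = np.random.default_rng(seed)
    K = 2 if mode == "bulk-transcript" else 3
    F, N = n_features, n_samples
    Y = rng.integers(*depth, size=(N, F))
    if pbar_u is None:
        pbar_u = rng.uniform(0.15, 0.85, size=F)
    if K == 2:
        pbar = np.column_stack([1 - pbar_u, pbar_u])
    else:
        pa = rng.uniform(0.05, 0.15, size=F)
        pbar = np.column_stack([(1 - pa) * (1 - pbar_u), (1 - pa) * pbar_u, pa])
    g = rng.gamma(delta_plus * pbar[None, :, :] * np.ones((N, 1, 1)))
    pi = g / g.sum(axis=2, keepdims=True)
    X = np.zeros((N, F, K), dtype=np.int64)
    rem = Y.copy()
    prem = np.ones((N, F))
    for k in range(K - 1):
        ratio = np.clip(pi[:, :, k] / prem, 0, 1)
        d = rng.binomial(rem, ratio)
        X[:, :, k] = d
        rem -= d
        prem -= pi[:, :, k]
    X[:, :, K - 1] = rem

    versions = ("S", "U") if K == 2 else ("S", "U", "A")
    eff = np.ones((F, 2)) if mode == "bulk-transcript" else None
    cat = FeatureCatalog(tuple(f"t{i}" for i in range(F)), mode=mode, eff_len=eff)
    ecs = []
    for f in range(F):
        for k, v in enumerate(versions):
            ecs.append(EquivalenceClass(((f"t{f}", v),), X[:, f, k].copy()))
    samples = tuple(f"s{i}" for i in range(N))
    ds = ECDataset(cat, samples, {s: "A" for s in samples}, ecs)
    return ds, X, pbar


def random_ec_dataset(n_features=20, n_samples=3, n_ecs=50, seed=0,
                      mode="bulk-transcript", two_groups=True):
    rng = np.random.default_rng(seed)
    versions = ("S", "U") if mode == "bulk-transcript" else ("S", "U", "A")
    eff = rng.uniform(100, 5000, size=(n_features, 2)) if mode == "bulk-transcript" else None
    cat = FeatureCatalog(tuple(f"f{i}" for i in range(n_features)), mode=mode, eff_len=eff)
    ecs = {}
    for _ in range(n_ecs):
        k = int(rng.integers(1, 4))
        members = set()
        while len(members) < k:
            members.add((f"f{rng.integers(n_features)}", versions[rng.integers(len(versions))]))
        key = tuple(sorted(members))
        counts = rng.integers(0, 100, size=n_samples)
        if key in ecs:
            ecs[key] = ecs[key] + counts
        else:
            ecs[key] = counts
    samples = tuple(f"s{i}" for i in range(n_samples))
    if two_groups:
        group_of = {s: ("A" if i < (n_samples + 1) // 2 else "B")
                    for i, s in enumerate(samples)}
    else:
        group_of = {s: "A" for s in samples}
    return ECDataset(cat, samples, group_of,
                     [EquivalenceClass(m, c) for m, c in ecs.items()])


@pytest.fixture
def conjugate_ds():
    return make_conjugate_dataset(seed=3)


@pytest.fixture
def random_ds():
    return random_ec_dataset(seed=1)
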