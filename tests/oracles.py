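"""Independent naive reference implementations used only by the tests.

Everything here is deliberately written with explicit loops and without
reusing any code path from the package, so that agreement between the two
routes is informative.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
from scipy.stats import rankdata


# ---------------------------------------------------------------------------
# ANOSIM by exhaustive enumeration
# ---------------------------------------------------------------------------


def brute_anosim(dist: np.ndarray, labels) -> tuple[float, float]:
    """ANOSIM R and its exact p over all label permutations.

    Mid-ranks on the condensed dissimilarities; p is the fraction of the
    n! label orderings (identity included) whose R is >= the observed R.
    """
    labels = np.asarray(labels)
    n = len(labels)
    pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
    d = np.array([dist[i, j] for i, j in pairs])
    ranks = rankdata(d)
    denom = n * (n - 1) / 4.0

    def r_of(lab):
        rw, nw, rb, nb = 0.0, 0, 0.0, 0
        for k, (i, j) in enumerate(pairs):
            if lab[i] == lab[j]:
                rw += ranks[k]
                nw += 1
            else:
                rb += ranks[k]
                nb += 1
        return (rb / nb - rw / nw) / denom

    r_obs = r_of(labels)
    count = total = 0
    for perm in itertools.permutations(range(n)):
        total += 1
        if r_of(labels[list(perm)]) >= r_obs - 1e-12:
            count += 1
    return r_obs, count / total


# ---------------------------------------------------------------------------
# Mantel by exhaustive enumeration
# ---------------------------------------------------------------------------


def brute_mantel_spearman(d1: np.ndarray, d2: np.ndarray) -> tuple[float, float]:
    """Spearman Mantel r and exact one-sided p over all n! permutations."""
    n = d1.shape[0]
    pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]

    def corr(a, b):
        ra, rb = rankdata(a), rankdata(b)
        ra = ra - ra.mean()
        rb = rb - rb.mean()
        return float((ra * rb).sum() / math.sqrt((ra ** 2).sum() * (rb ** 2).sum()))

    x = np.array([d1[i, j] for i, j in pairs])
    y = np.array([d2[i, j] for i, j in pairs])
    r_obs = corr(x, y)
    count = total = 0
    for perm in itertools.permutations(range(n)):
        yp = np.array([d2[perm[i], perm[j]] for i, j in pairs])
        total += 1
        if corr(x, yp) >= r_obs - 1e-12:
            count += 1
    return r_obs, count / total


# ---------------------------------------------------------------------------
# Naive betaMNTD / betaNTI
# ---------------------------------------------------------------------------


def naive_patristic(tree) -> tuple[np.ndarray, list[str]]:
    """Patristic matrix from parent pointers, recomputed from scratch."""
    leaves = list(tree.tree.leaf_node_iter())
    labels = [lf.taxon.label for lf in leaves]

    def path_to_root(node):
        out = []
        while node.parent_node is not None:
            out.append((id(node.parent_node), node.edge.length or 0.0))
            node = node.parent_node
        return out

    paths = [path_to_root(lf) for lf in leaves]
    n = len(leaves)
    D = np.zeros((n, n))
    for i in range(n):
        anc_i = {a: sum(l for _, l in paths[i][: k + 1])
                 for k, (a, _) in enumerate(paths[i])}
        for j in range(i + 1, n):
            acc = 0.0
            for k, (a, l) in enumerate(paths[j]):
                acc += l
                if a in anc_i:
                    D[i, j] = D[j, i] = anc_i[a] + acc
                    break
    return D, labels


def naive_betamntd(counts: np.ndarray, D: np.ndarray, weighted: bool = True) -> np.ndarray:
    """betaMNTD with explicit loops (no vectorisation, no shared code)."""
    n_samp, n_taxa = counts.shape
    out = np.zeros((n_samp, n_samp))
    for x in range(n_samp):
        for y in range(x + 1, n_samp):
            total = 0.0
            for a, b in ((x, y), (y, x)):
                fa = counts[a] / counts[a].sum()
                if not weighted:
                    pres = (counts[a] > 0).astype(float)
                    fa = pres / pres.sum()
                present_b = [j for j in range(n_taxa) if counts[b, j] > 0]
                acc = 0.0
                for i in range(n_taxa):
                    if fa[i] == 0:
                        continue
                    acc += fa[i] * min(D[i, j] for j in present_b)
                total += 0.5 * acc
            out[x, y] = out[y, x] = total
    return out


def naive_beta_nti(counts, D, n_null, seed, weighted=True):
    """betaNTI with the same PCG64 shuffle stream as the implementation,
    but betaMNTD recomputed by the naive loops above."""
    obs = naive_betamntd(counts, D, weighted)
    rng = np.random.Generator(np.random.PCG64(int(seed)))
    n_taxa = D.shape[0]
    nulls = []
    for _ in range(n_null):
        perm = rng.permutation(n_taxa)
        Dp = D[np.ix_(perm, perm)]
        nulls.append(naive_betamntd(counts, Dp, weighted))
    nulls = np.array(nulls)
    mean = nulls.mean(axis=0)
    sd = nulls.std(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (obs - mean) / sd
    z[sd < 1e-12] = np.nan
    np.fill_diagonal(z, 0.0)
    return z


# ---------------------------------------------------------------------------
# Exhaustive Raup-Crick null for tiny instances
# ---------------------------------------------------------------------------


def _subset_prob(weights: np.ndarray, subset: tuple[int, ...]) -> float:
    """Probability of drawing exactly this subset without replacement."""
    total = weights.sum()
    p = 0.0
    for order in itertools.permutations(subset):
        q, rem = 1.0, total
        for i in order:
            q *= weights[i] / rem
            rem -= weights[i]
        p += q
    return p


def enumerate_rc_null(richness, n_individuals, occupancy, regional):
    """Exact null distribution of one sample's community as {tuple: prob}.

    Enumerates occupancy-weighted subsets of the given richness, then all
    multinomial allocations of the remaining individuals with
    regional-abundance weights.
    """
    n_taxa = len(occupancy)
    out = {}
    extra = n_individuals - richness
    for subset in itertools.combinations(range(n_taxa), richness):
        ps = _subset_prob(occupancy, subset)
        w = np.array([regional[i] for i in subset], dtype=float)
        w = w / w.sum()
        for alloc in itertools.product(range(extra + 1), repeat=richness):
            if sum(alloc) != extra:
                continue
            pm = math.factorial(extra)
            for a, wi in zip(alloc, w):
                pm = pm / math.factorial(a) * (wi ** a)
            comm = [0] * n_taxa
            for i, a in zip(subset, alloc):
                comm[i] = 1 + a
            key = tuple(comm)
            out[key] = out.get(key, 0.0) + ps * pm
    return out


def exact_rc(sample_a, sample_b, occupancy, regional) -> float:
    """Exact RC for a pair, integrating over both samples' null spaces."""
    def bc(u, v):
        u, v = np.asarray(u, float), np.asarray(v, float)
        return float(np.abs(u - v).sum() / (u + v).sum())

    obs = bc(sample_a, sample_b)
    dist_a = enumerate_rc_null(int((np.asarray(sample_a) > 0).sum()),
                               int(sum(sample_a)), occupancy, regional)
    dist_b = enumerate_rc_null(int((np.asarray(sample_b) > 0).sum()),
                               int(sum(sample_b)), occupancy, regional)
    less = ties = 0.0
    for ca, pa in dist_a.items():
        for cb, pb in dist_b.items():
            v = bc(ca, cb)
            if v < obs - 1e-12:
                less += pa * pb
            elif abs(v - obs) <= 1e-12:
                ties += pa * pb
    return 2.0 * (less + 0.5 * ties) - 1.0


# ---------------------------------------------------------------------------
# Naive graph metrics (adjacency sets + BFS, no networkx)
# ---------------------------------------------------------------------------


def naive_graph_metrics(edges, nodes=None) -> dict:
    adj: dict = {}
    for a, b in edges:
        adj.setdefault(a, set()).add(b)
        adj.setdefault(b, set()).add(a)
    if nodes:
        for v in nodes:
            adj.setdefault(v, set())
    verts = sorted(adj)
    n = len(verts)
    m = len(edges)
    deg = {v: len(adj[v]) for v in verts}
    degrees = np.array([deg[v] for v in verts], dtype=float)

    # local clustering
    cc = []
    for v in verts:
        k = deg[v]
        if k < 2:
            cc.append(0.0)
            continue
        nb = list(adj[v])
        links = sum(1 for i in range(len(nb)) for j in range(i + 1, len(nb))
                    if nb[j] in adj[nb[i]])
        cc.append(2.0 * links / (k * (k - 1)))

    # components + BFS path lengths
    seen = set()
    comps = 0
    total_len = 0
    total_pairs = 0
    for v in verts:
        if v in seen:
            continue
        comps += 1
        comp = [v]
        seen.add(v)
        qi = 0
        while qi < len(comp):
            for w in adj[comp[qi]]:
                if w not in seen:
                    seen.add(w)
                    comp.append(w)
            qi += 1
        for s in comp:
            dist = {s: 0}
            queue = [s]
            qi2 = 0
            while qi2 < len(queue):
                u = queue[qi2]
                qi2 += 1
                for w in adj[u]:
                    if w not in dist:
                        dist[w] = dist[u] + 1
                        queue.append(w)
            total_len += sum(dist.values())
            total_pairs += len(dist) - 1

    return dict(
        edge_node_ratio=m / n,
        average_degree=2.0 * m / n,
        density=2.0 * m / (n * (n - 1)) if n > 1 else 0.0,
        max_degree=int(degrees.max()),
        clustering_coefficient=float(np.mean(cc)),
        connected_components=comps,
        centralization=(float((degrees.max() - degrees).sum() / ((n - 1) * (n - 2)))
                        if n >= 3 else float("nan")),
        heterogeneity=float(degrees.std() / degrees.mean()) if degrees.mean() else 0.0,
        average_path_length=(total_len / total_pairs if total_pairs else float("nan")),
    )
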