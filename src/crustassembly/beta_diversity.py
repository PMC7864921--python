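"""Dissimilarity, ordination and permutation tests.

Implements the community-difference toolkit used across the study angles:
Bray-Curtis dissimilarity, non-metric multidimensional scaling (Kruskal
stress-1 with Guttman updates), ANOSIM, a betadisper-style homogeneity of
multivariate dispersions test, the Mantel test (Spearman by default) and
the distance-decay regressions with their line intersection.

Permutation p-values use the ``(1 + #extreme) / (1 + n_perm)`` estimator so
p is never 0 and the smallest attainable p at 999 permutations is 0.001.
ANOSIM and Mantel additionally expose an exhaustive mode (``n_perm=None``)
that enumerates every label permutation — feasible for the small instances
used in oracle tests.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import isotonic_regression
from scipy.spatial.distance import pdist, squareform
from scipy.stats import linregress, rankdata

from .core_io import GroupAssignment, OtuTable, to_relative

__all__ = [
    "DistMatrix",
    "PermTestResult",
    "OrdinationResult",
    "LineFit",
    "DecayRegression",
    "bray_curtis",
    "nmds",
    "anosim",
    "dispersion_test",
    "mantel",
    "distance_decay",
    "site_pair_statistics",
]


# ---------------------------------------------------------------------------
# Types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DistMatrix:
    """Symmetric pairwise matrix over samples with a zero diagonal.

    The same container carries Bray-Curtis dissimilarities, geographic
    distances, beta-NTI and Raup-Crick values; entries may be negative or
    NaN (NaN = undefined pair) depending on the semantics.
    """

    ids: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("values must be a square matrix")
        if len(self.ids) != v.shape[0]:
            raise ValueError("ids length must match matrix size")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("duplicate ids")
        with np.errstate(invalid="ignore"):
            asym = np.nanmax(np.abs(v - v.T)) if v.size else 0.0
        if asym > 1e-12:
            raise ValueError(f"matrix not symmetric (max asymmetry {asym})")
        if np.nanmax(np.abs(np.diag(v))) > 0:
            raise ValueError("diagonal must be exactly 0")
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "ids", tuple(self.ids))

    @property
    def n(self) -> int:
        return len(self.ids)

    def condensed(self) -> np.ndarray:
        """Upper-triangle entries in scipy condensed order."""
        iu = np.triu_indices(self.n, k=1)
        return self.values[iu]

    def submatrix(self, ids) -> "DistMatrix":
        idx = [self.ids.index(i) for i in ids]
        return DistMatrix(tuple(ids), self.values[np.ix_(idx, idx)])

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.ids), columns=list(self.ids))

    @classmethod
    def from_condensed(cls, ids, condensed: np.ndarray) -> "DistMatrix":
        return cls(tuple(ids), squareform(condensed))


@dataclass(frozen=True)
class PermTestResult:
    """Outcome of a permutation test (ANOSIM R, dispersion F or Mantel r)."""

    method: str
    statistic: float
    p_value: float
    n_permutations: int
    n: int
    seed: int | None = None

    def __post_init__(self) -> None:
        if not math.isfinite(self.statistic):
            raise ValueError("statistic must be finite")


@dataclass(frozen=True)
class OrdinationResult:
    """NMDS configuration with Kruskal stress-1."""

    coordinates: pd.DataFrame  # samples x k
    stress: float
    n_restarts: int
    converged: bool
    stress_history: tuple[float, ...] = ()


@dataclass(frozen=True)
class LineFit:
    slope: float
    intercept: float
    r_squared: float
    p_value: float
    n: int

    def predict(self, x: float) -> float:
        return self.slope * x + self.intercept


@dataclass(frozen=True)
class DecayRegression:
    """Two distance-decay lines and, when the slopes differ, where they cross."""

    geography: LineFit
    succession: LineFit
    intersection_km: float | None


# ---------------------------------------------------------------------------
# Dissimilarity
# ---------------------------------------------------------------------------


def bray_curtis(t: OtuTable) -> DistMatrix:
    """Pairwise Bray-Curtis dissimilarity between samples.

    BC_xy = sum_i |x_i - y_i| / sum_i (x_i + y_i), computed on the table as
    provided (counts or relative abundances — the pipeline default is
    relative).
    """
    x = t.counts
    if (x.sum(axis=1) == 0).any():
        raise ValueError("Bray-Curtis undefined for all-zero samples")
    cond = pdist(x, metric="braycurtis")
    return DistMatrix.from_condensed(t.sample_ids, cond)


# ---------------------------------------------------------------------------
# Principal coordinates (shared by NMDS init and the dispersion test)
# ---------------------------------------------------------------------------


def _pcoa(d: DistMatrix, eps: float = 1e-9):
    """Eigendecomposition of the Gower-centred squared-distance matrix.

    Returns (positive-axis coordinates, negative-axis coordinates,
    eigenvalues descending).  Negative eigenvalues arise for semi-metric
    dissimilarities like Bray-Curtis; their axes are returned separately so
    callers can apply the imaginary-part correction.
    """
    D2 = d.values ** 2
    n = d.n
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ D2 @ J
    B = (B + B.T) / 2
    vals, vecs = np.linalg.eigh(B)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    pos = vals > eps * max(1.0, abs(vals[0]))
    neg = vals < -eps * max(1.0, abs(vals[0]))
    coords_pos = vecs[:, pos] * np.sqrt(vals[pos])
    coords_neg = vecs[:, neg] * np.sqrt(-vals[neg])
    return coords_pos, coords_neg, vals


# ---------------------------------------------------------------------------
# NMDS
# ---------------------------------------------------------------------------


def _stress1(dist: np.ndarray, dhat: np.ndarray) -> float:
    denom = float(np.sum(dist ** 2))
    if denom == 0:
        return 0.0
    return math.sqrt(float(np.sum((dist - dhat) ** 2)) / denom)


def _nmds_single(diss: np.ndarray, X0: np.ndarray, max_iter: int, tol: float):
    """One NMDS run: isotonic disparities + Guttman transform updates.

    The recorded stress trajectory is non-increasing by construction: an
    update that would raise stress is rejected and the run stops there.
    """
    n = X0.shape[0]
    order = np.argsort(diss, kind="stable")
    inv_order = np.empty_like(order)
    inv_order[order] = np.arange(len(order))
    X = X0.copy()
    history: list[float] = []
    converged = False
    dist = pdist(X)
    dhat = isotonic_regression(dist[order]).x[inv_order]
    stress = _stress1(dist, dhat)
    history.append(stress)
    for _ in range(max_iter):
        # Guttman transform toward the current disparities
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(dist > 0, dhat / dist, 0.0)
        W = squareform(ratio)
        B = -W
        np.fill_diagonal(B, W.sum(axis=1))
        X_new = B @ X / n
        dist_new = pdist(X_new)
        dhat_new = isotonic_regression(dist_new[order]).x[inv_order]
        stress_new = _stress1(dist_new, dhat_new)
        if stress_new > stress:          # reject non-improving step
            converged = True
            break
        improved = stress - stress_new
        X, dist, dhat, stress = X_new, dist_new, dhat_new, stress_new
        history.append(stress)
        if improved < tol:
            converged = True
            break
    return X, stress, history, converged


def _principal_axis_rotation(X: np.ndarray) -> np.ndarray:
    """Centre, rotate to principal axes, and fix axis signs.

    Sign convention: on each axis the coordinate with the largest absolute
    value is positive, so repeated runs agree up to this deterministic
    choice rather than an arbitrary reflection.
    """
    Xc = X - X.mean(axis=0)
    _, _, Vt = np.linalg.svd(Xc, full_matrices=False)
    Y = Xc @ Vt.T
    for j in range(Y.shape[1]):
        i = np.argmax(np.abs(Y[:, j]))
        if Y[i, j] < 0:
            Y[:, j] = -Y[:, j]
    return Y


def nmds(
    d: DistMatrix,
    k: int = 2,
    n_restarts: int = 4,
    max_iter: int = 300,
    tol: float = 1e-6,
    seed: int = 0,
) -> OrdinationResult:
    """Kruskal non-metric MDS of a dissimilarity matrix.

    The first start is the principal-coordinate configuration; the
    remaining ``n_restarts - 1`` starts are seeded random configurations.
    The best (lowest stress-1) solution is reported, rotated to principal
    axes with a deterministic sign convention.
    """
    if d.n < k + 2:
        raise ValueError(f"need at least k+2={k+2} samples for k={k}")
    diss = d.condensed()
    if not np.isfinite(diss).all():
        raise ValueError("non-finite dissimilarities")
    rng = np.random.Generator(np.random.PCG64(int(seed)))
    coords_pos, _, _ = _pcoa(d)
    scale = max(diss.max(), 1e-12)
    inits = []
    X0 = np.zeros((d.n, k))
    ncols = min(k, coords_pos.shape[1])
    X0[:, :ncols] = coords_pos[:, :ncols]
    inits.append(X0)
    for _ in range(max(0, n_restarts - 1)):
        inits.append(rng.normal(0.0, scale, size=(d.n, k)))

    best = None
    for X0 in inits:
        X, stress, history, converged = _nmds_single(diss, X0, max_iter, tol)
        if best is None or stress < best[1]:
            best = (X, stress, history, converged)
    X, stress, history, converged = best
    Y = _principal_axis_rotation(X)
    coords = pd.DataFrame(
        Y, index=list(d.ids), columns=[f"NMDS{i+1}" for i in range(k)]
    )
    return OrdinationResult(
        coordinates=coords,
        stress=float(stress),
        n_restarts=n_restarts,
        converged=bool(converged),
        stress_history=tuple(history),
    )


# ---------------------------------------------------------------------------
# ANOSIM
# ---------------------------------------------------------------------------


def _check_groups(labels: np.ndarray) -> None:
    levels, counts = np.unique(labels, return_counts=True)
    if len(levels) < 2:
        raise ValueError("need at least 2 groups")
    if (counts < 2).any():
        small = [str(l) for l, c in zip(levels, counts) if c < 2]
        raise ValueError(f"groups with fewer than 2 samples: {small}")


def _anosim_r(ranks: np.ndarray, within: np.ndarray, n: int) -> float:
    rw = ranks[within].mean()
    rb = ranks[~within].mean()
    return float((rb - rw) / (n * (n - 1) / 4.0))


def anosim(
    d: DistMatrix,
    g: GroupAssignment,
    n_perm: int | None = 999,
    seed: int = 0,
) -> PermTestResult:
    """Analysis of similarities with mid-rank ties.

    R = (mean between-group rank - mean within-group rank) / (N(N-1)/4),
    one-sided p against label permutations (R_perm >= R_obs).  With
    ``n_perm=None`` every one of the N! label permutations is enumerated
    and the exact p is #{R_perm >= R_obs} / N!.
    """
    labels = np.asarray([g.labels[i] for i in d.ids])
    _check_groups(labels)
    n = d.n
    iu, ju = np.triu_indices(n, k=1)
    ranks = rankdata(d.condensed())
    within = labels[iu] == labels[ju]
    r_obs = _anosim_r(ranks, within, n)

    if n_perm is None:
        count = 0
        total = 0
        for perm in itertools.permutations(range(n)):
            lp = labels[list(perm)]
            rp = _anosim_r(ranks, lp[iu] == lp[ju], n)
            count += rp >= r_obs - 1e-12
            total += 1
        return PermTestResult("anosim", r_obs, count / total, total, n, None)

    rng = np.random.Generator(np.random.PCG64(int(seed)))
    count = 0
    for _ in range(n_perm):
        lp = labels[rng.permutation(n)]
        rp = _anosim_r(ranks, lp[iu] == lp[ju], n)
        count += rp >= r_obs - 1e-12
    p = (1 + count) / (1 + n_perm)
    return PermTestResult("anosim", r_obs, p, n_perm, n, seed)


# ---------------------------------------------------------------------------
# betadisper-style dispersion test
# ---------------------------------------------------------------------------


def _dispersion_distances(d: DistMatrix, labels: np.ndarray) -> np.ndarray:
    """Distance of each sample to its group centroid in PCoA space.

    Negative eigenvalues contribute imaginary axes whose squared distances
    are subtracted (Anderson's correction); small negative squared
    distances from numerical error are clipped to zero.
    """
    pos, neg, _ = _pcoa(d)
    if pos.size == 0 or np.allclose(d.values, 0):
        raise ValueError("degenerate embedding: all points identical")
    z = np.empty(d.n)
    for lvl in np.unique(labels):
        mask = labels == lvl
        c_pos = pos[mask].mean(axis=0)
        d2 = ((pos[mask] - c_pos) ** 2).sum(axis=1)
        if neg.size:
            c_neg = neg[mask].mean(axis=0)
            d2 = d2 - ((neg[mask] - c_neg) ** 2).sum(axis=1)
        z[mask] = np.sqrt(np.clip(d2, 0.0, None))
    return z


def _anova_f(z: np.ndarray, labels: np.ndarray) -> float:
    grand = z.mean()
    ss_between = 0.0
    ss_within = 0.0
    levels = np.unique(labels)
    for lvl in levels:
        zi = z[labels == lvl]
        ss_between += len(zi) * (zi.mean() - grand) ** 2
        ss_within += ((zi - zi.mean()) ** 2).sum()
    df1 = len(levels) - 1
    df2 = len(z) - len(levels)
    if ss_within == 0:
        return 0.0 if ss_between == 0 else math.inf
    return float((ss_between / df1) / (ss_within / df2))


def dispersion_test(
    d: DistMatrix,
    g: GroupAssignment,
    n_perm: int = 999,
    seed: int = 0,
) -> PermTestResult:
    """Homogeneity of multivariate dispersions (betadisper-style).

    Samples are embedded by principal coordinates; each sample's distance
    to its group centroid (with the imaginary-axis correction for negative
    eigenvalues) is the response of a one-way ANOVA F test, with p from
    permuting group labels of those distances.
    """
    labels = np.asarray([g.labels[i] for i in d.ids])
    _check_groups(labels)
    z = _dispersion_distances(d, labels)
    f_obs = _anova_f(z, labels)
    rng = np.random.Generator(np.random.PCG64(int(seed)))
    count = 0
    for _ in range(n_perm):
        count += _anova_f(z, labels[rng.permutation(d.n)]) >= f_obs - 1e-12
    p = (1 + count) / (1 + n_perm)
    return PermTestResult("dispersion", f_obs, p, n_perm, d.n, seed)


# ---------------------------------------------------------------------------
# Mantel
# ---------------------------------------------------------------------------


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    xc = x - x.mean()
    yc = y - y.mean()
    denom = math.sqrt(float((xc ** 2).sum() * (yc ** 2).sum()))
    return float((xc * yc).sum() / denom)


def mantel(
    d1: DistMatrix,
    d2: DistMatrix,
    method: str = "spearman",
    n_perm: int | None = 999,
    seed: int = 0,
) -> PermTestResult:
    """Mantel correlation between two distance matrices over the same ids.

    r is the (rank, for Spearman) correlation of the upper triangles; p is
    one-sided (r_perm >= r_obs) against joint row+column permutations of
    the second matrix.  ``n_perm=None`` enumerates all n! permutations.
    """
    if d1.ids != d2.ids:
        raise ValueError("distance matrices must share ids in the same order")
    if method not in ("spearman", "pearson"):
        raise ValueError(f"unknown method {method!r}")
    n = d1.n
    if n < 3:
        raise ValueError("need at least 3 samples")
    x = d1.condensed()
    y = d2.condensed()
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("mantel undefined: zero variance in a distance triangle")
    if method == "spearman":
        x = rankdata(x)
        y = rankdata(y)
    r_obs = _pearson(x, y)

    # condensed-index lookup so a permutation of samples maps to a gather
    iu, ju = np.triu_indices(n, k=1)
    idx_of = np.zeros((n, n), dtype=int)
    idx_of[iu, ju] = idx_of[ju, iu] = np.arange(len(iu))

    def permuted_r(perm: np.ndarray) -> float:
        yp = y[idx_of[perm[iu], perm[ju]]]
        return _pearson(x, yp)

    if n_perm is None:
        count = total = 0
        for perm in itertools.permutations(range(n)):
            count += permuted_r(np.asarray(perm)) >= r_obs - 1e-12
            total += 1
        return PermTestResult(f"mantel_{method}", r_obs, count / total, total, n, None)

    rng = np.random.Generator(np.random.PCG64(int(seed)))
    count = 0
    for _ in range(n_perm):
        count += permuted_r(rng.permutation(n)) >= r_obs - 1e-12
    p = (1 + count) / (1 + n_perm)
    return PermTestResult(f"mantel_{method}", r_obs, p, n_perm, n, seed)


# ---------------------------------------------------------------------------
# Distance decay
# ---------------------------------------------------------------------------


def _fit_line(points) -> LineFit:
    xs = np.asarray([p[0] for p in points], dtype=float)
    ys = np.asarray([p[1] for p in points], dtype=float)
    if len(xs) < 3:
        raise ValueError("need at least 3 points per series")
    res = linregress(xs, ys)
    return LineFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue ** 2),
        p_value=float(res.pvalue),
        n=len(xs),
    )


def distance_decay(geography_pairs, succession_pairs) -> DecayRegression:
    """OLS fits of two (distance_km, statistic) series and their crossing.

    The geography series carries the between-site community difference at
    each site-pair distance; the succession series the between-stage
    difference for the same pairs.  The intersection distance
    ``(b2 - b1) / (a1 - a2)`` is where the two influences are equal; it is
    undefined (None) for parallel lines.
    """
    geo = _fit_line(geography_pairs)
    succ = _fit_line(succession_pairs)
    if math.isclose(geo.slope, succ.slope, rel_tol=1e-12, abs_tol=1e-15):
        inter = None
    else:
        inter = (succ.intercept - geo.intercept) / (geo.slope - succ.slope)
    return DecayRegression(geography=geo, succession=succ, intersection_km=inter)


def site_pair_statistics(
    t: OtuTable,
    meta,
    sites: list[str] | None = None,
    statistic: str = "R2",
    n_perm: int = 199,
    seed: int = 0,
):
    """Per-site-pair ANOSIM statistics for the distance-decay regressions.

    For every unordered pair of sites (restricted to ``sites`` when given)
    the samples of both sites are pooled and two ANOSIMs are run: grouping
    by site (geography series) and grouping by successional stage
    (succession series).  The statistic is ANOSIM R squared by default
    (``statistic="R"`` for the raw R), paired with the haversine distance
    between the sites.
    """
    from .core_io import haversine_km

    if statistic not in ("R", "R2"):
        raise ValueError("statistic must be 'R' or 'R2'")
    df = meta.data
    all_sites = sorted(df["site_id"].unique()) if sites is None else list(sites)
    coords = meta.site_coordinates()
    geo_pts, succ_pts = [], []
    rng = np.random.Generator(np.random.PCG64(int(seed)))
    for a, b in itertools.combinations(all_sites, 2):
        samp = list(df.index[df["site_id"].isin([a, b])])
        sub = t.select_samples(samp)
        d = bray_curtis(to_relative(sub))
        dist_km = haversine_km(
            coords.at[a, "lat"], coords.at[a, "lon"],
            coords.at[b, "lat"], coords.at[b, "lon"],
        )
        site_g = GroupAssignment(
            "site", df.loc[samp, "site_id"].astype(str), tuple(sorted({a, b}))
        )
        stage_labels = df.loc[samp, "stage"].astype(str)
        stages = tuple(sorted(stage_labels.unique()))
        sub_seed = int(rng.integers(0, 2**31))
        try:
            r_geo = anosim(d, site_g, n_perm=n_perm, seed=sub_seed).statistic
        except ValueError:
            continue
        try:
            stage_g = GroupAssignment("succession", stage_labels, stages)
            r_succ = anosim(d, stage_g, n_perm=n_perm, seed=sub_seed).statistic
        except ValueError:
            continue
        if statistic == "R2":
            r_geo, r_succ = r_geo ** 2, r_succ ** 2
        geo_pts.append((dist_km, r_geo))
        succ_pts.append((dist_km, r_succ))
    return geo_pts, succ_pts
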