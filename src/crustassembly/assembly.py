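"""Null-model partitioning of community assembly processes.

The engine of the analysis: phylogenetic turnover (beta mean nearest taxon
distance, betaMNTD) is compared against a tip-shuffle null to give the beta
nearest taxon index (betaNTI), taxonomic turnover against a
richness/abundance-constrained null to give the Raup-Crick Bray-Curtis
metric (RC_bray), and every sample pair is then classified into one of five
ecological processes:

* betaNTI < -2          -> homogeneous selection
* betaNTI > +2          -> heterogeneous selection
* |betaNTI| <= 2, RC < -0.95 -> homogenizing dispersal
* |betaNTI| <= 2, RC > +0.95 -> dispersal limitation (coupled with drift)
* otherwise             -> drift alone (the undominated residual)

The thresholds are configurable.  "Species sorting" is the sum of the two
selection fractions.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .core_io import OtuTable, PhyloTree, SampleMetadata, assign_groups, to_relative
from .beta_diversity import DistMatrix

__all__ = [
    "BetaNTIMatrix",
    "RaupCrickMatrix",
    "ProcessFractions",
    "PROCESS_NAMES",
    "betamntd",
    "beta_nti",
    "raup_crick_bray",
    "partition_processes",
    "assembly_by_angle",
]

PROCESS_NAMES = (
    "homogeneous_selection",
    "heterogeneous_selection",
    "homogenizing_dispersal",
    "dispersal_limitation",
    "drift",
)


@dataclass(frozen=True)
class BetaNTIMatrix:
    """betaNTI per sample pair; NaN entries are flagged-undefined pairs
    (null standard deviation below 1e-12, e.g. on a star phylogeny)."""

    dist: DistMatrix
    n_null: int
    seed: int

    @property
    def ids(self):
        return self.dist.ids

    @property
    def values(self) -> np.ndarray:
        return self.dist.values

    @property
    def undefined_pairs(self) -> int:
        iu = np.triu_indices(self.dist.n, k=1)
        return int(np.isnan(self.dist.values[iu]).sum())


@dataclass(frozen=True)
class RaupCrickMatrix:
    """Raup-Crick (Bray-Curtis variant) per sample pair, in [-1, 1]."""

    dist: DistMatrix
    n_null: int
    seed: int

    def __post_init__(self) -> None:
        iu = np.triu_indices(self.dist.n, k=1)
        v = self.dist.values[iu]
        if v.size and np.nanmax(np.abs(v)) > 1 + 1e-12:
            raise ValueError("RC values must lie in [-1, 1]")

    @property
    def ids(self):
        return self.dist.ids

    @property
    def values(self) -> np.ndarray:
        return self.dist.values


@dataclass(frozen=True)
class ProcessFractions:
    """Percentages of the five assembly processes over a set of pairs."""

    group: str
    percentages: dict
    n_pairs: int
    n_undefined: int = 0

    def __post_init__(self) -> None:
        missing = set(PROCESS_NAMES) - set(self.percentages)
        if missing:
            raise ValueError(f"missing process classes: {missing}")
        total = sum(self.percentages.values())
        if self.n_pairs > 0 and abs(total - 100.0) > 0.01:
            raise ValueError(f"percentages sum to {total}, not 100")

    @property
    def species_sorting(self) -> float:
        return (
            self.percentages["homogeneous_selection"]
            + self.percentages["heterogeneous_selection"]
        )

    @property
    def dominant(self) -> str:
        return max(self.percentages, key=self.percentages.get)


# ---------------------------------------------------------------------------
# betaMNTD / betaNTI
# ---------------------------------------------------------------------------


def _weights_and_supports(t: OtuTable, abundance_weighted: bool):
    rel = to_relative(t)
    F = rel.counts
    if not abundance_weighted:
        P = (F > 0).astype(float)
        F = P / P.sum(axis=1, keepdims=True)
    supports = [np.flatnonzero(row) for row in t.counts]
    return F, supports


def _betamntd_matrix(F: np.ndarray, supports, D: np.ndarray) -> np.ndarray:
    """betaMNTD for all sample pairs given a patristic matrix.

    For samples x, y: 0.5 * sum_i f_i^x min_{j in y} D_ij
                    + 0.5 * sum_j f_j^y min_{i in x} D_ij.
    A taxon shared by both samples has nearest-taxon distance 0.
    """
    n_samp = F.shape[0]
    # M[y, i] = min over taxa j present in sample y of D[i, j]
    M = np.empty((n_samp, F.shape[1]))
    for y in range(n_samp):
        M[y] = D[:, supports[y]].min(axis=1)
    comp = F @ M.T           # comp[x, y] = directed mean from x into y
    out = 0.5 * (comp + comp.T)
    np.fill_diagonal(out, 0.0)
    return out


def betamntd(
    t: OtuTable,
    tree: PhyloTree,
    abundance_weighted: bool = True,
) -> DistMatrix:
    """Between-community mean nearest taxon distance (betaMNTD).

    Abundance-weighted by default; the unweighted variant uses uniform
    weights over the taxa present in each sample.  Every taxon in the
    table must be a leaf of the tree.
    """
    D, _ = tree.patristic_matrix(t.taxon_ids)
    F, supports = _weights_and_supports(t, abundance_weighted)
    out = _betamntd_matrix(F, supports, D)
    out = (out + out.T) / 2  # exact symmetry against float noise
    np.fill_diagonal(out, 0.0)
    return DistMatrix(tuple(t.sample_ids), out)


def beta_nti(
    t: OtuTable,
    tree: PhyloTree,
    n_null: int = 999,
    seed: int = 0,
    abundance_weighted: bool = True,
) -> BetaNTIMatrix:
    """beta nearest taxon index: z-score of betaMNTD against a tip shuffle.

    The null shuffles taxon labels across all tree tips, randomising
    phylogenetic relationships while keeping abundances and richness fixed.
    One shuffle per null replicate is shared by all pairs (matrix-level
    null).  Pairs whose null standard deviation falls below 1e-12 (e.g. on
    a star tree, where every shuffle is distance-preserving) are flagged
    NaN rather than raising.
    """
    if n_null < 99:
        raise ValueError("n_null must be >= 99")
    # canonical (sorted) taxon order, so the result is invariant to the
    # column order of the table under the same seed-aligned null stream
    t = t.select_taxa(sorted(t.taxon_ids))
    D, _ = tree.patristic_matrix(t.taxon_ids)
    F, supports = _weights_and_supports(t, abundance_weighted)
    obs = _betamntd_matrix(F, supports, D)
    n = t.n_samples
    rng = np.random.Generator(np.random.PCG64(int(seed)))
    acc = np.zeros_like(obs)
    acc2 = np.zeros_like(obs)
    n_taxa = D.shape[0]
    for _ in range(n_null):
        perm = rng.permutation(n_taxa)
        Dp = D[np.ix_(perm, perm)]
        null = _betamntd_matrix(F, supports, Dp)
        acc += null
        acc2 += null ** 2
    mean = acc / n_null
    var = np.clip(acc2 / n_null - mean ** 2, 0.0, None)
    sd = np.sqrt(var)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (obs - mean) / sd
    z[sd < 1e-12] = np.nan
    z = (z + z.T) / 2
    np.fill_diagonal(z, 0.0)
    return BetaNTIMatrix(DistMatrix(tuple(t.sample_ids), z), n_null, seed)


# ---------------------------------------------------------------------------
# Raup-Crick (Bray-Curtis)
# ---------------------------------------------------------------------------


def _bray(a: np.ndarray, b: np.ndarray) -> float:
    s = (a + b).sum()
    return float(np.abs(a - b).sum() / s) if s else 0.0


def _null_community(
    richness: int,
    n_individuals: int,
    occupancy: np.ndarray,
    regional: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """One null assemblage with fixed richness and individual count.

    Occurring taxa are drawn without replacement with probability
    proportional to occupancy; each gets one individual, and the remaining
    individuals are distributed among them with probability proportional
    to regional relative abundance.
    """
    n_taxa = len(occupancy)
    chosen = rng.choice(n_taxa, size=richness, replace=False,
                        p=occupancy / occupancy.sum())
    counts = np.zeros(n_taxa)
    counts[chosen] = 1.0
    extra = n_individuals - richness
    if extra > 0:
        w = regional[chosen]
        counts[chosen] += rng.multinomial(extra, w / w.sum())
    return counts


def raup_crick_bray(
    t: OtuTable,
    n_null: int = 999,
    seed: int = 0,
    null_mode: str = "shared",
) -> RaupCrickMatrix:
    """Raup-Crick metric on Bray-Curtis, rescaled to [-1, 1].

    RC = 2 * ((#null BC < observed BC) + 0.5 * #ties) / n_null - 1: values
    near +1 mean the pair is more dissimilar than the stochastic
    expectation, near -1 more similar.  The null fixes each sample's
    richness and total individual count (see ``_null_community``).

    ``null_mode="shared"`` draws one null assemblage per sample per
    replicate and reuses it for every pair in that replicate (cheap, the
    per-pair marginal distribution is unchanged); ``"per_pair"`` draws
    fresh assemblages for each pair.
    """
    if n_null < 99:
        raise ValueError("n_null must be >= 99")
    counts = t.counts
    if t.is_relative or not np.allclose(counts, np.round(counts)):
        raise ValueError(
            "Raup-Crick requires integer counts; supply the counts table"
        )
    counts = np.round(counts)
    n_samp, n_taxa = counts.shape
    occupancy = (counts > 0).mean(axis=0)
    regional = counts.sum(axis=0)
    regional = regional / regional.sum()
    richness = (counts > 0).sum(axis=1).astype(int)
    totals = counts.sum(axis=1).astype(int)
    obs_bc = squareform(pdist(counts, metric="braycurtis"))

    rng = np.random.Generator(np.random.PCG64(int(seed)))
    less = np.zeros((n_samp, n_samp))
    ties = np.zeros((n_samp, n_samp))
    tol = 1e-12
    if null_mode == "shared":
        for _ in range(n_null):
            nulls = np.stack([
                _null_community(richness[i], totals[i], occupancy, regional, rng)
                for i in range(n_samp)
            ])
            null_bc = squareform(pdist(nulls, metric="braycurtis"))
            less += null_bc < obs_bc - tol
            ties += np.abs(null_bc - obs_bc) <= tol
    elif null_mode == "per_pair":
        for i, j in itertools.combinations(range(n_samp), 2):
            for _ in range(n_null):
                a = _null_community(richness[i], totals[i], occupancy, regional, rng)
                b = _null_community(richness[j], totals[j], occupancy, regional, rng)
                bc = _bray(a, b)
                if bc < obs_bc[i, j] - tol:
                    less[i, j] += 1
                elif abs(bc - obs_bc[i, j]) <= tol:
                    ties[i, j] += 1
            less[j, i] = less[i, j]
            ties[j, i] = ties[i, j]
    else:
        raise ValueError(f"unknown null_mode {null_mode!r}")

    rc = 2.0 * (less + 0.5 * ties) / n_null - 1.0
    rc = (rc + rc.T) / 2
    np.fill_diagonal(rc, 0.0)
    return RaupCrickMatrix(DistMatrix(tuple(t.sample_ids), rc), n_null, seed)


# ---------------------------------------------------------------------------
# Process partition
# ---------------------------------------------------------------------------


def classify_pair(bnti: float, rc: float,
                  bnti_threshold: float = 2.0,
                  rc_threshold: float = 0.95) -> str | None:
    """Five-way classification of one sample pair (None = undefined betaNTI)."""
    if np.isnan(bnti):
        return None
    if bnti > bnti_threshold:
        return "heterogeneous_selection"
    if bnti < -bnti_threshold:
        return "homogeneous_selection"
    if rc > rc_threshold:
        return "dispersal_limitation"
    if rc < -rc_threshold:
        return "homogenizing_dispersal"
    return "drift"


def partition_processes(
    bnti: BetaNTIMatrix,
    rc: RaupCrickMatrix,
    sample_ids=None,
    group: str = "all",
    bnti_threshold: float = 2.0,
    rc_threshold: float = 0.95,
) -> ProcessFractions:
    """Fractions of sample pairs attributed to each assembly process.

    Classifies every (optionally restricted) pair by its betaNTI and RC
    values; percentages are over classified pairs, and pairs with
    undefined betaNTI are counted separately, never silently dropped.
    """
    if tuple(bnti.ids) != tuple(rc.ids):
        raise ValueError("betaNTI and RC matrices must share ids")
    ids = list(bnti.ids)
    if sample_ids is not None:
        idx = [ids.index(s) for s in sample_ids]
    else:
        idx = list(range(len(ids)))
    if len(idx) < 2:
        raise ValueError("need at least 2 samples to form pairs")
    counts = {name: 0 for name in PROCESS_NAMES}
    n_undef = 0
    for a, b in itertools.combinations(idx, 2):
        cls = classify_pair(
            bnti.values[a, b], rc.values[a, b], bnti_threshold, rc_threshold
        )
        if cls is None:
            n_undef += 1
        else:
            counts[cls] += 1
    n_pairs = sum(counts.values())
    if n_pairs == 0:
        raise ValueError("no classifiable pairs (all undefined)")
    pct = {k: 100.0 * v / n_pairs for k, v in counts.items()}
    return ProcessFractions(group=group, percentages=pct,
                            n_pairs=n_pairs, n_undefined=n_undef)


def assembly_by_angle(
    t: OtuTable,
    tree: PhyloTree,
    meta: SampleMetadata,
    angle: str,
    n_null: int = 999,
    seed: int = 0,
    abundance_weighted: bool = True,
    bnti_threshold: float = 2.0,
    rc_threshold: float = 0.95,
) -> list[ProcessFractions]:
    """Per-group process fractions along one study angle.

    betaNTI and RC are computed once over all samples; each group level is
    then summarised over the pairs whose two samples share that level.
    Levels with fewer than 2 samples are skipped with a warning.
    """
    groups = assign_groups(meta, angle)
    seeds = np.random.SeedSequence(seed).spawn(2)
    bnti = beta_nti(t, tree, n_null=n_null,
                    seed=int(seeds[0].generate_state(1)[0] % (2**31)),
                    abundance_weighted=abundance_weighted)
    rcm = raup_crick_bray(t, n_null=n_null,
                          seed=int(seeds[1].generate_state(1)[0] % (2**31)))
    out = []
    for level in groups.levels:
        members = [s for s in groups.level_samples(level) if s in bnti.ids]
        if len(members) < 2:
            warnings.warn(
                f"angle {angle}: level {level!r} has fewer than 2 samples; skipped"
            )
            continue
        out.append(
            partition_processes(
                bnti, rcm, sample_ids=members, group=level,
                bnti_threshold=bnti_threshold, rc_threshold=rc_threshold,
            )
        )
    return out


def fractions_table(results: list[ProcessFractions]) -> pd.DataFrame:
    """Stack ProcessFractions into a processes x groups percentage table."""
    data = {r.group: [r.percentages[p] for p in PROCESS_NAMES] for r in results}
    df = pd.DataFrame(data, index=list(PROCESS_NAMES))
    df.loc["species_sorting"] = [r.species_sorting for r in results]
    return df
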