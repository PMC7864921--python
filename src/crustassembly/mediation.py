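"""Environment-community Mantel screening and sorting-environment links.

Two questions are answered here.  First, which environmental variables
covary with community structure within each sample group: a Mantel test
(Spearman) between the phylum-level Bray-Curtis distance and the
single-variable distance (absolute difference of within-group z-scored
values), one cell per (group, variable).  Second, which variables track
the deterministic share of assembly: the Spearman correlation between the
species-sorting percentage of each group and the group-mean of each
variable, computed separately per domain so opposite bacterial vs
eukaryotic directions can be flagged.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .core_io import EnvTable, GroupAssignment, OtuTable, TaxonomyTable, to_relative
from .beta_diversity import DistMatrix, bray_curtis, mantel
__all__ = [
    "MantelScreen",
    "SortingCorrelation",
    "phylum_table",
    "mantel_screen",
    "sorting_env_correlation",
]


@dataclass(frozen=True)
class MantelScreen:
    """Mantel r and p per (group level, environment variable)."""

    domain: str
    r: pd.DataFrame        # rows = group levels, cols = variables; NaN = undefined
    p: pd.DataFrame
    n_perm: int
    seed: int

    def strong(self, r_min: float = 0.3, p_max: float = 0.05) -> pd.DataFrame:
        """Boolean strong-correlation flags at the given cutoffs."""
        return (self.r >= r_min) & (self.p <= p_max)

    def long_format(self) -> pd.DataFrame:
        rows = []
        for grp in self.r.index:
            for var in self.r.columns:
                rows.append(dict(domain=self.domain, group=grp, variable=var,
                                 r=self.r.at[grp, var], p=self.p.at[grp, var]))
        return pd.DataFrame(rows)


@dataclass(frozen=True)
class SortingCorrelation:
    """Per-variable Spearman link between species sorting and environment."""

    table: pd.DataFrame     # rows = variables; columns rho_<dom>, p_<dom> per domain

    def opposition_report(self, domains: tuple[str, str] = ("Bacteria", "Eukaryota")) -> list[str]:
        """Variables whose correlation direction differs between domains."""
        a, b = domains
        out = []
        for var, row in self.table.iterrows():
            ra, rb = row.get(f"rho_{a}"), row.get(f"rho_{b}")
            if pd.notna(ra) and pd.notna(rb) and ra * rb < 0:
                out.append(var)
        return out


def phylum_table(
    t: OtuTable,
    tax: TaxonomyTable,
    min_mean_rel: float = 1e-4,
) -> OtuTable:
    """Aggregate OTUs to phylum-level relative abundances.

    OTUs without a taxonomy entry fall into an "Unclassified" phylum.
    Phyla whose overall mean relative abundance does not exceed
    ``min_mean_rel`` (default 0.01%) are removed; sample rows are kept as
    raw sums (they sum to 1 only when nothing is filtered).
    """
    rel = to_relative(t)
    phyla = [
        tax.phylum_of(tid) if tid in tax.data.index else "Unclassified"
        for tid in rel.taxon_ids
    ]
    agg = rel.data.T.groupby(pd.Index(phyla, name="phylum")).sum().T
    keep = agg.mean(axis=0) > min_mean_rel
    agg = agg.loc[:, keep]
    if agg.shape[1] == 0:
        raise ValueError("no phyla survive the abundance filter")
    return OtuTable(agg, is_relative=False)


def _env_distance(values: np.ndarray, ids) -> DistMatrix | None:
    """Distance matrix |z_i - z_j| of one z-scored variable; None if constant
    or too sparse after dropping missing values."""
    sd = np.nanstd(values)
    if not np.isfinite(sd) or sd == 0:
        return None
    z = (values - np.nanmean(values)) / sd
    d = np.abs(z[:, None] - z[None, :])
    np.fill_diagonal(d, 0.0)
    return DistMatrix(tuple(ids), d)


def mantel_screen(
    t_phylum: OtuTable,
    env: EnvTable,
    groups: GroupAssignment,
    n_perm: int = 999,
    seed: int = 0,
    domain: str = "",
    min_samples: int = 5,
) -> MantelScreen:
    """Mantel (Spearman) screen of every variable within every group level.

    Community distance is Bray-Curtis on the phylum table; environmental
    distance is the absolute difference of the variable z-scored within
    the level.  Samples with a missing value are dropped pairwise for that
    variable only.  Constant variables yield NaN cells (undefined), not
    exceptions.
    """
    variables = env.variables
    levels = [lvl for lvl in groups.levels
              if len(groups.level_samples(lvl)) >= min_samples]
    r_out = pd.DataFrame(np.nan, index=levels, columns=variables)
    p_out = pd.DataFrame(np.nan, index=levels, columns=variables)
    rng = np.random.Generator(np.random.PCG64(int(seed)))
    for lvl in levels:
        samples = [s for s in groups.level_samples(lvl)
                   if s in t_phylum.sample_ids]
        if len(samples) < min_samples:
            continue
        sub = t_phylum.select_samples(samples)
        d_comm_full = bray_curtis(to_relative(sub))
        for var in variables:
            vals = env.data.loc[samples, var].to_numpy(float)
            ok = np.isfinite(vals)
            if ok.sum() < min_samples:
                continue
            ids = [s for s, k in zip(samples, ok) if k]
            d_env = _env_distance(vals[ok], ids)
            if d_env is None:
                continue
            d_comm = d_comm_full.submatrix(ids) if not ok.all() else d_comm_full
            sub_seed = int(rng.integers(0, 2**31))
            try:
                res = mantel(d_comm, d_env, method="spearman",
                             n_perm=n_perm, seed=sub_seed)
            except ValueError:
                continue
            r_out.at[lvl, var] = res.statistic
            p_out.at[lvl, var] = res.p_value
    return MantelScreen(domain=domain, r=r_out, p=p_out, n_perm=n_perm, seed=seed)


def sorting_env_correlation(
    fractions: dict,
    env: EnvTable,
    group_samples: dict,
    summary: str = "mean",
) -> SortingCorrelation:
    """Correlate species-sorting percentages with group-level environments.

    ``fractions`` maps domain -> list of ProcessFractions (one per group
    level, pooled across study angles for power); ``group_samples`` maps
    group label -> sample ids, used to summarise each variable per level
    (mean by default, median optional).  Needs >= 3 levels; warns below 5.
    Constant sorting fractions give NaN (flagged undefined).
    """
    if summary not in ("mean", "median"):
        raise ValueError("summary must be 'mean' or 'median'")
    rows = {}
    for dom, frac_list in fractions.items():
        if len(frac_list) < 3:
            raise ValueError(
                f"domain {dom}: need >= 3 group levels, got {len(frac_list)}"
            )
        if len(frac_list) < 5:
            warnings.warn(
                f"domain {dom}: only {len(frac_list)} levels; correlation is underpowered"
            )
        sorting = np.array([f.species_sorting for f in frac_list])
        labels = [f.group for f in frac_list]
        for var in env.variables:
            means = []
            for lbl in labels:
                samples = group_samples[lbl]
                v = env.data.loc[samples, var].astype(float)
                means.append(v.mean() if summary == "mean" else v.median())
            means = np.asarray(means)
            key = (var, dom)
            if np.ptp(sorting) == 0 or np.nanstd(means) == 0:
                rows[key] = (np.nan, np.nan)
                continue
            rho, p = spearmanr(sorting, means, nan_policy="omit")
            rows[key] = (float(rho), float(p))
    variables = env.variables
    domains = list(fractions)
    data = {}
    for dom in domains:
        data[f"rho_{dom}"] = [rows[(v, dom)][0] for v in variables]
        data[f"p_{dom}"] = [rows[(v, dom)][1] for v in variables]
    table = pd.DataFrame(data, index=pd.Index(variables, name="variable"))
    return SortingCorrelation(table=table)
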