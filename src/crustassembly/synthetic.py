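"""Synthetic metacommunities with known assembly regimes.

The generator places sites on a one-dimensional geographic axis (mapped to
longitude), lays an environmental gradient over it, evolves taxon niche
optima by Brownian motion on a simulated phylogeny, and then samples local
communities whose composition reflects a chosen mixture of the four
classical assembly processes:

* **selection** -- sampling weights are down-weighted by the squared
  mismatch between a taxon's niche optimum and the local environment,
  ``exp(-sigma_sel * (trait - E)^2 / 2)``; ``sigma_sel`` is a selection
  *strength* (0 = neutral, large = strong environmental filtering);
* **dispersal limitation** -- each taxon has a home site and its weight
  decays as ``exp(-lambda * d_km(home, site))``;
* **homogenizing dispersal** -- a migration rate ``m`` mixes local relative
  abundances back toward the shared regional pool each drift round
  (``m`` near 1 keeps every community at the pool);
* **drift** -- repeated multinomial resampling of the J individuals.

Communities are multinomial draws of exactly ``community_size`` (J)
individuals, so every sample has the same sequencing depth by construction.
All randomness flows from one integer seed through ``numpy``
``SeedSequence`` spawning: the tree, the traits and the communities consume
independent substreams, so e.g. regenerating communities with a different
scenario leaves the tree unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd

from .core_io import (
    EnvTable,
    OtuTable,
    PhyloTree,
    SampleMetadata,
    TaxonomyTable,
    write_otu_table,
)

__all__ = [
    "ScenarioConfig",
    "SCENARIOS",
    "simulate_tree",
    "simulate_niche_traits",
    "simulate_metacommunity",
    "simulate_scenario",
    "make_fixture",
]

#: km per degree of longitude used to map the 1-D site axis to distances;
#: roughly a mid-latitude parallel, recorded in fixture metadata.
KM_PER_DEGREE = 85.0

#: Longitude span of the site axis (degrees E), matching the study region.
LON_MIN, LON_MAX = 87.0, 120.0

#: Sign/direction of the stage effect on the local environment (severe A ->
#: mild M); the magnitude is ``ScenarioConfig.stage_offset`` as a fraction of
#: the site-gradient span.
STAGE_ENV_OFFSET = {"A": 1.0, "C": 0.0, "M": -1.0}

#: MAP increases west -> east in the study region; the synthetic MAP runs
#: linearly from arid to mesic across the axis, within the 0-450 mm bins.
MAP_RANGE_MM = (30.0, 440.0)


@dataclass(frozen=True)
class ScenarioConfig:
    """Parameters of one simulated metacommunity.

    ``selection_strength`` (1 / trait-units^2) scales environmental
    filtering; ``dispersal_decay`` (1/km) scales distance decay of taxon
    weights; ``migration_rate`` in [0, 1] mixes local frequencies with the
    regional pool each drift round; ``drift_steps`` counts resampling
    rounds; ``community_size`` J is the exact number of individuals drawn
    per sample.
    """

    n_sites: int = 12
    samples_per_site: int = 4
    n_taxa: int = 200
    stages: tuple[str, ...] = ("A",)
    selection_strength: float = 0.0
    migration_rate: float = 0.1
    dispersal_decay: float = 0.0
    drift_steps: int = 0
    trait_signal: float = 1.0
    trait_conservatism: float = 4.0
    stage_offset: float = 0.15
    community_size: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.migration_rate <= 1:
            raise ValueError("migration_rate must be in [0, 1]")
        if self.selection_strength < 0 or self.dispersal_decay < 0:
            raise ValueError("rates must be >= 0")
        if self.drift_steps < 0:
            raise ValueError("drift_steps must be >= 0")
        if self.trait_signal <= 0:
            raise ValueError("trait_signal must be > 0")
        if self.community_size < 1:
            raise ValueError("community_size must be >= 1")
        if any(s not in ("A", "C", "M") for s in self.stages):
            raise ValueError("stages must be drawn from A/C/M")


#: Named regimes used by fixtures and the parameter-recovery tests.  The
#: non-focal rates are zero (or near-neutral) so each fixture isolates one
#: generating process.
SCENARIOS: dict[str, dict] = {
    "selection": dict(selection_strength=60.0, dispersal_decay=0.0,
                      migration_rate=0.02, drift_steps=0),
    "dispersal_limitation": dict(selection_strength=0.0, dispersal_decay=0.01,
                                 migration_rate=0.02, drift_steps=2),
    "homogenizing": dict(selection_strength=0.0, dispersal_decay=0.0,
                         migration_rate=1.0, drift_steps=0),
    "drift": dict(selection_strength=0.0, dispersal_decay=0.0,
                  migration_rate=0.1, drift_steps=15),
    "mixed_succession": dict(selection_strength=8.0, dispersal_decay=0.0005,
                             migration_rate=0.05, drift_steps=5,
                             stages=("A", "C", "M"), stage_offset=0.3),
}


def _spawn(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.Generator(np.random.PCG64(s))
            for s in np.random.SeedSequence(seed).spawn(n)]


def simulate_tree(n_taxa: int, birth_rate: float = 1.0, seed: int = 0) -> PhyloTree:
    """Pure-birth (Yule) tree with ``n_taxa`` leaves labelled OTU_1..OTU_n.

    Branch lengths are rescaled so the mean root-to-tip depth is 1, which
    puts Brownian trait variances on a unit scale.  The tree is not
    ultrametric-guaranteed after the stochastic branching (dendropy keeps
    extant tips contemporaneous, but no test relies on it).
    """
    if n_taxa < 2:
        raise ValueError("n_taxa must be >= 2")
    import random as _random

    rng = _random.Random(int(seed))
    if n_taxa == 2:
        # the birth-death simulator stops immediately at 2 extant tips;
        # build the cherry directly with an exponential split depth
        depth = rng.expovariate(birth_rate)
        tree = dendropy.Tree.get(
            data=f"(OTU_1:{depth + 1e-9},OTU_2:{depth + 1e-9});",
            schema="newick", preserve_underscores=True)
    else:
        tree = dendropy.model.birthdeath.birth_death_tree(
            birth_rate=birth_rate,
            death_rate=0.0,
            num_extant_tips=n_taxa,
            rng=rng,
        )
    leaves = list(tree.leaf_node_iter())
    # stable labelling independent of dendropy's internal naming
    for i, leaf in enumerate(leaves, start=1):
        leaf.taxon.label = f"OTU_{i}"
    depths = []
    for leaf in leaves:
        d, node = 0.0, leaf
        while node.parent_node is not None:
            d += node.edge.length or 0.0
            node = node.parent_node
        depths.append(d)
    mean_depth = float(np.mean(depths))
    if mean_depth <= 0:
        raise ValueError("degenerate tree with zero depth")
    for edge in tree.preorder_edge_iter():
        if edge.length is not None:
            edge.length = max(edge.length / mean_depth, 1e-9)
    return PhyloTree(tree)


def simulate_niche_traits(
    tree: PhyloTree,
    sigma_bm: float = 1.0,
    seed: int = 0,
    conservatism: float = 0.0,
) -> pd.Series:
    """Brownian-motion niche optima along the tree from a root value of 0.

    With ``conservatism=0`` (the default) a leaf's trait is normal with
    variance ``sigma_bm**2`` times its root-to-leaf path length, and
    covaries with other leaves through shared branches — the phylogenetic
    signal that makes nearest-taxon metrics informative about selection.

    ``conservatism > 0`` switches to an early-burst (ACDC) clock whose
    variance density decays as ``exp(-conservatism * depth)``: trait
    divergence concentrates on the deep branches, so clades are tight in
    niche space — the strong niche conservatism the assembly null models
    assume of real communities.
    """
    if sigma_bm <= 0:
        raise ValueError("sigma_bm must be > 0")
    total_length = sum(
        e.length or 0.0 for e in tree.tree.preorder_edge_iter()
    )
    if total_length <= 0:
        raise ValueError("tree has zero total branch length")
    rng = np.random.Generator(np.random.PCG64(int(seed)))
    rate = float(conservatism)
    values: dict[int, float] = {}
    depth: dict[int, float] = {}
    out: dict[str, float] = {}
    for node in tree.tree.preorder_node_iter():
        if node.parent_node is None:
            values[id(node)] = 0.0
            depth[id(node)] = 0.0
        else:
            parent = values[id(node.parent_node)]
            d0 = depth[id(node.parent_node)]
            length = node.edge.length or 0.0
            depth[id(node)] = d0 + length
            if rate > 0:
                var = sigma_bm ** 2 * (
                    np.exp(-rate * d0) - np.exp(-rate * (d0 + length))
                ) / rate
            else:
                var = sigma_bm ** 2 * length
            values[id(node)] = parent + rng.normal(0.0, np.sqrt(max(var, 0.0)))
        if node.is_leaf():
            out[node.taxon.label] = values[id(node)]
    return pd.Series(out, name="niche_optimum")


def _site_layout(cfg: ScenarioConfig, traits: pd.Series):
    """Site coordinates on the 1-D axis, with env gradient per site.

    The environmental optimum runs monotonically along the axis through
    the quantiles of the realised trait distribution (10th to 90th
    percentile), so every site has resident taxa near its optimum whatever
    the particular Brownian draw looks like.
    """
    axis = np.linspace(0.0, 1.0, cfg.n_sites)
    lon = LON_MIN + axis * (LON_MAX - LON_MIN)
    lat = np.full(cfg.n_sites, 40.0)
    dist_km = np.abs(lon[:, None] - lon[None, :]) * KM_PER_DEGREE
    env = np.quantile(traits.to_numpy(float), np.linspace(0.9, 0.1, cfg.n_sites))
    map_mm = MAP_RANGE_MM[0] + axis * (MAP_RANGE_MM[1] - MAP_RANGE_MM[0])
    site_ids = [f"S{i+1:02d}" for i in range(cfg.n_sites)]
    return site_ids, lat, lon, env, map_mm, dist_km


def simulate_metacommunity(
    cfg: ScenarioConfig,
    tree: PhyloTree,
    traits: pd.Series,
) -> tuple[OtuTable, SampleMetadata, EnvTable, TaxonomyTable]:
    """Sample site communities under the configured assembly regime.

    Returns the counts table (every row sums to J), sample metadata,
    a small synthetic environment table and a taxonomy assigning ~80% of
    taxa to Bacteria and the rest to Eukaryota.
    """
    taxa = tree.leaf_labels
    if set(traits.index) < set(taxa):
        raise ValueError("traits must cover all tree leaves")
    traits = traits.loc[taxa]
    n_taxa = len(taxa)

    rng_pool, rng_sites, rng_comm, rng_env = _spawn(cfg.seed, 4)

    site_ids, lat, lon, env, map_mm, dist_km = _site_layout(cfg, traits)
    span = float(env.max() - env.min()) or 1.0

    # lognormal regional pool: few dominant, many rare taxa
    pool = rng_pool.lognormal(mean=0.0, sigma=1.2, size=n_taxa)
    pool /= pool.sum()
    home_site = rng_pool.integers(0, cfg.n_sites, size=n_taxa)

    trait_vals = traits.to_numpy(float)

    rows, sample_ids, meta_rows, env_rows = [], [], [], []
    for s_idx, site in enumerate(site_ids):
        for stage in cfg.stages:
            e_local = env[s_idx] + STAGE_ENV_OFFSET[stage] * cfg.stage_offset * span
            w = pool.copy()
            if cfg.selection_strength > 0:
                w = w * np.exp(
                    -cfg.selection_strength * (trait_vals - e_local) ** 2 / 2.0
                )
            if cfg.dispersal_decay > 0:
                w = w * np.exp(-cfg.dispersal_decay * dist_km[home_site, s_idx])
            if w.sum() <= 0:
                raise ValueError("degenerate sampling weights (all zero)")
            w = (1 - cfg.migration_rate) * (w / w.sum()) + cfg.migration_rate * pool
            w /= w.sum()
            for rep in range(cfg.samples_per_site):
                counts = rng_comm.multinomial(cfg.community_size, w)
                p_drift = counts / cfg.community_size
                for _ in range(cfg.drift_steps):
                    p = (1 - cfg.migration_rate) * p_drift + cfg.migration_rate * pool
                    counts = rng_comm.multinomial(cfg.community_size, p / p.sum())
                    p_drift = counts / cfg.community_size
                sid = f"{site}_{stage}_{rep+1}"
                sample_ids.append(sid)
                rows.append(counts)
                meta_rows.append(
                    dict(site_id=site, lat=lat[s_idx], lon=lon[s_idx],
                         stage=stage, map_mm=map_mm[s_idx], replicate=rep + 1)
                )
                env_rows.append(
                    dict(
                        env_gradient=e_local + rng_env.normal(0, 0.05),
                        map_mm=map_mm[s_idx],
                        salinity=2.0 + 1.5 * e_local + rng_env.normal(0, 0.1),
                        soil_ph=8.0 - 0.4 * env[s_idx] + rng_env.normal(0, 0.1),
                        noise_var=rng_env.normal(0, 1.0),
                    )
                )

    counts_df = pd.DataFrame(np.array(rows), index=sample_ids, columns=taxa)
    # a sample could in principle come out all-zero only if J=0; invariant holds
    otu = OtuTable(counts_df, is_relative=False)
    meta = SampleMetadata(pd.DataFrame(meta_rows, index=sample_ids))
    envt = EnvTable(pd.DataFrame(env_rows, index=sample_ids))

    n_bact = int(round(0.8 * n_taxa))
    domains = ["Bacteria"] * n_bact + ["Eukaryota"] * (n_taxa - n_bact)
    # a handful of phyla per domain, assigned deterministically from the seed
    phyla_b = [f"B_phylum_{i+1}" for i in range(6)]
    phyla_e = [f"E_phylum_{i+1}" for i in range(4)]
    rng_tax = np.random.Generator(np.random.PCG64(cfg.seed + 101))
    phylum = [
        rng_tax.choice(phyla_b) if d == "Bacteria" else rng_tax.choice(phyla_e)
        for d in domains
    ]
    tax = TaxonomyTable(
        pd.DataFrame({"domain": domains, "phylum": phylum}, index=taxa)
    )
    return otu, meta, envt, tax


def simulate_scenario(
    name: str, seed: int = 0, **overrides
) -> tuple[OtuTable, SampleMetadata, EnvTable, TaxonomyTable, PhyloTree, pd.Series]:
    """Convenience wrapper: tree + traits + metacommunity for a named regime."""
    if name not in SCENARIOS:
        raise ValueError(f"unknown scenario {name!r}; choose from {sorted(SCENARIOS)}")
    params = dict(SCENARIOS[name])
    params.update(overrides)
    cfg = ScenarioConfig(seed=seed, **params)
    sub = np.random.SeedSequence(seed).spawn(2)
    tree = simulate_tree(cfg.n_taxa, seed=int(sub[0].generate_state(1)[0] % (2**31)))
    traits = simulate_niche_traits(
        tree, sigma_bm=cfg.trait_signal,
        seed=int(sub[1].generate_state(1)[0] % (2**31)),
        conservatism=cfg.trait_conservatism,
    )
    otu, meta, envt, tax = simulate_metacommunity(cfg, tree, traits)
    return otu, meta, envt, tax, tree, traits


def make_fixture(name: str, out_dir, seed: int = 0) -> Path:
    """Write a named scenario to disk in the canonical file layout.

    Produces ``otu.tsv`` (taxa as rows), ``taxonomy.tsv``, ``tree.nwk``,
    ``metadata.tsv``, ``env.tsv`` and ``fixture.json`` describing the
    scenario.  Sizes stay small (<= 60 samples, <= 300 taxa).
    """
    import json

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    overrides: dict = {}
    if name == "mixed_succession":
        # all three stages at every site; 5 sites x 3 stages x 4 reps = 60
        overrides = dict(n_sites=5)
    else:
        overrides = dict(n_sites=12)
    otu, meta, envt, tax, tree, traits = simulate_scenario(name, seed=seed, **overrides)
    assert otu.n_samples <= 60 and otu.n_taxa <= 300

    write_otu_table(otu, out_dir / "otu.tsv")
    tax.data.to_csv(out_dir / "taxonomy.tsv", sep="\t")
    (out_dir / "tree.nwk").write_text(tree.as_newick())
    meta.data.to_csv(out_dir / "metadata.tsv", sep="\t", float_format="%.10g")
    envt.data.to_csv(out_dir / "env.tsv", sep="\t", float_format="%.10g")
    manifest = {
        "scenario": name,
        "seed": seed,
        "km_per_degree": KM_PER_DEGREE,
        "parameters": {**SCENARIOS[name], **overrides},
    }
    manifest["parameters"]["stages"] = list(
        manifest["parameters"].get("stages", ("A",))
    )
    (out_dir / "fixture.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return out_dir
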