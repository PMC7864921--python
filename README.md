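# crustassembly

Community-assembly analysis for biocrust (biological soil crust)
microbiomes — and for any samples × OTUs dataset with a phylogeny,
metadata and environmental covariates.

Biocrust communities along dryland gradients are shaped by a mix of
deterministic environmental filtering ("species sorting") and stochastic
processes (dispersal and drift). This package implements the standard
null-model toolkit for quantifying that balance, plus the beta-diversity
and co-occurrence analyses that usually surround it:

* **Beta diversity** — Bray–Curtis dissimilarity, Kruskal NMDS
  (stress-1, best-of-restarts), ANOSIM, a betadisper-style homogeneity of
  dispersions test, and Mantel tests (Spearman), all with seeded
  permutation p-values and exhaustive-enumeration exact modes at small n.
* **Assembly processes** — abundance-weighted βMNTD from patristic
  distances; βNTI = (βMNTD_obs − mean βMNTD_null) / sd βMNTD_null against
  a tip-shuffle null; Raup–Crick on Bray–Curtis
  (RC = 2·P(null BC < obs) − 1) with richness- and abundance-constrained
  nulls; and the five-way partition per sample pair — βNTI < −2
  homogeneous selection, βNTI > 2 heterogeneous selection, otherwise
  RC > 0.95 dispersal limitation, RC < −0.95 homogenizing dispersal,
  else drift.
* **Gradient structure** — sample grouping along four study angles
  (succession A/C/M, longitude, latitude, MAP bins), distance-decay
  regressions of community difference vs km with the succession/geography
  line intersection, a per-group environment × phylum-level-community
  Mantel screen, and correlations of the species-sorting fraction with
  environmental variables.
* **Co-occurrence networks** — signed edges (coexistence/exclusion) from
  Spearman |ρ| ≥ 0.7 with a Bray–Curtis agreement filter, on the
  99%-cumulative-abundance OTU set, and a 13-metric topology panel
  (density, clustering, centralization, heterogeneity, path length, …).
* **Synthetic metacommunities** — a generator with known assembly regimes
  (selection, dispersal limitation, homogenizing dispersal, drift) over a
  simulated phylogeny, geography and environment, providing ground truth
  for every analysis stage.

## Worked example

Simulate a dispersal-limited metacommunity (6 sites × 4 replicate
samples, 200 OTUs, 1000 individuals per sample) and ask the null models
which process dominates:

```python
from crustassembly import (simulate_scenario, beta_nti, raup_crick_bray,
                           partition_processes)

otu, meta, env, tax, tree, traits = simulate_scenario(
    "dispersal_limitation", seed=0, n_sites=6)
bnti = beta_nti(otu, tree, n_null=199, seed=1)
rc = raup_crick_bray(otu, n_null=199, seed=2)
pf = partition_processes(bnti, rc)
for name, pct in pf.percentages.items():
    print(f"{name:25s} {pct:5.1f} %")
print(f"{'species sorting':25s} {pf.species_sorting:5.1f} %   "
      f"(n_pairs={pf.n_pairs}, dominant={pf.dominant})")
```

```
homogeneous_selection       0.4 %
heterogeneous_selection     2.9 %
homogenizing_dispersal     12.3 %
dispersal_limitation       84.4 %
drift                       0.0 %
species sorting             3.3 %   (n_pairs=276, dominant=dispersal_limitation)
```

84% of sample-pair turnover is attributed to dispersal limitation coupled
with drift — the process that generated the data — and only 3% to
selection: with no environmental filtering in the generator, |βNTI| stays
below 2 while the large between-site Bray–Curtis values exceed the
stochastic null (RC > 0.95).

The full study shape (ordination and group tests per angle, distance
decay, Mantel screen, Table-1-style process partition, topology panel,
sorting–environment correlations, per domain) runs from one config:

```bash
crustassembly simulate --scenario mixed_succession --seed 7 --out data/
crustassembly run --config run.yaml     # paths, angles, n_perm, n_null, seed
```

Each stage writes TSV/JSON under the output directory together with a
`manifest.json` recording every seed and threshold; a rerun from the same
manifest is byte-identical.

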