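# Methods

`crustassembly` quantifies how ecological processes assemble dryland
biocrust microbiomes sampled along succession (algae → lichen → moss
crusts) and geographic/climatic gradients (longitude, latitude, mean
annual precipitation). This note documents the models implemented, the
numerical choices made where the design was genuinely open, and what the
synthetic-data generator does and does not emulate.

## Community differences

**Bray–Curtis dissimilarity.** BC(x, y) = Σᵢ|xᵢ − yᵢ| / Σᵢ(xᵢ + yᵢ),
computed on the table as supplied; the pipeline default is per-sample
relative abundance. Pairs of all-zero samples are rejected rather than
imputed.

**NMDS.** Kruskal non-metric MDS minimising stress-1
√(Σ(d − d̂)² / Σd²), with disparities d̂ from isotonic (PAVA) regression
of configuration distances on the ranked dissimilarities and Guttman
transform updates. The first start is the principal-coordinate
configuration; remaining starts are seeded random configurations (default
4 starts). An update that would raise stress is rejected, so the stress
trajectory is non-increasing by construction; convergence is declared when
the improvement falls below `tol` (default 1e-6, max 300 iterations).
Reported coordinates are centred, rotated to principal axes, and
sign-fixed (largest-magnitude coordinate on each axis is positive) so
reruns agree exactly rather than up to reflection.

**ANOSIM.** R = (r̄_between − r̄_within) / (N(N−1)/4) on mid-ranked
dissimilarities. p is one-sided against label permutations with the
(1 + #{R_perm ≥ R_obs}) / (1 + n_perm) estimator, so p is never 0 and the
smallest attainable p at 999 permutations is 0.001. `n_perm=None`
enumerates all N! label permutations and returns the exact p — feasible
to N ≈ 8 and used by the oracle tests.

**Dispersion (betadisper-style).** Samples are embedded by principal
coordinates of the squared-distance Gower matrix. Negative eigenvalues
(semi-metric input) contribute "imaginary" axes whose squared distances
are subtracted from the real part (distances clipped at 0). The statistic
is the one-way ANOVA F of the distances to the group centroid; p permutes
the group labels of those distances (Levene-style residual permutation).
Note that vegan's betadisper permutes raw observations and recomputes
centroids; the residual scheme used here is simpler and asymptotically
equivalent, and is what the test-suite's independent re-implementation
checks.

**Mantel.** Spearman (default) correlation of the two condensed upper
triangles; permutations jointly permute rows and columns of the second
matrix; one-sided p as for ANOSIM, with the same exhaustive mode at small
n. Zero variance in either triangle is reported as undefined.

**Distance decay.** For every pair of regional-scale sites (sites
carrying all three successional stages) two ANOSIMs are run on the pooled
samples: grouping by site (geography series) and by stage (succession
series). The per-pair statistic is ANOSIM R² by default (R is a flag),
paired with the haversine distance between sites. Each series gets an OLS
fit; the intersection distance (b₂ − b₁)/(a₁ − a₂) is where the
succession effect and the geographic effect on community difference are
equal, and is undefined for parallel slopes.

## Null-model process partition

**βMNTD.** For samples x, y:
½ Σᵢ fᵢˣ · min_{j∈y} D(i, j) + ½ Σⱼ fⱼʸ · min_{i∈x} D(i, j), with f
relative abundances (presence/absence with uniform weights in the
unweighted variant) and D the patristic distance from the rooted tree.
A taxon shared by both samples contributes a nearest-taxon distance of 0.

**βNTI.** z-score of observed βMNTD against a null that shuffles taxon
labels across all tree tips, randomising phylogenetic relationships while
fixing abundances and richness. One shuffle per null replicate is shared
by all sample pairs (matrix-level null, the cheaper convention); βNTI is
computed in a canonical sorted-taxon order so results are invariant to
table column order under the same seed. Pairs whose null standard
deviation is below 1e-12 (e.g. any pair on a star phylogeny, or two
identical samples, where every shuffle is distance-preserving) are
flagged NaN and counted, never silently dropped and never an exception.

**Raup–Crick (Bray–Curtis).** For each pair, null assemblages preserve
each sample's observed richness S and individual count N: S taxa are
drawn without replacement with probability ∝ occupancy, each receives one
individual, and the remaining N − S individuals are assigned
multinomially with probability ∝ regional relative abundance among the
drawn taxa. RC = 2·((#null BC < obs) + ½·ties)/n_null − 1 ∈ [−1, 1].
Two null modes exist: `per_pair` (fresh assemblages per pair, the
textbook construction, default for two-sample use) and `shared` (one null
assemblage per sample per replicate reused across pairs — identical
per-pair marginals, much cheaper, default inside the grouped pipeline).

**Five-way classification.** Per pair: βNTI < −2 homogeneous selection;
βNTI > +2 heterogeneous selection; else RC > +0.95 dispersal limitation
(coupled with drift); RC < −0.95 homogenizing dispersal; otherwise drift
alone (the undominated residual). Thresholds (2, 0.95) are configuration,
not constants. "Species sorting" is the summed selection fractions.
Group-level tables classify only pairs whose two samples share the group
level; βNTI/RC are computed once over all samples for efficiency.

## Environment screening

Phylum-level tables sum OTU relative abundances per phylum
(unclassified OTUs pooled as "Unclassified") and drop phyla whose overall
mean relative abundance is ≤ 0.01% (configurable). The Mantel screen
correlates phylum-level Bray–Curtis distance with the absolute difference
of each variable z-scored within the group level (the single-variable
environmental distance; z-scoring makes units comparable). Missing values
drop the affected samples pairwise within that variable's Mantel only.
Constant variables yield undefined (NaN) cells.

The sorting–environment analysis computes the Spearman correlation
between the species-sorting percentage of each group level and the
level-mean (or median) of each variable, separately per domain, pooling
levels across study angles by default because three levels per angle give
no power; opposite bacterial vs eukaryotic correlation signs are listed
in an opposition report.

## Co-occurrence networks

Networks are built per group level on the 99%-cumulative-abundance OTU
set of each domain (pooled-abundance ranking; ties at the cutoff are all
retained). Candidate edges need |Spearman ρ| ≥ 0.7 across ≥5 samples
(mid-rank ties; zero-variance taxa dropped with a logged count). A
Bray–Curtis agreement filter then keeps a positive edge only when the
pair's profile similarity (1 − BC between the two taxa's
relative-abundance profiles) lies in the top 20% tail of all pairs, and a
negative edge only in the bottom tail. This two-measure agreement rule is
this package's deliberate simplification of multi-measure ensemble
inference: it preserves the two stated measures without reproducing an
unpublished ensemble; the tail fraction is configurable and the filter
can be disabled for Spearman-only networks.

Topology panel (sign-blind for paths and clustering, since a single value
per network is reported): |E|/|V|, % coexistence/exclusion edges, max
degree, mean local clustering (degree-<2 nodes contribute 0), connected
components, Freeman degree centralization Σ(deg_max − deg_i)/((|V|−1)(|V|−2))
(undefined below 3 nodes), density, degree heterogeneity sd(deg)/mean(deg)
(population sd), average degree, mean shortest-path length over connected
pairs only, and the domain share of nodes.

## Synthetic metacommunity generator

The generator is the source of ground truth for every downstream stage.
Sites sit on a 1-D axis mapped to longitude 87–120°E (85 km/degree); MAP
runs linearly from 30 to 440 mm along it. A pure-birth tree (depth
normalised to 1) carries niche optima evolved by Brownian motion; by
default an early-burst (ACDC) clock with rate 4 concentrates trait
variance on deep branches, giving clades tight in niche space — the
niche conservatism that phylogenetic turnover metrics assume. Site
optima follow the 10th–90th percentile quantiles of the realised trait
distribution, so every site has resident taxa near its optimum whatever
the Brownian draw; successional stages add ±(stage_offset × gradient
span) to the local optimum (severe A high, mild M low).

Sampling weights per taxon: lognormal regional pool ×
exp(−σ_sel(trait − E)²/2) × exp(−λ·d_km(home, site)), mixed with the pool
at migration rate m, then a multinomial draw of exactly J = 1000
individuals (four replicate samples per site, matching a four-replicate
field design). Drift is `drift_steps` rounds of multinomial resampling
with pool mixing. σ_sel is a selection *strength* (0 = neutral); λ is a
per-km decay; m ≈ 1 pins communities to the pool.

Named regimes (defaults chosen so one process dominates):
`selection` (σ_sel = 60), `dispersal_limitation` (λ = 0.01/km),
`homogenizing` (m = 1), `drift` (m = 0.1, 15 drift rounds), and
`mixed_succession` (σ_sel = 8, λ = 5·10⁻⁴, stage_offset = 0.3, all three
stages at every site) — the last reproduces the study-shaped pattern of
a significant succession ANOSIM together with rising-with-distance
geographic and falling-with-distance successional community differences.

What the generator does **not** emulate: sequencing noise and
compositional artefacts, uneven sampling depth, the real 28-variable
environment panel (only 5 synthetic variables, some pure noise), 2-D
geography, taxon-specific dispersal kernels, and latitude variation
(sites share one latitude, so the latitude angle is degenerate on
fixtures). Passing tests therefore demonstrate the statistical machinery
recovers known regimes under idealised sampling, not that real biocrust
data would behave as cleanly.

## Problem sizes and determinism

Tests and the acceptance script run reduced sizes chosen to keep the
suite quick while leaving the inference comfortably powered: regime
recovery uses 10 sites × 4 replicates (40 samples), 200 taxa and 199
nulls over 10 seeds per scenario; pipeline determinism uses the 60-sample
mixed fixture with 99 nulls. Null-model z-scores move by < 0.2 and RC by
< 0.05 when nulls are doubled (verified in the suite). All randomness
derives from one root seed via `numpy.random.SeedSequence` spawning;
pipeline outputs use a fixed float format (`%.10g`) so reruns are
byte-identical.

## Known limitations

* The Raup–Crick `shared` mode induces correlation between pairs sharing
  a sample within one null replicate; per-pair marginals are unchanged
  (the per-pair mode exists where independence matters).
* The dispersion test's residual permutation is not identical to
  recomputing centroids under permutation; F values agree, p-values can
  differ slightly in small samples.
* Drift and dispersal limitation are intrinsically hard to separate with
  RC alone: strong drift pushes RC toward +1 and is then classified as
  dispersal limitation, a property of the framework rather than a bug.
* Exhaustive permutation modes are factorial; they are guarded for the
  small instances the oracle tests use.
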