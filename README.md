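# streammeta

Tools for analysing **hierarchical stream metacommunities** — sets of
freshwater-invertebrate communities connected by dispersal across a dendritic
river network.  The central question the package addresses: at a given spatial
scale, is community composition governed by *environmental filtering* (species
sorting along local gradients), by *mass effects* (high dispersal overriding
local conditions), or by *dispersal limitation* (spatial structure unexplained
by the environment)?  It is aimed at community ecologists and biodiversity
analysts working with site-by-taxon abundance matrices sampled along streams,
but every estimator applies to any spatially structured multivariate
abundance data (e.g. microbiome beta-diversity surveys).

## What it computes

**Dispersal-route distances.** Three site-by-site distance matrices describe
alternative dispersal pathways on a stream network: geographic (GEO,
straight-line, km), topographic (TOP, 3-D overland distance across the
elevation surface), and watercourse (WAT, shortest path along channels).
Site pairs in separate drainages have no watercourse route (missing, never
infinite).

**Metacommunity connectivity.** For focal site *i*,

    Con_i = 1/(n-1) * Σ_{j≠i} ( Σ_{k ∈ pool(i,j)} p_jk / m_ij ) · exp(−d_ij)

where pool(*i*, *j*) is the union of taxa present at the two sites, *m_ij* its
size, and *p_jk* the presence of taxon *k* at site *j*; `Avg.Con` is the mean
over sites.  Connectivity decays with every pairwise distance and is bounded
in [0, 1].

**Variation partitioning.** Hellinger-transformed abundances are regressed
(redundancy analysis) on selected environmental variables E and positive
Moran's eigenvector maps S, yielding adjusted fractions [E|S], [S|E], [E∩S]
and residual; Δ = [E|S] − [S|E] summarises environmental versus spatial
control.  Two adjustments are available: classical (Ezekiel) and **Moran
spectral randomization (MSR)**, whose surrogate-based null removes the
spurious [E∩S] that arises when environment and community are independently
spatially autocorrelated.  Partitions are compared across datasets after
standardizing the taxon pool (random subsets of S = 20 taxa, 500 replicates).

**Distance decay (MLPE).** Bray–Curtis dissimilarity is regressed on each
route distance with the maximum-likelihood-population-effects covariance
(pairs sharing a site are correlated, ρ ∈ [0, 0.5)), and the fixed-effect
size is reported as Rβ² = qF / (qF + ν).

**Community structure.** PERMDISP (homogeneity of multivariate dispersions,
with negative-eigenvalue-corrected principal coordinates) and additive
diversity partitioning (γ = mean α + β) with a fixed-row/fixed-column
(Patefield) null model and standardized effect sizes.

**Synthetic metacommunities.** A first-class generator builds the three
hierarchical sampling designs (18 sites within one stream; 18 streams; four
sub-basins of 7/5/4/2 streams) with dendritic networks, elevation surfaces,
spatially autocorrelated environments, and communities assembled under
species sorting, mass effects, or dispersal limitation with Gaussian niche
responses and distance-kernel dispersal.

## Worked example

```python
import streammeta as sm

sites, network, surface = sm.generate_design(sm.DesignConfig(seed=1))
triplet = sm.design_distances(sites, network, surface)
env = sm.generate_environment(sites, autocorr_range=10.0, seed=2)
community = sm.generate_community(
    sites, env, triplet, sm.ScenarioConfig(regime="species_sorting", seed=3))

basis = sm.compute_mem(sm.build_swm(triplet["GEO"], "gabriel", "binary"))
M = basis.positive.iloc[:, :4]                                   # 4 broadest MEMs
E = sm.log1p_env(env - env.min().min()).iloc[:, :4]              # 4 env variables
for adjustment in ("classical", "msr"):
    res = sm.varpart(sm.hellinger(community), E, M, adjustment,
                     basis=basis, n_surrogates=199, seed=4)
    f = res.fractions()
    print(f"{adjustment:>9}:  [E|S]={f['E|S']:.3f}  [S|E]={f['S|E']:.3f}  "
          f"[E^S]={f['EintS']:.3f}  resid={f['residual']:.3f}  delta={f['delta']:.3f}")
```

prints

```
classical:  [E|S]=0.454  [S|E]=-0.014  [E^S]=0.184  resid=0.375  delta=0.468
      msr:  [E|S]=0.491  [S|E]=0.058  [E^S]=0.113  resid=0.338  delta=0.433
```

The community was assembled by species sorting, so the unique environmental
fraction dominates and Δ > 0 under both adjustments; the MSR adjustment
shrinks the spatially structured environmental overlap [E∩S] that the
classical analysis inflates.  The `examples/` directory holds one short
script per capability (distances, connectivity, partitioning, distance
decay, dispersion/diversity) with printed, annotated output, and the
`streammeta` command exposes the same steps as thin subcommands
(`simulate`, `distances`, `connectivity`, `basis`, `varpart`, `decay`,
`dispersion`, `diversity`, `run`, `validate`).

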