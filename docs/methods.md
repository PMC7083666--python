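# Methods

This note records the models, numerical choices and open design decisions
behind `streammeta`, in the spirit of a statistical appendix.  Nothing here
states an empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## Distances on dendritic networks

Coordinates are planar kilometres; users project before input.  At the
extents involved (≲ 500 km) planar error is small, and keeping geodesy out
keeps the package self-contained.

* **Geographic (GEO)** — Euclidean distance between site coordinates.
* **Topographic (TOP)** — the elevation surface (analytic function or
  bilinear raster) is sampled along the straight horizontal segment between
  the two sites at spacing ≤ `step` (default 0.01 km; the generated-design
  helper uses 0.05 km) and 3-D polyline lengths are summed.  This is a
  straight-path surface length, not a least-cost path: routing around
  barriers is out of scope, and the straight-path reading keeps TOP a
  deterministic function of the surface.  TOP ≥ GEO by construction; halving
  `step` moves entries by < 0.5 % on smooth surfaces (tested).
* **Watercourse (WAT)** — Dijkstra shortest paths over the channel graph,
  edge lengths in km, each edge at least the straight-line distance between
  its endpoints.  Pairs in different drainage basins are *missing* (NaN),
  never infinite: downstream analyses either drop those pairs (distance
  decay, with a logged count) or reject (connectivity), making the
  incompleteness explicit.  Sites snap to their nearest network node within
  a tolerance (default 0.1 km); farther sites are rejected by name.

Distance summaries use unordered off-diagonal pairs and the sample standard
deviation (n−1); a single pair reports sd 0.

## Connectivity index

`Con_i` averages, over the n−1 surrounding sites, the distance-discounted
fraction of the site-pair taxon pool present at the surrounding site (see
README for the formula).  Distances enter `exp(−d)` in raw km — no
rescaling — so values are tiny at large extents; that is informative, not a
defect.  Two normalization readings exist for the 1/m factor: per site pair
(m_ij inside the sum; every pair term bounded by 1, consistent with m being
defined per pair) and a single pool per focal site (the literal
outside-the-sum placement).  Per-pair is the default; `m_placement=
"per_focal"` switches for sensitivity analysis.  Empty pools contribute 0
(avoiding 0/0), and abundances are binarized before use.

## Spatial basis

Candidate spatial weighting matrices combine a connectivity graph (Gabriel,
relative neighbourhood, minimum spanning tree, distance bands at the 0.2 /
0.35 / 0.5 distance quantiles) with binary or linear-decay weights — a
standard, fully configurable grid.  MEMs are computed by eigendecomposing
the doubly-centered weight matrix inside an orthonormal basis of the
orthocomplement of the constant vector, which removes the null constant
direction exactly rather than by an eigenvalue tolerance.  Eigenvector signs
follow a first-nonzero-positive convention; Moran's I per vector uses the
identity I_k = (n / ΣW) λ_k.  Data-driven SWM choice scores each candidate
by the corrected AIC of the community on its forward-selected positive MEMs
(parameters = selected + 1); candidates failing the global test are
unscored, ties break by candidate order.

**Forward selection** applies a double stopping rule: a global permutation
test on the full predictor block gates the procedure (rows of Y permuted, p
= (b+1)/(m+1)), then columns enter greedily by added R², each admitted only
if its partial permutation test (residuals of the current model permuted) is
significant.  The adjusted-R² ceiling is checked *before* each admission
round: selection stops once the model under construction has reached the
global adjusted R².  Checking after admission — the more literal reading of
the rule — rejects the final true predictor on a coin flip, because
Ezekiel's adjustment is unbiased and a model already containing every real
predictor sits at the global adjusted R² in expectation; the before-round
check preserves the overfitting protection (the model never runs past the
global fit by more than one admitted variable) and makes recovery of a true
predictor set deterministic under strong signal.  Ties in added R² (within
1e-12) break by column index; constant columns are dropped.

**MSR surrogates** use the sign-flip scheme: each variable is written in the
full (n−1)-vector MEM basis, coefficient signs are flipped independently per
eigenvector, and the *same* sign vector is applied to every column, so
cross-correlations between variables are preserved and the squared Moran
spectrum — hence Moran's I — is preserved exactly.  Surrogates are rescaled
to the original column means and variances (an identity up to roundoff).
Rotation-based schemes are out of scope.

## Variation partitioning

Abundances are Hellinger transformed (zero-total sites rejected by name);
environmental variables are log(X+1) transformed and then z-standardized —
standardization cannot change the R² of a full block but makes forward
selection and AIC comparisons scale-free.  R² is the redundancy-analysis
trace ratio, computed by least squares on column-centered blocks; Ezekiel's
adjustment uses the *rank* of the predictor block as p, so duplicated or
collinear columns do not distort the correction.

Under the **MSR adjustment**, the environment-only model is adjusted by the
ratio formula 1 − (1−R²)/(1−mean(null R²)) with surrogate-E nulls; the joint
model is evaluated with surrogate E and the spatial block held fixed, and —
because the surrogates keep E's spatial structure while breaking its
alignment with the community — everything the real E adds beyond that null
*is* the unique environmental fraction [E|S].  The spatial-only model keeps
Ezekiel's correction (it contains no environmental block to randomize), the
joint total is [S] + [E|S], and the remaining fractions follow by
subtraction, so the identity [E|S] + [S|E] + [E∩S] + residual = 1 holds
algebraically under both adjustments.  Negative adjusted fractions are
reported as computed (clipping is a display option) precisely to preserve
that identity.

Taxon-count standardization draws S = 20 taxa without replacement (500
replicates by default), re-Hellingers each subset and repeats the partition;
a replicate that empties some site's row is discarded and redrawn with a
logged count — the degenerate case is not otherwise defined.  Replicate
summaries use the median, quartiles and Tukey fences (1.5 × IQR).
Dispersal-trait analyses subset taxa by their family's {low, high} class per
trait; taxa of unlisted families are dropped and counted.

## MLPE distance decay

For N site pairs the error correlation is C(ρ) = (1−2ρ)I + ρZZᵀ, with Z the
pairs-by-sites incidence matrix; ρ ∈ [0, 0.5) guarantees positive
definiteness and is parameterized through a scaled logistic transform.
Because ZZᵀ is fixed, one eigendecomposition turns every likelihood
evaluation into O(N) work, and the ML fit is a 1-D bounded optimization over
ρ (three fixed starts, seedable jitter on restart).  Slopes are per raw km —
no distance standardization — with the intercept absorbing any offset.

The fixed-effect F is the Wald statistic of the slope; a numerically perfect
flat fit (residual variance at roundoff level) reports F = 0.  The
denominator degrees of freedom ν use a Satterthwaite-style approximation —
ν = 2c²/Var(c) with c the slope's sampling variance as a function of
(σ², ρ), Var(c) from the numerical delta method against the observed
information — rather than the full Kenward–Roger machinery, which would add
covariance-adjustment terms of little consequence for a single-predictor
model; the output records `df_method`.  Rβ² = qF/(qF+ν).  Route comparisons
fit one model per route on that route's complete pairs and report missing
pair counts.

## PERMDISP and diversity partitioning

PERMDISP embeds the dissimilarity matrix by principal coordinates keeping
negative-eigenvalue axes, computes each site's distance to its group
centroid as sqrt(max(0, d²_real − d²_imag)), and compares groups by the
one-way ANOVA F.  Significance comes from permuting group labels with group
sizes fixed and *recomputing centroids* each time — the simplest
exchangeable-unit scheme — rather than permuting residual distances.
Centroids are group means in the embedding (the classical formulation; the
spatial-median variant is excluded).  A preset runs the test on Euclidean
distances of z-standardized environmental variables, the environmental-
heterogeneity use case.  Defaults: 1000 permutations for PERMDISP, 999 nulls
for diversity — both study-protocol constants, kept as separate defaults.

Diversity partitioning is richness-based: α_i is site richness, γ the pooled
richness, β = γ − mean(α); the abundance-weighted variant is deliberately
excluded.  Null communities fix both margins via Patefield's algorithm
(`scipy.stats.random_table`); *every* draw is assert-checked for exact
margin preservation.  Single-row or single-column matrices are fully
determined by their margins and are returned unchanged (the scipy sampler
misbehaves on that degenerate case).  SES = (obs − null mean)/null sd with a
two-sided rank p; because the margins fix γ, SES(α) = −SES(β) exactly, and a
zero null sd reports SES as undefined rather than infinite.

## Synthetic metacommunities

The generator's role is to produce data with the statistical structure the
estimators assume, under the three hierarchical designs, so that the whole
chain can be exercised and its qualitative behaviour verified — it makes no
claim to demographic realism.

*Designs.* Sites are spread with a minimum-separation rule and joined by the
Euclidean minimum spanning tree; channel lengths are Euclidean lengths times
a tortuosity factor (1.1–1.4 within a stream, 1.3–1.9 at the larger scales),
and node elevations grow upstream from the outlet at a random slope, so
elevation decreases downstream along every edge.  Default extents (15 / 60 /
250 km) and base elevations (2.2 / 0.05 / 0.1 km) follow the magnitudes of
the three study scales (within-stream pairwise distances of a few km, tens
of km among streams, a couple of hundred km among sub-basins).  The
among-sub-basin design can keep its four drainages disconnected
(`connect_subbasins=False`), making cross-basin watercourse distances
missing.  The overland elevation surface is an independent smooth random
field (tilted plane plus Gaussian hills) over the design's bounding box.

*Environment.* Each variable is a weighted sum of the positive MEMs of a
Gabriel-graph SWM on the sites plus white noise, z-scored; the eigenvector-
rank decay and the structured-variance share both grow with the
autocorrelation range, so range → 0 yields spatially unstructured noise
(Moran's I at its permutation expectation −1/(n−1)) and a range comparable
to the extent concentrates variance on the broadest eigenvector.  Building
fields from the same MEM machinery the analysis uses keeps the package
dependency-free and self-consistent; it also means environment fields are
*exactly* representable in the spatial basis — real covariates are not, so
passing tests bound behaviour under favourable, not adversarial, spatial
confounding.

*Communities.* Expected abundance under species sorting is a Gaussian niche
response on the two leading environmental axes (σ = 1 per axis, maximum
expectation M = 50 at the optimum; limiting the niche to two axes keeps
expected abundances at realistic magnitudes — a 10-axis product would
collapse them).  Mass effects redistribute the sorting expectation through a
row-normalized kernel exp(−d/λ) with λ defaulting to twice the extent
(homogenizing); dispersal limitation multiplies a flattened niche response
(σ inflated fivefold) by per-taxon occupancy clusters spread from a random
seed site with occupancy probability exp(−d/λ), λ defaulting to a sixth of
the extent.  A small uniform "vagrant" expectation (0.5 % of M per taxon)
keeps site totals positive and puts local richness in the tens —
the order of magnitude of real surveys at these scales — without adding
compositional signal.  Counts are negative-binomial by default (k = 5;
ecological counts are overdispersed), Poisson for clean tests, or the
round-half-to-even expectation for deterministic examples.  All-zero taxon
columns are dropped after sampling.  These regime parameters encode the
qualitative contrast between the three assembly hypotheses, not any
measured rates: downstream recovery (Δ > 0 under sorting, Δ < 0 under
limitation, depressed beta-SES under mass effects) is a check of estimator
behaviour under its assumed data-generating structure, not a statement
about field data.

*What the generator does not emulate:* temporal dynamics, speciation,
larval-drift versus adult-flight mechanics, sampling effort differences
among sites, taxonomic misassignment, and genuinely non-Gaussian niche
shapes.  Conclusions about real stream data require the real data.

## Pipeline

`run_pipeline` derives one seed per stage from the master seed through
`SeedSequence.spawn`, so a configuration is reproducible end-to-end and
changing the master seed changes draws but never the report schema.  Stages
fail independently: an error is recorded in the report and unrelated stages
still run.  Defaults mirror the study protocol (retain the first four
forward-selected environmental variables and positive MEMs; S = 20, 500
standardization replicates; 999 permutations and surrogates; 1000 PERMDISP
permutations).  When fewer than the retained number of variables pass
forward selection, all that pass are used and the count is logged; if none
passes, the first four columns are used with a warning, keeping the
partition comparable across runs.  The command-line interface is a thin
wrapper over these library calls; the problem sizes in
`scripts/acceptance.py` (18 sites per design, 100 standardization
replicates, 199 surrogates, 999 diversity nulls) were chosen as the
smallest at which the reported quantities are stable to the precision
shown.

## Known limitations

* Topographic distance ignores barrier-avoiding detours (straight-path
  reading); on terrain where real dispersal routes wind around relief it
  underestimates the effective overland distance.
* The MSR adjustment debiases fractions but its significance testing is
  limited: a surrogate-based test for [E|S] exists implicitly through the
  null distribution, yet is not exposed as a formal p-value (flagged
  experimental territory).
* Satterthwaite ν differs from Kenward–Roger's in small samples; Rβ² values
  are comparable across routes within a fit but not guaranteed to match
  mixed-model software df-for-df.
* Negative MEMs are computed but not used as predictors (positive-
  autocorrelation modeling only); flow-directed asymmetric weighting (AEM)
  is a plausible extension, not implemented.
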