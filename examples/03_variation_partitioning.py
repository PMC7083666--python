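"""Classical versus spatially-debiased (MSR) variation partitioning.

Hellinger-transformed abundances are partitioned between four selected
environmental variables (E) and four positive Moran eigenvectors (S).
delta = [E|S] - [S|E] summarizes whether environmental filtering (delta >
0) or spatial processes (delta < 0) dominate.  The partition is repeated
on random 20-taxon subsets so different communities are compared at the
same taxon-pool size.  Moran spectral randomization (MSR) replaces
Ezekiel's correction with a null built from surrogates that keep E's
spatial autocorrelation but break its link to the community — removing
the spurious environment-space overlap that classical partitioning books
under [E ^ S].
"""

import streammeta as sm

sites, network, surface = sm.generate_design(sm.DesignConfig(seed=1))
triplet = sm.design_distances(sites, network, surface)
env = sm.generate_environment(sites, autocorr_range=10.0, seed=2)
community = sm.generate_community(
    sites, env, triplet, sm.ScenarioConfig(regime="species_sorting", seed=3))

basis = sm.compute_mem(sm.build_swm(triplet["GEO"], "gabriel", "binary"))
M = basis.positive.iloc[:, :4]
E = sm.log1p_env(env - env.min().min()).iloc[:, :4]

for adjustment in ("classical", "msr"):
    res = sm.varpart(sm.hellinger(community), E, M, adjustment,
                     basis=basis, n_surrogates=199, seed=4)
    f = res.fractions()
    print(f"{adjustment:>9}:  [E|S]={f['E|S']:.3f}  [S|E]={f['S|E']:.3f}  "
          f"[E^S]={f['EintS']:.3f}  resid={f['residual']:.3f}  delta={f['delta']:.3f}")
    std = sm.standardized_varpart(
        community, E, M, sm.StandardizationConfig(S=20, n_reps=100, seed=5),
        adjustment, basis=basis, n_surrogates=199)
    print(f"           20-taxon standardized delta: median={std.median_delta:.3f}, "
          f"IQR=({std.iqr[0]:.3f}, {std.iqr[1]:.3f})")

print(
    "\nThis community was assembled by species sorting, so [E|S] dominates and"
    "\ndelta > 0 under both adjustments; the four fractions sum to 1 exactly."
)
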