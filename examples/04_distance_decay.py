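"""Distance decay of community similarity with MLPE mixed models.

Bray-Curtis dissimilarity between site pairs is regressed on each route
distance.  Pairs sharing a site are correlated, which the
maximum-likelihood-population-effects (MLPE) covariance handles through a
shared-site correlation rho.  The effect size Rbeta^2 = qF/(qF + nu)
measures how much of the dissimilarity the distance term explains; the
route with the highest Rbeta^2 is the best-supported dispersal pathway.
"""

import streammeta as sm

sites, network, surface = sm.generate_design(sm.DesignConfig(design="among_subbasin", seed=1))
triplet = sm.design_distances(sites, network, surface)
env = sm.generate_environment(sites, autocorr_range=30.0, seed=2)
community = sm.generate_community(
    sites, env, triplet,
    sm.ScenarioConfig(regime="dispersal_limitation", route="GEO", seed=3))

D = sm.bray_curtis(community)
table = sm.compare_routes(D, triplet, seed=4)
print(table[["beta1", "rho", "F", "nu", "r2_beta", "rank"]].round(4))

print(
    "\nAll three routes explain dissimilarity well because they are mutually"
    "\ncorrelated on one drainage network; the per-km decay beta1 is steepest"
    "\nfor GEO/TOP since watercourse paths cover more km between the same"
    "\nsites.  Decoupling a route from the generating kernel (e.g. shuffling"
    "\nits matrix) collapses its Rbeta^2."
)
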