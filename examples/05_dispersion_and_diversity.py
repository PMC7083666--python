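"""Environmental heterogeneity (PERMDISP) and diversity-partition SES.

PERMDISP compares the spread of groups of sites around their centroids in
multivariate environmental space; a significant F means the groups differ
in heterogeneity, not merely in mean conditions.  Additive diversity
partitioning splits gamma richness into mean within-site alpha and
among-site beta; the standardized effect size (SES) judges the observed
beta against null communities with both site and taxon totals fixed
(Patefield's algorithm) — a large positive SES marks compositional
aggregation beyond what the abundance margins impose, the signature of
dispersal limitation.
"""

import pandas as pd

import streammeta as sm

sites, network, surface = sm.generate_design(sm.DesignConfig(design="among_subbasin", seed=1))
triplet = sm.design_distances(sites, network, surface)
env = sm.generate_environment(sites, autocorr_range=30.0, seed=2)

disp = sm.env_heterogeneity(env, sites["subbasin_id"], n_perm=999, seed=4)
print("PERMDISP on environmental variables by sub-basin:")
print(disp.group_means.round(3))
print(f"F = {disp.F:.3f}, permutation p = {disp.p:.3f}\n")

rows = []
for regime in ("species_sorting", "mass_effects", "dispersal_limitation"):
    community = sm.generate_community(
        sites, env, triplet, sm.ScenarioConfig(regime=regime, seed=5))
    part = sm.diversity_ses(community, n_null=999, seed=6)
    rows.append({"regime": regime, "gamma": part.gamma, "mean_alpha": round(part.alpha, 1),
                 "beta": round(part.beta, 1), "SES_beta": round(part.ses_beta, 1),
                 "p": part.p})
print(pd.DataFrame(rows).to_string(index=False))

print(
    "\nBeta diversity and its SES are largest under dispersal limitation"
    "\n(taxa clumped in space) and smallest under mass effects (dispersal"
    "\nhomogenizes composition)."
)
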