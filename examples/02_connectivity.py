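"""Metacommunity connectivity under the three dispersal routes.

Connectivity of a site is the distance-discounted share of each site
pair's taxon pool found at the surrounding sites, exp(-d) weighting near
neighbours most.  Averaging over sites gives Avg.Con for the whole
metacommunity.  Because exp(-d) decays with distance, the same community
is less connected through longer routes (watercourse) than through the
straight-line route, and large-extent designs are less connected than
small ones.
"""

import streammeta as sm

for design in ("within_stream", "among_subbasin"):
    sites, network, surface = sm.generate_design(sm.DesignConfig(design=design, seed=1))
    triplet = sm.design_distances(sites, network, surface)
    env = sm.generate_environment(sites, autocorr_range=10.0, seed=2)
    community = sm.generate_community(
        sites, env, triplet, sm.ScenarioConfig(regime="species_sorting", seed=3))
    print(f"\n{design}:")
    for route, dmat in triplet.items():
        res = sm.average_connectivity(community, dmat, route=route)
        print(f"  Avg.Con via {route}: {res.avg_con:.3e}")

print(
    "\nAvg.Con is highest for the geographic route (shortest distances) and"
    "\ncollapses at the among-sub-basin scale, where sites are far apart on"
    "\nevery route."
)
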