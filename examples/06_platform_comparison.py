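"""Compare semibulk against spatial-spot compositions by joint clustering.

Both platforms sample the same three composition niches (null case), then
the spot platform loses access to the third niche (private case).  The
mixing fraction — semibulk units sharing a cluster with at least one spot —
distinguishes the two situations.
"""

import semibulk as sb
from semibulk.synthetic import simulate_archetype_compositions

types = ["podocyte", "proximal", "distal", "immune"]
niches = [[20, 1, 1, 1], [1, 20, 1, 1], [1, 1, 20, 1]]

sb_comp = simulate_archetype_compositions(types, 300, niches, seed=1)

for label, spot_niches in [("shared niches", niches), ("private niche", niches[:2])]:
    st_comp = simulate_archetype_compositions(types, 300, spot_niches, seed=2)
    pooled = sb.combine_platforms(sb_comp, st_comp)
    clustering = sb.joint_cluster(pooled, k=3, metric="euclidean", linkage_method="complete")
    mix = sb.mixing_fraction(clustering, pooled.platform)
    print(f"{label}: mixing fraction = {mix:.2f}")
    print(sb.cluster_membership_table(clustering, pooled.platform).to_string())
# When spots never sample the third niche its cluster is semibulk-only and
# the mixing fraction drops by roughly that niche's prevalence.
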