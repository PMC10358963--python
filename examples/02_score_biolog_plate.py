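"""Score a Biolog plate: standardized growth, resource use, niche width.

Standardized growth is each well's OD590 minus the isolate's water
control; values below 0.005 (the reader's photometric accuracy) count as
no growth. Niche width is the number of resources used.
"""
from endotraits import (
    CommunitySpec, build_trait_table, simulate_community, use_frequency,
)

com = simulate_community(CommunitySpec(seed=1))
traits = build_trait_table(com.plate)  # threshold 0.005, common fraction 0.5

print(f"common resources (used by >= 50% of isolates): "
      f"{len(traits.common)} of {len(com.plate.resources)}")
print(traits.summary.head().round(3))
freq = use_frequency(traits.use)
print("\nmost and least used resources (percent of isolates):")
print(freq.sort_values("percent_all").iloc[[0, -1]].round(1))
print("\nmean_sg_common feeds the slow/fast classification; mean_sg_all "
      "and growth_efficiency are sensitivity variants of the same mean.")
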