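"""Screen baseline variables as mediator-outcome confounders.

Each candidate is tested univariably against each mediator and the
outcome; anything with p < 0.10 on any test is retained.  The pooled
confounder set is the union of the two sites' selections plus the site
indicator.
"""

import intermed as im
from intermed.data import CONFOUNDER_CANDIDATES
from intermed.screening import pooled_union, screen_site, screening_frame, selected_variables

cc = im.complete_case_filter(im.from_frame(im.generate_trial(im.default_config(seed=7), seed=7)))

results = {}
for site in ("lima", "saopaulo"):
    results[site] = screen_site(cc.subset(site), list(CONFOUNDER_CANDIDATES))
    print(f"\n{site}: selected {selected_variables(results[site])}")
    print(screening_frame(results[site]).head(8).to_string(index=False))

print("\npooled set (union + site):", pooled_union(results["lima"], results["saopaulo"]))
print("these variables enter every mediator and outcome model downstream")
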