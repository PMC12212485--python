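"""Decompose the intervention effect into direct, indirect and dependence
components.

The estimator fits mediator models (marginal and sequential-joint) and a
logistic outcome model with mediator interactions, then computes
counterfactual outcome means by Monte Carlo integration on a K-fold
expanded dataset.  Shared uniform draws make the six components sum to the
total effect exactly.
"""

import numpy as np

import intermed as im
from intermed.data import CONFOUNDER_CANDIDATES

cc = im.complete_case_filter(im.from_frame(im.generate_trial(im.default_config(seed=7), seed=7)))
confs = list(CONFOUNDER_CANDIDATES) + ["site"]

models = im.fit_mediator_models(cc, confs)
outcome = im.fit_outcome_model(cc, confs)  # default mediator interactions
dec = im.decompose_effects(cc, models, outcome, k_copies=1000,
                           rng=np.random.default_rng(7))

print("interventional decomposition (probability-difference scale):")
for name, value in dec.components().items():
    print(f"  {name:7} {value:+.4f}")
gap = dec.additivity_gap()
print(f"additivity gap |DE+IE1+IE2+IE3+DEP-TE| = {gap:.2e} (exact by construction)")
print("each IE is the outcome change from switching that mediator's draw")
print("distribution from its control-arm to its intervention-arm law")
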