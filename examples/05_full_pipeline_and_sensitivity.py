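"""Run the full per-site/pooled pipeline and the recovery-outcome
sensitivity analysis.

``run_pipeline`` chains loading, complete-case filtering, confounder
screening, model fits, the decomposition and the bootstrap, and reports
moderated-mediation tests (does baseline medication, or study site,
modify the effect of behavioural activation on the outcome?).
``sensitivity_run`` repeats everything with recovery (six-month PHQ-9 < 10)
as the outcome and tabulates both side by side.
"""

import warnings

import intermed as im

cfg = im.PipelineConfig(
    seed=7,
    sites=("pooled",),
    k_copies=500,
    k_copies_bootstrap=50,
    resamples=300,
)
with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    out = im.sensitivity_run(cfg)

print(out["improved50"].summary_text())
print("sensitivity comparison (primary vs recovery outcome):")
print(out["comparison"].round(3).to_string(index=False))
print("\nbroadly similar components under both outcome definitions indicate")
print("the mediation conclusions are not artifacts of the outcome coding")
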