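"""A small Monte Carlo study of unanchored MAIC under an effect modifier.

Runs 20 seeded repetitions of the full pipeline for scenario 2 (menopausal
status both prognostic and effect-modifying), aggregates bias / MCV / MSE /
CI coverage per weighting strategy, and applies the omitted-confounder
bias-factor adjustment to the strategy that omitted the effect modifier.
At this size the numbers carry Monte-Carlo noise of roughly +/-0.013 on the
bias; the shipped study scale is 200+ repetitions.
"""

import umaic
from umaic.evaluation import render_text, report_tables

result = umaic.run_study(umaic.default_scenario(2), n_reps=20, master_seed=7)
print(render_text(report_tables(result)))

bf = result.bias_factor_adjustment()
print(
    f"Dividing the omit-effect-modifier estimates by the bias factor "
    f"{bf.bias_factor:.4f}\nshrinks their mean log-scale bias to "
    f"{bf.mean_adjusted_log_bias:+.4f}; the adjusted CI lower limit lies at or\n"
    f"below the true HR in {bf.pct_ll_below_truth:.0f}% of repetitions."
)
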