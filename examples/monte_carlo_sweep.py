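"""Run a small Monte Carlo sweep over the model slope gamma.

For each gamma, 3000-iteration production runs would be used; here 200
iterations per cell keep the example quick.  The headline number per cell is
the fraction of iterations in which the ground-truth-derived model had a
significantly higher AUC than the alternative-derived model (paired
bootstrap, 100 draws, alpha = 5 %).
"""

import ntcpsim as ns

spec = ns.SyntheticCohortSpec(n=605, rank_correlation=0.9, seed=7)
cohort = ns.normalize_cohort(ns.generate_cohort(spec))

config = ns.SimulationConfig(
    gamma_grid=(0.25, 0.75, 1.5),
    n_iterations=200,
    n_boot=100,
    master_seed=11,
)
summary, _ = ns.run_sweep({"MHD": cohort}, config, collect_iterations=False)

cols = ["gamma", "frac_significant_gt_better", "mean_auc_diff", "mean_event_pct"]
print(summary[cols].to_string(index=False, float_format=lambda x: f"{x:.3f}"))

# Reading the table: steeper predefined curves (larger gamma) make the same
# contour differences easier to detect — the significant fraction and the
# mean AUC difference both grow — while the event rate drifts below 50 %
# because the steep logistic is no longer linear over the skewed dose range.
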