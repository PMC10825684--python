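# ntcpsim

Monte Carlo estimation of how differences between two contour sets of the
same organ at risk translate into performance differences between the
normal tissue complication probability (NTCP) models derived from them.

## Who this is for

Radiotherapy researchers who develop toxicity models from retrospective
dose data and need to know whether their (often automatically generated)
organ contours are accurate enough: given a ground-truth and an alternative
contour set — or any two paired dose-parameter vectors — `ntcpsim` answers
*"how often would the model built on the alternative contours be
significantly worse?"*

## The method

One contour set is designated the ground truth. Outcomes are simulated from
a predefined logistic NTCP model applied to the ground-truth dosimetric
parameter (mean organ dose or VxGy), mean-normalized so that
`mean(D_gt) = 1`:

    NTCP(D) = 1 / (1 + exp(s (D50 − D))),    s = 4γ / D50,

with `D50 = 1` and γ the normalized slope at the midpoint. Per Monte Carlo
iteration, one Bernoulli outcome per patient is drawn from these
probabilities, one NTCP model is fitted by maximum likelihood to
`(D_gt, y)` and one to `(D_alt, y)`, and their AUCs are compared with a
paired bootstrap (100 draws): a model is significantly better in that
iteration if its AUC is higher in over 95 % of draws. Aggregated over 3000
iterations and swept over γ, dosimetric parameter and cohort size, this
yields the fraction of cohorts in which the contour differences would have
produced a significantly worse model. Geometric agreement (Dice, surface
Dice at a mm tolerance) and the DVH parameters feeding the simulation are
computed from voxel masks and an aligned dose grid. See
`docs/methods.md` for the full account.

## Worked example

```python
import ntcpsim as ns

# synthetic stand-in for a 605-patient cohort: right-skewed dose parameter,
# alternative contours with Spearman rank correlation 0.9 to the ground truth
spec = ns.SyntheticCohortSpec(n=605, rank_correlation=0.9, seed=7)
cohort = ns.normalize_cohort(ns.generate_cohort(spec))

config = ns.SimulationConfig(gamma_grid=(0.25, 0.75, 1.5),
                             n_iterations=200, n_boot=100, master_seed=11)
summary, _ = ns.run_sweep({"MHD": cohort}, config, collect_iterations=False)
print(summary[["gamma", "frac_significant_gt_better",
               "mean_auc_diff", "mean_event_pct"]])
```

prints

```
 gamma  frac_significant_gt_better  mean_auc_diff  mean_event_pct
 0.250                       0.360          0.014          49.367
 0.750                       0.955          0.032          45.626
 1.500                       1.000          0.047          41.715
```

Reading the table: with a shallow dose-response (γ = 0.25) the noise of
dichotomizing probabilities dominates and only 36 % of simulated cohorts
detect the contour differences; at γ = 1.5 essentially every cohort does,
with a mean AUC gap of 4.7 points. The event rate sits near 50 % for
shallow curves (the logistic is locally linear around `D50 = 1`) and drifts
down as the curve steepens over the right-skewed dose distribution.

The same sweep is available from the shell:

```bash
ntcpsim generate-cohort --n 605 --rank-correlation 0.9 --seed 7 --out MHD.csv
ntcpsim run --cohort MHD.csv --config config.yaml --out results/
ntcpsim metrics --mask-a manual.nrrd --mask-b auto.nrrd --dose dose.nrrd
```

The `examples/` directory contains one short script per capability
(model evaluation and slope conversions, single-cohort fitting, the Monte
Carlo sweep, contour metrics on an analytic phantom).

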