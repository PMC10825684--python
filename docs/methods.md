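# Methods

## The question the framework answers

Toxicity (NTCP) models for radiotherapy are increasingly built from
dosimetric parameters computed on automatically generated organ contours.
Two contour sets of the same organ — say, manual and deep-learning heart
contours — yield two slightly different dose-parameter vectors for the same
cohort, and hence two slightly different fitted models. `ntcpsim` estimates
how often, and by how much, the model built on one contour set outperforms
the model built on the other, when the first set is *designated* as the
ground truth that generates the outcomes.

Because the outcome is, by construction, fully determined by the
ground-truth dose parameter and the chosen NTCP shape, the ground-truth
model is the performance upper bound on that dataset. Any performance gap
is attributable only to the contour differences plus the irreducible noise
of dichotomizing probabilities into binary labels. The estimate is
therefore deliberately optimistic (an upper bound on the impact of contour
differences).

## Model

The dose-response is a logistic function of a scalar dosimetric parameter
`D` (mean organ dose, or a VxGy volume percentage):

    NTCP(D) = 1 / (1 + exp(s (D50 − D))),   s = 4γ / D50,

where `γ = D50 · dNTCP/dD |_{D50}` is the normalized slope at the midpoint.
Before simulation the ground-truth vector is divided by its own mean and
the *same* factor is applied to the alternative vector, so `mean(D_gt) = 1`
and the predefined model uses `D50 = 1` on that scale. Normalization is a
pure rescaling: it changes no ranks and no correlations, and it is applied
once to the full cohort (per-iteration subsample means may drift from 1 —
intended, since it mirrors a single cohort-level calibration).

γ is dimensionless on the normalized scale; against unnormalized doses it
carries units of Gy⁻¹. The LKB (probit) slope parameter `m` is related to
the normalized slope by `γ50 = 1/(m√(2π))`; this is the relation
`gamma_from_lkb_m` implements (m = 1.21 ↦ γ ≈ 0.33).

## Monte Carlo procedure

One *cell* of the simulation grid is a (dosimetric parameter, γ, cohort
size) combination. Default grid: γ from 0.1 to 1.5 in steps of 0.1; 3000
iterations per cell; cohort sizes full plus optional subsamples (the
reference design uses 605, 302 and 182). Per iteration:

1. subsample the requested number of patients **without replacement**
   (identity when the full size is requested);
2. compute each subsampled patient's NTCP from `D_gt` with the predefined
   `(D50, γ)`;
3. draw one Bernoulli outcome per patient;
4. fit one logistic NTCP model on `(D_gt, y)` and one on `(D_alt, y)` by
   maximum likelihood;
5. compare the two models' AUCs with a paired bootstrap (below);
6. store the iteration record.

Subsampling before outcome simulation (rather than after) is
distributionally equivalent; fixing this order makes per-iteration seeds
meaningful. Iterations whose outcome draw is degenerate (all events or all
non-events) or whose fit fails are recorded as invalid with a
machine-readable reason, excluded from aggregates, and counted; a cell with
more than 50 % invalid iterations aborts loudly rather than reporting
statistics from a degenerate setting.

## Fitting

`fit_ntcp` maximizes the Bernoulli log-likelihood over `(D50, γ)` with
L-BFGS-B on `(D50, log γ)` (analytic gradient), multi-started from
`D50 ∈ {median(D), 1}` × `γ ∈ {0.25, 1}`. Box bounds default to
`D50 ∈ [0.01, 100]·median(D)` and `γ ∈ [0.01, 50]`: under complete
separation the likelihood increases in γ without bound, so an explicit cap
is required. Because gradient methods stall once the logistic saturates,
completely separated data are detected directly (`max(D | y=0) <
min(D | y=1)`) and the supremum within the box — γ at its upper bound, D50
mid-gap — is placed explicitly; such fits carry a `separation` diagnostic.
Probabilities inside the likelihood are clipped to `[ε, 1−ε]` with
ε = 1e−12 (configurable) so the objective stays finite. Ties in `D` are
permitted and not jittered.

## AUC and the paired bootstrap

AUC is the Mann-Whitney concordance probability, computed from midranks
(ties count ½), in-sample (fit and evaluation on the same simulated cohort,
an acknowledged optimism of the design). For a univariate strictly
monotone model, the in-sample AUC of the fitted model equals the AUC of the
raw dose vector — discrimination depends only on the ranking.

Per iteration, 100 paired bootstrap draws resample patient indices with
replacement; the *same* indices are applied to `D_gt`, `D_alt` and `y`, and
both AUCs are recomputed per draw. Resamples that lose an outcome class are
redrawn (and counted). A model is "significantly better" in that iteration
iff its AUC is *strictly* higher in strictly more than `(1 − α)·n_boot`
draws (α = 0.05; per-draw ties count as not-higher — the convention is ours,
chosen so that identical dose vectors can never reach significance). The
test is evaluated in both directions; the headline statistic aggregates the
ground-truth direction.

The bootstrap does **not** refit `(D50, γ)` per draw by default: by the
rank-invariance above, refitting cannot change any draw's AUC, so the
shortcut is exact, not an approximation — this keeps a
3000-iteration × 100-draw cell in the tens of seconds. The literal refit is
available via `refit_in_bootstrap=True` as a sensitivity check, and a test
verifies both routes agree.

## Randomness and reproducibility

A `SeedSequence` hierarchy derives, from the master seed plus a stable
CRC-keyed cell identifier, one stream per cell; each iteration spawns its
own stream, which splits into subsample / outcome / bootstrap substreams.
Consequences: any cell (and any iteration) is reproducible in isolation,
results do not depend on the order cells are run in, and two sweeps with
the same master seed write byte-identical output tables.

## Synthetic cohorts

No patient data ship with the package; the generator emulates the
statistical features the method is sensitive to:

* **Marginal shape.** Default: lognormal with mean 1 and coefficient of
  variation 0.7 — a right-skewed, positive distribution typical of mean
  organ doses after mean normalization. The CV is a documented,
  configurable default, not a claim about any real cohort. A scaled Beta
  on [0, 100] is provided for VxGy-like parameters.
* **Coupling.** The alternative vector is tied to the ground truth through
  a Gaussian copula calibrated to a target **Spearman** correlation
  (Pearson on the latent normals via `ρ = 2 sin(πρ_s/6)`). Rank correlation
  is the right knob because AUC, the framework's metric, is rank-based.
  The coupling never touches the ground-truth margin.
* **Bias.** Optional multiplicative/additive offsets on the alternative
  mimic systematic contouring error; values are clipped to the marginal's
  support afterwards (a point mass at the support edge is permitted), and a
  bias that collapses the vector to a constant is rejected.

What the generator does *not* emulate: spatially structured contour errors,
dose-distribution shapes tied to treatment technique, inter-parameter
correlations of a real DVH, or cohort heterogeneity. Passing tests on
synthetic cohorts therefore validate the machinery and its qualitative
behaviors (slope, parameter and size effects), not any cohort-specific
published fraction.

## Contour metrics

Dice is voxel-count overlap. Surface Dice at tolerance τ uses a boundary
**voxel-face** surface representation: faces between foreground and
background (or out-of-grid) voxels, with Euclidean distances between face
centers in physical mm respecting anisotropic spacing; faces are counted
unweighted. Mesh-based surfaces or area weighting would shift values
slightly — the representation is a documented package convention. Mean dose
is the arithmetic mean over foreground voxels (uniform voxel volume); VxGy
uses an inclusive threshold (dose ≥ x). Grids must be co-registered;
mismatched geometry raises instead of silently resampling. Analytic
sphere/ellipsoid phantoms with closed-form volumes and lens-shaped overlaps
serve as oracles.

## Problem sizes in the shipped tests

The test suite and acceptance script run the full pipeline at desk scale:
3000 iterations for event-rate statistics (fits disabled there — they
cannot affect the event rate), 400–500 iterations per cell for the
slope-trend, null-calibration and size-effect checks, and n = 20 000 for
parameter recovery. These sizes were chosen so each check's Monte Carlo
error is comfortably below the asserted tolerance.

## Known limitations

* In-sample AUC and no train/test split: performance differences are upper
  bounds, as in the underlying design.
* Only the univariate logistic model is implemented; probit/LKB fitting and
  multivariable NTCP models are out of scope (the LKB appears only through
  the slope conversion).
* No DICOM RTSTRUCT/RTDOSE parsing or contour rasterization; voxel masks
  come from NRRD-like images or the phantom generator.
* Confidence intervals on fitted parameters are not provided; per-iteration
  fits are point estimates consumed by the AUC comparison.
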