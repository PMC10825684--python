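"""AUC computation and the paired bootstrap comparison of two NTCP models.

Discrimination is measured by the area under the ROC curve in its
Mann-Whitney form: the probability that a randomly chosen event patient has
a higher risk score than a randomly chosen non-event patient, with ties
counting one half.  Because the logistic NTCP model is strictly increasing
in dose for positive gamma, the in-sample AUC of a fitted model equals the
AUC of its raw dose vector — discrimination depends only on the dose
ranking, not on the fitted (D50, gamma).

The comparison between the ground-truth-derived and alternative-derived
models is a paired bootstrap: patients are resampled with replacement, the
*same* resample indices are applied to both dose vectors and the labels, and
both AUCs are recomputed per draw.  A model is deemed significantly superior
when it has the strictly higher AUC in more than ``(1 - alpha)`` of the
draws.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata

from .model_fit import DegenerateOutcomeError, FitSettings, fit_ntcp
from .ntcp_core import ntcp

__all__ = ["ComparisonResult", "auc", "bootstrap_compare"]

_MAX_REDRAW_ROUNDS = 1000


@dataclass(frozen=True)
class ComparisonResult:
    """Outcome of a paired bootstrap AUC comparison for one simulated cohort."""

    auc_gt: float
    auc_alt: float
    auc_diff: float
    frac_boot_gt_higher: float
    significant_gt_better: bool
    significant_alt_better: bool
    n_boot: int
    diagnostics: dict = field(default_factory=dict)


def _check_labels(labels: np.ndarray) -> np.ndarray:
    labels = np.asarray(labels)
    if not np.all((labels == 0) | (labels == 1)):
        raise ValueError("labels must be binary")
    n_events = int(labels.sum())
    if n_events == 0 or n_events == len(labels):
        raise DegenerateOutcomeError(
            f"degenerate labels: {n_events} events out of {len(labels)}"
        )
    return labels


def auc(scores, labels) -> float:
    """Mann-Whitney AUC: P(score_event > score_nonevent) + 0.5 * P(equal).

    Computed from midranks, which is exactly the pair-counting definition
    with ties counting one half.
    """
    s = np.asarray(scores, dtype=float)
    y = _check_labels(labels)
    if len(s) != len(y):
        raise ValueError(f"length mismatch: {len(s)} scores vs {len(y)} labels")
    n1 = int(y.sum())
    n0 = len(y) - n1
    ranks = rankdata(s)
    u = ranks[y == 1].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


def _auc_rows(scores: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Row-wise Mann-Whitney AUC for matrices of resampled scores/labels.

    Every row must contain both classes.
    """
    ranks = rankdata(scores, axis=1)
    n1 = labels.sum(axis=1)
    n0 = labels.shape[1] - n1
    u = (ranks * labels).sum(axis=1) - n1 * (n1 + 1) / 2.0
    return u / (n1 * n0)


def bootstrap_compare(
    D_gt,
    D_alt,
    y,
    n_boot: int = 100,
    alpha: float = 0.05,
    rng: np.random.Generator | None = None,
    refit_in_bootstrap: bool = False,
    fit_settings: FitSettings | None = None,
) -> ComparisonResult:
    """Paired bootstrap comparison of the two contour sets' model AUCs.

    Draws ``n_boot`` resamples of patient indices with replacement and applies
    the same indices to ``D_gt``, ``D_alt`` and ``y``; resamples that lose one
    outcome class are redrawn (the count is reported in ``diagnostics``).
    ``significant_gt_better`` is set iff the ground-truth AUC is strictly
    higher in strictly more than ``(1 - alpha) * n_boot`` draws (ties in a
    draw count as not-higher), and symmetrically for the alternative.

    By default the bootstrap does **not** refit (D50, gamma) per draw: for a
    univariate strictly monotone model the in-sample AUC depends only on the
    dose ranking, so refitting cannot change it.  Set
    ``refit_in_bootstrap=True`` to perform the literal refit as a sensitivity
    check (draws whose refit fails are redrawn and counted).
    """
    d_gt = np.asarray(D_gt, dtype=float)
    d_alt = np.asarray(D_alt, dtype=float)
    labels = _check_labels(y)
    if not (len(d_gt) == len(d_alt) == len(labels)):
        raise ValueError("D_gt, D_alt and y must have equal length")
    if rng is None:
        rng = np.random.default_rng()
    n = len(labels)

    auc_gt = auc(d_gt, labels)
    auc_alt = auc(d_alt, labels)

    # paired resample: one index matrix shared by both dose vectors and y
    indices = rng.integers(0, n, size=(n_boot, n))
    n_redraws = 0
    for _ in range(_MAX_REDRAW_ROUNDS):
        y_b = labels[indices]
        degenerate = (y_b.sum(axis=1) == 0) | (y_b.sum(axis=1) == n)
        if not degenerate.any():
            break
        n_redraws += int(degenerate.sum())
        indices[degenerate] = rng.integers(0, n, size=(int(degenerate.sum()), n))
    else:
        raise RuntimeError(
            "could not draw non-degenerate bootstrap resamples; "
            "outcome labels are too unbalanced"
        )

    if refit_in_bootstrap:
        boot_gt = np.empty(n_boot)
        boot_alt = np.empty(n_boot)
        for b in range(n_boot):
            idx = indices[b]
            fit_gt = fit_ntcp(d_gt[idx], labels[idx], fit_settings)
            fit_alt = fit_ntcp(d_alt[idx], labels[idx], fit_settings)
            boot_gt[b] = auc(ntcp(d_gt[idx], fit_gt.params_hat), labels[idx])
            boot_alt[b] = auc(ntcp(d_alt[idx], fit_alt.params_hat), labels[idx])
    else:
        y_b = labels[indices].astype(float)
        boot_gt = _auc_rows(d_gt[indices], y_b)
        boot_alt = _auc_rows(d_alt[indices], y_b)

    n_gt_higher = int(np.sum(boot_gt > boot_alt))
    n_alt_higher = int(np.sum(boot_alt > boot_gt))
    threshold = (1.0 - alpha) * n_boot
    return ComparisonResult(
        auc_gt=auc_gt,
        auc_alt=auc_alt,
        auc_diff=auc_gt - auc_alt,
        frac_boot_gt_higher=n_gt_higher / n_boot,
        significant_gt_better=n_gt_higher > threshold,
        significant_alt_better=n_alt_higher > threshold,
        n_boot=n_boot,
        diagnostics={
            "n_redraws": n_redraws,
            "mean_boot_auc_diff": float(np.mean(boot_gt - boot_alt)),
            "refit_in_bootstrap": refit_in_bootstrap,
        },
    )
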