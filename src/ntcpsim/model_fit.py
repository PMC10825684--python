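"""Maximum-likelihood estimation of the logistic NTCP parameters (D50, gamma).

The fit maximizes the Bernoulli log-likelihood

    LL = sum_i [ y_i * log p_i + (1 - y_i) * log(1 - p_i) ],
    p_i = NTCP(D_i; D50, gamma)

over ``(D50, gamma)`` inside box bounds, using L-BFGS-B on ``(D50,
log gamma)`` with an analytic gradient and a small multi-start grid.  The
log-gamma transform keeps the slope positive and makes the likelihood
surface better conditioned; the box bounds guard against the divergence of
gamma under complete separation, which the likelihood alone does not
penalize.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.special import expit

from .ntcp_core import NTCPParams, gamma_from_slope, ntcp

__all__ = [
    "FitSettings",
    "FitResult",
    "DegenerateOutcomeError",
    "log_likelihood",
    "fit_ntcp",
]


class DegenerateOutcomeError(ValueError):
    """Raised when all outcome labels agree, so no dose-response can be fit."""


@dataclass(frozen=True)
class FitSettings:
    """Optimizer configuration for :func:`fit_ntcp`.

    ``d50_bounds_rel`` is expressed relative to the median dose of the data
    being fit; ``clip_eps`` is the probability clipping applied inside the
    likelihood so that log terms remain finite when the logistic saturates.
    """

    d50_bounds_rel: tuple[float, float] = (0.01, 100.0)
    gamma_bounds: tuple[float, float] = (0.01, 50.0)
    d50_starts: tuple[float, ...] = ()  # empty -> {median(D), 1.0}
    gamma_starts: tuple[float, ...] = (0.25, 1.0)
    clip_eps: float = 1e-12
    maxiter: int = 500
    # gamma_hat within this relative distance of the upper bound is flagged
    # as (quasi-)separated data
    separation_rel_tol: float = 1e-3


@dataclass(frozen=True)
class FitResult:
    params_hat: NTCPParams
    log_likelihood: float
    converged: bool
    n_events: int
    diagnostics: dict = field(default_factory=dict)

    @property
    def separation(self) -> bool:
        return bool(self.diagnostics.get("separation", False))


def log_likelihood(D, y, params: NTCPParams, clip_eps: float = 1e-12) -> float:
    """Bernoulli log-likelihood of labels ``y`` under the logistic NTCP model.

    Probabilities are clipped to ``[clip_eps, 1 - clip_eps]`` so the value is
    always finite, even when the model saturates on some patients.
    """
    d = np.asarray(D, dtype=float)
    labels = np.asarray(y)
    if d.ndim != 1 or labels.ndim != 1 or len(d) != len(labels):
        raise ValueError(
            f"length mismatch: {len(d)} doses vs {len(labels)} labels"
        )
    if len(d) == 0:
        raise ValueError("empty cohort")
    if not np.all((labels == 0) | (labels == 1)):
        raise ValueError("labels must be binary")
    p = np.clip(ntcp(d, params), clip_eps, 1.0 - clip_eps)
    return float(np.sum(np.where(labels == 1, np.log(p), np.log1p(-p))))


def _neg_ll_and_grad(x, d, y, clip_eps):
    """Negative log-likelihood and gradient in (d50, log gamma) coordinates.

    With eta_i = s*(D_i - d50), s = 4*gamma/d50 and r_i = y_i - p_i:
        dLL/d(log gamma) = sum r_i * eta_i
        dLL/d(d50)       = sum r_i * (-eta_i / d50 - s)
    """
    d50, log_gamma = x
    gamma = np.exp(log_gamma)
    s = 4.0 * gamma / d50
    eta = s * (d - d50)
    p = expit(eta)
    pc = np.clip(p, clip_eps, 1.0 - clip_eps)
    ll = np.sum(np.where(y == 1, np.log(pc), np.log1p(-pc)))
    r = y - p
    g_d50 = np.sum(r * (-eta / d50 - s))
    g_lg = np.sum(r * eta)
    return -ll, np.array([-g_d50, -g_lg])


def fit_ntcp(D, y, settings: FitSettings | None = None) -> FitResult:
    """Fit (D50, gamma) by likelihood maximization.

    The result is invariant to patient reordering (the likelihood is a sum
    over patients).  Under complete separation the slope estimate runs into
    the configured upper bound; the fit is still returned, with a
    ``separation`` diagnostic set.

    Raises
    ------
    DegenerateOutcomeError
        If all labels are 0 or all are 1.
    ValueError
        If the dose vector is constant (no ranking information).
    """
    settings = settings or FitSettings()
    d = np.asarray(D, dtype=float)
    labels = np.asarray(y, dtype=float)
    if len(d) != len(labels):
        raise ValueError(f"length mismatch: {len(d)} doses vs {len(labels)} labels")
    if len(d) < 2:
        raise ValueError("need at least 2 patients to fit")
    if not np.all((labels == 0) | (labels == 1)):
        raise ValueError("labels must be binary")
    n_events = int(labels.sum())
    if n_events == 0 or n_events == len(labels):
        raise DegenerateOutcomeError(
            f"degenerate outcome: {n_events} events out of {len(labels)}"
        )
    med = float(np.median(d))
    if np.ptp(d) == 0:
        raise ValueError("constant dose vector: cannot fit a dose-response")
    if med <= 0:
        med = float(d[d > 0].mean()) if np.any(d > 0) else 1.0

    d50_lo, d50_hi = (b * med for b in settings.d50_bounds_rel)
    g_lo, g_hi = settings.gamma_bounds
    bounds = [(d50_lo, d50_hi), (np.log(g_lo), np.log(g_hi))]

    d50_starts = settings.d50_starts or (med, 1.0)
    starts = [
        (float(np.clip(d50_0, d50_lo, d50_hi)), float(np.clip(g0, g_lo, g_hi)))
        for d50_0 in d50_starts
        for g0 in settings.gamma_starts
    ]

    best = None
    best_res = None
    for d50_0, g0 in starts:
        res = minimize(
            _neg_ll_and_grad,
            x0=np.array([d50_0, np.log(g0)]),
            args=(d, labels, settings.clip_eps),
            jac=True,
            method="L-BFGS-B",
            bounds=bounds,
            options={"maxiter": settings.maxiter},
        )
        if best is None or res.fun < best:
            best = res.fun
            best_res = res

    d50_hat = float(best_res.x[0])
    gamma_hat = float(np.exp(best_res.x[1]))
    best_ll = -float(best_res.fun)

    # Complete separation: the likelihood is monotone increasing in gamma, so
    # its supremum within the box sits at the gamma bound with D50 anywhere in
    # the gap between the classes.  Gradient methods stall when the logistic
    # saturates, so place that candidate explicitly and keep the better one.
    thr_lo = float(d[labels == 0].max())
    thr_hi = float(d[labels == 1].min())
    if thr_lo < thr_hi:
        d50_sep = float(np.clip((thr_lo + thr_hi) / 2.0, d50_lo, d50_hi))
        ll_sep = log_likelihood(
            d, labels, NTCPParams(d50=d50_sep, gamma=g_hi), settings.clip_eps
        )
        if ll_sep >= best_ll:
            d50_hat, gamma_hat, best_ll = d50_sep, g_hi, ll_sep

    params_hat = NTCPParams(d50=d50_hat, gamma=gamma_hat)
    separated = gamma_hat >= g_hi * (1.0 - settings.separation_rel_tol)
    diagnostics = {
        "message": str(best_res.message),
        "n_iterations": int(best_res.nit),
        "n_starts": len(starts),
        "separation": separated,
        "at_d50_bound": d50_hat <= d50_lo * (1 + 1e-9) or d50_hat >= d50_hi * (1 - 1e-9),
    }
    return FitResult(
        params_hat=params_hat,
        log_likelihood=best_ll,
        converged=bool(best_res.success),
        n_events=n_events,
        diagnostics=diagnostics,
    )
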