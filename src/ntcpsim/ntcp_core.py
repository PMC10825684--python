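"""The logistic NTCP model, its parameterizations, and cohort normalization.

The normal tissue complication probability (NTCP) is modelled as a logistic
function of a scalar dosimetric parameter ``D`` (for example the mean heart
dose, or a VxGy volume percentage)::

    NTCP(D) = 1 / (1 + exp(s * (D50 - D)))

where ``D50`` is the dose at which the complication probability is 50 % and
``s = 4 * gamma / D50`` is the slope of the curve, expressed through the
normalized slope ``gamma = D50 * dNTCP/dD`` evaluated at ``D50``.  Steeper
dose-response relationships have larger ``gamma``.

Dose parameters are usually mean-normalized before simulation: the
ground-truth vector is divided by its own mean (so that ``mean(D_gt) = 1``)
and the *same* factor is applied to the alternative vector, preserving the
relative differences between the two contour sets.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "NTCPParams",
    "DoseCohort",
    "ntcp",
    "slope_from_gamma",
    "gamma_from_slope",
    "gamma_from_lkb_m",
    "lkb_m_from_gamma",
    "normalize_cohort",
    "read_cohort_csv",
    "write_cohort_csv",
]

_VXGY_RE = re.compile(r"^V\s*\d+(\.\d+)?\s*Gy$", re.IGNORECASE)


def slope_from_gamma(gamma: float, d50: float) -> float:
    """Logistic slope ``s = 4 * gamma / d50``.

    Parameters
    ----------
    gamma
        Normalized slope of the NTCP curve at ``d50``; must be positive.
    d50
        Dose-parameter value at 50 % complication probability; must be
        positive.
    """
    if gamma <= 0 or d50 <= 0:
        raise ValueError(f"gamma and d50 must be positive, got gamma={gamma}, d50={d50}")
    return 4.0 * gamma / d50


def gamma_from_slope(s: float, d50: float) -> float:
    """Inverse of :func:`slope_from_gamma`: ``gamma = s * d50 / 4``."""
    if s <= 0 or d50 <= 0:
        raise ValueError(f"s and d50 must be positive, got s={s}, d50={d50}")
    return s * d50 / 4.0


def gamma_from_lkb_m(m: float) -> float:
    """Convert the LKB (probit) slope parameter ``m`` to the normalized slope.

    The Lyman-Kutcher-Burman model parameterizes the dose-response slope with
    ``m``; its normalized slope at the midpoint is ``gamma50 = 1/(m*sqrt(2*pi))``.
    For example ``m = 1.21`` converts to ``gamma ~= 0.33``.
    """
    if m <= 0:
        raise ValueError(f"m must be positive, got {m}")
    return 1.0 / (m * math.sqrt(2.0 * math.pi))


def lkb_m_from_gamma(gamma: float) -> float:
    """Inverse of :func:`gamma_from_lkb_m`."""
    if gamma <= 0:
        raise ValueError(f"gamma must be positive, got {gamma}")
    return 1.0 / (gamma * math.sqrt(2.0 * math.pi))


@dataclass(frozen=True)
class NTCPParams:
    """Parameters of the logistic NTCP model.

    Attributes
    ----------
    d50
        Dose-parameter value at 50 % complication probability.  After mean
        normalization this is dimensionless (the predefined simulation model
        uses ``d50 = 1``); for non-normalized use it carries the parameter's
        units (Gy or %).
    gamma
        Normalized slope at ``d50`` (dimensionless per normalized-dose unit;
        per Gy when doses are not normalized).
    s
        Derived logistic slope ``4 * gamma / d50``.  Computed automatically;
        if given explicitly it must agree with the derived value.
    """

    d50: float
    gamma: float
    s: float = field(default=math.nan)

    def __post_init__(self) -> None:
        derived = slope_from_gamma(self.gamma, self.d50)  # validates positivity
        if math.isnan(self.s):
            object.__setattr__(self, "s", derived)
        elif not math.isclose(self.s, derived, rel_tol=1e-9, abs_tol=1e-12):
            raise ValueError(
                f"inconsistent slope: s={self.s} but 4*gamma/d50={derived}"
            )


def ntcp(D, params: NTCPParams):
    """Evaluate the logistic NTCP model, elementwise on ``D``.

    Uses :func:`scipy.special.expit` on ``s * (D - d50)``, which is
    numerically stable for arbitrarily large exponents (saturating to 0 or 1
    without overflow).

    Raises
    ------
    ValueError
        If any element of ``D`` is non-finite; the message identifies the
        first offending index.
    """
    from scipy.special import expit

    d = np.asarray(D, dtype=float)
    bad = ~np.isfinite(d)
    if np.any(bad):
        idx = int(np.flatnonzero(bad)[0])
        raise ValueError(f"non-finite dose value at index {idx}: {d.flat[idx]}")
    out = expit(params.s * (d - params.d50))
    if np.isscalar(D) or d.ndim == 0:
        return float(out)
    return out


@dataclass(frozen=True)
class DoseCohort:
    """Paired per-patient dosimetric parameter vectors for two contour sets.

    ``d_gt`` holds the value computed from the ground-truth contours and
    ``d_alt`` the value from the alternative contours, in the same patient
    order.  ``normalization_factor`` records the pre-normalization mean of
    ``d_gt`` once :func:`normalize_cohort` has been applied.
    """

    patient_ids: tuple
    parameter_name: str
    d_gt: np.ndarray
    d_alt: np.ndarray
    normalization_factor: float | None = None
    normalized: bool = False

    def __post_init__(self) -> None:
        d_gt = np.asarray(self.d_gt, dtype=float)
        d_alt = np.asarray(self.d_alt, dtype=float)
        object.__setattr__(self, "d_gt", d_gt)
        object.__setattr__(self, "d_alt", d_alt)
        object.__setattr__(self, "patient_ids", tuple(self.patient_ids))
        if d_gt.ndim != 1 or d_alt.ndim != 1:
            raise ValueError("dose parameter vectors must be 1-D")
        if len(d_gt) != len(d_alt) or len(d_gt) != len(self.patient_ids):
            raise ValueError(
                f"length mismatch: {len(self.patient_ids)} patients, "
                f"{len(d_gt)} ground-truth values, {len(d_alt)} alternative values"
            )
        if len(d_gt) < 2:
            raise ValueError("a cohort needs at least 2 patients")
        if not (np.all(np.isfinite(d_gt)) and np.all(np.isfinite(d_alt))):
            raise ValueError("dose parameter vectors must be finite")
        if np.any(d_gt < 0) or np.any(d_alt < 0):
            raise ValueError("dose parameter values must be non-negative")
        if not self.normalized and self.is_vxgy:
            if np.any(d_gt > 100) or np.any(d_alt > 100):
                raise ValueError(
                    f"{self.parameter_name} is a volume percentage; values must be in [0, 100]"
                )
        if self.normalized:
            if not math.isclose(float(d_gt.mean()), 1.0, rel_tol=1e-9, abs_tol=1e-9):
                raise ValueError(
                    "normalized cohort must have mean(d_gt) == 1, got "
                    f"{d_gt.mean():.6g}"
                )

    @property
    def is_vxgy(self) -> bool:
        return _VXGY_RE.match(self.parameter_name.strip()) is not None

    def __len__(self) -> int:
        return len(self.d_gt)

    def take(self, indices: np.ndarray) -> "DoseCohort":
        """Subcohort restricted to ``indices`` (patient order follows them).

        Used by the Monte Carlo engine for per-iteration subsampling; the
        normalization metadata is carried over unchanged (the subsample mean
        may deviate from 1, which is intentional: normalization is a one-off,
        full-cohort transformation).
        """
        idx = np.asarray(indices)
        sub = replace(
            self,
            patient_ids=tuple(self.patient_ids[i] for i in idx),
            d_gt=self.d_gt[idx],
            d_alt=self.d_alt[idx],
        )
        return sub


def normalize_cohort(cohort: DoseCohort) -> DoseCohort:
    """Divide both dose vectors by ``mean(d_gt)`` so that ``mean(d_gt) == 1``.

    The alternative vector is scaled by the ground-truth factor, not its own
    mean, so its post-normalization mean is generally not 1.  A pure
    rescaling: rank and linear correlations between the two vectors are
    unchanged.

    Raises
    ------
    ValueError
        If the cohort is already normalized (re-normalizing silently would
        overwrite the stored factor) or if ``mean(d_gt)`` is zero.
    """
    if cohort.normalized:
        raise ValueError("cohort is already normalized")
    factor = float(cohort.d_gt.mean())
    if factor <= 0:
        raise ValueError("cannot normalize: mean(d_gt) is not positive")
    return replace(
        cohort,
        d_gt=cohort.d_gt / factor,
        d_alt=cohort.d_alt / factor,
        normalization_factor=factor,
        normalized=True,
    )


def read_cohort_csv(path, parameter_name: str | None = None) -> DoseCohort:
    """Read a cohort from CSV with columns ``patient_id, D_gt, D_alt``.

    One file per dosimetric parameter; ``parameter_name`` defaults to the
    file stem.  Values are in their native units (Gy or %), i.e. the cohort
    is returned un-normalized.
    """
    import pathlib

    path = pathlib.Path(path)
    df = pd.read_csv(path)
    required = {"patient_id", "D_gt", "D_alt"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"cohort CSV {path} is missing columns: {sorted(missing)}")
    return DoseCohort(
        patient_ids=tuple(str(p) for p in df["patient_id"]),
        parameter_name=parameter_name or path.stem,
        d_gt=df["D_gt"].to_numpy(dtype=float),
        d_alt=df["D_alt"].to_numpy(dtype=float),
    )


def write_cohort_csv(cohort: DoseCohort, path) -> None:
    """Write a cohort as ``patient_id, D_gt, D_alt`` CSV."""
    pd.DataFrame(
        {
            "patient_id": list(cohort.patient_ids),
            "D_gt": cohort.d_gt,
            "D_alt": cohort.d_alt,
        }
    ).to_csv(path, index=False)
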