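"""Monte Carlo engine: iterate outcome simulation, dual fitting and comparison.

One *cell* of the simulation grid is a combination of (dosimetric parameter,
gamma, cohort size).  Within a cell, each iteration

1. subsamples ``cohort_size`` patients without replacement (identity when
   the full cohort is requested),
2. computes every subsampled patient's NTCP from the ground-truth dose
   vector with the predefined (D50, gamma),
3. draws one Bernoulli outcome per patient,
4. fits one logistic NTCP model on (D_gt, y) and one on (D_alt, y),
5. runs the paired bootstrap AUC comparison,
6. stores an :class:`IterationRecord`.

Iterations with a degenerate outcome draw (all events / all non-events) or a
failed fit are recorded as invalid, excluded from aggregates and counted; a
run where more than half the iterations are invalid fails loudly.

Randomness uses a spawning seed hierarchy built on ``numpy``'s
``SeedSequence``: the master seed and a stable per-cell key derive a cell
stream, each iteration spawns its own stream, and each iteration stream
splits into subsample / outcome / bootstrap substreams.  Cells and
iterations are therefore reproducible in isolation and independent of
scheduling order.
"""

from __future__ import annotations

import dataclasses
import json
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .evaluation import ComparisonResult, bootstrap_compare
from .model_fit import DegenerateOutcomeError, FitResult, FitSettings, fit_ntcp
from .ntcp_core import DoseCohort, NTCPParams, ntcp
from .outcome_sim import simulate_outcomes

__all__ = [
    "SimulationConfig",
    "IterationRecord",
    "run_cell",
    "run_sweep",
]

DEFAULT_GAMMA_GRID = tuple(round(0.1 * k, 1) for k in range(1, 16))


@dataclass(frozen=True)
class SimulationConfig:
    """Configuration of a Monte Carlo sweep.

    Defaults follow the reference study design: gamma from 0.1 to 1.5 in
    steps of 0.1, D50 = 1 on the mean-normalized dose scale, 3000 iterations
    per cell, 100 bootstrap draws at a 5 % significance level.

    ``cohort_sizes`` of ``None`` means "full cohort only".  ``fit_models``
    and ``compare_models`` allow switching off the per-iteration fits or the
    bootstrap comparison for runs that only need event-rate statistics.
    """

    gamma_grid: tuple[float, ...] = DEFAULT_GAMMA_GRID
    d50: float = 1.0
    n_iterations: int = 3000
    n_boot: int = 100
    alpha: float = 0.05
    cohort_sizes: tuple[int, ...] | None = None
    master_seed: int = 0
    refit_in_bootstrap: bool = False
    fit_models: bool = True
    compare_models: bool = True
    fit_settings: FitSettings = field(default_factory=FitSettings)
    max_invalid_fraction: float = 0.5

    def __post_init__(self) -> None:
        if any(g <= 0 for g in self.gamma_grid):
            raise ValueError("all gamma values must be positive")
        if self.d50 <= 0:
            raise ValueError("d50 must be positive")
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        object.__setattr__(self, "gamma_grid", tuple(float(g) for g in self.gamma_grid))
        if self.cohort_sizes is not None:
            object.__setattr__(
                self, "cohort_sizes", tuple(int(s) for s in self.cohort_sizes)
            )

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        fs = d.pop("fit_settings", None)
        if fs is not None:
            fs = FitSettings(**{k: tuple(v) if isinstance(v, list) else v for k, v in fs.items()})
            d["fit_settings"] = fs
        for key in ("gamma_grid", "cohort_sizes"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        return cls(**d)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["gamma_grid"] = list(self.gamma_grid)
        if self.cohort_sizes is not None:
            d["cohort_sizes"] = list(self.cohort_sizes)
        return d


@dataclass(frozen=True)
class IterationRecord:
    """Everything stored for a single Monte Carlo iteration."""

    iteration: int
    subsample_indices: np.ndarray
    event_fraction: float | None
    fit_gt: FitResult | None
    fit_alt: FitResult | None
    comparison: ComparisonResult | None
    valid: bool
    invalid_reason: str = ""

    def to_row(self) -> dict:
        row = {
            "iteration": self.iteration,
            "valid": self.valid,
            "invalid_reason": self.invalid_reason,
            "event_fraction": self.event_fraction,
        }
        for tag, fit in (("gt", self.fit_gt), ("alt", self.fit_alt)):
            row[f"d50_hat_{tag}"] = fit.params_hat.d50 if fit else np.nan
            row[f"gamma_hat_{tag}"] = fit.params_hat.gamma if fit else np.nan
            row[f"log_likelihood_{tag}"] = fit.log_likelihood if fit else np.nan
            row[f"converged_{tag}"] = fit.converged if fit else False
        c = self.comparison
        row.update(
            auc_gt=c.auc_gt if c else np.nan,
            auc_alt=c.auc_alt if c else np.nan,
            auc_diff=c.auc_diff if c else np.nan,
            frac_boot_gt_higher=c.frac_boot_gt_higher if c else np.nan,
            significant_gt_better=c.significant_gt_better if c else False,
            significant_alt_better=c.significant_alt_better if c else False,
        )
        return row


def _cell_seed_seq(master_seed: int, parameter_name: str, gamma: float, cohort_size: int) -> np.random.SeedSequence:
    """Stable per-cell seed, independent of the order cells are visited in."""
    key = f"{parameter_name}|{gamma:.6g}|{cohort_size}".encode()
    return np.random.SeedSequence([int(master_seed), zlib.crc32(key)])


def _summarize(
    records: list[IterationRecord],
    parameter_name: str,
    gamma: float,
    d50: float,
    cohort_size: int,
) -> dict:
    valid = [r for r in records if r.valid]
    row = {
        "parameter_name": parameter_name,
        "gamma": gamma,
        "d50": d50,
        "cohort_size": cohort_size,
        "n_iterations": len(records),
        "n_valid": len(valid),
        "n_invalid": len(records) - len(valid),
    }
    ev = np.array([r.event_fraction for r in records if r.event_fraction is not None])
    row["mean_event_pct"] = float(100 * ev.mean()) if len(ev) else np.nan
    row["sd_event_pct"] = float(100 * ev.std(ddof=1)) if len(ev) > 1 else np.nan
    comps = [r.comparison for r in valid if r.comparison is not None]
    if comps:
        diff = np.array([c.auc_diff for c in comps])
        a_gt = np.array([c.auc_gt for c in comps])
        a_alt = np.array([c.auc_alt for c in comps])
        row.update(
            frac_significant_gt_better=float(
                np.mean([c.significant_gt_better for c in comps])
            ),
            frac_significant_alt_better=float(
                np.mean([c.significant_alt_better for c in comps])
            ),
            mean_auc_diff=float(diff.mean()),
            sd_auc_diff=float(diff.std(ddof=1)) if len(diff) > 1 else np.nan,
            mean_auc_gt=float(a_gt.mean()),
            sd_auc_gt=float(a_gt.std(ddof=1)) if len(a_gt) > 1 else np.nan,
            mean_auc_alt=float(a_alt.mean()),
            sd_auc_alt=float(a_alt.std(ddof=1)) if len(a_alt) > 1 else np.nan,
        )
    else:
        row.update(
            frac_significant_gt_better=np.nan,
            frac_significant_alt_better=np.nan,
            mean_auc_diff=np.nan,
            sd_auc_diff=np.nan,
            mean_auc_gt=np.nan,
            sd_auc_gt=np.nan,
            mean_auc_alt=np.nan,
            sd_auc_alt=np.nan,
        )
    return row


def run_cell(
    cohort: DoseCohort,
    params: NTCPParams,
    config: SimulationConfig,
    cohort_size: int | None = None,
    seed_seq: np.random.SeedSequence | None = None,
) -> tuple[list[IterationRecord], dict]:
    """Run all Monte Carlo iterations of one (parameter, gamma, size) cell.

    Returns the per-iteration records and a summary row (a plain dict, one
    row of the sweep's summary table).  Bit-exact reproducible from the seed.
    """
    if not cohort.normalized:
        raise ValueError("cohort must be normalized before simulation")
    n = len(cohort)
    cohort_size = n if cohort_size is None else int(cohort_size)
    if cohort_size > n or cohort_size < 2:
        raise ValueError(f"cohort_size {cohort_size} out of range for cohort of {n}")
    if seed_seq is None:
        seed_seq = _cell_seed_seq(
            config.master_seed, cohort.parameter_name, params.gamma, cohort_size
        )

    iter_seqs = seed_seq.spawn(config.n_iterations)
    records: list[IterationRecord] = []
    for i, iter_seq in enumerate(iter_seqs):
        sub_ss, out_ss, boot_ss = iter_seq.spawn(3)
        sub_rng = np.random.default_rng(sub_ss)
        if cohort_size < n:
            idx = sub_rng.choice(n, size=cohort_size, replace=False)
        else:
            idx = np.arange(n)
        d_gt = cohort.d_gt[idx]
        d_alt = cohort.d_alt[idx]

        p = ntcp(d_gt, params)
        outcome = simulate_outcomes(
            p, np.random.default_rng(out_ss), rng_state_tag=f"iter{i}/outcome"
        )

        if outcome.is_degenerate:
            records.append(
                IterationRecord(
                    iteration=i,
                    subsample_indices=idx,
                    event_fraction=outcome.event_fraction,
                    fit_gt=None,
                    fit_alt=None,
                    comparison=None,
                    valid=False,
                    invalid_reason="degenerate_outcome",
                )
            )
            continue

        fit_gt = fit_alt = None
        comparison = None
        valid = True
        reason = ""
        try:
            if config.fit_models:
                fit_gt = fit_ntcp(d_gt, outcome.labels, config.fit_settings)
                fit_alt = fit_ntcp(d_alt, outcome.labels, config.fit_settings)
            if config.compare_models:
                comparison = bootstrap_compare(
                    d_gt,
                    d_alt,
                    outcome.labels,
                    n_boot=config.n_boot,
                    alpha=config.alpha,
                    rng=np.random.default_rng(boot_ss),
                    refit_in_bootstrap=config.refit_in_bootstrap,
                    fit_settings=config.fit_settings,
                )
        except (ValueError, RuntimeError, DegenerateOutcomeError) as exc:
            valid = False
            reason = f"failed_fit: {exc}"

        records.append(
            IterationRecord(
                iteration=i,
                subsample_indices=idx,
                event_fraction=outcome.event_fraction,
                fit_gt=fit_gt,
                fit_alt=fit_alt,
                comparison=comparison,
                valid=valid,
                invalid_reason=reason,
            )
        )

    n_invalid = sum(not r.valid for r in records)
    if n_invalid > config.max_invalid_fraction * len(records):
        raise RuntimeError(
            f"{n_invalid}/{len(records)} iterations invalid in cell "
            f"({cohort.parameter_name}, gamma={params.gamma}, n={cohort_size}); "
            "the simulation setting is degenerate"
        )
    summary = _summarize(
        records, cohort.parameter_name, params.gamma, params.d50, cohort_size
    )
    return records, summary


def run_sweep(
    cohorts: dict[str, DoseCohort],
    config: SimulationConfig,
    collect_iterations: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame | None]:
    """Sweep the full (parameter, gamma, cohort size) grid.

    Returns ``(summary, iterations)`` as tidy long-format tables: one summary
    row per grid cell and (optionally) one iterations row per Monte Carlo
    iteration.  Per-cell seeds are derived from ``master_seed`` and the cell
    coordinates, so any cell can be re-run in isolation.

    All cohorts must cover the same patients (one dosimetric parameter each).
    """
    if not cohorts:
        raise ValueError("no cohorts given")
    id_sets = {name: tuple(c.patient_ids) for name, c in cohorts.items()}
    reference = next(iter(id_sets.values()))
    for name, ids in id_sets.items():
        if set(ids) != set(reference):
            raise ValueError(
                f"cohort {name!r} covers a different patient set than the others"
            )

    summary_rows = []
    iter_rows = [] if collect_iterations else None
    for name, cohort in cohorts.items():
        if not cohort.normalized:
            raise ValueError(f"cohort {name!r} must be normalized before the sweep")
        sizes = config.cohort_sizes or (len(cohort),)
        for gamma in config.gamma_grid:
            params = NTCPParams(d50=config.d50, gamma=gamma)
            for size in sizes:
                records, summary = run_cell(cohort, params, config, cohort_size=size)
                summary_rows.append(summary)
                if iter_rows is not None:
                    for r in records:
                        row = r.to_row()
                        row.update(
                            parameter_name=name, gamma=gamma, cohort_size=size
                        )
                        iter_rows.append(row)

    summary_df = pd.DataFrame(summary_rows)
    iter_df = pd.DataFrame(iter_rows) if iter_rows is not None else None
    return summary_df, iter_df


def write_run_outputs(
    out_dir,
    summary: pd.DataFrame,
    iterations: pd.DataFrame | None,
    config: SimulationConfig,
) -> None:
    """Write ``summary.csv``, ``iterations.csv`` and ``run_meta.json``."""
    import pathlib

    import ntcpsim

    out = pathlib.Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary.to_csv(out / "summary.csv", index=False)
    if iterations is not None:
        iterations.to_csv(out / "iterations.csv", index=False)
    meta = {
        "config": config.to_dict(),
        "ntcpsim_version": ntcpsim.__version__,
        "numpy_version": np.__version__,
    }
    (out / "run_meta.json").write_text(json.dumps(meta, indent=2))
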