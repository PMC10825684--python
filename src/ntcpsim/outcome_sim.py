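"""Convert per-patient NTCP values into binary outcome labels.

Each Monte Carlo iteration draws one independent Bernoulli outcome per
patient from that patient's complication probability.  Both competing models
within an iteration are fitted to the *same* simulated labels, so the only
difference between them is the dose vector they see.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["OutcomeVector", "simulate_outcomes"]


@dataclass(frozen=True)
class OutcomeVector:
    """Binary outcome labels for one simulated cohort draw.

    ``rng_state_tag`` identifies the random substream that produced the draw,
    for traceability in multi-stream Monte Carlo runs.
    """

    labels: np.ndarray
    event_fraction: float
    rng_state_tag: str = ""

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels, dtype=np.int8)
        object.__setattr__(self, "labels", labels)
        if not np.all((labels == 0) | (labels == 1)):
            raise ValueError("labels must be binary")

    @property
    def is_degenerate(self) -> bool:
        """True when all labels agree (all events or all non-events)."""
        return self.labels.min() == self.labels.max()

    def __len__(self) -> int:
        return len(self.labels)


def simulate_outcomes(
    ntcp_values, rng: np.random.Generator, rng_state_tag: str = ""
) -> OutcomeVector:
    """Draw ``label_i ~ Bernoulli(ntcp_i)`` independently across patients.

    Reproducible: the same generator state yields bit-identical labels.

    Raises
    ------
    ValueError
        If any probability lies outside [0, 1].
    """
    p = np.asarray(ntcp_values, dtype=float)
    if p.ndim != 1 or len(p) == 0:
        raise ValueError("ntcp_values must be a non-empty 1-D vector")
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValueError("ntcp values must lie in [0, 1]")
    labels = (rng.random(len(p)) < p).astype(np.int8)
    return OutcomeVector(
        labels=labels,
        event_fraction=float(labels.mean()),
        rng_state_tag=rng_state_tag,
    )
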