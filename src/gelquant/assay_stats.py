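"""Viability, apoptosis and collagen-degradation percentages.

Counting assays score a fixed number of reference cells per field
(the 100% denominator) and the positive cells among them; fluorescent
degradation assays express the sample signal relative to the
background (no cells) and the total-degradation control
(collagenase-treated).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "FieldCounts",
    "DegradationReadout",
    "PercentSummary",
    "viability_percent",
    "apoptosis_percent",
    "degradation_percent",
]


@dataclass
class FieldCounts:
    """Per-field cell counts of a staining assay.

    ``n_reference`` cells (typically 100) are counted per field in the
    reference channel; ``n_positive`` of them are positive in the
    marker channel (propidium iodide for death, caspase-3/7 for
    apoptosis).
    """

    n_reference: np.ndarray  # per field
    n_positive: np.ndarray  # per field

    def __post_init__(self) -> None:
        self.n_reference = np.atleast_1d(np.asarray(self.n_reference, dtype=int))
        self.n_positive = np.atleast_1d(np.asarray(self.n_positive, dtype=int))
        if self.n_reference.shape != self.n_positive.shape:
            raise ValueError("per-field count arrays must match in length")
        if len(self.n_reference) < 1:
            raise ValueError("at least one field is required")
        if (self.n_reference <= 0).any():
            raise ValueError("reference counts must be positive")
        if ((self.n_positive < 0) | (self.n_positive > self.n_reference)).any():
            raise ValueError("positive counts must lie in [0, n_reference]")

    @property
    def n_fields(self) -> int:
        return len(self.n_reference)


@dataclass
class DegradationReadout:
    """Fluorescence readout (RFU) of a collagen-degradation assay."""

    sample_rfu: float
    background_rfu: float  # no-cell control
    total_rfu: float  # collagenase-treated total-degradation control

    def __post_init__(self) -> None:
        if self.total_rfu <= self.background_rfu:
            raise ValueError("total_rfu must exceed background_rfu")


@dataclass
class PercentSummary:
    mean: float
    sd: float
    per_field: np.ndarray


def viability_percent(counts: FieldCounts) -> PercentSummary:
    """Percent viable cells: 100 × (1 − positive/reference) per field.

    The percentage is taken per field first and then averaged, so the
    per-field death percentage and viability always sum to 100.
    """
    per_field = 100.0 * (1.0 - counts.n_positive / counts.n_reference)
    return PercentSummary(float(per_field.mean()),
                          float(per_field.std(ddof=1)) if len(per_field) > 1 else 0.0,
                          per_field)


def apoptosis_percent(counts: FieldCounts) -> PercentSummary:
    """Percent apoptotic (marker-positive) cells per field, averaged."""
    per_field = 100.0 * counts.n_positive / counts.n_reference
    return PercentSummary(float(per_field.mean()),
                          float(per_field.std(ddof=1)) if len(per_field) > 1 else 0.0,
                          per_field)


def degradation_percent(readout: DegradationReadout) -> float:
    """Collagen degradation relative to the collagenase total, percent.

    100 × (sample − background) / (total − background), clipped into
    [0, 100] with a warning when noise pushes the raw value outside
    the physical range.
    """
    raw = 100.0 * (readout.sample_rfu - readout.background_rfu) / (
        readout.total_rfu - readout.background_rfu)
    if raw < 0.0 or raw > 100.0:
        warnings.warn(f"degradation {raw:.2f}% outside [0, 100]; clipped",
                      stacklevel=2)
    return float(np.clip(raw, 0.0, 100.0))
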