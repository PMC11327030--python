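"""Invasion-depth profiling of cells in a 3D gel.

Depths are measured from the top of the gel; the depth range is
divided into equal "quartile" bins (250 μm each by default, with
750 μm taken as the maximum counted distance) and cells are counted
per bin.  The cohort's central tendency is the median depth with an
order-statistic (binomial) 95% confidence interval.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "InvasionProfile",
    "depths_from_positions",
    "quartile_counts",
    "median_depth",
]


@dataclass
class InvasionProfile:
    """Binned invasion-depth profile of one condition."""

    depths: np.ndarray  # μm, after clamping into [0, max_depth]
    bin_width: float  # μm
    max_depth: float  # μm
    bin_edges: np.ndarray  # len n_bins + 1
    counts: np.ndarray  # cells per bin; conserves the cohort size
    fractions: np.ndarray  # counts / n_cells (NaN-free only when n > 0)
    median: float  # μm; NaN for an empty cohort
    median_ci: tuple[float, float]  # 95% CI; NaN bounds when undefined
    mean: float  # μm; reported alongside the median

    @property
    def n_cells(self) -> int:
        return int(self.counts.sum())


def depths_from_positions(
    z_positions: np.ndarray,
    gel_top: float,
    deeper_is_positive: bool = True,
) -> np.ndarray:
    """Depths (μm) of cells below the gel surface.

    depth = ±(z − gel_top), signed so that deeper is positive.  Cells
    located above the top (negative depth, e.g. from segmentation
    jitter) are clamped to 0 with a warning.
    """
    z = np.asarray(z_positions, dtype=float)
    if not np.all(np.isfinite(z)):
        raise ValueError("z positions must be finite")
    depths = (z - gel_top) if deeper_is_positive else (gel_top - z)
    n_above = int((depths < 0).sum())
    if n_above:
        warnings.warn(f"{n_above} cell(s) above the gel top clamped to depth 0",
                      stacklevel=2)
        depths = np.maximum(depths, 0.0)
    return depths


def quartile_counts(
    depths: np.ndarray,
    bin_width: float = 250.0,
    max_depth: float = 750.0,
) -> InvasionProfile:
    """Count cells per equal-width depth bin.

    Bins are half-open [a, b) with the final bin closed at
    ``max_depth``; depths beyond ``max_depth`` are clamped into the
    final bin (logged, not discarded), so the counts always conserve
    the cohort.  Defaults give the three counted 250 μm bins up to a
    750 μm maximum; ``max_depth=1000`` gives four true quartiles of a
    1,000 μm gel.
    """
    if bin_width <= 0 or max_depth <= 0:
        raise ValueError("bin_width and max_depth must be positive")
    depths = np.asarray(depths, dtype=float)
    if (depths < 0).any():
        raise ValueError("depths must be non-negative")
    n_bins = max(int(math.ceil(max_depth / bin_width)), 1)
    edges = np.minimum(np.arange(n_bins + 1) * bin_width, max_depth)

    n_deep = int((depths > max_depth).sum())
    if n_deep:
        warnings.warn(
            f"{n_deep} cell(s) deeper than {max_depth} μm clamped into the last bin",
            stacklevel=2)
    clamped = np.minimum(depths, max_depth)
    if len(clamped):
        idx = np.minimum((clamped // bin_width).astype(int), n_bins - 1)
        counts = np.bincount(idx, minlength=n_bins)
    else:
        counts = np.zeros(n_bins, dtype=int)
    med, ci = median_depth(clamped) if len(clamped) else (float("nan"),
                                                          (float("nan"), float("nan")))
    return InvasionProfile(
        depths=clamped,
        bin_width=bin_width,
        max_depth=max_depth,
        bin_edges=edges,
        counts=counts,
        fractions=counts / len(clamped) if len(clamped) else np.full(n_bins, np.nan),
        median=med,
        median_ci=ci,
        mean=float(clamped.mean()) if len(clamped) else float("nan"),
    )


def median_depth(depths: np.ndarray) -> tuple[float, tuple[float, float]]:
    """Sample median with a distribution-free 95% confidence interval.

    The CI uses the standard order-statistic construction: with n
    observations, the interval [x_(j), x_(k)] where j and k are the
    0.025 and 0.975 quantiles of Binomial(n, ½).  A single observation
    returns a degenerate interval.
    """
    depths = np.asarray(depths, dtype=float)
    if len(depths) == 0:
        raise ValueError("median of an empty sample is undefined")
    s = np.sort(depths)
    n = len(s)
    med = float(np.median(s))
    if n == 1:
        return med, (med, med)
    j = int(stats.binom.ppf(0.025, n, 0.5))          # 0-based lower index
    k = int(stats.binom.isf(0.025, n, 0.5))          # 0-based upper index
    k = min(k, n - 1)
    return med, (float(s[j]), float(s[k]))
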