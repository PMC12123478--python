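"""Spatial segregation coefficient (SC) between two strains' zone counts.

SC compares the observed between-strain co-occurrence across zones with the
expectation under random mixing: 0 means complete spatial overlap (or a
single remaining strain), 1 means complete segregation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .tide_habitat import N_ZONES


@dataclass(frozen=True)
class ZoneCounts:
    """Per-zone larval counts for two strains."""

    x: np.ndarray
    y: np.ndarray

    def __post_init__(self) -> None:
        x = np.asarray(self.x, dtype=float)
        y = np.asarray(self.y, dtype=float)
        if x.shape != y.shape:
            raise ValueError("x and y must have the same shape")
        if np.any(x < 0) or np.any(y < 0):
            raise ValueError("counts must be non-negative")
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "y", y)


def segregation_coefficient(counts: ZoneCounts, corrected: bool = False) -> float:
    """Segregation coefficient SC in [0, 1].

    ``SC = 1 - (N / (X * Y)) * sum_z x_z * y_z / n_z`` with ``X = sum x``,
    ``Y = sum y``, ``n_z = x_z + y_z`` and ``N = X + Y``; empty zones
    contribute nothing.  If either strain is globally absent SC is 0 by
    convention.  ``corrected=True`` applies a finite-count pairing
    correction (``(N - 1)`` and ``(n_z - 1)`` in place of ``N`` and ``n_z``)
    for sensitivity checks only.
    """
    x, y = counts.x, counts.y
    X, Y = x.sum(), y.sum()
    N = X + Y
    if N == 0:
        raise ValueError("all-zero zone counts")
    if X == 0 or Y == 0:
        return 0.0
    n = x + y
    occ = n > (1 if corrected else 0)
    if corrected:
        mix = ((N - 1) / (X * Y)) * np.sum(x[occ] * y[occ] / (n[occ] - 1))
    else:
        mix = (N / (X * Y)) * np.sum(x[occ] * y[occ] / n[occ])
    sc = 1.0 - mix
    return float(min(1.0, max(0.0, sc)))


def time_averaged_sc(trace_x: np.ndarray, trace_y: np.ndarray,
                     corrected: bool = False) -> float:
    """SC over a 28-day cycle, pooling counts per zone over days.

    ``trace_x`` / ``trace_y`` have shape (28, 6): daily per-zone counts for
    each strain.  Pooling (rather than averaging daily SCs) keeps the
    statistic defined even on days when one strain has no larvae anywhere.
    """
    trace_x = np.asarray(trace_x, dtype=float)
    trace_y = np.asarray(trace_y, dtype=float)
    if trace_x.shape != (28, N_ZONES) or trace_y.shape != (28, N_ZONES):
        raise ValueError("traces must have shape (28, 6)")
    pooled = ZoneCounts(x=trace_x.sum(axis=0), y=trace_y.sum(axis=0))
    return segregation_coefficient(pooled, corrected=corrected)
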