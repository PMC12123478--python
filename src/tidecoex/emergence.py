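"""Strain timing traits: emergence peak day, window, and per-day weights.

A strain is characterised by the cycle day on which its adult emergence
peaks.  Emergence spans a 9-day window (peak - 4 .. peak + 4, wrapped around
the 28-day cycle) and the fraction emerging on each window day follows a
symmetric Beta(shape, shape) distribution discretised over nine equal
sub-intervals of [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .tide_habitat import CYCLE_DAYS

WINDOW_LEN = 9
#: Days before the window start at which final-stage maturation is triggered.
GATE_LEAD_DAYS = 16


def _wrap_day(day: int) -> int:
    return (day - 1) % CYCLE_DAYS + 1


@dataclass(frozen=True)
class StrainTiming:
    """Timing trait of one strain.

    Attributes
    ----------
    peak_day : int
        Cycle day (1..28) of peak emergence.
    shape : float
        Common Beta shape parameter; larger values concentrate emergence
        around the peak, shape 1 gives uniform emergence over the window.
    window_days : tuple of int
        The nine cycle days peak-4 .. peak+4, wrapped into 1..28.
    weights : numpy.ndarray
        Per-window-day emergence fractions; non-negative, sum to 1.
    """

    peak_day: int
    shape: float
    window_days: tuple
    weights: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "weights", np.asarray(self.weights, dtype=float))
        if len(self.window_days) != WINDOW_LEN:
            raise ValueError("window must span exactly 9 days")
        if abs(self.weights.sum() - 1.0) > 1e-12:
            raise ValueError("weights must sum to 1")


def emergence_weights(peak_day: int, shape: float) -> StrainTiming:
    """Build a strain's timing trait from its peak day and Beta shape.

    The weight of window slot ``k`` (k = 0..8) is the Beta(shape, shape)
    probability mass of the sub-interval ``[k/9, (k+1)/9]`` (CDF differences,
    which normalises exactly).  Slot ``k`` maps to cycle day
    ``peak_day - 4 + k`` wrapped into 1..28.
    """
    if not 1 <= peak_day <= CYCLE_DAYS:
        raise ValueError("peak_day must lie in 1..28")
    if shape <= 0:
        raise ValueError("shape must be positive")
    edges = np.linspace(0.0, 1.0, WINDOW_LEN + 1)
    cdf = stats.beta.cdf(edges, shape, shape)
    weights = np.diff(cdf)
    window_days = tuple(_wrap_day(peak_day - 4 + k) for k in range(WINDOW_LEN))
    return StrainTiming(
        peak_day=peak_day, shape=float(shape), window_days=window_days, weights=weights
    )


def window_start(timing: StrainTiming) -> int:
    """First day of the emergence window (peak - 4, wrapped into 1..28)."""
    return _wrap_day(timing.peak_day - 4)


def window_slot(timing: StrainTiming, cycle_day: int) -> int | None:
    """Slot index 0..8 if ``cycle_day`` is a window day, else ``None``."""
    k = (cycle_day - window_start(timing)) % CYCLE_DAYS
    return k if k < WINDOW_LEN else None
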