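"""Pairwise invasion experiments over emergence-timing combinations.

A resident strain is established to its attractor, a rare invader with a
different (or equal) emergence peak is introduced at 1% by proportional
relabelling, and the coupled dynamics are iterated until the 28-day-mean
resident frequency stabilises (or a 100-year cap).  Outcomes are classified
as coexistence, invader wins, or invader fails, and the terminal spatial
segregation between the two larval populations is recorded.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .emergence import StrainTiming, emergence_weights
from .population_dynamics import (
    DynamicsParams,
    PopulationState,
    N_STAGES,
    N_STRAINS,
    N_ZONES,
    _emergence_fractions,
    _step_day_inplace,
)
from .segregation_stats import ZoneCounts, segregation_coefficient
from .tide_habitat import CYCLE_DAYS, TidalSchedule, build_tidal_schedule

OUTCOME_COEXISTENCE = "coexistence"
OUTCOME_INVADER_WINS = "invader_wins"
OUTCOME_INVADER_FAILS = "invader_fails"
OUTCOME_BOTH_EXTINCT = "both_extinct"


class NonViableResidentError(RuntimeError):
    """The resident went extinct during burn-in (non-viable parameters)."""


@dataclass
class InvasionProtocol:
    """Protocol constants for a pairwise-invasion run.

    ``tol`` is the convergence criterion on the change of the 28-day-mean
    resident frequency between consecutive cycles.  A strain whose global
    larval count drops below ``extinction_threshold`` is zeroed out.  An
    invader that survives but never exceeds ``identical_factor`` times its
    initial fraction is classed as a failed invasion (captures the neutral
    identical-timing case without a drift model).
    """

    invader_init_frac: float = 0.01
    tol: float = 1e-5
    max_years: int = 100
    days_per_year: int = 364  # 13 cycles of 28 days
    burn_in_cycles: int = 26
    extinction_threshold: float = 10.0
    seed_density: float = 1000.0
    identical_factor: float = 2.0

    def __post_init__(self) -> None:
        if not 0 < self.invader_init_frac < 1:
            raise ValueError("invader_init_frac must lie in (0, 1)")
        if self.tol <= 0:
            raise ValueError("tol must be positive")
        if self.extinction_threshold <= 0:
            raise ValueError("extinction_threshold must be positive")

    @property
    def max_cycles(self) -> int:
        return self.max_years * self.days_per_year // CYCLE_DAYS


@dataclass
class InvasionResult:
    """Terminal summary of one invasion experiment."""

    resident_freq: float
    invader_freq: float
    outcome: str
    sc: float
    cycles_elapsed: int
    converged: bool
    resident_day: int | None = None
    invader_day: int | None = None

    def to_dict(self) -> dict:
        return {
            "resident_day": self.resident_day,
            "invader_day": self.invader_day,
            "outcome": self.outcome,
            "resident_freq": self.resident_freq,
            "invader_freq": self.invader_freq,
            "sc": self.sc,
            "cycles": self.cycles_elapsed,
            "converged": self.converged,
        }


def establish_resident(
    timing: StrainTiming,
    params: DynamicsParams,
    protocol: InvasionProtocol,
    schedule: TidalSchedule | None = None,
) -> PopulationState:
    """Seed the resident uniformly and run burn-in to its attractor.

    ``seed_density`` stage-0 larvae are placed in every zone and the
    dynamics run for at least ``burn_in_cycles`` full cycles, extending (up
    to 4x) until the cycle-mean total population changes by less than
    ``tol`` relatively between consecutive cycles.
    """
    schedule = schedule or build_tidal_schedule()
    larvae = np.zeros((N_STRAINS, N_ZONES, N_STAGES))
    larvae[0, :, 0] = protocol.seed_density
    state = PopulationState(larvae=larvae, day=1)
    if protocol.burn_in_cycles == 0:
        return state
    timings = (timing, timing)
    frac = np.stack([_emergence_fractions(t) for t in timings])
    prev_total = None
    max_cycles = max(20 * protocol.burn_in_cycles, protocol.burn_in_cycles)
    for cycle in range(1, max_cycles + 1):
        day_totals = 0.0
        for _ in range(CYCLE_DAYS):
            _step_day_inplace(state.larvae, state.day, params, timings, schedule, frac)
            state.day += 1
            day_totals += state.larvae.sum()
        mean_total = day_totals / CYCLE_DAYS
        if mean_total < protocol.extinction_threshold:
            raise NonViableResidentError(
                "resident extinct during burn-in; check viability bound "
                f"s_max**(21/r)*C = {params.viability_index():.3g}"
            )
        if (
            cycle >= protocol.burn_in_cycles
            and prev_total is not None
            and abs(mean_total - prev_total) < protocol.tol * prev_total
        ):
            break
        prev_total = mean_total
    return state


def introduce_invader(
    state: PopulationState, frac: float, rng: np.random.Generator | None = None
) -> PopulationState:
    """Relabel a fraction ``frac`` of every resident cell as invader.

    Preserves the total count and the spatial/stage distribution exactly, so
    the invader's global frequency is exactly ``frac``.  With ``rng`` the
    relabelling is a per-cell binomial draw (keeps integer counts for the
    stochastic mode, frequency exact in expectation).
    """
    if not 0 <= frac < 1:
        raise ValueError("frac must lie in [0, 1)")
    if state.larvae[1].sum() > 0:
        raise ValueError("state already contains an invader strain")
    out = state.copy()
    if rng is not None:
        out.larvae[1] = rng.binomial(out.larvae[0].astype(np.int64), frac)
    else:
        out.larvae[1] = frac * out.larvae[0]
    out.larvae[0] -= out.larvae[1]
    return out


def run_invasion(
    resident: StrainTiming | int,
    invader: StrainTiming | int,
    params: DynamicsParams,
    protocol: InvasionProtocol | None = None,
    schedule: TidalSchedule | None = None,
    resident_state: PopulationState | None = None,
) -> InvasionResult:
    """Run one pairwise-invasion experiment to termination.

    ``resident`` / ``invader`` may be peak days (built with the shared Beta
    shape 2) or full :class:`StrainTiming` objects.  ``resident_state``
    allows reusing one burn-in across invaders with the same resident.
    """
    protocol = protocol or InvasionProtocol()
    schedule = schedule or build_tidal_schedule()
    if isinstance(resident, (int, np.integer)):
        resident = emergence_weights(int(resident), 2.0)
    if isinstance(invader, (int, np.integer)):
        invader = emergence_weights(int(invader), 2.0)
    if resident_state is None:
        resident_state = establish_resident(resident, params, protocol, schedule)
    intro_rng = params.rng if params.mode == "stochastic" else None
    state = introduce_invader(resident_state, protocol.invader_init_frac, rng=intro_rng)

    timings = (resident, invader)
    frac = np.stack([_emergence_fractions(t) for t in timings])
    larvae = state.larvae
    day = state.day
    prev_mean: float | None = None
    converged = False
    small_deltas = 0  # consecutive sub-tolerance changes (guards transients)
    cycles = 0
    freq_sum = 0.0
    freq_days = 0
    zone_pool = np.zeros((N_STRAINS, N_ZONES))
    for cycle in range(1, protocol.max_cycles + 1):
        freq_sum = 0.0
        freq_days = 0
        zone_pool[:] = 0.0
        for _ in range(CYCLE_DAYS):
            _step_day_inplace(larvae, day, params, timings, schedule, frac)
            day += 1
            totals = larvae.sum(axis=(1, 2))
            # extinction is absorbing: zero a strain as soon as it dips below
            # the threshold so continuous tails cannot linger forever
            for s in range(N_STRAINS):
                if 0 < totals[s] < protocol.extinction_threshold:
                    larvae[s] = 0.0
                    totals[s] = 0.0
            grand = totals.sum()
            if grand > 0:
                freq_sum += totals[0] / grand
                freq_days += 1
            zone_pool += larvae.sum(axis=2)
        cycles = cycle
        if freq_days == 0:
            break  # both strains extinct
        mean_freq = freq_sum / freq_days
        if prev_mean is not None and abs(mean_freq - prev_mean) < protocol.tol:
            small_deltas += 1
            # demand two consecutive sub-tol changes: deterministic
            # trajectories can pass through flat turning points early on
            if small_deltas >= 2:
                converged = True
                break
        else:
            small_deltas = 0
        prev_mean = mean_freq

    totals = larvae.sum(axis=(1, 2))
    resident_alive = totals[0] >= protocol.extinction_threshold
    invader_alive = totals[1] >= protocol.extinction_threshold
    if freq_days > 0:
        resident_freq = freq_sum / freq_days
    else:
        resident_freq = float("nan")
    invader_freq = 1.0 - resident_freq if freq_days > 0 else float("nan")

    if not resident_alive and not invader_alive:
        outcome = OUTCOME_BOTH_EXTINCT
    elif not resident_alive:
        outcome = OUTCOME_INVADER_WINS
    elif not invader_alive:
        outcome = OUTCOME_INVADER_FAILS
        resident_freq, invader_freq = 1.0, 0.0
    elif invader_freq < protocol.identical_factor * protocol.invader_init_frac:
        # invader persists but never grew beyond (a factor of) its inoculum
        outcome = OUTCOME_INVADER_FAILS
    else:
        outcome = OUTCOME_COEXISTENCE

    sc = segregation_coefficient(ZoneCounts(x=zone_pool[0], y=zone_pool[1]))
    return InvasionResult(
        resident_freq=float(resident_freq),
        invader_freq=float(invader_freq),
        outcome=outcome,
        sc=sc,
        cycles_elapsed=cycles,
        converged=converged,
        resident_day=resident.peak_day,
        invader_day=invader.peak_day,
    )


def invasion_grid(
    params: DynamicsParams,
    protocol: InvasionProtocol | None = None,
    resident_days=None,
    invader_days=None,
    shape: float = 2.0,
    schedule: TidalSchedule | None = None,
    progress: bool = False,
) -> pd.DataFrame:
    """Full (or strided) factorial of pairwise invasions.

    Returns a long-format frame with one row per (resident_day,
    invader_day) cell: outcome, terminal frequencies, SC, cycles, converged.
    The resident burn-in is computed once per resident day and reused for
    every invader.  Per-cell failures are recorded as flagged rows rather
    than aborting the sweep.
    """
    protocol = protocol or InvasionProtocol()
    schedule = schedule or build_tidal_schedule()
    resident_days = list(resident_days or range(1, CYCLE_DAYS + 1))
    invader_days = list(invader_days or range(1, CYCLE_DAYS + 1))
    rows = []
    for rd in resident_days:
        r_timing = emergence_weights(rd, shape)
        try:
            base_state = establish_resident(r_timing, params, protocol, schedule)
        except NonViableResidentError as exc:
            for idv in invader_days:
                rows.append(
                    {
                        "resident_day": rd,
                        "invader_day": idv,
                        "outcome": "error",
                        "resident_freq": math.nan,
                        "invader_freq": math.nan,
                        "sc": math.nan,
                        "cycles": 0,
                        "converged": False,
                        "error": str(exc),
                    }
                )
            continue
        for idv in invader_days:
            i_timing = emergence_weights(idv, shape)
            try:
                res = run_invasion(
                    r_timing,
                    i_timing,
                    params,
                    protocol,
                    schedule,
                    resident_state=base_state.copy(),
                )
                row = res.to_dict()
                row["error"] = ""
            except Exception as exc:  # pragma: no cover - defensive
                row = {
                    "resident_day": rd,
                    "invader_day": idv,
                    "outcome": "error",
                    "resident_freq": math.nan,
                    "invader_freq": math.nan,
                    "sc": math.nan,
                    "cycles": 0,
                    "converged": False,
                    "error": str(exc),
                }
            rows.append(row)
        if progress:
            print(f"resident day {rd} done", flush=True)
    return pd.DataFrame(rows)


DEFAULT_SC_CUTS = (0.05, 0.5)


def bin_by_segregation(
    grid: pd.DataFrame, cuts: tuple[float, float] = DEFAULT_SC_CUTS
) -> pd.DataFrame:
    """Bin grid cells into four SC categories and summarise minority frequency.

    SC = 0 cells form their own bin (extinction forces SC to zero, so
    causality is ambiguous there); the remaining cells are split into
    low-but-nonzero (0, cuts[0]], middle (cuts[0], cuts[1]], and high
    (cuts[1], 1] bins.  Returns per-bin count, mean and standard error of
    the minority-strain terminal frequency.
    """
    if grid.empty:
        raise ValueError("empty grid")
    df = grid.copy()
    df["minority_freq"] = df[["resident_freq", "invader_freq"]].min(axis=1)
    lo, hi = cuts

    def _bin(sc: float) -> str:
        if not np.isfinite(sc):
            return "invalid"
        if sc == 0:
            return "zero"
        if sc <= lo:
            return "low"
        if sc <= hi:
            return "middle"
        return "high"

    df["sc_bin"] = df["sc"].map(_bin)
    out = []
    for name in ("zero", "low", "middle", "high"):
        sub = df[df["sc_bin"] == name]
        n = len(sub)
        mean = float(sub["minority_freq"].mean()) if n else math.nan
        se = float(sub["minority_freq"].std(ddof=1) / math.sqrt(n)) if n > 1 else math.nan
        out.append({"sc_bin": name, "n": n, "mean_minority_freq": mean, "se": se})
    return pd.DataFrame(out)
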