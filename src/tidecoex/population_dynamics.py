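"""Daily update engine for two strains of female larvae over six beach zones.

State is the continuous (expected-value) count of female offspring indexed by
(strain, zone, developmental stage 0..21).  Stage 0 is the egg/hatchling
stage laid at oviposition; stages 1..20 are feeding larval stages advancing
with daily probability ``r``; stage 20 matures to the non-feeding final
stage 21 on a strain-specific gate day 16 days before the emergence window.
Each simulated day applies, in fixed order: density-dependent survival,
stage transitions, emergence of final-stage larvae into adults, adult
migration (obligatory upward to the waterline if submerged, waterline-seeking
downward otherwise), and oviposition.  A seeded stochastic mode with integer
counts is available for convergence checks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .emergence import GATE_LEAD_DAYS, WINDOW_LEN, StrainTiming, window_start
from .tide_habitat import CYCLE_DAYS, N_ZONES, AlphaProfile, TidalSchedule, build_alpha_profile

N_STAGES = 22  # developmental stages 0..21 (0 = egg)
N_STRAINS = 2
STRAIN_LABELS = ("R", "I")
#: Number of r-driven stage transitions used for the development-time bound.
N_TRANSITIONS = 21
#: First stage subject to density-dependent (resource competition) mortality.
#: Stage-0 eggs are counted in zone density but do not yet feed, so they
#: suffer only the baseline mortality 1 - s_max.
FIRST_FEEDING_STAGE = 1


@dataclass
class DynamicsParams:
    """Parameters of the daily dynamics.

    ``C`` daughters per female, ``r`` daily stage-transition probability,
    ``s_max`` density-independent daily survival, ``alpha`` per-zone
    density-dependence strengths, ``m`` downward-migration propensity
    (fraction of the distance to the waterline covered; ``m = 1`` places
    every female at the water's edge).
    """

    C: float = 50.0
    r: float = 0.45
    s_max: float = 0.99
    alpha: AlphaProfile = field(default_factory=build_alpha_profile)
    m: float = 0.5
    mode: str = "deterministic"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.r <= 1:
            raise ValueError("r must lie in (0, 1]")
        if not 0 < self.s_max <= 1:
            raise ValueError("s_max must lie in (0, 1]")
        if not 0 <= self.m <= 1:
            raise ValueError("m must lie in [0, 1]")
        if self.C <= 0:
            raise ValueError("C must be positive")
        if self.mode not in ("deterministic", "stochastic"):
            raise ValueError("mode must be deterministic or stochastic")
        if self.viability_index() <= 1.0:
            warnings.warn(
                "non-viable parameters: the population cannot replace itself "
                "even without density dependence "
                f"(viability index {self.viability_index():.3g} <= 1)",
                stacklevel=2,
            )
        self._rng = np.random.default_rng(self.seed)

    def viability_index(self) -> float:
        """Crude replacement bound ``s_max**(21/r) * C`` (must exceed 1).

        The true requirement is stricter because final-stage larvae also
        wait out the 16-day pre-window period plus up to one cycle at the
        stage-20 gate; at the defaults (s_max = 0.99) both bounds hold.
        """
        return self.s_max ** (N_TRANSITIONS / self.r) * self.C

    @property
    def rng(self) -> np.random.Generator:
        return self._rng


@dataclass
class PopulationState:
    """Counts of female larvae by (strain, zone, stage) plus a day counter.

    ``larvae[s, z, i]`` holds strain ``s`` (0 = resident, 1 = invader) in
    zone ``z + 1`` at stage ``i``.  ``day`` is the global 1-based day.
    """

    larvae: np.ndarray
    day: int = 1

    def __post_init__(self) -> None:
        self.larvae = np.asarray(self.larvae, dtype=float)
        if self.larvae.shape != (N_STRAINS, N_ZONES, N_STAGES):
            raise ValueError("larvae must have shape (2, 6, 22)")
        if np.any(self.larvae < 0):
            raise ValueError("counts must be non-negative")

    @property
    def cycle_day(self) -> int:
        """Day within the 28-day cycle, in 1..28."""
        return (self.day - 1) % CYCLE_DAYS + 1

    def strain_totals(self) -> np.ndarray:
        """Global larval count per strain, shape (2,)."""
        return self.larvae.sum(axis=(1, 2))

    def zone_totals(self) -> np.ndarray:
        """Larval count per strain and zone, shape (2, 6)."""
        return self.larvae.sum(axis=2)

    def copy(self) -> "PopulationState":
        return PopulationState(larvae=self.larvae.copy(), day=self.day)


def empty_state(day: int = 1) -> PopulationState:
    return PopulationState(larvae=np.zeros((N_STRAINS, N_ZONES, N_STAGES)), day=day)


def daily_survival_fraction(N_total: float, alpha_z: float, s_max: float) -> float:
    """Daily survival under density dependence: ``s_max * exp(-alpha_z * N**2)``.

    The squared density keeps survival near ``s_max`` until competitor
    numbers become large, then drives it down sharply.
    """
    if N_total < 0:
        raise ValueError("N_total must be non-negative")
    return float(s_max * np.exp(-alpha_z * N_total**2))


def _survival_factors(larvae: np.ndarray, params: DynamicsParams) -> np.ndarray:
    """Per-zone survival fractions from the pre-survival zone totals."""
    n_z = larvae.sum(axis=(0, 2))  # all strains, all stages share one density
    return params.s_max * np.exp(-params.alpha.alpha * n_z**2)


def apply_survival(state: PopulationState, params: DynamicsParams) -> PopulationState:
    """Apply daily mortality zone by zone.

    All same-zone individuals contribute to the density ``N_Lz`` regardless
    of strain and stage, and all feeding stages (1..21) are scaled by the
    same zone-specific survival fraction.  Stage-0 eggs do not feed yet and
    survive at the density-independent rate ``s_max``; exempting them is
    what makes an established strain's own egg pulse fall on its offspring's
    later (feeding) days rather than on the day of laying.
    """
    out = state.copy()
    _apply_survival_inplace(out.larvae, params)
    return out


def _apply_survival_inplace(larvae: np.ndarray, params: DynamicsParams) -> None:
    s_z = _survival_factors(larvae, params)
    if params.mode == "stochastic":
        counts = larvae.astype(np.int64)
        larvae[:, :, FIRST_FEEDING_STAGE:] = params.rng.binomial(
            counts[:, :, FIRST_FEEDING_STAGE:], s_z[None, :, None]
        )
        larvae[:, :, 0] = params.rng.binomial(counts[:, :, 0], params.s_max)
    else:
        larvae[:, :, FIRST_FEEDING_STAGE:] *= s_z[None, :, None]
        larvae[:, :, 0] *= params.s_max


def _gate_day(timing: StrainTiming) -> int:
    """Cycle day on which the stage-20 pool matures to stage 21.

    This is the day exactly ``GATE_LEAD_DAYS`` (16) days before the strain's
    next emergence-window start, so every gated larva waits out the full
    16-day final-stage period before its window opens.
    """
    return (window_start(timing) - 1 - GATE_LEAD_DAYS) % CYCLE_DAYS + 1


def advance_stages(
    state: PopulationState,
    params: DynamicsParams,
    timings: tuple[StrainTiming, StrainTiming],
) -> PopulationState:
    """Daily stage transitions.

    Stages 0..19 advance one stage with probability ``r`` (a deterministic
    fraction ``r`` in expected-value mode).  Stage 20 ignores ``r``: the
    whole pool jumps to stage 21 on the day 16 days before the strain's next
    emergence-window start, and is static otherwise.  Stage 21 is held for
    emergence.  Same-day arrivals into stage 20 wait for the next gate day.
    """
    out = state.copy()
    _advance_stages_inplace(out.larvae, state.cycle_day, params, timings)
    return out


def _advance_stages_inplace(
    larvae: np.ndarray,
    cycle_day: int,
    params: DynamicsParams,
    timings: tuple[StrainTiming, StrainTiming],
) -> None:
    if params.mode == "stochastic":
        moved = params.rng.binomial(larvae[:, :, :20].astype(np.int64), params.r)
    else:
        moved = params.r * larvae[:, :, :20]
    gate20 = larvae[:, :, 20].copy()
    larvae[:, :, :20] -= moved
    larvae[:, :, 1:21] += moved
    for s, timing in enumerate(timings):
        if cycle_day == _gate_day(timing):
            larvae[s, :, 21] += gate20[s]
            larvae[s, :, 20] -= gate20[s]


def _emergence_fractions(timing: StrainTiming) -> np.ndarray:
    """Fraction of the stage-21 pool emerging on each cycle day (length 28).

    On window day with slot ``k`` the pool releases ``w_k / sum_{j>=k} w_j``
    of its current size, so a pool present for the whole window is split
    across days in proportion to the Beta weights and is empty afterwards.
    """
    frac = np.zeros(CYCLE_DAYS)
    w = timing.weights
    tail = np.cumsum(w[::-1])[::-1]
    ws = window_start(timing)
    for k in range(WINDOW_LEN):
        day = (ws - 1 + k) % CYCLE_DAYS
        frac[day] = w[k] / tail[k] if tail[k] > 0 else 0.0
    return frac


def emerge_adults(
    state: PopulationState, timing: StrainTiming, strain: int = 0
) -> tuple[PopulationState, np.ndarray]:
    """Release today's emergence fraction of one strain's stage-21 pool.

    Returns the updated state and the per-zone adult counts (length 6).
    Outside the window nothing emerges; on the last window day the pool
    empties completely.
    """
    out = state.copy()
    frac = _emergence_fractions(timing)[state.cycle_day - 1]
    adults = frac * out.larvae[strain, :, 21]
    out.larvae[strain, :, 21] -= adults
    return out, adults


def _migration_matrix(H_t: int, m: float) -> np.ndarray:
    """Zone-relocation matrix for emerged adults (rows: origin, cols: target).

    Zones below the waterline (z > H_t) are submerged: their adults move up
    to the lowermost exposed zone z = H_t.  Adults above the waterline are
    drawn toward the water's edge: they cover a fraction ``m`` of their
    zone-distance to the waterline, with the fractional remainder split
    between the two adjacent zones (so one zone above the waterline a
    proportion ``m`` steps down and 1 - m stays; ``m = 1`` brings everybody
    to the water's edge).
    """
    M = np.zeros((N_ZONES, N_ZONES))
    w = H_t - 1  # waterline zone, 0-based
    for z in range(N_ZONES):
        if z >= w:
            M[z, w if z > w else z] = 1.0
            continue
        target = z + m * (w - z)
        lo = int(np.floor(target))
        fr = target - lo
        M[z, lo] += 1.0 - fr
        if fr > 0:
            M[z, lo + 1] += fr
    return M


_MIGRATION_CACHE: dict[tuple[int, float], np.ndarray] = {}


def _migration_matrix_cached(H_t: int, m: float) -> np.ndarray:
    key = (H_t, m)
    M = _MIGRATION_CACHE.get(key)
    if M is None:
        M = _migration_matrix(H_t, m)
        _MIGRATION_CACHE[key] = M
    return M


def migrate_adults(adults: np.ndarray, H_t: int, m: float,
                   rng: np.random.Generator | None = None) -> np.ndarray:
    """Relocate emerged adults for oviposition.

    Step 1 (obligatory): adults in submerged zones (z > H_t) move up to the
    lowermost exposed zone z = H_t.  Step 2 (optional): adults above the
    waterline are carried toward the water's edge, covering a fraction ``m``
    of their distance to zone H_t; the fractional part of the displacement
    is realised as a split (or, stochastically, a Bernoulli draw) between
    the two neighbouring zones.  Total adults are conserved.
    """
    if not 1 <= H_t <= N_ZONES:
        raise ValueError("H_t must lie in 1..6")
    if not 0 <= m <= 1:
        raise ValueError("m must lie in [0, 1]")
    a = np.asarray(adults, dtype=float)
    M = _migration_matrix_cached(H_t, m)
    if rng is None:
        return a @ M
    out = np.zeros_like(a)
    flat = a.reshape(-1, N_ZONES)
    oflat = out.reshape(-1, N_ZONES)
    for row_in, row_out in zip(flat, oflat):
        for z in range(N_ZONES):
            n = int(row_in[z])
            if n == 0:
                continue
            targets = np.flatnonzero(M[z] > 0)
            if len(targets) == 1:
                row_out[targets[0]] += n
            else:
                k = rng.binomial(n, M[z, targets[1]])
                row_out[targets[0]] += n - k
                row_out[targets[1]] += k
    return out


def oviposit(adults: np.ndarray, C: float) -> np.ndarray:
    """Egg deposits per zone: each female lays ``C`` same-strain daughters in
    her post-dispersal zone and dies."""
    if C <= 0:
        raise ValueError("C must be positive")
    return np.asarray(adults, dtype=float) * C


def step_day(
    state: PopulationState,
    params: DynamicsParams,
    timings: tuple[StrainTiming, StrainTiming],
    schedule: TidalSchedule,
) -> PopulationState:
    """Advance the population one day.

    Fixed event order: survival -> stage transitions (incl. the stage-20
    gate) -> per-strain emergence -> adult migration -> oviposition ->
    day increment.  New eggs enter at stage 0 the day they are laid and
    first face mortality the following day.
    """
    out = state.copy()
    _step_day_inplace(out.larvae, out.day, params, timings, schedule)
    out.day += 1
    return out


def _step_day_inplace(
    larvae: np.ndarray,
    day: int,
    params: DynamicsParams,
    timings: tuple[StrainTiming, StrainTiming],
    schedule: TidalSchedule,
    emergence_frac: np.ndarray | None = None,
) -> None:
    """One day of dynamics on the raw (2, 6, 22) array, mutating in place.

    ``emergence_frac`` is an optional precomputed (2, 28) table of per-day
    pool-release fractions (a per-cell loop optimisation for grid sweeps).
    """
    cycle_day = (day - 1) % CYCLE_DAYS + 1
    H_t = schedule.exposure(cycle_day)
    rng = params.rng if params.mode == "stochastic" else None

    _apply_survival_inplace(larvae, params)
    _advance_stages_inplace(larvae, cycle_day, params, timings)

    for s, timing in enumerate(timings):
        if emergence_frac is not None:
            frac = emergence_frac[s, cycle_day - 1]
        else:
            frac = _emergence_fractions(timing)[cycle_day - 1]
        if frac <= 0:
            continue
        if rng is not None:
            adults = rng.binomial(larvae[s, :, 21].astype(np.int64), frac).astype(float)
        else:
            adults = frac * larvae[s, :, 21]
        larvae[s, :, 21] -= adults
        if adults.sum() <= 0:
            continue
        adults = migrate_adults(adults, H_t, params.m, rng=rng)
        larvae[s, :, 0] += oviposit(adults, params.C)


def run_days(
    state: PopulationState,
    n_days: int,
    params: DynamicsParams,
    timings: tuple[StrainTiming, StrainTiming],
    schedule: TidalSchedule,
) -> PopulationState:
    """Iterate ``step_day`` for ``n_days`` days (single in-place loop)."""
    out = state.copy()
    frac = np.stack([_emergence_fractions(t) for t in timings])
    for _ in range(n_days):
        _step_day_inplace(out.larvae, out.day, params, timings, schedule, frac)
        out.day += 1
    return out


def development_time_moments(n_transitions: int = N_TRANSITIONS, r: float = 0.45):
    """Mean and variance of a sum of ``n_transitions`` geometric waits with
    daily success probability ``r`` (closed form: n/r, n(1-r)/r^2)."""
    return n_transitions / r, n_transitions * (1 - r) / r**2


def simulate_development_times(
    n_larvae: int,
    r: float = 0.45,
    n_transitions: int = N_TRANSITIONS,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Simulate per-larva development durations as sums of geometric waits."""
    rng = np.random.default_rng() if rng is None else rng
    waits = rng.geometric(r, size=(n_larvae, n_transitions))
    return waits.sum(axis=1)
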