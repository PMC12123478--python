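"""Synthetic inputs with the statistical structure the analyses assume.

The cline generator emulates a two-strain larval sample along a depth
gradient: per-site strain-membership probability follows a logistic cline in
depth (elevation) with a site-level random intercept, individuals carry
diploid genotypes drawn from strain-typical allele frequencies (with
optional F1-like hybrids and missing calls).  Fixture populations provide
ready-to-run states for the headline simulation scenarios.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.special import expit

from .emergence import StrainTiming, emergence_weights
from .population_dynamics import (
    DynamicsParams,
    N_STAGES,
    N_STRAINS,
    N_ZONES,
    PopulationState,
)

CALL_NAMES = {2: "homFM", 1: "het", 0: "homNM"}


@dataclass
class ClineGeneratorConfig:
    """Configuration of the synthetic larval-sample generator.

    Depth is elevation in metres (decreasing toward the sea); with the
    default negative ``true_slope`` the FM-membership probability rises as
    elevation drops, mirroring the deeper distribution of the FM strain.
    ``n_larvae`` optionally fixes the total sample size (spread as evenly as
    possible over sites); otherwise each site gets ``larvae_per_site``.
    """

    n_sites: int = 49
    larvae_per_site: int = 2
    n_larvae: int | None = 94
    depth_range: tuple[float, float] = (-2.0, 2.0)
    true_slope: float = -2.48
    true_intercept: float = 0.0
    site_sd: float = 0.5
    hybrid_fraction: float = 0.1
    missing_rate: float = 0.05
    n_loci: int = 8
    within_strain_major_freq: float = 0.9
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("hybrid_fraction", "missing_rate", "within_strain_major_freq"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.n_loci < 1:
            raise ValueError("n_loci must be >= 1")
        if self.n_sites < 1:
            raise ValueError("n_sites must be >= 1")


def simulate_larval_sample(config: ClineGeneratorConfig) -> tuple[pd.DataFrame, dict]:
    """Draw a synthetic genotype table plus the generating truth record.

    Site depths are uniform over ``depth_range``; each site receives a
    Gaussian random intercept with SD ``site_sd``.  Per larva, strain
    membership is Bernoulli with the site's logistic FM probability (or an
    F1-like hybrid with probability ``hybrid_fraction``); per locus, two
    allele copies are drawn from the parental strains' FM-allele
    frequencies (``within_strain_major_freq`` in FM, its complement in NM).
    Calls are set missing uniformly at ``missing_rate``.
    """
    rng = np.random.default_rng(config.seed)
    depths = rng.uniform(*config.depth_range, config.n_sites)
    site_effects = rng.normal(0.0, config.site_sd, config.n_sites)

    if config.n_larvae is not None:
        base, extra = divmod(config.n_larvae, config.n_sites)
        per_site = np.full(config.n_sites, base, dtype=int)
        per_site[rng.choice(config.n_sites, extra, replace=False)] += 1
    else:
        per_site = np.full(config.n_sites, config.larvae_per_site, dtype=int)
    site_of = np.repeat(np.arange(config.n_sites), per_site)

    p_fm = expit(config.true_intercept + config.true_slope * depths + site_effects)
    f_fm = config.within_strain_major_freq
    f_nm = 1.0 - f_fm

    rows = []
    for i, s in enumerate(site_of):
        if rng.random() < config.hybrid_fraction:
            membership = "hybrid"
            a = rng.random(config.n_loci) < f_fm
            b = rng.random(config.n_loci) < f_nm
            copies = a.astype(int) + b.astype(int)
        else:
            is_fm = rng.random() < p_fm[s]
            membership = "FM" if is_fm else "NM"
            copies = rng.binomial(2, f_fm if is_fm else f_nm, config.n_loci)
        calls = [CALL_NAMES[c] for c in copies]
        miss = rng.random(config.n_loci) < config.missing_rate
        calls = [pd.NA if mi else c for c, mi in zip(calls, miss)]
        rows.append(
            {
                "individual": f"L{i + 1:03d}",
                "site": f"S{s + 1:02d}",
                "depth": depths[s],
                "membership": membership,
                **{f"locus{j + 1}": calls[j] for j in range(config.n_loci)},
            }
        )
    table = pd.DataFrame(rows)
    truth = {
        **asdict(config),
        "site_depths": depths.tolist(),
        "site_effects": site_effects.tolist(),
    }
    # the membership column is generator truth, not observable data
    return table, truth


FIGURE_SCENARIOS = ("fm_vs_nm", "symmetric_14day", "identical", "single_strain")


def fixture_population(
    scenario: str, m: float = 0.5, shape: float = 2.0, seed_density: float = 1000.0
) -> tuple[PopulationState, DynamicsParams, tuple[StrainTiming, StrainTiming]]:
    """Ready-to-run state, parameters and timing pair for a named scenario.

    Scenarios: ``fm_vs_nm`` (peaks 1 and 11), ``symmetric_14day`` (1 and
    15), ``identical`` (both at 1), ``single_strain`` (resident only).
    Parameters follow the headline configuration (Beta shape 2, constant
    density dependence 1e-8, configurable m).
    """
    if scenario not in FIGURE_SCENARIOS:
        raise ValueError(f"unknown scenario {scenario!r}; choose from {FIGURE_SCENARIOS}")
    peaks = {
        "fm_vs_nm": (1, 11),
        "symmetric_14day": (1, 15),
        "identical": (1, 1),
        "single_strain": (1, 1),
    }[scenario]
    timings = (emergence_weights(peaks[0], shape), emergence_weights(peaks[1], shape))
    params = DynamicsParams(m=m)
    larvae = np.zeros((N_STRAINS, N_ZONES, N_STAGES))
    larvae[0, :, 0] = seed_density
    if scenario != "single_strain":
        larvae[1, :, 0] = seed_density * 0.01
    return PopulationState(larvae=larvae, day=1), params, timings
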