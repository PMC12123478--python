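# tidecoex

Coexistence analysis for two reproductive-timing strains of an intertidal
midge whose lunar-cycle emergence timing determines where along the shore
females oviposit.

The package provides:

- **`tide_habitat`** — the discretised 28-day lunar/tidal cycle of habitat
  exposure (six vertical beach zones, one evening low tide per day) and
  zone-specific density-dependence profiles.
- **`emergence`** — strain timing traits: an emergence peak day, the 9-day
  emergence window, and per-day weights from a symmetric Beta distribution.
- **`population_dynamics`** — the daily update engine: density-dependent
  larval survival (`s_max * exp(-alpha_z * N^2)`), probabilistic stage
  transitions with a gated final maturation step, window-synchronised
  emergence, adult migration toward the waterline, and oviposition
  (50 daughters per female).
- **`invasion_analysis`** — resident establishment, 1%-invader experiments
  with a 1e-5 convergence rule and a 100-year cap, outcome classification,
  and the full (or strided) grid over all 28 x 28 emergence-peak
  combinations.
- **`segregation_stats`** — the segregation coefficient SC (0 = complete
  spatial overlap, 1 = complete segregation) between the two strains' larval
  zone distributions.
- **`genotype_cline`** — the empirical arm: SNP scorability filters
  (F_ST >= 0.3, major-allele > 0.8 in one strain, < 0.4 in the other),
  diploid genotype scoring (1 / 0.5 / 0), per-individual hybrid index, and a
  logit-link mixed model of score on sampling depth with a random intercept
  per site (cluster-robust GLM fallback).
- **`synthetic_data`** — generators: a two-strain larval sample whose strain
  membership follows a logistic cline in depth (with hybrids and missing
  calls), plus ready-to-run fixture populations for the headline scenarios.
- **`cli_workflow`** — a `tidecoex` command-line entry point tying it all
  together with manifests for bit-reproducible deterministic runs.

## Command line

```bash
tidecoex schedule                        # the 28-day exposure schedule
tidecoex invade --resident 1 --invader 11 --m 0.5
tidecoex grid --m 0.5 --stride 2 --out grid.csv
tidecoex figure4 --m 0.2 --m 0.5 --m 1.0 --stride 2 --out-dir out/
tidecoex sc --counts zone_counts.csv
tidecoex synth cline --out larvae.tsv --truth truth.json --seed 7
tidecoex genoscore --table larvae.tsv --out scores.tsv
tidecoex cline-fit --table larvae.tsv --out fit.json
tidecoex run-all --out-dir out/ --stride 2
```

Grid outputs are long-format CSV (resident day, invader day, outcome,
terminal frequencies, SC, cycles, convergence flag) plus a JSON manifest
with every parameter, the seed and a schedule hash.

## Headline behaviour

With the default parameters (C = 50, r = 0.45, s_max = 0.99,
alpha_z = 1e-8, Beta shape 2):

- two strains emerging at the same time, or exactly 14 days apart, share
  oviposition zones; the rare invader never establishes (priority effect);
- the real-strain combination (peaks on days 1 and 11) segregates spatially
  and coexists for every downward-migration rate m in {0.2, 0.5, 1.0};
- across the full grid, coexistence occurs where and only where the timing
  difference produces spatial segregation of larvae (higher SC).

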