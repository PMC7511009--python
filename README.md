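# trophlink

A tested, reusable pipeline for coupled **stomach-content and stable-isotope
trophic ecology**, built around the analysis design of demersal-fish diet
studies such as the whiting (*Merlangius merlangus*) surveys of the Eastern
English Channel and Southern North Sea: seasonal trawl surveys, 5-cm size
classes, a spatially varying isotopic baseline measured on queen scallops
(*Aequipecten opercularis*), and GLM inference of ontogenetic and seasonal
effects.

It is aimed at trophic ecologists who have (1) prey items recovered from
stomachs, (2) consumer muscle δ¹³C/δ¹⁵N measurements, and (3) baseline
invertebrate δ¹⁵N observations scattered in space, and who want the whole
chain — enumeration, indices, baseline interpolation, trophic levels,
inference — reproducible from one seeded configuration. A synthetic-study
generator with the survey's statistical structure makes every stage testable
without any data download.

## What it computes

**Diet indices (stomach contents).** Prey individuals are enumerated
parsimoniously: whole prey count as themselves, paired hard parts (otoliths,
eyes, claws) count as ⌈parts/2⌉ donors, and unquantifiable remains attest a
single individual only when no countable part of the same taxon is present.
From the enumerated stomachs:

- vacuity rate %V = 100 · n_empty / n_total (inverse proxy of feeding
  intensity),
- frequency of occurrence O_i = J_i / P over the P non-empty stomachs, with
  %O = 100 · O_i / Σ O_i,
- numerical abundance %N = 100 · N_i / Σ N_i,

per prey group (fish, benthic / pelagic / unidentified crustaceans,
mollusks, other), size class and season, plus a pooled table.

**Spatial δ¹⁵N baseline.** The empirical spatial covariance of the baseline
observations is binned by great-circle distance, a parametric model
(Gaussian by default, c(h) = sill · exp(−(h/range)²), optional nugget) is
fitted by weighted nonlinear least squares with the number of point pairs
per bin as weights, and **ordinary kriging** predicts a station-specific
baseline wherever no scallop was caught (weights solve the covariance
system under Σλ = 1).

**Trophic levels.** Post's equation with the station-specific baseline:

    TL_i = TL_B + (δ¹⁵N_i − δ¹⁵N_B) / TDF,   TL_B = 2, TDF = 3.4 ‰

after a C:N ≤ 3.5 screen (raw ratios are used; lipid-rich samples are
flagged, never silently corrected).

**Inference.** Gaussian (isotopes, TL), binomial-logit (prey occurrence) and
Poisson-log (prey counts) GLMs on size class × season, with **type-III
likelihood-ratio deviance tables** under sum-to-zero contrasts; aliased
interaction columns from empty design cells (no small whiting in winter)
are detected and dropped with their df.

## Worked example

```python
from trophlink import (SyntheticConfig, simulate_study, BaselineObservation,
                       baseline_for_stations, cn_screen, trophic_levels_table,
                       summarize_isotopes)
from trophlink.diet import vacuity_table

study = simulate_study(SyntheticConfig(seed=1))
print(vacuity_table(study.stomachs).to_string(index=False))

obs = [BaselineObservation(str(r.id), float(r.lat), float(r.lon), float(r.d15N))
       for r in study.baseline_obs.itertuples(index=False)]
kriged, model = baseline_for_stations(obs, study.stations)
print(f"fitted {model.family} covariance: sill={model.sill:.3f} permil^2, "
      f"range={model.range_km:.1f} km, adjR2={model.adj_r2:.2f}")

passed, flagged = cn_screen(study.isotopes)
tl = trophic_levels_table(passed, study.fish, kriged)
print(summarize_isotopes(tl)[["season", "size_class", "n", "TL_mean", "TL_sd"]]
      .round(2).to_string(index=False))
```

prints

```
season     pct_V  n_empty  n_total
autumn 16.129032       20      124
winter  6.451613        8      124
   all 11.290323       28      248
fitted gaussian covariance: sill=0.495 permil^2, range=33.7 km, adjR2=0.25
season size_class  n  TL_mean  TL_sd
autumn    10-15cm 20     3.85   0.10
autumn    15-20cm 19     4.06   0.11
autumn    20-25cm 22     4.36   0.09
autumn    25-30cm 20     4.42   0.11
autumn    30-35cm 24     4.33   0.10
autumn        35+ 19     4.09   0.09
winter    15-20cm 33     4.75   0.10
winter    20-25cm 23     4.46   0.08
winter    25-30cm 23     4.33   0.11
winter    30-35cm 31     4.33   0.12
winter        35+ 14     4.37   0.09
```

The vacuity rates sit at the configured seasonal probabilities (0.16 / 0.07
of 124 stomachs each), the fitted covariance is one noisy 76-observation
realisation of the true field (sill 0.81 ‰², range 40 km), and the per-cell
mean trophic levels recover the configured values (3.86–4.74) through the
kriged baseline to within a few hundredths of a level.

The same chain is available from the shell:

```bash
trophlink run --seed 1 --out-dir out/
```

which writes `stations.csv`, `baseline.csv`, `fish.csv`, `prey_items.csv`,
`isotopes.csv`, `diet_indices.csv`, `vacuity.csv`, `baseline_kriged.csv`,
`covariance_fit.json`, `trophic_levels.csv`, `table1_summary.csv`,
`table2_deviance.csv`, diagnostic figures and a run manifest. Identical
configs reproduce identical outputs byte for byte.

## Layout

- `src/trophlink/synthetic.py` — seeded synthetic-study generator
- `src/trophlink/diet.py` — prey enumeration, vacuity, O_i / %O / %N tables
- `src/trophlink/baseline.py` — covariogram, WLS covariance fit, ordinary kriging
- `src/trophlink/isotopes.py` — δ notation, C:N screen, Post trophic levels
- `src/trophlink/glm.py` — sum-contrast designs, GLM fits, type-III tables
- `src/trophlink/pipeline.py`, `cli.py` — orchestration, validated CSV I/O, CLI
- `docs/methods.md` — model, assumptions, numerical choices, limitations
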