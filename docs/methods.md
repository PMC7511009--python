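# Methods

This note documents the models, parameter choices and numerical decisions
behind trophlink, in the spirit of a statistical package's methods
documentation. Nothing here states an empirical result that the test suite
or `scripts/acceptance.py` does not itself compute.

## Parsimonious prey enumeration

Stomach contents arrive as *parts*: whole prey, paired hard structures
(otoliths, eyes, claws) and unquantifiable remains (muscle, gills,
bristles). The enumeration rule returns, per stomach and taxon, the
**smallest number of individuals consistent with the parts**:

- whole prey count one-for-one;
- `n` paired parts imply ⌈n/2⌉ donors (each individual carries two of a
  paired structure; an odd count still needs the extra donor);
- unquantifiable remains add one individual **only when no countable part
  of the taxon is present** — a countable part already attests a donor the
  remains can have come from.

A brute-force oracle in the test suite enumerates candidate donor counts
m = 0, 1, 2, … and accepts the first m that can physically produce the
observed parts; the closed-form rule equals this oracle exhaustively for
all part multisets up to six items and property-based samples beyond.

Design choice: the rule is deliberately an *undercount under uncertainty*.
It trades a small negative bias (remains of several individuals collapse
to one) for robustness against degradation-driven overcounting, which is
the dominant bias in stomach-content work.

## Diet indices

With P the number of non-empty stomachs, J_i the stomachs containing group
i, and N_i the enumerated individuals of group i:

    O_i = J_i / P,   %O = 100·O_i / Σ O_i,   %N = 100·N_i / Σ N_i,
    %V  = 100 · n_empty / n_total.

O_i is a presence/absence measure, so Σ O_i over groups may exceed 1 when
stomachs hold several groups; %O rescales for display. Indices are
computed per (season, size class) cell and pooled over all stomachs.
Biomass-based indices are intentionally not provided: differential
digestion of hard parts makes them less comparable with isotopic
(assimilation-based) information. Items belonging to groups outside the
requested group list still make a stomach non-empty (they count in P) but
receive no index row, so analyses can focus on the main prey groups.

Size classes are left-closed right-open 5-cm bins of total length,
[100, 150), …, [350, ∞) mm, labelled `10-15cm` … `35+`. A fish exactly at
an edge (150 mm) belongs to the upper class; this boundary convention is a
declared choice, as is reporting %N both per cell and pooled.

## Spatial baseline model

The isotopic baseline — queen scallop muscle δ¹⁵N, a suspension feeder at
trophic level 2 — varies in space, so each station needs its own baseline
value. The chain is:

1. **Empirical covariogram.** For all observation pairs within `max_lag`
   (default: half the maximum pairwise distance), the products
   (z_i − z̄)(z_j − z̄) around the global mean are averaged in distance
   bins of `bin_width` (default 10 km); the number of pairs per bin is
   retained. Distances are great-circle (haversine) on a 6371-km sphere —
   coordinates are lat/lon and at these scales (< 500 km) the spherical
   metric is accurate to well under a percent.
2. **Weighted least-squares fit.** A parametric covariance model —
   Gaussian c(h) = nugget·1(h=0) + sill·exp(−(h/range)²) by default;
   exponential and spherical available — is fitted by bounded nonlinear
   least squares minimising Σ_b n_pairs_b (ĉ_b − c(h_b))², from nine
   (sill, range) starts to avoid local minima. Fit quality is the adjusted
   R² of the weighted regression. The nugget defaults to 0 (a two-parameter
   fit); a three-parameter fit is available via a flag. A semivariogram
   mode (γ(h) = nugget + sill·(1 − ρ(h))) exists behind the same interface
   for comparison, since covariogram-versus-semivariogram is a genuine
   methodological fork in baseline-interpolation practice.
3. **Ordinary kriging.** Weights solve the augmented system
   [[C, 1], [1ᵀ, 0]][λ, μ] = [c₀, 1]; the prediction is Σλᵢzᵢ and the
   kriging variance sill + nugget − Σλᵢc(hᵢ₀) − μ. A 10⁻⁸ diagonal jitter
   keeps C positive definite; duplicate observation locations are averaged
   beforehand (they would otherwise make the system singular). With zero
   nugget the predictor interpolates exactly at observation sites.
   Stations co-located with an observation use the observed value
   directly. Negative weights — normal for smooth (Gaussian) covariances —
   are logged, never clipped.

Assumptions: second-order stationarity and isotropy of the baseline field,
and a constant mean (ordinary, not universal, kriging). Salinity or
inshore–offshore covariates are out of scope.

## Trophic levels

Post's two-source-free single-baseline equation:

    TL_i = TL_B + (δ¹⁵N_i − δ¹⁵N_B) / TDF

with TL_B = 2 (theoretical level of suspension feeders) and TDF = 3.4 ‰
per level, the classical nitrogen discrimination value. TL is computed
**per fish with its station's baseline** and then averaged per cell; a
pooled-baseline mode exists for sensitivity analysis. Per-cell summaries
report n and mean ± SD (sample SD, n − 1; single-fish cells report the SD
as missing).

C:N screening: samples with C:N ≤ 3.5 (the conventional lipid-correction
cutoff) pass with raw ratios; higher values are flagged and excluded from
the trophic table rather than lipid-corrected, because correction would
silently mix measured and modelled values.

## GLM inference

Every response is modelled on two crossed factors — size class (6 levels)
and season (2 levels) — plus their interaction, each fish or stomach being
one observation (individuals are replicates of their class; no random
effects). Families: Gaussian/identity for δ¹³C, δ¹⁵N and TL;
binomial/logit for per-group prey presence; Poisson/log for per-group
enumerated counts. Occurrence and abundance models use non-empty stomachs
(feeding-intensity information lives in %V, not in the diet-composition
models); the residual-df accounting is therefore n_non-empty − 11 for diet
responses and n_fish − 11 for isotope responses.

Type-III likelihood-ratio tests: for each term, the model without (only)
that term's columns — main effects removed *in the presence of* the
interaction — is refitted and the deviance difference referred to χ² with
the term's df. This is only meaningful under **sum-to-zero contrasts**,
which the design builder uses throughout. For the Gaussian family the
statistic is the scaled deviance (deviance divided by the full model's
Pearson dispersion), since raw RSS differences are not χ²; binomial and
Poisson deviances are already on that scale. The test suite verifies the
size-class test's null rejection rate is ≈ 0.05 by simulation.

The missing winter 10–15 cm cell makes the full interaction rank
deficient: the design builder detects aliased interaction columns by
incremental rank checks and drops them with a warning, giving the
interaction df = 4 instead of 5. A quirk worth knowing: when a strong
seasonal effect is concentrated in a single size class (the winter copepod
pulse), most of its deviance loads on the interaction term and the season
*main* effect — the seasonal effect averaged over classes — can be much
smaller than a type-II analysis would report.

Poisson models carry no overdispersion correction; a Pearson χ²/df
quasi-dispersion diagnostic is available (`quasi_dispersion`) and logged,
but inference stays plain Poisson. Binomial separation (diverging
coefficients) is flagged and capped at |β| = 20 rather than silently
reported as converged.

The Gaussian-model QQ diagnostic pairs sorted standardized residuals with
normal quantiles at (i − ½)/n and reports their correlation; exactly
fitted (zero-residual) models return the correlation as absent.

## Synthetic-study generator

The generator emulates the structure the analysis assumes, with defaults
set to the published EEC-SNS whiting survey values:

| parameter | default | source/rationale |
|---|---|---|
| per-cell fish counts | published n per (season, class); 248 total | survey design; no fish < 15 cm in winter |
| baseline mean, SD | 7.69 ‰, 0.90 ‰ | published baseline summary (76 obs) |
| baseline covariance | Gaussian, range 40 km | range is a **synthetic choice**; the survey does not publish one |
| p(empty stomach) | 0.16 autumn, 0.07 winter | published vacuity rates |
| per-cell true TL | published cell means, 3.86–4.74 | anchors parameter-recovery tests |
| TDF, TL_B | 3.4 ‰, 2 | classical values |
| δ¹⁵N noise SD | 0.35 ‰ | individual variation + analytical error (< 0.2 ‰) |
| δ¹³C sources | pelagic −18.3 ‰, benthic −15.8 ‰, noise 0.4 ‰ | reproduces the observed −17.3 … −16.6 ‰ cell means via benthic-fraction mixing |
| C:N | N(3.19, 0.08) truncated to [3.0, 3.5] | published summary and range |
| prey means | per-cell Poisson λ per group | encode the ontogenetic crustacean→fish/mollusk shift and a winter copepod pulse (15–20 cm class) sized to make winter pelagic-crustacean abundance ≈ 20× autumn |

Generation: stations uniform in a bbox approximating the study region; the
baseline field is one Gaussian-process draw via Cholesky factorisation of
the full covariance matrix (+10⁻⁸ jitter) — exact and fast at ≤ a few
thousand points; scallops are observed at a random subset of 76 stations,
the rest are held out for interpolation validation. Non-empty stomachs
draw per-group counts Poisson(λ_g) (one guaranteed individual from the
normalised composition if all draws are zero); each individual then leaves
whole parts (p = 0.6), paired parts (p = 0.3; occasionally one of the pair
is lost — ⌈n/2⌉ still recovers the donor count) or unquantifiable remains
only (p = 0.1), and stomachs sometimes show extra remains alongside
countable parts, so the parsimony rule is genuinely exercised. Fish δ¹⁵N
is the station's *true* field value + (TL_cell − 2)·3.4 + noise.

All randomness flows from one integer seed through named per-stage
substreams (`default_rng([seed, stage])`), so every table is reproducible
and stages are independent.

What the generator does **not** emulate — and hence what passing tests do
not demonstrate about real data: taxon-level prey structure (one
pseudo-taxon per group), preferential sampling of stations, gear
selectivity, within-class diet heterogeneity beyond the Poisson model,
temporal turnover of muscle tissue (isotope values reflect the assigned
cell TL instantly), baseline non-stationarity (coastal enrichment
gradients), and any correlation between diet composition and the
individual's isotope values beyond the shared cell parameters.

## Problem sizes and tolerances

The default validation sizes were chosen to keep the full suite fast on a
single core while leaving comfortable statistical margins: covariance
recovery uses 20 replicate fields of 500 stations (mean fitted sill and
range within 25 % of truth); kriging is cross-checked against a direct
matrix-inversion solve on 100 random 5-point problems at 10⁻⁸; the
type-III null calibration uses 1000 replicates of the survey's design
(rejection 0.05 ± 0.02); end-to-end trophic-level recovery demands every
per-cell mean within ±0.1 of its configured value with 76 baseline
points. Optimiser tolerances: IRLS deviance tolerance 10⁻⁸ (max 100
iterations); covariance WLS xtol/ftol/gtol 10⁻¹⁴ with bounded parameters
(sill, range > 0, nugget ≥ 0).

## Known limitations

- The covariogram of a *single* 76-point realisation is noisy; the fitted
  sill/range and adjusted R² for one study can deviate substantially from
  the field truth even though the estimator is well calibrated across
  replicates (the acceptance output reports both views).
- Type-III main-effect tests under a missing factor cell depend on which
  aliased interaction column is dropped; df bookkeeping is documented
  (interaction df = 4) but the partition of deviance between a main effect
  and the interaction is not unique in this design.
- Enumerated abundances are biased low when many individuals leave only
  unquantifiable remains; %N convergence to the configured composition
  holds exactly only when all parts are countable.
- Ordinary kriging assumes a constant mean; strong coastal baseline
  gradients would call for universal kriging with covariates, which is out
  of scope.
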