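# Methods

## The severity model

The Bevan damage classification assigns each insect species a damage-scale
value s ∈ {0,1,2,3,4} by damage type: predators of bark insects and species
feeding on wood-decay fungi score 0; species breeding between bark and wood
(bark beetles) 1; surface damage and decaying-wood species 2; heavy wood
damage 3; and species causing excessive economic damage (wood-boring
longhorns, jewel beetles, furniture beetles) 4. Severity is then a
*relative importance* score: the damage index of species i within a group is
100·f·s normalised by the group's total Σ f·s, so indices are percentages
that sum to 100 per group.

Two modelling commitments matter:

* **Frequency counts appearances, not individuals.** f is the number of
  distinct collection events (depot × year × month) with at least one
  individual. A single mass catch and a single stray both contribute 1; a
  species present in two months contributes 2. This separates "how often it
  shows up" (frequency, used by the index) from "how many" (abundance, used
  by density).
* **Normalisation groups follow the reporting unit.** Each province, the
  pooled pheromone-trap catch, and the stored-wood catch behave as separate
  percentage scales; the grouping is configurable (`tabulate_frequency`
  accepts any survey or depot metadata field). A group whose products f·s
  are all zero has no defined indices; such groups are returned explicitly
  flagged (`degenerate=True`), never as silent zeros — zero *scale* species
  inside a non-degenerate group do score an exact 0.

Presentation rounding is 1 decimal, half away from zero (`round_half_up`),
applied only at output; internal values keep full precision. Rankings break
index ties by species name ascending so reports are deterministic.

## Species scale registry

The survey literature rarely publishes per-species scale values; this
package reconstructs them as *data*: `data/family_scales.csv` maps each
family to a scale value following the damage-type semantics above (e.g.
Cerambycidae/Buprestidae/Anobiidae/Melandryidae → 4, Scolytinae → 1,
Tenebrionidae/Elateridae/Lucanidae/Scarabaeidae → 2, predator families
Cleridae/Trogositidae/Cantharidae/Zopheridae/Dasytidae and fungus feeders
→ 0), and `default_registry()` expands it over the reference species list.
Users who know a species better can pass their own registry CSV; the
computation never infers scales from anything else.

## Density and distance stratification

Density is D = (n/a)/t in individuals·ha⁻¹·yr⁻¹. Trap catchment areas are
not observable from catch records, so areas are caller input (default 1 ha
per depot) and the default duration is one April–October season
(7/12 ≈ 0.583 yr); both are explicit parameters everywhere. Stratification
uses the binary depot class (< 3 km / > 3 km to forest); each depot is in
exactly one stratum, so stratum frequencies partition the pooled frequency
and the two percentage shares per species sum to 100. Printed reference
densities in the `distance_t4` fixture are carried as transcription values
only — without published a and t they cannot be recomputed, and the package
does not try. Percentage comparisons against printed survey tables use a
0.15-percentage-point tolerance: such tables round irregularly (e.g.
12/49 = 24.49 printed as 24.4), so exact-decimal comparison would test the
source's typesetting, not the arithmetic.

## Phenology and correlation

Monthly series per family align frequency (distinct species × depot × month
detection events), species number, density (pooled monthly individuals over
total area and a per-month duration), and depot-averaged temperature and RH.
By default each (year, month) is its own point — two seasons give n = 14 —
with `pool_years=True` collapsing calendar months for figure-style views;
which of the two a given printed correlation used is generally
unknowable, so both are exposed and neither is asserted as canonical.

`pearson_with_p` is the sample Pearson coefficient with the two-sided
t-transform p (n−2 df), delegated to `scipy.stats.pearsonr`; the test suite
holds it against an independent covariance-formula oracle at 1e-12. Fewer
than 3 points or a zero-variance vector yields a flagged undefined result
(`defined=False`) rather than NaN. Strength labels on |r| use half-open bins
with cutpoints 0, 0.295, 0.705, 0.995 — the two-decimal rounding boundaries
of the conventional 0.01–0.29 / 0.30–0.70 / 0.71–0.99 / 1.00 bands, chosen
so that classification is total on [−1, 1]; negative coefficients are
classified by magnitude with the sign reported in r. Significance is marked
at 0.01 (the survey convention) and additionally at 0.05 for reporting. No
multiple-testing correction is applied, matching field practice for these
5×5 descriptive matrices.

## Synthetic scenario generator

The generator emulates the survey design so every stage is testable without
field data. Catch counts per species × depot × month are Poisson with

log λ = log(baseline) + A·exp(−(m−peak)²/(2·1.2²)) + β_family·(T − T̄) + log(d_far)

* **baseline** — per-depot-month catch intensity; the reference scenario
  spreads baselines geometrically from 0.60 down to ~0.02 across each
  family's species list so a few species dominate, as in real catches.
* **A = 1.5, sd 1.2 months** — a Gaussian flight-season bump centred on the
  species' peak month (July for Cerambycidae, August for Buprestidae in the
  reference scenario), giving unimodal seasonal curves.
* **β_family** — log-linear temperature link per °C anomaly from the
  seasonal mean. The Buprestidae default (0.18) was calibrated once by
  simulation so the recovered temperature–frequency correlation sits near
  0.9 at n = 14 (median 0.92 over 60 seeds on a β grid), mirroring reported
  magnitudes for strongly thermophilic families; Cerambycidae default 0.06
  gives a moderate, usually non-significant link.
* **d_far = 0.35** — multiplicative intensity for depots > 3 km from forest
  (9 of the 21 reference depots), reproducing the near-forest excess seen in
  distance stratifications.
* Temperature/RH follow temperate Black-Sea seasonal curves with Gaussian
  noise (sd 1.0 °C / 3 % RH), RH clipped to [0, 100].

Zero-count draws emit no record. A negative-binomial switch
(`overdispersion=k`, variance λ+λ²/k at unchanged mean) is available for
overdispersed catches. All randomness flows from one integer seed through
independent substreams (depots/environment/survey), so identical seed and
config reproduce a byte-identical record stream regardless of call order.
The null counterpart (`scenario_null`) zeroes both the temperature link and
the seasonality, making monthly catches exchangeable — under it, a "high"
temperature–frequency correlation at n = 14 is a ~0.5 % event, which the
recovery tests bound at 10 % over 200 seeded replicates.

What the generator does **not** emulate: species interactions (predation),
wood-volume depletion over storage time, trap-level heterogeneity beyond the
binary distance class, inter-annual population trends, and pheromone-lure
species selectivity. Passing recovery tests therefore shows the pipeline
measures what the model injects; it does not validate the Poisson or
log-linear form against real log-depot data.

## Reference-table fixtures

The packaged CSVs transcribe the survey's printed tables. The damage-index
table distinguishes blank cells (species not detected in that column, NaN)
from explicit zeros (detected, zero index — the predator rows). The source
rendering concatenates numeric cells, so sparse rows whose province
placement cannot be uniquely determined are flagged in a `note` column
(`prov_uncertain` — values are in printed order but the province columns are
uncertain; `cols_uncertain` — even the P/stored-wood assignment rests on
stated reading rules) instead of being silently guessed. Pooled-column (P),
stored-wood (ST) and several province anchors are fixed by the source's own
prose and are not flagged. Per-species raw frequencies behind the index
table are unpublished, so those indices serve ranking/reporting tests only
and are never "recomputed".

## Problem sizes

Property tests run 1,000 random tables (index closure) and 1,000 random
vector pairs (Pearson oracle); recovery tests run 200 seeded replicates per
scenario of the full 21-depot, 2-season reference configuration (~0.2 s per
replicate). These sizes give binomial standard errors well under the
decision margins (a true 90 % pass rate is estimated to ±2 % at 200
replicates).

## Known limitations

* Scale values are family-level defaults; within-family variation in damage
  behaviour (e.g. predatory Tenebrionidae) is only representable through a
  user-supplied registry.
* Density values are only as meaningful as the supplied areas; with the
  default 1 ha placeholder they are comparable across strata but not
  interpretable in absolute terms.
* Monthly temperature/RH averages are taken over depots contributing records
  (falling back to all depots), which slightly couples the environment
  series to the catch series when depot coverage varies month to month.
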