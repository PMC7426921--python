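# bevan-severity

Damage-severity analysis of wood-destroying insects in log depots — the
outdoor yards where harvested logs wait for transport and where beetles
(Cerambycidae, Buprestidae, bark beetles and their predators) colonise the
stored wood. The package is aimed at forest entomologists and wood-protection
researchers who collect monthly pheromone-trap and stored-wood survey records
and want reproducible severity, density and phenology reports.

## What it computes

**Bevan damage index.** Each species carries a damage-scale value
*s* ∈ {0,…,4} by damage type (0 = predators of bark insects and fungus
feeders, 4 = species causing excessive economic wood damage). Its frequency
*f* is the number of distinct collection events (depot × year × month) in
which it appeared — appearances over time, not individuals. Within a
normalisation group (a province, the pooled pheromone catch, the stored-wood
catch, …) the index of species *i* is

```
index_i = 100 · f_i · s_i / Σ_j f_j · s_j      (percent; sums to 100)
```

**Insect density.** `D = (n/a)/t` — individuals per hectare per year, with
`n` the pooled count, `a` the surveyed field area and `t` the observation
time. Depots are stratified by their binary distance-to-forest class
(< 3 km vs > 3 km).

**Phenology.** Per family, aligned monthly series of frequency, species
number and density over the April–October season are correlated with mean
temperature and relative humidity (sample Pearson *r*, two-sided *p* from
the *t* transform with *n*−2 df), and |r| is labelled
none / low / intermediate / high / excellent on the survey convention
(cutpoints ≈ 0.29 / 0.70 / 0.99).

Because no raw per-trap catch data are published with the study, the package
ships transcriptions of the printed reference tables
(`load_fixture("depots_t1" | "scales_t2" | "damage_index_t3" | "distance_t4")`)
and a seeded synthetic generator whose reference scenario mirrors the survey
design: 21 depots in 7 provinces, two April–October seasons, Poisson catches
with a July (Cerambycidae) / August (Buprestidae) flight peak, a
temperature-linked intensity and reduced catches far from forest.

## Worked example

```python
from bevan_severity import (scenario_paperlike, generate_depots,
                            generate_environment, generate_survey,
                            tabulate_frequency, damage_index, rank_species,
                            monthly_series, pearson_with_p)

cfg = scenario_paperlike(seed=42)
depots = generate_depots(cfg)
env = generate_environment(cfg, depots)
records = generate_survey(cfg, env, depots)      # 2714 records

scales = {s.species: s.scale_value for s in cfg.species_pool}
(freq,) = tabulate_frequency(records)            # pooled group
table = damage_index(freq, scales)
for sp, idx in rank_species(table, 3):
    print(f"{sp:32s} {idx:5.1f} %")

series = monthly_series(records, env, "Buprestidae")
res = pearson_with_p(series.temperature, series.frequency)
print(f"r={res.r:.3f} p={res.p:.4f} n={res.n} strength={res.strength.value}")
```

prints

```
Anastrangalia reyi                 5.8 %
Anthaxia semicuprea                5.6 %
Chrysobothris affinis              5.3 %
r=0.911 p=0.0000 n=14 strength=high
```

The three indices are percentages of the pooled group's total damage weight
Σ f·s (all indices in the group sum to 100). The Pearson line says monthly
Buprestidae catch frequency tracked monthly mean temperature across the
14 month-year points of the two simulated seasons — a "high" correlation,
recovering the temperature link the scenario builds in.

The same pipeline runs from the shell:

```sh
bevan-severity simulate --seed 42 --out-dir sim
bevan-severity report-all --survey sim/survey.csv --registry sim/registry.csv \
    --depots sim/depots.csv --env sim/environment.csv --out-dir report
```

which writes the damage-index report (per-province, pooled-pheromone and
stored-wood groups), the distance stratification, per-family correlation
matrices and monthly phenology series, plus a `manifest.json` recording the
run.

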