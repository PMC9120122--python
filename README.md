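# urbanfilter

Trait–environment analysis of urban pollinator communities.

Cities filter which pollinator species persist: sealed surfaces and
buildings fragment habitat in three dimensions, and species pass or fail
this "urban filter" depending on their functional traits (diet breadth,
sociality, nesting strategy, body size, larval ecology). `urbanfilter`
implements the full statistical chain used to study this on
site-by-species survey data:

- **Landscape metrics** — urbanisation as the percentage of impervious
  surface within a 500-m buffer, and a building-aware *3D connectivity*
  variant of Hanski's incidence-function index
  `S_i = Σ_{j≠i} exp(−α·d*_ij)·A_j`, where the effective distance `d*_ij`
  is the edge-to-edge patch distance **plus the summed heights of all
  buildings** intersecting a 25-m corridor between the patches. Both
  metrics are classified into low/medium/high bins (20/50 % impervious;
  0.03/0.10 on the connectivity index).
- **Community preparation** — rarity filters (species with total abundance
  ≤ 2 and sites with < 3 individuals dropped), Wisconsin double
  standardisation with square-root transform, Bray–Curtis dissimilarities.
- **Ordination** — non-metric multidimensional scaling (Kruskal stress-1,
  SMACOF with isotonic regression, 100 random starts) and `envfit`-style
  fitting of environmental vectors with add-one permutation p-values.
- **Indicator species** — Dufrêne–Legendre IndVal (`IV = A·B`, specificity
  × fidelity) per urbanisation/connectivity class, with the `IV ≥ 0.3`
  selection rule.
- **Trait–environment tests** — RLQ ordination and the fourth-corner
  statistic between every environmental variable and every coded trait
  column, tested with permutation model 2 (rows of the abundance matrix),
  plus Poisson-GLM direction checks on per-site trait counts.
- **Synthetic surveys** — a generator for landscapes, trait tables and
  Poisson communities whose log-rates carry planted trait × environment
  interactions (`log λ_ij = β₀ + a_i + b_j + Σ c_kt x_ik z_jt`), so the
  whole pipeline is testable without field data and its type-I error and
  power are measurable.

## Worked example

```python
from urbanfilter.synth import SyntheticScenario, generate_dataset
from urbanfilter.community import filter_rare, wisconsin_sqrt, bray_curtis
from urbanfilter.ordination import nmds, envfit
from urbanfilter.traitenv import code_traits, fourth_corner

scen = SyntheticScenario(
    n_sites=49, n_species=50, seed=3,
    interaction_coeffs={("urbanisation_pct", "diet:polylectic"): 0.8},
)
ds = generate_dataset(scen, with_landscape=False)
filt = filter_rare(ds.community)
env = ds.env.loc[filt.matrix.index]

ordn = nmds(bray_curtis(wisconsin_sqrt(filt.matrix)), n_starts=100, seed=0)
fit = envfit(ordn, env, n_perm=9999, seed=0)
print(f"stress = {ordn.stress:.3f}")
print(fit.table[["r2", "p_perm"]].round(4))

w = filt.matrix.sum(axis=0) / filt.matrix.to_numpy().sum()
coded, _ = code_traits(ds.traits.loc[filt.matrix.columns], species_weights=w)
fc = fourth_corner(env, filt.matrix, coded, n_perm=9999, seed=0)
print(fc.table.loc[("urbanisation_pct", "diet:polylectic")])
```

prints

```
stress = 0.254
                         r2  p_perm
urbanisation_pct     0.3218  0.0004
connectivity_S       0.0235  0.5759
patch_size_m2        0.0065  0.8617
herb_cover_pct       0.0248  0.5708
nonnative_cover_pct  0.0260  0.5456
mean_air_temp_C      0.0669  0.1985
stat      0.368486
p_perm      0.0001
sign             +
```

The planted urbanisation × polylectic-diet interaction is the one pair the
fourth-corner test flags (positive pseudo-correlation 0.37, minimal
permutation p), and urbanisation is the one variable envfit finds aligned
with the ordination — exactly the structure that was generated.

The same chain runs from the shell:

```sh
urbanfilter run --config run.yaml --out results/
urbanfilter synth --config scenario.yaml --out data/ --seed 1
urbanfilter landscape --geojson data/landscape.geojson --out env_landscape.csv
```

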