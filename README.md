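# flyway

Annual-cycle repeatability and migration-route fidelity statistics for
GPS-tracked migratory birds.

Movement ecologists increasingly ask whether individual migrants are
*consistent*: does a bird return to the same wintering mudflat, depart on
the same calendar day, and fly the same route year after year?  `flyway`
packages the full analysis chain needed to answer that question from raw
GPS fixes:

1. **Segmentation** of multi-year trajectories into wintering, breeding,
   stopover and migration-flight phases using rule-based operational
   definitions (24 km/h flight threshold, ≥ 60 min stopovers, > 20 d
   wintering residencies, 20 km site buffers, 0.0001° nest grid).
2. **Migration metrics**: departure/arrival dates, durations, linear
   (great-circle) and flown distances, stopover number and length, per
   bird × season × year, with 250 km spatial clustering of breeding and
   wintering sites and migration-distance classes.
3. **Adjusted repeatability**: for each trait, the intraclass correlation

   R = σ²~between~ / (σ²~between~ + σ²~within~)

   from the random-intercept mixed model `y ~ cluster + log(dt + 1) + (1 | ID)`,
   estimated by REML, with parametric-bootstrap 95% confidence intervals
   (n = 1000), permutation p-values, a Poisson/latent-scale pathway for
   count traits (with overdispersion check and √-Gaussian fallback),
   cluster-radius and covariate sensitivity analyses, and a
   distance-class trend test.
4. **Route fidelity**: directed nearest-neighbour distances between track
   pairs, and a mixed-model contrast of within- vs between-individual
   route separation.

Because real tracking archives are rarely public, the package ships a
first-class synthetic trajectory generator with full ground truth (true
sites, true buffer-crossing phenology, true stopovers, latent individual
effects and the implied repeatability), so the entire chain is testable
end to end.

## Worked example

Estimate adjusted repeatability on a simulated repeated-measures table
whose true intraclass correlation is 0.7:

```python
from flyway.simulate import simulate_repeatability_table
from flyway.repeatability import adjusted_repeatability
from flyway.config import PipelineConfig

table = simulate_repeatability_table(r_true=0.7, n_ids=50, n_obs_per_id=4, seed=1)
res = adjusted_repeatability(table, "y", config=PipelineConfig(n_boot=1000, n_perm=1000, seed=1))
print(f"R = {res.R:.3f}  95% CI [{res.ci95[0]:.3f}, {res.ci95[1]:.3f}]  p_perm = {res.p_perm:.4f}")
print(f"sigma2_id = {res.components.sigma2_id:.3f}  sigma2_res = {res.components.sigma2_res:.3f}")
```

prints

```
R = 0.677  95% CI [0.533, 0.771]  p_perm = 0.0010
sigma2_id = 1.845  sigma2_res = 0.881
```

i.e. the estimator recovers the generating value (0.7 lies inside the
bootstrap interval), about two thirds of the trait variance is between
individuals, and no permutation of the individual labels produced a
repeatability as large as the observed one (p at its floor of
1/(n_perm + 1)).

The full pipeline runs from a YAML config:

```bash
flyway run-all --config examples/synthetic_run.yaml --seed 11 --out runs/demo
```

which simulates a small flyway population, segments it, writes the master
parameter table, the repeatability table (one row per trait × season with
R, CI, permutation p and variance components), the similarity records and
contrast, phase annotations as CSV/GeoJSON, and a manifest that makes the
run byte-for-byte reproducible.

## Layout

```
src/flyway/
  simulate.py       synthetic trajectories + repeated-measures tables with ground truth
  track_io.py       Movebank-dialect CSV in/out, gap filter, GeoJSON/manifest output
  segmentation.py   movement classification, sites, phenology, stopovers, phases
  metrics.py        migration parameter table, clustering, distance classes
  repeatability.py  REML variance components, bootstrap, permutation, sensitivity
  similarity.py     directed nearest-neighbour route fidelity + contrast model
  pipeline.py/cli.py  orchestration and the `flyway` command
docs/methods.md     model, assumptions, parameter choices, limitations
```
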