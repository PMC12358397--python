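# parasdm

Habitat modelling for obligate parasites: a maximum-entropy species
distribution model (SDM) coupled to a host-suitability constraint, with
model tuning, suitability classification, range-change and centroid
analysis, scenario comparison, and land-use overlay — all exercisable on
synthetic landscapes with known truth, so the whole pipeline is testable
without downloading any climate or occurrence data.

## Who this is for

Ecologists and spatial biostatisticians modelling species whose range is
limited not only by climate and soil but by another organism — classically
a root parasite such as *Cistanche deserticola*, which grows only on the
shrub *Haloxylon ammodendron*.  A conventional presence-background SDM
treats the parasite like a free-living plant and overpredicts into
host-free terrain; `parasdm` builds the host into the model.

## The model

The core engine estimates a Gibbs (maximum-entropy) distribution over
grid cells,

    raw(x) = exp(λ·f(x)) / Z,

where f expands predictors into linear, quadratic, product, hinge and
threshold features and λ maximizes the L1-penalized presence
log-likelihood

    (1/m) Σ_presence λ·f(x) − log Σ_background e^{λ·f(b)} − Σ_j β_j |λ_j|.

The penalty widths β_j scale with a regularization multiplier (RM);
candidate models crossing six feature combinations with RM ∈ {0.5, …, 4.0}
are ranked by AICc and the delta.AICc = 0 model is selected.  Suitability
is reported on the logistic scale P ∈ (0, 1).

Host dependency enters twice (the Parasitic Constraint Scenario, PCS):
the host's fitted suitability layer P_HA becomes an extra predictor, and
the *conditional probability transfer* zeroes the parasite's suitability
wherever P_HA < θ (default 0.4).  The environment-only model is the
Natural Habitat Scenario (NHS).  Scenarios are compared per suitability
class (unsuitable/low/medium/high at breaks 0.2/0.4/0.6) by the area
difference rate

    (area_PCS − area_NHS) / area_NHS × 100 %

and by the great-circle shift of the suitable-area centroid.  See
`docs/methods.md` for the full account.

## Worked example

Generate the canonical synthetic host–parasite system (100×100 grid of
2.5′ cells, three correlated predictors, 234 host and 88 parasite
occurrences) and run the two-scenario comparison:

```python
import parasdm as ps

env, host, parasite = ps.make_study_system(seed=7)
host_occ = ps.sample_occurrences(host, 234, seed=8)
par_occ  = ps.sample_occurrences(parasite, 88, seed=9)

comparison = ps.run_two_scenarios(
    par_occ, env, host_occ,
    fc="LQ", rm=1.0,          # fixed settings; omit to tune on the AICc grid
    n_replicates=5, seed=10, n_background=2000,
)
print(comparison.summary_text())
```

which prints

```
class	area_nhs_km2	area_pcs_km2	difference_rate_pct
unsuitable	151856.50	152964.28	0.73
low	8370.07	7069.16	-15.54
medium	6645.70	7261.18	9.26
high	4335.96	3913.61	-9.74
centroid_nhs	83.305	36.054
centroid_pcs	83.035	36.282
centroid_shift_km	35.0
```

Reading this: the host constraint trims the parasite's high-suitability
area by 9.7 % (4336 → 3914 km² on this synthetic landscape) and moves the
suitable-area centroid 35 km — the constrained range is both smaller and
displaced toward the host's core.  The replicate reports give
`comparison.report_nhs.mean_test_auc ≈ 0.933` and
`comparison.report_pcs.mean_test_auc ≈ 0.941`: the host-aware model
discriminates held-out presences slightly better, as expected when the
truth is host-masked.

## Command line

Every stage is also a subcommand of the `parasdm` CLI:

```sh
parasdm simulate --out demo --seed 3            # synthetic landscape + occurrences
parasdm thin --occurrences demo/parasite_occurrences.csv \
             --template demo/env/env1.asc --out thinned.csv
parasdm tune --occurrences thinned.csv --env demo/env --out tuning.csv
parasdm run-study --config study.yaml --out run1 --seed 3
```

`run-study` reads a YAML config (occurrence paths, env directory, theta,
grids, replicates, seed), writes rasters, tuning tables, the scenario
comparison and a manifest that records every parameter and seed needed to
re-run the study bit-stably.  `constrain`, `classify`, `change`,
`centroid` and `landuse` operate on rasters standalone.

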