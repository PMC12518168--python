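# urbanhab

Habitat-suitability and ecological-sensitivity analysis for urban
landscapes: a from-scratch presence-background **maximum-entropy (MaxEnt)
species distribution model**, four-class suitability mapping with
scenario-change accounting, and an **AHP-weighted ecological-sensitivity
index**, built around the kind of study a city-scale insect-conservation
team runs — e.g. butterfly habitat in the Kunming urban core, where
occurrence records from green-space surveys are combined with gridded
bioclimatic, terrain and anthropogenic layers to map where habitat is, how
it shifts under SSP climate scenarios, and which green spaces deserve
monitoring effort.

## The model

Given presence points and a background sample of landscape cells with
features `f(x) ∈ [0,1]^d` (linear, quadratic, product, hinge and
categorical-indicator transforms of the environmental variables), the
estimator chooses the Gibbs distribution over background cells

    raw(x) = exp(λ·f(x)) / Z,   Z = Σ_b exp(λ·f(b)),

whose weights maximise the L1-regularised training gain

    G(λ) = (1/m) Σ_i λ·f(x_i) − log Z + log N − Σ_j β_j |λ_j|,
    β_j = β · s_j / √m,

by cyclic coordinate descent with soft-threshold Newton steps (gain is
non-decreasing by construction, and per-step gain increments drive the
percent-contribution accounting).  Suitability is the entropy-anchored
logistic transform `raw·e^H / (1 + raw·e^H)`.  Evaluation uses AUC
(Mann–Whitney), TSS, and spatially blocked k-fold cross-validation;
variable importance comes from percent contribution, permutation
importance and jackknife gains; response curves yield optimal
environmental ranges at a suitability threshold (default 0.239).

Downstream, logistic surfaces are binned into four classes
(unsuitable [0,0.1), low [0.1,0.3), medium [0.3,0.5), high [0.5,1.0]),
areas are booked in km² per scenario, and changes/centroid shifts are
tracked against a baseline.  The sensitivity overlay computes
`EI = Σ_j Y_j·W_j` from min-max-standardised indicator layers with
hierarchical AHP weights (principal eigenvector, Saaty CR < 0.1 gate), and
zones EI into five levels.

A fully seeded synthetic-data module generates correlated smooth
environmental fields, a known Gibbs truth, presence samples and shifted
"future" stacks, so every stage — including truth-weight recovery — is
testable offline.

## Worked example

```python
import urbanhab as u

scenario = u.demo_scenario(seed=1)            # 100×100 grid, known truth
occ = u.OccurrenceSet(scenario.occurrences)   # 5000 presence points
cov = u.extract_covariates(occ, scenario.baseline_stack)
background = scenario.baseline_stack.table()[["bio7", "bio17", "bio2"]]

spec = u.FeatureSpec(classes=("linear",), beta=0.1)
model = u.fit(cov.table[["bio7", "bio17", "bio2"]], background, spec)
for i, var in enumerate(["bio7", "bio17", "bio2"]):
    lo, hi = model.feature_map.bounds[var]
    print(var, round(model.lambdas[i] / (hi - lo), 3))

cv = u.spatial_cross_validate(occ, scenario.baseline_stack, spec,
                              k=10, block_cells=10, seed=0)
print("CV mean AUC:", round(cv.auc_mean, 4))
```

prints

```
bio7 3.975
bio17 -3.046
bio2 2.535
CV mean AUC: 0.967
```

i.e. the fitted per-variable effects recover the generator's truth
(+4.0, −3.0, +2.5) within ~1.5%, and the spatially blocked cross-validated
discrimination is strong.  The same workflow runs end to end from a YAML
config via the CLI:

```bash
urbanhab simulate --seed 7 --out scenario/
urbanhab thin --occurrences scenario/occurrences.csv --out thinned.csv
urbanhab report --config pipeline.yaml     # full pipeline + report.json
```

The published Kunming class-area table ships as a reference input; its
change accounting is one command:

```bash
urbanhab change --areas src/urbanhab/data/kunming_class_areas.csv \
    --baseline 1970-2000,baseline --total 459 --total-tolerance 0.02
```

which reports, e.g., a suitable-area change of −12.69 km² for SSP1-2.6 in
2021–2040 and a high-class maximum of 138.73 km².

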