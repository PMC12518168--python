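# Methods

This note documents the models, numerical choices and limitations of the
package, module by module, in the order the pipeline runs.

## Rasters and geometry

All layers are ESRI ASCII grids with a lower-left corner origin and row 0 at
the north; in memory NaN is the single canonical nodata value.  Grids must
share one geometry exactly (six header fields to 1e-9) — the pipeline never
resamples, since study layers are assumed standardised to a common
resolution upstream.  Cell area is the equal-area cosine approximation
`(cellsize·111.320·cos φc) × (cellsize·110.574)` km² at the domain-centre
latitude φc.  For a city-scale domain (~0.5°) the bias of treating the area
as constant is far below the km²-scale class-area differences the pipeline
reports.  Point-in-cell assignment uses half-open cells with inclusive
west/north edges, so every point resolves to exactly one cell; distances on
points use the haversine formula with the mean Earth radius 6371.0088 km,
adequate at these scales.  Domain area is data-driven (valid cells × cell
area) rather than a fixed constant, since published clip boundaries are
rarely distributed.

## Synthetic ground truth

The generator exists so that every stage of the analysis has a knowable
right answer without downloading climate data.

* **Fields.** Smooth surfaces are Gaussian-kernel-smoothed seeded white
  noise standardised to zero mean/unit variance; `smoothness` is the kernel
  length-scale in cells (0 = white noise).
* **Correlation.** Latent fields are empirically orthonormalised (QR over
  cells) before mixing with the Cholesky factor of the target correlation
  matrix, so generated layers hit the requested *sample* correlations
  exactly — which makes collinearity-screening tests sharp.
* **Terrain.** Elevation is a broad smooth field plus a ridged component;
  slope/aspect use Horn's 3×3 method (the de-facto GIS standard), aspect
  reported as the downslope bearing clockwise from north, flat cells −1.
* **Truth and presences.** Presences are drawn over valid cells with
  probability ∝ exp(Σ w_v x_v) — the same exponential-family law the
  estimator fits — and jittered uniformly within the cell; a "logistic"
  truth kind is available as a deliberate misspecification toggle.  Future
  stacks are the baseline plus per-variable additive/multiplicative shifts.
* **The bundled study.** `demo_config()` defines a 100×100 grid
  (cellsize 0.0055°, ≈0.55° domain at Kunming-like coordinates), three
  correlated climate-like fields (length-scale 5 cells, r(bio7,bio2)=0.3),
  truth weights bio7 +4.0, bio17 −3.0, bio2 +2.5 — strong enough that
  discrimination survives spatially blocked evaluation — n = 5000
  presences, and warming/drying shifts for two periods × three emission
  pathways.  These sizes keep the full recovery study (fit + 10-fold
  blocked CV + importance + jackknife) to a few seconds on one CPU.

What the generator does **not** emulate: sampling bias, observation error,
non-stationary spatial covariance, realistic climate downscaling, or biotic
interactions.  Passing recovery tests therefore demonstrates correctness of
the estimator under its own assumptions, not real-world predictive skill.

## Occurrence handling

Loading drops and counts rows with unparseable or out-of-range coordinates.
Spatial thinning is greedy in input order (keep a record iff ≥ radius from
every previously kept record, default 1 km): deterministic, idempotent, and
standard SDM practice; the optimal maximum-independent-set variant is
deliberately avoided.  The train/test split takes round(fraction·n) records
(round-half-even), optionally stratified by a site-type column; the default
is simple random, with stratification exposed as a flag because published
workflows often say "stratified" without defining strata.

## Collinearity screening

Pearson r over shared valid cells (optionally a seeded subsample),
categorical layers excluded (undefined for nominal data) and retained by
default.  Pairs with |r| ≥ 0.8 (inclusive) are resolved against a
user-supplied ecological priority list: flagged pairs are visited in
priority order and the lower-priority member of each still-retained pair is
dropped.  This makes the "retain ecologically meaningful variables" step
reproducible and auditable; the screened set provably contains no flagged
pair.  Constant layers correlate 0 with everything, with a warning.

## The maximum-entropy estimator

* **Features.** Continuous variables are min-max scaled on the *training
  background* bounds; linear, squared, pairwise-product, and k forward +
  k reverse hinge features (knots at background quantiles, default 10 per
  direction), plus one indicator per observed category for categorical
  variables.  All components lie in [0,1] on the background.  Constant
  variables contribute no features (warning).
* **Regularisation.** β_j = β·s_j/√m with s_j the feature's presence-sample
  standard deviation floored at 1e-3: this captures the sample-size
  dependence of the classic MaxEnt regularisation without its per-class
  lookup tables; the single multiplier β is the user's tuning knob
  (default 1.0).
* **Optimiser.** Cyclic coordinate descent; each update is a Newton
  soft-threshold step on one weight with a backtracking halving line
  search, so the regularised gain is non-decreasing along the whole path
  (asserted by tests and matched to a generic convex optimiser to 1e-4 on
  small instances).  An "iteration" is one coordinate update;
  convergence = a full sweep improving the gain by < tol (default 1e-5)
  within the iteration budget (default 5000); exhausting the budget sets
  `converged=False` rather than raising.  Each step's gain increment is
  credited to the updated feature's source variable (half each for
  products) — that path-defined credit is what percent contribution
  normalises to 100%.
* **Outputs.** Raw output is normalised over the training background
  (Σ raw = 1 to 1e-9).  The suitability output is the entropy-anchored
  logistic `raw·e^H/(1+raw·e^H)` — the classic default transform, with
  cloglog behind a flag.  Projection values outside the training range are
  clamped to the bounds ("fade by clamping") and counted, since published
  workflows rarely state an extrapolation policy.
* **Background.** All shared-valid cells up to 10,000, else a seeded
  sample — a conventional default; background size is exposed everywhere.
* **Evaluation.** AUC via the Mann–Whitney statistic with ties counted ½;
  TSS maximised over midpoints of observed scores (lowest threshold on
  ties), background treated as pseudo-absences.  Spatial cross-validation
  tiles the grid into square blocks (size in cells is a config knob,
  default 10), shuffles blocks with the seed, assigns them round-robin to k
  folds, fits on out-of-fold presences/background, and scores in-fold
  presences against in-fold background; folds without test presences are
  skipped with a warning — expected when a strongly concentrated species
  occupies few blocks.
* **Importance.** Permutation importance permutes one variable jointly
  across presence + background rows (default 10 repetitions), takes the
  mean AUC drop, floors negatives at 0 and normalises to 100%.  Jackknife
  refits with-only/without each variable at the same per-feature β
  schedule, so gain-without can never exceed the full gain beyond numerical
  slack.  Response curves sweep one variable across its background range
  with the others at background means (categoricals at mode); the optimal
  range is where suitability ≥ a threshold, default 0.239 — a literature
  convention shipped as a config default, not derivable from first
  principles.
* **Persistence.** Models serialise to a single JSON document (feature
  definitions, normalisation bounds, λ, log-partition, entropy, gain
  bookkeeping), which round-trips exactly.

## Suitability classes and change accounting

Bins are left-closed/right-open with a closed top bin: [0,0.1) unsuitable,
[0.1,0.3) low, [0.3,0.5) medium, [0.5,1.0] high — published intervals touch
at the printed endpoints, so the boundary convention is fixed here and
tested.  Class areas are cell counts × cell area.  Change accounting
reports per-class deltas against a baseline row; the total-suitable delta
is computed as −Δ(unsuitable), which is identical to Δ(low+medium+high)
when row totals agree exactly and remains internally consistent for tables
digitised from rounded print (such tables need an explicit row-total
tolerance, e.g. 0.02 km²; the strict default is 1e-6 of the total).
Centroids are unweighted means of class cell centres (a suitability-
weighted variant would be a one-line change; unweighted is the default
because published analyses rarely state the weighting), with haversine
distance and initial bearing.  Site screening reports, per site, its class
and a status of ok / flagged / off-grid — off-grid sites are listed, never
silently dropped.

## Ecological sensitivity

Weights come either directly from a published two-level table (group ×
factor, both levels summing to 1; effective weight = product, renormalised
to absorb printed-rounding residue) or from pairwise comparison matrices
via the principal-eigenvector AHP with Saaty's RI table and the CR < 0.1
gate (orders 1–9).  Indicators are min-max standardised with an explicit
benefit/cost direction flag — the direction of each indicator is a
modelling decision that ships in configuration, not code.  EI is the
weighted sum, guaranteed in [0,1].  Zoning is equal-interval
([0,0.2)→1 … [0.8,1]→5) by default because it is parameter-free and
reproducible; exact Jenks natural breaks (O(k·n²) dynamic programming, on a
seeded subsample of at most 2000 cells for large rasters) are available
behind a flag since published break values are usually unstated.  The
overlay is a 5×4 sensitivity-level × suitability-class km² contingency
table.

## Pipeline and CLI

All intermediate artefacts are plain text (ASCII grids, CSV, JSON, JSONL
event log), so stages are independently inspectable and the CLI subcommands
(`simulate, thin, screen, fit, evaluate, classify, change, sensitivity,
report`) compose through files.  A single config seed feeds every stage
through derived child seeds; re-running a config reproduces all artefacts
bit-for-bit.  A `STALE` marker file flags aborted runs.  `fit` exits
nonzero when the optimiser did not converge.

## Known limitations

* No reprojection/resampling, no vector-data processing (road networks,
  lake polygons), no GeoTIFF/cartographic output — rasters in and out are
  ASCII grids.
* The equal-area cell approximation and spherical distances are city-scale
  tools; continental domains would need a proper equal-area projection.
* Percent contribution depends on the coordinate-descent path (as in the
  reference accounting); permutation importance is the path-independent
  alternative reported alongside.
* The coordinate-descent iteration cap, not a trust-region safeguard,
  bounds degenerate fits (e.g. perfectly separable binary features), where
  weights legitimately diverge.
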