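# Methods

## Measurement model

The package treats a street scene photograph as a noisy sensor of its
surroundings. A per-pixel classifier over the 19-class street-scene palette
turns each image into class pixel fractions f_c ∈ [0, 1]; with the void
(unlabeled) fraction these sum to 1, an invariant enforced on every summary.
Fractions rather than raw pixel counts are used throughout so image
resolution never enters the analysis.

Neighbourhood-scale exposures are means of image fractions over a zone.
Three zone constructions are available:

* `l1_diamond` (default for postal-code centroids): the taxicab ball
  {|dx| + |dy| ≤ r} — the literal reading of a "Manhattan-style buffer";
* `euclidean_disc` (default for intersection buffer sweeps);
* `network`: street locations within path distance r of the anchor's
  nearest network point, padded into a 25 m corridor polygon.

All three are closed regions (boundary points belong to the zone) so
membership is deterministic. For the analytic metrics the exact distance
predicate, not the polygon discretization, decides membership.

Targets keep their native municipal units and are standardized only at
modeling time, because different cities define nominally identical counts
differently (annualized counts vs rush-hour totals).

## Sampling

Points are placed on every segment with the centered rule: a segment of
length L gets n = max(1, ⌊L / s⌋) points at offsets (i − ½)·L/n, with
s = 150 m by default. The rule reproduces the midpoint convention for
short segments as its n = 1 case and leaves half-interval margins at
segment ends. 150 m matches the ~75–100 m distance at which street objects
remain detectable, trading a little overlap against missed coverage.
Points are never deduplicated across adjacent segments.

A point whose four cardinal images are all unavailable is excluded;
partial imagery (1–3 images) keeps the point, with only the fetched images
contributing. Discarding partially-imaged points would be stricter than
the exclusion rule requires.

Hexagonal thinning (`hex_downsample`) covers the points' bounding box with
a flat-top hexagonal grid (`cell_width_m` = across-flats width, 50–500 m)
and keeps, per cell, the point nearest the cell centroid, ties broken by
smallest point id — an arbitrary but reproducible rule.

## Models and evaluation

Families: ordinary least squares; gradient-boosted trees (200 trees,
learning rate 0.1, depth chosen from {2, 3, 4}); RBF support-vector
regression (cost from {0.25, 1, 4}, bandwidth by the scale heuristic).
Grid parameters are selected by an inner 3-fold CV inside each training
fold, so out-of-fold predictions never see their own tuning.

Fivefold CV is stratified by target quartile and derived deterministically
from the seed. RMSE and MAE are computed on the pooled out-of-fold
predictions; R² is their squared Pearson correlation with the
observations, defined as 0 when predictions are constant. This keeps R²
in [0, 1] and matches the convention of reporting R² = 0.00 for models
with no out-of-sample signal.

Transfer: features are standardized with the *training* city's statistics
everywhere; targets within city (default), since the two cities' traffic
targets are not the same quantity. The calibration gap is mean(prediction)
− mean(observation) on the test city. Both standardization policies are
supported; the choice changes metric interpretation and is recorded with
the stats' provenance.

Buffer sweep: radii 50, 100, …, 2000 m (40 values). Besides the raw
argmin of cv-RMSE, the smallest radius within one standard error (over
folds) of the minimum is reported, operationalizing the size-vs-accuracy
tradeoff; under exactly flat performance this degenerates to the smallest
radius.

Sidewalk classification: an image detects a sidewalk when its sidewalk
fraction reaches τ = 0.005 of image area (τ = 0 degenerates to "any
sidewalk pixel"); a segment is positive when any of its images detects
one. Binary "detected" needs a threshold once the evidence is a fraction;
half a percent rejects stray pixels while catching any visible sidewalk.
Zone sidewalk length sums positively-labelled segments clipped to the zone
polygon (clipping makes the measure monotone in zone radius).

## Synthetic city generator

The generator is a pure function of `CityConfig` (every stage draws from a
seed-derived stream), emulating the study design end to end:

* **Network**: a jittered grid, `grid_n` blocks of `block_m` = 150 m;
  middle row/column arterial, outer ring rural, rest residential.
* **Trees**: inhomogeneous Poisson along streets; intensity =
  `tree_base_per_m` (0.04 /m) × a smooth Gaussian-bump field (range
  ≈ 0.2–2). Trees sit 2–8 m off the roadway.
* **Sidewalks**: Bernoulli by road class (residential 0.9, arterial 0.7,
  rural 0.05).
* **Traffic, signs, lights**: gravity-style decay from the city centre
  (length scale 1200 m) with an arterial boost; lights and signs
  concentrate at arterial intersections.
* **Image summaries**: linear links on local truth with per-image Gaussian
  noise, clipped to [0, 1]; building and sky absorb the remainder so
  conservation holds exactly. Vegetation rises with trees visible within
  75 m of the point (each tree attaches to its nearest sample point);
  visible road falls with traffic; car pixels mix a driving term
  (+ traffic) with a parked term (+ parked-car prevalence, − traffic), so
  high parking makes the car fraction *anticorrelate* with traffic;
  rural segments without sidewalks can show a paved-shoulder signal with
  probability `shoulder_confusion`. A "test city" is the same machinery
  with a shift block: more parking (0.85 vs 0.35), more shoulder
  confusion, and a rescaled, noisier traffic-count definition.
* **Masks** (optional path): summaries rasterize to 64×64 label masks by
  largest-remainder apportionment, exact to one pixel (1/4096), and render
  to RGB via the standard palette for the image→mask round trip.

Calibration: `calibrate_vegetation_noise` finds the per-image noise sd at
which the zone-level squared correlation between the vegetation feature
and the tree-count target equals a requested population R² (0.60 in the
recovery experiment). An analytic attenuation formula seeds a bisection on
the actually rendered system, so clipping and conservation renormalization
are accounted for rather than assumed away.

What the generator does **not** emulate: real image appearance (and hence
real segmentation error structure beyond the confounders modelled above),
irregular street topologies, panorama capture-point geometry, seasonal or
temporal imagery variation, and spatial autocorrelation of model errors.
Passing tests therefore demonstrate that the pipeline machinery is correct
and recovers designed effects — not that a particular real city would
yield comparable accuracy.

## Problem sizes and numerical choices

Experiments use city sizes chosen to keep estimates stable at desk scale:
the effect-size recovery uses a 24-block city (1200 segments, ≈ 4800
images) with 400 postal zones of 500 m radius; transfer and sweep
experiments use 16-block cities (289 intersections); thinning uses a
22-block city (1012 points). Fold splits, generator draws and model seeds
all derive from a single integer seed; two runs with the same seed are
byte-identical. Degenerate inputs fail loudly: zero-sd variables in
standardization, zones without imagery (flagged missing and dropped from
modeling), backends returning wrong shapes or labels, anchors farther than
the radius from the network.

## Known limitations

* The local equirectangular projection used for degree inputs is accurate
  well below 0.5% at city scale but is not a substitute for a proper
  projected CRS over large or high-latitude extents.
* Network buffers approximate the service area with a 25 m corridor
  polygon; very dense parallel streets closer than the pad width can merge.
* The real-API image client is a documented, cache-backed stub; it
  performs no network access unless a transport is injected.
* Real-city accuracy depends on proprietary imagery, trained segmentation
  weights, and municipal ground-truth extracts, none of which ship here;
  the synthetic experiments reproduce directions and mechanisms, not
  real-deployment magnitudes.
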