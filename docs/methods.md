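# Methods

## Model

One half of the embryonic heart is represented as a rectangular slab.
The heart surface is approximated by a sphere of radius `r` (default
315 µm, measured at e13.5), so the slab's square face has area
`2πr²` ≈ 623,449 µm² (side ≈ 789.6 µm); its depth (default 97.5 µm)
spans epicardium to endocardium. The slab is a plain box: no curvature,
no periodic boundaries, no edge correction.

Clone formation is a homogeneous spatial Poisson process. For a clone
generation rate `m` (expected clones per half heart), the clone count
is `X ~ Poisson(m)`; centroids are i.i.d. uniform over the slab volume.
Only centroids are constrained to the box — the clone spheres (radius
54 µm, the average clone dimension at e13.5) may protrude through the
slab faces.

Because an experimenter only ever scores hearts that show at least one
labeled cluster, simulations are conditioned on `X ≥ 1`, making the
clone count zero-truncated Poisson with
`P(X = k | X ≥ 1) = e^{-m} m^k / (k! (1 - e^{-m}))`. Conditioning is
implemented by rejection sampling (redraw on zero), which leaves the
truncated distribution unbiased; a cap of 10⁶ consecutive rejections
turns an unsatisfiable condition (`m = 0`) into an error instead of a
hang.

## Cluster merging

Two clones are scored as one observed cluster when cells from the two
clones cannot be separated under the microscope. Cells fill the clone
sphere, so the default rule (`merge_metric="surface"`) links two clones
when the gap between their sphere surfaces is below the discrimination
distance `d`, i.e. when centroid distance `< 2·54 + d` (158 µm at the
default `d = 50 µm`). Observed clusters are the connected components
of the link graph — single linkage, the transitive closure of pairwise
links. The inequality is strict: a pair at exactly the threshold stays
separate (a measure-zero event either way; the strict reading matches
"closer than").

The cutoff could also be read as a centroid-to-centroid distance
(`merge_metric="centroid"`, threshold `d` itself). The two readings
were compared at full scale with the default parameters:

| metric   | threshold | calibrated m | clonality |
|----------|-----------|--------------|-----------|
| surface  | 158 µm    | ~4.0         | ~0.83     |
| centroid | 50 µm     | ~3.2         | ~0.99     |

Under the centroid reading merging is almost nonexistent (a 50 µm
centroid separation means heavily overlapping 54 µm spheres), so
essentially every cluster is scored clonal — inconsistent with the
known behaviour of the analysis this package implements. The surface
reading is therefore the default; the centroid variant remains
available for exploration.

## Calibration and clonality

`m` is estimated by moment matching on a grid, default 0.5–10.0 in
steps of 0.1. The grid range follows the analysis being reproduced;
the 0.1 step resolves mean-cluster differences (~0.06–0.08 per step)
comfortably above the Monte Carlo noise of the mean at 10,000
simulations per grid point (SE ≈ 0.016). For each grid value the mean
observed cluster count over 10,000 conditioned regions is computed;
`best_m` minimizes the absolute deviation from the observed target mean
(default 3.3 clusters per half heart), ties broken toward the smaller
rate. A target outside the attainable range of the curve flags the
result as extrapolated rather than failing.

The clonality rate is the fraction of observed clusters comprising
exactly one clone, pooled over all clusters of all regions
(cluster-weighted, not region-averaged, per the definition of the
quantity: a property of clusters, not of hearts). It is computed from
a *fresh* batch of 10,000 simulations at `best_m`, not from the
calibration draws, so that selecting the best-fitting grid point cannot
bias the estimate. Each estimate carries a binomial-approximation
standard error `sqrt(p(1-p)/N)` over the `N` pooled clusters (~33,000
at the calibrated rate), about 0.2 percentage points — small against
the seed-to-seed spread, which is itself under 2 points.

The per-cluster-count stratification reports the pooled clonality
restricted to regions with exactly `c` clusters, `c = 1..6`; counts
with no regions are reported as missing, not zero. The sensitivity
sweep recalibrates from scratch at each discrimination distance
(the mean-cluster curve shifts with the cutoff, so `best_m` must be
re-estimated) and shares the root seed across distances (common random
numbers).

## Randomness and reproducibility

All randomness flows from one root seed (`SimulationConfig.seed`)
through `numpy.random.SeedSequence`. Child streams are spawned per
batch — one per grid point plus one for the fresh clonality batch —
with sequential consumption inside a batch; a fixed configuration
therefore reproduces every output byte for byte, which the tests assert
on CSV output. Distances are exact Euclidean in double precision; with
~4 clones per region, the O(k²) adjacency plus flood fill is both exact
and fast (~10⁶ regions in well under a minute), so no spatial index is
used.

## Synthetic cohorts

`heartclones.synthetic` forward-simulates the model itself to create
mock observed datasets: each synthetic heart is one conditioned region
at a known `true_m`, and the recorded observation is its cluster count
— what microscopy provides — while clone positions are retained
separately for independent re-tallies in tests. Cohort summaries use
the sample standard deviation (`n−1` denominator; configurable). The
generator emulates the statistical structure the analysis assumes
(truncated-Poisson clone counts, uniform placement, perfect cluster
detection); it does not emulate imaging noise, missed or split
clusters, fluorophore detection efficiency, or anatomical deviations
from the slab geometry, so recovery tests validate the inference
machinery, not the realism of those assumptions.

Parameter-recovery tests use cohorts of 10,000 hearts and 10,000
simulations per grid point so that the combined Monte Carlo error on
the recovered rate (~0.04) sits well inside the one-grid-step (0.1)
recovery criterion; the production analysis itself always uses the
10,000-simulation protocol above.

## Known limitations

- Clones are static, identical spheres; growth over developmental
  time, migration and anisotropic shapes are out of scope.
- Only the observed *mean* cluster count is matched; the per-heart
  count distribution is not fit, and no likelihood-based or Bayesian
  estimate of `m` is attempted.
- The geometry constants (315 µm radius, 97.5 µm depth, 54 µm clone
  radius, 50 µm cutoff) are taken as given empirical measurements; the
  package does not model their uncertainty beyond the discrimination-
  distance sweep.
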