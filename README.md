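# heartclones

Simulation-based clonality analysis for sparsely labeled cell clusters
in the embryonic heart.

## The problem

Sparse genetic labeling (e.g. MADM, Mosaic Analysis with Double Markers)
marks rare progenitor cells and all of their progeny with a fluorophore.
An experimenter looking at an embryonic heart sees a handful of labeled
cell *clusters* per half heart and would like to treat each cluster as a
*clone* — the progeny of a single labeling event. But if two independent
labeling events happen to land close together, their clones merge into
one apparent cluster and the clonal interpretation is wrong for that
cluster. `heartclones` quantifies how often that happens.

## The model

A half heart is modeled as a box of face area `2πr²` (half the surface
of a sphere of radius `r = 315 µm`) and depth `97.5 µm` (epicardium to
endocardium). Clones are spheres of radius `54 µm`. For a clone
generation rate `m`, the number of clones per half heart is
`X ~ Poisson(m)`, conditioned on `X ≥ 1` (unlabeled hearts are never
scored, so `X` is zero-truncated Poisson); clone centroids are uniform
in the box. Two clones merge into one observed cluster when the gap
between their sphere surfaces is smaller than the discrimination
distance `d = 50 µm` — i.e. centroids closer than `2·54 + 50 = 158 µm`
— and clusters are the single-linkage (transitive) closure of that
relation.

The rate `m` is not observable; it is calibrated on a grid
(0.5–10.0, step 0.1) by matching the simulated mean cluster count per
half heart (10,000 simulations per grid point) to the observed mean of
3.3 clusters. The **clonality rate** — the fraction of observed
clusters consisting of exactly one clone — is then estimated from a
fresh batch of 10,000 simulations at the calibrated rate, overall and
stratified by the number of clusters per heart. A sensitivity sweep
repeats the entire calibration at alternative discrimination distances
(25, 75, 100 µm).

## Worked example

```python
from heartclones import (
    RateGrid, SimulationConfig, calibrate_rate, make_half_heart_slab,
)

config = SimulationConfig(geometry=make_half_heart_slab(),  # 315 µm / 97.5 µm
                          n_sims=10_000, seed=20315)
result = calibrate_rate(target_mean=3.3, grid=RateGrid.from_range(),
                        config=config)
print(f"best_m={result.best_m}  "
      f"clonality={result.clonality_at_best:.4f} ± {result.clonality_se:.4f}")
for count, rate in sorted(result.clonality_by_count.items()):
    print(f"  hearts with {count} clusters: clonality {rate:.3f}")
```

prints

```
best_m=4.0  clonality=0.8271 ± 0.0021
  hearts with 1 clusters: clonality 0.789
  hearts with 2 clusters: clonality 0.811
  hearts with 3 clusters: clonality 0.818
  hearts with 4 clusters: clonality 0.825
  hearts with 5 clusters: clonality 0.840
  hearts with 6 clusters: clonality 0.848
```

meaning: a generation rate of about 4 clones per half heart best
reproduces the observed mean of 3.3 clusters (merging makes clusters
scarcer than clones), and at that rate about 83% of observed clusters
derive from a single labeling event — similarly across hearts showing
1–6 clusters.

The same analysis from the shell:

```sh
heartclones calibrate --out-dir runs/default --seed 20315
heartclones sweep --disc-dists 25,50,75,100 --out-dir runs/sweep --seed 20315
```

which writes the rate curves, the per-cluster-count table, the sweep
table and a `manifest.json` sufficient to reproduce every output byte
for byte (`--config runs/default/manifest.json`).

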