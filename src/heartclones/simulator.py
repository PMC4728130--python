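"""Monte Carlo simulation of clone formation in a half-heart slab.

One simulated region is produced in three steps: the number of clones is
drawn from a Poisson distribution with rate ``m`` (the clone generation
rate, expected clones per half heart); clone centroids are placed
uniformly at random in the slab volume; and clones lying closer than the
merge threshold are joined, by single linkage, into observed "clusters".

A clone is the sphere of labeled cells descending from one recombination
event (radius 54 µm by default).  Under the microscope two clones whose
cells come within the discrimination distance of each other cannot be
told apart, so the default merge rule links two clones when the gap
between their sphere surfaces is smaller than the discrimination
distance, i.e. when their centroids are closer than
``2*clone_radius + disc_dist``.  A centroid-to-centroid reading of the
cutoff is retained as an option (``merge_metric="centroid"``).

Simulations are normally conditioned on containing at least one clone
(only hearts with visible labeled clusters are ever scored), which makes
the clone count zero-truncated Poisson; conditioning is implemented by
rejection sampling.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterator, Literal, Sequence

import numpy as np
import pandas as pd

from .geometry import GeometryParams, make_half_heart_slab

__all__ = [
    "SimulationConfig",
    "RegionSim",
    "sample_clone_count",
    "place_clone_centroids",
    "merge_into_clusters",
    "simulate_region",
    "simulate_regions",
    "regions_to_frame",
    "DEFAULT_CLONE_RADIUS",
    "DEFAULT_DISC_DIST",
    "DEFAULT_N_SIMS",
]

#: Default clone sphere radius (µm), the average e13.5 clone dimension.
DEFAULT_CLONE_RADIUS = 54.0
#: Default discrimination distance (µm).
DEFAULT_DISC_DIST = 50.0
#: Default number of simulated regions per setting.
DEFAULT_N_SIMS = 10_000

#: Consecutive empty-region rejections tolerated before erroring.
_MAX_REJECTIONS = 10**6

MergeMetric = Literal["surface", "centroid"]


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one simulation experiment.

    ``rate_m`` is the Poisson intensity: the expected number of clones
    generated per half heart.  ``merge_metric`` selects how the
    discrimination distance is applied: ``"surface"`` (default) links
    clones whose sphere surfaces are separated by less than
    ``disc_dist``; ``"centroid"`` links clones whose centroids are.
    """

    geometry: GeometryParams = field(default_factory=make_half_heart_slab)
    clone_radius: float = DEFAULT_CLONE_RADIUS
    disc_dist: float = DEFAULT_DISC_DIST
    rate_m: float = 1.0
    merge_metric: MergeMetric = "surface"
    condition_nonempty: bool = True
    n_sims: int = DEFAULT_N_SIMS
    seed: int = 0

    def __post_init__(self) -> None:
        if self.clone_radius < 0:
            raise ValueError("clone_radius must be non-negative")
        if self.disc_dist < 0:
            raise ValueError("disc_dist must be non-negative")
        if self.rate_m < 0:
            raise ValueError("rate_m must be non-negative")
        if self.n_sims < 1:
            raise ValueError("n_sims must be at least 1")
        if self.merge_metric not in ("surface", "centroid"):
            raise ValueError(f"unknown merge_metric {self.merge_metric!r}")

    @property
    def merge_threshold(self) -> float:
        """Centroid-distance threshold below which two clones merge (µm)."""
        if self.merge_metric == "surface":
            return 2.0 * self.clone_radius + self.disc_dist
        return self.disc_dist

    def with_rate(self, rate_m: float) -> "SimulationConfig":
        return replace(self, rate_m=rate_m)


@dataclass(frozen=True)
class RegionSim:
    """One simulated half-heart region.

    Attributes
    ----------
    clones : ndarray, shape (k, 3)
        Clone centroids (x, y, z) in µm.
    labels : ndarray, shape (k,)
        Cluster label of each clone; labels are consecutive integers
        starting at 0 in order of first appearance.
    """

    clones: np.ndarray
    labels: np.ndarray

    @property
    def n_clones(self) -> int:
        return len(self.clones)

    @property
    def cluster_sizes(self) -> np.ndarray:
        """Number of clones in each cluster, indexed by label."""
        if len(self.labels) == 0:
            return np.zeros(0, dtype=np.intp)
        return np.bincount(self.labels)

    @property
    def n_clusters(self) -> int:
        return len(self.cluster_sizes)

    @property
    def n_singleton_clusters(self) -> int:
        """Number of clusters consisting of exactly one clone."""
        return int(np.count_nonzero(self.cluster_sizes == 1))

    @property
    def clusters(self) -> list[np.ndarray]:
        """Partition of clone indices into clusters, by label order."""
        return [
            np.flatnonzero(self.labels == c) for c in range(self.n_clusters)
        ]


def sample_clone_count(rate_m: float, rng: np.random.Generator) -> int:
    """Draw the number of clones in one region from Poisson(``rate_m``)."""
    if rate_m < 0:
        raise ValueError("rate_m must be non-negative")
    return int(rng.poisson(rate_m))


def place_clone_centroids(
    k: int, geometry: GeometryParams, rng: np.random.Generator
) -> np.ndarray:
    """Place ``k`` clone centroids uniformly in the slab volume.

    Returns an array of shape ``(k, 3)``; x and y range over
    ``[0, slab_side]`` and z over ``[0, slab_depth]``.  Only centroids
    are constrained to the box — clone spheres may protrude past the
    slab faces.
    """
    if k < 0:
        raise ValueError("k must be non-negative")
    pts = rng.uniform(size=(k, 3))
    pts[:, 0] *= geometry.slab_side
    pts[:, 1] *= geometry.slab_side
    pts[:, 2] *= geometry.slab_depth
    return pts


def merge_into_clusters(
    clones: np.ndarray,
    clone_radius: float,
    disc_dist: float,
    merge_metric: MergeMetric = "surface",
) -> np.ndarray:
    """Single-linkage merging of clones into observed clusters.

    Two clones are directly linked when their centroid distance is
    strictly below the merge threshold (``2*clone_radius + disc_dist``
    for the surface metric, ``disc_dist`` for the centroid metric);
    clusters are the connected components of the link graph, i.e. the
    transitive closure of direct links.  Boundary ties (distance exactly
    equal to the threshold) are not merged.

    Returns the cluster label of every clone, with labels numbered in
    order of first appearance.
    """
    if clone_radius < 0:
        raise ValueError("clone_radius must be non-negative")
    if disc_dist < 0:
        raise ValueError("disc_dist must be non-negative")
    if merge_metric == "surface":
        threshold = 2.0 * clone_radius + disc_dist
    elif merge_metric == "centroid":
        threshold = disc_dist
    else:
        raise ValueError(f"unknown merge_metric {merge_metric!r}")

    pts = np.asarray(clones, dtype=float)
    k = len(pts)
    labels = np.full(k, -1, dtype=np.intp)
    if k == 0:
        return labels
    diff = pts[:, None, :] - pts[None, :, :]
    adjacent = np.einsum("ijk,ijk->ij", diff, diff) < threshold * threshold
    np.fill_diagonal(adjacent, False)

    # Breadth-first flood fill over the adjacency matrix; regions hold
    # at most a few dozen clones so O(k^2) storage is immaterial.
    next_label = 0
    for start in range(k):
        if labels[start] >= 0:
            continue
        labels[start] = next_label
        frontier = [start]
        while frontier:
            i = frontier.pop()
            for j in np.flatnonzero(adjacent[i]):
                if labels[j] < 0:
                    labels[j] = next_label
                    frontier.append(j)
        next_label += 1
    return labels


def simulate_region(
    config: SimulationConfig, rng: np.random.Generator
) -> RegionSim:
    """Simulate one half-heart region under ``config``.

    Draws the clone count, places centroids, and merges clones into
    clusters.  With ``condition_nonempty`` set, zero-clone draws are
    rejected and redrawn so the returned clone count follows the
    zero-truncated Poisson distribution.

    Raises
    ------
    RuntimeError
        If conditioning cannot be satisfied (e.g. ``rate_m`` is 0) after
        a bounded number of rejections.
    """
    k = sample_clone_count(config.rate_m, rng)
    if config.condition_nonempty:
        rejections = 0
        while k == 0:
            rejections += 1
            if rejections > _MAX_REJECTIONS:
                raise RuntimeError(
                    "could not draw a non-empty region; rate_m is zero "
                    "or vanishingly small"
                )
            k = sample_clone_count(config.rate_m, rng)
    pts = place_clone_centroids(k, config.geometry, rng)
    labels = merge_into_clusters(
        pts, config.clone_radius, config.disc_dist, config.merge_metric
    )
    return RegionSim(clones=pts, labels=labels)


def simulate_regions(
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
    n: int | None = None,
) -> Iterator[RegionSim]:
    """Yield ``n`` (default ``config.n_sims``) independent regions.

    When ``rng`` is omitted a fresh generator is seeded from
    ``config.seed``, so a fixed config reproduces the exact same
    sequence of regions.
    """
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    if n is None:
        n = config.n_sims
    for _ in range(n):
        yield simulate_region(config, rng)


def regions_to_frame(regions: Sequence[RegionSim]) -> pd.DataFrame:
    """Flatten regions into a clone-level table.

    Columns: ``region_id, clone_id, x, y, z, cluster_id`` — one row per
    clone.  Intended for debugging dumps and for recomputing cluster
    statistics by an independent tally.
    """
    rows = []
    for rid, region in enumerate(regions):
        for cid in range(region.n_clones):
            x, y, z = region.clones[cid]
            rows.append((rid, cid, x, y, z, int(region.labels[cid])))
    return pd.DataFrame(
        rows, columns=["region_id", "clone_id", "x", "y", "z", "cluster_id"]
    )
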