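"""Synthetic observed datasets for end-to-end testing of calibration.

The real experimental input to the analysis is a list of per-half-heart
labeled-cluster counts (summarized as mean ± sd).  This module
forward-simulates the clone-formation model itself at a known generation
rate and records, for each synthetic heart, only what a microscopist
would see: the number of merged clusters.  Calibration can then be run
against the synthetic summary and checked for recovery of the known
rate.  Clone positions are retained separately so that cluster
statistics can be re-tallied independently in tests.

No imaging noise, missed clusters, or detection efficiency is modeled:
observed clusters are treated as perfectly detected, exactly as the
clone-formation model assumes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .inference import ObservedSummary
from .simulator import RegionSim, SimulationConfig, simulate_region

__all__ = [
    "SyntheticStudy",
    "generate_observed_hearts",
    "summarize_observed",
    "write_study",
    "read_study",
]


@dataclass(frozen=True)
class SyntheticStudy:
    """A synthetic cohort of half hearts with known generation rate.

    ``per_heart_counts`` is the observation an experimenter records (one
    cluster count per heart); ``regions`` keeps the underlying simulated
    clone positions and partitions for oracle checks.
    """

    true_m: float
    n_hearts: int
    per_heart_counts: tuple[int, ...]
    summary: ObservedSummary
    regions: tuple[RegionSim, ...]

    def __post_init__(self) -> None:
        if len(self.per_heart_counts) != self.n_hearts:
            raise ValueError("per_heart_counts length must equal n_hearts")


def summarize_observed(
    per_heart_counts: Sequence[int], ddof: int = 1
) -> ObservedSummary:
    """Mean and sample standard deviation of per-heart cluster counts.

    Uses the ``n - 1`` denominator by default; a single heart yields
    ``sd = 0``.  Raises ``ValueError`` on an empty list or non-positive
    counts.
    """
    return ObservedSummary.from_counts(per_heart_counts, ddof=ddof)


def generate_observed_hearts(
    true_m: float,
    n_hearts: int,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> SyntheticStudy:
    """Forward-simulate a cohort of hearts at a known generation rate.

    Each heart is one conditioned region at ``true_m``; its recorded
    observation is the cluster count.  All counts are therefore >= 1.
    """
    if true_m <= 0:
        raise ValueError("true_m must be positive")
    if n_hearts < 1:
        raise ValueError("n_hearts must be at least 1")
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    sim_config = config.with_rate(true_m)
    if not sim_config.condition_nonempty:
        raise ValueError(
            "synthetic hearts must be conditioned on >= 1 clone; an "
            "experimenter never scores an unlabeled heart"
        )
    regions = tuple(simulate_region(sim_config, rng) for _ in range(n_hearts))
    counts = tuple(r.n_clusters for r in regions)
    return SyntheticStudy(
        true_m=float(true_m),
        n_hearts=n_hearts,
        per_heart_counts=counts,
        summary=summarize_observed(counts),
        regions=regions,
    )


def write_study(study: SyntheticStudy, csv_path: str | Path) -> Path:
    """Write a study as CSV (heart_id, n_clusters) plus a JSON sidecar.

    The sidecar (``<stem>.json`` next to the CSV) records ``true_m``,
    ``n_hearts`` and the summary statistics so the study provenance
    survives the plain-text round trip.  Returns the sidecar path.
    """
    csv_path = Path(csv_path)
    pd.DataFrame(
        {
            "heart_id": np.arange(len(study.per_heart_counts)),
            "n_clusters": study.per_heart_counts,
        }
    ).to_csv(csv_path, index=False)
    sidecar = csv_path.with_suffix(".json")
    sidecar.write_text(
        json.dumps(
            {
                "true_m": study.true_m,
                "n_hearts": study.n_hearts,
                "mean": study.summary.mean,
                "sd": study.summary.sd,
            },
            indent=2,
        )
        + "\n"
    )
    return sidecar


def read_study(csv_path: str | Path) -> tuple[ObservedSummary, dict]:
    """Read a study CSV and its JSON sidecar.

    Returns the recomputed summary and the sidecar metadata.  Clone
    positions are not round-tripped; only the counts are.
    """
    csv_path = Path(csv_path)
    counts = pd.read_csv(csv_path)["n_clusters"].tolist()
    meta = json.loads(csv_path.with_suffix(".json").read_text())
    return summarize_observed(counts), meta
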