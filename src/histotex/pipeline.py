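"""End-to-end orchestration of the clustering assessment workflow.

One *attempt* mirrors the study design: take the two reference groups (the
untreated control and the toxicant-only group) plus one dose group under
test, cluster their samples into two clusters — optionally after Fisher
top-k feature selection when the descriptors are the (many) texture
parameters — and summarize the result as a group-distribution table and a
weighted-average descriptor profile.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

from .characterize import (
    ClusterDistribution,
    WeightedAverageProfile,
    cluster_distribution,
    weighted_average_profile,
)
from .nnc import CompetitiveLearningClusterer, train_nnc
from .selection import FCoefficientResult, select_top_k

__all__ = ["AttemptReport", "run_attempt"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class AttemptReport:
    """Everything one clustering attempt produced."""

    test_group: str | None
    model: CompetitiveLearningClusterer
    assignment: pd.DataFrame
    distribution: ClusterDistribution
    profile: WeightedAverageProfile
    selection: FCoefficientResult | None = None


def run_attempt(
    table: pd.DataFrame,
    reference_groups: tuple[str, str],
    test_group: str | None = None,
    top_k: int | None = None,
    n_clusters: int = 2,
    seed: int | None = 0,
    epochs: int = 100,
    learning_rate: float = 0.5,
) -> AttemptReport:
    """Cluster {reference groups [+ test group]} and characterize the result.

    ``top_k=None`` uses every descriptor (the assay-indicator route, where
    all eight indicators carry meaning); an integer applies Fisher top-k
    selection first (the texture route, where descriptors are legion).
    """
    if test_group is not None and test_group in reference_groups:
        raise ValueError(
            f"test group {test_group!r} must differ from the reference groups"
        )
    wanted = [g for g in (*reference_groups, test_group) if g is not None]
    available = set(table["group"])
    missing = [g for g in wanted if g not in available]
    if missing:
        raise ValueError(
            f"group(s) {missing} not in the table; available: {sorted(available)}"
        )
    subset = table[table["group"].isin(wanted)].reset_index(drop=True)

    selection = None
    if top_k is not None:
        subset, selection = select_top_k(subset, k=top_k)
        logger.info(
            "Fisher selection kept %d features: %s",
            top_k,
            ", ".join(selection.ranking.loc[selection.ranking["selected"], "feature"]),
        )

    model, assignment = train_nnc(
        subset,
        n_clusters=n_clusters,
        seed=seed,
        epochs=epochs,
        learning_rate=learning_rate,
    )
    dist = cluster_distribution(assignment, reference_groups)
    profile = weighted_average_profile(
        subset, assignment, cluster_order=dist.cluster_order
    )
    return AttemptReport(
        test_group=test_group,
        model=model,
        assignment=assignment,
        distribution=dist,
        profile=profile,
        selection=selection,
    )
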