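"""Cluster characterization: group-by-cluster tables and descriptor profiles.

Two summaries turn a raw cluster assignment into interpretable output:

* `cluster_distribution` — for each experimental group, the percentage of
  its samples falling into each cluster.  Cluster indices are arbitrary, so
  the table is canonicalized against two designated *reference groups* (the
  untreated control and the toxicant-only group): cluster 1 is the majority
  cluster of the first reference group, cluster 2 that of the second.  A
  test group's row then reads directly as "how much does this group look
  like the control vs. the damaged reference".
* `weighted_average_profile` — for each cluster and descriptor the relative
  deviation ``(mu_d - mu_a) / mu_a`` of the cluster mean ``mu_d`` from the
  mean over all samples ``mu_a``.  With ``mu_a`` taken over all samples the
  profile obeys an exact mass balance, ``sum_c n_c * wa_c = 0``, for every
  descriptor.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .table import feature_columns

__all__ = [
    "ClusterDistribution",
    "WeightedAverageProfile",
    "cluster_distribution",
    "weighted_average_profile",
    "export_report",
]


@dataclass(frozen=True)
class ClusterDistribution:
    """Percentages of each group's samples per (canonicalized) cluster.

    ``table`` — rows indexed by group, columns ``cluster_1``, ``cluster_2``,
    ... in canonical order; each row sums to 100.
    ``cluster_order`` — raw cluster indices in canonical column order.
    ``reference_groups`` — the (g1, g2) pair used for canonicalization.
    ``degenerate`` — True when both reference groups share the same
    majority cluster, in which case raw index order is kept.
    """

    table: pd.DataFrame
    cluster_order: tuple[int, ...]
    reference_groups: tuple[str, str]
    degenerate: bool = False


@dataclass(frozen=True)
class WeightedAverageProfile:
    """Per-cluster relative deviation of every descriptor's mean.

    ``values`` — rows = canonical clusters, columns = descriptors, entries
    ``(mu_d - mu_a)/mu_a`` (NaN where undefined).  ``cluster_sizes`` — number
    of samples per row.  ``undefined`` — descriptors whose overall mean is
    zero, for which the relative deviation does not exist.
    """

    values: pd.DataFrame
    cluster_sizes: pd.Series
    undefined: tuple[str, ...] = field(default=())


def _majority_cluster(assignment: pd.DataFrame, group: str) -> int:
    sub = assignment.loc[assignment["group"] == group, "cluster"]
    counts = sub.value_counts()
    top = counts[counts == counts.max()]
    return int(min(top.index))  # lowest cluster index wins exact ties


def cluster_distribution(
    assignment: pd.DataFrame,
    reference_groups: tuple[str, str],
) -> ClusterDistribution:
    """Group-by-cluster percentage table, canonicalized by reference majorities.

    ``assignment`` needs columns ``group`` and ``cluster``.  Both reference
    groups must be present among the group labels.
    """
    g1, g2 = reference_groups
    present = set(assignment["group"])
    for g in (g1, g2):
        if g not in present:
            raise ValueError(
                f"reference group {g!r} absent; available groups: {sorted(present)}"
            )

    pct = (
        pd.crosstab(assignment["group"], assignment["cluster"], normalize="index")
        * 100.0
    )
    all_clusters = sorted(assignment["cluster"].unique())
    for c in all_clusters:  # groups with zero members in a cluster
        if c not in pct.columns:
            pct[c] = 0.0
    pct = pct[all_clusters]

    maj1 = _majority_cluster(assignment, g1)
    maj2 = _majority_cluster(assignment, g2)
    degenerate = maj1 == maj2
    if degenerate:
        order = list(all_clusters)
    else:
        rest = [c for c in all_clusters if c not in (maj1, maj2)]
        order = [maj1, maj2] + rest

    pct = pct[order]
    pct.columns = [f"cluster_{k + 1}" for k in range(len(order))]
    pct.index.name = "group"
    return ClusterDistribution(
        table=pct,
        cluster_order=tuple(order),
        reference_groups=(g1, g2),
        degenerate=degenerate,
    )


def weighted_average_profile(
    table: pd.DataFrame,
    assignment: pd.DataFrame,
    cluster_order: tuple[int, ...] | None = None,
) -> WeightedAverageProfile:
    """Relative deviation of each cluster's descriptor means from the overall mean.

    ``table`` and ``assignment`` are aligned on ``sample_id``.  Descriptors
    whose overall mean is exactly zero are flagged undefined (NaN column).
    ``cluster_order`` (e.g. from `ClusterDistribution`) controls row order;
    default is ascending raw index.
    """
    feats = feature_columns(table)
    merged = table.merge(
        assignment[["sample_id", "cluster"]], on="sample_id", validate="one_to_one"
    )
    clusters = (
        list(cluster_order)
        if cluster_order is not None
        else sorted(merged["cluster"].unique())
    )
    sizes = merged["cluster"].value_counts()
    for c in clusters:
        if sizes.get(c, 0) == 0:
            raise ValueError(f"cluster {c} is empty")

    mu_a = merged[feats].mean()
    undefined = tuple(f for f in feats if mu_a[f] == 0.0)

    rows = []
    for c in clusters:
        mu_d = merged.loc[merged["cluster"] == c, feats].mean()
        wa = (mu_d - mu_a) / mu_a
        wa[list(undefined)] = np.nan
        rows.append(wa)
    values = pd.DataFrame(rows, index=[f"cluster_{k + 1}" for k in range(len(clusters))])
    values.index.name = "cluster"
    cluster_sizes = pd.Series(
        [int(sizes[c]) for c in clusters], index=values.index, name="n"
    )
    return WeightedAverageProfile(
        values=values, cluster_sizes=cluster_sizes, undefined=undefined
    )


def export_report(
    dist: ClusterDistribution,
    profile: WeightedAverageProfile,
    path: str | Path,
    prefix: str = "report",
) -> list[Path]:
    """Write the distribution CSV, one profile histogram per cluster, and JSON.

    Returns the list of files written.  Content is deterministic for fixed
    inputs.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    outdir = Path(path)
    try:
        outdir.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise IOError(f"cannot create output directory {outdir}: {exc}") from exc

    written: list[Path] = []

    csv_path = outdir / f"{prefix}_distribution.csv"
    dist.table.round(6).to_csv(csv_path)
    written.append(csv_path)

    for cluster in profile.values.index:
        wa = profile.values.loc[cluster].dropna()
        fig, ax = plt.subplots(figsize=(max(4, 0.45 * len(wa)), 3.2))
        ax.bar(range(len(wa)), wa.to_numpy(), color="#4878a8")
        ax.set_xticks(range(len(wa)))
        ax.set_xticklabels(wa.index, rotation=90, fontsize=7)
        ax.axhline(0.0, color="black", linewidth=0.8)
        ax.set_ylabel("weighted average (mu_d - mu_a)/mu_a")
        ax.set_title(f"{cluster} (n={int(profile.cluster_sizes[cluster])})")
        fig.tight_layout()
        png_path = outdir / f"{prefix}_wa_{cluster}.png"
        fig.savefig(png_path, dpi=120)
        plt.close(fig)
        written.append(png_path)

    payload = {
        "distribution": json.loads(dist.table.round(9).to_json(orient="index")),
        "cluster_order": list(dist.cluster_order),
        "reference_groups": list(dist.reference_groups),
        "degenerate": dist.degenerate,
        "weighted_average": json.loads(profile.values.round(9).to_json(orient="index")),
        "cluster_sizes": profile.cluster_sizes.to_dict(),
        "undefined_descriptors": list(profile.undefined),
    }
    json_path = outdir / f"{prefix}.json"
    json_path.write_text(json.dumps(payload, indent=2, sort_keys=True))
    written.append(json_path)
    return written
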