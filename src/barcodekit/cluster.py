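"""Fixed-threshold clustering of barcode sequences with accuracy scoring.

Sequences are clustered by single-linkage transitive closure: two
sequences share a cluster iff they are connected by a chain of pairwise
p-distances each within the threshold.  Because chaining is transitive, a
cluster's largest internal distance can exceed the threshold — a
*threshold violation*, counted per cluster.  *Taxonomic accuracy* is the
percentage of recognised species represented by a perfect cluster (one
containing all sequences of exactly one species and only those).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .distances import DistanceMatrix
from .io import BarcodeRecord

logger = logging.getLogger(__name__)


@dataclass
class ClusterPartition:
    """A threshold clustering and its quality statistics."""

    threshold: float
    ids: list[str]
    labels: np.ndarray  # cluster index per id
    max_internal: list[float]  # per cluster; NaN if no defined internal pair
    violation: list[bool]
    n_clusters: int
    perfect: list[bool] | None = None
    taxonomic_accuracy: float | None = None
    violation_percent: float | None = None
    max_species_per_cluster: int | None = None
    n_recognized_species: int | None = None
    has_undefined_pairs: bool = False

    def clusters(self) -> list[list[str]]:
        out: list[list[str]] = [[] for _ in range(self.n_clusters)]
        for id_, lab in zip(self.ids, self.labels):
            out[lab].append(id_)
        return out

    def n_violations(self) -> int:
        return sum(self.violation)

    def to_assignment_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"id": self.ids, "cluster": self.labels})


def cluster_at_threshold(m: DistanceMatrix, threshold: float) -> ClusterPartition:
    """Single-linkage transitive-closure clustering at a fixed threshold.

    Undefined pairs (insufficient overlap) are treated as non-edges; a
    warning is logged when any exist since they can only split, never
    join, clusters.
    """
    mask = ~np.isnan(m.d)
    np.fill_diagonal(mask, True)
    has_undefined = not mask.all()
    if has_undefined:
        logger.warning(
            "distance matrix has %d undefined pairs; treated as non-edges",
            int((~mask).sum()) // 2,
        )
    adj = mask & (np.nan_to_num(m.d, nan=np.inf) <= threshold)
    n_clusters, labels = connected_components(
        csr_matrix(adj), directed=False, connection="weak"
    )
    max_internal: list[float] = []
    violation: list[bool] = []
    for k in range(n_clusters):
        idx = np.flatnonzero(labels == k)
        if len(idx) < 2:
            max_internal.append(math.nan)
            violation.append(False)
            continue
        sub = m.d[np.ix_(idx, idx)]
        vals = sub[np.triu_indices(len(idx), 1)]
        vals = vals[~np.isnan(vals)]
        mx = float(vals.max()) if vals.size else math.nan
        max_internal.append(mx)
        violation.append(bool(vals.size) and mx > threshold)
    return ClusterPartition(
        threshold=threshold,
        ids=list(m.ids),
        labels=labels,
        max_internal=max_internal,
        violation=violation,
        n_clusters=n_clusters,
        has_undefined_pairs=has_undefined,
    )


def accuracy_and_violations(
    partition: ClusterPartition,
    records: Sequence[BarcodeRecord],
    n_recognized_species: int | None = None,
) -> ClusterPartition:
    """Fill in perfect-cluster flags, taxonomic accuracy and violation rate.

    ``n_recognized_species`` defaults to the number of distinct species
    labels in the dataset; pass the accepted-taxonomy count explicitly when
    the library does not cover every recognised species.
    """
    species_of = {r.id: r.species for r in records}
    species_members: dict[str, set[str]] = {}
    for r in records:
        species_members.setdefault(r.species, set()).add(r.id)
    if n_recognized_species is None:
        n_recognized_species = len(species_members)
    if n_recognized_species <= 0:
        raise ValueError("n_recognized_species must be positive")

    perfect = []
    max_sp = 0
    for members in partition.clusters():
        sp = {species_of[i] for i in members}
        max_sp = max(max_sp, len(sp))
        perfect.append(
            len(sp) == 1 and set(members) == species_members[next(iter(sp))]
        )
    partition.perfect = perfect
    partition.taxonomic_accuracy = taxonomic_accuracy(
        sum(perfect), n_recognized_species
    )
    partition.violation_percent = violation_percent(
        partition.n_violations(), partition.n_clusters
    )
    partition.max_species_per_cluster = max_sp
    partition.n_recognized_species = n_recognized_species
    return partition


def taxonomic_accuracy(n_perfect: int, n_recognized_species: int) -> float:
    """Percent of recognised species represented by a perfect cluster."""
    if n_recognized_species <= 0:
        raise ValueError("n_recognized_species must be positive")
    return 100.0 * n_perfect / n_recognized_species


def violation_percent(n_violating: int, n_clusters: int) -> float:
    """Percent of clusters whose largest internal distance exceeds the threshold."""
    if n_clusters <= 0:
        raise ValueError("n_clusters must be positive")
    return 100.0 * n_violating / n_clusters


def threshold_sweep(
    m: DistanceMatrix,
    records: Sequence[BarcodeRecord],
    thresholds: Sequence[float],
    n_recognized_species: int | None = None,
) -> list[ClusterPartition]:
    """Cluster at each threshold and score against the accepted taxonomy."""
    return [
        accuracy_and_violations(
            cluster_at_threshold(m, t), records, n_recognized_species
        )
        for t in thresholds
    ]


def sweep_summary(partitions: Sequence[ClusterPartition]) -> pd.DataFrame:
    """Taxonomic-accuracy table: one row per threshold."""
    rows = []
    for p in partitions:
        rows.append(
            {
                "threshold": p.threshold,
                "n_clusters": p.n_clusters,
                "n_perfect": sum(p.perfect) if p.perfect is not None else None,
                "taxonomic_accuracy_percent": p.taxonomic_accuracy,
                "max_species_per_cluster": p.max_species_per_cluster,
                "n_violations": p.n_violations(),
                "violation_percent": p.violation_percent,
            }
        )
    return pd.DataFrame(rows)
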