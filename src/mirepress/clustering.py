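"""Biomarker-panel evaluation by hierarchical clustering of samples.

A panel of miRNAs is extracted from TPM profiles into a sample ×
panel-miRNA matrix of log2(TPM + 1) values (a miRNA absent from a sample
contributes log2(1) = 0), samples are agglomeratively clustered, and the
separation between known groups (e.g. tumor vs normal) is quantified by
cluster purity at a chosen cut.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .datatypes import ClusteringResult, NormalizedProfile, PanelMatrix

__all__ = ["panel_matrix", "hierarchical_cluster", "cluster_purity"]

_DISTANCES = ("euclidean", "correlation")
_LINKAGES = ("average", "complete", "single")


def panel_matrix(profiles: Sequence[NormalizedProfile], panel: Sequence[str]) -> PanelMatrix:
    """Build the sample × panel matrix of log2(TPM + 1) values."""
    if not panel:
        raise ValueError("panel must be non-empty")
    if not profiles:
        raise ValueError("profiles must be non-empty")
    panel = list(panel)
    values = np.empty((len(profiles), len(panel)), dtype=float)
    for i, p in enumerate(profiles):
        for j, mirna in enumerate(panel):
            values[i, j] = np.log2(p.get(mirna) + 1.0)
    return PanelMatrix(tuple(p.sample_id for p in profiles), tuple(panel), values)


def hierarchical_cluster(
    matrix: PanelMatrix,
    distance: str = "euclidean",
    linkage: str = "average",
) -> ClusteringResult:
    """Agglomerative clustering of samples with flat labels at every cut.

    Merge heights are non-decreasing for the supported (monotone) linkages,
    and cutting the merge sequence after n − k merges yields exactly k
    non-empty clusters for every 1 ≤ k ≤ n, even in the presence of ties.
    """
    if distance not in _DISTANCES:
        raise ValueError(f"distance must be one of {_DISTANCES}, got {distance!r}")
    if linkage not in _LINKAGES:
        raise ValueError(f"linkage must be one of {_LINKAGES}, got {linkage!r}")
    n = len(matrix.sample_ids)
    if n < 2:
        raise ValueError("need at least two samples to cluster")
    d = pdist(matrix.values, metric=distance)
    # correlation distance is NaN for constant rows; treat those as maximally
    # distant from everything but other constant rows (distance 0 between them)
    if np.isnan(d).any():
        d = np.nan_to_num(d, nan=2.0)
    Z = hierarchy.linkage(d, method=linkage)
    cuts = hierarchy.cut_tree(Z)  # column j = labels with n - j clusters
    labels_at_k: dict[int, dict[str, int]] = {}
    for j in range(n):
        k = n - j
        labels_at_k[k] = {
            sid: int(cuts[i, j]) for i, sid in enumerate(matrix.sample_ids)
        }
    merge_tree = tuple((int(a), int(b), float(h)) for a, b, h, _ in Z)
    return ClusteringResult(matrix.sample_ids, merge_tree, labels_at_k)


def cluster_purity(labels: Mapping[str, int], truth: Mapping[str, str]) -> float:
    """Fraction of samples assigned to a cluster whose majority group is theirs.

    purity = (Σ over clusters of the largest truth-group count) / n.
    """
    if set(labels) != set(truth):
        raise ValueError("labels and truth must cover the same samples")
    if not labels:
        raise ValueError("labels must be non-empty")
    by_cluster: dict[int, dict[str, int]] = {}
    for sid, cl in labels.items():
        group = truth[sid]
        by_cluster.setdefault(cl, {}).setdefault(group, 0)
        by_cluster[cl][group] += 1
    return sum(max(groups.values()) for groups in by_cluster.values()) / len(labels)
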