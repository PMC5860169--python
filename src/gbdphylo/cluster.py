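"""Threshold clustering against a reference taxonomy.

Implements fraction-linkage threshold clustering (F = 0 reduces to single
linkage / connected components, F = 1 to complete linkage / cliques), the
partition-agreement index (MRI, realized as the Hubert-Arabie adjusted Rand
index), and threshold optimization by scanning the midpoints between
observed distances.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import adjusted_rand_score

from .errors import UsageError, ValidationError
from .gbdp import DistanceMatrix

Partition = dict  # genome id -> cluster label


@dataclass(frozen=True)
class ClusterParams:
    """T: distance threshold; F: required linked fraction for merging."""

    T: float
    F: float = 0.5

    def __post_init__(self):
        if not 0.0 <= self.F <= 1.0:
            raise ValidationError(f"F={self.F} outside [0, 1]")
        if not 0.0 <= self.T <= 1.0:
            raise ValidationError(f"T={self.T} outside [0, 1]")


def blocks(partition: Mapping) -> list[frozenset]:
    out: dict = {}
    for item, lab in partition.items():
        out.setdefault(lab, set()).add(item)
    return [frozenset(b) for b in out.values()]


def threshold_cluster(
    matrix: DistanceMatrix, T: float, F: float = 0.5
) -> Partition:
    """Fraction-linkage agglomeration.

    Pairs with d <= T are links.  Starting from singletons, repeatedly merge
    the cluster pair with the highest linked fraction f = links/(|P|*|Q|)
    subject to f >= F and at least one link; ties on f are broken by the
    smallest minimum inter-cluster distance, then by the lexicographically
    smallest member labels.  Cluster labels are each block's smallest member.
    """
    labels = list(matrix.labels)
    n = len(labels)
    linked = matrix.values <= T
    clusters: list[set[int]] = [{i} for i in range(n)]

    def stats(p: set, q: set) -> tuple[float, float]:
        ij = np.ix_(sorted(p), sorted(q))
        nlinks = int(linked[ij].sum())
        return nlinks / (len(p) * len(q)), float(matrix.values[ij].min())

    while True:
        best = None
        for a in range(len(clusters)):
            for b in range(a + 1, len(clusters)):
                f, dmin = stats(clusters[a], clusters[b])
                if f <= 0 or f < F:
                    continue
                pair_labs = tuple(
                    sorted(
                        (
                            min(labels[i] for i in clusters[a]),
                            min(labels[i] for i in clusters[b]),
                        )
                    )
                )
                key = (-f, dmin, pair_labs)
                if best is None or key < best[0]:
                    best = (key, a, b)
        if best is None:
            break
        _, a, b = best
        clusters[a] |= clusters[b]
        del clusters[b]
    out: Partition = {}
    for block in clusters:
        lab = min(labels[i] for i in block)
        for i in block:
            out[labels[i]] = lab
    return out


def mri(p1: Mapping, p2: Mapping) -> float:
    """Partition agreement as the chance-adjusted Rand index.

    Equals 1 iff the partitions are identical and decreases with
    disagreement (can be negative for worse-than-chance agreement).
    """
    if set(p1) != set(p2):
        raise UsageError("partitions cover different element sets")
    items = sorted(p1)
    return float(adjusted_rand_score([p1[i] for i in items], [p2[i] for i in items]))


def candidate_thresholds(matrix: DistanceMatrix) -> list[float]:
    """Midpoints between consecutive distinct off-diagonal distances, plus one
    candidate below the minimum and one above the maximum."""
    n = len(matrix.labels)
    vals = sorted(
        {float(matrix.values[i, j]) for i in range(n) for j in range(i + 1, n)}
    )
    eps = 1e-9
    cands = [vals[0] - eps]
    for lo, hi in zip(vals, vals[1:]):
        cands.append(0.5 * (lo + hi))
    cands.append(vals[-1] + eps)
    return cands


def optimize_threshold(
    matrix: DistanceMatrix, reference: Mapping, F: float = 0.5
) -> tuple[float, float, Partition]:
    """Scan candidate thresholds and return (T*, MRI*, partition*) maximizing
    agreement with the reference partition; ties resolved to the smallest T."""
    missing = sorted(set(matrix.labels) - set(reference))
    if missing:
        raise UsageError(f"reference partition misses labels: {missing}")
    reference = {lab: reference[lab] for lab in matrix.labels}
    best = None
    for T in candidate_thresholds(matrix):
        part = threshold_cluster(matrix, T, F)
        score = mri(part, reference)
        if best is None or score > best[1] + 1e-15:
            best = (T, score, part)
    return best


def rank_pipeline(
    matrix: DistanceMatrix,
    taxonomy: pd.DataFrame,
    rank: str,
    F: float = 0.5,
    T: float | None = None,
) -> tuple[float, float, Partition]:
    """Cluster at one taxonomic rank.

    Genomes unassigned at the requested rank are dropped first.  With
    ``T=None`` the threshold is optimized against the taxonomy; with a fixed
    ``T`` the clustering is computed directly (MRI still reported against
    the taxonomy-derived reference).
    """
    if rank not in taxonomy.columns:
        raise UsageError(f"taxonomy has no rank column {rank!r}")
    assigned = taxonomy[taxonomy[rank] != ""]
    keep = [lab for lab in matrix.labels if lab in set(assigned["genome_id"])]
    if not keep:
        raise UsageError(f"no genome has a {rank} assignment")
    sub = matrix.submatrix(keep)
    ref = assigned.set_index("genome_id")[rank].to_dict()
    ref = {lab: ref[lab] for lab in keep}
    if T is None:
        return optimize_threshold(sub, ref, F)
    part = threshold_cluster(sub, T, F)
    return T, mri(part, ref), part
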