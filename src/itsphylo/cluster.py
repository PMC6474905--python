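"""Hierarchical clustering of ITS2 structure features.

Block (Manhattan / city-block) distances between 12-element feature
vectors, agglomerated with between-groups linkage — the average of all
cross-pair distances, i.e. average linkage under its SPSS name.  The merge
history is kept explicitly so it can be emitted as an ultrametric Newick
dendrogram or a merge table.

Feature scaling is off by default (raw degrees / base pairs / counts);
min–max scaling is available because angular features otherwise dominate
the Manhattan sum.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .structure import Its2Features


@dataclass
class Merge:
    step: int
    members_a: frozenset[str]
    members_b: frozenset[str]
    height: float


@dataclass
class Dendrogram:
    merges: list[Merge]
    leaves: list[str]
    linkage: str = "between-groups (average)"
    distance: str = "block (Manhattan)"

    def __post_init__(self) -> None:
        heights = [m.height for m in self.merges]
        if any(b < a - 1e-9 for a, b in zip(heights, heights[1:])):
            raise ValueError("merge heights must be non-decreasing")
        if self.merges:
            final = self.merges[-1].members_a | self.merges[-1].members_b
            if final != set(self.leaves):
                raise ValueError("final merge must contain all leaves")

    def top_split(self) -> tuple[frozenset[str], frozenset[str]]:
        last = self.merges[-1]
        return last.members_a, last.members_b

    def merge_table(self) -> str:
        lines = ["step\theight\tcluster_a\tcluster_b"]
        for m in self.merges:
            lines.append(
                f"{m.step}\t{m.height:.6g}\t"
                f"{','.join(sorted(m.members_a))}\t{','.join(sorted(m.members_b))}")
        return "\n".join(lines) + "\n"


def block_distance(u: Its2Features | np.ndarray, v: Its2Features | np.ndarray) -> float:
    """Manhattan distance between two feature vectors."""
    a = u.vector if isinstance(u, Its2Features) else np.asarray(u, dtype=float)
    b = v.vector if isinstance(v, Its2Features) else np.asarray(v, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"vector length mismatch: {a.shape} vs {b.shape}")
    return float(np.sum(np.abs(a - b)))


def minmax_scale(matrix: np.ndarray) -> np.ndarray:
    """Per-feature min–max scaling to [0, 1]; constant features map to 0."""
    lo = matrix.min(axis=0)
    span = matrix.max(axis=0) - lo
    span[span == 0] = 1.0
    return (matrix - lo) / span


def between_groups_cluster(features: Sequence[Its2Features],
                           scaling: str = "none") -> Dendrogram:
    """Agglomerative clustering with average linkage on block distances.

    The inter-cluster distance is the mean over all cross pairs of the
    (optionally min–max scaled) Manhattan distances.  Ties break toward
    the pair containing the smallest leaf index, so the result does not
    depend on floating-point dictionary order.
    """
    n = len(features)
    if n < 2:
        raise ValueError("clustering needs at least 2 vectors")
    if scaling not in ("none", "minmax"):
        raise ValueError(f"unknown scaling {scaling!r}")
    names = [f.taxon for f in features]
    if len(set(names)) != n:
        raise ValueError("duplicate taxon names in feature list")
    X = np.vstack([f.vector for f in features])
    if scaling == "minmax":
        X = minmax_scale(X)
    D = np.abs(X[:, None, :] - X[None, :, :]).sum(axis=2)

    # Lance–Williams average linkage over explicit member sets
    clusters: dict[int, frozenset[int]] = {i: frozenset([i]) for i in range(n)}
    sizes: dict[int, int] = {i: 1 for i in range(n)}
    dist: dict[tuple[int, int], float] = {
        (i, j): float(D[i, j]) for i in range(n) for j in range(i + 1, n)
    }
    merges: list[Merge] = []
    next_id = n
    active = sorted(clusters)
    step = 0
    while len(active) > 1:
        best_pair = None
        best = np.inf
        for ai in range(len(active)):
            for aj in range(ai + 1, len(active)):
                i, j = active[ai], active[aj]
                dij = dist[(min(i, j), max(i, j))]
                if (best_pair is None or dij < best - 1e-12
                        or (abs(dij - best) <= 1e-12
                            and _tie_key(clusters, i, j) < _tie_key(clusters, *best_pair))):
                    best, best_pair = dij, (i, j)
        i, j = best_pair
        step += 1
        merges.append(Merge(
            step=step,
            members_a=frozenset(names[k] for k in clusters[i]),
            members_b=frozenset(names[k] for k in clusters[j]),
            height=best,
        ))
        u = next_id
        next_id += 1
        ni, nj = sizes[i], sizes[j]
        for k in active:
            if k in (i, j):
                continue
            dik = dist[(min(i, k), max(i, k))]
            djk = dist[(min(j, k), max(j, k))]
            dist[(min(u, k), max(u, k))] = (ni * dik + nj * djk) / (ni + nj)
        clusters[u] = clusters[i] | clusters[j]
        sizes[u] = ni + nj
        active = [k for k in active if k not in (i, j)] + [u]
    return Dendrogram(merges=merges, leaves=list(names))


def _tie_key(clusters: dict[int, frozenset[int]], i: int, j: int) -> tuple[int, int]:
    members = sorted(clusters[i] | clusters[j])
    return (members[0], members[1] if len(members) > 1 else members[0])


def dendrogram_to_newick(dg: Dendrogram) -> str:
    """Ultrametric Newick: a cluster merged at height h sits at age h/2, so
    two leaves merging at height h appear as (A:h/2,B:h/2)."""
    age: dict[frozenset[str], float] = {frozenset([l]): 0.0 for l in dg.leaves}
    newick: dict[frozenset[str], str] = {frozenset([l]): l for l in dg.leaves}
    for m in dg.merges:
        h = m.height / 2.0
        parts = []
        for side in (m.members_a, m.members_b):
            parts.append(f"{newick[side]}:{h - age[side]:.6f}")
        merged = m.members_a | m.members_b
        newick[frozenset(merged)] = "(" + ",".join(parts) + ")"
        age[frozenset(merged)] = h
    return newick[frozenset(dg.leaves)] + ";"
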