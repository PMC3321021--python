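"""Distances, neighbor-joining trees and threshold MOTU clustering.

Marker distances follow Nei–Li (Dice on shared band presences, shared
absences ignored); sequence distances are uncorrected p-distances with
pairwise deletion.  Neighbor joining is the standard Saitou–Nei algorithm
with deterministic tie breaking; bootstrap support comes from locus
resampling.  MOTU clustering is single-linkage transitive closure at a
distance threshold (default 3%).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import dendropy

from .io import MISSING, MarkerMatrix, SequenceSet

__all__ = [
    "DistanceMatrix",
    "Partition",
    "nei_li_distance",
    "neighbor_joining",
    "p_distance",
    "motu_cluster",
]


@dataclass
class DistanceMatrix:
    """Symmetric non-negative dissimilarity matrix with labelled rows."""

    ids: list[str]
    values: np.ndarray
    kind: str = "generic"          # nei_li | p_distance | fst | km | generic

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("distance matrix must be square")
        if len(self.ids) != v.shape[0]:
            raise ValueError("ids/matrix size mismatch")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("distance matrix not symmetric")
        if not np.allclose(np.diag(v), 0, atol=1e-12):
            raise ValueError("distance matrix diagonal not zero")
        if (v < -1e-12).any():
            raise ValueError("negative distances")
        self.values = (v + v.T) / 2
        np.fill_diagonal(self.values, 0.0)

    @property
    def n(self) -> int:
        return len(self.ids)

    def submatrix(self, ids: list[str]) -> "DistanceMatrix":
        idx = [self.ids.index(i) for i in ids]
        return DistanceMatrix(list(ids), self.values[np.ix_(idx, idx)], self.kind)

    def to_tsv(self, path) -> None:
        import pandas as pd
        pd.DataFrame(self.values, index=self.ids, columns=self.ids).to_csv(path, sep="\t")


@dataclass
class Partition:
    """id -> cluster label map produced at a given distance threshold."""

    labels: dict[str, str]
    threshold: float

    def n_clusters(self) -> int:
        return len(set(self.labels.values()))

    def clusters(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for i, c in self.labels.items():
            out.setdefault(c, []).append(i)
        return {c: sorted(m) for c, m in out.items()}


# ---------------------------------------------------------------------------
# distances
# ---------------------------------------------------------------------------

def nei_li_distance(mm: MarkerMatrix, include_replicates: bool = False) -> DistanceMatrix:
    """Nei–Li distance D = 1 - 2*n_xy/(n_x + n_y) over mutually scored loci.

    n_x and n_y count presences of each sample at loci non-missing in both;
    n_xy counts shared presences.  Shared absences do not contribute.
    """
    if not include_replicates:
        mm = mm.drop_replicates()
    if mm.n_samples < 2:
        raise ValueError("need >= 2 samples")
    P = (mm.calls == 1).astype(np.float64)
    M = (mm.calls != MISSING).astype(np.float64)
    comparable = M @ M.T
    if (comparable == 0).any():
        i, j = np.argwhere(comparable == 0)[0]
        if i != j:
            raise ValueError(
                f"no mutually scored loci for pair "
                f"({mm.sample_ids[i]!r}, {mm.sample_ids[j]!r})"
            )
    n_xy = P @ P.T
    n_x = P @ M.T                      # presences of row sample at shared loci
    tot = n_x + n_x.T
    with np.errstate(divide="ignore", invalid="ignore"):
        d = 1.0 - 2.0 * n_xy / tot
    if (tot == 0).any():
        warnings.warn("pairs with no presences at all: distance defined as 0",
                      stacklevel=2)
        d[tot == 0] = 0.0
    np.fill_diagonal(d, 0.0)
    d = np.clip((d + d.T) / 2, 0.0, None)
    return DistanceMatrix(list(mm.sample_ids), d, kind="nei_li")


_VALID = np.frombuffer(b"ACGT", dtype=np.uint8)


def p_distance(ss: SequenceSet) -> DistanceMatrix:
    """Uncorrected p-distance with pairwise deletion of gaps/ambiguities."""
    if not ss.aligned:
        raise ValueError("sequences must be aligned")
    arr = np.array([np.frombuffer(s.encode(), dtype=np.uint8) for s in ss.seqs])
    valid = np.isin(arr, _VALID)
    n = len(ss)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            comp = valid[i] & valid[j]
            nc = int(comp.sum())
            if nc == 0:
                raise ValueError(
                    f"no comparable sites for pair ({ss.ids[i]!r}, {ss.ids[j]!r})"
                )
            d[i, j] = d[j, i] = np.count_nonzero(arr[i][comp] != arr[j][comp]) / nc
    return DistanceMatrix(list(ss.ids), d, kind="p_distance")


# ---------------------------------------------------------------------------
# neighbor joining
# ---------------------------------------------------------------------------

def _nj_topology(ids: list[str], dist: np.ndarray, tns: dendropy.TaxonNamespace) -> dendropy.Tree:
    """Saitou–Nei NJ; ties in the Q criterion break to the lowest (i,j)."""
    n = len(ids)
    nodes: list[dendropy.Node] = []
    for s in ids:
        taxon = tns.get_taxon(s) or tns.new_taxon(s)
        nd = dendropy.Node(taxon=taxon)
        nodes.append(nd)
    D = dist.astype(float).copy()
    active = list(range(n))

    while len(active) > 3:
        m = len(active)
        sub = D[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        # lowest-index tie break: scan in (i,j) order
        best = None
        best_q = np.inf
        for a in range(m):
            for b in range(a + 1, m):
                if q[a, b] < best_q - 1e-15:
                    best_q = q[a, b]
                    best = (a, b)
        a, b = best
        i, j = active[a], active[b]
        dij = D[i, j]
        li = 0.5 * dij + (r[a] - r[b]) / (2 * (m - 2))
        lj = dij - li
        if li < 0:
            li, lj = 0.0, dij
        elif lj < 0:
            li, lj = dij, 0.0
        parent = dendropy.Node()
        parent.add_child(nodes[i])
        nodes[i].edge.length = li
        parent.add_child(nodes[j])
        nodes[j].edge.length = lj
        # distances from the new node
        new_row = 0.5 * (D[i, :] + D[j, :] - dij)
        D = np.vstack([D, new_row])
        D = np.column_stack([D, np.append(new_row, 0.0)])
        nodes.append(parent)
        k = D.shape[0] - 1
        active = [x for x in active if x not in (i, j)] + [k]

    # resolve the final three around a central node (closed form)
    x, y, z = active
    center = dendropy.Node()
    lx = 0.5 * (D[x, y] + D[x, z] - D[y, z])
    ly = 0.5 * (D[x, y] + D[y, z] - D[x, z])
    lz = 0.5 * (D[x, z] + D[y, z] - D[x, y])
    for idx, ln in ((x, lx), (y, ly), (z, lz)):
        center.add_child(nodes[idx])
        nodes[idx].edge.length = max(ln, 0.0)
    tree = dendropy.Tree(taxon_namespace=tns, seed_node=center)
    tree.is_rooted = False
    return tree


def neighbor_joining(
    dm: DistanceMatrix,
    bootstrap: tuple[MarkerMatrix, int, int] | None = None,
) -> dendropy.Tree:
    """NJ tree from a distance matrix; optional locus bootstrap.

    ``bootstrap`` = (marker matrix, n_replicates, seed): loci are resampled
    with replacement, the Nei–Li distance and tree recomputed, and internal
    nodes of the point-estimate tree labelled with bipartition support
    percentages.
    """
    if dm.n < 3:
        raise ValueError("need >= 3 taxa")
    if not np.isfinite(dm.values).all():
        raise ValueError("non-finite distances")
    tns = dendropy.TaxonNamespace()
    tree = _nj_topology(dm.ids, dm.values, tns)
    if bootstrap is None:
        return tree

    mm, n_reps, seed = bootstrap
    mm = mm.drop_replicates()
    rng = np.random.default_rng(seed)
    tree.encode_bipartitions()
    counts: dict[int, int] = {}
    for _ in range(n_reps):
        cols = rng.integers(0, mm.n_loci, mm.n_loci)
        bmm = MarkerMatrix(
            list(mm.sample_ids),
            [f"b{c}_{k}" for k, c in enumerate(cols)],
            mm.calls[:, cols],
        )
        bdm = nei_li_distance(bmm)
        btree = _nj_topology(bdm.ids, bdm.values, tns)
        btree.encode_bipartitions()
        for bp in btree.bipartition_encoding:
            key = int(bp.split_bitmask)
            counts[key] = counts.get(key, 0) + 1
    for edge in tree.preorder_edge_iter():
        head = edge.head_node
        if head.is_leaf() or head is tree.seed_node:
            continue
        support = 100.0 * counts.get(int(edge.bipartition.split_bitmask), 0) / n_reps
        head.label = f"{support:g}"
    return tree


# ---------------------------------------------------------------------------
# MOTU clustering
# ---------------------------------------------------------------------------

def motu_cluster(dm: DistanceMatrix, threshold: float = 0.03) -> Partition:
    """Single-linkage transitive closure at ``threshold`` (inclusive).

    Two ids share a cluster whenever a chain of pairwise distances
    <= threshold connects them.  Cluster labels are the smallest member id.
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    n = dm.n
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i in range(n):
        for j in range(i + 1, n):
            if dm.values[i, j] <= threshold:
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[rj] = ri

    members: dict[int, list[str]] = {}
    for i in range(n):
        members.setdefault(find(i), []).append(dm.ids[i])
    labels = {}
    for mem in members.values():
        tag = min(mem)
        for s in mem:
            labels[s] = tag
    return Partition(labels, threshold)
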