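"""Genetic-interaction profile clustering.

Profiles (rows of an interaction-score matrix) are compared with a
correlation distance computed over pairwise-complete columns, then merged by
unweighted average linkage (UPGMA).  Shared interactions across query rows
and co-clustering of a query group under a tree cut are the two readouts.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from typing import IO, Iterable, Optional

import numpy as np

from .errors import ParseError, ValidationError

METRICS = ("centered", "uncentered")
MIN_OVERLAP = 3


@dataclass
class InteractionMatrix:
    rows: list[str]                 # query mutant labels
    cols: list[str]                 # array gene labels
    values: np.ndarray              # float matrix, NaN = missing

    def __post_init__(self) -> None:
        if len(set(self.rows)) != len(self.rows):
            raise ValidationError("duplicate row labels in interaction matrix")
        if len(set(self.cols)) != len(self.cols):
            raise ValidationError("duplicate column labels in interaction matrix")
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.rows), len(self.cols)):
            raise ValidationError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.rows)} rows x {len(self.cols)} cols"
            )


@dataclass(frozen=True)
class Merge:
    node_a: str
    node_b: str
    height: float
    new_id: str


@dataclass
class LinkageTree:
    leaves: list[str]
    merges: list[Merge] = field(default_factory=list)

    def heights(self) -> list[float]:
        return [m.height for m in self.merges]


@dataclass
class SharedHits:
    shared_genes: set[str]          # array genes hit by >= 2 query rows
    per_pair: dict[tuple[str, str], list[str]]

    @property
    def n_shared(self) -> int:
        return len(self.shared_genes)


def read_matrix(stream: IO[str]) -> InteractionMatrix:
    """Read a score TSV: first column = query label, header = array genes."""
    reader = csv.reader(stream, delimiter="\t")
    try:
        header = next(reader)
    except StopIteration:
        raise ParseError("empty interaction matrix file") from None
    cols = [c.strip() for c in header[1:]]
    rows: list[str] = []
    data: list[list[float]] = []
    for rec in reader:
        if not rec or (len(rec) == 1 and not rec[0].strip()):
            continue
        if len(rec) != len(cols) + 1:
            raise ParseError(
                f"row {rec[0]!r} has {len(rec) - 1} values, expected {len(cols)}"
            )
        rows.append(rec[0].strip())
        data.append([float(v) if v.strip() else math.nan for v in rec[1:]])
    return InteractionMatrix(rows=rows, cols=cols, values=np.array(data))


def write_matrix(matrix: InteractionMatrix, stream: IO[str]) -> None:
    stream.write("query\t" + "\t".join(matrix.cols) + "\n")
    for label, row in zip(matrix.rows, matrix.values):
        cells = ["" if math.isnan(v) else f"{v:.6g}" for v in row]
        stream.write(label + "\t" + "\t".join(cells) + "\n")


def correlation_distance(
    matrix: InteractionMatrix, metric: str = "centered"
) -> np.ndarray:
    """Pairwise distance 1 - r over pairwise-complete columns.

    ``centered`` uses Pearson correlation; ``uncentered`` the cosine-style
    correlation about zero (the Cluster 3.0 alternative).  Every row pair
    must share at least MIN_OVERLAP non-missing columns and have non-zero
    variance (or norm) over the shared columns.
    """
    if metric not in METRICS:
        raise ValidationError(f"metric must be one of {METRICS}, got {metric!r}")
    if len(matrix.rows) < 2:
        raise ValidationError("need >= 2 rows to compute distances")
    X = matrix.values
    m = len(matrix.rows)
    finite = np.isfinite(X)
    D = np.zeros((m, m))
    for i in range(m):
        for j in range(i + 1, m):
            both = finite[i] & finite[j]
            if both.sum() < MIN_OVERLAP:
                raise ValidationError(
                    f"rows {matrix.rows[i]!r} and {matrix.rows[j]!r} share only "
                    f"{int(both.sum())} columns (need >= {MIN_OVERLAP})"
                )
            x, y = X[i, both], X[j, both]
            if metric == "centered":
                x = x - x.mean()
                y = y - y.mean()
            nx, ny = np.sqrt((x * x).sum()), np.sqrt((y * y).sum())
            if nx == 0.0 or ny == 0.0:
                which = matrix.rows[i] if nx == 0.0 else matrix.rows[j]
                raise ValidationError(
                    f"row {which!r} has zero variance over the overlap with "
                    f"{matrix.rows[j] if nx == 0.0 else matrix.rows[i]!r}"
                )
            r = float((x * y).sum() / (nx * ny))
            D[i, j] = D[j, i] = min(2.0, max(0.0, 1.0 - r))
    return D


def average_linkage(dist: np.ndarray, labels: Iterable[str]) -> LinkageTree:
    """UPGMA: merge the closest pair; inter-cluster distance is the
    size-weighted mean of member distances (Lance-Williams update).

    Tied minimum distances are broken by lexicographic order of the sorted
    node-id pair, making the merge sequence deterministic.
    """
    labels = list(labels)
    dist = np.asarray(dist, dtype=float)
    n = len(labels)
    if dist.shape != (n, n):
        raise ValidationError("distance matrix shape does not match labels")
    if not np.allclose(dist, dist.T):
        raise ValidationError("distance matrix must be symmetric")
    if (dist < 0).any():
        raise ValidationError("distance matrix must be non-negative")
    if n < 2:
        raise ValidationError("need >= 2 leaves to cluster")

    # active cluster state: id -> (size, index row in working distance dict)
    d: dict[frozenset[str], float] = {}
    active: dict[str, int] = {lab: 1 for lab in labels}
    for i in range(n):
        for j in range(i + 1, n):
            d[frozenset((labels[i], labels[j]))] = float(dist[i, j])

    merges: list[Merge] = []
    next_id = 1
    while len(active) > 1:
        best: Optional[tuple[float, str, str]] = None
        for pair, dij in d.items():
            a, b = sorted(pair)
            cand = (dij, a, b)
            if best is None or cand < best:
                best = cand
        assert best is not None
        height, a, b = best
        new_id = f"N{next_id}"
        next_id += 1
        size_a, size_b = active.pop(a), active.pop(b)
        del d[frozenset((a, b))]
        for other in active:
            da = d.pop(frozenset((a, other)))
            db = d.pop(frozenset((b, other)))
            d[frozenset((new_id, other))] = (size_a * da + size_b * db) / (
                size_a + size_b
            )
        active[new_id] = size_a + size_b
        merges.append(Merge(node_a=a, node_b=b, height=height, new_id=new_id))
    return LinkageTree(leaves=labels, merges=merges)


def cut_tree(tree: LinkageTree, n_clusters: int) -> dict[str, int]:
    """Cut into ``n_clusters`` groups by dropping the highest merges.

    Merges are applied in order except the final (n_clusters - 1); UPGMA
    heights are non-decreasing, so those are the highest.  Cluster indices
    are assigned by the sorted label of each cluster's first leaf.
    """
    n = len(tree.leaves)
    if not 1 <= n_clusters <= n:
        raise ValidationError(f"n_clusters must be in [1, {n}], got {n_clusters}")
    keep = len(tree.merges) - (n_clusters - 1)
    parent: dict[str, str] = {}

    def find(x: str) -> str:
        while x in parent:
            x = parent[x]
        return x

    for merge in tree.merges[:keep]:
        parent[find(merge.node_a)] = merge.new_id
        parent[find(merge.node_b)] = merge.new_id
    groups: dict[str, list[str]] = {}
    for leaf in tree.leaves:
        groups.setdefault(find(leaf), []).append(leaf)
    assignment: dict[str, int] = {}
    for idx, root in enumerate(sorted(groups, key=lambda r: min(groups[r]))):
        for leaf in groups[root]:
            assignment[leaf] = idx
    return assignment


def cocluster(
    tree: LinkageTree, queries: Iterable[str], n_clusters: int
) -> tuple[bool, dict[str, int]]:
    """Whether all query leaves fall in one cluster at the given cut."""
    queries = set(queries)
    unknown = queries - set(tree.leaves)
    if unknown:
        raise ValidationError(f"unknown query label(s): {sorted(unknown)}")
    assignment = cut_tree(tree, n_clusters)
    together = len({assignment[q] for q in queries}) <= 1
    return together, assignment


def shared_hits(
    matrix: InteractionMatrix,
    score_cutoff: float,
    direction: Optional[str] = None,
) -> SharedHits:
    """Array genes that are interactions for >= 2 query rows.

    An interaction is |score| >= cutoff by default; ``direction`` restricts
    to "negative" (score <= -cutoff, synthetic sick/lethal) or "positive"
    (score >= cutoff, suppression).
    """
    if score_cutoff <= 0:
        raise ValidationError("score_cutoff must be > 0")
    if direction not in (None, "negative", "positive"):
        raise ValidationError("direction must be None, 'negative' or 'positive'")
    X = matrix.values
    with np.errstate(invalid="ignore"):
        if direction == "negative":
            hit = X <= -score_cutoff
        elif direction == "positive":
            hit = X >= score_cutoff
        else:
            hit = np.abs(X) >= score_cutoff
    hit &= np.isfinite(X)
    counts = hit.sum(axis=0)
    shared = {matrix.cols[j] for j in np.flatnonzero(counts >= 2)}
    per_pair: dict[tuple[str, str], list[str]] = {}
    for i in range(len(matrix.rows)):
        for j in range(i + 1, len(matrix.rows)):
            genes = [
                matrix.cols[c] for c in np.flatnonzero(hit[i] & hit[j])
            ]
            if genes:
                per_pair[(matrix.rows[i], matrix.rows[j])] = genes
    return SharedHits(shared_genes=shared, per_pair=per_pair)


def to_newick(tree: LinkageTree) -> str:
    """Nested-parenthesis export with ultrametric branch lengths (height/2)."""
    node_height: dict[str, float] = {leaf: 0.0 for leaf in tree.leaves}
    rendered: dict[str, str] = {leaf: leaf for leaf in tree.leaves}
    root = tree.leaves[0] if not tree.merges else tree.merges[-1].new_id
    for merge in tree.merges:
        h = merge.height
        parts = []
        for child in (merge.node_a, merge.node_b):
            bl = h / 2.0 - node_height[child] / 2.0
            parts.append(f"{rendered[child]}:{bl:.6g}")
        rendered[merge.new_id] = "(" + ",".join(parts) + ")"
        node_height[merge.new_id] = h
    return rendered[root] + ";"
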