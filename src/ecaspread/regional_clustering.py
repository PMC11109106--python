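"""Regional clustering of occurrence points.

Two complementary hierarchies are used.  A top-down (divisive) pass splits
the full occurrence set into ``k`` regional clusters — implemented as
recursive bisection: the cluster with the largest within-cluster sum of
squared distances is repeatedly split by 2-means until ``k`` clusters exist.
A bottom-up (agglomerative) pass then orders the points *within* each
cluster into a nested inclusion sequence S0 ⊂ S1 ⊂ … ⊂ Sn, which stands in
for the missing time series: rasterized, it becomes the image sequence
C0 → … → Cn whose transitions are fed to the rule classifier.

Distances are Euclidean on raw (lon, lat) degrees: the study areas this is
meant for span ~2°, where the metric distortion is immaterial.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage as scipy_linkage
from sklearn.cluster import KMeans

__all__ = [
    "RegionalCluster",
    "InclusionSequence",
    "read_occurrences",
    "write_occurrences",
    "divisive_cluster",
    "cluster_labels",
    "agglomerative_order",
    "cluster_summary",
]

#: KMeans restarts per bisection; fixed for determinism
_BISECT_RESTARTS = 10


@dataclass
class RegionalCluster:
    """One regional cluster: id (1-based, formation order), its points, and
    the indices of those points in the original occurrence set."""

    cluster_id: int
    points: np.ndarray  # (n, 2) lon/lat
    indices: np.ndarray  # (n,) positions in the input occurrence set

    @property
    def n_points(self) -> int:
        return len(self.points)

    @property
    def centroid(self) -> tuple[float, float]:
        """Arithmetic-mean (lon, lat) of the member points."""
        c = self.points.mean(axis=0)
        return (float(c[0]), float(c[1]))


@dataclass
class InclusionSequence:
    """Strictly nested point subsets ending in the full cluster.

    ``subsets`` holds local indices into ``points``; subset j is a strict
    superset of subset j-1.
    """

    points: np.ndarray
    subsets: list[np.ndarray] = field(default_factory=list)

    def __post_init__(self) -> None:
        prev: set[int] = set()
        for sub in self.subsets:
            cur = set(int(i) for i in sub)
            if not (prev < cur or (not prev and cur)):
                raise ValueError("inclusion sequence subsets must be strictly nested")
            prev = cur
        if self.subsets and len(prev) != len(self.points):
            raise ValueError("final subset must contain every cluster point")

    def __len__(self) -> int:
        return len(self.subsets)

    def point_subsets(self):
        """Yield each subset as an (m, 2) coordinate array."""
        for sub in self.subsets:
            yield self.points[sub]


def read_occurrences(path: str | Path) -> pd.DataFrame:
    """Read an ``id,lon,lat`` delimited text file of occurrence points."""
    df = pd.read_csv(path)
    missing = {"lon", "lat"} - set(df.columns)
    if missing:
        raise ValueError(f"occurrence file {path} lacks columns: {sorted(missing)}")
    if "id" not in df.columns:
        df.insert(0, "id", np.arange(len(df)))
    return df[["id", "lon", "lat"]]


def write_occurrences(df: pd.DataFrame, path: str | Path) -> None:
    df[["id", "lon", "lat"]].to_csv(path, index=False)


def _coords(occurrences) -> np.ndarray:
    if isinstance(occurrences, pd.DataFrame):
        pts = occurrences[["lon", "lat"]].to_numpy(dtype=float)
    else:
        pts = np.asarray(occurrences, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError(f"expected (n, 2) lon/lat coordinates, got shape {pts.shape}")
    if not np.isfinite(pts).all():
        raise ValueError("occurrence coordinates contain non-finite values")
    return pts


def _within_sse(pts: np.ndarray) -> float:
    return float(((pts - pts.mean(axis=0)) ** 2).sum())


def _bisect(pts: np.ndarray, seed: int) -> tuple[np.ndarray, np.ndarray]:
    """Split one point set in two with 2-means; returns local index arrays."""
    if len(np.unique(pts, axis=0)) < 2:
        # all points coincide: 2-means is undefined, peel off the first point
        return np.array([0]), np.arange(1, len(pts))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # duplicate points can trip ConvergenceWarning
        km = KMeans(n_clusters=2, n_init=_BISECT_RESTARTS, random_state=seed)
        lab = km.fit_predict(pts)
    a, b = np.flatnonzero(lab == 0), np.flatnonzero(lab == 1)
    if len(a) == 0 or len(b) == 0:  # degenerate fit
        return np.array([0]), np.arange(1, len(pts))
    return a, b


def divisive_cluster(occurrences, k: int, seed: int = 0) -> list[RegionalCluster]:
    """Top-down split of the occurrence set into exactly ``k`` clusters.

    Recursive bisection: starting from one cluster holding everything, the
    cluster with the largest within-cluster sum of squared Euclidean
    distances is split by 2-means (10 restarts, seeded) until ``k`` clusters
    exist.  Ids record formation order: the first split yields ids 1 and 2;
    at each later split the larger child keeps its parent's id and the other
    child takes the next unused id.

    Returns the clusters sorted by id; together they partition the input.
    """
    pts = _coords(occurrences)
    n = len(pts)
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    if k > n:
        raise ValueError(f"k={k} exceeds the number of points ({n})")

    clusters: list[tuple[int, np.ndarray]] = [(1, np.arange(n))]  # (id, indices)
    next_id = 2
    while len(clusters) < k:
        # split the cluster with the largest within-cluster SSE (ties: lowest id)
        splittable = [(cid, idx) for cid, idx in clusters if len(idx) >= 2]
        cid, idx = max(splittable, key=lambda t: (_within_sse(pts[t[1]]), -t[0]))
        a, b = _bisect(pts[idx], seed)
        ia, ib = idx[a], idx[b]
        if len(ia) < len(ib) or (len(ia) == len(ib) and ia.min() > ib.min()):
            ia, ib = ib, ia  # larger child (tie: smaller first index) keeps the id
        clusters = [(c, i) for c, i in clusters if c != cid]
        clusters.append((cid, ia))
        clusters.append((next_id, ib))
        next_id += 1

    clusters.sort(key=lambda t: t[0])
    return [
        RegionalCluster(cluster_id=cid, points=pts[idx], indices=idx)
        for cid, idx in clusters
    ]


def cluster_labels(clusters: list[RegionalCluster], n_points: int) -> np.ndarray:
    """Per-point cluster-id array recovered from a divisive partition."""
    labels = np.full(n_points, -1, dtype=int)
    for c in clusters:
        labels[c.indices] = c.cluster_id
    if (labels < 0).any():
        raise ValueError("clusters do not cover all points")
    return labels


def agglomerative_order(
    cluster: RegionalCluster, linkage: str = "single"
) -> InclusionSequence:
    """Order a cluster's points into a nested inclusion sequence.

    Agglomerative clustering (default single linkage) is run on the member
    points; merges are traversed in order of merge distance.  S0 is the pair
    joined by the first merge; every later merge that touches the growing
    main component contributes a new subset containing all points newly
    connected to it.  Merges among points not yet connected to the main
    component are deferred until the merge that joins them, so the sequence
    is strictly nested and ends in the full cluster.

    A single-point cluster yields the length-1 sequence with a warning.
    """
    pts = cluster.points
    n = len(pts)
    if n < 2:
        warnings.warn(
            f"cluster {cluster.cluster_id} has a single point; "
            "inclusion sequence has length 1"
        )
        return InclusionSequence(points=pts, subsets=[np.array([0])])

    Z = scipy_linkage(pts, method=linkage)
    members: dict[int, list[int]] = {i: [i] for i in range(n)}
    subsets: list[np.ndarray] = []
    main_node = -1
    main_set: set[int] = set()
    for j, (a, b, _dist, _cnt) in enumerate(Z):
        a, b = int(a), int(b)
        merged = members.pop(a) + members.pop(b)
        node = n + j
        members[node] = merged
        if main_node < 0 or a == main_node or b == main_node:
            main_node = node
            main_set.update(merged)
            subsets.append(np.array(sorted(main_set)))
        # else: a side component; it joins wholesale when merged with main
    return InclusionSequence(points=pts, subsets=subsets)


def cluster_summary(clusters: list[RegionalCluster]) -> pd.DataFrame:
    """Per-cluster table: id, point count, centroid lon/lat."""
    if not clusters:
        raise ValueError("no clusters to summarise")
    rows = [
        {
            "cluster_id": c.cluster_id,
            "n_points": c.n_points,
            "lon": c.centroid[0],
            "lat": c.centroid[1],
        }
        for c in clusters
    ]
    return pd.DataFrame(rows)
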