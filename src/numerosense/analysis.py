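"""Unsupervised structure discovery in the learned embedding space.

After action-prediction training, image embeddings of scenes with 0..30
objects arrange themselves along a near one-dimensional curve with tight
"islands" for the smallest counts.  This module quantifies that structure:

* density-based clustering (HDBSCAN) to recover number categories;
* a cluster-by-count confusion matrix and the subitization limit (largest L
  such that each count 0..L owns a single pure cluster);
* a calibrated *embedding line*: origin at the zero cluster (which collapses
  to a point because all empty images are identical), unit length from the
  zero-one inter-cluster distance, yielding a continuous perceived numerosity;
* the rank-1 linear-approximation error of the mean-centered embedding matrix;
* the action-derived directed graph over clusters, whose PUT edges traverse
  the numbers in ascending order (TAKE in reverse);
* power-law fits of perceived versus true numerosity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

OUTLIER = -1


class AnalysisError(ValueError):
    pass


class AmbiguityError(AnalysisError):
    """Two candidate zero clusters are indistinguishable."""


class ClusterGraphError(AnalysisError):
    """The action graph over clusters is inconsistent (cycle/conflict)."""


# ---------------------------------------------------------------------------
# clustering

@dataclass
class ClusterLabeling:
    """Per-point cluster assignment; ``OUTLIER`` (-1) marks excluded points."""

    labels: np.ndarray
    cluster_ids: np.ndarray = field(init=False)
    sizes: dict[int, int] = field(init=False)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        ids = np.unique(self.labels)
        self.cluster_ids = ids[ids != OUTLIER]
        self.sizes = {int(c): int((self.labels == c).sum()) for c in self.cluster_ids}

    @property
    def n_clusters(self) -> int:
        return len(self.cluster_ids)

    @property
    def outlier_mask(self) -> np.ndarray:
        return self.labels == OUTLIER


def cluster_embeddings(embeddings: np.ndarray,
                       min_cluster_size: int = 90) -> ClusterLabeling:
    """Density-based hierarchical clustering of the embedding points.

    HDBSCAN with Euclidean metric; ``min_cluster_size`` is the single free
    parameter (90 by default), everything else at library defaults.  Points
    the algorithm cannot assign are labeled ``OUTLIER``.
    """
    from sklearn.cluster import HDBSCAN

    z = np.asarray(embeddings, dtype=np.float64)
    if z.ndim != 2:
        raise AnalysisError("embeddings must be a 2-D matrix")
    if len(z) < min_cluster_size:
        raise AnalysisError(f"need at least {min_cluster_size} points, got {len(z)}")
    if np.allclose(z, z[0]):
        # degenerate density: a single point mass is a single cluster
        return ClusterLabeling(np.zeros(len(z), dtype=int))
    labels = HDBSCAN(min_cluster_size=min_cluster_size).fit_predict(z)
    return ClusterLabeling(labels)


# ---------------------------------------------------------------------------
# cluster-number correspondence

@dataclass
class NumberConfusion:
    """Cluster-by-count membership matrix and derived purity statistics."""

    matrix: "object"               # DataFrame: rows cluster id, cols true count
    purity: dict[int, float]       # per-cluster max fraction of one count
    dominant_count: dict[int, int]
    subitization_limit: int


def number_confusion(labeling: ClusterLabeling, true_counts: np.ndarray,
                     purity_threshold: float = 0.95) -> NumberConfusion:
    """Confusion matrix between clusters and true counts, plus the
    subitization limit: the largest L such that every count 0..L maps
    one-to-one onto a single pure cluster (purity and recall >= threshold).
    """
    import pandas as pd

    true_counts = np.asarray(true_counts, dtype=int)
    if len(true_counts) != len(labeling.labels):
        raise AnalysisError("labels and counts have different lengths")
    keep = ~labeling.outlier_mask
    mat = pd.crosstab(pd.Series(labeling.labels[keep], name="cluster"),
                      pd.Series(true_counts[keep], name="count"))
    purity, dominant = {}, {}
    for cid in mat.index:
        row = mat.loc[cid]
        purity[int(cid)] = float(row.max() / row.sum())
        dominant[int(cid)] = int(row.idxmax())

    limit = -1
    for c in range(int(true_counts.max()) + 1):
        owners = [cid for cid, d in dominant.items() if d == c]
        if len(owners) != 1 or purity[owners[0]] < purity_threshold:
            break
        col = mat[c] if c in mat.columns else None
        if col is None or col.sum() == 0:
            break
        recall = float(mat.loc[owners[0], c] / col.sum())
        if recall < purity_threshold:
            break
        limit = c
    return NumberConfusion(matrix=mat, purity=purity, dominant_count=dominant,
                           subitization_limit=limit)


def find_zero_cluster(embeddings: np.ndarray, labeling: ClusterLabeling,
                      tol: float = 1e-9) -> int:
    """The zero cluster is the one with minimal internal spread: empty
    scenes render identically, so their embeddings collapse to a point."""
    z = np.asarray(embeddings, dtype=np.float64)
    spreads = {}
    for cid in labeling.cluster_ids:
        pts = z[labeling.labels == cid]
        spreads[int(cid)] = float(np.linalg.norm(pts - pts.mean(axis=0), axis=1).mean())
    if not spreads:
        raise AnalysisError("no clusters")
    order = sorted(spreads, key=spreads.get)
    if len(order) > 1 and spreads[order[1]] - spreads[order[0]] < tol:
        raise AmbiguityError("two clusters tie for minimal spread")
    return order[0]


# ---------------------------------------------------------------------------
# the embedding line

@dataclass
class LineModel:
    """Calibrated embedding line: origin, unit direction, and yardstick.

    ``origin`` is the zero-cluster centroid; ``direction`` the first right
    singular vector of the mean-centered embeddings, signed so counts grow
    along +direction; ``unit`` the zero-one inter-cluster distance.
    """

    origin: np.ndarray
    direction: np.ndarray
    unit: float
    zero_cluster: int
    one_cluster: int

    def to_json(self) -> dict:
        return {"origin": self.origin.tolist(), "direction": self.direction.tolist(),
                "unit": self.unit, "zero_cluster": self.zero_cluster,
                "one_cluster": self.one_cluster}


def calibrate_line(embeddings: np.ndarray, labeling: ClusterLabeling,
                   unit_method: str = "cross_pairs") -> LineModel:
    """Self-calibrate the embedding line without any count supervision.

    The zero cluster is found by minimal spread; the "one" cluster is the
    nearest other cluster centroid along the principal direction; the unit
    is the mean distance over all zero-one cross pairs (``cross_pairs``) or
    between the two centroids (``centroids``).
    """
    from scipy.spatial.distance import cdist

    z = np.asarray(embeddings, dtype=np.float64)
    if labeling.n_clusters < 2:
        raise AnalysisError("need at least two clusters to calibrate a unit")
    zero = find_zero_cluster(z, labeling)

    keep = ~labeling.outlier_mask
    centered = z[keep] - z[keep].mean(axis=0)
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    direction = vt[0]

    origin = z[labeling.labels == zero].mean(axis=0)
    proj = {int(c): float((z[labeling.labels == c].mean(axis=0) - origin) @ direction)
            for c in labeling.cluster_ids}
    others = [c for c in proj if c != zero]
    one = min(others, key=lambda c: abs(proj[c]))
    if proj[one] < 0:
        direction = -direction

    zero_pts = z[labeling.labels == zero]
    one_pts = z[labeling.labels == one]
    if unit_method == "cross_pairs":
        unit = float(cdist(zero_pts, one_pts).mean())
    elif unit_method == "centroids":
        unit = float(np.linalg.norm(one_pts.mean(axis=0) - origin))
    else:
        raise ValueError(f"unknown unit_method {unit_method!r}")
    if unit <= 0:
        raise AnalysisError("degenerate unit: zero and one clusters coincide")
    return LineModel(origin=origin, direction=direction, unit=unit,
                     zero_cluster=int(zero), one_cluster=int(one))


def perceived_numerosity(line: LineModel, z: np.ndarray,
                         mode: str = "distance") -> np.ndarray:
    """Continuous count estimate of one or many embeddings.

    ``distance`` (default): Euclidean distance from the origin in units of
    the yardstick, signed by the side of the origin along the line (points
    behind the origin report negative values rather than being clamped).
    ``projection``: signed line coordinate / unit.  ``feature``: first
    embedding feature relative to the origin / unit (the summation-unit
    reading, where a single coordinate acts as the numerosity signal).
    """
    z = np.asarray(z, dtype=np.float64)
    single = z.ndim == 1
    pts = np.atleast_2d(z)
    coord = (pts - line.origin) @ line.direction
    if mode == "distance":
        vals = np.sign(np.where(coord == 0, 1.0, coord)) * \
            np.linalg.norm(pts - line.origin, axis=1) / line.unit
    elif mode == "projection":
        vals = coord / line.unit
    elif mode == "feature":
        vals = (pts[:, 0] - line.origin[0]) / line.unit
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return float(vals[0]) if single else vals


def linear_approximation_error(embeddings: np.ndarray) -> float:
    """Relative rank-1 residual of the mean-centered embedding matrix.

    ||Z_c - Z_1||_F / ||Z_c||_F where Z_1 is the best rank-1 SVD
    approximation; 0 iff the points are exactly collinear after centering.
    """
    z = np.asarray(embeddings, dtype=np.float64)
    if z.ndim != 2 or len(z) < 2:
        raise AnalysisError("need a matrix of at least two points")
    centered = z - z.mean(axis=0)
    s = np.linalg.svd(centered, compute_uv=False)
    total = float((s ** 2).sum())
    if total == 0.0:
        raise AnalysisError("all points identical: rank-1 ratio undefined")
    return float(np.sqrt((s[1:] ** 2).sum() / total))


# ---------------------------------------------------------------------------
# action-derived cluster ordering

@dataclass
class ClusterGraph:
    """Directed links between clusters induced by PUT/TAKE transitions."""

    put_edges: dict[tuple[int, int], int]    # (from, to) -> traversal count
    take_edges: dict[tuple[int, int], int]
    order: list[int]                         # ascending chain from the zero cluster


def cluster_graph_from_actions(actions, labels_before, labels_after,
                               zero_cluster: int,
                               agreement: float = 0.9) -> ClusterGraph:
    """Recover the number ordering from actions alone.

    Every PUT pair whose two images fall in (non-outlier) clusters a, b
    casts a vote for the directed edge a -> b; TAKE votes b <- a.  Edges
    need >= ``agreement`` directional consistency, PUT and TAKE edges
    between a pair must point in opposite directions, and the majority PUT
    edges must chain the clusters into a cycle-free ascending order
    starting at the zero cluster.
    """
    from . import scenes

    put_votes: dict[tuple[int, int], int] = {}
    take_votes: dict[tuple[int, int], int] = {}
    for act, a, b in zip(actions, labels_before, labels_after):
        if a == OUTLIER or b == OUTLIER or a == b:
            continue
        act = scenes.ActionKind(act)
        if act is scenes.ActionKind.PUT:
            put_votes[(a, b)] = put_votes.get((a, b), 0) + 1
        elif act is scenes.ActionKind.TAKE:
            take_votes[(a, b)] = take_votes.get((a, b), 0) + 1

    def majority(votes: dict[tuple[int, int], int]) -> dict[tuple[int, int], int]:
        edges = {}
        seen = set()
        for (a, b) in votes:
            key = (min(a, b), max(a, b))
            if key in seen:
                continue
            seen.add(key)
            fwd, rev = votes.get((a, b), 0), votes.get((b, a), 0)
            total = fwd + rev
            if fwd >= rev:
                if fwd / total < agreement:
                    raise ClusterGraphError(
                        f"conflicting edge between clusters {a} and {b}")
                edges[(a, b)] = fwd
            else:
                if rev / total < agreement:
                    raise ClusterGraphError(
                        f"conflicting edge between clusters {a} and {b}")
                edges[(b, a)] = rev
        return edges

    put_edges = majority(put_votes)
    take_edges = majority(take_votes)
    for (a, b) in put_edges:
        if (a, b) in take_edges:
            raise ClusterGraphError(
                f"PUT and TAKE edges both point {a} -> {b}")

    # follow the strongest PUT edge out of each cluster, starting at zero
    order = [zero_cluster]
    while True:
        outgoing = {b: n for (a, b), n in put_edges.items() if a == order[-1]}
        if not outgoing:
            break
        nxt = max(outgoing, key=outgoing.get)
        if nxt in order:
            raise ClusterGraphError("PUT edges form a cycle: clustering failed")
        order.append(nxt)
    return ClusterGraph(put_edges=put_edges, take_edges=take_edges, order=order)


# ---------------------------------------------------------------------------
# psychophysical power law

@dataclass
class PowerLawFit:
    """perceived ~ a * n**b, fitted by least squares in log-log space."""

    coefficient: float
    exponent: float
    residual: float


def fit_power_law(true_counts: np.ndarray, perceived: np.ndarray) -> PowerLawFit:
    """Fit the compressive mapping between true and perceived numerosity.

    Only counts >= 1 and positive perceived values enter the log-log
    regression (zero has no logarithm; negative estimates are diagnostic
    failures upstream).  An exponent below 1 is the classic
    underestimation-of-large-numbers bias.
    """
    n = np.asarray(true_counts, dtype=float)
    p = np.asarray(perceived, dtype=float)
    mask = (n >= 1) & (p > 0)
    n, p = n[mask], p[mask]
    if len(np.unique(n)) < 3:
        raise AnalysisError("need at least 3 distinct counts >= 1 to fit")
    slope, intercept = np.polyfit(np.log(n), np.log(p), 1)
    resid = float(np.sqrt(np.mean((np.log(p) - (slope * np.log(n) + intercept)) ** 2)))
    return PowerLawFit(coefficient=float(np.exp(intercept)), exponent=float(slope),
                       residual=resid)
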