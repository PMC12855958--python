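"""Effective dimension and radius of representational manifolds.

The estimator follows the anchor-point (support) geometry of manifold
capacity theory: a manifold is the point cloud of population states evoked
by related stimuli; random Gaussian probe directions select extremal
("anchor") points of its convex hull, and the spread and alignment of those
anchors define the manifold's radius R_M and effective dimension D_M.

Manifolds are segmented from the full set of representations with Louvain
community detection on a k-nearest-neighbor similarity graph, and the whole
procedure is repeated over random neuron subsamples, mirroring the
permutation protocol used for cortical recordings (100 neurons x 20
repeats, or 30 x 30 for small per-animal pools).

Implementation note: anchors are computed in the row space of the centered
point cloud via the Gram matrix, so that D_M and R_M are exactly invariant
to global rotations of the ambient space.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from networkx.algorithms.community import louvain_communities
from sklearn.neighbors import kneighbors_graph

from .synth import RecordingTable

__all__ = [
    "ManifoldGeometryConfig",
    "ManifoldGeometryResult",
    "louvain_partition",
    "anchor_geometry",
    "region_geometry",
    "participation_ratio",
]


@dataclass(frozen=True)
class ManifoldGeometryConfig:
    """Subsampling and estimator settings for manifold geometry."""

    n_neurons_per_draw: int = 100
    n_repeats: int = 20
    n_probes: int = 500
    kappa: float = 0.0  # margin of the anchor support problem
    knn_k: int = 15
    resolution: float = 1.0
    # Per-neuron z-scoring before geometry is exposed but off by default:
    # centering places the grand-mean state at the origin, so any manifold
    # whose centroid passes near the origin makes the centroid-normalized
    # radius ill-conditioned; raw nonnegative rates keep it stable.
    zscore: bool = False
    min_manifold_size: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_neurons_per_draw, self.n_repeats, self.n_probes, self.knn_k) <= 0:
            raise ValueError("counts must be positive")
        if self.kappa < 0:
            raise ValueError("kappa must be >= 0")


@dataclass
class ManifoldGeometryResult:
    dimension_per_repeat: np.ndarray  # mean D_M over manifolds, per repeat
    radius_per_repeat: np.ndarray  # mean R_M over manifolds, per repeat
    per_manifold: list[dict] = field(default_factory=list)

    @property
    def mean_dimension(self) -> float:
        return float(np.mean(self.dimension_per_repeat))

    @property
    def mean_radius(self) -> float:
        return float(np.mean(self.radius_per_repeat))


def participation_ratio(x: np.ndarray) -> float:
    """(sum eig)^2 / sum eig^2 of the covariance: a spectral dimensionality."""
    x = np.asarray(x, dtype=float)
    x = x - x.mean(axis=0)
    ev = np.linalg.svd(x, compute_uv=False) ** 2
    return float(ev.sum() ** 2 / (ev**2).sum())


def louvain_partition(
    representations: np.ndarray,
    knn_k: int = 15,
    resolution: float = 1.0,
    seed: int = 0,
) -> np.ndarray:
    """Segment points into manifolds by Louvain modularity optimization on a
    k-NN graph with Gaussian-kernel edge weights.

    Returns an integer label per point. Deterministic given ``seed``.
    """
    x = np.asarray(representations, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2:
        raise ValueError("need at least two points")
    n = x.shape[0]
    if knn_k >= n:
        raise ValueError(f"knn_k={knn_k} must be smaller than n={n} points")
    adj = kneighbors_graph(x, knn_k, mode="distance", include_self=False)
    adj = adj.maximum(adj.T).tocoo()  # symmetrize
    # bandwidth = largest retained neighbor distance: keeps edge weights
    # near-uniform inside a homogeneous cloud (cluster separation comes from
    # the graph topology, not the kernel)
    sigma = adj.data.max() if adj.data.size and adj.data.max() > 0 else 1.0
    weights = np.exp(-(adj.data**2) / (2.0 * sigma**2))
    g = nx.Graph()
    g.add_nodes_from(range(n))
    g.add_weighted_edges_from(zip(adj.row.tolist(), adj.col.tolist(), weights))
    comms = louvain_communities(g, weight="weight", resolution=resolution, seed=seed)
    labels = np.empty(n, dtype=int)
    # deterministic label order: communities sorted by their smallest member
    for lab, comm in enumerate(sorted(comms, key=min)):
        labels[list(comm)] = lab
    return labels


def _gram_coordinates(points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Row-space coordinates B (n x r) with B @ B.T = Gram(points).

    Built from the eigendecomposition of the Gram matrix, hence identical for
    any global rotation of the ambient space.
    """
    g = points @ points.T
    g = 0.5 * (g + g.T)
    evals, evecs = np.linalg.eigh(g)
    tol = max(g.shape[0], 1) * np.finfo(float).eps * max(evals.max(), 0.0)
    keep = evals > max(tol, 1e-12)
    b = evecs[:, keep] * np.sqrt(evals[keep])
    return b, evals[keep]


def _anchor_kappa(b: np.ndarray, g: np.ndarray, t: np.ndarray, kappa: float,
                  tol: float = 1e-8, max_iter: int = 500) -> np.ndarray:
    """Maximize <t, S a> - kappa * ||S a|| over the simplex by projected
    gradient ascent, in Gram coordinates. Returns the weight vector a."""
    n = b.shape[0]
    a = np.full(n, 1.0 / n)
    score = b @ t
    lr = 1.0 / (np.abs(g).sum(axis=1).max() + 1e-12)
    prev = -np.inf
    for _ in range(max_iter):
        norm = np.sqrt(max(a @ g @ a, 1e-30))
        grad = score - kappa * (g @ a) / norm
        a = _project_simplex(a + lr * grad)
        val = a @ score - kappa * np.sqrt(max(a @ g @ a, 0.0))
        if abs(val - prev) < tol:
            break
        prev = val
    return a


def _project_simplex(v: np.ndarray) -> np.ndarray:
    u = np.sort(v)[::-1]
    css = np.cumsum(u) - 1.0
    rho = np.nonzero(u * np.arange(1, v.size + 1) > css)[0][-1]
    return np.maximum(v - css[rho] / (rho + 1.0), 0.0)


def anchor_geometry(
    points: np.ndarray,
    n_probes: int = 500,
    kappa: float = 0.0,
    seed: int = 0,
    center: bool = True,
) -> tuple[float, float]:
    """Effective dimension D_M and radius R_M of one manifold.

    Points are centered on the manifold centroid and normalized by the
    centroid norm. For each Gaussian probe direction the anchor point is the
    convex combination of manifold points solving the margin-``kappa``
    support problem (at ``kappa = 0`` this is the extremal vertex in the
    probe direction). D_M is the mean squared alignment of probes with unit
    anchors; R_M is the root-mean-square anchor norm.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 1:
        raise ValueError("points must be a 2-D array")
    if center:
        c = pts.mean(axis=0)
        scale = np.linalg.norm(c)
        pts = (pts - c) / (scale if scale > 1e-12 else 1.0)
    b, _ = _gram_coordinates(pts)
    if b.shape[1] == 0:  # all points identical
        warnings.warn("degenerate manifold (all points identical): D=R=0")
        return 0.0, 0.0
    gram = b @ b.T
    norms_sq = np.diag(gram).copy()
    rng = np.random.default_rng(seed)
    probes = rng.standard_normal(size=(n_probes, b.shape[1]))
    aligns = np.empty(n_probes)
    anchor_norms_sq = np.empty(n_probes)
    if kappa == 0.0:
        scores = probes @ b.T  # (n_probes, n_points)
        idx = np.argmax(scores, axis=1)
        anchor_norms_sq = norms_sq[idx]
        best = scores[np.arange(n_probes), idx]
        with np.errstate(invalid="ignore", divide="ignore"):
            aligns = best / np.sqrt(anchor_norms_sq)
        aligns[anchor_norms_sq <= 1e-24] = 0.0
    else:
        for k, t in enumerate(probes):
            a = _anchor_kappa(b, gram, t, kappa)
            ns = max(a @ gram @ a, 0.0)
            anchor_norms_sq[k] = ns
            aligns[k] = (a @ (b @ t)) / np.sqrt(ns) if ns > 1e-24 else 0.0
    d_m = float(np.mean(aligns**2))
    r_m = float(np.sqrt(np.mean(anchor_norms_sq)))
    return d_m, r_m


def region_geometry(
    rec: RecordingTable, config: ManifoldGeometryConfig | None = None
) -> ManifoldGeometryResult:
    """Manifold dimension and radius for a region under the subsampling
    protocol: per repeat, draw ``n_neurons_per_draw`` neurons, segment the
    condition representations with Louvain, and average anchor geometry over
    the segmented manifolds."""
    cfg = config or ManifoldGeometryConfig()
    if rec.n_neurons < cfg.n_neurons_per_draw:
        raise ValueError(
            f"table has {rec.n_neurons} neurons but {cfg.n_neurons_per_draw} are "
            "requested per draw; for small pools use the per-animal variant "
            "(n_neurons_per_draw=30, n_repeats=30)"
        )
    rng = np.random.default_rng(cfg.seed)
    dims, radii, records = [], [], []
    for rep in range(cfg.n_repeats):
        neurons = rng.choice(rec.n_neurons, size=cfg.n_neurons_per_draw, replace=False)
        x = rec.responses[neurons].T.astype(float)  # conditions x neurons
        if cfg.zscore:
            mu, sd = x.mean(axis=0), x.std(axis=0)
            sd[sd == 0] = 1.0
            x = (x - mu) / sd
        labels = louvain_partition(
            x, knn_k=cfg.knn_k, resolution=cfg.resolution, seed=cfg.seed + rep
        )
        rep_d, rep_r = [], []
        for lab in np.unique(labels):
            pts = x[labels == lab]
            if pts.shape[0] < cfg.min_manifold_size:
                continue
            d, r = anchor_geometry(
                pts, n_probes=cfg.n_probes, kappa=cfg.kappa, seed=cfg.seed + 7919 * rep + lab
            )
            rep_d.append(d)
            rep_r.append(r)
            records.append({"repeat": rep, "manifold": int(lab), "n_points": pts.shape[0], "D": d, "R": r})
        if rep_d:
            dims.append(np.mean(rep_d))
            radii.append(np.mean(rep_r))
    return ManifoldGeometryResult(np.asarray(dims), np.asarray(radii), records)
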