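"""kNN graphs, farthest-point sampling, and dilated neighborhoods.

The local edge-convolution layers use a k-nearest-neighbor graph built
in whatever feature space the layer currently operates in (the *dynamic*
graph).  The dilated operator instead takes a much larger neighbor set
``N_b(i)`` in the metric space of the face centers, then farthest-point
samples ``f`` members ``N_s(i)`` from it, spreading the receptive field
without growing the edge count.  Because it depends only on the face
centers it is static and can be precomputed once per mesh.

Everything here is exact and deterministic: brute-force distances,
distance ties broken by ascending index, FPS seeded at the candidate
nearest the query.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass

import numpy as np

from .errors import ParameterError

__all__ = ["NeighborIndex", "knn_graph", "farthest_point_sample",
           "dilated_neighborhood", "save_neighbor_index",
           "load_neighbor_index", "mesh_hash"]


@dataclass
class NeighborIndex:
    """M×k table of neighbor face indices.

    ``dilated`` marks a farthest-point-sampled neighborhood drawn from a
    larger set of ``source_k`` nearest neighbors.
    """

    indices: np.ndarray           # (M, k) int64
    space_dim: int
    dilated: bool = False
    source_k: int = 0

    def __post_init__(self):
        self.indices = np.asarray(self.indices, dtype=np.int64)
        if self.indices.ndim != 2:
            raise ParameterError("indices must be an M×k matrix")

    @property
    def n_points(self) -> int:
        return self.indices.shape[0]

    @property
    def k(self) -> int:
        return self.indices.shape[1]


def _argext_tiebreak(values: np.ndarray, tiebreak: np.ndarray,
                     mode: str) -> np.ndarray:
    """Row-wise arg-min/max of ``values``; exact ties resolved by the
    smallest ``tiebreak`` entry.  Returns column positions."""
    if mode == "min":
        ext = values.min(axis=1, keepdims=True)
    else:
        ext = values.max(axis=1, keepdims=True)
    mask = values == ext
    big = np.iinfo(np.int64).max
    return np.argmin(np.where(mask, tiebreak, big), axis=1)


def knn_graph(points: np.ndarray, k: int, chunk: int = 1024) -> NeighborIndex:
    """Exact k-nearest-neighbor graph under Euclidean distance.

    Row i lists the k nearest points to i in ascending distance, self
    excluded, distance ties broken by ascending index.  Candidates are
    preselected with the inner-product expansion of the squared distance
    (with slack), then re-ranked with exactly computed coordinate
    differences so ordering and tie-breaks are reproducible.
    """
    points = np.asarray(points)
    if points.dtype not in (np.float32, np.float64):
        points = points.astype(np.float64)
    m = len(points)
    if k < 1 or k >= m:
        raise ParameterError(f"k must satisfy 1 <= k < M (k={k}, M={m})")
    sq = (points * points).sum(axis=1)
    pad = min(m - 1, k + 8)
    out = np.empty((m, k), dtype=np.int64)
    for lo in range(0, m, chunk):
        hi = min(lo + chunk, m)
        rows = np.arange(hi - lo)
        approx = sq[lo:hi, None] + sq[None, :] \
            - 2.0 * (points[lo:hi] @ points.T)
        approx[rows, lo + rows] = np.inf
        if pad < m - 1:
            cand = np.argpartition(approx, pad - 1, axis=1)[:, :pad]
        else:
            cand = np.broadcast_to(np.arange(m), (hi - lo, m)).copy()
            # drop self from the full candidate list
            cand = cand[approx[rows[:, None], cand] < np.inf].reshape(
                hi - lo, m - 1)
        diff = points[cand] - points[lo:hi, None, :]
        exact = (diff * diff).sum(axis=-1)
        order = np.lexsort((cand, exact), axis=1)
        out[lo:hi] = np.take_along_axis(cand, order, axis=1)[:, :k]
    return NeighborIndex(out, space_dim=points.shape[1])


def farthest_point_sample(points: np.ndarray, candidates, f: int,
                          query: int) -> np.ndarray:
    """Greedy farthest-point sampling of ``f`` members of ``candidates``.

    The first pick is the candidate nearest to ``query``; each later
    pick maximizes the minimum distance to the already-picked set.  All
    ties go to the lowest candidate index.  Returns picks in pick order.
    """
    points = np.asarray(points, dtype=np.float64)
    cand = np.asarray(list(candidates), dtype=np.int64)
    if f > len(cand):
        raise ParameterError(f"f={f} exceeds candidate count {len(cand)}")
    if query in cand:
        raise ParameterError("query must not be among the candidates")
    cpts = points[cand]
    d_query = ((cpts - points[query]) ** 2).sum(axis=1)
    picks = np.empty(f, dtype=np.int64)
    pos = _argext_tiebreak(d_query[None, :], cand[None, :], "min")[0]
    picks[0] = cand[pos]
    mind = ((cpts - cpts[pos]) ** 2).sum(axis=1)
    mind[pos] = -np.inf
    for t in range(1, f):
        pos = _argext_tiebreak(mind[None, :], cand[None, :], "max")[0]
        picks[t] = cand[pos]
        mind = np.minimum(mind, ((cpts - cpts[pos]) ** 2).sum(axis=1))
        mind[pos] = -np.inf
    return picks


def dilated_neighborhood(face_centers: np.ndarray, k_b: int, f: int,
                         chunk: int = 512) -> NeighborIndex:
    """Dilated neighborhood index N_s: for every face, farthest-point
    sample ``f`` faces from its ``k_b`` nearest neighbors (face centers,
    metric space).  Pure function of the centers, hence precomputable."""
    face_centers = np.asarray(face_centers, dtype=np.float64)
    m = len(face_centers)
    if not 1 <= f <= k_b or k_b >= m:
        raise ParameterError(
            f"need 1 <= f <= k_b < M (f={f}, k_b={k_b}, M={m})")
    base = knn_graph(face_centers, k_b)
    out = np.empty((m, f), dtype=np.int64)
    for lo in range(0, m, chunk):
        hi = min(lo + chunk, m)
        cand = base.indices[lo:hi]                       # (B, k_b)
        cpts = face_centers[cand]                        # (B, k_b, 3)
        qpts = face_centers[lo:hi]
        rows = np.arange(hi - lo)
        d0 = ((cpts - qpts[:, None, :]) ** 2).sum(axis=2)
        pos = _argext_tiebreak(d0, cand, "min")
        out[lo:hi, 0] = cand[rows, pos]
        mind = ((cpts - cpts[rows, pos][:, None, :]) ** 2).sum(axis=2)
        mind[rows, pos] = -np.inf
        for t in range(1, f):
            pos = _argext_tiebreak(mind, cand, "max")
            out[lo:hi, t] = cand[rows, pos]
            d_new = ((cpts - cpts[rows, pos][:, None, :]) ** 2).sum(axis=2)
            mind = np.minimum(mind, d_new)
            mind[rows, pos] = -np.inf
    return NeighborIndex(out, space_dim=3, dilated=True, source_k=k_b)


# ---------------------------------------------------------------------------
# precomputed-index sidecars


def mesh_hash(vertices: np.ndarray, faces: np.ndarray) -> str:
    h = hashlib.sha256()
    h.update(np.ascontiguousarray(vertices, dtype=np.float64).tobytes())
    h.update(np.ascontiguousarray(faces, dtype=np.int64).tobytes())
    return h.hexdigest()


def save_neighbor_index(path, index: NeighborIndex, mesh_key: str) -> None:
    """Serialize a precomputed dilated index keyed by mesh hash."""
    np.savez(path, indices=index.indices, space_dim=index.space_dim,
             dilated=int(index.dilated), source_k=index.source_k,
             mesh_key=np.array(mesh_key))


def load_neighbor_index(path, expect_mesh_key: str | None = None
                        ) -> NeighborIndex:
    with np.load(path) as z:
        key = str(z["mesh_key"])
        if expect_mesh_key is not None and key != expect_mesh_key:
            raise ParameterError(
                "precomputed index belongs to a different mesh")
        return NeighborIndex(z["indices"], space_dim=int(z["space_dim"]),
                             dilated=bool(z["dilated"]),
                             source_k=int(z["source_k"]))
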