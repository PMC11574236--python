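"""Quadric-error edge-collapse mesh decimation (Garland–Heckbert style).

Each vertex carries the sum of the squared-distance quadrics of its
incident face planes (area-weighted).  Edges are collapsed cheapest-first
to the position minimizing the combined quadric, with a link-condition
check so every collapse removes a predictable number of faces and the
mesh stays manifold.  The loop is driven to an *exact* face target:
an interior-edge collapse removes two faces, a boundary-edge collapse
one, so a final boundary collapse absorbs odd remainders.
"""

from __future__ import annotations

import heapq
import itertools

import numpy as np

from .errors import SimplificationError


def _face_quadric(v0, v1, v2):
    n = np.cross(v1 - v0, v2 - v0)
    area = 0.5 * np.linalg.norm(n)
    if area < 1e-14:
        return np.zeros((4, 4)), 0.0
    n = n / (2.0 * area)
    d = -np.dot(n, v0)
    p = np.array([n[0], n[1], n[2], d])
    return area * np.outer(p, p), area


class _Collapser:
    def __init__(self, vertices: np.ndarray, faces: np.ndarray):
        self.V = vertices.astype(np.float64).copy()
        self.faces = [tuple(int(i) for i in f) for f in faces]
        self.alive = [True] * len(self.faces)
        self.n_alive = len(self.faces)
        nv = len(self.V)
        self.quadrics = np.zeros((nv, 4, 4))
        self.vert_faces: list[set[int]] = [set() for _ in range(nv)]
        for fi, (a, b, c) in enumerate(self.faces):
            q, _ = _face_quadric(self.V[a], self.V[b], self.V[c])
            for v in (a, b, c):
                self.quadrics[v] += q
                self.vert_faces[v].add(fi)
        self.version = [0] * nv
        self.heap: list = []
        self.counter = itertools.count()
        for u, v in self._edges():
            self._push(u, v)

    def _edges(self):
        seen = set()
        for a, b, c in self.faces:
            for u, v in ((a, b), (b, c), (c, a)):
                e = (u, v) if u < v else (v, u)
                if e not in seen:
                    seen.add(e)
                    yield e

    def _optimal(self, u: int, v: int):
        q = self.quadrics[u] + self.quadrics[v]
        a = q[:3, :3]
        b = -q[:3, 3]
        scale = max(np.abs(a).max(), 1e-30)
        if abs(np.linalg.det(a)) > 1e-9 * scale ** 3:
            x = np.linalg.solve(a, b)
        else:
            x = 0.5 * (self.V[u] + self.V[v])
        h = np.append(x, 1.0)
        return x, float(h @ q @ h)

    def _push(self, u: int, v: int):
        if u > v:
            u, v = v, u
        x, cost = self._optimal(u, v)
        heapq.heappush(self.heap, (cost, next(self.counter), u, v,
                                   self.version[u], self.version[v], x))

    def _shared_faces(self, u: int, v: int) -> list[int]:
        return [fi for fi in self.vert_faces[u] & self.vert_faces[v]
                if self.alive[fi]]

    def _neighbors(self, u: int) -> set[int]:
        out: set[int] = set()
        for fi in self.vert_faces[u]:
            if self.alive[fi]:
                out.update(self.faces[fi])
        out.discard(u)
        return out

    def _collapse(self, u: int, v: int, x: np.ndarray) -> int:
        """Collapse v into u placed at x; return number of faces removed."""
        removed = self._shared_faces(u, v)
        for fi in removed:
            self.alive[fi] = False
            self.n_alive -= 1
        self.V[u] = x
        self.quadrics[u] = self.quadrics[u] + self.quadrics[v]
        for fi in list(self.vert_faces[v]):
            if not self.alive[fi]:
                continue
            f = tuple(u if w == v else w for w in self.faces[fi])
            self.faces[fi] = f
            self.vert_faces[u].add(fi)
        self.vert_faces[v] = set()
        self.version[u] += 1
        self.version[v] += 1
        for w in self._neighbors(u):
            self._push(u, w)
        return len(removed)

    def _pop_valid(self, want_boundary: bool | None):
        """Pop the cheapest structurally valid edge.

        want_boundary: None = any; True = only edges whose collapse removes
        exactly one face (boundary edges).
        """
        deferred = []
        result = None
        while self.heap:
            cost, cnt, u, v, vu, vv, x = heapq.heappop(self.heap)
            if self.version[u] != vu or self.version[v] != vv:
                continue
            shared = self._shared_faces(u, v)
            if not shared:
                continue
            # link condition: common neighbor vertices must be exactly the
            # third vertices of the shared faces, else collapse pinches
            common = self._neighbors(u) & self._neighbors(v)
            thirds = {w for fi in shared for w in self.faces[fi]
                      if w not in (u, v)}
            if common != thirds or len(shared) > 2:
                continue
            if want_boundary and len(shared) != 1:
                deferred.append((cost, cnt, u, v, vu, vv, x))
                continue
            result = (u, v, x, len(shared))
            break
        for item in deferred:
            heapq.heappush(self.heap, item)
        return result

    def run(self, target_faces: int):
        while self.n_alive > target_faces:
            excess = self.n_alive - target_faces
            pick = self._pop_valid(want_boundary=(excess == 1))
            if pick is None:
                raise SimplificationError(
                    f"cannot reach {target_faces} faces; stuck at "
                    f"{self.n_alive}")
            u, v, x, _ = pick
            self._collapse(u, v, x)
        return self._compact()

    def _compact(self):
        faces = np.array([f for f, a in zip(self.faces, self.alive) if a],
                         dtype=np.int64)
        used = np.unique(faces)
        remap = np.full(len(self.V), -1, dtype=np.int64)
        remap[used] = np.arange(len(used))
        return self.V[used], remap[faces]


def quadric_collapse(vertices: np.ndarray, faces: np.ndarray,
                     target_faces: int) -> tuple[np.ndarray, np.ndarray]:
    """Decimate to exactly ``target_faces`` faces.

    Returns (vertices, faces) with unused vertices dropped.  Raises
    :class:`SimplificationError` when the target cannot be reached
    (e.g. an odd target on a closed surface, or a degenerate input).
    """
    return _Collapser(vertices, faces).run(int(target_faces))
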