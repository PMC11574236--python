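"""Deterministic synthetic dental arches for testing and toy training.

The generator emulates the geometry regime of an intraoral scan at desk
scale: a parabolic gum band studded with hemispherical tooth bumps, one
per non-missing class, equally spaced along the arch.  Bumps come in two
shape families — narrow "incisor-like" and wide "molar-like" — assigned
by position, so within a family the class of a bump is recoverable only
from its position along the arch, not from its own geometry.  That is
exactly the ambiguity a wide receptive field is meant to resolve.

All randomness flows through the single seed in :class:`ArchSpec`; the
same spec always yields a bit-identical mesh.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import SpecError
from .mesh_io import TriMesh, simplify_mesh

__all__ = ["ArchSpec", "generate_arch", "family_labels", "INCISOR_LIKE",
           "MOLAR_LIKE"]

# class -> shape family; positions 1-4 of each quadrant (incisors,
# canine, first premolar) get the narrow family, 5-8 the wide one
INCISOR_LIKE = frozenset(
    c for c in range(1, 17) if ((c - 1) % 8) < 4)
MOLAR_LIKE = frozenset(range(1, 17)) - INCISOR_LIKE

_NARROW_SCALE = 0.85
_WIDE_SCALE = 1.20


@dataclass(frozen=True)
class ArchSpec:
    """Parameters of a synthetic arch.

    Lengths are in mm.  ``n_teeth`` selects classes 1..n_teeth as
    candidate bumps; ``missing`` removes classes from that set, leaving a
    gap at the corresponding position.
    """

    n_teeth: int = 14
    missing: frozenset[int] = frozenset()
    target_faces: int = 4000
    tooth_radius: float = 2.2
    arch_width: float = 50.0
    arch_depth: float = 30.0
    jitter_sd: float = 0.05
    seed: int = 0

    def __post_init__(self):
        if not 0 <= self.n_teeth <= 16:
            raise SpecError("n_teeth must be in 0..16")
        if not set(self.missing) <= set(range(1, 17)):
            raise SpecError("missing must be a subset of {1..16}")
        if self.target_faces < 100:
            raise SpecError("target_faces must be >= 100")
        if self.tooth_radius <= 0 or self.jitter_sd < 0:
            raise SpecError("tooth_radius must be > 0, jitter_sd >= 0")
        object.__setattr__(self, "missing", frozenset(self.missing))

    @property
    def present_classes(self) -> frozenset[int]:
        return frozenset(range(1, self.n_teeth + 1)) - self.missing


def tooth_radius_for(cls: int, base_radius: float) -> float:
    scale = _NARROW_SCALE if cls in INCISOR_LIKE else _WIDE_SCALE
    return scale * base_radius


def family_labels(labels: np.ndarray) -> np.ndarray:
    """Collapse 17-class labels to the three-class toy task:
    0 = gum, 1 = incisor-like bump, 2 = molar-like bump."""
    labels = np.asarray(labels, dtype=np.int64)
    out = np.zeros_like(labels)
    out[np.isin(labels, list(INCISOR_LIKE))] = 1
    out[np.isin(labels, list(MOLAR_LIKE))] = 2
    return out


def _centerline(s: np.ndarray, spec: ArchSpec):
    """Parabolic arch centerline and its in-plane unit normal."""
    t = 2.0 * s - 1.0                            # [-1, 1]
    x = 0.5 * spec.arch_width * t
    y = spec.arch_depth * (1.0 - t * t)
    dx = np.full_like(t, spec.arch_width)        # d/dt scaled; direction only
    dy = -4.0 * spec.arch_depth * t
    norm = np.hypot(dx, dy)
    # in-plane normal of the tangent
    nx, ny = dy / norm, -dx / norm
    return np.stack([x, y], axis=-1), np.stack([nx, ny], axis=-1)


def _arc_positions(spec: ArchSpec, n_slots: int) -> np.ndarray:
    """Equally spaced (by arc length) parameter positions for n_slots."""
    s_fine = np.linspace(0.0, 1.0, 2048)
    pts, _ = _centerline(s_fine, spec)
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    arc = np.concatenate([[0.0], np.cumsum(seg)])
    total = arc[-1]
    margin = 1.5 * _WIDE_SCALE * spec.tooth_radius
    targets = np.linspace(margin, total - margin, max(n_slots, 1))
    return np.interp(targets, arc, s_fine)


def generate_arch(spec: ArchSpec) -> TriMesh:
    """Generate a labeled synthetic arch with exactly
    ``spec.target_faces`` faces.

    Raises :class:`SpecError` if adjacent bumps would overlap.
    """
    classes = sorted(spec.present_classes)
    n_slots = spec.n_teeth
    slot_s = _arc_positions(spec, n_slots) if n_slots else np.empty(0)
    centers2d, _ = (_centerline(slot_s, spec) if n_slots
                    else (np.empty((0, 2)), None))
    radii = np.array([tooth_radius_for(c, spec.tooth_radius)
                      for c in range(1, n_slots + 1)])

    # feasibility: adjacent present bumps must not overlap
    present_idx = [c - 1 for c in classes]
    for a, b in zip(present_idx, present_idx[1:]):
        gap = np.linalg.norm(centers2d[a] - centers2d[b])
        if gap < radii[a] + radii[b]:
            raise SpecError(
                f"tooth bumps {a + 1} and {b + 1} overlap "
                f"(gap {gap:.2f} mm)")

    band = 2.4 * spec.tooth_radius

    # grid sized ~60% above target so internal simplification has slack
    raw_faces = max(int(1.6 * spec.target_faces), spec.target_faces + 200)
    n_v = max(int(np.sqrt(raw_faces / 12.0)), 4)
    n_u = raw_faces // (2 * (n_v - 1)) + 1

    s = np.linspace(0.0, 1.0, n_u)
    v = np.linspace(-1.0, 1.0, n_v)
    line, normal = _centerline(s, spec)
    # vertex grid: centerline offset across the band
    xy = (line[:, None, :] + normal[:, None, :] * (band * v)[None, :, None])
    grid = xy.reshape(-1, 2)

    # bump heights: hemisphere over each present tooth center
    z = np.zeros(len(grid))
    labels2d = np.zeros(len(grid), dtype=np.int64)
    for c in classes:
        r = radii[c - 1]
        d2 = ((grid - centers2d[c - 1]) ** 2).sum(axis=1)
        inside = d2 < r * r
        h = np.sqrt(np.maximum(r * r - d2[inside], 0.0))
        z[inside] = np.maximum(z[inside], h)
        labels2d[inside] = c

    vertices = np.concatenate([grid, z[:, None]], axis=1)

    iu, iv = np.meshgrid(np.arange(n_u - 1), np.arange(n_v - 1),
                         indexing="ij")
    v00 = (iu * n_v + iv).ravel()
    v01 = v00 + 1
    v10 = v00 + n_v
    v11 = v10 + 1
    faces = np.concatenate([
        np.stack([v00, v10, v11], axis=1),
        np.stack([v00, v11, v01], axis=1),
    ])
    faces = faces[np.lexsort((faces[:, 2], faces[:, 1], faces[:, 0]))]

    rng = np.random.default_rng(spec.seed)
    if spec.jitter_sd > 0:
        vertices = vertices + rng.normal(0.0, spec.jitter_sd,
                                         vertices.shape)

    # face labels from the unjittered parameterization: a face belongs to
    # the bump whose disk contains its (u,v)-grid centroid
    fc2d = grid[faces].mean(axis=1)
    face_labels = np.zeros(len(faces), dtype=np.int64)
    for c in classes:
        r = radii[c - 1]
        d2 = ((fc2d - centers2d[c - 1]) ** 2).sum(axis=1)
        face_labels[d2 < r * r] = c

    mesh = TriMesh(vertices, faces, face_labels)
    return simplify_mesh(mesh, spec.target_faces)
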