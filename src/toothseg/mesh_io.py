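"""Mesh and label I/O, simplification, and per-face feature extraction.

A dental surface is a triangular mesh whose faces carry one of 17 labels:
0 for gum and 1..16 for the teeth of one arch, in fixed correspondence
with FDI two-digit tooth codes.  Each face is described by a 24-vector:
the three vertex coordinates and the face center (12 numbers) followed by
the three vertex normals and the face normal (12 numbers).  Features are
z-scored per mesh before entering the network.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import trimesh

from ._quadric import quadric_collapse
from .errors import (FormatError, GeometryError, LabelError, ParameterError,
                     StateError)

__all__ = [
    "TriMesh", "FaceFeatureMatrix", "read_mesh", "write_mesh",
    "write_colored_ply", "simplify_mesh", "compute_face_features",
    "zscore_normalize", "fdi_to_class", "class_to_fdi",
    "N_CLASSES", "FEATURE_DIM",
]

N_CLASSES = 17
FEATURE_DIM = 24
_AREA_TOL = 1e-12

# Class 0 is gum.  Classes 1..8 are the right-quadrant teeth from central
# incisor to 3rd molar (FDI 11..18), classes 9..16 the left quadrant
# (FDI 21..28).  Lower-arch codes 31..38 / 41..48 map onto the same 16
# positional classes so one label space covers both arches.
_CLASS_TO_FDI = {0: 0, **{c: 10 + c for c in range(1, 9)},
                 **{c: 20 + (c - 8) for c in range(9, 17)}}
_FDI_TO_CLASS = {0: 0}
for _q, _base in ((1, 0), (2, 8), (3, 8), (4, 0)):
    for _pos in range(1, 9):
        _FDI_TO_CLASS[_q * 10 + _pos] = _base + _pos


def class_to_fdi(label: int) -> int:
    """Map internal class 0..16 to its (upper-arch) FDI code."""
    try:
        return _CLASS_TO_FDI[int(label)]
    except KeyError:
        raise LabelError(f"class index {label} outside 0..16") from None


def fdi_to_class(code: int) -> int:
    """Map an FDI tooth code (or 0 for gum) to the internal class 0..16."""
    try:
        return _FDI_TO_CLASS[int(code)]
    except KeyError:
        raise LabelError(f"unknown FDI code {code}") from None


@dataclass
class TriMesh:
    """Triangular surface mesh with optional per-face class labels."""

    vertices: np.ndarray                    # (V, 3) float64, mm
    faces: np.ndarray                       # (F, 3) int64
    face_labels: np.ndarray | None = None   # (F,) int64 in 0..16

    def __post_init__(self):
        self.vertices = np.asarray(self.vertices, dtype=np.float64)
        self.faces = np.asarray(self.faces, dtype=np.int64)
        if self.face_labels is not None:
            self.face_labels = np.asarray(self.face_labels, dtype=np.int64)
        self.validate()

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    @property
    def face_centers(self) -> np.ndarray:
        return self.vertices[self.faces].mean(axis=1)

    def validate(self) -> None:
        v, f = self.vertices, self.faces
        if v.ndim != 2 or v.shape[1] != 3 or f.ndim != 2 or f.shape[1] != 3:
            raise GeometryError("vertices must be (V,3), faces (F,3)")
        if f.size and (f.min() < 0 or f.max() >= len(v)):
            raise GeometryError("face index out of range")
        if ((f[:, 0] == f[:, 1]) | (f[:, 1] == f[:, 2])
                | (f[:, 0] == f[:, 2])).any():
            raise GeometryError("face with repeated vertex index")
        areas = 0.5 * np.linalg.norm(
            np.cross(v[f[:, 1]] - v[f[:, 0]], v[f[:, 2]] - v[f[:, 0]]),
            axis=1)
        bad = np.nonzero(areas < _AREA_TOL)[0]
        if bad.size:
            raise GeometryError(f"zero-area face at index {bad[0]}")
        if self.face_labels is not None:
            if len(self.face_labels) != len(f):
                raise LabelError("label count does not match face count")
            if self.face_labels.size and (
                    self.face_labels.min() < 0
                    or self.face_labels.max() >= N_CLASSES):
                raise LabelError("face label outside 0..16")


@dataclass
class FaceFeatureMatrix:
    """M×24 per-face descriptor matrix.

    Columns 0–8: vertex coordinates, 9–11: face center, 12–20: vertex
    normals, 21–23: face normal.
    """

    values: np.ndarray
    normalized: bool = False
    per_dim_mean: np.ndarray | None = None
    per_dim_std: np.ndarray | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2 or self.values.shape[1] != FEATURE_DIM:
            raise GeometryError(
                f"feature matrix must be M×{FEATURE_DIM}, got "
                f"{self.values.shape}")

    @property
    def n_faces(self) -> int:
        return self.values.shape[0]

    @property
    def centers(self) -> np.ndarray:
        return self.values[:, 9:12]

    def inverse_transform(self) -> "FaceFeatureMatrix":
        """Undo z-scoring using the recorded per-column moments."""
        if not self.normalized:
            raise StateError("matrix is not normalized")
        raw = self.values * self.per_dim_std + self.per_dim_mean
        return FaceFeatureMatrix(raw, normalized=False)


# ---------------------------------------------------------------------------
# reading / writing


def _face_labels_from_vertex(faces: np.ndarray,
                             vlabels: np.ndarray) -> np.ndarray:
    """Majority vote over the face's three vertex labels; ties take the
    lowest class index."""
    tri = vlabels[faces]                              # (F, 3)
    out = np.empty(len(faces), dtype=np.int64)
    a, b, c = tri[:, 0], tri[:, 1], tri[:, 2]
    # a label occurring at least twice wins; otherwise all distinct -> min
    out[:] = np.minimum(np.minimum(a, b), c)
    pair = np.where(a == b, a, np.where(a == c, a, np.where(b == c, b, -1)))
    maj = pair >= 0
    out[maj] = pair[maj]
    return out


def _read_labels(label_path, n_vertices: int, n_faces: int,
                 faces: np.ndarray) -> np.ndarray:
    with open(label_path) as fh:
        payload = json.load(fh)
    if not isinstance(payload, dict) or "labels" not in payload:
        raise LabelError("label sidecar must be a JSON object with 'labels'")
    codes = np.asarray(payload["labels"], dtype=np.int64)
    granularity = payload.get("granularity", "vertex")
    classes = np.array([fdi_to_class(c) for c in codes], dtype=np.int64)
    if granularity == "face":
        if len(classes) != n_faces:
            raise LabelError(
                f"face-granularity sidecar has {len(classes)} labels for "
                f"{n_faces} faces")
        return classes
    if granularity == "vertex":
        if len(classes) != n_vertices:
            raise LabelError(
                f"vertex-granularity sidecar has {len(classes)} labels for "
                f"{n_vertices} vertices")
        return _face_labels_from_vertex(faces, classes)
    raise LabelError(f"unknown granularity {granularity!r}")


def read_mesh(path, label_path=None) -> TriMesh:
    """Read an OBJ/PLY/STL mesh, optionally with a JSON label sidecar.

    The sidecar holds FDI codes (0 = gum) at vertex or face granularity;
    vertex labels are converted to face labels by majority vote.
    """
    path = Path(path)
    if not path.exists() or path.stat().st_size == 0:
        raise FormatError(f"unreadable or empty mesh file: {path}")
    try:
        loaded = trimesh.load(str(path), process=False, force="mesh")
    except Exception as exc:
        raise FormatError(f"cannot parse {path}: {exc}") from exc
    if not isinstance(loaded, trimesh.Trimesh) or len(loaded.faces) == 0:
        raise FormatError(f"no triangular faces in {path}")
    vertices = np.asarray(loaded.vertices, dtype=np.float64)
    faces = np.asarray(loaded.faces, dtype=np.int64)
    labels = None
    if label_path is not None:
        labels = _read_labels(label_path, len(vertices), len(faces), faces)
    return TriMesh(vertices, faces, labels)


def write_mesh(mesh: TriMesh, path, label_path=None) -> None:
    """Write a mesh (format from extension) and optionally its labels as a
    face-granularity FDI sidecar."""
    path = Path(path)
    tm = trimesh.Trimesh(vertices=mesh.vertices, faces=mesh.faces,
                         process=False)
    kwargs = {}
    if path.suffix.lower() == ".ply":
        kwargs["encoding"] = "ascii"
    tm.export(str(path), **kwargs)
    if label_path is not None:
        if mesh.face_labels is None:
            raise LabelError("mesh carries no labels to write")
        codes = [class_to_fdi(c) for c in mesh.face_labels]
        with open(label_path, "w") as fh:
            json.dump({"labels": codes, "granularity": "face"}, fh)


# fixed 17-color table (RGB 0-255); gum is gray
_PALETTE = np.array(
    [[160, 160, 160],
     [228, 26, 28], [55, 126, 184], [77, 175, 74], [152, 78, 163],
     [255, 127, 0], [255, 255, 51], [166, 86, 40], [247, 129, 191],
     [102, 194, 165], [252, 141, 98], [141, 160, 203], [231, 138, 195],
     [166, 216, 84], [255, 217, 47], [229, 196, 148], [179, 179, 179]],
    dtype=np.uint8)


def write_colored_ply(mesh: TriMesh, labels: np.ndarray, path) -> None:
    """Write an ascii PLY with per-face colors from the fixed 17-color
    table, for visual inspection of predictions."""
    labels = np.asarray(labels, dtype=np.int64)
    if len(labels) != mesh.n_faces:
        raise LabelError("label count does not match face count")
    tm = trimesh.Trimesh(vertices=mesh.vertices, faces=mesh.faces,
                         process=False)
    colors = np.concatenate([_PALETTE[labels % N_CLASSES],
                             np.full((len(labels), 1), 255, np.uint8)],
                            axis=1)
    tm.visual.face_colors = colors
    tm.export(str(path), encoding="ascii")


# ---------------------------------------------------------------------------
# simplification


def nearest_centroid_labels(src_centers: np.ndarray, src_labels: np.ndarray,
                            dst_centers: np.ndarray,
                            chunk: int = 512) -> np.ndarray:
    """Label each destination face with the label of the source face whose
    centroid is nearest (exact; ties take the lowest source index)."""
    out = np.empty(len(dst_centers), dtype=np.int64)
    for lo in range(0, len(dst_centers), chunk):
        hi = min(lo + chunk, len(dst_centers))
        d = np.linalg.norm(
            dst_centers[lo:hi, None, :] - src_centers[None, :, :], axis=2)
        out[lo:hi] = src_labels[np.argmin(d, axis=1)]
    return out


def simplify_mesh(mesh: TriMesh, target_faces: int) -> TriMesh:
    """Quadric edge-collapse decimation to exactly ``target_faces`` faces.

    Meshes at or below the target are returned unchanged.  Labels are
    transferred by nearest input-face centroid.
    """
    if target_faces < 4:
        raise ParameterError("target_faces must be >= 4")
    if mesh.n_faces <= target_faces:
        return mesh
    v, f = quadric_collapse(mesh.vertices, mesh.faces, target_faces)
    labels = None
    if mesh.face_labels is not None:
        new_centers = v[f].mean(axis=1)
        labels = nearest_centroid_labels(mesh.face_centers, mesh.face_labels,
                                         new_centers)
    return TriMesh(v, f, labels)


# ---------------------------------------------------------------------------
# features


def compute_face_features(mesh: TriMesh) -> FaceFeatureMatrix:
    """Assemble the M×24 descriptor: vertex coords, face center, vertex
    normals (area-weighted average of incident face normals), face normal.
    """
    v, f = mesh.vertices, mesh.faces
    tri = v[f]                                    # (F, 3, 3)
    cross = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
    double_area = np.linalg.norm(cross, axis=1)
    bad = np.nonzero(double_area < _AREA_TOL)[0]
    if bad.size:
        raise GeometryError(f"zero-area face at index {bad[0]}")
    face_normals = cross / double_area[:, None]
    centers = tri.mean(axis=1)

    # area-weighted vertex normals; cross already carries 2x face area
    vnorm = np.zeros_like(v)
    for k in range(3):
        np.add.at(vnorm, f[:, k], cross)
    norms = np.linalg.norm(vnorm, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    vnorm = vnorm / norms

    feats = np.concatenate([
        tri.reshape(len(f), 9),
        centers,
        vnorm[f].reshape(len(f), 9),
        face_normals,
    ], axis=1)
    return FaceFeatureMatrix(feats, normalized=False)


def zscore_normalize(features: FaceFeatureMatrix,
                     eps: float = 1e-8) -> FaceFeatureMatrix:
    """Z-score each of the 24 columns over the faces of this mesh
    (population std).  Constant columns become all-zero."""
    if features.normalized:
        raise StateError("features already normalized")
    x = features.values
    mean = x.mean(axis=0)
    std = x.std(axis=0)
    scale = np.where(std < eps, 1.0, std)
    z = (x - mean) / scale
    z[:, std < eps] = 0.0
    return FaceFeatureMatrix(z, normalized=True, per_dim_mean=mean,
                             per_dim_std=std)
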