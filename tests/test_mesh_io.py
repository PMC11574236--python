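"""Mesh reading/writing, simplification, and feature extraction."""

import json

import numpy as np
import pytest

from toothseg import TriMesh, read_mesh, simplify_mesh, write_mesh
from toothseg.errors import (FormatError, GeometryError, LabelError,
                             ParameterError, StateError)
from toothseg.mesh_io import (FaceFeatureMatrix, class_to_fdi,
                              compute_face_features, fdi_to_class,
                              nearest_centroid_labels, write_colored_ply,
                              zscore_normalize)


def _square(z=0.0):
    """Two triangles covering the unit square."""
    v = np.array([[0, 0, z], [1, 0, z], [0, 1, z], [1, 1, z]], float)
    f = np.array([[0, 1, 2], [1, 3, 2]])
    return v, f


class TestReadWrite:
    def test_single_triangle_obj(self, tmp_path):
        path = tmp_path / "tri.obj"
        path.write_text("v 0 0 0\nv 1 0 0\nv 0 1 0\nf 1 2 3\n")
        mesh = read_mesh(path)
        assert len(mesh.vertices) == 3
        assert len(mesh.faces) == 1
        assert mesh.face_labels is None

    @pytest.mark.parametrize("ext", ["ply", "obj", "stl"])
    def test_roundtrip_formats(self, arch_small, tmp_path, ext):
        path = tmp_path / f"arch.{ext}"
        labels = tmp_path / "arch.labels.json"
        write_mesh(arch_small, path, label_path=labels)
        back = read_mesh(path, label_path=labels if ext != "stl" else None)
        if ext == "stl":  # STL stores triangle soup; only geometry survives
            assert len(back.faces) == arch_small.n_faces
            return
        np.testing.assert_allclose(back.vertices, arch_small.vertices,
                                   atol=1e-6)
        np.testing.assert_array_equal(back.faces, arch_small.faces)
        np.testing.assert_array_equal(back.face_labels,
                                      arch_small.face_labels)

    def test_vertex_majority_vote(self, tmp_path):
        path = tmp_path / "tri.obj"
        path.write_text("v 0 0 0\nv 1 0 0\nv 0 1 0\nf 1 2 3\n")
        sidecar = tmp_path / "tri.json"
        sidecar.write_text(json.dumps(
            {"labels": [0, 0, 11], "granularity": "vertex"}))
        mesh = read_mesh(path, label_path=sidecar)
        assert mesh.face_labels.tolist() == [0]  # gum wins 2:1

    def test_all_distinct_vertex_labels_take_lowest_class(self, tmp_path):
        path = tmp_path / "tri.obj"
        path.write_text("v 0 0 0\nv 1 0 0\nv 0 1 0\nf 1 2 3\n")
        sidecar = tmp_path / "tri.json"
        sidecar.write_text(json.dumps(
            {"labels": [12, 11, 13], "granularity": "vertex"}))
        mesh = read_mesh(path, label_path=sidecar)
        assert mesh.face_labels.tolist() == [fdi_to_class(11)]

    def test_errors(self, tmp_path):
        with pytest.raises(FormatError):
            read_mesh(tmp_path / "missing.obj")
        empty = tmp_path / "empty.ply"
        empty.touch()
        with pytest.raises(FormatError):
            read_mesh(empty)
        tri = tmp_path / "tri.obj"
        tri.write_text("v 0 0 0\nv 1 0 0\nv 0 1 0\nf 1 2 3\n")
        bad_len = tmp_path / "bad.json"
        bad_len.write_text(json.dumps({"labels": [0, 0], "granularity":
                                       "vertex"}))
        with pytest.raises(LabelError):
            read_mesh(tri, label_path=bad_len)
        bad_code = tmp_path / "code.json"
        bad_code.write_text(json.dumps({"labels": [0, 0, 99],
                                        "granularity": "vertex"}))
        with pytest.raises(LabelError, match="99"):
            read_mesh(tri, label_path=bad_code)

    def test_colored_ply(self, arch_small, tmp_path):
        out = tmp_path / "colored.ply"
        write_colored_ply(arch_small, arch_small.face_labels, out)
        assert out.stat().st_size > 0


class TestFdiMapping:
    def test_bidirectional(self):
        for c in range(17):
            assert fdi_to_class(class_to_fdi(c)) == c

    def test_lower_arch_codes_accepted(self):
        assert fdi_to_class(31) == fdi_to_class(21)
        assert fdi_to_class(48) == fdi_to_class(18)

    def test_unknown_code(self):
        with pytest.raises(LabelError, match="19"):
            fdi_to_class(19)


class TestTriMeshValidation:
    def test_repeated_vertex_rejected(self):
        v, _ = _square()
        with pytest.raises(GeometryError):
            TriMesh(v, np.array([[0, 0, 1]]))

    def test_zero_area_rejected(self):
        v = np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0]], float)
        with pytest.raises(GeometryError):
            TriMesh(v, np.array([[0, 1, 2]]))

    def test_out_of_range_index(self):
        v, _ = _square()
        with pytest.raises(GeometryError):
            TriMesh(v, np.array([[0, 1, 7]]))


class TestSimplify:
    def test_exact_target(self):
        import trimesh
        ico = trimesh.creation.icosphere(subdivisions=3)
        mesh = TriMesh(np.asarray(ico.vertices), np.asarray(ico.faces))
        out = simplify_mesh(mesh, 320)
        assert out.n_faces == 320

    def test_noop_below_target(self, arch_small):
        out = simplify_mesh(arch_small, 16000)
        assert out is arch_small

    def test_target_too_small(self, arch_small):
        with pytest.raises(ParameterError):
            simplify_mesh(arch_small, 3)

    def test_label_transfer_matches_bruteforce(self, arch_small):
        out = simplify_mesh(arch_small, 500)
        assert out.n_faces == 500
        # O(n^2) oracle: nearest input centroid, lowest index on ties
        src = arch_small.face_centers
        dst = out.face_centers
        d = ((dst[:, None, :] - src[None, :, :]) ** 2).sum(-1)
        expect = arch_small.face_labels[np.argmin(d, axis=1)]
        np.testing.assert_array_equal(out.face_labels, expect)

    def test_nearest_centroid_tie_takes_lowest_index(self):
        src = np.array([[0, 0, 0.], [2, 0, 0]])
        dst = np.array([[1, 0, 0.]])
        labels = np.array([5, 9])
        assert nearest_centroid_labels(src, labels, dst).tolist() == [5]


class TestFaceFeatures:
    def test_hand_geometry(self):
        v = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0]], float)
        mesh = TriMesh(v, np.array([[0, 1, 2]]))
        feats = compute_face_features(mesh).values[0]
        np.testing.assert_allclose(feats[9:12], [1 / 3, 1 / 3, 0])
        np.testing.assert_allclose(feats[21:24], [0, 0, 1])
        # single face: all vertex normals equal the face normal
        np.testing.assert_allclose(feats[12:21].reshape(3, 3),
                                   [[0, 0, 1]] * 3)

    def test_translation_moves_coords_not_normals(self, arch_small):
        base = compute_face_features(arch_small).values
        shifted = TriMesh(arch_small.vertices + 5.0, arch_small.faces,
                          arch_small.face_labels)
        moved = compute_face_features(shifted).values
        np.testing.assert_allclose(moved[:, :12], base[:, :12] + 5.0,
                                   atol=1e-9)
        np.testing.assert_allclose(moved[:, 12:], base[:, 12:], atol=1e-9)

    def test_winding_flip_negates_normals(self):
        v, f = _square()
        base = compute_face_features(TriMesh(v, f)).values
        flipped = compute_face_features(TriMesh(v, f[:, ::-1])).values
        np.testing.assert_allclose(flipped[:, 21:24], -base[:, 21:24])

    def test_vertex_normals_unit_and_consistent(self, arch_small):
        feats = compute_face_features(arch_small).values
        vnorms = feats[:, 12:21].reshape(-1, 3, 3)
        lengths = np.linalg.norm(vnorms, axis=2)
        np.testing.assert_allclose(lengths, 1.0, atol=1e-5)
        # oracle: area-weighted incident-face-normal average per vertex
        v, f = arch_small.vertices, arch_small.faces
        cross = np.cross(v[f[:, 1]] - v[f[:, 0]], v[f[:, 2]] - v[f[:, 0]])
        acc = np.zeros_like(v)
        for k in range(3):
            np.add.at(acc, f[:, k], cross)
        acc /= np.linalg.norm(acc, axis=1, keepdims=True)
        np.testing.assert_allclose(vnorms, acc[f], atol=1e-9)
        # every vertex normal agrees in direction with its incident faces
        fnorm = feats[:, 21:24]
        dots = (vnorms * fnorm[:, None, :]).sum(-1)
        assert (dots > 0).mean() > 0.99


class TestZscore:
    def test_constant_column_zeroed(self):
        x = np.ones((5, 24))
        x[:, 3] = np.arange(5)
        out = zscore_normalize(FaceFeatureMatrix(x))
        assert np.all(out.values[:, 0] == 0)
        assert abs(out.values[:, 3].std() - 1) < 1e-12

    def test_two_point_column(self):
        x = np.zeros((2, 24))
        x[:, 0] = [0.0, 2.0]
        out = zscore_normalize(FaceFeatureMatrix(x))
        np.testing.assert_allclose(out.values[:, 0], [-1.0, 1.0])

    def test_moments_after_transform(self, arch_small):
        feats = compute_face_features(arch_small)
        out = zscore_normalize(feats)
        nonconst = feats.values.std(axis=0) >= 1e-8
        means = out.values[:, nonconst].mean(axis=0)
        stds = out.values[:, nonconst].std(axis=0)
        assert np.abs(means).max() < 1e-6
        assert np.abs(stds - 1).max() < 1e-6

    def test_double_normalization_rejected(self):
        out = zscore_normalize(FaceFeatureMatrix(np.random.rand(4, 24)))
        with pytest.raises(StateError):
            zscore_normalize(out)

    def test_inverse_recovers_raw(self, arch_small):
        feats = compute_face_features(arch_small)
        out = zscore_normalize(feats)
        back = out.inverse_transform()
        np.testing.assert_allclose(back.values, feats.values, atol=1e-6)
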