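"""Shared fixtures: synthetic arches and small network configs.

Everything is generated programmatically; session scope keeps the more
expensive meshes to one build per run.
"""

from __future__ import annotations

import numpy as np
import pytest

from toothseg import ArchSpec, generate_arch
from toothseg.mesh_io import compute_face_features, zscore_normalize
from toothseg.network import NetworkConfig


@pytest.fixture(scope="session")
def arch_small():
    """Labeled arch with 800 faces, 6 teeth — cheap unit-test mesh."""
    return generate_arch(ArchSpec(n_teeth=6, target_faces=800, seed=11))


@pytest.fixture(scope="session")
def arch_medium():
    """Labeled arch with 2000 faces and 14 teeth."""
    return generate_arch(ArchSpec(n_teeth=14, target_faces=2000, seed=7))


@pytest.fixture(scope="session")
def arch_features(arch_medium):
    return zscore_normalize(compute_face_features(arch_medium))


@pytest.fixture(scope="session")
def arch_small_features(arch_small):
    return zscore_normalize(compute_face_features(arch_small))


@pytest.fixture()
def tiny_config():
    """Smallest sensible network for fast forward passes."""
    return NetworkConfig(
        n_local_layers=2, local_k=8, local_widths=[16, 16],
        dilated_kb_list=[40, 80], dilated_f=8, dilated_width=24,
        head_widths=[32, 16], n_classes=3, seed=3)


def oracle_knn(points: np.ndarray, k: int) -> np.ndarray:
    """O(M^2) full-sort nearest neighbors, ties by ascending index."""
    m = len(points)
    d = ((points[:, None, :] - points[None, :, :]) ** 2).sum(-1)
    np.fill_diagonal(d, np.inf)
    order = np.lexsort((np.broadcast_to(np.arange(m), (m, m)), d), axis=1)
    return order[:, :k]


def oracle_fps(points: np.ndarray, candidates, f: int,
               query: int) -> list[int]:
    """Brute-force greedy farthest-point sampling with lowest-index
    tie-breaks, written as explicit loops."""
    cand = list(candidates)
    dist = {c: float(((points[c] - points[query]) ** 2).sum())
            for c in cand}
    first = min(cand, key=lambda c: (dist[c], c))
    picked = [first]
    remaining = [c for c in cand if c != first]
    while len(picked) < f:
        best, best_d = None, -1.0
        for c in remaining:
            d = min(float(((points[c] - points[p]) ** 2).sum())
                    for p in picked)
            if d > best_d or (d == best_d and c < best):
                best, best_d = c, d
        picked.append(best)
        remaining.remove(best)
    return picked
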