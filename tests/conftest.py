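"""Shared fixtures: tiny frames, topologies and mesh builders."""

import numpy as np
import pytest

from micellekit.structures import BeadSpec, Box, Frame, MoleculeTopology


@pytest.fixture
def minimal_topology():
    """Two-bead surfactant: one head, one tail (tail sigma 3.40 A)."""
    return MoleculeTopology(
        name="SURF",
        beads=(BeadSpec("H", "R", "head"), BeadSpec("T", "T", "tail")),
    )


def frame_from_tail_points(points, box, topology, time=0.0):
    """Frame of 2-bead surfactants whose tail beads sit at ``points``.

    The head bead is stacked 0.1 A above its tail so clustering behaviour is
    controlled purely by the tail positions.
    """
    points = np.asarray(points, dtype=float)
    n = points.shape[0]
    coords = np.empty((2 * n, 3))
    coords[0::2] = points + [0.0, 0.0, 0.1]   # heads
    coords[1::2] = points                      # tails
    return Frame(
        time=time,
        box=box,
        coordinates=coords,
        mol_index=np.repeat(np.arange(n), 2),
        species=np.full(n, topology.name, dtype=object),
        topologies={topology.name: topology},
    )


@pytest.fixture
def make_tail_frame(minimal_topology):
    def _make(points, box=Box(100.0, 100.0, 100.0), time=0.0):
        return frame_from_tail_points(points, box, minimal_topology, time)

    return _make


def brute_force_partition(points, box, r_cut):
    """Union-find over all minimum-image tail pair distances (O(n^2) oracle)."""
    points = np.asarray(points, dtype=float)
    n = points.shape[0]
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    L = box.lengths
    for i in range(n):
        for j in range(i + 1, n):
            d = points[j] - points[i]
            d = d - L * np.floor(d / L + 0.5)
            if np.sqrt((d * d).sum()) <= r_cut:
                parent[find(i)] = find(j)
    groups = {}
    for i in range(n):
        groups.setdefault(find(i), set()).add(i)
    return {frozenset(g) for g in groups.values()}


def icosphere(radius=10.0, depth=4, center=(50.0, 50.0, 50.0)):
    """Subdivided icosahedron projected to a sphere, outward-oriented faces."""
    t = (1.0 + np.sqrt(5.0)) / 2.0
    verts = np.array([
        [-1, t, 0], [1, t, 0], [-1, -t, 0], [1, -t, 0],
        [0, -1, t], [0, 1, t], [0, -1, -t], [0, 1, -t],
        [t, 0, -1], [t, 0, 1], [-t, 0, -1], [-t, 0, 1],
    ], dtype=float)
    verts /= np.linalg.norm(verts, axis=1, keepdims=True)
    faces = [
        (0, 11, 5), (0, 5, 1), (0, 1, 7), (0, 7, 10), (0, 10, 11),
        (1, 5, 9), (5, 11, 4), (11, 10, 2), (10, 7, 6), (7, 1, 8),
        (3, 9, 4), (3, 4, 2), (3, 2, 6), (3, 6, 8), (3, 8, 9),
        (4, 9, 5), (2, 4, 11), (6, 2, 10), (8, 6, 7), (9, 8, 1),
    ]
    verts = [tuple(v) for v in verts]
    for _ in range(depth):
        cache = {}
        new_faces = []

        def midpoint(i, j):
            key = (min(i, j), max(i, j))
            if key not in cache:
                m = (np.array(verts[i]) + np.array(verts[j])) / 2.0
                m /= np.linalg.norm(m)
                verts.append(tuple(m))
                cache[key] = len(verts) - 1
            return cache[key]

        for a, b, c in faces:
            ab, bc, ca = midpoint(a, b), midpoint(b, c), midpoint(c, a)
            new_faces += [(a, ab, ca), (b, bc, ab), (c, ca, bc), (ab, bc, ca)]
        faces = new_faces
    v = np.array(verts) * radius + np.asarray(center)
    return v, np.array(faces, dtype=int)
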