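"""Triangulated surface meshes with per-vertex scalar fields.

Coordinates are millimetres in RAS orientation (x lateral+, y anterior+,
z superior+). Triangles are 0-based vertex index triples, counter-clockwise
when viewed from the outward side.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["SurfaceMesh", "mesh_edges", "vertex_onering_areas", "triangle_areas"]


@dataclass
class SurfaceMesh:
    """A triangle mesh plus named per-vertex scalar fields.

    Parameters
    ----------
    vertices : (n, 3) float array
        Vertex coordinates in RAS millimetres.
    triangles : (m, 3) int array
        Vertex index triples.
    scalars : dict of str -> (n,) array
        Named per-vertex fields (labels, internal coordinates, ...).
    """

    vertices: np.ndarray
    triangles: np.ndarray
    scalars: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.triangles = np.asarray(self.triangles, dtype=np.int64)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise ValueError("vertices must be an (n, 3) array")
        if self.triangles.size and (
            self.triangles.ndim != 2 or self.triangles.shape[1] != 3
        ):
            raise ValueError("triangles must be an (m, 3) array")
        self.triangles = self.triangles.reshape(-1, 3)
        if self.triangles.size:
            if self.triangles.min() < 0 or self.triangles.max() >= self.n_vertices:
                raise ValueError("triangle indices out of range")
        for name, values in self.scalars.items():
            values = np.asarray(values)
            if values.shape[0] != self.n_vertices:
                raise ValueError(
                    f"scalar field {name!r} has {values.shape[0]} values for "
                    f"{self.n_vertices} vertices"
                )
            self.scalars[name] = values

    @property
    def n_vertices(self) -> int:
        return self.vertices.shape[0]

    @property
    def n_triangles(self) -> int:
        return self.triangles.shape[0]

    def copy(self) -> "SurfaceMesh":
        return SurfaceMesh(
            self.vertices.copy(),
            self.triangles.copy(),
            {k: v.copy() for k, v in self.scalars.items()},
        )

    def with_vertices(self, vertices: np.ndarray) -> "SurfaceMesh":
        """Same topology and scalars, different coordinates."""
        return SurfaceMesh(
            np.asarray(vertices, dtype=float),
            self.triangles.copy(),
            {k: v.copy() for k, v in self.scalars.items()},
        )

    def has_duplicate_triangles(self) -> bool:
        tri = np.sort(self.triangles, axis=1)
        return len(np.unique(tri, axis=0)) != len(tri)

    def degenerate_triangles(self, atol: float = 1e-12) -> np.ndarray:
        """Indices of zero-area triangles."""
        return np.flatnonzero(triangle_areas(self.vertices, self.triangles) <= atol)

    def is_edge_manifold(self) -> bool:
        """True when every edge is shared by at most two triangles."""
        _, counts = mesh_edges(self.triangles, return_counts=True)
        return bool(counts.size == 0 or counts.max() <= 2)


def triangle_areas(vertices: np.ndarray, triangles: np.ndarray) -> np.ndarray:
    v = np.asarray(vertices, dtype=float)
    t = np.asarray(triangles, dtype=np.int64).reshape(-1, 3)
    if t.size == 0:
        return np.zeros(0)
    a = v[t[:, 1]] - v[t[:, 0]]
    b = v[t[:, 2]] - v[t[:, 0]]
    return 0.5 * np.linalg.norm(np.cross(a, b), axis=1)


def mesh_edges(triangles: np.ndarray, return_counts: bool = False):
    """Unique undirected edges of a triangle list.

    Returns the (e, 2) sorted edge array, optionally with the number of
    incident triangles per edge.
    """
    t = np.asarray(triangles, dtype=np.int64).reshape(-1, 3)
    raw = np.concatenate([t[:, [0, 1]], t[:, [1, 2]], t[:, [2, 0]]], axis=0)
    raw = np.sort(raw, axis=1)
    edges, counts = np.unique(raw, axis=0, return_counts=True)
    if return_counts:
        return edges, counts
    return edges


def vertex_onering_areas(mesh: SurfaceMesh) -> np.ndarray:
    """Per-vertex one-ring surface area (sum of incident triangle areas)."""
    areas = triangle_areas(mesh.vertices, mesh.triangles)
    out = np.zeros(mesh.n_vertices)
    for k in range(3):
        np.add.at(out, mesh.triangles[:, k], areas)
    return out
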