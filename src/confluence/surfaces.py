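"""Continuous confluence model: stitching and geometric axes.

Builds one surface model out of an isocortical mesh pair and an
allocortical (hippocampal) mesh pair by bridging them at the medial-most
subicular vertices, then maps every vertex by its signed geodesic distance
to that seam (negative on the isocortical side) and by its y-coordinate
(anterior-posterior position).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components, dijkstra
from scipy.spatial import cKDTree

from .labels import MESIOTEMPORAL_REGIONS, REGION_CODES
from .mesh import SurfaceMesh, mesh_edges

__all__ = [
    "ConfluenceModel",
    "find_bridgeheads",
    "match_bridgeheads_to_isocortex",
    "stitch_confluence",
    "compute_axis",
    "restrict_and_label",
    "geodesic_distances",
]


@dataclass
class ConfluenceModel:
    """Stitched inner/outer surface pair with per-vertex axes.

    ``inner`` and ``outer`` share one triangle list with matched vertex
    identity. ``origin`` is +1 for vertices of allocortical origin, -1 for
    isocortical origin, 0 at bridgeheads.
    """

    inner: SurfaceMesh
    outer: SurfaceMesh
    bridgeheads: np.ndarray
    origin: np.ndarray
    axis_mm: np.ndarray | None = None
    subregion: np.ndarray | None = None
    extra: dict = field(default_factory=dict)

    @property
    def ap_mm(self) -> np.ndarray:
        return self.inner.vertices[:, 1]

    @property
    def n_vertices(self) -> int:
        return self.inner.n_vertices


def find_bridgeheads(allo_mesh: SurfaceMesh, pd_field: str = "pd",
                     ap_field: str = "ap", decimals: int = 9) -> np.ndarray:
    """Vertices attaining the per-anterior-posterior-row minimum of the
    proximal-distal coordinate (the medial aspect of the subiculum).

    Rows are groups of vertices sharing an anterior-posterior coordinate
    (rounded to ``decimals``); the result is ordered by that coordinate.
    Ties within a row go to the lowest vertex index.
    """
    if pd_field not in allo_mesh.scalars:
        raise ValueError(
            f"allocortical mesh is missing the proximal-distal field {pd_field!r}"
        )
    if ap_field not in allo_mesh.scalars:
        raise ValueError(f"allocortical mesh is missing the field {ap_field!r}")
    pd = np.asarray(allo_mesh.scalars[pd_field], dtype=float)
    ap = np.asarray(allo_mesh.scalars[ap_field], dtype=float)
    if np.ptp(pd) == 0:
        raise ValueError(
            "proximal-distal coordinate is constant; every vertex is a "
            "bridgehead candidate - supply a non-degenerate coordinate"
        )
    keys = np.round(ap, decimals)
    out = []
    for value in np.unique(keys):
        members = np.flatnonzero(keys == value)
        row_pd = pd[members]
        best = members[row_pd == row_pd.min()]
        out.append(int(best.min()))
    order = np.argsort(ap[out], kind="stable")
    return np.asarray(out, dtype=np.int64)[order]


def match_bridgeheads_to_isocortex(
    bridgeheads: np.ndarray,
    allo_mesh: SurfaceMesh,
    iso_mesh: SurfaceMesh,
    region_field: str = "region",
    allowed_regions=MESIOTEMPORAL_REGIONS,
) -> np.ndarray:
    """Match each bridgehead to the closest inferior isocortical vertex.

    Candidates are isocortical vertices carrying one of ``allowed_regions``
    labels whose z-coordinate is strictly below the bridgehead's. Ties in
    distance go to the lowest vertex index.
    """
    bridgeheads = np.asarray(bridgeheads, dtype=np.int64)
    if region_field in iso_mesh.scalars:
        codes = [REGION_CODES[r] for r in allowed_regions]
        candidate_mask = np.isin(iso_mesh.scalars[region_field], codes)
    else:
        candidate_mask = np.ones(iso_mesh.n_vertices, dtype=bool)
    candidates = np.flatnonzero(candidate_mask)
    if candidates.size == 0:
        raise ValueError("no isocortical candidate vertices in allowed regions")
    cand_xyz = iso_mesh.vertices[candidates]
    matches = np.empty(bridgeheads.size, dtype=np.int64)
    for i, b in enumerate(bridgeheads):
        bx = allo_mesh.vertices[b]
        inferior = cand_xyz[:, 2] < bx[2]
        if not np.any(inferior):
            raise ValueError(
                f"bridgehead {int(b)} has no inferior isocortical candidate"
            )
        sub = candidates[inferior]
        d2 = np.sum((iso_mesh.vertices[sub] - bx) ** 2, axis=1)
        best = d2 == d2.min()
        matches[i] = int(sub[best].min())
    return matches


def _bridge_triangles(bridgeheads, matches) -> np.ndarray:
    """Deduplicated triangles {b_i, match_i, b_{i-1}} and {b_i, match_i, b_{i+1}}."""
    tris = set()
    nb = len(bridgeheads)
    for i in range(nb):
        for j in (i - 1, i + 1):
            if 0 <= j < nb:
                tri = (int(bridgeheads[i]), int(matches[i]), int(bridgeheads[j]))
                if len(set(tri)) == 3:
                    tris.add(tuple(sorted(tri)))
    out = sorted(tris)
    return np.asarray(out, dtype=np.int64).reshape(-1, 3)


def stitch_confluence(
    iso_pair: tuple[SurfaceMesh, SurfaceMesh],
    allo_pair: tuple[SurfaceMesh, SurfaceMesh],
    bridgeheads: np.ndarray,
    matches: np.ndarray,
    region_field: str = "region",
    subfield_field: str = "subfield",
) -> ConfluenceModel:
    """Stitch iso and allo mesh pairs into one confluent model.

    The output contains the allocortical inner vertices and the surviving
    mesiotemporal pial vertices with their original triangles, plus bridge
    triangles joining each bridgehead with its matched isocortical vertex
    and the neighbouring bridgehead on either side. Isocortical vertices
    whose (Euclidean-)nearest bridgehead is inferior to them are removed.
    Vertex coordinates are never modified. The same triangle list links the
    white/outer pair.
    """
    iso_inner, iso_outer = iso_pair
    allo_inner, allo_outer = allo_pair
    bridgeheads = np.asarray(bridgeheads, dtype=np.int64)
    matches = np.asarray(matches, dtype=np.int64)
    if bridgeheads.size == 0 or matches.size != bridgeheads.size:
        raise ValueError("need equally many bridgeheads and matches, at least one")
    if bridgeheads.size == 1:
        warnings.warn("single bridgehead: no bridge triangles can be formed")

    # remove isocortical vertices whose nearest bridgehead is inferior
    bh_xyz = allo_inner.vertices[bridgeheads]
    tree = cKDTree(bh_xyz)
    _, nearest = tree.query(iso_inner.vertices)
    keep_iso = bh_xyz[nearest, 2] >= iso_inner.vertices[:, 2]
    if not np.any(keep_iso):
        raise ValueError("the bridgehead-inferior rule removed every isocortical vertex")
    dropped_matches = ~keep_iso[matches]
    if np.any(dropped_matches):
        raise ValueError(
            "matched isocortical vertices were removed by the "
            "bridgehead-inferior rule; matching and removal are inconsistent"
        )

    n_allo = allo_inner.n_vertices
    iso_new = np.full(iso_inner.n_vertices, -1, dtype=np.int64)
    iso_new[keep_iso] = n_allo + np.arange(int(keep_iso.sum()))

    allo_tris = allo_inner.triangles
    iso_tris = iso_inner.triangles
    iso_tris_kept = iso_tris[np.all(keep_iso[iso_tris], axis=1)]
    iso_tris_kept = iso_new[iso_tris_kept]
    bridge = _bridge_triangles(bridgeheads, iso_new[matches])
    triangles = np.vstack([allo_tris, iso_tris_kept, bridge])

    inner_v = np.vstack([allo_inner.vertices, iso_inner.vertices[keep_iso]])
    outer_v = np.vstack([allo_outer.vertices, iso_outer.vertices[keep_iso]])

    origin = np.concatenate([
        np.ones(n_allo, dtype=np.int8),
        -np.ones(int(keep_iso.sum()), dtype=np.int8),
    ])
    origin[bridgeheads] = 0

    subregion = np.zeros(inner_v.shape[0], dtype=np.int32)
    if subfield_field in allo_inner.scalars:
        subregion[:n_allo] = allo_inner.scalars[subfield_field]
    if region_field in iso_inner.scalars:
        subregion[n_allo:] = np.asarray(iso_inner.scalars[region_field])[keep_iso]

    scalars = {"origin": origin.astype(np.int32), "subregion": subregion}
    for name in ("ap", "gt_axis"):
        vals = []
        if name in allo_inner.scalars and name in iso_inner.scalars:
            vals = np.concatenate([
                np.asarray(allo_inner.scalars[name], dtype=float),
                np.asarray(iso_inner.scalars[name], dtype=float)[keep_iso],
            ])
            scalars[name] = vals

    inner = SurfaceMesh(inner_v, triangles, dict(scalars))
    outer = SurfaceMesh(outer_v, triangles.copy(), dict(scalars))

    _check_seam_manifold(inner, bridgeheads)

    model = ConfluenceModel(
        inner=inner,
        outer=outer,
        bridgeheads=bridgeheads.copy(),
        origin=origin,
        subregion=subregion,
        extra={"n_bridge_triangles": len(bridge), "iso_index_map": iso_new},
    )
    return model


def _check_seam_manifold(mesh: SurfaceMesh, bridgeheads: np.ndarray) -> None:
    """Validate edge-manifoldness, tolerating the designed seam double-cover.

    The bridge recipe covers each seam edge (consecutive bridgeheads) with
    up to two bridge triangles in addition to the allocortical boundary
    triangle; those edges may carry three incident triangles. Any other
    over-used edge is an error.
    """
    edges, counts = mesh_edges(mesh.triangles, return_counts=True)
    over = edges[counts > 2]
    if over.size == 0:
        return
    bh = set(int(b) for b in bridgeheads)
    offending = [e for e in over if not (int(e[0]) in bh and int(e[1]) in bh)]
    if offending:
        raise ValueError(
            f"stitched mesh is not edge-manifold along the seam; offending "
            f"edges: {[tuple(int(v) for v in e) for e in offending[:10]]}"
        )


def _surface_graph(mesh: SurfaceMesh, augment: bool = True):
    """Sparse symmetric edge-length graph of a mesh.

    With ``augment`` the edge set is extended by the 'diagonals' joining
    the two vertices opposite a shared edge of adjacent triangles, which
    reduces the metric distortion of graph geodesics.
    """
    tris = mesh.triangles
    pairs = np.vstack([tris[:, [0, 1]], tris[:, [1, 2]], tris[:, [2, 0]]])
    if augment:
        edge_opp: dict[tuple[int, int], list[int]] = {}
        for t in tris:
            for k in range(3):
                e = (int(t[k]), int(t[(k + 1) % 3]))
                e = (min(e), max(e))
                edge_opp.setdefault(e, []).append(int(t[(k + 2) % 3]))
        diag = [
            (opp[i], opp[j])
            for opp in edge_opp.values() if len(opp) >= 2
            for i in range(len(opp)) for j in range(i + 1, len(opp))
            if opp[i] != opp[j]
        ]
        if diag:
            pairs = np.vstack([pairs, np.asarray(diag, dtype=np.int64)])
    # deduplicate: repeated pairs would otherwise sum in the sparse matrix
    pairs = np.unique(np.sort(pairs, axis=1), axis=0)
    lengths = np.linalg.norm(
        mesh.vertices[pairs[:, 0]] - mesh.vertices[pairs[:, 1]], axis=1
    )
    n = mesh.n_vertices
    graph = coo_matrix(
        (np.concatenate([lengths, lengths]),
         (np.concatenate([pairs[:, 0], pairs[:, 1]]),
          np.concatenate([pairs[:, 1], pairs[:, 0]]))),
        shape=(n, n),
    ).tocsr()
    return graph


def geodesic_distances(mesh: SurfaceMesh, sources: np.ndarray,
                       augment: bool = True) -> np.ndarray:
    """Multi-source graph geodesic distance from ``sources`` to every vertex."""
    graph = _surface_graph(mesh, augment=augment)
    d = dijkstra(graph, directed=False, indices=np.asarray(sources, dtype=np.int64))
    return d.min(axis=0) if d.ndim == 2 else d


def compute_axis(model: ConfluenceModel, augment: bool = True) -> np.ndarray:
    """Signed geodesic distance to the bridgehead seam, on the inner surface.

    Negative for vertices of isocortical origin, positive for allocortical
    origin, exactly zero at bridgeheads. Stored on the model as ``axis_mm``.
    """
    n_comp, comp = connected_components(
        _surface_graph(model.inner, augment=False), directed=False
    )
    if n_comp > 1:
        main = np.bincount(comp).argmax()
        unreachable = np.flatnonzero(comp != main)
        raise ValueError(
            f"confluence mesh is disconnected; unreachable vertices: "
            f"{unreachable[:10].tolist()}{'...' if unreachable.size > 10 else ''}"
        )
    dist = geodesic_distances(model.inner, model.bridgeheads, augment=augment)
    sign = np.where(model.origin < 0, -1.0, 1.0)
    axis = sign * dist
    axis[model.bridgeheads] = 0.0
    model.axis_mm = axis
    model.inner.scalars["axis_mm"] = axis
    model.outer.scalars["axis_mm"] = axis
    return axis


def restrict_and_label(model: ConfluenceModel, ap_range: tuple[float, float],
                       atlas_labels: np.ndarray | None = None) -> ConfluenceModel:
    """Restrict the model to an anterior-posterior range.

    Vertices outside ``ap_range`` (inclusive) are dropped and triangles
    re-indexed; subregion labels (optionally overridden by
    ``atlas_labels``) are preserved.
    """
    lo, hi = ap_range
    keep = (model.ap_mm >= lo) & (model.ap_mm <= hi)
    if not np.any(keep):
        raise ValueError("ap_range excludes every vertex")
    if not np.any(keep & (model.origin > 0)) and not np.any(
        keep & (model.origin == 0)
    ):
        raise ValueError(
            "ap_range drops all hippocampal vertices; the axis would be undefined"
        )
    new_index = np.full(model.n_vertices, -1, dtype=np.int64)
    new_index[keep] = np.arange(int(keep.sum()))
    tris = model.inner.triangles
    tris = tris[np.all(keep[tris], axis=1)]
    tris = new_index[tris]

    def cut(mesh: SurfaceMesh) -> SurfaceMesh:
        return SurfaceMesh(
            mesh.vertices[keep],
            tris.copy(),
            {k: np.asarray(v)[keep] for k, v in mesh.scalars.items()},
        )

    labels = model.subregion if atlas_labels is None else np.asarray(atlas_labels)
    bridge_keep = keep[model.bridgeheads]
    return ConfluenceModel(
        inner=cut(model.inner),
        outer=cut(model.outer),
        bridgeheads=new_index[model.bridgeheads[bridge_keep]],
        origin=model.origin[keep],
        axis_mm=None if model.axis_mm is None else model.axis_mm[keep],
        subregion=None if labels is None else labels[keep],
        extra=dict(model.extra),
    )
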