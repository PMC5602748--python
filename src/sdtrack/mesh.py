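"""Triangle surface meshes and the geometric operations the trajectory
reconstruction rests on.

The cortical surface is represented as a discrete two-manifold: a grid of
triangles in 3-D space. Distances between points on the surface are geodesic
distances, computed here as shortest paths on the vertex--edge graph
(Dijkstra), which converge to the true surface metric as the mesh is refined.
Up-sampling (interpolating 4-split subdivision) exists precisely to shrink
that graph-metric error; edge-length-preserving Laplacian smoothing removes
unnaturally edgy areas from reconstructed surfaces without distorting the
intrinsic metric.

All coordinates are world millimetres; vertex indices are 0-based.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.sparse.csgraph import dijkstra as _csgraph_dijkstra

from .errors import (
    InsufficientMarginError,
    MeshValidationError,
    SmoothingDivergenceError,
)

__all__ = [
    "TriMesh",
    "GeodesicMap",
    "Patch",
    "geodesic_from",
    "shortest_path",
    "geodesic_distances",
    "extract_patch",
    "upsample_4split",
    "smooth_laplacian_edge_preserving",
    "curvature_proxy",
]


@dataclass
class TriMesh:
    """A triangulated surface: ``vertices`` (N, 3) in mm, ``faces`` (M, 3)
    0-based vertex indices, plus an optional per-vertex scalar channel used
    for heatmap export."""

    vertices: np.ndarray
    faces: np.ndarray
    scalar: np.ndarray | None = None

    _cache: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self):
        self.vertices = np.asarray(self.vertices, dtype=np.float64).reshape(-1, 3)
        self.faces = np.asarray(self.faces, dtype=np.int64).reshape(-1, 3)
        if self.scalar is not None:
            self.scalar = np.asarray(self.scalar, dtype=np.float64)

    # ------------------------------------------------------------------ sizes
    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    # ------------------------------------------------------------- topology
    @property
    def edges(self) -> np.ndarray:
        """Unique undirected edges as sorted (i, j) pairs, shape (E, 2)."""
        if "edges" not in self._cache:
            e = np.concatenate(
                [self.faces[:, [0, 1]], self.faces[:, [1, 2]], self.faces[:, [2, 0]]]
            )
            e = np.sort(e, axis=1)
            self._cache["edges"] = np.unique(e, axis=0)
        return self._cache["edges"]

    @property
    def edge_lengths(self) -> np.ndarray:
        e = self.edges
        return np.linalg.norm(self.vertices[e[:, 0]] - self.vertices[e[:, 1]], axis=1)

    @property
    def adjacency(self) -> sparse.csr_matrix:
        """Symmetric sparse matrix of edge lengths (the geodesic graph)."""
        if "adjacency" not in self._cache:
            e = self.edges
            w = self.edge_lengths
            n = self.n_vertices
            a = sparse.coo_matrix(
                (np.concatenate([w, w]),
                 (np.concatenate([e[:, 0], e[:, 1]]),
                  np.concatenate([e[:, 1], e[:, 0]]))),
                shape=(n, n),
            )
            self._cache["adjacency"] = a.tocsr()
        return self._cache["adjacency"]

    @property
    def neighbor_lists(self) -> list[np.ndarray]:
        if "neighbors" not in self._cache:
            adj = self.adjacency
            self._cache["neighbors"] = [
                adj.indices[adj.indptr[i]: adj.indptr[i + 1]]
                for i in range(self.n_vertices)
            ]
        return self._cache["neighbors"]

    @property
    def boundary_vertices(self) -> np.ndarray:
        """Boolean mask of vertices on edges shared by exactly one face."""
        if "boundary" not in self._cache:
            e = np.concatenate(
                [self.faces[:, [0, 1]], self.faces[:, [1, 2]], self.faces[:, [2, 0]]]
            )
            e = np.sort(e, axis=1)
            uniq, counts = np.unique(e, axis=0, return_counts=True)
            mask = np.zeros(self.n_vertices, dtype=bool)
            border = uniq[counts == 1]
            mask[border.ravel()] = True
            self._cache["boundary"] = mask
        return self._cache["boundary"]

    def invalidate(self):
        self._cache.clear()

    # ------------------------------------------------------------- geometry
    def face_areas(self) -> np.ndarray:
        v = self.vertices
        a, b, c = v[self.faces[:, 0]], v[self.faces[:, 1]], v[self.faces[:, 2]]
        return 0.5 * np.linalg.norm(np.cross(b - a, c - a), axis=1)

    def area(self) -> float:
        return float(self.face_areas().sum())

    def mean_edge_length(self) -> float:
        return float(self.edge_lengths.mean())

    # ------------------------------------------------------------- validity
    def validate(self) -> None:
        """Raise :class:`MeshValidationError` on any structural defect."""
        if self.n_vertices == 0 or self.n_faces == 0:
            raise MeshValidationError("empty mesh")
        if self.faces.min() < 0 or self.faces.max() >= self.n_vertices:
            bad = np.where(
                (self.faces < 0).any(axis=1)
                | (self.faces >= self.n_vertices).any(axis=1)
            )[0][0]
            raise MeshValidationError(
                f"face {bad} references vertex out of range: {self.faces[bad].tolist()}"
            )
        if (self.edge_lengths <= 0).any():
            raise MeshValidationError("zero-length edge present")
        # edge-manifold: each undirected edge in at most 2 faces
        e = np.concatenate(
            [self.faces[:, [0, 1]], self.faces[:, [1, 2]], self.faces[:, [2, 0]]]
        )
        e = np.sort(e, axis=1)
        _, counts = np.unique(e, axis=0, return_counts=True)
        if (counts > 2).any():
            raise MeshValidationError("non-manifold edge (shared by >2 faces)")
        # consistent orientation: a directed half-edge appears at most once
        he = np.concatenate(
            [self.faces[:, [0, 1]], self.faces[:, [1, 2]], self.faces[:, [2, 0]]]
        )
        _, hc = np.unique(he, axis=0, return_counts=True)
        if (hc > 1).any():
            raise MeshValidationError("inconsistent face orientation")

    def copy(self) -> "TriMesh":
        return TriMesh(
            self.vertices.copy(),
            self.faces.copy(),
            None if self.scalar is None else self.scalar.copy(),
        )


@dataclass
class GeodesicMap:
    """Single-source geodesic distances on the edge graph.

    ``dist[v]`` is the shortest-path length (mm) from ``source`` to ``v``
    (``inf`` if unreachable); ``pred[v]`` is the predecessor on the canonical
    shortest path (−1 at the source and at unreachable vertices). Ties are
    broken toward the smallest predecessor id, so paths are deterministic.
    """

    source: int
    dist: np.ndarray
    pred: np.ndarray

    def reachable(self, v: int) -> bool:
        return np.isfinite(self.dist[v])


def geodesic_from(mesh: TriMesh, source: int) -> GeodesicMap:
    """Dijkstra from ``source`` with smallest-predecessor-id tie-breaking."""
    n = mesh.n_vertices
    if not (0 <= source < n):
        raise IndexError(f"source vertex {source} out of range (0..{n - 1})")
    adj = mesh.adjacency
    indptr, indices, data = adj.indptr, adj.indices, adj.data
    dist = np.full(n, np.inf)
    pred = np.full(n, -1, dtype=np.int64)
    dist[source] = 0.0
    done = np.zeros(n, dtype=bool)
    heap = [(0.0, source)]
    while heap:
        d, u = heapq.heappop(heap)
        if done[u]:
            continue
        done[u] = True
        for k in range(indptr[u], indptr[u + 1]):
            v = indices[k]
            if done[v]:
                continue
            nd = d + data[k]
            if nd < dist[v]:
                dist[v] = nd
                pred[v] = u
                heapq.heappush(heap, (nd, v))
            elif nd == dist[v] and u < pred[v]:
                pred[v] = u
    return GeodesicMap(source=source, dist=dist, pred=pred)


def shortest_path(gmap: GeodesicMap, target: int) -> list[int]:
    """Canonical shortest path source→target as a vertex-id list."""
    if not np.isfinite(gmap.dist[target]):
        raise ValueError(f"target vertex {target} unreachable from {gmap.source}")
    path = [int(target)]
    v = int(target)
    while v != gmap.source:
        v = int(gmap.pred[v])
        if v < 0:
            raise ValueError("broken predecessor chain")
        path.append(v)
    path.reverse()
    return path


def geodesic_distances(
    mesh: TriMesh, sources, limit: float = np.inf
) -> np.ndarray:
    """Bulk geodesic distances from several sources (rows) to all vertices.

    Same edge-graph metric as :func:`geodesic_from`, delegated to scipy's
    compiled Dijkstra; no predecessor information.
    """
    sources = np.atleast_1d(np.asarray(sources, dtype=np.int64))
    return _csgraph_dijkstra(
        mesh.adjacency, directed=False, indices=sources, limit=limit
    )


# ---------------------------------------------------------------------------
# Patch extraction
# ---------------------------------------------------------------------------

@dataclass
class Patch:
    """Sub-mesh cut around an electrode strip.

    ``electrodes`` maps electrode label → patch vertex id; ``parent_vertices``
    maps patch vertex id → parent vertex id; ``boundary`` flags patch vertices
    on the cut boundary. Every electrode is at geodesic distance >
    ``radius`` from every boundary vertex, so candidate disks never feel the
    cut.
    """

    mesh: TriMesh
    parent_vertices: np.ndarray
    electrodes: dict[str, int]
    boundary: np.ndarray
    radius: float

    @property
    def electrode_vertices(self) -> list[int]:
        return list(self.electrodes.values())


def extract_patch(mesh: TriMesh, electrodes, radius: float = 30.0) -> Patch:
    """Cut the union of geodesic disks of ``radius`` mm around each electrode.

    ``electrodes`` is a mapping label → parent vertex id, or a sequence of
    parent vertex ids (labelled E1..En in the given order). The patch keeps
    one extra vertex ring beyond the radius so that every boundary vertex is
    strictly farther than ``radius`` from every electrode.
    """
    if not isinstance(electrodes, dict):
        electrodes = {f"E{i + 1}": int(v) for i, v in enumerate(electrodes)}
    evs = np.array(list(electrodes.values()), dtype=np.int64)
    if (evs < 0).any() or (evs >= mesh.n_vertices).any():
        raise IndexError("electrode vertex out of range")

    dist = geodesic_distances(mesh, evs)          # (n_elec, N)
    dmin = dist.min(axis=0)
    core = dmin <= radius

    parent_boundary = mesh.boundary_vertices
    if (core & parent_boundary).any():
        raise InsufficientMarginError(
            "insufficient margin: an electrode lies within "
            f"{radius} mm of the parent mesh boundary"
        )

    # dilate by one ring so boundary vertices of the patch are beyond radius
    keep = core.copy()
    adj = mesh.adjacency
    reach = adj[core].indices
    keep[reach] = True

    face_keep = keep[mesh.faces].all(axis=1)
    faces = mesh.faces[face_keep]
    used = np.unique(faces)
    remap = -np.ones(mesh.n_vertices, dtype=np.int64)
    remap[used] = np.arange(len(used))
    sub = TriMesh(mesh.vertices[used], remap[faces])
    patch_electrodes = {lab: int(remap[v]) for lab, v in electrodes.items()}
    return Patch(
        mesh=sub,
        parent_vertices=used,
        electrodes=patch_electrodes,
        boundary=sub.boundary_vertices.copy(),
        radius=float(radius),
    )


# ---------------------------------------------------------------------------
# Interpolating 4-split subdivision
# ---------------------------------------------------------------------------

def _edge_face_maps(mesh: TriMesh):
    """Per-edge adjacent face list and per-(edge, face) opposite vertex."""
    edge_index: dict[tuple[int, int], int] = {}
    edges = mesh.edges
    for i, (a, b) in enumerate(edges):
        edge_index[(int(a), int(b))] = i
    opposite: list[list[int]] = [[] for _ in range(len(edges))]
    for f in mesh.faces:
        fi = [int(x) for x in f]
        for k in range(3):
            a, b = fi[k], fi[(k + 1) % 3]
            c = fi[(k + 2) % 3]
            ei = edge_index[(min(a, b), max(a, b))]
            opposite[ei].append(c)
    return edge_index, opposite


def _butterfly_point(mesh, edge_index, opposite, u, v, valence):
    """Classic 8-point butterfly stencil for a regular interior edge; returns
    None when the stencil is unavailable (irregular or boundary wing)."""
    ei = edge_index[(min(u, v), max(u, v))]
    opp = opposite[ei]
    if len(opp) != 2 or valence[u] != 6 or valence[v] != 6:
        return None
    w1, w2 = opp
    wings = []
    for w in (w1, w2):
        for e in ((u, w), (v, w)):
            ej = edge_index.get((min(e), max(e)))
            if ej is None:
                return None
            others = [c for c in opposite[ej] if c not in (u, v, w1, w2)]
            if len(others) != 1:
                return None
            wings.append(others[0])
    V = mesh.vertices
    return (
        0.5 * (V[u] + V[v])
        + 0.125 * (V[w1] + V[w2])
        - 0.0625 * (V[wings[0]] + V[wings[1]] + V[wings[2]] + V[wings[3]])
    )


def upsample_4split(
    mesh: TriMesh, iterations: int = 1, scheme: str = "butterfly"
) -> TriMesh:
    """Interpolating 4-split subdivision: each triangle → 4, one new vertex
    per edge, original vertices unmoved.

    ``scheme="butterfly"`` places new vertices by the interpolating butterfly
    spline stencil where the edge is regular (both endpoints valence 6,
    full wing available), falling back to the plain edge midpoint elsewhere;
    ``scheme="midpoint"`` always uses midpoints. Both schemes reproduce
    planar input exactly. Counts obey V' = V + E and F' = 4F.
    """
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    if scheme not in ("butterfly", "midpoint"):
        raise ValueError(f"unknown scheme {scheme!r}")
    out = mesh
    for _ in range(iterations):
        out.validate()
        edges = out.edges
        edge_index, opposite = _edge_face_maps(out)
        valence = np.zeros(out.n_vertices, dtype=np.int64)
        for a, b in edges:
            valence[a] += 1
            valence[b] += 1

        new_pts = 0.5 * (out.vertices[edges[:, 0]] + out.vertices[edges[:, 1]])
        if scheme == "butterfly":
            boundary = out.boundary_vertices
            for i, (a, b) in enumerate(edges):
                a, b = int(a), int(b)
                if boundary[a] or boundary[b]:
                    continue
                p = _butterfly_point(out, edge_index, opposite, a, b, valence)
                if p is not None:
                    new_pts[i] = p

        nv = out.n_vertices
        verts = np.vstack([out.vertices, new_pts])
        mid = {
            (int(a), int(b)): nv + i for i, (a, b) in enumerate(edges)
        }

        faces = np.empty((4 * out.n_faces, 3), dtype=np.int64)
        for fi, (i, j, k) in enumerate(out.faces):
            i, j, k = int(i), int(j), int(k)
            mij = mid[(min(i, j), max(i, j))]
            mjk = mid[(min(j, k), max(j, k))]
            mki = mid[(min(k, i), max(k, i))]
            faces[4 * fi + 0] = (i, mij, mki)
            faces[4 * fi + 1] = (j, mjk, mij)
            faces[4 * fi + 2] = (k, mki, mjk)
            faces[4 * fi + 3] = (mij, mjk, mki)
        out = TriMesh(verts, faces)
    return out


# ---------------------------------------------------------------------------
# Edge-length-preserving Laplacian smoothing
# ---------------------------------------------------------------------------

def curvature_proxy(mesh: TriMesh) -> np.ndarray:
    """Magnitude of the umbrella (uniform Laplacian) displacement per interior
    vertex — a discrete mean-curvature proxy used to monitor smoothing."""
    nbrs = mesh.neighbor_lists
    boundary = mesh.boundary_vertices
    out = np.zeros(mesh.n_vertices)
    V = mesh.vertices
    for i in range(mesh.n_vertices):
        if boundary[i] or len(nbrs[i]) == 0:
            continue
        out[i] = np.linalg.norm(V[nbrs[i]].mean(axis=0) - V[i])
    return out[~boundary]


def smooth_laplacian_edge_preserving(
    mesh: TriMesh,
    iterations: int = 10,
    step: float = 0.5,
    restore_passes: int = 50,
    restore_tol: float = 0.0025,
) -> TriMesh:
    """Laplacian smoothing that retains the original edge lengths.

    Each iteration applies an umbrella Laplacian displacement scaled by
    ``step`` to interior vertices (boundary fixed), then iterates a local
    projection pulling every edge back toward its original length (at most
    ``restore_passes`` sweeps, stopping once the mean relative edge-length
    error drops below ``restore_tol``), so that the smoothing changes angles
    (global curvature) but not the intrinsic metric. Aborts if any edge ever
    drifts more than 10 % from its original length.
    """
    if not (0.0 < step <= 1.0):
        raise ValueError("step must be positive and <= 1")
    edges = mesh.edges
    L0 = mesh.edge_lengths
    boundary = mesh.boundary_vertices
    interior = ~boundary
    V = mesh.vertices.copy()
    n = mesh.n_vertices

    # uniform umbrella operator as a sparse matrix
    adj = (mesh.adjacency > 0).astype(np.float64)
    deg = np.asarray(adj.sum(axis=1)).ravel()
    deg[deg == 0] = 1.0

    i_idx, j_idx = edges[:, 0], edges[:, 1]
    movable_i = interior[i_idx].astype(float)
    movable_j = interior[j_idx].astype(float)

    for _ in range(iterations):
        mean_nbr = adj.dot(V) / deg[:, None]
        disp = mean_nbr - V
        V[interior] += step * disp[interior]

        for _ in range(restore_passes):
            d = V[j_idx] - V[i_idx]
            L = np.linalg.norm(d, axis=1)
            L[L == 0] = 1e-12
            if np.abs((L - L0) / L0).mean() < restore_tol:
                break
            err = (L - L0) / L            # fraction of current length to remove
            w = movable_i + movable_j
            w[w == 0] = 1.0
            corr = (err / w)[:, None] * d
            upd = np.zeros_like(V)
            np.add.at(upd, i_idx, corr * movable_i[:, None])
            np.add.at(upd, j_idx, -corr * movable_j[:, None])
            cnt = np.zeros(n)
            np.add.at(cnt, i_idx, movable_i)
            np.add.at(cnt, j_idx, movable_j)
            cnt[cnt == 0] = 1.0
            V += upd / cnt[:, None]

        L = np.linalg.norm(V[j_idx] - V[i_idx], axis=1)
        rel = np.abs(L - L0) / L0
        if rel.max() > 0.10:
            raise SmoothingDivergenceError(
                f"edge length drifted {rel.max():.1%} (> 10%); "
                "reduce step or restore more aggressively"
            )

    return TriMesh(V, mesh.faces.copy(),
                   None if mesh.scalar is None else mesh.scalar.copy())
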